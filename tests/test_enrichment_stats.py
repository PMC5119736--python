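"""Overlap counting, fold enrichment, empirical p, replicate aggregation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dhsenrich.enrichment_stats import (
    aggregate_tissue,
    bh_adjust,
    count_overlaps,
    enrichment,
    null_count_distribution,
    significant_pairs,
)
from dhsenrich.io_formats import DhsTrack, SnpPool
from dhsenrich.locus_model import Locus, LocusSet
from dhsenrich.null_matching import compute_pool_covariates, sample_null_sets


def _locus_set(intervals, window=500_000, study="S"):
    from dhsenrich.io_formats import TagSnp

    loci = [
        Locus(
            chrom, start, end,
            [TagSnp(rsid=f"m{i}", chromosome=chrom, position=(start + end) // 2,
                    pvalue=1e-9, maf=0.2)],
        )
        for i, (chrom, start, end) in enumerate(intervals)
    ]
    return LocusSet(study_id=study, window_size=window, loci=loci)


class TestCountOverlaps:
    def test_one_base_overlap_counts(self):
        track = DhsTrack("t", [("chr1", 100, 200)])
        assert count_overlaps(_locus_set([("chr1", 150, 500_150)]), track) == 1

    def test_half_open_abutment_is_no_overlap(self):
        track = DhsTrack("t", [("chr1", 100, 200)])
        assert count_overlaps(_locus_set([("chr1", 200, 500_200)]), track) == 0

    def test_peak_spanning_two_loci_counts_twice(self):
        track = DhsTrack("t", [("chr1", 990, 1_010)])
        ls = _locus_set([("chr1", 0, 1_000), ("chr1", 1_000, 2_000)])
        assert count_overlaps(ls, track) == 2

    def test_matches_pairwise_scan(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            starts = rng.integers(0, 1_000_000, 200)
            peaks = [
                ("chr1", int(s), int(s + rng.integers(50, 2_000)))
                for s in starts
            ]
            track = DhsTrack("t", peaks)
            loci = []
            for _ in range(5):
                s = int(rng.integers(0, 900_000))
                loci.append(("chr1", s, s + int(rng.integers(1_000, 100_000))))
            ls = _locus_set(loci)
            brute = sum(
                1
                for (_, ls_, le) in loci
                for (_, ps, pe) in peaks
                if ps < le and pe > ls_
            )
            assert count_overlaps(ls, track) == brute


@pytest.fixture
def sampled_nulls(annotation, make_snp):
    rng = np.random.default_rng(23)
    n = 1_000
    chroms = np.where(rng.random(n) < 0.67, "chr1", "chr2")
    lengths = np.array([annotation.chromosomes[c] for c in chroms])
    pool = SnpPool(
        rsids=np.array([f"rs{i}" for i in range(n)]),
        chroms=chroms,
        positions=rng.integers(0, lengths),
        mafs=rng.uniform(0.05, 0.45, n),
    )
    compute_pool_covariates(pool, annotation, 100_000)
    tags = [
        make_snp(rsid=f"tag{i}", chrom=str(pool.chroms[i]),
                 pos=int(pool.positions[i]), maf=float(pool.mafs[i]))
        for i in (5, 300, 700)
    ]
    from dhsenrich.locus_model import build_loci

    loci = build_loci(tags, 100_000, annotation)
    nulls = sample_null_sets(loci, pool, annotation, n_sets=50, seed=6)
    return loci, nulls


class TestNullCountDistribution:
    def test_empty_track_gives_zeros(self, sampled_nulls):
        _, nulls = sampled_nulls
        track = DhsTrack("t", [])
        assert (null_count_distribution(nulls, track) == 0).all()

    def test_each_set_matches_standalone_count(self, sampled_nulls, annotation):
        loci, nulls = sampled_nulls
        rng = np.random.default_rng(29)
        peaks = []
        for chrom, length in annotation.chromosomes.items():
            for s in rng.integers(0, length - 2_000, 300):
                peaks.append((chrom, int(s), int(s) + int(rng.integers(50, 2_000))))
        track = DhsTrack("t", peaks)
        counts = null_count_distribution(nulls, track)
        for j in (0, 7, 49):
            standalone = _locus_set(
                [(c, s, e) for c, s, e, _ in nulls.null_set(j)], window=100_000
            )
            assert counts[j] == count_overlaps(standalone, track)

    def test_identical_sets_identical_counts(self):
        # a degenerate collection where every set is the same null locus
        from dhsenrich.null_matching import NullLocusDraws, NullSetCollection

        draws = NullLocusDraws(
            chrom_codes=np.zeros(10, dtype=np.int64),
            starts=np.full(10, 100),
            ends=np.full(10, 10_000),
            pool_indices=np.zeros(10, dtype=np.int64),
        )
        pool = SnpPool(
            rsids=np.array(["rs1"]), chroms=np.array(["chr1"]),
            positions=np.array([5_000], dtype=np.int64),
            mafs=np.array([0.1]),
        )
        nsc = NullSetCollection(
            study_id="S", n_sets=10, seed=0, chrom_order=["chr1"],
            loci=[draws], pool=pool,
        )
        track = DhsTrack("t", [("chr1", 500, 600), ("chr1", 20_000, 20_100)])
        counts = null_count_distribution(nsc, track)
        assert (counts == counts[0]).all() and counts[0] == 1


class TestEnrichment:
    def test_closed_form(self):
        res = enrichment(30, np.full(1_000, 20))
        assert res.fold_enrichment == pytest.approx(1.5)
        assert res.p_empirical == 1 / 1_000
        assert res.null_sd == 0.0

    def test_observed_at_null_median(self):
        rng = np.random.default_rng(31)
        nulls = rng.poisson(100, 10_000)
        obs = int(np.median(nulls))
        res = enrichment(obs, nulls)
        k = int((nulls >= obs).sum())
        assert res.p_empirical == k / 10_000
        assert 0.4 < res.p_empirical < 0.65
        assert res.fold_enrichment == pytest.approx(1.0, abs=0.05)

    def test_floor_when_observed_beats_every_null(self):
        res = enrichment(1_000, np.full(50_000, 20))
        assert res.p_empirical == 2e-5  # exactly 1/50,000

    def test_monotone_in_observed(self):
        rng = np.random.default_rng(37)
        nulls = rng.poisson(50, 2_000)
        folds, ps = [], []
        for obs in range(30, 80, 5):
            r = enrichment(obs, nulls)
            folds.append(r.fold_enrichment)
            ps.append(r.p_empirical)
        assert all(a < b for a, b in zip(folds, folds[1:]))
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_zero_null_mean_with_signal(self):
        res = enrichment(5, np.zeros(100, dtype=int))
        assert not res.fold_defined
        assert res.p_empirical == 1 / 100

    def test_zero_null_mean_without_signal(self):
        res = enrichment(0, np.zeros(100, dtype=int))
        assert not res.fold_defined
        assert res.p_empirical == 1.0

    def test_population_sd(self):
        nulls = np.array([1, 3])
        assert enrichment(2, nulls).null_sd == 1.0  # ddof=0


def _res(fold, p, study="S", sample="x"):
    nulls = np.array([10.0])
    r = enrichment(10, np.full(10, 10), study_id=study, sample_id=sample)
    r.fold_enrichment = fold
    r.p_empirical = p
    return r


class TestAggregateTissue:
    def test_mean_of_replicates(self):
        summary = aggregate_tissue(
            "S", "kidney", [_res(1.5, 0.03), _res(1.6, 0.2), _res(1.4, 0.1)]
        )
        assert summary.afe == pytest.approx(1.5)
        assert summary.summary_p == 0.03
        assert summary.n_replicates == 3

    def test_single_replicate(self):
        s = aggregate_tissue("S", "kidney", [_res(1.2, 0.5)])
        assert (s.afe, s.afe_sd) == (1.2, 0.0)

    def test_undefined_fold_excluded_with_warning(self):
        results = [_res(1.5, 0.03), _res(float("nan"), 0.2)]
        with pytest.warns(UserWarning, match="undefined fold"):
            s = aggregate_tissue("S", "kidney", results)
        assert s.afe == 1.5
        assert s.n_replicates == 2

    def test_sample_sd_across_replicates(self):
        s = aggregate_tissue("S", "t", [_res(1.0, 0.5), _res(2.0, 0.5)])
        assert s.afe_sd == pytest.approx(np.std([1.0, 2.0], ddof=1))


class TestSignificantPairs:
    def test_count_below_alpha(self):
        results = [_res(1.0, 0.01, sample=f"a{i}") for i in range(4)]
        results += [_res(1.0, 0.5, sample=f"b{i}") for i in range(6)]
        assert significant_pairs(results, alpha=0.05) == 4
        assert significant_pairs(results, alpha=0.0) == 0

    @given(
        st.lists(st.floats(1e-6, 1.0, allow_nan=False), min_size=2, max_size=30)
    )
    def test_bh_is_monotone_in_raw_p(self, ps):
        adjusted = bh_adjust(ps)
        order = np.argsort(ps)
        assert (np.diff(adjusted[order]) >= -1e-12).all()
        assert (adjusted >= np.asarray(ps) - 1e-12).all()
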