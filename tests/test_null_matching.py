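"""Matching covariates and null-set sampling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dhsenrich.io_formats import GenomeAnnotation, PoolSnp, SnpPool
from dhsenrich.locus_model import build_loci
from dhsenrich.null_matching import (
    DISTANCE_BIN_EDGES,
    DISTANCE_BIN_LABELS,
    N_DISTANCE_BINS,
    MatchingError,
    assign_distance_bin,
    assign_distance_bins,
    candidate_indices,
    candidate_pool,
    compute_pool_covariates,
    sample_null_sets,
    signed_tss_distance,
    tag_covariates,
    tss_count,
    tss_count_category,
)


class TestSignedTssDistance:
    def test_upstream_of_plus_strand_gene(self, annotation):
        # geneA TSS at 100,000 on +; 7 kb toward smaller coordinates is 5'
        assert signed_tss_distance(93_000, "chr1", annotation) == -7_000

    def test_upstream_of_minus_strand_gene(self, annotation):
        # geneD TSS at 50,000 on -; 5' of a minus-strand gene is the
        # larger coordinate side
        assert signed_tss_distance(57_000, "chr2", annotation) == -7_000

    def test_downstream_of_plus_strand_gene(self, annotation):
        assert signed_tss_distance(107_000, "chr1", annotation) == 7_000

    def test_zero_at_tss(self, annotation):
        assert signed_tss_distance(100_000, "chr1", annotation) == 0

    def test_chromosome_without_tss_rejected(self):
        ann = GenomeAnnotation(
            chromosomes={"chr1": 1_000, "chr2": 1_000},
            tss_sites=[("chr1", 10, "+", "g")],
        )
        with pytest.raises(MatchingError, match="chr2"):
            signed_tss_distance(5, "chr2", ann)

    def test_matches_exhaustive_scan(self, random_annotation):
        rng = np.random.default_rng(7)
        tss = [
            (c, p, s) for c, p, s, _ in random_annotation.tss_sites
        ]
        for _ in range(300):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            pos = int(rng.integers(0, random_annotation.chromosomes[chrom]))
            got = signed_tss_distance(pos, chrom, random_annotation)
            same = [(p, s) for c, p, s in tss if c == chrom]
            best = min(same, key=lambda t: (abs(pos - t[0]), t[0]))
            expected = (pos - best[0]) * (1 if best[1] == "+" else -1)
            assert got == expected


class TestDistanceBins:
    @pytest.mark.parametrize(
        "distance, label",
        [
            (-7_000, "(-10000,-5000]"),
            (0, "(-5000,0]"),
            (300_000, "(200000,inf)"),
            (-200_000, "(-inf,-200000]"),
            (-200_001, "(-inf,-200000]"),
            (5_000, "(0,5000]"),
            (5_001, "(5000,10000]"),
            (200_000, "(100000,200000]"),
        ],
    )
    def test_boundary_assignment(self, distance, label):
        assert DISTANCE_BIN_LABELS[assign_distance_bin(distance)] == label

    @given(st.integers(-10**9, 10**9))
    def test_bins_partition_the_line(self, d):
        b = assign_distance_bin(d)
        assert 0 <= b < N_DISTANCE_BINS
        # right-closed: distances at an edge belong to the bin ending there
        lo = -np.inf if b == 0 else DISTANCE_BIN_EDGES[b - 1]
        hi = np.inf if b == N_DISTANCE_BINS - 1 else DISTANCE_BIN_EDGES[b]
        assert lo < d <= hi or (b == N_DISTANCE_BINS - 1 and d > lo)


class TestTssCountCategory:
    @pytest.mark.parametrize(
        "count, cat",
        [(0, "LOW"), (9, "LOW"), (10, "MID"), (24, "MID"), (25, "HIGH"),
         (1000, "HIGH")],
    )
    def test_boundaries(self, count, cat):
        assert tss_count_category(count) == cat

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            tss_count_category(-1)

    def test_tss_count_window(self, annotation):
        # chr1 TSS at 100k, 500k, 1500k; ±250 kb of 300k covers 100k & 500k
        assert tss_count(300_000, "chr1", annotation, 500_000) == 2


def _manual_pool():
    """A tiny pool with hand-set covariates for predicate tests."""
    return SnpPool(
        rsids=np.array(["p1", "p2", "p3", "p4", "p5"]),
        chroms=np.array(["chr1"] * 5),
        positions=np.arange(5, dtype=np.int64) * 1_000,
        mafs=np.array([0.16, 0.18, 0.12, 0.16, 0.16]),
        signed_tss_distances=np.zeros(5, dtype=np.int64),
        distance_bins=np.array([5, 5, 5, 6, 5]),
        tss_counts=np.array([3, 3, 3, 3, 12]),
        tss_count_categories=np.array([0, 0, 0, 0, 1], dtype=np.int8),
    )


def _tag(maf=0.12, bin_=5, cat="LOW", rsid="tag"):
    return PoolSnp(
        rsid=rsid, chromosome="chr1", position=0, maf=maf,
        signed_tss_distance=0, distance_bin=bin_, tss_count=3,
        tss_count_category=cat,
    )


class TestCandidatePool:
    def test_maf_within_halfwidth_included(self):
        idx = candidate_indices(_tag(maf=0.12), _manual_pool())
        # p1 (0.16, same bin/cat) in; p2 (0.18) out by MAF; p4 out by bin;
        # p5 out by category; p3 (0.12) in
        assert sorted(idx) == [0, 2]

    def test_self_excluded_by_rsid(self):
        idx = candidate_indices(_tag(maf=0.12, rsid="p3"), _manual_pool())
        assert sorted(idx) == [0]

    def test_empty_candidates_is_an_error(self):
        with pytest.raises(MatchingError, match="tagX"):
            candidate_indices(_tag(maf=0.45, rsid="tagX"), _manual_pool())

    def test_matches_linear_scan(self, random_annotation):
        rng = np.random.default_rng(11)
        n = 400
        chroms = np.where(rng.random(n) < 0.5, "chr1", "chr2")
        lengths = np.array(
            [random_annotation.chromosomes[c] for c in chroms]
        )
        pool = SnpPool(
            rsids=np.array([f"rs{i}" for i in range(n)]),
            chroms=chroms,
            positions=rng.integers(0, lengths),
            mafs=rng.uniform(0, 0.5, n),
        )
        compute_pool_covariates(pool, random_annotation, 100_000)
        for t in range(20):
            tag = pool.snp(int(rng.integers(0, n)))
            got = set(candidate_indices(tag, pool))
            expected = {
                i
                for i in range(n)
                if abs(pool.snp(i).maf - tag.maf) <= 0.05
                and pool.snp(i).distance_bin == tag.distance_bin
                and pool.snp(i).tss_count_category == tag.tss_count_category
                and pool.snp(i).rsid != tag.rsid
            }
            assert got == expected

    def test_candidate_pool_returns_records(self):
        records = candidate_pool(_tag(maf=0.12), _manual_pool())
        assert all(isinstance(r, PoolSnp) for r in records)
        assert {r.rsid for r in records} == {"p1", "p3"}


@pytest.fixture
def matched_setup(random_annotation, make_snp):
    rng = np.random.default_rng(5)
    n = 2_000
    chroms = np.where(rng.random(n) < 0.67, "chr1", "chr2")
    lengths = np.array([random_annotation.chromosomes[c] for c in chroms])
    pool = SnpPool(
        rsids=np.array([f"rs{i}" for i in range(n)]),
        chroms=chroms,
        positions=rng.integers(0, lengths),
        mafs=rng.uniform(0.05, 0.45, n),
    )
    compute_pool_covariates(pool, random_annotation, 100_000)
    tags = [
        make_snp(rsid=f"tag{i}", chrom=str(pool.chroms[i]),
                 pos=int(pool.positions[i]), maf=float(pool.mafs[i]))
        for i in rng.choice(n, 3, replace=False)
    ]
    loci = build_loci(tags, 100_000, random_annotation)
    return loci, pool, random_annotation


class TestSampleNullSets:
    def test_shapes_and_contract(self, matched_setup):
        loci, pool, ann = matched_setup
        nulls = sample_null_sets(loci, pool, ann, n_sets=10, seed=1)
        assert nulls.n_sets == 10
        assert len(nulls.loci) == len(loci)
        assert all(len(ld.starts) == 10 for ld in nulls.loci)
        assert len(nulls.null_set(0)) == len(loci)

    def test_same_seed_is_identical(self, matched_setup):
        loci, pool, ann = matched_setup
        a = sample_null_sets(loci, pool, ann, n_sets=25, seed=9)
        b = sample_null_sets(loci, pool, ann, n_sets=25, seed=9)
        for la, lb in zip(a.loci, b.loci):
            assert np.array_equal(la.pool_indices, lb.pool_indices)
            assert np.array_equal(la.starts, lb.starts)

    def test_every_draw_satisfies_matching(self, matched_setup):
        loci, pool, ann = matched_setup
        nulls = sample_null_sets(loci, pool, ann, n_sets=200, seed=3)
        for locus, draws in zip(loci.loci, nulls.loci):
            tag = tag_covariates(locus.member_snps[0], ann, loci.window_size)
            allowed = set(candidate_indices(tag, pool))
            assert set(np.unique(draws.pool_indices)) <= allowed

    def test_null_window_copies_observed_span(self, matched_setup):
        loci, pool, ann = matched_setup
        nulls = sample_null_sets(loci, pool, ann, n_sets=50, seed=2)
        for locus, draws in zip(loci.loci, nulls.loci):
            spans = draws.ends - draws.starts
            assert (spans <= locus.span).all()
            # unclipped draws have exactly the observed span
            interior = (draws.starts > 0) & (
                draws.ends
                < np.array([ann.chromosomes[nulls.chrom_order[c]]
                            for c in draws.chrom_codes])
            )
            assert (spans[interior] == locus.span).all()

    def test_single_candidate_degenerates(self, annotation, make_snp):
        # both SNPs sit ~100-110 kb upstream of geneB: same distance bin,
        # same (LOW) gene-density category, equal MAF -> "only" is the
        # sole candidate for "tagsnp"
        pool = SnpPool(
            rsids=np.array(["only", "tagsnp"]),
            chroms=np.array(["chr1", "chr1"]),
            positions=np.array([600_000, 610_000], dtype=np.int64),
            mafs=np.array([0.2, 0.2]),
        )
        compute_pool_covariates(pool, annotation, 100_000)
        tag = make_snp(rsid="tagsnp", pos=610_000, maf=0.2)
        loci = build_loci([tag], 100_000, annotation)
        nulls = sample_null_sets(loci, pool, annotation, n_sets=20, seed=4)
        assert (nulls.loci[0].pool_indices == 0).all()
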