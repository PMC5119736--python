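"""Synthetic genomes, SNP pools, GWAS hit lists and DHS tracks with
planted, known statistical structure.

The generator emulates the shape of the real inputs at desk scale: a
small multi-chromosome genome with stranded TSS, a genotyping-chip-like
background SNP pool with Beta-distributed folded MAFs, GWAS lead SNPs
drawn from that pool (so matched candidates always exist), and DHS peak
tracks whose peak density inside the designated trait loci is a
controllable factor ``f`` times the background density.  ``f = 1`` is the
uniform null; the full pipeline should recover ``f`` as its fold
enrichment.

Every generator is a pure function of (config, seed); each one uses its
own derived stream so that, e.g., regenerating the pool does not perturb
the peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import DhsTrack, GenomeAnnotation, GwasStudy, SnpPool, TagSnp
from .locus_model import LocusSet, build_loci
from .null_matching import compute_pool_covariates

__all__ = [
    "SimConfig",
    "make_genome",
    "make_snp_pool",
    "make_gwas",
    "make_dhs_track",
    "make_replicates",
    "make_fixture",
    "SyntheticFixture",
]

_CODING_TERMS = (
    "missense_variant",
    "splice_region_variant",
    "frameshift_variant",
    "stop_gained",
    "stop_lost",
    "feature_elongation",
    "splice_donor_variant",
)
_NONCODING_TERMS = ("intron_variant", "intergenic_variant", "", "3_prime_UTR_variant")

# per-generator stream keys, mixed with the config seed
_STREAM_GENOME = 11
_STREAM_POOL = 12
_STREAM_GWAS = 13
_STREAM_TRACK = 14
_STREAM_REPLICATES = 15


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic fixture (desk scale).

    The default genome is 1/300 the size of the human genome (2 × 10 Mb);
    peak number and length keep a comparable per-track genome coverage.
    The locus window is scaled to 50 kb so that the 20 planted trait loci
    occupy ~5% of the genome — at the paper-scale 500 kb window they would
    cover half of a 20 Mb genome, a geometry the real analysis never
    approaches and in which the planted factor is not identifiable.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 10_000_000
    n_genes: int = 300
    pool_size: int = 20_000
    maf_beta_a: float = 1.2
    maf_beta_b: float = 3.0
    n_trait_loci: int = 20
    window_size: int = 50_000
    peaks_per_track: int = 2_000
    peak_length_median: float = 250.0
    peak_length_sigma: float = 0.5
    peak_length_min: int = 50
    peak_length_max: int = 2_000
    enrichment_factor: float = 1.0
    n_replicates: int = 3
    replicate_jitter: int = 100
    replicate_drop_fraction: float = 0.05
    coding_fraction: float = 0.1
    replication_probability: float = 0.7

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes",
            "chromosome_length",
            "pool_size",
            "n_trait_loci",
            "window_size",
            "peaks_per_track",
            "n_replicates",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.enrichment_factor < 0:
            raise ValueError("enrichment_factor must be >= 0")
        if self.replicate_jitter < 0:
            raise ValueError("replicate_jitter must be >= 0")
        if not (0.0 <= self.replicate_drop_fraction < 1.0):
            raise ValueError("replicate_drop_fraction must be in [0, 1)")


def _rng(config: SimConfig, stream: int, seed: int | None) -> np.random.Generator:
    if seed is not None:
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def make_genome(config: SimConfig, seed: int | None = None) -> GenomeAnnotation:
    """Equal-length chromosomes with uniformly placed, randomly stranded TSS.

    Every chromosome receives at least one TSS (the TSS-distance covariate
    is undefined on a TSS-free chromosome); the remainder are allocated
    uniformly across the genome.
    """
    if config.n_genes <= 0:
        raise ValueError("n_genes must be positive (matching undefined without TSS)")
    if config.n_genes < config.n_chromosomes:
        raise ValueError("need at least one gene per chromosome")
    rng = _rng(config, _STREAM_GENOME, seed)
    names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chromosomes = {name: config.chromosome_length for name in names}
    chrom_idx = np.concatenate(
        [
            np.arange(config.n_chromosomes),
            rng.integers(0, config.n_chromosomes,
                         config.n_genes - config.n_chromosomes),
        ]
    )
    positions = rng.integers(0, config.chromosome_length, config.n_genes)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    tss_sites = [
        (names[int(c)], int(p), str(s), f"gene{i + 1:05d}")
        for i, (c, p, s) in enumerate(zip(chrom_idx, positions, strands))
    ]
    return GenomeAnnotation(chromosomes=chromosomes, tss_sites=tss_sites)


def make_snp_pool(
    annotation: GenomeAnnotation,
    config: SimConfig,
    seed: int | None = None,
) -> SnpPool:
    """Background SNP pool with covariates precomputed.

    Positions are uniform over the genome; folded MAFs follow
    ``0.5 × Beta(a, b)`` (defaults skew toward low frequencies, as on a
    genotyping chip), truncated into (0, 0.5].
    """
    rng = _rng(config, _STREAM_POOL, seed)
    names = list(annotation.chromosomes)
    lengths = np.array([annotation.chromosomes[n] for n in names], dtype=np.int64)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(names), size=config.pool_size, p=probs)
    positions = rng.integers(0, lengths[chrom_idx])
    mafs = 0.5 * rng.beta(config.maf_beta_a, config.maf_beta_b, config.pool_size)
    mafs = np.clip(mafs, 1e-4, 0.5)
    order = np.lexsort((positions, chrom_idx))
    pool = SnpPool(
        rsids=np.array([f"rs{i + 1:06d}" for i in range(config.pool_size)]),
        chroms=np.array([names[int(c)] for c in chrom_idx[order]]),
        positions=positions[order].astype(np.int64),
        mafs=mafs[order],
    )
    return compute_pool_covariates(pool, annotation, config.window_size)


def make_gwas(
    pool: SnpPool,
    annotation: GenomeAnnotation,
    config: SimConfig,
    seed: int | None = None,
    study_id: str = "SIM001",
    trait: str = "synthetic trait",
    max_retries: int = 10,
) -> tuple[GwasStudy, LocusSet]:
    """A synthetic GWAS whose tag SNPs are pool members, plus its true loci.

    Tag SNPs are drawn so that same-chromosome pairs are at least one
    window apart (disjoint loci, no merging); association p-values are
    log-uniform below genome-wide significance.  Returns the study and the
    planted trait loci (the built locus set) used by the track generator.
    """
    if len(pool) < config.n_trait_loci:
        raise ValueError("pool smaller than requested number of trait loci")
    rng = _rng(config, _STREAM_GWAS, seed)
    for _attempt in range(max_retries):
        perm = rng.permutation(len(pool))
        chosen: list[int] = []
        for i in perm:
            ok = all(
                pool.chroms[i] != pool.chroms[j]
                or abs(int(pool.positions[i]) - int(pool.positions[j]))
                >= config.window_size
                for j in chosen
            )
            if ok:
                chosen.append(int(i))
            if len(chosen) == config.n_trait_loci:
                break
        if len(chosen) == config.n_trait_loci:
            break
    else:
        raise ValueError(
            "could not place trait loci with the required spacing; "
            "reduce n_trait_loci or window_size"
        )

    log_p = rng.uniform(-30.0, np.log10(5e-8), config.n_trait_loci)
    coding = rng.random(config.n_trait_loci) < config.coding_fraction
    snps = []
    for k, i in enumerate(chosen):
        term = (
            _CODING_TERMS[rng.integers(0, len(_CODING_TERMS))]
            if coding[k]
            else _NONCODING_TERMS[rng.integers(0, len(_NONCODING_TERMS))]
        )
        snps.append(
            TagSnp(
                rsid=str(pool.rsids[i]),
                chromosome=str(pool.chroms[i]),
                position=int(pool.positions[i]),
                pvalue=float(10.0 ** log_p[k]),
                maf=float(pool.mafs[i]),
                consequences=(term,) if term else (),
            )
        )
    study = GwasStudy(
        study_id=study_id,
        trait=trait,
        has_replication=bool(rng.random() < config.replication_probability),
        snps=snps,
    )
    loci = build_loci(snps, config.window_size, annotation, study_id=study_id)
    return study, loci


def _interval_arrays(
    annotation: GenomeAnnotation, trait_loci: LocusSet | None
) -> tuple[list, list]:
    """(trait intervals, complement intervals) as (chrom, start, end) lists."""
    inside = (
        [(l.chromosome, l.start, l.end) for l in trait_loci.loci]
        if trait_loci is not None
        else []
    )
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in inside:
        by_chrom.setdefault(chrom, []).append((s, e))
    outside = []
    for chrom, length in annotation.chromosomes.items():
        cursor = 0
        for s, e in sorted(by_chrom.get(chrom, [])):
            if s > cursor:
                outside.append((chrom, cursor, s))
            cursor = max(cursor, e)
        if cursor < length:
            outside.append((chrom, cursor, length))
    return inside, outside


def _draw_positions(
    intervals: Sequence[tuple[str, int, int]], n: int, rng: np.random.Generator
) -> list[tuple[str, int]]:
    if n == 0:
        return []
    spans = np.array([e - s for _, s, e in intervals], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(spans)])
    u = rng.integers(0, cum[-1], n)
    idx = np.searchsorted(cum, u, side="right") - 1
    return [
        (intervals[int(i)][0], int(intervals[int(i)][1] + u[k] - cum[int(i)]))
        for k, i in enumerate(idx)
    ]


def make_dhs_track(
    annotation: GenomeAnnotation,
    trait_loci: LocusSet | None,
    config: SimConfig,
    seed: int | None = None,
    sample_id: str = "SIM_DHS",
    tissue: str = "synthetic_tissue",
    replicate: int = 1,
) -> DhsTrack:
    """A peak track with planted enrichment factor ``f`` inside trait loci.

    Peak start positions come from a two-component mixture: a peak falls
    inside the trait loci with probability ``f·T / (f·T + (G − T))`` (T =
    trait span, G = genome size), uniformly within the chosen component,
    so the expected within-locus start density is exactly ``f`` times the
    background density.  Peak lengths are log-normal around the configured
    median, clipped to [min, max] and to the chromosome end.
    """
    rng = _rng(config, _STREAM_TRACK, seed)
    inside, outside = _interval_arrays(annotation, trait_loci)
    T = sum(e - s for _, s, e in inside)
    G = annotation.total_length
    if T >= G:
        raise ValueError("trait loci span the whole genome")
    f = config.enrichment_factor
    n = config.peaks_per_track
    denom = f * T + (G - T)
    p_in = (f * T / denom) if denom > 0 else 0.0
    n_in = int(rng.binomial(n, p_in)) if inside else 0
    starts = _draw_positions(inside, n_in, rng) + _draw_positions(
        outside, n - n_in, rng
    )
    lengths = np.exp(
        rng.normal(np.log(config.peak_length_median), config.peak_length_sigma, n)
    )
    lengths = np.clip(lengths, config.peak_length_min, config.peak_length_max)
    peaks = []
    for (chrom, start), length in zip(starts, lengths):
        end = min(start + int(round(length)), annotation.chromosomes[chrom])
        if end <= start:
            end = start + 1
        peaks.append((chrom, start, end))
    return DhsTrack(
        sample_id=sample_id,
        peaks=peaks,
        tissue=tissue,
        replicate=replicate,
        source="synthetic",
    )


def make_replicates(
    track: DhsTrack,
    config: SimConfig,
    annotation: GenomeAnnotation | None = None,
    seed: int | None = None,
) -> list[DhsTrack]:
    """Biological-replicate emulation: jittered, thinned copies of a track.

    Each replicate independently shifts every peak by a uniform offset in
    [−jitter, +jitter] (length preserved, clipped to chromosome bounds when
    an annotation is given) and drops each peak with the configured
    probability.  Replicate indices run 1..n_replicates.
    """
    rng = _rng(config, _STREAM_REPLICATES, seed)
    out = []
    for r in range(1, config.n_replicates + 1):
        n = track.n_peaks
        shifts = rng.integers(-config.replicate_jitter,
                              config.replicate_jitter + 1, n)
        keep = rng.random(n) >= config.replicate_drop_fraction
        peaks = []
        for (chrom, start, end), shift, k in zip(track.peaks, shifts, keep):
            if not k:
                continue
            length = end - start
            new_start = start + int(shift)
            if annotation is not None:
                new_start = min(
                    max(new_start, 0), annotation.chromosomes[chrom] - length
                )
            else:
                new_start = max(new_start, 0)
            peaks.append((chrom, new_start, new_start + length))
        out.append(
            DhsTrack(
                sample_id=f"{track.sample_id}_rep{r}",
                peaks=peaks,
                tissue=track.tissue,
                replicate=r,
                source=track.source,
            )
        )
    return out


@dataclass
class SyntheticFixture:
    """Everything one end-to-end run needs, generated in memory."""

    config: SimConfig
    annotation: GenomeAnnotation
    pool: SnpPool
    studies: list[GwasStudy]
    trait_loci: dict[str, LocusSet]
    tracks: list[DhsTrack]


def make_fixture(
    config: SimConfig,
    n_studies: int = 1,
    n_background_tissues: int = 1,
) -> SyntheticFixture:
    """A complete synthetic dataset: genome, pool, studies and tracks.

    The first study's trait loci receive planted enrichment in the
    ``target_tissue`` tracks (``config.n_replicates`` replicates); each
    background tissue is uniform (f = 1 geometry, i.e. no trait loci).
    """
    annotation = make_genome(config)
    pool = make_snp_pool(annotation, config)
    studies, trait_loci = [], {}
    for s in range(n_studies):
        sid = f"SIM{s + 1:03d}"
        study, loci = make_gwas(
            pool,
            annotation,
            config,
            seed=int(np.random.SeedSequence([config.seed, _STREAM_GWAS, s])
                     .generate_state(1)[0] % 2**31),
            study_id=sid,
            trait=f"synthetic trait {s + 1}",
        )
        studies.append(study)
        trait_loci[sid] = loci
    tracks: list[DhsTrack] = []
    planted = make_dhs_track(
        annotation,
        trait_loci[studies[0].study_id],
        config,
        sample_id="target_tissue",
        tissue="target_tissue",
    )
    tracks.extend(make_replicates(planted, config, annotation))
    for b in range(n_background_tissues):
        base = make_dhs_track(
            annotation,
            None,
            config,
            seed=int(np.random.SeedSequence([config.seed, _STREAM_TRACK, b + 1])
                     .generate_state(1)[0] % 2**31),
            sample_id=f"background_{b + 1}",
            tissue=f"background_{b + 1}",
        )
        tracks.extend(
            make_replicates(
                base, config, annotation,
                seed=int(np.random.SeedSequence(
                    [config.seed, _STREAM_REPLICATES, b + 1]
                ).generate_state(1)[0] % 2**31),
            )
        )
    return SyntheticFixture(
        config=config,
        annotation=annotation,
        pool=pool,
        studies=studies,
        trait_loci=trait_loci,
        tracks=tracks,
    )
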