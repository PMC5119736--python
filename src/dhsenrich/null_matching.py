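"""Covariate-matched null-locus sampling.

The null model controls for three confounders of overlap between GWAS
loci and regulatory annotation:

* minor allele frequency — candidates must lie within an absolute
  half-width (default ±0.05) of the tag SNP's MAF;
* position relative to genes — the signed distance to the nearest TSS
  (negative upstream of the gene, positive downstream) must fall in the
  same of 12 ordered location bins;
* local gene density — the number of TSS within ±window/2 of the SNP
  must fall in the same of three categories (0–9, 10–24, ≥25).

For each observed locus, one matched background SNP is drawn uniformly
(with replacement across null sets) and a null window of the same span as
the observed locus is centered on it.  Sampling 50,000 such sets gives
the Monte-Carlo null distribution of overlap counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    TSS_COUNT_CATEGORIES,
    GenomeAnnotation,
    PoolSnp,
    SnpPool,
    TagSnp,
)
from .locus_model import LocusSet

__all__ = [
    "MatchingError",
    "DISTANCE_BIN_EDGES",
    "DISTANCE_BIN_LABELS",
    "N_DISTANCE_BINS",
    "DEFAULT_MAF_HALFWIDTH",
    "DEFAULT_N_SETS",
    "signed_tss_distance",
    "assign_distance_bin",
    "assign_distance_bins",
    "tss_count",
    "tss_count_category",
    "compute_pool_covariates",
    "tag_covariates",
    "candidate_indices",
    "candidate_pool",
    "NullLocusDraws",
    "NullSetCollection",
    "sample_null_sets",
]

#: Interior boundaries of the signed TSS-distance bins (bp).  With the two
#: unbounded tails they define 12 right-closed bins:
#: (−inf,−200k], (−200k,−100k], …, (−5k,0], (0,5k], …, (100k,200k], (200k,inf).
DISTANCE_BIN_EDGES = np.array(
    [-200_000, -100_000, -25_000, -10_000, -5_000, 0,
     5_000, 10_000, 25_000, 100_000, 200_000],
    dtype=np.int64,
)
N_DISTANCE_BINS = len(DISTANCE_BIN_EDGES) + 1


def _bin_labels() -> tuple[str, ...]:
    edges = ["-inf"] + [str(int(e)) for e in DISTANCE_BIN_EDGES] + ["inf"]
    labels = []
    for i in range(N_DISTANCE_BINS):
        right = ")" if i == N_DISTANCE_BINS - 1 else "]"
        labels.append(f"({edges[i]},{edges[i + 1]}{right}")
    return tuple(labels)


DISTANCE_BIN_LABELS = _bin_labels()

DEFAULT_MAF_HALFWIDTH = 0.05
DEFAULT_N_SETS = 50_000


class MatchingError(ValueError):
    """Covariate matching is impossible for some SNP or chromosome."""


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def _nearest_signed(positions: np.ndarray, chromosome: str,
                    annotation: GenomeAnnotation) -> np.ndarray:
    """Vectorised signed distance to the nearest TSS on one chromosome.

    Ties between an upstream and a downstream TSS at equal distance break
    toward the smaller coordinate, for determinism.
    """
    arrays = annotation.tss_arrays().get(chromosome)
    if arrays is None or len(arrays[0]) == 0:
        raise MatchingError(
            f"chromosome {chromosome} has no annotated TSS; "
            "the TSS-distance covariate is undefined there"
        )
    tss_pos, tss_sign = arrays
    idx = np.searchsorted(tss_pos, positions)
    left = np.clip(idx - 1, 0, len(tss_pos) - 1)
    right = np.clip(idx, 0, len(tss_pos) - 1)
    d_left = np.abs(positions - tss_pos[left])
    d_right = np.abs(tss_pos[right] - positions)
    use_left = d_left <= d_right  # tie -> smaller-coordinate TSS
    nearest = np.where(use_left, left, right)
    return (positions - tss_pos[nearest]) * tss_sign[nearest]


def signed_tss_distance(position: int, chromosome: str,
                        annotation: GenomeAnnotation) -> int:
    """Signed distance (bp) to the nearest TSS on the same chromosome.

    Negative when the position is upstream of the gene (5' of the TSS with
    respect to strand), positive downstream, 0 at the TSS itself.
    """
    return int(
        _nearest_signed(np.array([position], dtype=np.int64), chromosome,
                        annotation)[0]
    )


def assign_distance_bins(distances: np.ndarray) -> np.ndarray:
    """Map signed distances to bin indices 0..11 (right-closed bins)."""
    return np.searchsorted(DISTANCE_BIN_EDGES, distances, side="left")


def assign_distance_bin(distance: int) -> int:
    return int(assign_distance_bins(np.array([distance], dtype=np.int64))[0])


def tss_count(position: int, chromosome: str, annotation: GenomeAnnotation,
              window_size: int) -> int:
    """Number of TSS within ±window_size/2 of the position (inclusive)."""
    arrays = annotation.tss_arrays().get(chromosome)
    if arrays is None or len(arrays[0]) == 0:
        raise MatchingError(f"chromosome {chromosome} has no annotated TSS")
    tss_pos, _ = arrays
    half = window_size // 2
    lo = np.searchsorted(tss_pos, position - half, side="left")
    hi = np.searchsorted(tss_pos, position + half, side="right")
    return int(hi - lo)


def tss_count_category(count: int) -> str:
    """Gene-density category: LOW 0–9, MID 10–24, HIGH ≥25."""
    if count < 0:
        raise ValueError("TSS count cannot be negative")
    if count <= 9:
        return "LOW"
    if count <= 24:
        return "MID"
    return "HIGH"


def _categorise_counts(counts: np.ndarray) -> np.ndarray:
    if counts.min(initial=0) < 0:
        raise ValueError("TSS count cannot be negative")
    return np.where(counts <= 9, 0, np.where(counts <= 24, 1, 2)).astype(np.int8)


def compute_pool_covariates(
    pool: SnpPool,
    annotation: GenomeAnnotation,
    window_size: int = 500_000,
    absolute_distance: bool = False,
) -> SnpPool:
    """Fill the matching covariates of a background pool in place.

    ``absolute_distance=True`` bins |distance| instead of the signed
    distance (an alternative convention; signed is the default because the
    bin boundaries themselves are signed).
    """
    n = len(pool)
    dist = np.zeros(n, dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)
    for chrom in np.unique(pool.chroms):
        mask = pool.chroms == chrom
        positions = pool.positions[mask].astype(np.int64)
        dist[mask] = _nearest_signed(positions, str(chrom), annotation)
        arrays = annotation.tss_arrays()[str(chrom)]
        half = window_size // 2
        lo = np.searchsorted(arrays[0], positions - half, side="left")
        hi = np.searchsorted(arrays[0], positions + half, side="right")
        counts[mask] = hi - lo
    binned = np.abs(dist) if absolute_distance else dist
    pool.signed_tss_distances = dist
    pool.distance_bins = assign_distance_bins(binned)
    pool.tss_counts = counts
    pool.tss_count_categories = _categorise_counts(counts)
    return pool


def tag_covariates(
    snp: TagSnp,
    annotation: GenomeAnnotation,
    window_size: int = 500_000,
    absolute_distance: bool = False,
) -> PoolSnp:
    """Matching covariates of a tag SNP, as a filled :class:`PoolSnp`."""
    dist = signed_tss_distance(snp.position, snp.chromosome, annotation)
    count = tss_count(snp.position, snp.chromosome, annotation, window_size)
    binned = abs(dist) if absolute_distance else dist
    return PoolSnp(
        rsid=snp.rsid,
        chromosome=snp.chromosome,
        position=snp.position,
        maf=snp.maf,
        signed_tss_distance=dist,
        distance_bin=assign_distance_bin(binned),
        tss_count=count,
        tss_count_category=tss_count_category(count),
    )


# ---------------------------------------------------------------------------
# candidate selection and null sampling
# ---------------------------------------------------------------------------


def candidate_indices(
    tag: PoolSnp,
    pool: SnpPool,
    maf_halfwidth: float = DEFAULT_MAF_HALFWIDTH,
) -> np.ndarray:
    """Indices of pool SNPs matching a tag SNP on all three covariates.

    The tag SNP itself (by rsid) is excluded.  An empty candidate set is an
    error — matching is never silently relaxed.
    """
    if not pool.has_covariates:
        raise MatchingError("pool covariates not computed")
    if tag.distance_bin is None or tag.tss_count_category is None:
        raise MatchingError(f"tag SNP {tag.rsid}: covariates not computed")
    cat_code = TSS_COUNT_CATEGORIES.index(tag.tss_count_category)
    mask = (
        (np.abs(pool.mafs - tag.maf) <= maf_halfwidth)
        & (pool.distance_bins == tag.distance_bin)
        & (pool.tss_count_categories == cat_code)
        & (pool.rsids != tag.rsid)
    )
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise MatchingError(
            f"no matched null candidates for tag SNP {tag.rsid} "
            f"(MAF={tag.maf:.3f}, bin={DISTANCE_BIN_LABELS[tag.distance_bin]}, "
            f"TSS category={tag.tss_count_category})"
        )
    return idx


def candidate_pool(
    tag: PoolSnp,
    pool: SnpPool,
    maf_halfwidth: float = DEFAULT_MAF_HALFWIDTH,
) -> list[PoolSnp]:
    """Materialised matched-candidate list (see :func:`candidate_indices`)."""
    return [pool.snp(int(i)) for i in candidate_indices(tag, pool, maf_halfwidth)]


@dataclass
class NullLocusDraws:
    """All null draws for one observed locus, column-oriented.

    Arrays have length ``n_sets``; ``chrom_codes`` index into the owning
    collection's ``chrom_order``; ``pool_indices`` index into the pool.
    """

    chrom_codes: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    pool_indices: np.ndarray


@dataclass
class NullSetCollection:
    """``n_sets`` matched null locus sets for one study's observed loci."""

    study_id: str
    n_sets: int
    seed: int
    chrom_order: list[str]
    loci: list[NullLocusDraws]
    pool: SnpPool = field(repr=False)

    def null_set(self, j: int) -> list[tuple[str, int, int, str]]:
        """Null set ``j`` as (chromosome, start, end, source rsid) rows."""
        return [
            (
                self.chrom_order[int(ld.chrom_codes[j])],
                int(ld.starts[j]),
                int(ld.ends[j]),
                str(self.pool.rsids[int(ld.pool_indices[j])]),
            )
            for ld in self.loci
        ]


def sample_null_sets(
    locus_set: LocusSet,
    pool: SnpPool,
    annotation: GenomeAnnotation,
    n_sets: int = DEFAULT_N_SETS,
    seed: int = 0,
    maf_halfwidth: float = DEFAULT_MAF_HALFWIDTH,
    absolute_distance: bool = False,
) -> NullSetCollection:
    """Draw ``n_sets`` covariate-matched null locus sets for a study.

    Each observed locus is represented for matching by its first-reported
    member SNP; the null window copies the observed locus's span (so merged
    loci keep comparable overlap opportunity) centered on the drawn SNP and
    clipped to chromosome bounds.  Draws are uniform over the candidate set,
    with replacement across and within sets; null loci are not merged even
    if they collide.  Fully reproducible given ``seed``.
    """
    if not pool.has_covariates:
        raise MatchingError("pool covariates not computed")
    chrom_order = list(annotation.chromosomes)
    chrom_lengths = np.array(
        [annotation.chromosomes[c] for c in chrom_order], dtype=np.int64
    )
    pool_codes = pd.Categorical(pool.chroms, categories=chrom_order).codes.astype(
        np.int64
    )
    if (pool_codes < 0).any():
        bad = pool.chroms[pool_codes < 0][0]
        raise MatchingError(f"pool SNP on unknown chromosome {bad}")

    rng = np.random.default_rng(seed)
    draws: list[NullLocusDraws] = []
    for locus in locus_set.loci:
        rep = locus.member_snps[0]
        tag = tag_covariates(
            rep, annotation, locus_set.window_size, absolute_distance
        )
        cand = candidate_indices(tag, pool, maf_halfwidth)
        chosen = cand[rng.integers(0, cand.size, size=n_sets)]
        span = locus.span
        centers = pool.positions[chosen].astype(np.int64)
        starts = np.maximum(centers - span // 2, 0)
        ends = starts + span
        lens = chrom_lengths[pool_codes[chosen]]
        ends = np.minimum(ends, lens)
        draws.append(
            NullLocusDraws(
                chrom_codes=pool_codes[chosen],
                starts=starts,
                ends=ends,
                pool_indices=chosen,
            )
        )
    return NullSetCollection(
        study_id=locus_set.study_id,
        n_sets=n_sets,
        seed=seed,
        chrom_order=chrom_order,
        loci=draws,
        pool=pool,
    )
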