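"""GWAS-level annotation: inclusion filter, coding consequences,
per-study covariate summaries, and green/orange/red stratification.

Studies enter the analysis only if, after dropping SNPs below genome-wide
significance (p < 5×10⁻⁸), they retain at least 12 independent (merged)
loci.  Each study is then stratified by the best (minimum) enrichment
p-value it achieves across all DHS samples: green ≤ 1e-4, orange ≤ 1e-2,
red above.  Group-level metrics are compared with an unpaired rank-sum
(Mann–Whitney) test — the groups are independent and of unequal size, so
a paired signed-rank statistic is not applicable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import GenomeAnnotation, GwasStudy
from .locus_model import independent_locus_count
from .null_matching import (
    N_DISTANCE_BINS,
    assign_distance_bin,
    signed_tss_distance,
)

__all__ = [
    "CODING_CONSEQUENCES",
    "Group",
    "StudySummary",
    "GroupComparison",
    "is_coding",
    "filter_gwas",
    "assign_group",
    "summarize_study",
    "compare_groups",
    "replication_fraction",
]

#: Consequence terms counted as having potential impact on the protein
#: product; any one term suffices, case-insensitively.
CODING_CONSEQUENCES = frozenset(
    {
        "missense_variant",
        "splice_region_variant",
        "frameshift_variant",
        "stop_gained",
        "stop_lost",
        "feature_elongation",
        "splice_donor_variant",
    }
)

GENOME_WIDE_SIGNIFICANCE = 5e-8


class Group(str, Enum):
    GREEN = "green"
    ORANGE = "orange"
    RED = "red"


@dataclass
class StudySummary:
    """Per-study covariate summary plus enrichment-based group."""

    study_id: str
    trait: str
    n_loci: int
    coding_fraction: float
    mean_maf: float
    tss_bin_fractions: tuple[float, ...]
    has_replication: bool
    best_p: float
    group: Group


@dataclass
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    pvalue: float


def is_coding(consequences: Iterable[str]) -> bool:
    """True iff any consequence term is in the coding set (case-insensitive)."""
    return any(t.strip().lower() in CODING_CONSEQUENCES for t in consequences)


def filter_gwas(
    catalog: Sequence[GwasStudy],
    annotation: GenomeAnnotation,
    min_loci: int = 12,
    p_threshold: float = GENOME_WIDE_SIGNIFICANCE,
    window_size: int = 500_000,
    use_merged_counts: bool = True,
) -> list[GwasStudy]:
    """Apply the study-inclusion filter.

    Per study, SNPs with ``p ≥ p_threshold`` are dropped first; the study
    is kept iff the number of independent (merged) loci among the survivors
    is at least ``min_loci``.  ``use_merged_counts=False`` counts surviving
    SNP rows instead of merged loci.
    """
    kept: list[GwasStudy] = []
    for study in catalog:
        snps = [s for s in study.snps if s.pvalue < p_threshold]
        if not snps:
            continue
        if use_merged_counts:
            n = independent_locus_count(snps, window_size, annotation)
        else:
            n = len(snps)
        if n >= min_loci:
            kept.append(
                GwasStudy(
                    study_id=study.study_id,
                    trait=study.trait,
                    has_replication=study.has_replication,
                    snps=snps,
                )
            )
    return kept


def assign_group(
    best_p: float,
    green_threshold: float = 1e-4,
    orange_threshold: float = 1e-2,
) -> Group:
    """Stratify a study by its best enrichment p across all DHS samples.

    Boundaries are inclusive on the more significant side: ``p = 1e-4`` is
    green and ``p = 1e-2`` is orange.
    """
    if not (0.0 < best_p <= 1.0):
        raise ValueError(f"best_p {best_p} outside (0, 1]")
    if best_p <= green_threshold:
        return Group.GREEN
    if best_p <= orange_threshold:
        return Group.ORANGE
    return Group.RED


def summarize_study(
    study: GwasStudy,
    annotation: GenomeAnnotation,
    best_p: float,
    window_size: int = 500_000,
    green_threshold: float = 1e-4,
    orange_threshold: float = 1e-2,
) -> StudySummary:
    """Covariate summary of one (already filtered) study.

    The TSS-distance histogram is the fraction of the study's SNPs falling
    in each of the 12 signed-distance bins; fractions sum to 1.
    """
    n_loci = independent_locus_count(study.snps, window_size, annotation)
    coding = float(np.mean([is_coding(s.consequences) for s in study.snps]))
    mean_maf = float(np.mean([s.maf for s in study.snps]))
    hist = np.zeros(N_DISTANCE_BINS, dtype=float)
    for snp in study.snps:
        d = signed_tss_distance(snp.position, snp.chromosome, annotation)
        hist[assign_distance_bin(d)] += 1
    hist /= len(study.snps)
    return StudySummary(
        study_id=study.study_id,
        trait=study.trait,
        n_loci=n_loci,
        coding_fraction=coding,
        mean_maf=mean_maf,
        tss_bin_fractions=tuple(hist),
        has_replication=study.has_replication,
        best_p=best_p,
        group=assign_group(best_p, green_threshold, orange_threshold),
    )


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    metric: str = "",
) -> list[GroupComparison]:
    """Pairwise rank-based comparison of a per-study metric between groups.

    Two-sided Mann–Whitney rank-sum per group pair; a pair where either
    group has fewer than two values is skipped with a warning.  When every
    value in both groups is identical the test is degenerate and p = 1.
    """
    results: list[GroupComparison] = []
    names = list(values_by_group)
    for a, b in combinations(names, 2):
        va = np.asarray(values_by_group[a], dtype=float)
        vb = np.asarray(values_by_group[b], dtype=float)
        if va.size < 2 or vb.size < 2:
            warnings.warn(
                f"metric {metric!r}: group pair ({a}, {b}) skipped "
                "(fewer than 2 values in a group)",
                stacklevel=2,
            )
            continue
        if np.unique(np.concatenate([va, vb])).size == 1:
            stat, p = va.size * vb.size / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(va, vb, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        results.append(
            GroupComparison(
                metric=metric,
                group_a=a,
                group_b=b,
                n_a=int(va.size),
                n_b=int(vb.size),
                statistic=stat,
                pvalue=p,
            )
        )
    return results


def replication_fraction(
    studies_by_group: Mapping[str, Sequence],
) -> dict[str, float | None]:
    """Per group, the fraction of studies with a replication cohort.

    Empty groups yield ``None`` with a warning (the fraction is undefined).
    """
    out: dict[str, float | None] = {}
    for group, studies in studies_by_group.items():
        if not studies:
            warnings.warn(
                f"group {group}: empty, replication fraction undefined",
                stacklevel=2,
            )
            out[group] = None
            continue
        out[group] = float(
            np.mean([bool(s.has_replication) for s in studies])
        )
    return out
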