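"""Susceptibility-locus construction.

A susceptibility locus is a fixed-width window (default 500 kb) centered
on a reported lead SNP, clipped to chromosome bounds.  Lead SNPs whose
windows overlap are "neighboring" and merge transitively into a single
locus covering the union of their windows, so the loci of one study are
pairwise disjoint and no DHS peak can be double-counted within a study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io_formats import GenomeAnnotation, TagSnp

__all__ = ["Locus", "LocusSet", "build_loci", "independent_locus_count"]

DEFAULT_WINDOW_SIZE = 500_000


@dataclass
class Locus:
    """A merged susceptibility window; 0-based half-open coordinates."""

    chromosome: str
    start: int
    end: int
    member_snps: list[TagSnp]

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("locus has non-positive span")
        if not self.member_snps:
            raise ValueError("locus has no member SNPs")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class LocusSet:
    """All loci of one study, sorted by (chromosome, start)."""

    study_id: str
    window_size: int
    loci: list[Locus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        self.loci = sorted(self.loci, key=lambda l: (l.chromosome, l.start))

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def total_span(self) -> int:
        return sum(l.span for l in self.loci)


def _window(snp: TagSnp, window_size: int, chrom_length: int) -> tuple[int, int]:
    # Clip at chromosome bounds rather than shifting: shifting would bias
    # the TSS-distance covariate of edge loci.
    half = window_size // 2
    return max(0, snp.position - half), min(chrom_length, snp.position + half)


def build_loci(
    snps: Sequence[TagSnp],
    window_size: int,
    annotation: GenomeAnnotation,
    study_id: str = "",
) -> LocusSet:
    """Build merged susceptibility loci for a set of lead SNPs.

    Each SNP contributes the window ``[pos - w/2, pos + w/2)`` clipped to
    its chromosome; same-chromosome windows that overlap (strictly — two
    half-open windows that merely abut stay separate) are merged
    transitively.  ``member_snps`` of a merged locus keeps the input
    (reported) order, so ``member_snps[0]`` is the first-reported SNP.
    """
    if window_size % 2 != 0:
        raise ValueError("window_size must be even")
    for snp in snps:
        if snp.chromosome not in annotation.chromosomes:
            raise ValueError(
                f"SNP {snp.rsid}: unknown chromosome {snp.chromosome}"
            )
        if snp.position >= annotation.chromosomes[snp.chromosome]:
            raise ValueError(f"SNP {snp.rsid}: position beyond chromosome end")

    loci: list[Locus] = []
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, snp in enumerate(snps):
        start, end = _window(snp, window_size, annotation.chromosomes[snp.chromosome])
        by_chrom.setdefault(snp.chromosome, []).append((start, end, idx))

    for chrom in sorted(by_chrom):
        windows = sorted(by_chrom[chrom])
        cur_start, cur_end, cur_members = windows[0][0], windows[0][1], [windows[0][2]]
        for start, end, idx in windows[1:]:
            if start < cur_end:  # strict: abutting windows do not merge
                cur_end = max(cur_end, end)
                cur_members.append(idx)
            else:
                loci.append(
                    Locus(chrom, cur_start, cur_end,
                          [snps[i] for i in sorted(cur_members)])
                )
                cur_start, cur_end, cur_members = start, end, [idx]
        loci.append(
            Locus(chrom, cur_start, cur_end, [snps[i] for i in sorted(cur_members)])
        )

    return LocusSet(study_id=study_id, window_size=window_size, loci=loci)


def independent_locus_count(
    snps: Sequence[TagSnp], window_size: int, annotation: GenomeAnnotation
) -> int:
    """Number of merged loci; the quantity the study-inclusion filter uses."""
    if not snps:
        return 0
    return len(build_loci(snps, window_size, annotation))
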