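"""Validated domain containers and every file format the pipeline touches.

All internal coordinates are 0-based half-open (the BED convention).  The
only 1-based surfaces are the position columns of the GWAS table, the
SNP-pool table and the TSS annotation table; those are shifted at parse
and serialise time so that no other module ever sees a 1-based number.

Floats are serialised with ``repr`` (shortest round-tripping form), which
makes every write → read round trip exact and every rerun with the same
seed byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "TagSnp",
    "GwasStudy",
    "GenomeAnnotation",
    "DhsTrack",
    "PoolSnp",
    "SnpPool",
    "TSS_COUNT_CATEGORIES",
    "read_bed",
    "write_bed",
    "read_gwas_table",
    "write_gwas_table",
    "read_snp_pool",
    "write_snp_pool",
    "read_genome_annotation",
    "write_genome_annotation",
    "read_sample_sheet",
    "write_sample_sheet",
    "load_dhs_tracks",
    "write_results",
]

#: Ordered labels for the gene-density (TSS count) matching covariate.
TSS_COUNT_CATEGORIES = ("LOW", "MID", "HIGH")

GWAS_COLUMNS = (
    "study_id",
    "trait",
    "rsid",
    "chr",
    "pos_1based",
    "pvalue",
    "maf",
    "consequences",
    "has_replication",
)
POOL_COLUMNS = ("rsid", "chr", "pos_1based", "maf")
SAMPLE_SHEET_COLUMNS = ("sample_id", "tissue", "replicate", "source")


class ParseError(ValueError):
    """An input file violates the declared schema or an invariant."""


def _fmt(value) -> str:
    """Serialise one table cell; floats via repr so they round-trip."""
    if value is None:
        return "NA"
    if isinstance(value, (float, np.floating)):
        v = float(value)
        return "NA" if np.isnan(v) else repr(v)
    return str(value)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TagSnp:
    """A reported GWAS lead variant.

    ``position`` is 0-based; ``maf`` is the folded minor allele frequency;
    ``consequences`` are free-form annotation terms (classified downstream).
    """

    rsid: str
    chromosome: str
    position: int
    pvalue: float
    maf: float
    consequences: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise ParseError(
                f"SNP {self.rsid}: p-value {self.pvalue} outside (0, 1]"
            )
        if not (0.0 <= self.maf <= 0.5):
            raise ParseError(f"SNP {self.rsid}: MAF {self.maf} outside [0, 0.5]")
        if self.position < 0:
            raise ParseError(f"SNP {self.rsid}: negative position")


@dataclass
class GwasStudy:
    """One study's worth of catalog rows: a trait and its lead SNPs."""

    study_id: str
    trait: str
    has_replication: bool
    snps: list[TagSnp]

    def __post_init__(self) -> None:
        if not self.snps:
            raise ParseError(f"study {self.study_id}: no SNPs")


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus stranded transcription start sites.

    ``tss_sites`` rows are (chromosome, 0-based position, strand, gene_id).
    Per-chromosome sorted TSS arrays are cached for nearest-TSS queries.
    """

    chromosomes: dict[str, int]
    tss_sites: list[tuple[str, int, str, str]]
    _tss_cache: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ParseError("annotation has no chromosomes")
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ParseError(f"chromosome {name}: non-positive length")
        if not self.tss_sites:
            raise ParseError("annotation has no TSS (matching undefined)")
        for chrom, pos, strand, gene in self.tss_sites:
            if chrom not in self.chromosomes:
                raise ParseError(f"TSS {gene}: unknown chromosome {chrom}")
            if not (0 <= pos < self.chromosomes[chrom]):
                raise ParseError(f"TSS {gene}: position {pos} out of bounds")
            if strand not in ("+", "-"):
                raise ParseError(f"TSS {gene}: bad strand {strand!r}")

    @property
    def total_length(self) -> int:
        return sum(self.chromosomes.values())

    def tss_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per chromosome: (sorted positions, aligned strand signs ±1)."""
        if self._tss_cache is None:
            cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for chrom, pos, strand, _gene in self.tss_sites:
                by_chrom.setdefault(chrom, []).append(
                    (pos, 1 if strand == "+" else -1)
                )
            for chrom, rows in by_chrom.items():
                pos = np.array([r[0] for r in rows], dtype=np.int64)
                sgn = np.array([r[1] for r in rows], dtype=np.int64)
                order = np.argsort(pos, kind="stable")
                cache[chrom] = (pos[order], sgn[order])
            self._tss_cache = cache
        return self._tss_cache


@dataclass
class DhsTrack:
    """One sample's DNase I hypersensitive-site peaks plus metadata.

    Peaks are (chromosome, start, end) in 0-based half-open coordinates,
    kept sorted by (chromosome, start, end).
    """

    sample_id: str
    peaks: list[tuple[str, int, int]]
    tissue: str = ""
    replicate: int = 1
    source: str = ""
    _arrays: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for chrom, start, end in self.peaks:
            if start >= end:
                raise ParseError(
                    f"track {self.sample_id}: peak {chrom}:{start}-{end} has "
                    "start >= end"
                )
            if start < 0:
                raise ParseError(f"track {self.sample_id}: negative coordinate")
        self.peaks = sorted(self.peaks)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def peak_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per chromosome: independently sorted start and end arrays.

        Sorting starts and ends separately is what the counting identity
        ``#overlaps = #(start < E) - #(end <= S)`` requires.
        """
        if self._arrays is None:
            arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for chrom, start, end in self.peaks:
                by_chrom.setdefault(chrom, []).append((start, end))
            for chrom, rows in by_chrom.items():
                starts = np.sort(np.array([r[0] for r in rows], dtype=np.int64))
                ends = np.sort(np.array([r[1] for r in rows], dtype=np.int64))
                arrays[chrom] = (starts, ends)
            self._arrays = arrays
        return self._arrays


@dataclass(frozen=True)
class PoolSnp:
    """A background SNP with (optionally computed) matching covariates."""

    rsid: str
    chromosome: str
    position: int
    maf: float
    signed_tss_distance: int | None = None
    distance_bin: int | None = None
    tss_count: int | None = None
    tss_count_category: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 0.5):
            raise ParseError(f"pool SNP {self.rsid}: MAF {self.maf} outside [0, 0.5]")


@dataclass
class SnpPool:
    """Column-oriented background SNP pool.

    Covariate columns are ``None`` until
    :func:`dhsenrich.null_matching.compute_pool_covariates` fills them.
    ``tss_count_categories`` holds int8 codes into :data:`TSS_COUNT_CATEGORIES`.
    """

    rsids: np.ndarray
    chroms: np.ndarray
    positions: np.ndarray
    mafs: np.ndarray
    signed_tss_distances: np.ndarray | None = None
    distance_bins: np.ndarray | None = None
    tss_counts: np.ndarray | None = None
    tss_count_categories: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.rsids)
        if not (len(self.chroms) == len(self.positions) == len(self.mafs) == n):
            raise ParseError("pool columns have unequal lengths")
        mafs = np.asarray(self.mafs, dtype=float)
        if n and (mafs.min() < 0.0 or mafs.max() > 0.5):
            bad = self.rsids[(mafs < 0.0) | (mafs > 0.5)][0]
            raise ParseError(f"pool SNP {bad}: MAF outside [0, 0.5]")

    def __len__(self) -> int:
        return len(self.rsids)

    @property
    def has_covariates(self) -> bool:
        return self.distance_bins is not None

    def snp(self, i: int) -> PoolSnp:
        """Materialise row ``i`` as a :class:`PoolSnp` record."""
        if self.has_covariates:
            return PoolSnp(
                rsid=str(self.rsids[i]),
                chromosome=str(self.chroms[i]),
                position=int(self.positions[i]),
                maf=float(self.mafs[i]),
                signed_tss_distance=int(self.signed_tss_distances[i]),
                distance_bin=int(self.distance_bins[i]),
                tss_count=int(self.tss_counts[i]),
                tss_count_category=TSS_COUNT_CATEGORIES[
                    int(self.tss_count_categories[i])
                ],
            )
        return PoolSnp(
            rsid=str(self.rsids[i]),
            chromosome=str(self.chroms[i]),
            position=int(self.positions[i]),
            maf=float(self.mafs[i]),
        )


# ---------------------------------------------------------------------------
# BED peaks
# ---------------------------------------------------------------------------


def read_bed(
    path,
    sample_id: str | None = None,
    tissue: str = "",
    replicate: int = 1,
    source: str = "",
    annotation: GenomeAnnotation | None = None,
) -> DhsTrack:
    """Read a BED3+ peak file into a sorted, validated :class:`DhsTrack`.

    Columns beyond the first three are ignored.  If ``annotation`` is given,
    peak chromosomes must be a subset of the annotation's.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    peaks: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative start")
            if annotation is not None:
                if chrom not in annotation.chromosomes:
                    raise ParseError(
                        f"{path}:{lineno}: unknown chromosome {chrom}"
                    )
                if end > annotation.chromosomes[chrom]:
                    raise ParseError(
                        f"{path}:{lineno}: peak end {end} beyond chromosome"
                    )
            peaks.append((chrom, start, end))
    if not peaks:
        warnings.warn(f"{path}: BED file contains no peaks", stacklevel=2)
    return DhsTrack(
        sample_id=sample_id,
        peaks=peaks,
        tissue=tissue,
        replicate=replicate,
        source=source,
    )


def write_bed(track: DhsTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in track.peaks:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# GWAS catalog table
# ---------------------------------------------------------------------------


def read_gwas_table(path, consequence_delimiter: str = ",") -> list[GwasStudy]:
    """Read the tab-separated GWAS association table.

    Rows are grouped by ``study_id`` preserving file order.  Positions are
    1-based in the file and converted to 0-based.  A duplicated
    (study_id, rsid) pair keeps the first row with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")

    studies: dict[str, dict] = {}
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        sid, rsid = row.study_id, row.rsid
        if (sid, rsid) in seen:
            warnings.warn(
                f"{path}: duplicate ({sid}, {rsid}); keeping first",
                stacklevel=2,
            )
            continue
        seen.add((sid, rsid))
        terms = tuple(
            t.strip()
            for t in row.consequences.split(consequence_delimiter)
            if t.strip()
        )
        snp = TagSnp(
            rsid=rsid,
            chromosome=row.chr,
            position=int(row.pos_1based) - 1,
            pvalue=float(row.pvalue),
            maf=float(row.maf),
            consequences=terms,
        )
        entry = studies.setdefault(
            sid,
            {
                "trait": row.trait,
                "has_replication": row.has_replication.strip() in ("1", "true", "True"),
                "snps": [],
            },
        )
        entry["snps"].append(snp)
    return [
        GwasStudy(study_id=sid, trait=e["trait"],
                  has_replication=e["has_replication"], snps=e["snps"])
        for sid, e in studies.items()
    ]


def write_gwas_table(studies: Sequence[GwasStudy], path,
                     consequence_delimiter: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GWAS_COLUMNS) + "\n")
        for study in studies:
            rep = "1" if study.has_replication else "0"
            for snp in study.snps:
                fh.write(
                    "\t".join(
                        [
                            study.study_id,
                            study.trait,
                            snp.rsid,
                            snp.chromosome,
                            str(snp.position + 1),
                            _fmt(snp.pvalue),
                            _fmt(snp.maf),
                            consequence_delimiter.join(snp.consequences),
                            rep,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# SNP pool
# ---------------------------------------------------------------------------


def read_snp_pool(path) -> SnpPool:
    """Read the background SNP pool; covariates are left uncomputed."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in POOL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    dup = df["rsid"].duplicated()
    if dup.any():
        warnings.warn(
            f"{path}: {int(dup.sum())} duplicate rsids; keeping first",
            stacklevel=2,
        )
        df = df[~dup]
    mafs = df["maf"].astype(float).to_numpy()
    if len(mafs) and (mafs.min() < 0.0 or mafs.max() > 0.5):
        bad = df["rsid"].to_numpy()[(mafs < 0.0) | (mafs > 0.5)][0]
        raise ParseError(f"{path}: SNP {bad}: MAF outside [0, 0.5]")
    return SnpPool(
        rsids=df["rsid"].to_numpy(),
        chroms=df["chr"].to_numpy(),
        positions=df["pos_1based"].astype(np.int64).to_numpy() - 1,
        mafs=mafs,
    )


def write_snp_pool(pool: SnpPool, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(POOL_COLUMNS) + "\n")
        for i in range(len(pool)):
            fh.write(
                f"{pool.rsids[i]}\t{pool.chroms[i]}\t"
                f"{int(pool.positions[i]) + 1}\t{_fmt(float(pool.mafs[i]))}\n"
            )


# ---------------------------------------------------------------------------
# genome annotation
# ---------------------------------------------------------------------------


def read_genome_annotation(chrom_sizes_path, tss_path) -> GenomeAnnotation:
    sizes = pd.read_csv(chrom_sizes_path, sep="\t", dtype=str)
    for col in ("chr", "length"):
        if col not in sizes.columns:
            raise ParseError(f"{chrom_sizes_path}: missing column {col}")
    if sizes["chr"].duplicated().any():
        raise ParseError(f"{chrom_sizes_path}: duplicate chromosome names")
    chromosomes = {
        str(r.chr): int(r.length) for r in sizes.itertuples(index=False)
    }
    tss = pd.read_csv(tss_path, sep="\t", dtype=str)
    for col in ("chr", "pos_1based", "strand", "gene_id"):
        if col not in tss.columns:
            raise ParseError(f"{tss_path}: missing column {col}")
    tss_sites = [
        (str(r.chr), int(r.pos_1based) - 1, str(r.strand), str(r.gene_id))
        for r in tss.itertuples(index=False)
    ]
    return GenomeAnnotation(chromosomes=chromosomes, tss_sites=tss_sites)


def write_genome_annotation(annotation: GenomeAnnotation,
                            chrom_sizes_path, tss_path) -> None:
    with open(chrom_sizes_path, "w") as fh:
        fh.write("chr\tlength\n")
        for name, length in annotation.chromosomes.items():
            fh.write(f"{name}\t{length}\n")
    with open(tss_path, "w") as fh:
        fh.write("chr\tpos_1based\tstrand\tgene_id\n")
        for chrom, pos, strand, gene in annotation.tss_sites:
            fh.write(f"{chrom}\t{pos + 1}\t{strand}\t{gene}\n")


# ---------------------------------------------------------------------------
# sample sheet and track loading
# ---------------------------------------------------------------------------


def read_sample_sheet(path) -> list[dict]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id")
    return [
        {
            "sample_id": r.sample_id,
            "tissue": r.tissue,
            "replicate": int(r.replicate),
            "source": r.source,
        }
        for r in df.itertuples(index=False)
    ]


def write_sample_sheet(tracks: Sequence[DhsTrack], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SAMPLE_SHEET_COLUMNS) + "\n")
        for t in tracks:
            fh.write(f"{t.sample_id}\t{t.tissue}\t{t.replicate}\t{t.source}\n")


def load_dhs_tracks(
    sample_sheet_path, bed_dir, annotation: GenomeAnnotation | None = None
) -> list[DhsTrack]:
    """Load every track named in the sample sheet from ``bed_dir``."""
    bed_dir = Path(bed_dir)
    tracks = []
    for row in read_sample_sheet(sample_sheet_path):
        bed_path = bed_dir / f"{row['sample_id']}.bed"
        if not bed_path.exists():
            raise ParseError(f"sample sheet names missing BED file {bed_path}")
        tracks.append(
            read_bed(
                bed_path,
                sample_id=row["sample_id"],
                tissue=row["tissue"],
                replicate=row["replicate"],
                source=row["source"],
                annotation=annotation,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

DETAIL_COLUMNS = (
    "study_id",
    "sample_id",
    "tissue",
    "replicate",
    "observed_count",
    "null_mean",
    "null_sd",
    "fold_enrichment",
    "p_empirical",
    "p_bh",
    "n_sets",
    "seed",
)
TISSUE_COLUMNS = (
    "study_id",
    "tissue",
    "n_replicates",
    "afe",
    "afe_sd",
    "summary_p",
    "replicate_folds",
    "replicate_pvalues",
)
STUDY_COLUMNS = (
    "study_id",
    "trait",
    "n_loci",
    "coding_fraction",
    "mean_maf",
    "has_replication",
    "best_p",
    "group",
)


def write_results(
    results: Sequence,
    tissue_summaries: Sequence,
    study_summaries: Sequence,
    out_dir,
    *,
    sample_meta: Mapping[str, tuple[str, int]],
    seed: int,
    config_hash: str,
    bh_pvalues: Sequence[float] | None = None,
) -> dict[str, Path]:
    """Write the detail, tissue-summary and study-summary TSVs.

    ``sample_meta`` maps sample_id → (tissue, replicate).  Each file starts
    with a header comment recording the seed and a hash of the scientific
    parameters, so reruns are auditable and byte-comparable.
    """
    if not results:
        raise ValueError("no results to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = f"# dhsenrich seed={seed} params={config_hash}\n"
    paths = {
        "detail": out_dir / "enrichment_detail.tsv",
        "tissue": out_dir / "tissue_summary.tsv",
        "study": out_dir / "study_summary.tsv",
    }

    with open(paths["detail"], "w") as fh:
        fh.write(header)
        fh.write("\t".join(DETAIL_COLUMNS) + "\n")
        for i, r in enumerate(results):
            tissue, replicate = sample_meta[r.sample_id]
            p_bh = bh_pvalues[i] if bh_pvalues is not None else float("nan")
            fh.write(
                "\t".join(
                    [
                        r.study_id,
                        r.sample_id,
                        tissue,
                        str(replicate),
                        str(r.observed_count),
                        _fmt(r.null_mean),
                        _fmt(r.null_sd),
                        _fmt(r.fold_enrichment),
                        _fmt(r.p_empirical),
                        _fmt(p_bh),
                        str(r.n_sets),
                        str(r.seed),
                    ]
                )
                + "\n"
            )

    with open(paths["tissue"], "w") as fh:
        fh.write(header)
        fh.write("\t".join(TISSUE_COLUMNS) + "\n")
        for t in tissue_summaries:
            fh.write(
                "\t".join(
                    [
                        t.study_id,
                        t.tissue,
                        str(t.n_replicates),
                        _fmt(t.afe),
                        _fmt(t.afe_sd),
                        _fmt(t.summary_p),
                        ",".join(_fmt(f) for f in t.replicate_folds),
                        ",".join(_fmt(p) for p in t.replicate_pvalues),
                    ]
                )
                + "\n"
            )

    n_bins = (
        len(study_summaries[0].tss_bin_fractions) if study_summaries else 0
    )
    with open(paths["study"], "w") as fh:
        fh.write(header)
        cols = list(STUDY_COLUMNS) + [f"tss_bin_frac_{i}" for i in range(n_bins)]
        fh.write("\t".join(cols) + "\n")
        for s in study_summaries:
            row = [
                s.study_id,
                s.trait,
                str(s.n_loci),
                _fmt(s.coding_fraction),
                _fmt(s.mean_maf),
                "1" if s.has_replication else "0",
                _fmt(s.best_p),
                s.group.value,
            ] + [_fmt(f) for f in s.tss_bin_fractions]
            fh.write("\t".join(row) + "\n")

    return paths
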