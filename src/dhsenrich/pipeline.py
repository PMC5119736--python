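"""End-to-end orchestration: read inputs, filter studies, sample matched
nulls, count overlaps, summarise, write result tables.

Per-study null sampling uses a seed derived deterministically from the
master seed and the study's rank in sorted study-id order, so results are
byte-identical across reruns and independent of processing order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import enrichment_stats, gwas_annotation, io_formats, null_matching
from .enrichment_stats import EnrichmentResult, TissueSummary
from .gwas_annotation import StudySummary
from .io_formats import DhsTrack, GenomeAnnotation, GwasStudy, SnpPool
from .locus_model import build_loci
from .synthetic_data import SimConfig, make_dhs_track, make_genome, make_gwas, make_snp_pool

__all__ = [
    "RunConfig",
    "StageError",
    "run_enrich",
    "run_report",
    "enrich_catalog",
    "simulate_and_enrich",
]

logger = logging.getLogger("dhsenrich")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:
        raise StageError(f"stage '{name}': {exc}") from exc
    logger.info("stage %s: done", name)


@dataclass
class RunConfig:
    """Paths and scientific parameters for one pipeline run."""

    gwas_path: str
    pool_path: str
    chrom_sizes_path: str
    tss_path: str
    sample_sheet_path: str
    bed_dir: str
    out_dir: str
    window_size: int = 500_000
    n_sets: int = 50_000
    seed: int = 0
    alpha: float = 0.05
    maf_halfwidth: float = 0.05
    min_loci: int = 12
    p_threshold: float = 5e-8
    green_threshold: float = 1e-4
    orange_threshold: float = 1e-2
    absolute_distance: bool = False
    log_level: str = "INFO"

    def param_hash(self) -> str:
        """Hash of the scientific parameters only (never paths), so two
        runs of the same analysis in different directories compare equal."""
        params = {
            k: v
            for k, v in asdict(self).items()
            if k not in {
                "gwas_path", "pool_path", "chrom_sizes_path", "tss_path",
                "sample_sheet_path", "bed_dir", "out_dir", "log_level",
            }
        }
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _study_seed(master_seed: int, study_rank: int) -> int:
    ss = np.random.SeedSequence([master_seed, study_rank])
    return int(ss.generate_state(1)[0] % 2**31)


def enrich_catalog(
    studies: Sequence[GwasStudy],
    tracks: Sequence[DhsTrack],
    pool: SnpPool,
    annotation: GenomeAnnotation,
    *,
    window_size: int = 500_000,
    n_sets: int = 50_000,
    seed: int = 0,
    maf_halfwidth: float = 0.05,
    absolute_distance: bool = False,
    green_threshold: float = 1e-4,
    orange_threshold: float = 1e-2,
) -> tuple[list[EnrichmentResult], list[TissueSummary], list[StudySummary]]:
    """Run matching + enrichment for every (study, track) pair.

    Studies must already have passed the inclusion filter; the pool must
    have covariates computed with the same window.  One null-set
    collection is sampled per study and reused across tracks.
    """
    results: list[EnrichmentResult] = []
    tissue_by_sample = {t.sample_id: t.tissue for t in tracks}
    best_p: dict[str, float] = {}
    sorted_studies = sorted(studies, key=lambda s: s.study_id)
    sorted_tracks = sorted(tracks, key=lambda t: t.sample_id)
    for rank, study in enumerate(sorted_studies):
        loci = build_loci(
            study.snps, window_size, annotation, study_id=study.study_id
        )
        study_seed = _study_seed(seed, rank)
        nulls = null_matching.sample_null_sets(
            loci,
            pool,
            annotation,
            n_sets=n_sets,
            seed=study_seed,
            maf_halfwidth=maf_halfwidth,
            absolute_distance=absolute_distance,
        )
        logger.info(
            "study %s: %d loci, %d null sets (seed %d)",
            study.study_id, len(loci), n_sets, study_seed,
        )
        for track in sorted_tracks:
            observed = enrichment_stats.count_overlaps(loci, track)
            null_counts = enrichment_stats.null_count_distribution(nulls, track)
            res = enrichment_stats.enrichment(
                observed,
                null_counts,
                study_id=study.study_id,
                sample_id=track.sample_id,
                seed=study_seed,
            )
            results.append(res)
            bp = best_p.get(study.study_id)
            best_p[study.study_id] = (
                res.p_empirical if bp is None else min(bp, res.p_empirical)
            )

    tissue_summaries = enrichment_stats.aggregate_tissues(results, tissue_by_sample)
    study_summaries = [
        gwas_annotation.summarize_study(
            study,
            annotation,
            best_p[study.study_id],
            window_size=window_size,
            green_threshold=green_threshold,
            orange_threshold=orange_threshold,
        )
        for study in sorted_studies
    ]
    return results, tissue_summaries, study_summaries


def run_enrich(config: RunConfig):
    """File-level pipeline: read inputs, enrich, write the three TSVs."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    with _stage("read-annotation"):
        annotation = io_formats.read_genome_annotation(
            config.chrom_sizes_path, config.tss_path
        )
    with _stage("read-tracks"):
        tracks = io_formats.load_dhs_tracks(
            config.sample_sheet_path, config.bed_dir, annotation
        )
    with _stage("read-gwas"):
        catalog = io_formats.read_gwas_table(config.gwas_path)
    with _stage("read-pool"):
        pool = io_formats.read_snp_pool(config.pool_path)
    with _stage("filter-gwas"):
        studies = gwas_annotation.filter_gwas(
            catalog,
            annotation,
            min_loci=config.min_loci,
            p_threshold=config.p_threshold,
            window_size=config.window_size,
        )
        dropped = {s.study_id for s in catalog} - {s.study_id for s in studies}
        if dropped:
            logger.info("inclusion filter dropped studies: %s", sorted(dropped))
        if not studies:
            raise StageError("stage 'filter-gwas': no studies pass the filter")
    with _stage("pool-covariates"):
        null_matching.compute_pool_covariates(
            pool, annotation, config.window_size, config.absolute_distance
        )
    with _stage("enrich"):
        results, tissue_summaries, study_summaries = enrich_catalog(
            studies,
            tracks,
            pool,
            annotation,
            window_size=config.window_size,
            n_sets=config.n_sets,
            seed=config.seed,
            maf_halfwidth=config.maf_halfwidth,
            absolute_distance=config.absolute_distance,
            green_threshold=config.green_threshold,
            orange_threshold=config.orange_threshold,
        )
    with _stage("write-results"):
        bh = enrichment_stats.bh_adjust([r.p_empirical for r in results])
        paths = io_formats.write_results(
            results,
            tissue_summaries,
            study_summaries,
            config.out_dir,
            sample_meta={t.sample_id: (t.tissue, t.replicate) for t in tracks},
            seed=config.seed,
            config_hash=config.param_hash(),
            bh_pvalues=bh,
        )
    logger.info(
        "wrote %d detail rows, %d tissue summaries, %d study summaries",
        len(results), len(tissue_summaries), len(study_summaries),
    )
    return paths


def run_report(out_dir, alpha: float = 0.05):
    """Summarise a finished run: studies sorted by best enrichment p,
    significant-pair count at ``alpha``, replication fraction per group."""
    out_dir = Path(out_dir)
    detail_path = out_dir / "enrichment_detail.tsv"
    study_path = out_dir / "study_summary.tsv"
    if not detail_path.exists() or not study_path.exists():
        raise StageError(f"stage 'report': no results found under {out_dir}")
    detail = pd.read_csv(detail_path, sep="\t", comment="#")
    studies = pd.read_csv(study_path, sep="\t", comment="#")
    if detail.empty or studies.empty:
        raise StageError("stage 'report': results tables are empty")
    studies = studies.sort_values("best_p", kind="stable").reset_index(drop=True)
    n_significant = int((detail["p_empirical"] < alpha).sum())
    replication = {
        group: (float(sub["has_replication"].mean()) if len(sub) else None)
        for group, sub in studies.groupby("group")
    }
    report = {
        "n_studies": int(len(studies)),
        "n_pairs": int(len(detail)),
        "alpha": alpha,
        "significant_pairs": n_significant,
        "replication_fraction": replication,
    }
    report_path = out_dir / "report_studies.tsv"
    studies.to_csv(report_path, sep="\t", index=False)
    with open(out_dir / "report_summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return studies, report


# ---------------------------------------------------------------------------
# single-run simulation helper (used by examples, tests and acceptance)
# ---------------------------------------------------------------------------


def simulate_and_enrich(
    sim: SimConfig,
    n_sets: int = 1_000,
    seed: int | None = None,
) -> EnrichmentResult:
    """One simulated study against one planted track, through the full path.

    Generates a genome, pool, GWAS and a DHS track with the configured
    planted factor, samples matched nulls and returns the enrichment
    result.  ``seed`` (default: the sim config's seed) drives both the
    generators and the null sampling through derived streams.
    """
    if seed is not None:
        sim = SimConfig(**{**asdict(sim), "seed": seed})
    annotation = make_genome(sim)
    pool = make_snp_pool(annotation, sim)
    study, loci = make_gwas(pool, annotation, sim)
    track = make_dhs_track(annotation, loci, sim)
    null_seed = int(
        np.random.SeedSequence([sim.seed, 99]).generate_state(1)[0] % 2**31
    )
    nulls = null_matching.sample_null_sets(
        loci, pool, annotation, n_sets=n_sets, seed=null_seed
    )
    observed = enrichment_stats.count_overlaps(loci, track)
    null_counts = enrichment_stats.null_count_distribution(nulls, track)
    return enrichment_stats.enrichment(
        observed,
        null_counts,
        study_id=study.study_id,
        sample_id=track.sample_id,
        seed=null_seed,
    )
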