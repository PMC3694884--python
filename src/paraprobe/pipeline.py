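"""End-to-end pipeline: cluster -> classify -> segregation -> scan -> compare.

``run_pipeline`` ties the stages together over a final-report intensity
table (and optionally a probe manifest plus reference FASTA for the scan
stage), writing per-locus classifications, a genotype matrix, probe hit
reports, summary tables and a run-metadata record of every tolerance used.
Runs are deterministic given the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .classify import (
    Category,
    ClassifierConfig,
    GenotypeCallError,
    LocusClassification,
    call_genotypes,
    classify_locus,
)
from .cluster import ClusterConfig, ClusterSet, UnusableLocusError, cluster_locus, write_cluster_table
from .io import read_intensity_table, read_probe_manifest
from .probescan import (
    MALUS_HOMEOLOGY,
    HomeologyMap,
    ProbeHitReport,
    ScanConfig,
    categorize_probe,
    empty_report,
    load_homeology_map,
    load_reference_fasta,
    scan_probe,
    write_hits_table,
    write_report_table,
)
from .report import cluster_position_table, gentrain_by_category, summarize_categories

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline"]

log = logging.getLogger("paraprobe")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage}: {detail}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    intensities: str
    out_dir: str
    manifest: str | None = None
    reference: str | None = None
    homeology_map: str | None = None
    parents: tuple[str, str] | None = None
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        for key, sub in (
            ("cluster", ClusterConfig),
            ("classifier", ClassifierConfig),
            ("scan", ScanConfig),
        ):
            if key in raw:
                raw[key] = sub(**raw[key])
        if raw.get("parents"):
            raw["parents"] = tuple(raw["parents"])
        raw.update(overrides)
        return cls(**raw)


@dataclass
class PipelineResult:
    classifications: dict[str, LocusClassification]
    genotypes: pd.DataFrame
    hit_reports: dict[str, ProbeHitReport]
    summaries: dict[str, pd.DataFrame]
    metadata: dict
    out_dir: Path


def _check_inputs(config: PipelineConfig) -> None:
    for name in ("intensities", "manifest", "reference", "homeology_map"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            raise PipelineError("setup", f"{name} file not found: {path}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every applicable stage and write the report bundle."""
    _check_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stages_run: list[str] = []
    stages_skipped: list[str] = []

    # --- cluster + classify -------------------------------------------------
    try:
        intensities = read_intensity_table(config.intensities)
    except Exception as err:
        raise PipelineError("read_intensities", str(err)) from err
    stages_run.append("read_intensities")

    cluster_sets: dict[str, ClusterSet] = {}
    classifications: dict[str, LocusClassification] = {}
    geno_cols: dict[str, pd.Series] = {}
    flags: list[str] = []
    for locus_id, rec in intensities.items():
        try:
            cs = cluster_locus(rec, config.cluster)
        except UnusableLocusError as err:
            cs = ClusterSet(locus_id=locus_id, clusters=[], removed=[],
                            config=config.cluster)
            flags.append(str(err))
        except Exception as err:  # pragma: no cover - defensive
            raise PipelineError("cluster", f"locus {locus_id}: {err}") from err
        cluster_sets[locus_id] = cs
        try:
            cl = classify_locus(cs, config.classifier)
        except Exception as err:  # pragma: no cover - defensive
            raise PipelineError("classify", f"locus {locus_id}: {err}") from err
        classifications[locus_id] = cl
        log.debug("locus %s -> %s (%s)", locus_id, cl.category.value, cl.reason)
        try:
            calls = call_genotypes(cl, cs, parents=config.parents)
            geno_cols[locus_id] = calls.genotypes
            flags.extend(calls.flags)
        except GenotypeCallError:
            pass
    stages_run += ["cluster", "classify"]
    log.info("classified %d loci", len(classifications))

    genotypes = pd.DataFrame(geno_cols)
    genotypes.index.name = "sample_id"

    # --- probe scan ---------------------------------------------------------
    hit_reports: dict[str, ProbeHitReport] = {}
    all_hits = []
    homeology = MALUS_HOMEOLOGY
    if config.homeology_map:
        homeology = load_homeology_map(config.homeology_map)
    if config.manifest and config.reference:
        try:
            probes = read_probe_manifest(config.manifest)
            reference = load_reference_fasta(config.reference)
            for probe in probes:
                hits = scan_probe(probe, reference, config.scan)
                all_hits.extend(hits)
                hit_reports[probe.probe_id] = (
                    categorize_probe(hits, homeology)
                    if hits else empty_report(probe.probe_id)
                )
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError("probescan", str(err)) from err
        stages_run.append("probescan")
        log.info("scanned %d probes", len(hit_reports))
    else:
        stages_skipped.append("probescan (no manifest/reference supplied)")

    # --- summaries ----------------------------------------------------------
    taxa = None
    if config.manifest and config.reference:
        taxa = {p.probe_id: p.taxon or "all" for p in probes}
    summaries = summarize_categories(
        list(classifications.values()), hit_reports or None, taxa
    )
    summaries["cluster_positions"] = cluster_position_table(
        list(classifications.values()), cluster_sets, hit_reports or None
    )
    scores = {
        lid: rec.gentrain
        for lid, rec in intensities.items()
        if rec.gentrain is not None
    }
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        summaries["gentrain"] = gentrain_by_category(
            list(classifications.values()), scores or None
        )
    stages_run.append("report")

    # --- outputs ------------------------------------------------------------
    write_cluster_table(cluster_sets.values(), out / "clusters.tsv")
    with open(out / "classifications.tsv", "w", encoding="utf-8") as fh:
        fh.write("snp_id\tcategory\tn_clusters\tratio\tchi2\tp\tlabels\treason\n")
        for cl in classifications.values():
            fh.write(
                f"{cl.locus_id}\t{cl.category.value}\t{cl.n_clusters}\t"
                f"{cl.segregation.ratio}\t{cl.segregation.statistic:.4f}\t"
                f"{cl.segregation.p:.6g}\t{','.join(cl.labels)}\t{cl.reason}\n"
            )
    genotypes.to_csv(out / "genotypes.tsv", sep="\t", na_rep="NC")
    if hit_reports:
        write_hits_table(all_hits, out / "probe_hits.tsv")
        write_report_table(hit_reports.values(), out / "probe_report.tsv")
    summaries["categories"].to_csv(out / "summary_categories.tsv", sep="\t", index=False)
    summaries["cluster_positions"].to_csv(
        out / "cluster_positions.tsv", sep="\t", index=False, float_format="%.6f"
    )
    if len(summaries["gentrain"]):
        summaries["gentrain"].to_csv(out / "gentrain_summary.tsv", sep="\t", index=False)

    metadata = {
        "version": __version__,
        "seed": config.seed,
        "stages_run": stages_run,
        "stages_skipped": stages_skipped,
        "flags": flags,
        "n_loci": len(classifications),
        "cluster": dataclasses.asdict(config.cluster),
        "classifier": dataclasses.asdict(config.classifier),
        "scan": dataclasses.asdict(config.scan),
    }
    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=2, sort_keys=True))

    return PipelineResult(
        classifications=classifications,
        genotypes=genotypes,
        hit_reports=hit_reports,
        summaries=summaries,
        metadata=metadata,
        out_dir=out,
    )
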