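"""Summary tables and the end-to-end pipeline: conservation, determinism,
percentage accounting and stage skipping."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest

from conftest import make_cluster_set
from paraprobe.classify import ClassifierConfig, classify_locus
from paraprobe.cluster import ClusterConfig, cluster_locus
from paraprobe.io import write_probe_manifest, ProbeManifestEntry
from paraprobe.pipeline import PipelineConfig, PipelineError, run_pipeline
from paraprobe.probescan import Stringency, categorize_probe, empty_report
from paraprobe.report import (
    cluster_position_table,
    gentrain_by_category,
    summarize_categories,
)
from paraprobe.simulate import (
    Behavior,
    PlantedCopy,
    SimConfig,
    plant_probe_sites,
    simulate_progeny_dataset,
    write_reference_fasta,
)

CFG = ClassifierConfig()


def classify_all(ds):
    out = {}
    for lid, rec in ds.intensities.items():
        out[lid] = classify_locus(cluster_locus(rec, ClusterConfig()), CFG)
    return out


class TestSummaries:
    def test_noise_free_tallies_equal_truth_counts(self):
        config = SimConfig(
            n_loci=40, n_offspring=60, noise_sd=0.0, seed=21,
            mix={Behavior.SINGLE_COPY: 0.5, Behavior.NULL_ALLELE: 0.25,
                 Behavior.TRIALLELIC: 0.25},
        )
        ds = simulate_progeny_dataset(config)
        truth_counts = pd.Series(
            [t.behavior.value for t in ds.truths]
        ).value_counts()
        cls = classify_all(ds)
        tables = summarize_categories(list(cls.values()))
        tally = tables["categories"].groupby("category")["n"].sum()
        assert tally["SINGLE_LOCUS"] == truth_counts["SINGLE_COPY"]
        assert tally["NULL_ALLELE"] == truth_counts["NULL_ALLELE"]
        assert tally["TRIALLELIC"] == truth_counts["TRIALLELIC"]

    def test_percentages_follow_count_over_taxon_total(self):
        """A class of 295 among a 725-probe taxon reads 40.70% in the
        published accounting (1-dp rounding, zero-padded)."""
        cls = []
        taxa = {}
        specs = [("PARALOG", 295), ("OTHER", 430)]
        idx = 0
        for kind, n in specs:
            for _ in range(n):
                lid = f"L{idx:04d}"
                idx += 1
                if kind == "PARALOG":
                    cs = make_cluster_set(
                        [(0.1, 1.0, 30), (0.3, 1.0, 30)], locus_id=lid
                    )
                else:
                    cs = make_cluster_set(
                        [(0.0, 1.0, 30), (0.5, 1.0, 60), (1.0, 1.0, 30)],
                        locus_id=lid,
                    )
                cls.append(classify_locus(cs, CFG))
                taxa[lid] = "Malus"
        tally = summarize_categories(cls, taxa=taxa)["categories"]
        row = tally[tally["category"] == "PARALOG_SHIFT"]
        assert int(row["n"].sum()) == 295
        pct = float(row["pct"].sum())
        assert pct == pytest.approx(40.70, abs=0.02)
        # percentages within the taxon close to 100
        assert tally["pct"].sum() == pytest.approx(100, abs=0.05)

    def test_empty_input_gives_empty_tables(self):
        tables = summarize_categories([])
        assert list(tables["categories"].columns) == [
            "taxon", "category", "ratio", "n", "pct"
        ]
        assert len(tables["categories"]) == 0

    def test_conservation_each_locus_once(self):
        ds = simulate_progeny_dataset(
            SimConfig(n_loci=25, n_offspring=40, seed=3)
        )
        cls = classify_all(ds)
        tables = summarize_categories(list(cls.values()))
        assert int(tables["categories"]["n"].sum()) == 25


class TestClusterPositionTable:
    def test_single_hit_noise_free_loci_near_canonical(self):
        ds = simulate_progeny_dataset(
            SimConfig(n_loci=10, n_offspring=60, noise_sd=0.0, seed=5)
        )
        cls = classify_all(ds)
        from paraprobe.probescan import AlignmentHit

        reports = {
            lid: categorize_probe(
                [AlignmentHit(lid, "chr01", 0, "+", 0, Stringency.FULL50_EXACT)]
            )
            for lid in cls
        }
        table = cluster_position_table(list(cls.values()), hit_reports=reports)
        assert set(table["hit_tag"]) == {"single"}
        dev = np.minimum.reduce(
            [np.abs(table["mean_theta"] - c) for c in (0.0, 0.5, 1.0)]
        )
        assert (dev <= 0.10).all()

    def test_paralog_loci_off_canonical_and_unknown_passthrough(self):
        ds = simulate_progeny_dataset(
            SimConfig(
                n_loci=10, n_offspring=60, noise_sd=0.0, seed=6,
                mix={Behavior.PARALOG_FIXED: 1.0},
            )
        )
        cls = classify_all(ds)
        table = cluster_position_table(list(cls.values()))
        assert set(table["hit_tag"]) == {"unknown"}
        per_locus_far = (
            table.assign(
                far=np.minimum.reduce(
                    [np.abs(table["mean_theta"] - c) for c in (0.0, 0.5, 1.0)]
                ) > 0.10
            ).groupby("snp_id")["far"].any()
        )
        assert per_locus_far.all()


class TestGentrainSummary:
    def _classifications(self):
        specs = {
            "L1": [(0.0, 1.0, 30), (0.5, 1.0, 60), (1.0, 1.0, 30)],
            "L2": [(0.1, 1.0, 30), (0.3, 1.0, 30)],
            "L3": [(0.0, 1.0, 30), (0.5, 1.0, 60), (1.0, 1.0, 30)],
        }
        return [
            classify_locus(make_cluster_set(s, locus_id=lid), CFG)
            for lid, s in specs.items()
        ]

    def test_constant_scores_zero_iqr(self):
        cls = self._classifications()
        df = gentrain_by_category(cls, {"L1": 0.7, "L2": 0.7, "L3": 0.7})
        assert (df["q3"] - df["q1"]).eq(0).all()

    def test_shifted_distributions_recovered_in_medians(self, rng):
        cls = []
        scores = {}
        for i in range(120):
            lid = f"S{i:03d}"
            if i % 2:
                spec = [(0.0, 1.0, 30), (0.5, 1.0, 60), (1.0, 1.0, 30)]
                scores[lid] = float(np.clip(rng.normal(0.8, 0.03), 0, 1))
            else:
                spec = [(0.1, 1.0, 30), (0.3, 1.0, 30)]
                scores[lid] = float(np.clip(rng.normal(0.5, 0.03), 0, 1))
            cls.append(classify_locus(make_cluster_set(spec, locus_id=lid), CFG))
        df = gentrain_by_category(cls, scores).set_index("category")
        assert df.loc["SINGLE_LOCUS", "median"] == pytest.approx(0.8, abs=0.05)
        assert df.loc["PARALOG_SHIFT", "median"] == pytest.approx(0.5, abs=0.05)

    def test_absent_scores_empty_summary_with_warning(self):
        with pytest.warns(UserWarning, match="GenTrain"):
            df = gentrain_by_category(self._classifications(), None)
        assert df.empty


@pytest.fixture
def pipeline_bundle(tmp_path):
    """A 50-locus simulated bundle with manifest + reference for the scan."""
    config = SimConfig(
        n_loci=50, n_offspring=60, seed=33,
        mix={Behavior.SINGLE_COPY: 0.4, Behavior.PARALOG_FIXED: 0.3,
             Behavior.NULL_ALLELE: 0.3},
    )
    ds = simulate_progeny_dataset(config)
    ipath, _ = ds.write(tmp_path / "sim")
    rng = np.random.default_rng(7)
    probes = [
        ProbeManifestEntry(
            lid, "".join(rng.choice(list("ACGT"), size=50)), "Malus"
        )
        for lid in list(ds.intensities)[:10]
    ]
    copies = {
        probes[0].probe_id: [PlantedCopy("chr01")],
        probes[1].probe_id: [PlantedCopy("chr01"), PlantedCopy("chr02")],
    }
    ref, _ = plant_probe_sites(probes, 2, copies, seed=8, chrom_length=3000)
    refpath = tmp_path / "ref.fasta"
    write_reference_fasta(ref, refpath)
    mpath = tmp_path / "manifest.csv"
    write_probe_manifest(probes, mpath)
    return tmp_path, ipath, mpath, refpath


class TestPipeline:
    def test_full_run_outputs_present_and_consistent(self, pipeline_bundle):
        tmp_path, ipath, mpath, refpath = pipeline_bundle
        config = PipelineConfig(
            intensities=str(ipath), manifest=str(mpath),
            reference=str(refpath), out_dir=str(tmp_path / "out"),
            parents=("P1", "P2"),
        )
        result = run_pipeline(config)
        out = result.out_dir
        for name in (
            "clusters.tsv", "classifications.tsv", "genotypes.tsv",
            "probe_hits.tsv", "probe_report.tsv", "summary_categories.tsv",
            "cluster_positions.tsv", "run_metadata.json",
        ):
            assert (out / name).exists(), name
        cls_table = pd.read_csv(out / "classifications.tsv", sep="\t")
        assert len(cls_table) == 50  # every locus exactly once
        assert cls_table["snp_id"].is_unique
        assert int(result.summaries["categories"]["n"].sum()) == 50
        report = pd.read_csv(out / "probe_report.tsv", sep="\t")
        assert len(report) == 10
        meta = json.loads((out / "run_metadata.json").read_text())
        assert "probescan" in meta["stages_run"]
        assert meta["classifier"]["theta_canonical_tol"] == 0.10

    def test_same_config_twice_byte_identical(self, pipeline_bundle):
        tmp_path, ipath, mpath, refpath = pipeline_bundle
        outs = []
        for name in ("o1", "o2"):
            config = PipelineConfig(
                intensities=str(ipath), manifest=str(mpath),
                reference=str(refpath), out_dir=str(tmp_path / name),
            )
            run_pipeline(config)
            outs.append(tmp_path / name)
        for f in sorted(outs[0].iterdir()):
            assert f.read_bytes() == (outs[1] / f.name).read_bytes(), f.name

    def test_classification_only_run_skips_scan(self, pipeline_bundle):
        tmp_path, ipath, *_ = pipeline_bundle
        config = PipelineConfig(
            intensities=str(ipath), out_dir=str(tmp_path / "noscan")
        )
        result = run_pipeline(config)
        assert result.hit_reports == {}
        assert any("probescan" in s for s in result.metadata["stages_skipped"])
        assert not (result.out_dir / "probe_hits.tsv").exists()

    def test_missing_input_fails_with_stage_name(self, tmp_path):
        config = PipelineConfig(
            intensities=str(tmp_path / "nope.tsv"), out_dir=str(tmp_path / "o")
        )
        with pytest.raises(PipelineError, match="setup"):
            run_pipeline(config)
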