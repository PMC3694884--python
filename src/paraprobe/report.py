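"""Summary tables: category tallies, cluster-position tables and
GenTrain-score summaries.

These reproduce the accounting layout of a paralog-aware array re-annotation:
counts and within-taxon percentages by cluster type and segregation ratio,
a cross-tabulation of cluster category against probe-hit multiplicity, the
per-cluster mean Theta/R table split by hit multiplicity (the scatter-plot
substrate), and descriptive summaries of vendor GenTrain scores by category
(scores are consumed as metadata, never computed).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import Category, LocusClassification
from .cluster import ClusterSet
from .probescan import HitCategory, ProbeHitReport, Stringency

__all__ = [
    "summarize_categories",
    "cluster_position_table",
    "gentrain_by_category",
]


def _hit_tag(report: ProbeHitReport | None) -> str:
    if report is None:
        return "unknown"
    cat = report.category[Stringency.FULL50_EXACT]
    if cat is HitCategory.SINGLE:
        return "single"
    if cat in (HitCategory.MULTI_SINGLE_LG, HitCategory.MULTI_MULTI_LG):
        return "multi"
    return "unknown"


def summarize_categories(
    classifications: Sequence[LocusClassification],
    hit_reports: Mapping[str, ProbeHitReport] | None = None,
    taxa: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Tally tables over the classified loci.

    Returns ``{"categories": ..., "crosstab": ...}``.  The category table
    follows the taxon / cluster-type / segregation-ratio layout with
    percentages computed within taxon (count / taxon total x 100); with no
    taxon mapping every locus falls in one "all" group.  The crosstab
    crosses cluster category with full-length hit multiplicity and is empty
    when no hit reports are supplied.
    """
    rows = []
    for cl in classifications:
        taxon = (taxa or {}).get(cl.locus_id, "all")
        rows.append(
            {
                "taxon": taxon,
                "category": cl.category.value,
                "ratio": cl.segregation.ratio,
                "snp_id": cl.locus_id,
            }
        )
    if not rows:
        cat = pd.DataFrame(columns=["taxon", "category", "ratio", "n", "pct"])
        xtab = pd.DataFrame()
        return {"categories": cat, "crosstab": xtab}
    df = pd.DataFrame(rows)
    tally = (
        df.groupby(["taxon", "category", "ratio"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = df.groupby("taxon").size()
    tally["pct"] = [
        round(n / totals[t] * 100, 2) for t, n in zip(tally["taxon"], tally["n"])
    ]

    if hit_reports:
        tags = [_hit_tag(hit_reports.get(cl.locus_id)) for cl in classifications]
        xtab = pd.crosstab(
            pd.Series([cl.category.value for cl in classifications], name="category"),
            pd.Series(tags, name="hits"),
        )
    else:
        xtab = pd.DataFrame()
    return {"categories": tally, "crosstab": xtab}


def cluster_position_table(
    classifications: Sequence[LocusClassification],
    cluster_sets: Mapping[str, ClusterSet] | None = None,
    hit_reports: Mapping[str, ProbeHitReport] | None = None,
) -> pd.DataFrame:
    """Per-cluster mean Theta/R rows tagged single-hit vs multi-hit.

    Loci without scan results are tagged ``unknown`` and passed through.
    """
    rows = []
    for cl in classifications:
        cs = (cluster_sets or {}).get(cl.locus_id, cl.clusters)
        tag = _hit_tag((hit_reports or {}).get(cl.locus_id))
        for idx, c in enumerate(cs.clusters):
            rows.append(
                {
                    "snp_id": cl.locus_id,
                    "cluster_idx": idx,
                    "mean_theta": c.mean_theta,
                    "mean_r": c.mean_r,
                    "n": c.size,
                    "category": cl.category.value,
                    "hit_tag": tag,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id", "cluster_idx", "mean_theta", "mean_r", "n",
            "category", "hit_tag",
        ],
    )


def gentrain_by_category(
    classifications: Sequence[LocusClassification],
    scores: Mapping[str, float] | None,
) -> pd.DataFrame:
    """Descriptive per-category summary (n, median, quartiles) of vendor
    GenTrain scores.  Missing scores reduce n; with no scores at all an
    empty frame is returned with a warning."""
    cols = ["category", "n", "median", "q1", "q3"]
    if not scores:
        warnings.warn("no GenTrain scores available", stacklevel=2)
        return pd.DataFrame(columns=cols)
    rows = []
    by_cat: dict[str, list[float]] = {}
    for cl in classifications:
        s = scores.get(cl.locus_id)
        if s is None or (isinstance(s, float) and np.isnan(s)):
            continue
        by_cat.setdefault(cl.category.value, []).append(float(s))
    for cat in sorted(by_cat):
        vals = np.array(by_cat[cat])
        rows.append(
            {
                "category": cat,
                "n": len(vals),
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25)),
                "q3": float(np.percentile(vals, 75)),
            }
        )
    if not rows:
        warnings.warn("no GenTrain scores available", stacklevel=2)
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)
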