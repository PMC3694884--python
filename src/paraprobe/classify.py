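"""Automatic annotation of per-locus cluster geometries.

Encodes, as a fixed decision cascade, the visual rules an analyst applies
to Infinium cluster plots in a genome of polyploid origin:

1. more than four clusters  -> MULTI_LOCUS (two heterozygous loci under one
   probe);
2. exactly four             -> TRIALLELIC (AB x AC cross);
3. a cluster with mean R below ``r_null_tol`` -> NULL_ALLELE (no probe
   binding for that class; all such clusters are pooled first, because
   Theta carries no information at R ~ 0);
4. two clusters at the same Theta but vertically separated in R
   -> DIVERGENT_SITE (reduced binding efficiency of one haplotype);
5. 2-3 clusters all near the canonical Theta positions {0, 0.5, 1}
   -> SINGLE_LOCUS (one cluster -> MONOMORPHIC);
6. 2-3 clusters otherwise -> PARALOG_SHIFT (probe co-annealing to a
   paralogous site mixes channel signal and pulls Theta off-canonical);
7. overlapping clusters that fit none of the above -> UNSCOREABLE.

Segregation of the retained genotype classes is tested against the
Mendelian candidates 1:1, 3:1 and 1:2:1 by Pearson chi-square goodness of
fit; 3:1 is only entertained for two-class (dominant-style) readouts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import Cluster, ClusterSet

__all__ = [
    "Category",
    "Triage",
    "ClassifierConfig",
    "SegregationFit",
    "LocusClassification",
    "GenotypeCallError",
    "classify_locus",
    "fit_segregation",
    "call_genotypes",
    "triage_germplasm",
    "CANONICAL_THETA",
    "SEGREGATION_CANDIDATES",
]

CANONICAL_THETA = (0.0, 0.5, 1.0)

#: candidate segregation ratios; 3:1 applies only to two-class readouts
SEGREGATION_CANDIDATES: tuple[tuple[str, tuple[int, ...]], ...] = (
    ("1:1", (1, 1)),
    ("3:1", (3, 1)),
    ("1:2:1", (1, 2, 1)),
)


class Category(str, enum.Enum):
    MONOMORPHIC = "MONOMORPHIC"
    SINGLE_LOCUS = "SINGLE_LOCUS"
    PARALOG_SHIFT = "PARALOG_SHIFT"
    DIVERGENT_SITE = "DIVERGENT_SITE"
    NULL_ALLELE = "NULL_ALLELE"
    TRIALLELIC = "TRIALLELIC"
    MULTI_LOCUS = "MULTI_LOCUS"
    UNSCOREABLE = "UNSCOREABLE"


class Triage(str, enum.Enum):
    ROBUST = "ROBUST"
    AMBIGUOUS = "AMBIGUOUS"
    UNSCOREABLE = "UNSCOREABLE"


@dataclass(frozen=True)
class ClassifierConfig:
    """Geometry tolerances (Theta/R units) and the segregation-test level.

    theta_canonical_tol
        max |mean Theta - {0, 0.5, 1}| for a cluster to count as canonical.
    theta_equal_tol
        max Theta difference for two clusters to count as "same Theta".
    r_null_tol
        mean R below this marks a null (non-binding) cluster.
    r_shift_min
        minimum relative R separation, |dR| / max(R), to call a vertical
        shift between same-Theta clusters.
    alpha
        level below which a segregation ratio is rejected.
    germplasm_min_class
        minimum genotype-class size for panel triage to call a locus robust.
    """

    theta_canonical_tol: float = 0.10
    theta_equal_tol: float = 0.05
    r_null_tol: float = 0.05
    r_shift_min: float = 0.3
    alpha: float = 0.05
    germplasm_min_class: int = 3

    def __post_init__(self) -> None:
        for name in (
            "theta_canonical_tol", "theta_equal_tol", "r_null_tol",
            "r_shift_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class SegregationFit:
    ratio: str  # "1:1", "3:1", "1:2:1", "monomorphic", "none"
    statistic: float
    p: float


@dataclass
class LocusClassification:
    locus_id: str
    category: Category
    labels: list[str]            # one per geometry cluster, Theta order
    clusters: ClusterSet
    segregation: SegregationFit
    reason: str = ""
    #: clusters after null pooling — the geometry the labels refer to
    geometry: list[Cluster] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.geometry) if self.geometry else self.clusters.n_clusters


class GenotypeCallError(ValueError):
    """The classification does not support per-sample genotype calls."""


def fit_segregation(
    counts,
    candidates: tuple[tuple[str, tuple[int, ...]], ...] = SEGREGATION_CANDIDATES,
    alpha: float = 0.05,
) -> SegregationFit:
    """Pearson chi-square fit of class counts against candidate ratios.

    ``counts`` must be ordered consistently with the ratio terms (e.g.
    AA, AB, BB against 1:2:1).  Only candidates with matching class number
    are tested; the best fit is the highest p, ties resolved toward the
    candidate listed first (fewer classes first in the default set).
    Returns ratio "none" when every candidate is rejected at ``alpha``.
    """
    counts = [int(c) for c in counts]
    if len(counts) < 2:
        raise ValueError("need at least two class counts")
    total = sum(counts)
    best: SegregationFit | None = None
    for name, ratio in candidates:
        if len(ratio) != len(counts):
            continue
        expected = np.array(ratio, dtype=float) * total / sum(ratio)
        if np.any(expected == 0):
            continue
        stat, p = stats.chisquare(counts, expected)
        if best is None or p > best.p:
            best = SegregationFit(ratio=name, statistic=float(stat), p=float(p))
    if best is None:
        return SegregationFit(ratio="none", statistic=float("nan"), p=float("nan"))
    if best.p < alpha:
        return replace(best, ratio="none")
    return best


def _pool_null(clusters: list[Cluster], tol: float) -> list[Cluster]:
    """Pool clusters hugging the R floor into one null class.

    Theta carries no information when the probe binds nothing, so under
    noise a null class smears across Theta and fragments in the cluster
    engine.  "Approaching zero" is judged on the locus's own intensity
    scale: a cluster is floor-hugging when its mean R is below ``tol`` or
    below 10% of the locus's strongest cluster signal.
    """
    if not clusters:
        return []
    r_max = max(c.mean_r for c in clusters)
    cut = max(tol, 0.1 * r_max)
    nulls = [c for c in clusters if c.mean_r < cut]
    if len(nulls) <= 1:
        return list(clusters)
    members = tuple(sorted(m for c in nulls for m in c.members))
    n = len(members)
    pooled = Cluster(
        members=members,
        mean_theta=sum(c.mean_theta * c.size for c in nulls) / n,
        mean_r=sum(c.mean_r * c.size for c in nulls) / n,
    )
    rest = [c for c in clusters if c.mean_r >= cut]
    return sorted(rest + [pooled], key=lambda c: (c.mean_theta, c.mean_r))


def _nearest_canonical(theta: float) -> tuple[float, float]:
    c = min(CANONICAL_THETA, key=lambda t: abs(theta - t))
    return c, abs(theta - c)


def _base_letter(clusters: list[Cluster]) -> str:
    """A or B side of a divergent/null pattern, from the bound clusters."""
    bound = [c for c in clusters if c.mean_r >= 0.5] or clusters
    theta = float(np.mean([c.mean_theta for c in bound]))
    return "A" if theta < 0.5 else "B"


def classify_locus(
    clusters: ClusterSet, config: ClassifierConfig | None = None
) -> LocusClassification:
    """Assign a cluster-geometry category, genotype labels and a
    segregation ratio to one locus."""
    config = config or ClassifierConfig()
    cs = clusters
    pooled = _pool_null(cs.clusters, config.r_null_tol)

    def result(category, labels, seg=None, reason=""):
        seg = seg or SegregationFit("none", float("nan"), float("nan"))
        return LocusClassification(
            locus_id=cs.locus_id, category=category, labels=labels,
            clusters=cs, segregation=seg, reason=reason, geometry=pooled,
        )

    if not cs.clusters:
        return result(Category.UNSCOREABLE, [], reason="no clusters retained")
    k = len(pooled)
    has_null = any(c.mean_r < config.r_null_tol for c in pooled)

    if k > 4:
        return result(
            Category.MULTI_LOCUS, [f"C{i + 1}" for i in range(k)],
            reason="more than four genotype classes",
        )
    if k == 4:
        return result(
            Category.TRIALLELIC, [f"C{i + 1}" for i in range(k)],
            reason="four genotype classes (three segregating alleles)",
        )

    # counts ordered to match the labels we assign below
    if has_null:
        base = _base_letter(pooled)
        by_r = sorted(pooled, key=lambda c: -c.mean_r)
        if k == 3:
            labels_by_r = [base * 2, base + "n", "nn"]
        elif k == 2:
            labels_by_r = [base + "n", "nn"]
        else:
            labels_by_r = ["nn"]
        order = {id(c): i for i, c in enumerate(by_r)}
        labels = [labels_by_r[order[id(c)]] for c in pooled]
        seg = (
            fit_segregation([c.size for c in by_r], alpha=config.alpha)
            if k >= 2 else SegregationFit("monomorphic", 0.0, 1.0)
        )
        return result(Category.NULL_ALLELE, labels, seg,
                      reason="cluster with R below null tolerance")

    # vertical (R) shift at equal Theta -> divergent probe site
    divergent = False
    overlapping = False
    for i in range(k):
        for j in range(i + 1, k):
            a, b = pooled[i], pooled[j]
            if abs(a.mean_theta - b.mean_theta) <= config.theta_equal_tol:
                rel = abs(a.mean_r - b.mean_r) / max(a.mean_r, b.mean_r)
                if rel >= config.r_shift_min:
                    divergent = True
                else:
                    overlapping = True
    if divergent:
        base = _base_letter(pooled)
        by_r = sorted(pooled, key=lambda c: -c.mean_r)
        prime = base + "'"
        if k == 3:
            labels_by_r = [base * 2, base + prime, prime + prime]
        else:
            labels_by_r = [base * 2, base + prime][:k]
        order = {id(c): i for i, c in enumerate(by_r)}
        labels = [labels_by_r[order[id(c)]] for c in pooled]
        seg = (
            fit_segregation([c.size for c in by_r], alpha=config.alpha)
            if k >= 2 else SegregationFit("monomorphic", 0.0, 1.0)
        )
        return result(Category.DIVERGENT_SITE, labels, seg,
                      reason="same Theta, vertically shifted R")
    if overlapping:
        return result(
            Category.UNSCOREABLE, [f"C{i + 1}" for i in range(k)],
            reason="clusters overlap without clear vertical separation",
        )

    if k == 1:
        c, _ = _nearest_canonical(pooled[0].mean_theta)
        label = {0.0: "AA", 0.5: "AB", 1.0: "BB"}[c]
        return result(
            Category.MONOMORPHIC, [label],
            SegregationFit("monomorphic", 0.0, 1.0),
        )

    canonical = []
    for c in pooled:
        near, dist = _nearest_canonical(c.mean_theta)
        canonical.append(near if dist <= config.theta_canonical_tol else None)
    if all(c is not None for c in canonical) and len(set(canonical)) == k:
        labels = [{0.0: "AA", 0.5: "AB", 1.0: "BB"}[c] for c in canonical]
        seg = fit_segregation([c.size for c in pooled], alpha=config.alpha)
        return result(Category.SINGLE_LOCUS, labels, seg)

    # off-canonical 2-3 clusters: paralog-shifted target classes in
    # Theta order, '*' marking the paralog contribution
    labels = [l + "*" for l in ("AA", "AB", "BB")[:k]]
    seg = fit_segregation([c.size for c in pooled], alpha=config.alpha)
    return result(Category.PARALOG_SHIFT, labels, seg,
                  reason="clusters off canonical Theta positions")


# expected offspring label sets for a codominant single-locus cross
_MENDEL = {
    frozenset({"AA", "AA"}): {"AA"},
    frozenset({"BB", "BB"}): {"BB"},
    frozenset({"AA", "BB"}): {"AB"},
    frozenset({"AA", "AB"}): {"AA", "AB"},
    frozenset({"BB", "AB"}): {"AB", "BB"},
    frozenset({"AB", "AB"}): {"AA", "AB", "BB"},
}


@dataclass
class GenotypeCalls:
    locus_id: str
    genotypes: pd.Series  # sample id -> label ("NC" for no-call)
    flags: list[str]


def call_genotypes(
    classification: LocusClassification,
    clusters: ClusterSet | None = None,
    parents: tuple[str, str] | None = None,
) -> GenotypeCalls:
    """Per-sample genotype labels from a scoreable classification.

    Samples removed by the small-cluster filter get "NC".  When parent
    sample ids are supplied and the locus is single-copy codominant, the
    offspring classes are checked for Mendelian consistency with the
    parental classes; inconsistencies are flagged, never dropped.
    """
    cs = clusters or classification.clusters
    if classification.category in (
        Category.UNSCOREABLE, Category.MULTI_LOCUS, Category.TRIALLELIC,
    ):
        raise GenotypeCallError(
            f"locus {classification.locus_id}: {classification.category.value} "
            "loci could not be assigned genotypic classes for mapping"
        )
    # labels refer to the (possibly null-pooled) geometry; map each raw
    # cluster to the pooled label by membership
    member_label: dict[str, str] = {}
    pooled = classification.geometry or cs.clusters
    for cluster, label in zip(pooled, classification.labels):
        for m in cluster.members:
            member_label[m] = label
    calls = {}
    for c in cs.clusters:
        for m in c.members:
            calls[m] = member_label.get(m, "NC")
    for m in cs.removed:
        calls[m] = "NC"
    series = pd.Series(calls, name=classification.locus_id).sort_index()

    flags: list[str] = []
    if parents is not None:
        p1, p2 = parents
        have = [p in series.index and series[p] != "NC" for p in parents]
        if not all(have):
            flags.append(f"parent(s) missing or no-call at {classification.locus_id}")
        elif classification.category is Category.SINGLE_LOCUS:
            expected = _MENDEL.get(frozenset({series[p1], series[p2]}))
            if expected is None:
                expected = {series[p1], series[p2]}
            observed = {
                g for s, g in series.items()
                if s not in (p1, p2) and g != "NC"
            }
            extra = observed - expected
            if extra:
                flags.append(
                    f"offspring classes {sorted(extra)} not producible from "
                    f"parents {series[p1]} x {series[p2]}"
                )
    return GenotypeCalls(
        locus_id=classification.locus_id, genotypes=series, flags=flags
    )


def triage_germplasm(
    clusters: ClusterSet, config: ClassifierConfig | None = None
) -> Triage:
    """Scoreability triage for a diversity panel (no cross structure):
    ROBUST = 1-3 well-separated clusters, all classes populated, no null;
    AMBIGUOUS = 1-3 clusters with a thin class, a null class or marginal
    separation; UNSCOREABLE = anything beyond three clusters (or none)."""
    config = config or ClassifierConfig()
    k = clusters.n_clusters
    if k == 0 or k > 3:
        return Triage.UNSCOREABLE
    if any(c.mean_r < config.r_null_tol for c in clusters.clusters):
        return Triage.AMBIGUOUS
    if any(c.size < config.germplasm_min_class for c in clusters.clusters):
        return Triage.AMBIGUOUS
    if clusters.removed:
        return Triage.AMBIGUOUS
    for i in range(k):
        for j in range(i + 1, k):
            a, b = clusters.clusters[i], clusters.clusters[j]
            if abs(a.mean_theta - b.mean_theta) <= config.theta_equal_tol:
                rel = abs(a.mean_r - b.mean_r) / max(a.mean_r, b.mean_r)
                if rel < config.r_shift_min:
                    return Triage.AMBIGUOUS
    return Triage.ROBUST
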