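"""Simulation of Infinium-like normalized Theta/R intensity data with truth.

The generator emulates the probe behaviors seen on SNP arrays in genomes of
polyploid origin: clean single-copy biallelic loci, clusters shifted
horizontally (in Theta) by a probe co-annealing to a paralogous site,
clusters shifted vertically (in R) by sequence divergence under the probe
footprint — down to complete null alleles with R ~ 0 — tri-allelic AB x AC
loci, and probes reading out two segregating loci at once.

Signal model
------------
Each annealing site contributes a per-haplotype dose to two channels,

    X = sum_sites sum_haplotypes beta * x_frac(allele) * a_intensity
    Y = likewise with y_frac and b_intensity,

where beta in [0, 1] is the binding efficiency of the haplotype under the
probe (1 = full binding, 0 = null).  Channels are rescaled so a fully bound
heterozygote at every site reads R = 1, then i.i.d. Gaussian noise is added
per channel (and negatives clipped at 0), and

    Theta = arctan2(Y, X) / (pi/2),        R = X + Y.

Allele codes: ``A``/``B`` ordinary alleles; ``D`` a B-type allele whose
probe site has diverged (reduced beta, default 0.3); ``n`` a null allele
(beta = 0); ``C`` a third allele at the assayed position, contributing half
intensity to each channel.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import (
    LocusIntensities,
    ProbeManifestEntry,
    write_intensity_table,
    write_truth_table,
)

__all__ = [
    "Behavior",
    "SignalModel",
    "LocusScenario",
    "TruthRecord",
    "ScenarioError",
    "simulate_locus",
    "default_scenario",
    "SimConfig",
    "SimulatedDataset",
    "simulate_progeny_dataset",
    "reference_mix",
    "PlantedCopy",
    "PlantedSite",
    "plant_probe_sites",
]


class Behavior(str, enum.Enum):
    """Probe-behavior classes planted by the simulator."""

    SINGLE_COPY = "SINGLE_COPY"
    PARALOG_FIXED = "PARALOG_FIXED"
    PARALOG_SEGREGATING = "PARALOG_SEGREGATING"
    DIVERGENT_SITE = "DIVERGENT_SITE"
    NULL_ALLELE = "NULL_ALLELE"
    TRIALLELIC = "TRIALLELIC"
    MULTI_LOCUS = "MULTI_LOCUS"


class ScenarioError(ValueError):
    """A locus scenario is internally inconsistent."""


# channel fractions per allele code: (share on A channel, share on B channel)
_CHANNEL_FRAC: dict[str, tuple[float, float]] = {
    "A": (1.0, 0.0),
    "B": (0.0, 1.0),
    "D": (0.0, 1.0),  # divergent B-type allele
    "n": (0.0, 0.0),  # null: binds nothing
    "C": (0.5, 0.5),  # third allele, splits between channels
}


def _default_betas() -> dict[str, float]:
    return {"A": 1.0, "B": 1.0, "C": 1.0, "D": 0.3, "n": 0.0}


@dataclass(frozen=True)
class SignalModel:
    """Channel intensities, per-allele binding efficiencies and noise."""

    allele_a_intensity: float = 1.0
    allele_b_intensity: float = 1.0
    noise_sd: float = 0.03
    binding_efficiency: Mapping[str, float] = field(default_factory=_default_betas)

    def __post_init__(self) -> None:
        if self.allele_a_intensity <= 0 or self.allele_b_intensity <= 0:
            raise ScenarioError("allele intensities must be positive")
        if self.noise_sd < 0:
            raise ScenarioError("noise_sd must be non-negative")
        for code, beta in self.binding_efficiency.items():
            if not 0.0 <= beta <= 1.0:
                raise ScenarioError(
                    f"binding_efficiency[{code!r}]={beta} outside [0, 1]"
                )

    def beta(self, allele: str) -> float:
        return self.binding_efficiency.get(allele, 1.0)


def _check_genotype(gt: str, fieldname: str) -> None:
    if len(gt) != 2 or any(a not in _CHANNEL_FRAC for a in gt):
        raise ScenarioError(
            f"{fieldname}: {gt!r} is not a two-allele genotype over "
            f"{sorted(_CHANNEL_FRAC)}"
        )


def _is_het(gt: str) -> bool:
    return gt[0] != gt[1]


@dataclass(frozen=True)
class LocusScenario:
    """One simulated locus: a cross, a behavior, and optional paralog site."""

    locus_id: str
    behavior: Behavior
    parent_genotypes: tuple[str, str] = ("AB", "AB")
    n_offspring: int = 180
    paralog_parent_genotypes: tuple[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        p1, p2 = self.parent_genotypes
        _check_genotype(p1, "parent_genotypes")
        _check_genotype(p2, "parent_genotypes")
        if self.n_offspring < 0:
            raise ScenarioError("n_offspring: must be non-negative")
        b = self.behavior
        pp = self.paralog_parent_genotypes
        if pp is not None:
            _check_genotype(pp[0], "paralog_parent_genotypes")
            _check_genotype(pp[1], "paralog_parent_genotypes")
        if b in (
            Behavior.PARALOG_FIXED,
            Behavior.PARALOG_SEGREGATING,
            Behavior.MULTI_LOCUS,
        ):
            if pp is None:
                raise ScenarioError(
                    f"paralog_parent_genotypes: required for behavior {b.value}"
                )
        elif pp is not None:
            raise ScenarioError(
                f"paralog_parent_genotypes: not allowed for behavior {b.value}"
            )
        if b is Behavior.PARALOG_FIXED and pp[0] != pp[1]:
            raise ScenarioError(
                "paralog_parent_genotypes: PARALOG_FIXED requires the same "
                "fixed genotype in both parents (the site does not segregate)"
            )
        if b is Behavior.PARALOG_SEGREGATING and not (
            _is_het(pp[0]) or _is_het(pp[1])
        ):
            raise ScenarioError(
                "paralog_parent_genotypes: PARALOG_SEGREGATING requires a "
                "heterozygous paralog parent"
            )
        if b is Behavior.MULTI_LOCUS and not (
            _is_het(p1) and _is_het(p2) and _is_het(pp[0]) and _is_het(pp[1])
        ):
            raise ScenarioError(
                "parent_genotypes: MULTI_LOCUS requires both parents "
                "heterozygous at both sites"
            )
        if b is Behavior.TRIALLELIC:
            shared = set(p1) & set(p2)
            if not (
                _is_het(p1)
                and _is_het(p2)
                and len(shared) == 1
                and len(set(p1) | set(p2)) == 3
            ):
                raise ScenarioError(
                    "parent_genotypes: TRIALLELIC requires heterozygous "
                    "parents sharing exactly one allele (e.g. AB x AC)"
                )
        if b is Behavior.NULL_ALLELE and "n" not in p1 + p2:
            raise ScenarioError(
                "parent_genotypes: NULL_ALLELE requires a null (n) allele "
                "in a parent"
            )
        if b is Behavior.DIVERGENT_SITE and "D" not in p1 + p2:
            raise ScenarioError(
                "parent_genotypes: DIVERGENT_SITE requires a divergent (D) "
                "allele in a parent"
            )
        if b is Behavior.SINGLE_COPY and set(p1 + p2) - {"A", "B"}:
            raise ScenarioError(
                "parent_genotypes: SINGLE_COPY admits only A/B alleles"
            )


@dataclass
class TruthRecord:
    """Ground truth for one simulated locus, aligned with the samples."""

    locus_id: str
    behavior: Behavior
    sample_ids: list[str]
    target_genotypes: list[str]
    paralog_genotypes: list[str] | None
    beta: list[float]  # mean binding efficiency across target haplotypes

    def rows(self):
        for i, sid in enumerate(self.sample_ids):
            yield {
                "snp_id": self.locus_id,
                "sample_id": sid,
                "behavior": self.behavior.value,
                "target_genotype": self.target_genotypes[i],
                "paralog_genotype": (
                    self.paralog_genotypes[i] if self.paralog_genotypes else "NA"
                ),
                "beta": f"{self.beta[i]:.4f}",
            }


_DEFAULT_CROSSES: dict[Behavior, dict] = {
    Behavior.SINGLE_COPY: dict(parent_genotypes=("AB", "AB")),
    Behavior.PARALOG_FIXED: dict(
        parent_genotypes=("AB", "AB"), paralog_parent_genotypes=("AA", "AA")
    ),
    Behavior.PARALOG_SEGREGATING: dict(
        parent_genotypes=("AA", "AA"), paralog_parent_genotypes=("AB", "AB")
    ),
    Behavior.DIVERGENT_SITE: dict(parent_genotypes=("BD", "BD")),
    Behavior.NULL_ALLELE: dict(parent_genotypes=("Bn", "Bn")),
    Behavior.TRIALLELIC: dict(parent_genotypes=("AB", "AC")),
    Behavior.MULTI_LOCUS: dict(
        parent_genotypes=("AB", "AB"), paralog_parent_genotypes=("AB", "AB")
    ),
}


def default_scenario(
    behavior: Behavior,
    locus_id: str = "SNP_0001",
    n_offspring: int = 180,
    seed: int = 0,
) -> LocusScenario:
    """The canonical cross for each behavior (the study conditions)."""
    kw = _DEFAULT_CROSSES[Behavior(behavior)]
    return LocusScenario(
        locus_id=locus_id,
        behavior=Behavior(behavior),
        n_offspring=n_offspring,
        seed=seed,
        **kw,
    )


def _gametes(gt: str, rng: np.random.Generator, n: int) -> np.ndarray:
    picks = rng.integers(0, 2, size=n)
    return np.array([gt[p] for p in picks])


def _sort_gt(a: str, b: str) -> str:
    order = "ABCDn"
    return "".join(sorted((a, b), key=order.index))


def simulate_locus(
    scenario: LocusScenario, model: SignalModel | None = None
) -> tuple[LocusIntensities, TruthRecord]:
    """Simulate one locus for parents P1, P2 and their offspring.

    Returns the intensity record and the aligned truth record.  The noise
    RNG is seeded from ``scenario.seed`` so output is reproducible.
    """
    model = model or SignalModel()
    rng = np.random.default_rng(scenario.seed)
    n_off = scenario.n_offspring
    sample_ids = ["P1", "P2"] + [f"O{i + 1:03d}" for i in range(n_off)]
    width = max(3, len(str(max(n_off, 1))))
    if width > 3:
        sample_ids = ["P1", "P2"] + [f"O{i + 1:0{width}d}" for i in range(n_off)]

    sites = [scenario.parent_genotypes]
    if scenario.paralog_parent_genotypes is not None:
        sites.append(scenario.paralog_parent_genotypes)

    # per-site genotypes: parents keep theirs, offspring draw one gamete
    # from each parent independently per site; a fixed paralog site is
    # constant across samples (it may be fixed-heterozygous, as in a
    # homeologous duplication)
    site_genotypes: list[list[str]] = []
    for site_idx, (p1, p2) in enumerate(sites):
        if site_idx == 1 and scenario.behavior is Behavior.PARALOG_FIXED:
            gts = [p1] * (n_off + 2)
        else:
            g1 = _gametes(p1, rng, n_off)
            g2 = _gametes(p2, rng, n_off)
            gts = [p1, p2] + [_sort_gt(a, b) for a, b in zip(g1, g2)]
        site_genotypes.append(gts)

    a_int, b_int = model.allele_a_intensity, model.allele_b_intensity
    norm = len(sites) * (a_int + b_int)  # fully-bound het at every site -> R 1
    n = len(sample_ids)
    x = np.zeros(n)
    y = np.zeros(n)
    for gts in site_genotypes:
        for i, gt in enumerate(gts):
            for allele in gt:
                beta = model.beta(allele)
                fx, fy = _CHANNEL_FRAC[allele]
                x[i] += beta * fx * a_int
                y[i] += beta * fy * b_int
    x /= norm
    y /= norm
    if model.noise_sd > 0:
        x = x + rng.normal(0.0, model.noise_sd, size=n)
        y = y + rng.normal(0.0, model.noise_sd, size=n)
    np.clip(x, 0.0, None, out=x)
    np.clip(y, 0.0, None, out=y)
    theta = np.arctan2(y, x) / (np.pi / 2.0)
    r = x + y

    target_gts = site_genotypes[0]
    betas = [
        (model.beta(gt[0]) + model.beta(gt[1])) / 2.0 for gt in target_gts
    ]
    truth = TruthRecord(
        locus_id=scenario.locus_id,
        behavior=scenario.behavior,
        sample_ids=sample_ids,
        target_genotypes=list(target_gts),
        paralog_genotypes=list(site_genotypes[1]) if len(sites) > 1 else None,
        beta=betas,
    )
    rec = LocusIntensities(
        locus_id=scenario.locus_id,
        sample_ids=sample_ids,
        theta=theta,
        r=r,
    )
    return rec, truth


def reference_mix() -> dict[Behavior, float]:
    """Behavior mix mirroring the observed re-annotation proportions
    (202 divergent-site : 616 paralog : 91 four-cluster : 33 multi-locus,
    with the divergent class split into its with-signal and null halves and
    the paralog class split evenly between fixed and segregating sites)."""
    total = 942.0
    return {
        Behavior.DIVERGENT_SITE: 96 / total,
        Behavior.NULL_ALLELE: 106 / total,
        Behavior.PARALOG_FIXED: 308 / total,
        Behavior.PARALOG_SEGREGATING: 308 / total,
        Behavior.TRIALLELIC: 91 / total,
        Behavior.MULTI_LOCUS: 33 / total,
    }


@dataclass(frozen=True)
class SimConfig:
    """Batch simulation settings for a mapping-progeny dataset."""

    n_loci: int = 100
    n_offspring: int = 180
    mix: Mapping[Behavior, float] = field(
        default_factory=lambda: {Behavior.SINGLE_COPY: 1.0}
    )
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ScenarioError("n_loci must be positive")
        total = sum(self.mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ScenarioError(f"mix proportions sum to {total}, not 1")


@dataclass
class SimulatedDataset:
    intensities: dict[str, LocusIntensities]
    truths: list[TruthRecord]
    flags: list[str]

    def write(self, out_prefix: str | Path) -> tuple[Path, Path]:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        ipath = prefix.with_name(prefix.name + ".intensities.tsv")
        tpath = prefix.with_name(prefix.name + ".truth.tsv")
        write_intensity_table(self.intensities.values(), ipath)
        rows = (row for t in self.truths for row in t.rows())
        write_truth_table(rows, tpath)
        return ipath, tpath


def simulate_progeny_dataset(config: SimConfig) -> SimulatedDataset:
    """Simulate a shared parents+offspring panel over a mix of behaviors.

    Deterministic under a fixed seed: the same config writes byte-identical
    files on re-run.
    """
    rng = np.random.default_rng(config.seed)
    behaviors = sorted(config.mix, key=lambda b: b.value)
    probs = np.array([config.mix[b] for b in behaviors], dtype=float)
    probs /= probs.sum()
    draws = rng.choice(len(behaviors), size=config.n_loci, p=probs)
    model = SignalModel(noise_sd=config.noise_sd)

    flags = []
    if config.n_offspring == 0:
        flags.append("parents-only dataset: no offspring simulated")

    intensities: dict[str, LocusIntensities] = {}
    truths: list[TruthRecord] = []
    width = max(5, len(str(config.n_loci)))
    for i, k in enumerate(draws):
        locus_id = f"SNP_{i + 1:0{width}d}"
        seed = int(rng.integers(0, 2**31 - 1))
        scenario = default_scenario(
            behaviors[k], locus_id=locus_id,
            n_offspring=config.n_offspring, seed=seed,
        )
        rec, truth = simulate_locus(scenario, model)
        intensities[locus_id] = rec
        truths.append(truth)
    return SimulatedDataset(intensities=intensities, truths=truths, flags=flags)


# ---------------------------------------------------------------------------
# synthetic reference genomes with planted probe annealing sites

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class PlantedCopy:
    """Where and how to plant one copy of a probe sequence.

    ``mismatch_positions`` are 1-based positions within the 50-mer probe at
    which the planted copy differs from the probe (positions 27..50 fall in
    the 3' 24-mer).
    """

    chrom: str
    strand: str = "+"
    mismatch_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ScenarioError(f"strand {self.strand!r} not in {{+,-}}")
        for p in self.mismatch_positions:
            if not 1 <= p <= 50:
                raise ScenarioError(
                    f"mismatch position {p} outside 1..50"
                )


@dataclass(frozen=True)
class PlantedSite:
    """Truth for one planted annealing site (0-based start, forward coords)."""

    probe_id: str
    chrom: str
    start: int
    strand: str
    mismatch_positions: tuple[int, ...]


_NEXT_BASE = {"A": "C", "C": "G", "G": "T", "T": "A"}


def _mutate(seq: str, positions: Sequence[int]) -> str:
    chars = list(seq)
    for p in positions:
        chars[p - 1] = _NEXT_BASE[chars[p - 1]]
    return "".join(chars)


def plant_probe_sites(
    probes: Sequence[ProbeManifestEntry],
    n_chromosomes: int,
    copies_spec: Mapping[str, Sequence[PlantedCopy]],
    seed: int = 0,
    chrom_length: int = 20000,
) -> tuple[dict[str, str], list[PlantedSite]]:
    """Build a random reference with probe copies planted at known sites.

    Returns (reference dict chrom -> sequence, truth list).  The background
    is re-drawn (deterministically) if it happens to contain an accidental
    exact 50-mer match to any probe.
    """
    by_id = {p.probe_id: p for p in probes}
    for pid in copies_spec:
        if pid not in by_id:
            raise ScenarioError(f"copies_spec names unknown probe {pid!r}")
    chroms = [f"chr{i + 1:02d}" for i in range(n_chromosomes)]
    for pid, copies in copies_spec.items():
        for c in copies:
            if c.chrom not in chroms:
                raise ScenarioError(
                    f"probe {pid}: chromosome {c.chrom!r} not in {chroms}"
                )

    for attempt in range(20):
        rng = np.random.default_rng(seed + attempt)
        ref = {
            c: "".join(rng.choice(list("ACGT"), size=chrom_length))
            for c in chroms
        }
        taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        truth: list[PlantedSite] = []
        ok = True
        for pid in sorted(copies_spec):
            probe = by_id[pid]
            for copy in copies_spec[pid]:
                insert = _mutate(probe.sequence, copy.mismatch_positions)
                if copy.strand == "-":
                    insert = _revcomp(insert)
                # place without overlapping previous insertions
                for _ in range(200):
                    start = int(rng.integers(0, chrom_length - 50))
                    if all(
                        start + 50 <= a or start >= b
                        for a, b in taken[copy.chrom]
                    ):
                        break
                else:  # pragma: no cover - would need a saturated chromosome
                    raise ScenarioError("could not place probe copy")
                s = ref[copy.chrom]
                ref[copy.chrom] = s[:start] + insert + s[start + 50:]
                taken[copy.chrom].append((start, start + 50))
                truth.append(
                    PlantedSite(
                        probe_id=pid,
                        chrom=copy.chrom,
                        start=start,
                        strand=copy.strand,
                        mismatch_positions=tuple(copy.mismatch_positions),
                    )
                )
        # verify no accidental exact 50-mer match beyond the planted ones
        expected_exact: dict[str, int] = {p.probe_id: 0 for p in probes}
        for site in truth:
            if not site.mismatch_positions:
                expected_exact[site.probe_id] += 1
        for p in probes:
            found = 0
            for s in ref.values():
                for query in (p.sequence, _revcomp(p.sequence)):
                    pos = s.find(query)
                    while pos != -1:
                        found += 1
                        pos = s.find(query, pos + 1)
            if found != expected_exact[p.probe_id]:
                ok = False
                break
        if ok:
            return ref, truth
    raise ScenarioError(  # pragma: no cover - vanishingly unlikely
        "could not build a collision-free background"
    )


def write_reference_fasta(reference: Mapping[str, str], path: str | Path) -> None:
    """Write the synthetic reference as FASTA (60-column wrap)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in reference.items()
    ]
    SeqIO.write(records, str(path), "fasta")
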