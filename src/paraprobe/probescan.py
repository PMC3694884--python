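"""Two-stringency matching of 50-mer array probes against a reference.

A probe is searched (a) as a perfect full-length 50-mer and (b) as its
3' 24-mer — the part of the probe closest to the assayed SNP — allowing up
to two substitutions (Hamming distance, no indels: an idealization of a
short-query BLAST at that stringency).  Both strands are searched and hits
deduplicated by (chromosome, start, strand).

The mismatch search seeds on the pigeonhole principle: the 24-mer is split
into max_mismatches+1 chunks, one of which must match exactly; chunk
occurrences are located with plain string search and candidate windows
verified by Hamming count.

Hit multiplicity is then summarized per probe: a single hit, multiple hits
confined to one linkage group (copy-number variation), or hits on several
linkage groups — the signature of paralogous annealing after whole-genome
duplication.  Multi-group hits confined to one homeologous chromosome
group are flagged, with the Malus homeology map (LG pairs 5-10, 3-11,
9-17, 13-16, 6-14 and the groups 4/12/14, 1/7/2, 8/15) shipped as the
packaged default.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import ProbeManifestEntry

__all__ = [
    "Stringency",
    "HitCategory",
    "Placement",
    "ScanConfig",
    "AlignmentHit",
    "ProbeHitReport",
    "HomeologyMap",
    "MALUS_HOMEOLOGY",
    "load_reference_fasta",
    "scan_probe",
    "categorize_probe",
    "compare_map_positions",
    "load_homeology_map",
    "write_hits_table",
    "write_report_table",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class Stringency(str, enum.Enum):
    FULL50_EXACT = "FULL50_EXACT"
    TAIL24_MM2 = "TAIL24_MM2"


class HitCategory(str, enum.Enum):
    NO_HIT = "NO_HIT"
    SINGLE = "SINGLE"
    MULTI_SINGLE_LG = "MULTI_SINGLE_LG"
    MULTI_MULTI_LG = "MULTI_MULTI_LG"


class Placement(str, enum.Enum):
    EXPECTED = "EXPECTED"
    HOMEOLOGOUS = "HOMEOLOGOUS"
    UNEXPECTED = "UNEXPECTED"
    UNPLACED = "UNPLACED"


@dataclass(frozen=True)
class ScanConfig:
    full_length: int = 50
    tail_length: int = 24
    max_tail_mismatches: int = 2
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.tail_length > self.full_length:
            raise ValueError("tail_length must not exceed full_length")
        if self.max_tail_mismatches < 0:
            raise ValueError("max_tail_mismatches must be >= 0")


@dataclass(frozen=True, order=True)
class AlignmentHit:
    """One probe-to-reference match; ``start`` is 0-based half-open on the
    forward strand and spans the matched window (50 or 24 bases)."""

    probe_id: str
    chrom: str
    start: int
    strand: str
    mismatches: int
    stringency: Stringency

    def __post_init__(self) -> None:
        if self.stringency is Stringency.FULL50_EXACT and self.mismatches != 0:
            raise ValueError("FULL50_EXACT hits must have 0 mismatches")


def _normalize_chrom(name: str) -> str:
    """'chr05', 'LG5', '05', 5 -> '5' (shared naming scheme)."""
    s = str(name).strip()
    m = re.fullmatch(r"(?:chr|lg|chromosome)?\s*0*(\d+)", s, flags=re.I)
    if not m:
        raise ValueError(f"cannot normalize chromosome name {name!r}")
    return m.group(1)


@dataclass(frozen=True)
class HomeologyMap:
    """Chromosome groups descending from whole-genome duplication."""

    groups: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        for g in self.groups:
            if len(g) < 2:
                raise ValueError("homeology groups need >= 2 chromosomes")

    @property
    def chromosomes(self) -> frozenset[str]:
        return frozenset(c for g in self.groups for c in g)

    def share_group(self, a: str, b: str) -> bool:
        a, b = _normalize_chrom(a), _normalize_chrom(b)
        return any(a in g and b in g for g in self.groups)

    def contains_set(self, chroms: Iterable[str]) -> bool:
        s = {_normalize_chrom(c) for c in chroms}
        return any(s <= g for g in self.groups)


def _make_map(*groups: Sequence[int]) -> HomeologyMap:
    return HomeologyMap(
        groups=tuple(frozenset(str(c) for c in g) for g in groups)
    )


#: homeologous Malus linkage groups (packaged default)
MALUS_HOMEOLOGY = _make_map(
    (5, 10), (3, 11), (9, 17), (13, 16), (6, 14),
    (4, 12, 14), (1, 7, 2), (8, 15),
)


def load_homeology_map(path: str | Path) -> HomeologyMap:
    """One group per line, comma-separated chromosome names."""
    groups = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        groups.append(frozenset(_normalize_chrom(c) for c in line.split(",")))
    return HomeologyMap(groups=tuple(groups))


def load_reference_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def _find_exact(hay: str, needle: str) -> list[int]:
    out = []
    pos = hay.find(needle)
    while pos != -1:
        out.append(pos)
        pos = hay.find(needle, pos + 1)
    return out


def _hamming_within(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _find_mm(hay: str, needle: str, max_mm: int) -> list[tuple[int, int]]:
    """(start, mismatches) of every window matching within max_mm
    substitutions, via pigeonhole chunk seeding."""
    k = len(needle)
    n_chunks = max_mm + 1
    bounds = [round(i * k / n_chunks) for i in range(n_chunks + 1)]
    candidates: set[int] = set()
    for i in range(n_chunks):
        lo, hi = bounds[i], bounds[i + 1]
        chunk = needle[lo:hi]
        for pos in _find_exact(hay, chunk):
            start = pos - lo
            if 0 <= start <= len(hay) - k:
                candidates.add(start)
    out = []
    for start in sorted(candidates):
        mm = _hamming_within(hay[start:start + k], needle, max_mm)
        if mm <= max_mm:
            out.append((start, mm))
    return out


def scan_probe(
    probe: ProbeManifestEntry,
    reference: Mapping[str, str],
    config: ScanConfig | None = None,
) -> list[AlignmentHit]:
    """All hits of one probe at both stringencies, deduplicated and sorted.

    Probes containing ambiguous bases (N) are skipped with a warning.
    """
    config = config or ScanConfig()
    seq = probe.sequence.upper()
    if "N" in seq:
        warnings.warn(
            f"probe {probe.probe_id}: ambiguous bases, skipped", stacklevel=2
        )
        return []
    if len(seq) != config.full_length:
        raise ValueError(
            f"probe {probe.probe_id}: length {len(seq)} != {config.full_length}"
        )
    tail = seq[-config.tail_length:]
    strands = ("+", "-") if config.both_strands else ("+",)
    hits: set[AlignmentHit] = set()
    for chrom, ref_seq in reference.items():
        ref_seq = ref_seq.upper()
        for strand in strands:
            # a '-' strand hit means the reverse complement of the query
            # occurs on the forward reference
            full_q = seq if strand == "+" else revcomp(seq)
            tail_q = tail if strand == "+" else revcomp(tail)
            for pos in _find_exact(ref_seq, full_q):
                hits.add(AlignmentHit(
                    probe_id=probe.probe_id, chrom=chrom, start=pos,
                    strand=strand, mismatches=0,
                    stringency=Stringency.FULL50_EXACT,
                ))
            for pos, mm in _find_mm(ref_seq, tail_q, config.max_tail_mismatches):
                hits.add(AlignmentHit(
                    probe_id=probe.probe_id, chrom=chrom, start=pos,
                    strand=strand, mismatches=mm,
                    stringency=Stringency.TAIL24_MM2,
                ))
    return sorted(hits)


@dataclass
class ProbeHitReport:
    probe_id: str
    hits: dict[Stringency, list[AlignmentHit]]
    category: dict[Stringency, HitCategory]
    homeolog_flag: bool
    multi_region_count: int


def _category(hits: Sequence[AlignmentHit]) -> HitCategory:
    if not hits:
        return HitCategory.NO_HIT
    if len(hits) == 1:
        return HitCategory.SINGLE
    if len({h.chrom for h in hits}) == 1:
        return HitCategory.MULTI_SINGLE_LG
    return HitCategory.MULTI_MULTI_LG


def categorize_probe(
    hits: Sequence[AlignmentHit],
    homeology: HomeologyMap = MALUS_HOMEOLOGY,
) -> ProbeHitReport:
    """Summarize one probe's hits into multiplicity categories.

    The homeolog flag and region count describe the relaxed (3' 24-mer)
    stringency, where paralogous annealing shows; the flag is set only for
    MULTI_MULTI_LG probes whose hit chromosomes all fall in one homeology
    group.
    """
    if not hits:
        raise ValueError("categorize_probe needs at least the probe's id; "
                         "got an empty hit list (use a report with NO_HIT)")
    probe_id = hits[0].probe_id
    by_str: dict[Stringency, list[AlignmentHit]] = {s: [] for s in Stringency}
    for h in hits:
        by_str[h.stringency].append(h)
    category = {s: _category(by_str[s]) for s in Stringency}
    tail_hits = by_str[Stringency.TAIL24_MM2]
    n_regions = len(tail_hits)
    homeolog = False
    if category[Stringency.TAIL24_MM2] is HitCategory.MULTI_MULTI_LG:
        try:
            homeolog = homeology.contains_set({h.chrom for h in tail_hits})
        except ValueError:
            homeolog = False
    return ProbeHitReport(
        probe_id=probe_id, hits=by_str, category=category,
        homeolog_flag=homeolog, multi_region_count=n_regions,
    )


def empty_report(probe_id: str) -> ProbeHitReport:
    return ProbeHitReport(
        probe_id=probe_id,
        hits={s: [] for s in Stringency},
        category={s: HitCategory.NO_HIT for s in Stringency},
        homeolog_flag=False,
        multi_region_count=0,
    )


def compare_map_positions(
    mapped_lg: str,
    physical_chrom: str | None,
    homeology: HomeologyMap = MALUS_HOMEOLOGY,
) -> Placement:
    """Genetic vs. physical placement of a mapped marker: same chromosome,
    its homeolog, elsewhere, or physically unplaced."""
    if physical_chrom is None or str(physical_chrom).upper() in ("", "NA"):
        return Placement.UNPLACED
    lg = _normalize_chrom(mapped_lg)
    chrom = _normalize_chrom(physical_chrom)
    valid = homeology.chromosomes
    for name, value in (("mapped_lg", lg), ("physical_chrom", chrom)):
        if value not in valid:
            raise ValueError(
                f"{name} {value!r} unknown; valid chromosomes: "
                f"{sorted(valid, key=int)}"
            )
    if lg == chrom:
        return Placement.EXPECTED
    if homeology.share_group(lg, chrom):
        return Placement.HOMEOLOGOUS
    return Placement.UNEXPECTED


def write_hits_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Hits TSV with 1-based inclusive start coordinates."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\tstringency\tchrom\tstart\tstrand\tmismatches\n")
        for h in hits:
            fh.write(
                f"{h.probe_id}\t{h.stringency.value}\t{h.chrom}\t"
                f"{h.start + 1}\t{h.strand}\t{h.mismatches}\n"
            )


def write_report_table(reports: Iterable[ProbeHitReport], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\tcategory50\tcategory24\thomeolog\tn_regions\n")
        for r in reports:
            fh.write(
                f"{r.probe_id}\t{r.category[Stringency.FULL50_EXACT].value}\t"
                f"{r.category[Stringency.TAIL24_MM2].value}\t"
                f"{int(r.homeolog_flag)}\t{r.multi_region_count}\n"
            )
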