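"""Readers and writers for intensity tables, probe manifests and truth tables.

The on-disk dialects are plain text:

* intensity "final report" TSV with header
  ``snp_id  sample_id  theta  r  gtype  gentrain`` (the last two optional,
  ``NA`` allowed anywhere a value is missing);
* probe manifest CSV with header ``probe_id,sequence,taxon,chrom,pos``;
* truth TSV with header
  ``snp_id  sample_id  behavior  target_genotype  paralog_genotype  beta``.

File coordinates are 1-based inclusive (array-manifest convention); the
internal representation is 0-based half-open.  These readers/writers are the
only place the conversion happens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LocusIntensities",
    "ProbeManifestEntry",
    "IntensityFormatError",
    "read_intensity_table",
    "write_intensity_table",
    "read_probe_manifest",
    "write_probe_manifest",
    "write_truth_table",
    "read_truth_table",
]

#: fraction of missing samples above which a locus is flagged unusable
MAX_MISSING_FRACTION = 0.20

INTENSITY_COLUMNS = ("snp_id", "sample_id", "theta", "r", "gtype", "gentrain")
MANIFEST_COLUMNS = ("probe_id", "sequence", "taxon", "chrom", "pos")
TRUTH_COLUMNS = (
    "snp_id",
    "sample_id",
    "behavior",
    "target_genotype",
    "paralog_genotype",
    "beta",
)


class IntensityFormatError(ValueError):
    """A file violated the intensity/manifest dialect."""


@dataclass
class LocusIntensities:
    """All samples' normalized (Theta, R) points for one probe.

    Theta is the angular allele-ratio coordinate in [0, 1]; R the total
    signal intensity (>= 0).  Missing values are NaN in both arrays and
    flagged by :attr:`missing`; they are never silently dropped.
    """

    locus_id: str
    sample_ids: list[str]
    theta: np.ndarray
    r: np.ndarray
    gtype: list[str] | None = None
    gentrain: float | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.sample_ids)
        if self.theta.shape != (n,) or self.r.shape != (n,):
            raise IntensityFormatError(
                f"locus {self.locus_id}: theta/r length does not match "
                f"{n} sample ids"
            )
        if len(set(self.sample_ids)) != n:
            raise IntensityFormatError(
                f"locus {self.locus_id}: duplicate sample ids"
            )
        ok = ~np.isnan(self.theta)
        if np.any((self.theta[ok] < 0) | (self.theta[ok] > 1)):
            raise IntensityFormatError(
                f"locus {self.locus_id}: theta outside [0, 1]"
            )
        okr = ~np.isnan(self.r)
        if np.any(self.r[okr] < 0):
            raise IntensityFormatError(f"locus {self.locus_id}: negative r")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask, True where a sample has no usable intensity."""
        return np.isnan(self.theta) | np.isnan(self.r)

    @property
    def usable(self) -> bool:
        """False when more than 20% of samples are missing."""
        if self.n_samples == 0:
            return False
        return self.missing.mean() <= MAX_MISSING_FRACTION


@dataclass(frozen=True)
class ProbeManifestEntry:
    """One 50-mer array probe with its expected genomic placement.

    ``chrom``/``pos`` may be None for unplaced probes; ``pos`` is stored
    0-based internally.
    """

    probe_id: str
    sequence: str
    taxon: str = ""
    chrom: str | None = None
    pos: int | None = None  # 0-based

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) != 50:
            raise IntensityFormatError(
                f"probe {self.probe_id}: sequence length {len(seq)} != 50"
            )
        if set(seq) - set("ACGTN"):
            raise IntensityFormatError(
                f"probe {self.probe_id}: sequence contains characters "
                f"outside ACGTN"
            )
        if self.pos is not None:
            if self.chrom is None:
                raise IntensityFormatError(
                    f"probe {self.probe_id}: position without chromosome"
                )
            if self.pos < 0:
                raise IntensityFormatError(
                    f"probe {self.probe_id}: negative position"
                )


def _check_header(
    columns: Sequence[str], required: Sequence[str], optional: Sequence[str], path
) -> None:
    missing = [c for c in required if c not in columns]
    if missing:
        raise IntensityFormatError(f"{path}: missing column(s) {missing}")
    unknown = [c for c in columns if c not in (*required, *optional)]
    if unknown:
        warnings.warn(
            f"{path}: ignoring unknown column(s) {unknown}", stacklevel=3
        )


def read_intensity_table(path: str | Path) -> dict[str, LocusIntensities]:
    """Read a final-report-dialect TSV into per-locus records.

    Returns a dict keyed by locus id, in file order.  Raises
    :class:`IntensityFormatError` naming the offending data row (1-based,
    header = row 1) for out-of-range values.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype={"snp_id": str, "sample_id": str},
        na_values=["NA"], keep_default_na=True,
    )
    _check_header(df.columns, INTENSITY_COLUMNS[:4], INTENSITY_COLUMNS[4:], path)

    theta = pd.to_numeric(df["theta"], errors="coerce")
    r = pd.to_numeric(df["r"], errors="coerce")
    bad = theta.notna() & ((theta < 0) | (theta > 1))
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise IntensityFormatError(
            f"{path}: row {row}: theta={theta[bad.idxmax()]} outside [0, 1]"
        )
    badr = r.notna() & (r < 0)
    if badr.any():
        row = int(badr.idxmax()) + 2
        raise IntensityFormatError(f"{path}: row {row}: negative r")

    out: dict[str, LocusIntensities] = {}
    df = df.assign(_theta=theta, _r=r)
    for locus_id, grp in df.groupby("snp_id", sort=False):
        gtype = None
        if "gtype" in grp.columns and grp["gtype"].notna().any():
            gtype = ["NC" if pd.isna(g) else str(g) for g in grp["gtype"]]
        gentrain = None
        if "gentrain" in grp.columns:
            scores = pd.to_numeric(grp["gentrain"], errors="coerce").dropna()
            if len(scores):
                gentrain = float(scores.iloc[0])
        out[str(locus_id)] = LocusIntensities(
            locus_id=str(locus_id),
            sample_ids=[str(s) for s in grp["sample_id"]],
            theta=grp["_theta"].to_numpy(),
            r=grp["_r"].to_numpy(),
            gtype=gtype,
            gentrain=gentrain,
        )
    return out


def write_intensity_table(
    records: Iterable[LocusIntensities], path: str | Path
) -> None:
    """Write records back to the final-report dialect, 6 decimals."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(INTENSITY_COLUMNS) + "\n")
        for rec in records:
            gts = rec.gtype or ["NA"] * rec.n_samples
            gscore = "NA" if rec.gentrain is None else f"{rec.gentrain:.4f}"
            for i, sid in enumerate(rec.sample_ids):
                th = "NA" if np.isnan(rec.theta[i]) else f"{rec.theta[i]:.6f}"
                rr = "NA" if np.isnan(rec.r[i]) else f"{rec.r[i]:.6f}"
                fh.write(
                    f"{rec.locus_id}\t{sid}\t{th}\t{rr}\t{gts[i]}\t{gscore}\n"
                )


def read_probe_manifest(path: str | Path) -> list[ProbeManifestEntry]:
    """Read the probe manifest CSV; sequences are upper-cased and length- and
    alphabet-checked.  File positions are 1-based and converted to 0-based."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"probe_id": str, "chrom": str}, na_values=["NA"])
    _check_header(df.columns, MANIFEST_COLUMNS[:2], MANIFEST_COLUMNS[2:], path)
    entries = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            pos = None
            if "pos" in df.columns and not pd.isna(getattr(row, "pos", None)):
                pos1 = int(row.pos)
                if pos1 < 1:
                    raise IntensityFormatError("position < 1")
                pos = pos1 - 1
            chrom = None
            if "chrom" in df.columns and not pd.isna(getattr(row, "chrom", None)):
                chrom = str(row.chrom)
            entries.append(
                ProbeManifestEntry(
                    probe_id=str(row.probe_id),
                    sequence=str(row.sequence),
                    taxon="" if pd.isna(getattr(row, "taxon", "")) else str(getattr(row, "taxon", "")),
                    chrom=chrom,
                    pos=pos,
                )
            )
        except IntensityFormatError as err:
            raise IntensityFormatError(f"{path}: row {i + 2}: {err}") from None
    return entries


def write_probe_manifest(
    entries: Iterable[ProbeManifestEntry], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(MANIFEST_COLUMNS) + "\n")
        for e in entries:
            chrom = e.chrom if e.chrom is not None else "NA"
            pos = str(e.pos + 1) if e.pos is not None else "NA"
            fh.write(f"{e.probe_id},{e.sequence},{e.taxon},{chrom},{pos}\n")


def write_truth_table(rows: Iterable[Mapping], path: str | Path) -> None:
    """Write simulator ground truth; ``rows`` are mappings with the
    TRUTH_COLUMNS keys."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in TRUTH_COLUMNS) + "\n")


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"snp_id": str, "sample_id": str})
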