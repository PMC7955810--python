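"""Peptide-level deuterium-uptake ingestion and bookkeeping.

Hydrogen-deuterium exchange mass spectrometry (HDX-MS) reports, for every
proteolytic peptide, the centroid mass of its isotope cluster after a series
of labeling times in D2O buffer.  This module handles the arithmetic between
raw centroids and the quantities downstream statistics consume:

* theoretical maximum deuteration (``compute_max_deuteration``),
* neutral centroid mass from an isotope cluster (``centroid_of_cluster``),
* deuterium incorporation #D relative to the undeuterated reference
  (``incorporation``),
* the buffer-D2O-fraction correction that converts #D into a percentage of
  the theoretical maximum (``apply_correction``),
* a plain-text CSV dialect for replicate-level uptake tables
  (``write_uptake_csv`` / ``parse_uptake_csv``).

No back-exchange correction is applied anywhere: uptake values are relative,
with the D2O fraction of the labeling buffer as the only correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "PROTON_MASS",
    "STANDARD_AA",
    "Peptide",
    "UptakeStat",
    "CorrectionConfig",
    "UptakeDataset",
    "compute_max_deuteration",
    "exchangeable_positions",
    "centroid_of_cluster",
    "incorporation",
    "apply_correction",
    "write_uptake_csv",
    "parse_uptake_csv",
    "read_fasta_sequence",
]

#: Mass of a proton in Da (CODATA), used for m/z -> neutral mass conversion.
PROTON_MASS = 1.00727646688

#: The twenty standard one-letter amino-acid codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Number of N-terminal residues of a peptide with no observable amide
#: deuteron: residue 1 has no backbone amide proton after digestion and
#: residue 2 back-exchanges too fast to retain label.
N_TERM_EXCLUDED = 2

MAXD_CONVENTION = "N-2-prolines(pos>=3)"


def compute_max_deuteration(sequence: str, n_term_excluded: int = N_TERM_EXCLUDED) -> int:
    """Theoretical maximum deuterium incorporation (Max D) of a peptide.

    Max D counts the exchangeable backbone amides: every residue except the
    first ``n_term_excluded`` N-terminal positions and every proline (which
    has no amide hydrogen).

    Parameters
    ----------
    sequence : str
        Peptide sequence in one-letter code (standard residues only).
    n_term_excluded : int
        How many N-terminal positions to exclude (default 2: no amide on
        residue 1, fast back-exchange on residue 2).

    Raises
    ------
    ValueError
        If the sequence is empty or contains a non-standard letter.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    seq = sequence.upper()
    for ch in seq:
        if ch not in STANDARD_AA:
            raise ValueError(f"non-standard amino-acid letter {ch!r} in sequence")
    n = len(seq)
    prolines = sum(1 for i, ch in enumerate(seq, start=1) if ch == "P" and i > n_term_excluded)
    return max(0, n - n_term_excluded - prolines)


def exchangeable_positions(
    sequence: str, start: int = 1, n_term_excluded: int = N_TERM_EXCLUDED
) -> list[int]:
    """Positions (1-based, in the parent protein numbering when ``start`` is
    the peptide's first residue number) that carry an observable amide
    deuteron under the Max-D convention: peptide-local position greater than
    ``n_term_excluded`` and not a proline."""
    seq = sequence.upper()
    out = []
    for local, ch in enumerate(seq, start=1):
        if local <= n_term_excluded or ch == "P":
            continue
        out.append(start + local - 1)
    return out


@dataclass(frozen=True)
class Peptide:
    """An identified proteolytic peptide.

    Residue numbering is 1-based inclusive (``start``..``end``) in the parent
    protein; ``max_d`` is the theoretical maximum deuteration computed from
    the sequence unless supplied.
    """

    start: int
    end: int
    sequence: str
    charge: int = 1
    retention_time: float = 0.0
    max_d: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"require 1 <= start <= end, got {self.start}..{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match span "
                f"{self.start}..{self.end}"
            )
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.max_d is None:
            object.__setattr__(self, "max_d", compute_max_deuteration(self.sequence))
        if not (0 <= self.max_d <= max(0, len(self.sequence) - 1)):
            raise ValueError(f"max_d {self.max_d} out of range for {self.sequence!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def central_residue(self) -> float:
        return (self.start + self.end) / 2.0

    def exchangeable_residues(self) -> list[int]:
        """Protein-numbered residues of this peptide with observable amides."""
        return exchangeable_positions(self.sequence, start=self.start)

    def key(self) -> tuple[int, int, str, int]:
        return (self.start, self.end, self.sequence, self.charge)


def centroid_of_cluster(
    mz_intensity_pairs: Sequence[tuple[float, float]], charge: int
) -> float:
    """Neutral mass (Da) from the intensity-weighted centroid of an isotope
    cluster.

    The centroid m/z is the intensity-weighted mean of the peak positions;
    the neutral mass is ``(centroid_mz - proton_mass) * charge``.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    pairs = list(mz_intensity_pairs)
    if not pairs:
        raise ValueError("isotope cluster must contain at least one peak")
    mz = np.asarray([p[0] for p in pairs], dtype=float)
    inten = np.asarray([p[1] for p in pairs], dtype=float)
    if np.any(inten < 0):
        raise ValueError("negative peak intensity")
    total = inten.sum()
    if total <= 0:
        raise ValueError("all-zero intensities: centroid undefined")
    centroid_mz = float(np.dot(mz, inten) / total)
    return (centroid_mz - PROTON_MASS) * charge


def incorporation(mass_t: float, mass_ref: float) -> float:
    """Deuterium incorporation #D = labeled centroid mass minus the
    undeuterated reference mass, in Da.  Slightly negative values from mass
    noise are preserved (not clipped) so replicate statistics stay unbiased."""
    return float(mass_t) - float(mass_ref)


@dataclass(frozen=True)
class UptakeStat:
    """Replicate-aggregated deuterium incorporation for one peptide, state,
    and labeling time."""

    mean_d: float
    sd_d: float
    n: int
    pct_d: float = math.nan

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd_d < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class CorrectionConfig:
    """Buffer-D2O-fraction correction.

    ``d2o_fraction`` is the D2O fraction of the labeling buffer (0.62 for the
    mutant comparisons, 0.755 for the inhibitor screens).  ``apply_to``
    selects whether only %D is put on the corrected scale (default) or the
    deuteron counts are divided by the fraction as well.
    """

    d2o_fraction: float
    apply_to: Literal["percent_only", "percent_and_deuterons"] = "percent_only"

    def __post_init__(self) -> None:
        if not (0.0 < self.d2o_fraction <= 1.0):
            raise ValueError("d2o_fraction must be in (0, 1]")
        if self.apply_to not in ("percent_only", "percent_and_deuterons"):
            raise ValueError(f"unknown apply_to {self.apply_to!r}")


def apply_correction(stat: UptakeStat, peptide: Peptide, cfg: CorrectionConfig) -> UptakeStat:
    """Fill in %D (and optionally rescale #D) using the buffer D2O fraction.

    pct_D = 100 * mean_D / (maxD * f).  A peptide with maxD = 0 has no
    defined percentage; pct_d is NaN so such peptides are excluded from
    percent-based significance tests.
    """
    f = cfg.d2o_fraction
    if peptide.max_d == 0:
        pct = math.nan
    else:
        pct = 100.0 * stat.mean_d / (peptide.max_d * f)
    mean_d, sd_d = stat.mean_d, stat.sd_d
    if cfg.apply_to == "percent_and_deuterons":
        mean_d, sd_d = mean_d / f, sd_d / f
    return UptakeStat(mean_d=mean_d, sd_d=sd_d, n=stat.n, pct_d=pct)


# ---------------------------------------------------------------------------
# Dataset container and CSV dialect
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ["Sequence", "S", "E", "Z", "Max D", "RT", "State", "Exposure", "Replicate"]
_VALUE_COLUMNS = ("#D", "Centroid Mass")


@dataclass
class UptakeDataset:
    """Replicate-level uptake records for one or more states.

    ``records`` holds one row per (peptide, state, timepoint, replicate) with
    columns: start, end, sequence, charge, max_d, retention_time, state,
    timepoint, replicate, num_deuterons.  ``metadata`` carries at least the
    buffer ``d2o_fraction`` and the Max-D convention string.
    """

    peptides: list[Peptide]
    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        needed = {
            "start", "end", "sequence", "charge", "max_d",
            "retention_time", "state", "timepoint", "replicate", "num_deuterons",
        }
        missing = needed - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")

    @property
    def d2o_fraction(self) -> float:
        return float(self.metadata.get("d2o_fraction", 1.0))

    def states(self) -> list[str]:
        return sorted(self.records["state"].unique())

    def timepoints(self) -> list[float]:
        return sorted(self.records["timepoint"].unique())

    def subset_state(self, state: str) -> "UptakeDataset":
        """Single-state view of a multi-state dataset (shares metadata)."""
        if state not in self.states():
            raise ValueError(f"state {state!r} not in dataset (have {self.states()})")
        recs = self.records[self.records["state"] == state].reset_index(drop=True)
        return UptakeDataset(peptides=list(self.peptides), records=recs,
                             metadata=dict(self.metadata))

    def replicate_values(self, peptide: Peptide, state: str, timepoint: float) -> np.ndarray:
        r = self.records
        sel = (
            (r["start"] == peptide.start)
            & (r["end"] == peptide.end)
            & (r["charge"] == peptide.charge)
            & (r["state"] == state)
            & (r["timepoint"] == timepoint)
        )
        return r.loc[sel, "num_deuterons"].to_numpy(dtype=float)

    def aggregate(self, correction: CorrectionConfig | None = None) -> pd.DataFrame:
        """Per (peptide, state, timepoint) mean/sd/n, with %D when a
        correction config (or a metadata d2o_fraction) is available."""
        if correction is None:
            correction = CorrectionConfig(d2o_fraction=self.d2o_fraction)
        by_key = {p.key(): p for p in self.peptides}
        rows = []
        grouped = self.records.groupby(
            ["start", "end", "sequence", "charge", "state", "timepoint"], sort=True
        )
        for (s, e, seq, z, state, t), grp in grouped:
            vals = grp["num_deuterons"].to_numpy(dtype=float)
            pep = by_key.get((s, e, seq, z)) or Peptide(s, e, seq, z)
            stat = UptakeStat(
                mean_d=float(vals.mean()),
                sd_d=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                n=len(vals),
            )
            stat = apply_correction(stat, pep, correction)
            rows.append(
                dict(start=s, end=e, sequence=seq, charge=z, max_d=pep.max_d,
                     state=state, timepoint=t, mean_d=stat.mean_d, sd_d=stat.sd_d,
                     n=stat.n, pct_d=stat.pct_d)
            )
        return pd.DataFrame(rows)

    def equals(self, other: "UptakeDataset") -> bool:
        a = self.records.sort_values(
            ["start", "end", "charge", "state", "timepoint", "replicate"]
        ).reset_index(drop=True)
        b = other.records.sort_values(
            ["start", "end", "charge", "state", "timepoint", "replicate"]
        ).reset_index(drop=True)
        if set(a.columns) != set(b.columns) or len(a) != len(b):
            return False
        return bool(np.allclose(a["num_deuterons"], b["num_deuterons"], atol=1e-9)) and all(
            (a[c] == b[c]).all() for c in ("start", "end", "sequence", "charge", "state", "replicate")
        ) and np.allclose(a["timepoint"], b["timepoint"])


def write_uptake_csv(dataset: UptakeDataset, path: str | Path) -> None:
    """Write a replicate-level uptake table.

    The dialect is RFC-4180 comma-separated UTF-8 with a metadata block of
    '#'-prefixed lines (buffer D2O fraction and Max-D convention) followed by
    a header row: Sequence, S, E, Z, Max D, RT, State, Exposure, Replicate, #D.
    """
    path = Path(path)
    meta = dict(dataset.metadata)
    meta.setdefault("maxd_convention", MAXD_CONVENTION)
    lines = [f"# {k} = {v}" for k, v in sorted(meta.items())]
    df = dataset.records.copy()
    out = pd.DataFrame(
        {
            "Sequence": df["sequence"],
            "S": df["start"],
            "E": df["end"],
            "Z": df["charge"],
            "Max D": df["max_d"],
            "RT": df["retention_time"],
            "State": df["state"],
            "Exposure": df["timepoint"],
            "Replicate": df["replicate"],
            "#D": df["num_deuterons"],
        }
    )
    with path.open("w", encoding="utf-8", newline="") as fh:
        for line in lines:
            fh.write(line + "\n")
        out.to_csv(fh, index=False)


def parse_uptake_csv(path: str | Path) -> UptakeDataset:
    """Parse the CSV dialect written by :func:`write_uptake_csv`.

    Raises ``ValueError`` naming missing required columns, rows with missing
    required fields (with their line numbers), and duplicate (peptide,
    charge, state, timepoint, replicate) rows (citing both line numbers).
    """
    path = Path(path)
    metadata: dict = {}
    header_line = 0
    with path.open("r", encoding="utf-8") as fh:
        raw = fh.readlines()
    data_lines = []
    for i, line in enumerate(raw, start=1):
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                metadata[k.strip()] = _coerce(v.strip())
            continue
        if not data_lines:
            header_line = i
        data_lines.append((i, line))
    if not data_lines:
        raise ValueError(f"{path}: no header row found")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(line for _, line in data_lines)))
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    value_col = next((c for c in _VALUE_COLUMNS if c in df.columns), None)
    if value_col is None:
        raise ValueError(f"{path}: need one of {_VALUE_COLUMNS!r}")

    # line number of each data row in the original file
    line_numbers = np.array([ln for ln, _ in data_lines[1:]])
    bad = df[_REQUIRED_COLUMNS + [value_col]].isna().any(axis=1)
    if bad.any():
        rows = ", ".join(str(line_numbers[i]) for i in np.flatnonzero(bad.to_numpy()))
        raise ValueError(f"{path}: rows with missing required fields at line(s) {rows}")

    dup_key = df[["S", "E", "Sequence", "Z", "State", "Exposure", "Replicate"]]
    dupes = dup_key.duplicated(keep=False)
    if dupes.any():
        msgs = []
        for key, sub in df[dupes].groupby(list(dup_key.columns)):
            lns = ", ".join(str(line_numbers[i]) for i in sub.index)
            msgs.append(f"{key} at lines {lns}")
        raise ValueError(f"{path}: duplicate replicate row(s): " + "; ".join(msgs))

    records = pd.DataFrame(
        {
            "start": df["S"].astype(int),
            "end": df["E"].astype(int),
            "sequence": df["Sequence"].astype(str),
            "charge": df["Z"].astype(int),
            "max_d": df["Max D"].astype(int),
            "retention_time": df["RT"].astype(float),
            "state": df["State"].astype(str),
            "timepoint": df["Exposure"].astype(float),
            "replicate": df["Replicate"].astype(int),
            "num_deuterons": df[value_col].astype(float),
        }
    )
    peptides = sorted(
        {
            Peptide(int(s), int(e), seq, int(z), float(rt), int(md))
            for s, e, seq, z, rt, md in zip(
                records["start"], records["end"], records["sequence"],
                records["charge"], records["retention_time"], records["max_d"],
            )
        },
        key=lambda p: p.key(),
    )
    return UptakeDataset(peptides=peptides, records=records, metadata=metadata)


def _coerce(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def read_fasta_sequence(path: str | Path) -> str:
    """First record of a FASTA file as an upper-case one-letter string."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq).upper()
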