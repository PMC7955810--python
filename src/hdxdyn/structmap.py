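"""Project peptide-level HDX differences onto a structure via B-factors.

Significant exchange differences are resolved to per-residue values and
written into the B-factor column of a PDB file so any molecular viewer can
color the structure by them.  Residues without peptide coverage carry an
explicit "no data" sentinel (default -1.00) distinct from a genuine zero.
Everything outside the B-factor field (columns 61–66) is preserved
byte-for-byte, so the output diffs cleanly against the input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

from .differential import ComparisonResult, DifferenceRecord, peptide_significance

__all__ = [
    "ResidueValue",
    "ResidueValueMap",
    "DEFAULT_BINS",
    "assign_bin",
    "residues_from_peptides",
    "write_bfactor_pdb",
    "read_bfactors",
    "BFactorReport",
]

#: Default category bin edges in %: strong/moderate/weak decreases below
#: -5%, mirrored increases above +5%.  Configurable — numeric edges are a
#: package choice, not a community standard.
DEFAULT_BINS = (-25.0, -15.0, -5.0, 5.0, 15.0, 25.0)

_BIN_LABELS = (
    "decrease_strong", "decrease_moderate", "decrease_weak",
    "no_change", "increase_weak", "increase_moderate", "increase_strong",
)


def assign_bin(value: float, edges: Sequence[float] = DEFAULT_BINS) -> str:
    """Category label for a signed %-difference under the given bin edges."""
    labels = _BIN_LABELS if len(edges) == len(_BIN_LABELS) - 1 else tuple(
        f"bin{i}" for i in range(len(edges) + 1)
    )
    for i, edge in enumerate(edges):
        if value <= edge:
            return labels[i]
    return labels[-1]


@dataclass(frozen=True)
class ResidueValue:
    value: float
    peptide: tuple[int, int]  # provenance span
    category: str


@dataclass
class ResidueValueMap:
    """One signed value per covered residue (author numbering); residues
    absent from coverage are simply absent, never stored as 0."""

    values: dict[int, ResidueValue] = field(default_factory=dict)
    units: str = "%"

    def __contains__(self, resid: int) -> bool:
        return resid in self.values

    def __getitem__(self, resid: int) -> ResidueValue:
        return self.values[resid]

    def residues(self) -> list[int]:
        return sorted(self.values)

    def as_plain_dict(self) -> dict[int, float]:
        return {r: v.value for r, v in self.values.items()}


def residues_from_peptides(
    comparison: ComparisonResult | Sequence[DifferenceRecord],
    rule: Literal["max-abs", "shortest-peptide"] = "max-abs",
    span: Literal["full", "exchangeable"] = "full",
    bin_edges: Sequence[float] = DEFAULT_BINS,
) -> ResidueValueMap:
    """Resolve significant peptide-level differences to per-residue values.

    Each significant peptide (any timepoint passing) carries the signed
    delta_pct of its largest-|delta_pct| passing timepoint.  When several
    significant peptides cover a residue, ``max-abs`` keeps the value of
    largest magnitude; ``shortest-peptide`` prefers the shortest covering
    peptide (higher spatial resolution), breaking ties by magnitude.  The
    value is painted over the peptide's full residue interval by default
    (matching how peptide-level differences are usually colored on
    structures); ``span="exchangeable"`` restricts it to the residues that
    actually carry observable amides.
    """
    records = comparison.records if isinstance(comparison, ComparisonResult) else list(comparison)
    by_pep: dict[tuple, list[DifferenceRecord]] = {}
    for r in records:
        by_pep.setdefault(r.peptide.key(), []).append(r)

    candidates = []  # (peptide, value)
    for recs in by_pep.values():
        if peptide_significance(recs) == "none":
            continue
        passing = [r for r in recs if r.passes and not math.isnan(r.delta_pct)]
        best = max(passing, key=lambda r: abs(r.delta_pct))
        candidates.append((recs[0].peptide, best.delta_pct))

    out = ResidueValueMap()
    for pep, value in candidates:
        residues = (
            range(pep.start, pep.end + 1) if span == "full" else pep.exchangeable_residues()
        )
        for resid in residues:
            incumbent = out.values.get(resid)
            if incumbent is None:
                take = True
            elif rule == "max-abs":
                take = abs(value) > abs(incumbent.value)
            elif rule == "shortest-peptide":
                inc_len = incumbent.peptide[1] - incumbent.peptide[0]
                new_len = pep.end - pep.start
                take = new_len < inc_len or (new_len == inc_len and abs(value) > abs(incumbent.value))
            else:
                raise ValueError(f"unknown rule {rule!r}")
            if take:
                out.values[resid] = ResidueValue(value, (pep.start, pep.end), assign_bin(value, bin_edges))
    return out


@dataclass
class BFactorReport:
    n_atoms_written: int
    n_residues_matched: int
    n_map_residues_unmatched: int
    unmatched_residues: list[int]


def write_bfactor_pdb(
    structure_pdb: str | Path,
    out_path: str | Path,
    value_map: ResidueValueMap,
    chain: str,
    sentinel: float = -1.0,
    legend_path: str | Path | None = None,
    bin_edges: Sequence[float] = DEFAULT_BINS,
) -> BFactorReport:
    """Write per-residue values into the B-factor column of a PDB file.

    Only the B-factor field (columns 61–66, %6.2f) of ATOM/HETATM records in
    the selected chain is rewritten: mapped residues get their value,
    unmapped residues the sentinel.  All other bytes — coordinates,
    occupancies, headers, other chains — are copied unchanged, so writing
    the same map twice is byte-idempotent.  Insertion codes are unsupported
    (error).  If more than half of the map's residues are absent from the
    chain, the residue numbering is presumed mismatched and a hard error is
    raised.  A JSON legend sidecar recording the category bins is written
    when ``legend_path`` is given.
    """
    structure_pdb, out_path = Path(structure_pdb), Path(out_path)
    text = structure_pdb.read_bytes().decode("latin-1")
    lines = text.splitlines(keepends=True)
    seen_residues: set[int] = set()
    n_atoms = 0
    out_lines = []
    for line in lines:
        if line.startswith(("ATOM  ", "HETATM")) and len(line.rstrip("\r\n")) >= 66 \
                and line[21] == chain:
            icode = line[26]
            if icode not in (" ", ""):
                raise ValueError(
                    f"insertion code {icode!r} at residue {line[22:26].strip()}: unsupported"
                )
            resid = int(line[22:26])
            seen_residues.add(resid)
            value = value_map[resid].value if resid in value_map else sentinel
            line = line[:60] + f"{value:6.2f}" + line[66:]
            n_atoms += 1
        out_lines.append(line)

    map_residues = set(value_map.residues())
    unmatched = sorted(map_residues - seen_residues)
    if map_residues and len(unmatched) > 0.5 * len(map_residues):
        raise ValueError(
            f"{len(unmatched)} of {len(map_residues)} mapped residues absent from "
            f"chain {chain}: residue numbering mismatch"
        )
    out_path.write_bytes("".join(out_lines).encode("latin-1"))

    if legend_path is not None:
        legend = {
            "units": value_map.units,
            "sentinel_no_data": sentinel,
            "bin_edges": list(bin_edges),
            "bin_labels": list(_BIN_LABELS),
            "chain": chain,
            "n_residues_mapped": len(map_residues),
        }
        Path(legend_path).write_text(json.dumps(legend, indent=2), encoding="utf-8")
    return BFactorReport(
        n_atoms_written=n_atoms,
        n_residues_matched=len(map_residues & seen_residues),
        n_map_residues_unmatched=len(unmatched),
        unmatched_residues=unmatched,
    )


def read_bfactors(pdb_path: str | Path, chain: str) -> dict[int, float]:
    """Per-residue B-factor read-back (first atom of each residue) for
    round-trip checks of :func:`write_bfactor_pdb`."""
    out: dict[int, float] = {}
    for line in Path(pdb_path).read_text(encoding="latin-1").splitlines():
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 66 and line[21] == chain:
            resid = int(line[22:26])
            out.setdefault(resid, float(line[60:66]))
    return out
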