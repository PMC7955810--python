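"""Synthetic exchange-kinetics datasets and toy coordinate ensembles.

The generator produces ground-truth HDX-MS datasets with the statistical
structure the downstream analysis assumes: an overlapping peptide map, a
3–3000 s time course in triplicate, sub-Dalton centroid mass noise, and two
conditions differing only by localized changes in protection.  Exchange
follows Linderstrøm-Lang EX2 kinetics: each exchangeable amide i exchanges
with rate k_i = k_int / PF_i, so a peptide's noiseless deuterium content at
labeling time t is

    D(t) = f * sum_i (1 - exp(-k_i * t))

where f is the buffer D2O fraction and the sum runs over the peptide's
observable amides (peptide-local position >= 3, non-proline).  Protection
factors default to a log-uniform draw over [10, 1e6]; the intrinsic rate is
a single global constant (pluggable) because pipeline validation does not
need residue-specific exchange chemistry.

Toy coordinate ensembles (static, harmonic jitter, straight-axis helix pairs
at a set angle, donor–H–acceptor triads at set geometry) give the dynamics
metrics exactly constructed answers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .dynamics import Ensemble
from .ingest import (
    MAXD_CONVENTION,
    Peptide,
    UptakeDataset,
    compute_max_deuteration,
    exchangeable_positions,
)

__all__ = [
    "ExchangeModel",
    "PerturbationSpec",
    "SimulationConfig",
    "generate_peptide_map",
    "simulate_uptake",
    "peptide_uptake_curve",
    "write_ground_truth",
    "make_toy_ensemble",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """A localized change in protection over residues [start, end]
    (1-based inclusive).  pf_multiplier < 1 lowers protection factors and so
    increases exchange; > 1 decreases it.  Perturbed PFs are clamped to >= 1."""

    start: int
    end: int
    pf_multiplier: float

    def __post_init__(self) -> None:
        if self.end < self.start or self.start < 1:
            raise ValueError(f"bad region {self.start}..{self.end}")
        if self.pf_multiplier <= 0:
            raise ValueError("pf_multiplier must be > 0")


@dataclass(frozen=True)
class ExchangeModel:
    """Per-residue EX2 exchange model.

    sequence : one-letter amino-acid string.
    protection_factors : per-residue PF_i >= 1 (length = len(sequence));
        entries for prolines and the first two residues are ignored (those
        positions carry no exchangeable amide).
    k_int : global intrinsic exchange rate, 1/s.
    d2o_fraction : buffer D2O fraction f in (0, 1].
    """

    sequence: str
    protection_factors: tuple[float, ...]
    k_int: float = 1.0
    d2o_fraction: float = 0.62
    temperature_label: str = "20C"

    def __post_init__(self) -> None:
        if len(self.protection_factors) != len(self.sequence):
            raise ValueError("protection_factors length must match sequence")
        if any(pf < 1.0 for pf in self.protection_factors):
            raise ValueError("protection factors must be >= 1")
        if not (0.0 < self.d2o_fraction <= 1.0):
            raise ValueError("d2o_fraction must be in (0, 1]")
        if self.k_int <= 0:
            raise ValueError("k_int must be > 0")
        compute_max_deuteration(self.sequence)  # validates the alphabet

    @classmethod
    def random(
        cls,
        sequence: str,
        seed: int,
        pf_range: tuple[float, float] = (10.0, 1e6),
        **kwargs,
    ) -> "ExchangeModel":
        """Draw per-residue protection factors log-uniformly from pf_range."""
        rng = np.random.default_rng(seed)
        lo, hi = np.log10(pf_range[0]), np.log10(pf_range[1])
        pf = 10.0 ** rng.uniform(lo, hi, size=len(sequence))
        return cls(sequence=sequence, protection_factors=tuple(pf), **kwargs)

    def rates(self) -> np.ndarray:
        """Effective per-residue exchange rates k_i = k_int / PF_i (1/s);
        NaN at positions without an exchangeable amide."""
        k = self.k_int / np.asarray(self.protection_factors, dtype=float)
        exch = set(exchangeable_positions(self.sequence))
        mask = np.array([(i + 1) in exch for i in range(len(self.sequence))])
        k[~mask] = np.nan
        return k

    def perturb(self, perturbations: Sequence[PerturbationSpec]) -> "ExchangeModel":
        """Apply PF multipliers over regions, clamping perturbed PFs to >= 1."""
        pf = np.asarray(self.protection_factors, dtype=float).copy()
        n = len(self.sequence)
        for spec in perturbations:
            if spec.end > n:
                raise ValueError(f"region {spec.start}..{spec.end} outside sequence (len {n})")
            sl = slice(spec.start - 1, spec.end)
            pf[sl] = np.maximum(pf[sl] * spec.pf_multiplier, 1.0)
        return replace(self, protection_factors=tuple(pf))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator: a 3–3000 s time course,
    three replicates, and Gaussian centroid mass noise of 0.05 Da."""

    timepoints: tuple[float, ...] = (3.0, 30.0, 300.0, 3000.0)
    n_replicates: int = 3
    mass_noise_sd: float = 0.05
    seed: int = 0
    peptide_mean_length: int = 12
    peptide_overlap_step: int = 6
    peptide_length_jitter: int = 2

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.timepoints)
        if any(t <= 0 for t in tp) or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing and positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.mass_noise_sd < 0:
            raise ValueError("mass_noise_sd must be >= 0")
        if self.peptide_overlap_step < 1 or self.peptide_mean_length < 1:
            raise ValueError("peptide map parameters must be >= 1")


def generate_peptide_map(sequence: str, config: SimulationConfig) -> list[Peptide]:
    """Tile the sequence with overlapping peptides.

    Starts advance by ``peptide_overlap_step``; lengths are drawn around
    ``peptide_mean_length`` (uniform integer jitter, clamped so consecutive
    peptides always overlap) and the tiling stops once a peptide reaches the
    C-terminus, which the last peptide is extended to if needed.  The result
    is deterministic given ``config.seed``.
    """
    n = len(sequence)
    if n < 5:
        raise ValueError(f"sequence of length {n} is shorter than the minimum peptide length")
    rng = np.random.default_rng(config.seed)
    step = config.peptide_overlap_step
    min_len = max(step, 5)
    peptides: list[Peptide] = []
    start = 1
    while start <= n:
        jitter = int(rng.integers(-config.peptide_length_jitter, config.peptide_length_jitter + 1)) \
            if config.peptide_length_jitter > 0 else 0
        length = max(min_len, config.peptide_mean_length + jitter)
        end = min(start + length - 1, n)
        if end - start + 1 < 2:
            # degenerate tail: fold into the previous peptide instead
            break
        charge = int(rng.integers(1, 4))
        rt = round(2.0 + 28.0 * start / n, 2)
        peptides.append(Peptide(start, end, sequence[start - 1 : end], charge, rt))
        if end >= n:
            break
        start += step
    last = peptides[-1]
    if last.end < n:
        peptides[-1] = Peptide(last.start, n, sequence[last.start - 1 :], last.charge, last.retention_time)
    return peptides


def peptide_uptake_curve(
    model: ExchangeModel, peptide: Peptide, timepoints: Sequence[float]
) -> np.ndarray:
    """Noiseless deuterium content D(t) = f * sum_i (1 - exp(-k_i t)) over
    the peptide's observable amides, for each labeling time (t >= 0)."""
    t = np.asarray(timepoints, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative labeling time")
    rates = model.rates()
    idx = [r - 1 for r in peptide.exchangeable_residues() if r >= 3]
    if not idx:
        return np.zeros_like(t)
    k = rates[idx]
    k = k[np.isfinite(k)]
    return model.d2o_fraction * (1.0 - np.exp(-np.outer(t, k))).sum(axis=1)


def simulate_uptake(
    model: ExchangeModel,
    peptides: Sequence[Peptide],
    config: SimulationConfig,
    perturbations: Sequence[PerturbationSpec] | None = None,
    state_names: tuple[str, str] = ("reference", "perturbed"),
) -> UptakeDataset:
    """Simulate replicate-level uptake for one state, or two states when
    perturbations are given (the second state's protection factors are the
    perturbed ones; peptide map and noise model are shared, so any
    difference between states is attributable solely to the perturbation).

    Per (peptide, state, timepoint, replicate): the noiseless EX2 uptake
    plus Gaussian mass noise of sd ``mass_noise_sd``.  A t = 0 reference row
    is included per replicate.  Random streams are spawned per (state,
    replicate) from the root seed, so results are reproducible and adding a
    state never disturbs the other state's draws.
    """
    n = len(model.sequence)
    for p in peptides:
        if p.end > n:
            raise ValueError(f"peptide {p.start}..{p.end} outside sequence (len {n})")
    models = {state_names[0]: model}
    if perturbations is not None:
        models[state_names[1]] = model.perturb(perturbations)

    timepoints = (0.0,) + tuple(config.timepoints)
    root = np.random.SeedSequence(config.seed)
    streams = {}
    for si, state in enumerate(models):
        for rep in range(1, config.n_replicates + 1):
            streams[(state, rep)] = np.random.default_rng(
                np.random.SeedSequence(entropy=root.entropy, spawn_key=(si, rep))
            )

    rows = []
    for state, m in models.items():
        noiseless = {p.key(): peptide_uptake_curve(m, p, timepoints) for p in peptides}
        for rep in range(1, config.n_replicates + 1):
            rng = streams[(state, rep)]
            for p in peptides:
                clean = noiseless[p.key()]
                noise = (
                    rng.normal(0.0, config.mass_noise_sd, size=len(timepoints))
                    if config.mass_noise_sd > 0
                    else np.zeros(len(timepoints))
                )
                for t, d in zip(timepoints, clean + noise):
                    rows.append(
                        dict(
                            start=p.start, end=p.end, sequence=p.sequence,
                            charge=p.charge, max_d=p.max_d,
                            retention_time=p.retention_time, state=state,
                            timepoint=t, replicate=rep, num_deuterons=float(d),
                        )
                    )
    import pandas as pd

    records = pd.DataFrame(rows)
    metadata = {
        "d2o_fraction": model.d2o_fraction,
        "maxd_convention": MAXD_CONVENTION,
        "k_int": model.k_int,
        "mass_noise_sd": config.mass_noise_sd,
        "seed": config.seed,
    }
    return UptakeDataset(peptides=list(peptides), records=records, metadata=metadata)


def write_ground_truth(
    model: ExchangeModel,
    perturbations: Sequence[PerturbationSpec] | None,
    path: str | Path,
) -> None:
    """YAML sidecar with the generative truth (per-residue PFs and perturbed
    regions) for recovery scoring."""
    doc = {
        "sequence": model.sequence,
        "k_int": float(model.k_int),
        "d2o_fraction": float(model.d2o_fraction),
        "protection_factors": [float(x) for x in model.protection_factors],
        "perturbations": [
            {"start": p.start, "end": p.end, "pf_multiplier": float(p.pf_multiplier)}
            for p in (perturbations or [])
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


# ---------------------------------------------------------------------------
# Toy coordinate ensembles
# ---------------------------------------------------------------------------


def _random_cloud(n_atoms: int, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(-10.0, 10.0, size=(n_atoms, 3))


def make_toy_ensemble(kind: str, n_frames: int = 100, seed: int = 0, **params) -> Ensemble:
    """Construct a labeled coordinate ensemble with known geometry.

    kinds
    -----
    ``static``
        ``n_atoms`` (default 10) random atoms, identical in every frame.
    ``harmonic``
        the same cloud with per-frame isotropic Gaussian jitter of sd
        ``sd`` Å (default 0.5) on every coordinate.
    ``helix_pair``
        two straight-line Cα traces (idealized helix axes, rise
        ``rise`` = 1.5 Å, ``n_res`` = 12 residues each): the first along +x,
        the second rotated by ``angle_deg`` (default 90) in the xy plane.
        Residues are numbered 1..n_res and 101..100+n_res.
    ``hbond_triad``
        a donor N, explicit H, and acceptor O; in ``formed_frames`` of the
        frames the geometry is d(H,A) = ``d_on`` (default 2.0 Å) at 180°,
        in the rest d(H,A) = ``d_off`` (default 3.5 Å).
    """
    rng = np.random.default_rng(seed)
    if kind == "static":
        n_atoms = int(params.get("n_atoms", 10))
        base = _random_cloud(n_atoms, rng)
        coords = np.repeat(base[None, :, :], n_frames, axis=0)
        return _cloud_ensemble(coords)
    if kind == "harmonic":
        n_atoms = int(params.get("n_atoms", 10))
        sd = float(params.get("sd", 0.5))
        base = _random_cloud(n_atoms, rng)
        coords = base[None, :, :] + rng.normal(0.0, sd, size=(n_frames, n_atoms, 3))
        return _cloud_ensemble(coords)
    if kind == "helix_pair":
        angle = np.radians(float(params.get("angle_deg", 90.0)))
        n_res = int(params.get("n_res", 12))
        rise = float(params.get("rise", 1.5))
        axis_a = np.array([1.0, 0.0, 0.0])
        axis_b = np.array([np.cos(angle), np.sin(angle), 0.0])
        pos_a = np.outer(np.arange(n_res) * rise, axis_a)
        pos_b = np.array([30.0, 30.0, 0.0]) + np.outer(np.arange(n_res) * rise, axis_b)
        base = np.vstack([pos_a, pos_b])
        coords = np.repeat(base[None, :, :], n_frames, axis=0)
        resids = list(range(1, n_res + 1)) + list(range(101, 101 + n_res))
        n_atoms = 2 * n_res
        return Ensemble(
            coords=coords,
            resids=resids,
            resnames=["ALA"] * n_atoms,
            atom_names=["CA"] * n_atoms,
            elements=["C"] * n_atoms,
        )
    if kind == "hbond_triad":
        d_on = float(params.get("d_on", 2.0))
        d_off = float(params.get("d_off", 3.5))
        formed = params.get("formed_frames", n_frames)
        if isinstance(formed, float) and 0 <= formed <= 1:
            formed = int(round(formed * n_frames))
        formed = int(formed)
        frames = []
        nh = 1.0  # N-H bond length, Å
        for i in range(n_frames):
            d = d_on if i < formed else d_off
            # collinear N - H ... O along +x: DHA angle exactly 180 degrees
            frames.append(
                np.array([[0.0, 0.0, 0.0], [nh, 0.0, 0.0], [nh + d, 0.0, 0.0]])
            )
        coords = np.stack(frames)
        return Ensemble(
            coords=coords,
            resids=[1, 1, 2],
            resnames=["ALA", "ALA", "ALA"],
            atom_names=["N", "H", "O"],
            elements=["N", "H", "O"],
        )
    raise ValueError(f"unknown toy-ensemble kind {kind!r}")


def _cloud_ensemble(coords: np.ndarray) -> Ensemble:
    n_atoms = coords.shape[1]
    return Ensemble(
        coords=coords,
        resids=list(range(1, n_atoms + 1)),
        resnames=["ALA"] * n_atoms,
        atom_names=["CA"] * n_atoms,
        elements=["C"] * n_atoms,
    )
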