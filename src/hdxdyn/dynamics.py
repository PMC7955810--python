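"""Structural-dynamics metrics on coordinate ensembles.

Works on any multi-frame coordinate set (multi-model PDB, or frames built in
memory): rigid-body superposition (Kabsch), per-atom RMSF, inter-helical
angles from turn center-of-mass vectors, geometric hydrogen-bond occupancy
(Baker–Hubbard criterion), and principal component analysis in a space
shared across systems.

Default residue selections follow the PI3Kγ p110γ kinase domain: alignment
over Cα atoms of residues 726–1088, and helix-axis endpoints for the
C-terminal regulatory helices kα8–kα11.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Ensemble",
    "HelixAxisDef",
    "HBondCriterion",
    "PCAResult",
    "KINASE_DOMAIN_RANGE",
    "HELIX_AXES",
    "align_ensemble",
    "rmsf",
    "rmsf_across_replicas",
    "interhelix_angle",
    "interhelix_angles",
    "hbond_occupancy",
    "pca_shared_space",
]

#: Cα residue range used to superpose kinase-domain frames.
KINASE_DOMAIN_RANGE = (726, 1088)

#: Standard atomic masses for the elements that occur in protein PDB files.
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}


@dataclass(frozen=True)
class HelixAxisDef:
    """A helix axis defined by two turn center-of-mass endpoints.

    ``point1_residues`` and ``point2_residues`` are inclusive residue ranges
    whose Cα centers of mass define the axis vector point2 - point1.
    """

    name: str
    point1_residues: tuple[int, int]
    point2_residues: tuple[int, int]

    def __post_init__(self) -> None:
        for lo, hi in (self.point1_residues, self.point2_residues):
            if hi < lo:
                raise ValueError(f"{self.name}: empty residue range {lo}-{hi}")
        a, b = sorted([self.point1_residues, self.point2_residues])
        if a[1] >= b[0]:
            raise ValueError(f"{self.name}: endpoint ranges overlap")


#: Axis endpoints for the regulatory-motif helices (turn COM residue ranges).
HELIX_AXES = {
    "ka8": HelixAxisDef("ka8", (1020, 1023), (1004, 1007)),
    "ka9": HelixAxisDef("ka9", (1024, 1027), (1034, 1037)),
    "ka10": HelixAxisDef("ka10", (1053, 1056), (1046, 1049)),
    "ka11": HelixAxisDef("ka11", (1062, 1065), (1074, 1077)),
}


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition (Baker–Hubbard): the bond is formed
    when the H···acceptor distance is at most ``max_h_acceptor_distance`` (Å)
    and the donor–H···acceptor angle is at least ``min_dha_angle`` degrees."""

    max_h_acceptor_distance: float = 2.5
    min_dha_angle: float = 120.0

    def __post_init__(self) -> None:
        if self.max_h_acceptor_distance <= 0:
            raise ValueError("distance cutoff must be > 0")
        if not (0 < self.min_dha_angle <= 180):
            raise ValueError("angle cutoff must be in (0, 180]")


@dataclass
class Ensemble:
    """frames x atoms coordinate set with residue/atom labels.

    coords has shape (n_frames, n_atoms, 3) in Å; resids, resnames,
    atom_names, elements are length-n_atoms label arrays.
    """

    coords: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    replica_id: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        n = self.coords.shape[1]
        for arr, name in (
            (self.resids, "resids"), (self.resnames, "resnames"),
            (self.atom_names, "atom_names"), (self.elements, "elements"),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != atom count {n}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(
        self,
        atom_name: str | None = None,
        resid_range: tuple[int, int] | None = None,
        resids: Iterable[int] | None = None,
    ) -> np.ndarray:
        """Indices of atoms matching all given filters."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if atom_name is not None:
            mask &= np.array([a == atom_name for a in self.atom_names])
        if resid_range is not None:
            lo, hi = resid_range
            mask &= (self.resids >= lo) & (self.resids <= hi)
        if resids is not None:
            wanted = set(int(r) for r in resids)
            mask &= np.array([int(r) in wanted for r in self.resids])
        return np.flatnonzero(mask)

    def masses(self) -> np.ndarray:
        return np.array([_MASSES.get(str(e).upper(), 12.011) for e in self.elements])

    def copy(self) -> "Ensemble":
        return Ensemble(
            coords=self.coords.copy(),
            resids=self.resids.copy(),
            resnames=self.resnames.copy(),
            atom_names=self.atom_names.copy(),
            elements=self.elements.copy(),
            replica_id=self.replica_id,
        )

    # -- PDB I/O ------------------------------------------------------------

    @classmethod
    def from_pdb(cls, path: str | Path, replica_id: int | None = None) -> "Ensemble":
        """Read a (possibly multi-model) PDB file into an Ensemble."""
        from Bio.PDB import PDBParser

        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("ens", str(path))
        frames, labels = [], None
        for model in structure:
            xyz, resids, resnames, names, elements = [], [], [], [], []
            for chain in model:
                for residue in chain:
                    for atom in residue:
                        xyz.append(atom.coord)
                        resids.append(residue.id[1])
                        resnames.append(residue.resname.strip())
                        names.append(atom.get_name())
                        elements.append(atom.element or atom.get_name()[0])
            frames.append(np.asarray(xyz, dtype=float))
            if labels is None:
                labels = (resids, resnames, names, elements)
        if not frames:
            raise ValueError(f"{path}: no models found")
        counts = {f.shape[0] for f in frames}
        if len(counts) != 1:
            raise ValueError(f"{path}: atom count varies across models: {sorted(counts)}")
        resids, resnames, names, elements = labels
        return cls(
            coords=np.stack(frames),
            resids=resids,
            resnames=resnames,
            atom_names=names,
            elements=elements,
            replica_id=replica_id,
        )

    def to_pdb(self, path: str | Path, chain: str = "A", bfactors: np.ndarray | None = None) -> None:
        """Write the ensemble as a fixed-column multi-model PDB file."""
        path = Path(path)
        b = np.zeros(self.n_atoms) if bfactors is None else np.asarray(bfactors, float)
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            for m in range(self.n_frames):
                fh.write(f"MODEL     {m + 1:4d}\n")
                for i in range(self.n_atoms):
                    x, y, z = self.coords[m, i]
                    name = str(self.atom_names[i])
                    # PDB atom-name column convention: names of <4 chars start
                    # in column 14 unless the element symbol is two letters.
                    name_field = f" {name:<3s}" if len(name) < 4 else name
                    fh.write(
                        f"ATOM  {i + 1:5d} {name_field}{'':1s}{str(self.resnames[i]):>3s} "
                        f"{chain}{int(self.resids[i]):4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b[i]:6.2f}"
                        f"          {str(self.elements[i]):>2s}\n"
                    )
                fh.write("ENDMDL\n")
            fh.write("END\n")


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rotation R and centroids aligning ``mobile`` onto
    ``target``; a proper rotation (det +1) is enforced."""
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, cm, ct


def align_ensemble(
    ensemble: Ensemble,
    reference_frame: int | np.ndarray = 0,
    selection: np.ndarray | None = None,
) -> Ensemble:
    """Superpose every frame onto a reference by least-squares rigid-body
    (Kabsch) fit over the selected atoms.

    Parameters
    ----------
    reference_frame : int or (n_atoms, 3) array
        Frame index of the ensemble, or explicit reference coordinates.
    selection : array of atom indices
        Atoms used for the fit (default: all).  Needs at least 3 atoms.
    """
    sel = np.arange(ensemble.n_atoms) if selection is None else np.asarray(selection, int)
    if len(sel) < 3:
        raise ValueError("superposition needs at least 3 selection atoms")
    if isinstance(reference_frame, (int, np.integer)):
        ref = ensemble.coords[int(reference_frame)]
    else:
        ref = np.asarray(reference_frame, dtype=float)
    ref_sel = ref[sel]
    out = ensemble.copy()
    for i in range(ensemble.n_frames):
        rot, cm, ct = _kabsch(ensemble.coords[i, sel], ref_sel)
        out.coords[i] = (ensemble.coords[i] - cm) @ rot.T + ct
    return out


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------


def rmsf(ensemble: Ensemble, selection: np.ndarray | None = None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the ensemble-mean position.

    RMSF_a = sqrt(mean_t |x_a(t) - <x_a>|^2), in Å.  The ensemble should be
    aligned first; requires at least 2 frames.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = np.arange(ensemble.n_atoms) if selection is None else np.asarray(selection, int)
    xyz = ensemble.coords[:, sel, :]
    dev = xyz - xyz.mean(axis=0, keepdims=True)
    return np.sqrt((dev**2).sum(axis=2).mean(axis=0))


def rmsf_across_replicas(
    replicas: Sequence[Ensemble],
    selection: np.ndarray | None = None,
    quantiles: Sequence[float] = (0.25, 0.5, 0.75),
) -> dict:
    """RMSF per replica plus across-replica quantiles and SD per atom.

    Returns a dict with keys ``per_replica`` (n_replicas x n_atoms),
    ``quantiles`` (len(quantiles) x n_atoms), ``sd`` and ``mean``.
    """
    vals = np.stack([rmsf(e, selection) for e in replicas])
    return {
        "per_replica": vals,
        "quantiles": np.quantile(vals, quantiles, axis=0),
        "mean": vals.mean(axis=0),
        "sd": vals.std(axis=0, ddof=1) if len(replicas) > 1 else np.zeros(vals.shape[1]),
        "n": len(replicas),
    }


# ---------------------------------------------------------------------------
# Inter-helical angles
# ---------------------------------------------------------------------------


def _axis_vector(
    ensemble: Ensemble, frame: np.ndarray, axis: HelixAxisDef, mass_weighted: bool
) -> np.ndarray:
    points = []
    for lo, hi in (axis.point1_residues, axis.point2_residues):
        idx = ensemble.select(atom_name="CA", resid_range=(lo, hi))
        if len(idx) == 0:
            raise ValueError(f"{axis.name}: no CA atoms in residues {lo}-{hi}")
        if mass_weighted:
            w = ensemble.masses()[idx]
            points.append((frame[idx] * w[:, None]).sum(axis=0) / w.sum())
        else:
            points.append(frame[idx].mean(axis=0))
    v = points[1] - points[0]
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError(f"{axis.name}: zero-length axis vector")
    return v / norm


def interhelix_angle(
    ensemble: Ensemble,
    frame_index: int,
    def_a: HelixAxisDef,
    def_b: HelixAxisDef,
    mass_weighted: bool = False,
) -> float:
    """Angle in degrees between the two helix-axis vectors in one frame.

    Each axis connects the (Cα, unweighted by default) centers of mass of
    the helix's first and last turn; the angle is reported in [0, 180]°
    without folding, so antiparallel arrangements are distinguishable.
    """
    frame = ensemble.coords[frame_index]
    va = _axis_vector(ensemble, frame, def_a, mass_weighted)
    vb = _axis_vector(ensemble, frame, def_b, mass_weighted)
    cosang = float(np.clip(np.dot(va, vb), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def interhelix_angles(
    ensemble: Ensemble,
    def_a: HelixAxisDef,
    def_b: HelixAxisDef,
    mass_weighted: bool = False,
) -> np.ndarray:
    """Per-frame inter-helical angles (degrees) across the whole ensemble."""
    return np.array(
        [interhelix_angle(ensemble, i, def_a, def_b, mass_weighted) for i in range(ensemble.n_frames)]
    )


# ---------------------------------------------------------------------------
# Hydrogen-bond occupancy
# ---------------------------------------------------------------------------


def _resolve_atom(ensemble: Ensemble, spec) -> int:
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    resid, name = spec
    idx = ensemble.select(atom_name=name, resids=[resid])
    if len(idx) != 1:
        raise ValueError(f"atom ({resid}, {name}) matched {len(idx)} atoms")
    return int(idx[0])


def hbond_occupancy(
    replicas: Ensemble | Sequence[Ensemble],
    bonds: Sequence[tuple],
    criterion: HBondCriterion = HBondCriterion(),
) -> list[dict]:
    """Occupancy (%) of explicit donor–H···acceptor bonds across frames.

    Parameters
    ----------
    replicas : Ensemble or sequence of Ensemble
        One or more replicas; occupancies are averaged across replicas with
        their standard deviation (n = number of replicas).
    bonds : sequence of (donor, hydrogen, acceptor)
        Each element is an atom index or a (resid, atom_name) pair.  The
        hydrogen atom must be an explicit H.

    A bond is formed in a frame iff d(H, acceptor) <= cutoff and the
    D–H···A angle >= the angle cutoff; occupancy is 100 x formed / total.
    """
    if isinstance(replicas, Ensemble):
        replicas = [replicas]
    results = []
    for bond in bonds:
        per_replica = []
        for ens in replicas:
            d_i, h_i, a_i = (_resolve_atom(ens, s) for s in bond)
            if not str(ens.elements[h_i]).upper().startswith("H"):
                raise ValueError(
                    f"atom index {h_i} ({ens.atom_names[h_i]}) is not a hydrogen; "
                    "add explicit hydrogens upstream before computing occupancies"
                )
            d_xyz = ens.coords[:, d_i, :]
            h_xyz = ens.coords[:, h_i, :]
            a_xyz = ens.coords[:, a_i, :]
            dist_ha = np.linalg.norm(a_xyz - h_xyz, axis=1)
            v1 = d_xyz - h_xyz
            v2 = a_xyz - h_xyz
            cosang = (v1 * v2).sum(axis=1) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            formed = (dist_ha <= criterion.max_h_acceptor_distance) & (
                ang >= criterion.min_dha_angle
            )
            per_replica.append(100.0 * formed.sum() / ens.n_frames)
        arr = np.asarray(per_replica)
        results.append(
            {
                "bond": bond,
                "occupancy_mean": float(arr.mean()),
                "occupancy_sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                "per_replica": arr,
                "n": len(arr),
            }
        )
    return results


# ---------------------------------------------------------------------------
# Shared-space PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    components: np.ndarray          # (n_components, 3*n_sel_atoms)
    explained_variance_ratio: np.ndarray
    projections: list[np.ndarray]   # per system, (n_frames, n_components)
    mean: np.ndarray


def pca_shared_space(
    ensembles: Sequence[Ensemble],
    selection: np.ndarray | Sequence[np.ndarray] | None = None,
    n_components: int | None = None,
) -> PCAResult:
    """Fit one PCA on the concatenated flattened coordinates of all systems
    and project each system into that shared component space.

    All ensembles must contribute the same number of selected atoms (they
    should already be aligned to a single common reference).  Explained
    variance ratios are those of the shared fit.
    """
    from sklearn.decomposition import PCA

    if selection is None:
        sels = [np.arange(e.n_atoms) for e in ensembles]
    elif isinstance(selection, np.ndarray) and selection.ndim == 1:
        sels = [np.asarray(selection, int)] * len(ensembles)
    else:
        sels = [np.asarray(s, int) for s in selection]
    counts = {len(s) for s in sels}
    if len(counts) != 1:
        raise ValueError(f"mismatched atom selections across systems: {sorted(counts)}")
    flat = [e.coords[:, s, :].reshape(e.n_frames, -1) for e, s in zip(ensembles, sels)]
    stacked = np.concatenate(flat, axis=0)
    if n_components is None:
        n_components = min(stacked.shape)
    pca = PCA(n_components=n_components)
    pca.fit(stacked)
    projections = [pca.transform(x) for x in flat]
    return PCAResult(
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        projections=projections,
        mean=pca.mean_,
    )
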