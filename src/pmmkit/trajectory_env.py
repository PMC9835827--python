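"""MD trajectory ingestion and evaluation of the perturbing electrostatics.

Splits each MD frame into quantum-center (QC) atoms and environment point
charges, superimposes the QC reference geometry onto the frame (mass-weighted
Kabsch fit), and evaluates the electric potential and field that the
environment's classical charge distribution exerts at the QC expansion
origin and at each QC nucleus.  Everything downstream of the file readers
works in Hartree atomic units (bohr, e, hartree).

Periodic boundaries: when the trajectory carries a box, displacement vectors
from the evaluation point to each environment charge are reduced by the
minimum-image convention (triclinic-safe, via fractional coordinates), so an
atom and its periodic image are never both counted.  The Coulomb sums run
over every environment atom in the box — no distance cutoff by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from . import units
from .qc_io import QCProperties

__all__ = [
    "EnvironmentSnapshot",
    "PerturbationTerms",
    "TrajectoryError",
    "ClashError",
    "parse_selection",
    "assign_charges",
    "load_system",
    "fit_rototranslation",
    "electric_potential",
    "electric_field",
    "potentials_at_nuclei",
    "compute_perturbation",
]


class TrajectoryError(ValueError):
    """Inconsistent trajectory, topology, selection or charge inputs."""


class ClashError(ValueError):
    """An environment charge (numerically) coincides with the field point."""


#: default minimum allowed charge-to-point distance (bohr)
CLASH_THRESHOLD = 1e-6


@dataclass
class EnvironmentSnapshot:
    """One MD frame split into QC atoms and environment point charges."""

    frame_index: int
    qc_coords: np.ndarray     # (n_qc, 3), bohr
    env_coords: np.ndarray    # (m, 3), bohr
    env_charges: np.ndarray   # (m,), e
    box: np.ndarray | None = None   # (3, 3) cell vectors (rows), bohr

    def __post_init__(self) -> None:
        self.qc_coords = np.asarray(self.qc_coords, float).reshape(-1, 3)
        self.env_coords = np.asarray(self.env_coords, float).reshape(-1, 3)
        self.env_charges = np.asarray(self.env_charges, float).ravel()
        if self.env_charges.shape[0] != self.env_coords.shape[0]:
            raise TrajectoryError(
                f"frame {self.frame_index}: {self.env_charges.shape[0]} "
                f"charges for {self.env_coords.shape[0]} environment atoms")
        if self.box is not None:
            self.box = np.asarray(self.box, float).reshape(3, 3)


@dataclass
class PerturbationTerms:
    """Electrostatic perturbation of one frame, in the QC reference frame.

    ``v0`` is the potential at the expansion origin r0 (the fitted QC center
    of mass), ``e0`` the field at r0 rotated into the QC reference frame,
    ``vn`` the potential at each (fitted) QC nucleus.  ``rotation`` maps
    reference-frame vectors into the lab frame; ``origin`` is r0 in lab
    coordinates.
    """

    v0: float
    e0: np.ndarray            # (3,), hartree/(e*bohr), QC reference frame
    vn: np.ndarray            # (n_qc_atoms,), hartree/e
    rotation: np.ndarray      # (3, 3), proper rotation, det +1
    origin: np.ndarray        # (3,), bohr, lab frame
    rmsd: float = 0.0         # mass-weighted fit RMSD, bohr


def parse_selection(selection: str | list[int], n_atoms: int) -> np.ndarray:
    """Parse a 1-based atom-index selection into sorted 0-based indices.

    Accepts a list of 1-based integers or a string of comma-separated
    indices and inclusive ranges, e.g. ``"1-24,30"``.
    """
    if isinstance(selection, str):
        idx: list[int] = []
        for part in selection.split(","):
            part = part.strip()
            if not part:
                continue
            if "-" in part[1:]:  # allow no negatives, just ranges
                lo_s, hi_s = part.split("-", 1)
                try:
                    lo, hi = int(lo_s), int(hi_s)
                except ValueError:
                    raise TrajectoryError(
                        f"bad selection token {part!r}") from None
                if hi < lo:
                    raise TrajectoryError(
                        f"descending range {part!r} in selection")
                idx.extend(range(lo, hi + 1))
            else:
                try:
                    idx.append(int(part))
                except ValueError:
                    raise TrajectoryError(
                        f"bad selection token {part!r}") from None
    else:
        idx = [int(i) for i in selection]
    if not idx:
        raise TrajectoryError("empty QC selection")
    arr = np.unique(np.asarray(idx, dtype=int))
    if arr[0] < 1 or arr[-1] > n_atoms:
        bad = arr[0] if arr[0] < 1 else arr[-1]
        raise TrajectoryError(
            f"selection index {bad} outside 1..{n_atoms}")
    return arr - 1


def assign_charges(
    charge_source: str | Path | np.ndarray,
    n_atoms: int | None = None,
    universe=None,
) -> np.ndarray:
    """Obtain the per-atom classical charge vector for the whole system.

    ``charge_source`` may be a plain-text file (one charge per whitespace
    token, in e), an array, or the string ``"topology"`` to pull charges
    from an MDAnalysis universe whose topology format carries them.
    """
    if isinstance(charge_source, (str, Path)) and str(charge_source) == "topology":
        if universe is None or not hasattr(universe.atoms, "charges"):
            raise TrajectoryError(
                "topology does not carry partial charges; provide a charge file")
        charges = np.asarray(universe.atoms.charges, dtype=float)
    elif isinstance(charge_source, (str, Path)):
        tokens = Path(charge_source).read_text().split()
        try:
            charges = np.array([float(t) for t in tokens], dtype=float)
        except ValueError as exc:
            raise TrajectoryError(
                f"{charge_source}: non-numeric charge entry ({exc})") from None
    else:
        charges = np.asarray(charge_source, dtype=float).ravel()
    if n_atoms is not None and charges.shape[0] != n_atoms:
        raise TrajectoryError(
            f"charge vector has {charges.shape[0]} entries but the system "
            f"has {n_atoms} atoms")
    return charges


def _box_from_dimensions(dimensions) -> np.ndarray | None:
    """MDAnalysis [lx,ly,lz,alpha,beta,gamma] (angstrom) -> 3x3 bohr, or None."""
    if dimensions is None:
        return None
    dims = np.asarray(dimensions, dtype=float)
    if dims.size < 6 or np.allclose(dims[:3], 0.0):
        return None
    from MDAnalysis.lib.mdamath import triclinic_vectors

    return units.angstrom_to_bohr(np.asarray(triclinic_vectors(dims), float))


def load_system(
    topology_path: str | Path,
    trajectory_path: str | Path | None = None,
    qc_selection: str | list[int] = "",
    charge_source: str | Path | np.ndarray = "topology",
) -> Iterator[EnvironmentSnapshot]:
    """Iterate over MD frames as :class:`EnvironmentSnapshot` objects.

    Formats are whatever MDAnalysis can read (GRO, PDB, XTC/TRR, ...);
    coordinates are converted angstrom -> bohr.  ``qc_selection`` is a
    1-based index list or range expression; all remaining atoms form the
    environment.  QC atoms' classical charges are retained in the topology
    but excluded from every field evaluation.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if trajectory_path is None:
                u = mda.Universe(str(topology_path))
            else:
                u = mda.Universe(str(topology_path), str(trajectory_path))
        except Exception as exc:
            raise TrajectoryError(
                f"could not load system from {topology_path}"
                + (f" + {trajectory_path}" if trajectory_path else "")
                + f": {exc}") from exc

    n_atoms = len(u.atoms)
    qc_idx = parse_selection(qc_selection, n_atoms)
    env_mask = np.ones(n_atoms, dtype=bool)
    env_mask[qc_idx] = False
    charges = assign_charges(charge_source, n_atoms=n_atoms, universe=u)
    env_charges = charges[env_mask]

    for i, ts in enumerate(u.trajectory):
        pos = units.angstrom_to_bohr(np.asarray(ts.positions, dtype=float))
        yield EnvironmentSnapshot(
            frame_index=i,
            qc_coords=pos[qc_idx],
            env_coords=pos[env_mask],
            env_charges=env_charges,
            box=_box_from_dimensions(ts.dimensions),
        )


def fit_rototranslation(
    ref_geometry: np.ndarray,
    masses: np.ndarray,
    frame_qc_coords: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Mass-weighted Kabsch superposition of the QC reference onto a frame.

    Returns ``(rotation, origin, rmsd)`` where ``rotation`` is the proper
    rotation (det +1; reflections excluded even for a mirror-image frame)
    such that ``rotation @ (ref - com_ref) + origin`` best matches the frame
    QC coordinates, ``origin`` is the frame QC center of mass, and ``rmsd``
    the minimized mass-weighted RMSD (bohr).
    """
    ref = np.asarray(ref_geometry, float).reshape(-1, 3)
    frm = np.asarray(frame_qc_coords, float).reshape(-1, 3)
    m = np.asarray(masses, float).ravel()
    if ref.shape != frm.shape or ref.shape[0] != m.shape[0]:
        raise TrajectoryError(
            f"reference ({ref.shape[0]} atoms) and frame "
            f"({frm.shape[0]} atoms) QC geometries do not match")
    w = m / m.sum()
    com_ref = w @ ref
    com_frm = w @ frm
    a = ref - com_ref
    b = frm - com_frm
    # rotation is determined only if the reference spans a plane
    sv = np.linalg.svd(a * np.sqrt(w)[:, None], compute_uv=False)
    if ref.shape[0] < 3 or sv[1] < 1e-10 * max(sv[0], 1.0):
        raise TrajectoryError(
            "rotation underdetermined: need at least 3 non-collinear QC atoms")
    h = (w[:, None] * a).T @ b
    u_m, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u_m.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u_m.T
    resid = b - a @ rot.T
    rmsd = float(np.sqrt((w * (resid**2).sum(axis=1)).sum()))
    return rot, com_frm, rmsd


def _displacements(env_coords, point, box):
    """point -> charge displacement vectors, minimum-imaged when box given."""
    d = np.asarray(env_coords, float) - np.asarray(point, float)
    if box is not None:
        h = np.asarray(box, float)          # rows are cell vectors
        frac = d @ np.linalg.inv(h)
        frac -= np.round(frac)
        d = frac @ h
    return d


def _checked_distances(env_coords, point, box, clash_threshold):
    d = _displacements(env_coords, point, box)
    r = np.linalg.norm(d, axis=1)
    if r.size and r.min() < clash_threshold:
        i = int(np.argmin(r))
        raise ClashError(
            f"environment atom {i} is {r[i]:.3e} bohr from the evaluation "
            f"point (clash threshold {clash_threshold:g})")
    return d, r


def electric_potential(
    env_coords: np.ndarray,
    env_charges: np.ndarray,
    point: np.ndarray,
    box: np.ndarray | None = None,
    clash_threshold: float = CLASH_THRESHOLD,
) -> float:
    """Coulomb potential V = sum_i q_i / |r_i - point| (hartree/e)."""
    q = np.asarray(env_charges, float).ravel()
    if q.size == 0:
        return 0.0
    _, r = _checked_distances(env_coords, point, box, clash_threshold)
    return float(np.sum(q / r))


def electric_field(
    env_coords: np.ndarray,
    env_charges: np.ndarray,
    point: np.ndarray,
    box: np.ndarray | None = None,
    clash_threshold: float = CLASH_THRESHOLD,
) -> np.ndarray:
    """Coulomb field E = sum_i q_i (point - r_i)/|point - r_i|^3 (a.u.).

    Satisfies E = -grad V of :func:`electric_potential` (checked numerically
    in the test suite).
    """
    q = np.asarray(env_charges, float).ravel()
    if q.size == 0:
        return np.zeros(3)
    d, r = _checked_distances(env_coords, point, box, clash_threshold)
    return -np.sum(q[:, None] * d / r[:, None] ** 3, axis=0)


def potentials_at_nuclei(
    snapshot: EnvironmentSnapshot,
    fitted_qc_coords: np.ndarray,
    clash_threshold: float = CLASH_THRESHOLD,
) -> np.ndarray:
    """Potential V(R_N) at each (lab-frame) QC nucleus position."""
    coords = np.asarray(fitted_qc_coords, float).reshape(-1, 3)
    return np.array([
        electric_potential(snapshot.env_coords, snapshot.env_charges,
                           rn, snapshot.box, clash_threshold)
        for rn in coords
    ])


def compute_perturbation(
    qc: QCProperties,
    snapshot: EnvironmentSnapshot,
    clash_threshold: float = CLASH_THRESHOLD,
) -> PerturbationTerms:
    """Fit the QC reference onto a frame and evaluate all perturbation terms.

    The expansion origin r0 is the mass-weighted center of the fitted QC in
    the frame.  The lab-frame field at r0 is rotated back into the QC
    reference frame (so the frame-fixed dipole matrix can contract with it
    directly).  A single-atom QC needs no rotational fit: the lab and
    reference frames are taken as parallel and r0 is the atom position.
    """
    if qc.n_atoms != snapshot.qc_coords.shape[0]:
        raise TrajectoryError(
            f"QC has {qc.n_atoms} atoms but frame {snapshot.frame_index} "
            f"selection has {snapshot.qc_coords.shape[0]}")
    if qc.n_atoms == 1:
        rot = np.eye(3)
        origin = snapshot.qc_coords[0].astype(float)
        rmsd = 0.0
    else:
        rot, origin, rmsd = fit_rototranslation(
            qc.geometry, qc.masses, snapshot.qc_coords)
    w = qc.masses / qc.masses.sum()
    fitted = (qc.geometry - w @ qc.geometry) @ rot.T + origin

    v0 = electric_potential(snapshot.env_coords, snapshot.env_charges,
                            origin, snapshot.box, clash_threshold)
    e_lab = electric_field(snapshot.env_coords, snapshot.env_charges,
                           origin, snapshot.box, clash_threshold)
    vn = potentials_at_nuclei(snapshot, fitted, clash_threshold)
    return PerturbationTerms(
        v0=v0, e0=rot.T @ e_lab, vn=vn,
        rotation=rot, origin=origin, rmsd=rmsd)
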