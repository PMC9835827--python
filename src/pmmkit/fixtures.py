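"""Synthetic quantum-center property sets, point-charge trajectories and
closed-form oracles.

These generators make every pipeline stage testable without any external
quantum-chemistry or MD output: a two-state quantum center with a chosen
energy gap and transition dipole, a minimal trajectory of one environment
point charge orbit-free on the x axis (fixed distance, linear ramp, or
seeded jitter), and the analytic two-level eigensolution the numerical path
must reproduce.  All files use the package's own text dialects (the
trajectory is a multi-MODEL PDB, readable by any structural-biology tool);
nothing here emulates a realistic solvent box.

Trajectory coordinates are quantized to the PDB precision of 1e-3 angstrom
before writing, and the returned distance schedule is the quantized one, so
closed-form oracles and the file-reading pipeline see identical geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import qc_io, units

__all__ = [
    "TwoStateQCFiles",
    "PointChargeTrajectory",
    "make_two_state_qc",
    "make_point_charge_trajectory",
    "analytic_two_level",
]


@dataclass
class TwoStateQCFiles:
    geometry: Path
    energies: Path
    dipoles: Path
    state_charges: Path | None
    total_charge: int

    def load(self) -> qc_io.QCProperties:
        return qc_io.load_qc_properties(
            self.geometry, self.energies, self.dipoles,
            state_charges_path=self.state_charges,
            total_charge=self.total_charge)


@dataclass
class PointChargeTrajectory:
    topology: Path            # multi-MODEL PDB; also the trajectory
    charges: Path             # per-atom classical charges, text
    qc_selection: str         # 1-based selection of the QC atom(s)
    distances: np.ndarray     # per-frame QC-to-charge distance, bohr
    charge: float             # environment point charge, e


def make_two_state_qc(
    directory: str | Path,
    gap: float,
    transition_dipole=(1.0, 0.0, 0.0),
    total_charge: int = 0,
    with_state_charges: bool = False,
) -> TwoStateQCFiles:
    """Write the four QC text inputs for a single-atom two-state system.

    Energies are (0, gap) hartree; the dipole matrix has the given
    off-diagonal element and zero diagonals.  With ``with_state_charges``
    each state carries the total charge on the single atom, making the
    fixture ready for the atom-based expansion.
    """
    if gap < 0:
        raise ValueError(f"gap must be non-negative, got {gap}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mu = np.asarray(transition_dipole, float).reshape(3)

    geom = directory / "qc_geometry.xyz"
    qc_io.write_geometry(geom, ["H"], np.zeros((1, 3)),
                         comment="two-state fixture QC")
    ener = directory / "qc_energies.txt"
    qc_io.write_energies(ener, np.array([0.0, gap]))
    dip = directory / "qc_dipoles.txt"
    dipole = np.zeros((2, 2, 3))
    dipole[0, 1] = mu
    dipole[1, 0] = mu
    qc_io.write_dipole_matrix(dip, dipole)
    chrg = None
    if with_state_charges:
        chrg = directory / "qc_state_charges.txt"
        qc_io.write_state_charges(
            chrg, np.full((2, 1), float(total_charge)))
    return TwoStateQCFiles(geometry=geom, energies=ener, dipoles=dip,
                           state_charges=chrg, total_charge=total_charge)


def _pdb_atom(serial: int, name: str, resseq: int, xyz, element: str) -> str:
    x, y, z = xyz
    return (f"ATOM  {serial:5d} {name:<4s} MOL A{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}\n")


def make_point_charge_trajectory(
    directory: str | Path,
    n_frames: int,
    charge: float,
    distance_schedule,
    seed: int | None = None,
    box_angstrom: float | None = None,
) -> PointChargeTrajectory:
    """Write a 2-atom trajectory: a QC atom at the origin and one
    environment point charge on the +x axis.

    ``distance_schedule`` (bohr) is either a scalar (fixed distance), a
    ``("ramp", d0, d1)`` linear ramp across the frames, a ``("jitter", d0,
    amplitude)`` uniform jitter (requires ``seed``), or an explicit array of
    per-frame distances.  ``box_angstrom`` adds a cubic cell for
    periodic-boundary tests.  Returns the quantized per-frame distances
    actually encoded in the file.
    """
    if n_frames < 1:
        raise ValueError(f"need at least one frame, got {n_frames}")
    if isinstance(distance_schedule, (tuple, list)) and distance_schedule \
            and isinstance(distance_schedule[0], str):
        kind = distance_schedule[0]
        if kind == "ramp":
            _, d0, d1 = distance_schedule
            dists = np.linspace(float(d0), float(d1), n_frames)
        elif kind == "jitter":
            _, d0, amp = distance_schedule
            if seed is None:
                raise ValueError("jitter schedule requires a seed")
            rng = np.random.default_rng(seed)
            dists = float(d0) + float(amp) * rng.uniform(-1, 1, n_frames)
        else:
            raise ValueError(f"unknown schedule kind {kind!r}")
    else:
        arr = np.asarray(distance_schedule, float)
        if arr.ndim == 1 and arr.shape[0] != n_frames:
            raise ValueError(
                f"schedule length {arr.shape[0]} does not match "
                f"{n_frames} frames")
        dists = np.broadcast_to(arr, (n_frames,)).copy()
    from .trajectory_env import CLASH_THRESHOLD

    if np.any(dists <= CLASH_THRESHOLD):
        raise ValueError("schedule contains distances at or below the "
                         "clash threshold")

    # Quantize to the precision the trajectory reader yields: PDB carries
    # 3 decimals (angstrom) and coordinate arrays are single precision, so
    # the recorded ground-truth schedule is the decimal-rounded value passed
    # through float32.  Oracles computed from `distances` then agree with
    # the file-reading pipeline to full double precision.
    dists_ang = np.round(units.bohr_to_angstrom(dists), 3)
    dists = units.angstrom_to_bohr(
        np.float64(np.float32(dists_ang)))

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    topo = directory / "system.pdb"
    with open(topo, "w") as fh:
        if box_angstrom is not None:
            fh.write(f"CRYST1{box_angstrom:9.3f}{box_angstrom:9.3f}"
                     f"{box_angstrom:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} "
                     f"P 1           1\n")
        for t in range(n_frames):
            fh.write(f"MODEL     {t + 1}\n")
            fh.write(_pdb_atom(1, "QC", 1, (0.0, 0.0, 0.0), "H"))
            fh.write(_pdb_atom(2, "EV", 2, (dists_ang[t], 0.0, 0.0), "H"))
            fh.write("ENDMDL\n")
        fh.write("END\n")

    chrg = directory / "charges.txt"
    chrg.write_text(f"0.0\n{float(charge):.17g}\n")
    return PointChargeTrajectory(
        topology=topo, charges=chrg, qc_selection="1",
        distances=dists, charge=float(charge))


def analytic_two_level(gap: float, coupling: float):
    """Closed-form eigensolution of H = [[0, c], [c, gap]].

    Returns (eigenvalues, eigenvectors): eigenvalues
    ``gap/2 -/+ sqrt(gap^2/4 + c^2)`` ascending, eigenvector columns
    normalized with the leading-coefficient-positive sign convention.  This
    is the independent oracle for the numerical diagonalization path.
    """
    g, c = float(gap), float(coupling)
    root = np.sqrt(g * g / 4.0 + c * c)
    vals = np.array([g / 2.0 - root, g / 2.0 + root])
    if c == 0.0:
        vecs = np.eye(2) if g >= 0 else np.eye(2)[:, ::-1].copy()
    else:
        cols = []
        for k, lam in enumerate(vals):
            v = np.array([c, lam])
            nrm = np.linalg.norm(v)
            if nrm == 0.0:   # c underflowed and lam == 0: unperturbed limit
                v = np.eye(2)[:, k]
            else:
                v = v / nrm
            cols.append(v)
        vecs = np.column_stack(cols)
        lead = np.abs(vecs).argmax(axis=0)
        flip = vecs[lead, np.arange(2)] < 0
        vecs[:, flip] *= -1.0
    return vals, vecs
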