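"""Per-frame construction and diagonalization of the perturbed Hamiltonian.

For each MD frame the electronic Hamiltonian of the quantum center, perturbed
by the environment's charge distribution, is expressed on the unperturbed
basis and diagonalized:

* QC-based (dipolar) expansion about the QC center of mass:
  ``H[l,l'] = (e0_l + q_T V(r0)) d_ll' - E(r0) . mu[l,l']``
  — a monopole shift on the diagonal plus the dipole coupling.

* Atom-based (hybrid) expansion: diagonal elements are rebuilt from the
  per-state unperturbed atomic charges times the potential at each nucleus,
  ``H[l,l] = e0_l + sum_N q_N^l V(R_N)`` (unperturbed atomic dipoles are
  neglected, their density being near-symmetric about each nucleus), while
  off-diagonal elements keep the dipolar form above.

The eigenvectors give each perturbed state as a linear combination of
unperturbed states; their sign and, under degeneracy, their order are fixed
by a continuity convention against the previous frame so that coefficient
trajectories are smooth rather than sign-flickering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .qc_io import QCProperties
from .trajectory_env import EnvironmentSnapshot, PerturbationTerms, compute_perturbation

__all__ = [
    "PMMTrajectory",
    "PMMError",
    "build_hamiltonian_qc",
    "build_hamiltonian_hybrid",
    "diagonalize",
    "run_pmm",
    "write_eigenvalue_file",
    "write_eigenvector_file",
    "read_eigenvalue_file",
    "read_eigenvector_file",
]


class PMMError(ValueError):
    pass


MODES = ("qc_based", "atom_based")


@dataclass
class PMMTrajectory:
    """Perturbed eigenvalues and eigenvectors along a trajectory.

    ``eigenvalues[t]`` holds the frame-t perturbed energies in ascending
    order (hartree); ``eigenvectors[t][:, i]`` holds the coefficients of
    perturbed state i on the unperturbed basis.
    """

    eigenvalues: np.ndarray    # (n_frames, n_states), hartree
    eigenvectors: np.ndarray   # (n_frames, n_states, n_states)
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def n_states(self) -> int:
        return self.eigenvalues.shape[1]

    def __post_init__(self) -> None:
        self.eigenvalues = np.atleast_2d(np.asarray(self.eigenvalues, float))
        self.eigenvectors = np.asarray(self.eigenvectors, float)
        if self.eigenvectors.shape != (
                self.n_frames, self.n_states, self.n_states):
            raise PMMError(
                f"eigenvector array shape {self.eigenvectors.shape} does not "
                f"match {self.n_frames} frames x {self.n_states} states")

    def validate(self, atol: float = 1e-8) -> None:
        """Check per-frame orthonormality and eigenvalue ordering."""
        eye = np.eye(self.n_states)
        for t in range(self.n_frames):
            c = self.eigenvectors[t]
            if np.abs(c.T @ c - eye).max() > atol:
                raise PMMError(f"frame {t}: eigenvectors not orthonormal")
            if np.any(np.diff(self.eigenvalues[t]) < -atol):
                raise PMMError(f"frame {t}: eigenvalues not ascending")


def build_hamiltonian_qc(
    qc: QCProperties, terms: PerturbationTerms
) -> np.ndarray:
    """QC-based dipolar Hamiltonian matrix on the unperturbed basis."""
    e0 = np.asarray(terms.e0, float).ravel()
    if e0.shape != (3,):
        raise PMMError(f"field vector has shape {e0.shape}, expected (3,)")
    h = np.diag(qc.energies + qc.total_charge * terms.v0)
    h = h - np.einsum("ijk,k->ij", qc.dipole_matrix, e0)
    return h


def build_hamiltonian_hybrid(
    qc: QCProperties, terms: PerturbationTerms
) -> np.ndarray:
    """Hybrid Hamiltonian: atom-based diagonal, dipolar off-diagonals."""
    if qc.state_charges is None:
        raise PMMError(
            "atom-based expansion requires per-state atomic charges "
            "(provide them via the -ch input)")
    vn = np.asarray(terms.vn, float).ravel()
    if vn.shape[0] != qc.n_atoms:
        raise PMMError(
            f"{vn.shape[0]} nuclear potentials for {qc.n_atoms} QC atoms")
    h = build_hamiltonian_qc(qc, terms)
    diag = qc.energies + qc.state_charges @ vn
    np.fill_diagonal(h, diag)
    return h


def _fix_signs_initial(vecs: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude coefficient positive."""
    v = vecs.copy()
    lead = np.abs(v).argmax(axis=0)
    flip = v[lead, np.arange(v.shape[1])] < 0
    v[:, flip] *= -1.0
    return v


def _align_to_previous(
    vals: np.ndarray, vecs: np.ndarray, prev: np.ndarray,
    degeneracy_tol: float,
) -> np.ndarray:
    """Continuity convention: within degenerate eigenvalue groups, reorder
    columns by greedy maximal |overlap| with the previous frame, then flip
    signs so each column's overlap with its predecessor is non-negative."""
    n = vals.shape[0]
    v = vecs.copy()
    # group indices of (numerically) degenerate eigenvalues
    scale = max(1.0, float(np.abs(vals).max()))
    start = 0
    for end in range(1, n + 1):
        if end == n or vals[end] - vals[end - 1] > degeneracy_tol * scale:
            if end - start > 1:
                cols = np.arange(start, end)
                ov = np.abs(prev[:, cols].T @ v[:, cols])
                order = np.full(end - start, -1, dtype=int)
                used: set[int] = set()
                for _ in range(end - start):
                    i, j = np.unravel_index(np.argmax(ov), ov.shape)
                    order[i] = j
                    used.add(j)
                    ov[i, :] = -1.0
                    ov[:, j] = -1.0
                v[:, cols] = v[:, cols[order]]
            start = end
    flip = np.einsum("li,li->i", prev, v) < 0
    v[:, flip] *= -1.0
    return v


def diagonalize(
    h: np.ndarray,
    prev_vectors: np.ndarray | None = None,
    symmetry_tol: float = 1e-8,
    degeneracy_tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a real symmetric Hamiltonian.

    Eigenvalues ascend; eigenvectors are orthonormal columns with the sign
    (and degenerate-subspace order) convention described in the module
    docstring: against ``prev_vectors`` when given, otherwise
    leading-coefficient-positive.
    """
    h = np.asarray(h, float)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise PMMError(f"Hamiltonian has shape {h.shape}, expected square")
    asym = np.abs(h - h.T).max()
    if asym > symmetry_tol:
        raise PMMError(
            f"Hamiltonian not symmetric (max asymmetry {asym:.3e})")
    vals, vecs = np.linalg.eigh((h + h.T) / 2.0)
    if prev_vectors is None:
        vecs = _fix_signs_initial(vecs)
    else:
        vecs = _align_to_previous(
            vals, vecs, np.asarray(prev_vectors, float), degeneracy_tol)
    return vals, vecs


def run_pmm(
    qc: QCProperties,
    snapshots: Iterable[EnvironmentSnapshot],
    mode: str = "qc_based",
    output_prefix: str | Path | None = None,
) -> PMMTrajectory:
    """Run the per-frame PMM loop over a trajectory.

    For each frame: fit the QC reference geometry, evaluate the perturbing
    potential and field, build the Hamiltonian in the requested expansion
    ``mode`` (``"qc_based"`` or ``"atom_based"``) and diagonalize it.  Any
    frame failure aborts the run with the frame index — frames are never
    silently skipped.  With ``output_prefix`` the eigenvalue and eigenvector
    trajectories are also written to ``<prefix>_eigvals.txt`` and
    ``<prefix>_eigvecs.txt``.
    """
    if mode not in MODES:
        raise PMMError(f"unknown expansion mode {mode!r}; use one of {MODES}")
    build = build_hamiltonian_qc if mode == "qc_based" else build_hamiltonian_hybrid
    if mode == "atom_based" and qc.state_charges is None:
        raise PMMError(
            "atom-based expansion requires per-state atomic charges "
            "(provide them via the -ch input)")

    all_vals, all_vecs = [], []
    prev = None
    n_done = 0
    for snap in snapshots:
        try:
            terms = compute_perturbation(qc, snap)
            h = build(qc, terms)
            vals, vecs = diagonalize(h, prev_vectors=prev)
        except Exception as exc:
            raise PMMError(
                f"frame {snap.frame_index}: {exc}") from exc
        all_vals.append(vals)
        all_vecs.append(vecs)
        prev = vecs
        n_done += 1
    if n_done == 0:
        raise PMMError("trajectory contained no frames")

    traj = PMMTrajectory(
        eigenvalues=np.array(all_vals),
        eigenvectors=np.array(all_vecs),
        metadata={"mode": mode, "n_states": qc.n_states,
                  "n_qc_atoms": qc.n_atoms},
    )
    if output_prefix is not None:
        write_eigenvalue_file(f"{output_prefix}_eigvals.txt", traj)
        write_eigenvector_file(f"{output_prefix}_eigvecs.txt", traj)
    return traj


# --- plain-text eigenvalue / eigenvector trajectory files ---

def write_eigenvalue_file(path: str | Path, traj: PMMTrajectory) -> None:
    """One line per frame: frame index then the perturbed energies (hartree)."""
    with open(path, "w") as fh:
        fh.write(f"# perturbed eigenvalues (hartree); "
                 f"{traj.n_frames} frames, {traj.n_states} states\n")
        for t in range(traj.n_frames):
            row = " ".join(f"{v:.16e}" for v in traj.eigenvalues[t])
            fh.write(f"{t} {row}\n")


def write_eigenvector_file(path: str | Path, traj: PMMTrajectory) -> None:
    """Frame-blocked n x n coefficient matrices (rows = unperturbed index)."""
    with open(path, "w") as fh:
        fh.write(f"# perturbed eigenvectors; "
                 f"{traj.n_frames} frames, {traj.n_states} states\n")
        for t in range(traj.n_frames):
            fh.write(f"# frame {t}\n")
            for row in traj.eigenvectors[t]:
                fh.write(" ".join(f"{c:.16e}" for c in row) + "\n")


def read_eigenvalue_file(path: str | Path) -> np.ndarray:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        rows.append([float(t) for t in tok[1:]])
    if not rows:
        raise PMMError(f"{path}: no eigenvalue rows")
    return np.array(rows, dtype=float)


def read_eigenvector_file(path: str | Path) -> np.ndarray:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        rows.append([float(t) for t in line.split()])
    if not rows:
        raise PMMError(f"{path}: no eigenvector rows")
    arr = np.array(rows, dtype=float)
    n = arr.shape[1]
    if arr.shape[0] % n:
        raise PMMError(
            f"{path}: {arr.shape[0]} coefficient rows is not a multiple of "
            f"the {n}-state block size")
    return arr.reshape(-1, n, n)
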