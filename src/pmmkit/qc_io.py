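"""Reading and validation of the unperturbed quantum-center (QC) properties.

The quantum center is the subsystem treated quantum mechanically.  Its
gas-phase (unperturbed) electronic structure — reference geometry, state
energies, electric-dipole matrix over states and, optionally, per-state
atomic charges — is computed once with an external quantum-chemistry program
and supplied to this package as plain-text files.  This module defines those
repo-specific text dialects, parses them, validates their mutual consistency
and assembles a :class:`QCProperties` record in atomic units.

File dialects (all whitespace-separated text, ``#`` comments allowed):

* geometry — XYZ: count line, comment line, then ``element x y z`` in
  angstrom; a bare 4-column variant without the two header lines is also
  accepted.  An optional 5th column overrides the atomic mass (amu).
* energies — one unperturbed state energy per line, hartree, file order
  defines the state index.
* dipole matrix — one row per state pair: ``l l' mux muy muz`` with 1-based
  state indices and components in atomic units (e*bohr).  Missing (l', l)
  rows are filled by symmetry.
* state charges — one row (or whitespace block) per state with one charge
  per QC atom, elementary charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import units

__all__ = [
    "QCProperties",
    "QCFileError",
    "read_reference_geometry",
    "read_energies",
    "read_dipole_matrix",
    "read_state_charges",
    "load_qc_properties",
    "write_geometry",
    "write_energies",
    "write_dipole_matrix",
    "write_state_charges",
]


class QCFileError(ValueError):
    """Malformed or mutually inconsistent QC input files."""


# Isotope-averaged atomic masses (amu), standard atomic weights.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "He": 4.002602,
    "Li": 6.94, "Be": 9.0121831, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998403163, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815385, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.0983, "Ca": 40.078, "Sc": 44.955908, "Ti": 47.867,
    "V": 50.9415, "Cr": 51.9961, "Mn": 54.938044, "Fe": 55.845,
    "Co": 58.933194, "Ni": 58.6934, "Cu": 63.546, "Zn": 65.38,
    "Ga": 69.723, "Ge": 72.630, "As": 74.921595, "Se": 78.971,
    "Br": 79.904, "Kr": 83.798, "Rb": 85.4678, "Sr": 87.62,
    "I": 126.90447, "Xe": 131.293, "Cs": 132.90545196, "Ba": 137.327,
}


@dataclass
class QCProperties:
    """Unperturbed electronic properties of the quantum center.

    All stored quantities are in Hartree atomic units: ``geometry`` in bohr,
    ``energies`` in hartree, ``dipole_matrix`` in e*bohr.  ``masses`` are in
    amu (they only ever enter mass-weighted fits, where the unit cancels).
    """

    geometry: np.ndarray          # (n_atoms, 3), bohr
    masses: np.ndarray            # (n_atoms,), amu
    elements: list[str]
    energies: np.ndarray          # (n_states,), hartree
    dipole_matrix: np.ndarray     # (n_states, n_states, 3), e*bohr
    total_charge: int = 0
    state_charges: np.ndarray | None = None   # (n_states, n_atoms), e
    charge_tolerance: float = field(default=1e-3, repr=False)

    @property
    def n_states(self) -> int:
        return len(self.energies)

    @property
    def n_atoms(self) -> int:
        return self.geometry.shape[0]

    def __post_init__(self) -> None:
        self.geometry = np.asarray(self.geometry, dtype=float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=float).ravel()
        self.energies = np.asarray(self.energies, dtype=float).ravel()
        self.dipole_matrix = np.asarray(self.dipole_matrix, dtype=float)
        self.validate()

    def validate(self) -> None:
        n, na = self.n_states, self.n_atoms
        if self.masses.shape != (na,):
            raise QCFileError(
                f"masses has {self.masses.shape[0]} entries for {na} atoms")
        if len(self.elements) != na:
            raise QCFileError(
                f"{len(self.elements)} element labels for {na} atoms")
        if self.dipole_matrix.shape != (n, n, 3):
            raise QCFileError(
                f"dipole matrix shape {self.dipole_matrix.shape} does not "
                f"match n_states={n}")
        asym = np.abs(self.dipole_matrix
                      - self.dipole_matrix.transpose(1, 0, 2)).max()
        if asym > 1e-10:
            raise QCFileError(
                f"dipole matrix not symmetric under state exchange "
                f"(max asymmetry {asym:.3e} > 1e-10)")
        if self.state_charges is not None:
            sc = np.asarray(self.state_charges, dtype=float)
            if sc.shape != (n, na):
                raise QCFileError(
                    f"state charges shape {sc.shape}, expected ({n}, {na})")
            sums = sc.sum(axis=1)
            bad = np.abs(sums - self.total_charge) > self.charge_tolerance
            if bad.any():
                l = int(np.argmax(bad))
                raise QCFileError(
                    f"state {l + 1} atomic charges sum to {sums[l]:.6f}, "
                    f"expected total charge {self.total_charge} "
                    f"(tolerance {self.charge_tolerance})")
            self.state_charges = sc


def _data_lines(path: str | Path) -> list[tuple[int, str]]:
    """Non-empty, non-comment lines with their 1-based line numbers."""
    out = []
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append((i, line))
    return out


def read_reference_geometry(
    path: str | Path,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Read the QC reference geometry.

    Accepts standard XYZ (count line, comment line, atom lines) or a bare
    ``element x y z`` table; coordinates in angstrom.  Returns coordinates
    in bohr, element symbols, and masses in amu (from the packaged table
    unless a 5th numeric column overrides them).
    """
    lines = _data_lines(path)
    if not lines:
        raise QCFileError(f"{path}: empty geometry file")

    declared = None
    first_tokens = lines[0][1].split()
    if len(first_tokens) == 1:
        try:
            declared = int(first_tokens[0])
        except ValueError:
            raise QCFileError(
                f"{path}:{lines[0][0]}: expected an atom count or an atom "
                f"line, got {lines[0][1]!r}") from None
        # XYZ: the raw second physical line is a free-form comment; drop it
        # whether or not the comment survived comment-stripping.
        raw = Path(path).read_text().splitlines()
        body_start = None
        count_seen = False
        for i, rawline in enumerate(raw):
            stripped = rawline.split("#", 1)[0].strip()
            if not count_seen:
                if stripped:
                    count_seen = True
            else:
                body_start = i + 1
                break
        if body_start is None:
            raise QCFileError(f"{path}: XYZ header present but no atoms")
        atom_lines = []
        for j, rawline in enumerate(raw[body_start:], start=body_start + 1):
            stripped = rawline.split("#", 1)[0].strip()
            if stripped:
                atom_lines.append((j, stripped))
    else:
        atom_lines = lines

    coords, elements, masses = [], [], []
    for lineno, line in atom_lines:
        tok = line.split()
        if len(tok) not in (4, 5):
            raise QCFileError(
                f"{path}:{lineno}: expected 'element x y z [mass]', "
                f"got {line!r}")
        el = tok[0].capitalize()
        try:
            xyz = [float(t) for t in tok[1:4]]
        except ValueError:
            raise QCFileError(
                f"{path}:{lineno}: non-numeric coordinate in {line!r}"
            ) from None
        if len(tok) == 5:
            try:
                mass = float(tok[4])
            except ValueError:
                raise QCFileError(
                    f"{path}:{lineno}: non-numeric mass override in {line!r}"
                ) from None
        elif el in ATOMIC_MASSES:
            mass = ATOMIC_MASSES[el]
        else:
            raise QCFileError(
                f"{path}:{lineno}: unknown element symbol {tok[0]!r} and no "
                f"mass override column")
        coords.append(xyz)
        elements.append(el)
        masses.append(mass)

    if declared is not None and declared != len(coords):
        raise QCFileError(
            f"{path}: header declares {declared} atoms but "
            f"{len(coords)} coordinate lines found")
    return (units.angstrom_to_bohr(np.array(coords, dtype=float)),
            elements, np.array(masses, dtype=float))


def read_energies(path: str | Path) -> np.ndarray:
    """Read unperturbed state energies (hartree), one per state, file order.

    Ordering is preserved: the state index identity must match the dipole
    matrix, so the values are never re-sorted.
    """
    lines = _data_lines(path)
    if not lines:
        raise QCFileError(f"{path}: empty energies file")
    vals = []
    for lineno, line in lines:
        for tok in line.split():
            try:
                vals.append(float(tok))
            except ValueError:
                raise QCFileError(
                    f"{path}:{lineno}: non-numeric energy {tok!r}") from None
    return np.array(vals, dtype=float)


def read_dipole_matrix(path: str | Path, n_states: int) -> np.ndarray:
    """Read the electric-dipole matrix over unperturbed states (e*bohr).

    Rows are ``l l' mux muy muz`` with 1-based indices.  Missing (l', l)
    entries are filled by symmetry; if both orders are given they must agree
    to 1e-8.
    """
    lines = _data_lines(path)
    if not lines:
        raise QCFileError(f"{path}: empty dipole-matrix file")
    mat = np.full((n_states, n_states, 3), np.nan)
    for lineno, line in lines:
        tok = line.split()
        if len(tok) != 5:
            raise QCFileError(
                f"{path}:{lineno}: expected 'l lp mux muy muz', got {line!r}")
        try:
            l, lp = int(tok[0]), int(tok[1])
            vec = np.array([float(t) for t in tok[2:5]])
        except ValueError:
            raise QCFileError(
                f"{path}:{lineno}: non-numeric token in {line!r}") from None
        if not (1 <= l <= n_states and 1 <= lp <= n_states):
            raise QCFileError(
                f"{path}:{lineno}: state pair ({l},{lp}) outside "
                f"1..{n_states}")
        if np.isfinite(mat[l - 1, lp - 1]).all():
            raise QCFileError(
                f"{path}:{lineno}: duplicate entry for pair ({l},{lp})")
        mat[l - 1, lp - 1] = vec

    # symmetry completion / consistency
    for l in range(n_states):
        for lp in range(n_states):
            have = np.isfinite(mat[l, lp]).all()
            have_t = np.isfinite(mat[lp, l]).all()
            if have and have_t and l < lp:
                if np.abs(mat[l, lp] - mat[lp, l]).max() > 1e-8:
                    raise QCFileError(
                        f"{path}: entries ({l + 1},{lp + 1}) and "
                        f"({lp + 1},{l + 1}) disagree by more than 1e-8")
            elif have and not have_t:
                mat[lp, l] = mat[l, lp]
            elif have_t and not have:
                mat[l, lp] = mat[lp, l]
            elif not have and not have_t:
                raise QCFileError(
                    f"{path}: no entry for state pair "
                    f"({l + 1},{lp + 1}) and none to symmetrize from")
    return mat


def read_state_charges(
    path: str | Path, n_states: int, n_atoms: int
) -> np.ndarray:
    """Read per-state QM atomic charges (e), one row/block per state.

    Needed only for the atom-based expansion of the perturbation.  The file
    is a flat whitespace-separated stream of ``n_states * n_atoms`` reals,
    state-major.
    """
    lines = _data_lines(path)
    if not lines:
        raise QCFileError(f"{path}: empty state-charges file")
    vals = []
    for lineno, line in lines:
        for tok in line.split():
            try:
                vals.append(float(tok))
            except ValueError:
                raise QCFileError(
                    f"{path}:{lineno}: non-numeric charge {tok!r}") from None
    expected = n_states * n_atoms
    if len(vals) != expected:
        raise QCFileError(
            f"{path}: found {len(vals)} charges, expected "
            f"{n_states} states x {n_atoms} atoms = {expected}")
    return np.array(vals, dtype=float).reshape(n_states, n_atoms)


def load_qc_properties(
    geometry_path: str | Path,
    energies_path: str | Path,
    dipoles_path: str | Path,
    state_charges_path: str | Path | None = None,
    total_charge: int = 0,
    charge_tolerance: float = 1e-3,
) -> QCProperties:
    """Read all QC input files and assemble a validated QCProperties."""
    geometry, elements, masses = read_reference_geometry(geometry_path)
    energies = read_energies(energies_path)
    dipoles = read_dipole_matrix(dipoles_path, len(energies))
    charges = None
    if state_charges_path is not None:
        charges = read_state_charges(
            state_charges_path, len(energies), geometry.shape[0])
    return QCProperties(
        geometry=geometry, masses=masses, elements=elements,
        energies=energies, dipole_matrix=dipoles,
        total_charge=total_charge, state_charges=charges,
        charge_tolerance=charge_tolerance)


# --- writers (round-trip partners of the readers; used by fixtures) ---

def write_geometry(path: str | Path, elements: list[str],
                   coords_bohr: np.ndarray, comment: str = "") -> None:
    coords = units.bohr_to_angstrom(np.asarray(coords_bohr, float))
    with open(path, "w") as fh:
        fh.write(f"{len(elements)}\n{comment}\n")
        for el, (x, y, z) in zip(elements, coords):
            fh.write(f"{el} {float(x):.17g} {float(y):.17g} {float(z):.17g}\n")


def write_energies(path: str | Path, energies: np.ndarray) -> None:
    with open(path, "w") as fh:
        for e in np.asarray(energies, float).ravel():
            fh.write(f"{float(e):.17g}\n")


def write_dipole_matrix(path: str | Path, dipoles: np.ndarray) -> None:
    d = np.asarray(dipoles, float)
    n = d.shape[0]
    with open(path, "w") as fh:
        for l in range(n):
            for lp in range(l, n):
                x, y, z = d[l, lp]
                fh.write(f"{l + 1} {lp + 1} {float(x):.17g} "
                         f"{float(y):.17g} {float(z):.17g}\n")


def write_state_charges(path: str | Path, charges: np.ndarray) -> None:
    with open(path, "w") as fh:
        for row in np.asarray(charges, float):
            fh.write(" ".join(f"{float(c):.17g}" for c in row) + "\n")
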