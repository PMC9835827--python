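import numpy as np
import pytest

from pmmkit import fixtures
from pmmkit.pmm_core import run_pmm
from pmmkit.qc_io import QCProperties
from pmmkit.trajectory_env import EnvironmentSnapshot


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def two_state_qc(tmp_path):
    """A single-atom, two-state QC (gap 0.1 hartree, mu_x = 1 a.u.)."""
    return fixtures.make_two_state_qc(tmp_path / "qc", 0.1, (1.0, 0.0, 0.0)).load()


def make_multistate_qc(n_states=4, n_atoms=3, seed=7, total_charge=0,
                       with_state_charges=False):
    """In-memory multi-state QC with a random symmetric dipole matrix."""
    rng = np.random.default_rng(seed)
    geometry = rng.normal(scale=1.5, size=(n_atoms, 3))
    masses = rng.uniform(1.0, 16.0, size=n_atoms)
    energies = np.sort(rng.uniform(0.0, 0.3, size=n_states))
    dip = rng.normal(size=(n_states, n_states, 3))
    dip = (dip + dip.transpose(1, 0, 2)) / 2.0
    charges = None
    if with_state_charges:
        charges = rng.normal(scale=0.2, size=(n_states, n_atoms))
        charges += (total_charge - charges.sum(axis=1, keepdims=True)) / n_atoms
    return QCProperties(
        geometry=geometry, masses=masses,
        elements=["C"] * n_atoms, energies=energies,
        dipole_matrix=dip, total_charge=total_charge,
        state_charges=charges)


def random_field_snapshots(qc, n_frames, seed, charge=0.8, radius=6.0):
    """Snapshots with one env charge at a random direction/distance per frame.

    The QC sits at its reference coordinates every frame (identity fit), so
    the perturbing field direction varies freely frame to frame.
    """
    rng = np.random.default_rng(seed)
    snaps = []
    for t in range(n_frames):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        d = radius * rng.uniform(0.8, 1.2)
        snaps.append(EnvironmentSnapshot(
            frame_index=t,
            qc_coords=qc.geometry.copy(),
            env_coords=(d * direction)[None, :],
            env_charges=np.array([charge]),
        ))
    return snaps


@pytest.fixture
def random_field_run():
    """Factory: full run_pmm over a random-field synthetic trajectory."""
    def _make(n_frames=50, n_states=4, seed=11, mode="qc_based", qc=None):
        if qc is None:
            qc = make_multistate_qc(
                n_states=n_states,
                with_state_charges=(mode == "atom_based"))
        snaps = random_field_snapshots(qc, n_frames, seed)
        return qc, run_pmm(qc, snaps, mode=mode)
    return _make


@pytest.fixture
def two_level_trajectory(tmp_path):
    """On-disk single-point-charge trajectory paired with its QC files."""
    qcf = fixtures.make_two_state_qc(tmp_path / "qc", 0.1, (1.0, 0.0, 0.0))
    traj = fixtures.make_point_charge_trajectory(
        tmp_path / "traj", 40, 0.5, ("jitter", 4.0, 0.6), seed=99)
    return qcf, traj
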