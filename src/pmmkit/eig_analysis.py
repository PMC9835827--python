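"""Composition analysis of the perturbed eigenvectors along the trajectory.

Each perturbed state i is a linear combination of unperturbed states l with
coefficients c_l^i.  The squared coefficients (c_l^i)^2 measure how much
unperturbed character l contributes to perturbed state i at a given frame;
their per-frame scatter reveals state inversions and environment-driven
mixing, and their time average summarizes the composition as a cumulative
histogram.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pmm_core import PMMTrajectory

__all__ = ["squared_projections", "mean_composition", "pairwise_scatter"]


def _check_state(traj: PMMTrajectory, idx: int, name: str) -> None:
    if not (0 <= idx < traj.n_states):
        raise IndexError(
            f"{name} index {idx} outside 0..{traj.n_states - 1}")


def squared_projections(traj: PMMTrajectory, perturbed_index: int) -> np.ndarray:
    """Per-frame squared coefficients (c_l^i)^2 of perturbed state i.

    Returns an (n_frames, n_states) array whose rows sum to 1 (the
    eigenvector columns are normalized).
    """
    _check_state(traj, perturbed_index, "perturbed state")
    return traj.eigenvectors[:, :, perturbed_index] ** 2


def mean_composition(traj: PMMTrajectory) -> np.ndarray:
    """Time-averaged composition matrix M[i, l] = < (c_l^i)^2 >.

    Each frame's squared-coefficient matrix is doubly stochastic (squares of
    an orthogonal matrix), a property preserved by averaging: rows and
    columns of M each sum to 1.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    return np.mean(traj.eigenvectors**2, axis=0).T


def pairwise_scatter(
    traj: PMMTrajectory,
    perturbed_index: int,
    unperturbed_l: int,
    unperturbed_lp: int,
) -> pd.DataFrame:
    """Signed coefficient pairs (c_l^i, c_l'^i) per frame, for scatter plots.

    Emits the signed coefficients (under the continuity sign convention of
    the PMM run), not their squares — mixing patterns live in the relative
    sign.  Returns a tidy frame with columns ``frame``, ``c_l``, ``c_lp``.
    """
    _check_state(traj, perturbed_index, "perturbed state")
    _check_state(traj, unperturbed_l, "unperturbed state")
    _check_state(traj, unperturbed_lp, "unperturbed state")
    return pd.DataFrame({
        "frame": np.arange(traj.n_frames),
        "c_l": traj.eigenvectors[:, unperturbed_l, perturbed_index],
        "c_lp": traj.eigenvectors[:, unperturbed_lp, perturbed_index],
    })
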