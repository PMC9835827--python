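"""Reaction and redox free energies from paired PMM runs (free_en stage).

For a reaction R -> P the Helmholtz free energy change is estimated by
exponential (Zwanzig) averaging of the per-frame vertical energy gap
DU = U_P - U_R over the two sampled ensembles:

    forward (R ensemble):  dA_f = -kT ln < exp(-b DU) >_R
    reverse (P ensemble):  dA_r = +kT ln < exp(+b DU) >_P

When the ionic-relaxation contributions of the two directions cancel (the
usual assumption for a rigid quantum center changing charge state), the two
estimates are combined as their arithmetic mean.  DU is obtained from two
PMM calculations over the SAME frames — one with the R-species and one with
the P-species electronic properties — using the perturbed ground-state
eigenvalue of each.  The sign convention DU = U_P - U_R is fixed in both
ensembles; the direction of each exponential average is keyed to the
ensemble, never to re-signed data.  Quantum vibrational contributions are
outside the model.

Energies are carried in kJ/mol at this stage (the natural unit for the
reported free energies); the eigenvalue-file helpers convert from hartree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import units

__all__ = [
    "FreeEnergyEstimate",
    "delta_U_per_frame",
    "exponential_average",
    "combine_estimates",
    "reduction_potential",
    "convergence_curve",
    "block_bootstrap_stderr",
    "estimate_free_energy",
]

TEMPERATURE_DEFAULT_K = 300.0


@dataclass
class FreeEnergyEstimate:
    """Forward, reverse and combined free-energy change (kJ/mol)."""

    delta_A_forward: float
    delta_A_reverse: float
    delta_A: float
    temperature: float
    n_frames_R: int
    n_frames_P: int
    stderr: float | None = None
    convergence_R: pd.DataFrame | None = None
    convergence_P: pd.DataFrame | None = None


def delta_U_per_frame(
    eigvals_R_species: np.ndarray,
    eigvals_P_species: np.ndarray,
    gas_phase_offset: float = 0.0,
) -> np.ndarray:
    """Per-frame energy gap DU_n = e0_P(n) - e0_R(n) + offset, in kJ/mol.

    Inputs are perturbed eigenvalue trajectories in hartree, both computed
    over the same frames of one ensemble — one run with the R-species and
    one with the P-species quantum-center properties.  The perturbed ground
    state (lowest eigenvalue) of each is used.  ``gas_phase_offset``
    (hartree) reconciles the two species' absolute energy scales when the
    input energies were relative; it is an explicit input, never inferred.
    """
    r = np.atleast_2d(np.asarray(eigvals_R_species, float))
    p = np.atleast_2d(np.asarray(eigvals_P_species, float))
    if r.shape[0] != p.shape[0]:
        raise ValueError(
            f"frame-count mismatch: {r.shape[0]} R-species vs "
            f"{p.shape[0]} P-species frames")
    return units.hartree_to_kj_mol(p[:, 0] - r[:, 0] + gas_phase_offset)


def _beta(temperature: float) -> float:
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (units.KB_KJ_MOL_K * temperature)


def exponential_average(
    delta_U: np.ndarray, temperature: float, direction: str
) -> float:
    """Overflow-safe Zwanzig estimator over one ensemble (kJ/mol).

    ``direction="forward"`` evaluates -kT ln<exp(-b DU)> (use on the R
    ensemble); ``"reverse"`` evaluates +kT ln<exp(+b DU)> (use on the P
    ensemble).  Accumulation is done in log space (max-shifted), so
    |b DU| up to ~1e4 poses no overflow problem.
    """
    du = np.asarray(delta_U, float).ravel()
    if du.size == 0:
        raise ValueError("empty energy-gap sample")
    b = _beta(temperature)
    kt = 1.0 / b
    if direction == "forward":
        return float(-kt * (logsumexp(-b * du) - np.log(du.size)))
    if direction == "reverse":
        return float(kt * (logsumexp(b * du) - np.log(du.size)))
    raise ValueError(f"direction must be 'forward' or 'reverse', "
                     f"got {direction!r}")


def combine_estimates(forward: float, reverse: float) -> float:
    """Two-ensemble combination: the mean of forward and reverse estimates.

    Valid when the ionic relaxation free energies of the two directions
    cancel; then the combined value is bracketed by the two one-sided
    estimates.
    """
    if not (np.isfinite(forward) and np.isfinite(reverse)):
        raise ValueError(
            f"non-finite estimate(s): forward={forward}, reverse={reverse}")
    return 0.5 * (forward + reverse)


def reduction_potential(
    delta_A_kj_mol: float,
    e_she: float = units.E_SHE_DEFAULT_V,
    n_electrons: int = 1,
) -> float:
    """Reduction potential vs SHE: E0 = -dA/(nF) - E_SHE (volts)."""
    if n_electrons <= 0:
        raise ValueError(f"n_electrons must be positive, got {n_electrons}")
    return (-delta_A_kj_mol * 1000.0
            / (n_electrons * units.FARADAY_C_MOL)) - e_she


def convergence_curve(
    delta_U: np.ndarray, temperature: float, direction: str, step: int
) -> pd.DataFrame:
    """Estimator vs number of frames used (prefix evaluation).

    Rows at frame counts step, 2*step, ..., N (N always included); the last
    row equals the full-sample estimate.
    """
    du = np.asarray(delta_U, float).ravel()
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    if step > du.size:
        raise ValueError(
            f"step {step} exceeds the {du.size} available frames")
    counts = list(range(step, du.size + 1, step))
    if counts[-1] != du.size:
        counts.append(du.size)
    est = [exponential_average(du[:n], temperature, direction)
           for n in counts]
    return pd.DataFrame({"frames_used": counts, "estimate": est})


def block_bootstrap_stderr(
    delta_U_R: np.ndarray,
    delta_U_P: np.ndarray,
    temperature: float,
    n_blocks: int = 50,
    n_resamples: int = 1000,
    seed: int = 0,
) -> float:
    """Block-bootstrap standard error of the combined estimate (kJ/mol).

    Each ensemble's gap sequence is cut into ``n_blocks`` contiguous blocks
    (respecting serial correlation within blocks); blocks are resampled with
    replacement and the combined estimator recomputed per resample.
    """
    rng = np.random.default_rng(seed)
    du_r = np.asarray(delta_U_R, float).ravel()
    du_p = np.asarray(delta_U_P, float).ravel()
    blocks_r = np.array_split(du_r, min(n_blocks, du_r.size))
    blocks_p = np.array_split(du_p, min(n_blocks, du_p.size))
    vals = np.empty(n_resamples)
    for k in range(n_resamples):
        rs = np.concatenate([
            blocks_r[i] for i in rng.integers(len(blocks_r), size=len(blocks_r))])
        ps = np.concatenate([
            blocks_p[i] for i in rng.integers(len(blocks_p), size=len(blocks_p))])
        vals[k] = combine_estimates(
            exponential_average(rs, temperature, "forward"),
            exponential_average(ps, temperature, "reverse"))
    return float(vals.std(ddof=1))


def estimate_free_energy(
    delta_U_R: np.ndarray,
    delta_U_P: np.ndarray,
    temperature: float = TEMPERATURE_DEFAULT_K,
    convergence_step: int | None = None,
    bootstrap_seed: int = 0,
    n_blocks: int = 50,
    n_resamples: int = 1000,
) -> FreeEnergyEstimate:
    """Full free_en pipeline from the two ensembles' gap samples (kJ/mol)."""
    forward = exponential_average(delta_U_R, temperature, "forward")
    reverse = exponential_average(delta_U_P, temperature, "reverse")
    combined = combine_estimates(forward, reverse)
    conv_r = conv_p = None
    if convergence_step is not None:
        conv_r = convergence_curve(
            delta_U_R, temperature, "forward", convergence_step)
        conv_p = convergence_curve(
            delta_U_P, temperature, "reverse", convergence_step)
    stderr = block_bootstrap_stderr(
        delta_U_R, delta_U_P, temperature,
        n_blocks=n_blocks, n_resamples=n_resamples, seed=bootstrap_seed)
    return FreeEnergyEstimate(
        delta_A_forward=forward,
        delta_A_reverse=reverse,
        delta_A=combined,
        temperature=temperature,
        n_frames_R=int(np.asarray(delta_U_R).size),
        n_frames_P=int(np.asarray(delta_U_P).size),
        stderr=stderr,
        convergence_R=conv_r,
        convergence_P=conv_p,
    )
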