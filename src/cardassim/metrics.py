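"""Ensemble verification scores and action-potential physiology metrics."""

from __future__ import annotations

import numpy as np

from .fk import Grid3D, TissueState
from .letkf import Ensemble
from .observations import ObservationSet, observation_operator

__all__ = [
    "spread",
    "spread_by_depth",
    "rmse_obs",
    "crps",
    "extract_apd_apa",
]


def spread(ens: Ensemble) -> dict[str, np.ndarray]:
    """Per-node, per-variable ensemble spread.

    Computed as (M-1)^-1 * (sum_m |x_m - xbar|^2)^(1/2) per node; note the
    normalization sits outside the square root, following the convention of
    the verification literature this package reproduces.
    """
    if ens.M < 2:
        raise ValueError("spread requires M >= 2")
    out = {}
    for name in ("u", "v", "w"):
        arr = getattr(ens, name)
        dev = arr - arr.mean(axis=0)
        out[name] = np.sqrt((dev**2).sum(axis=0)) / (ens.M - 1)
    return out


def spread_by_depth(ens: Ensemble) -> tuple[np.ndarray, np.ndarray]:
    """Depth profile of voltage spread, layer index 0 = epicardium.

    Returns (mean of squared spreads per layer, its square root); the first
    follows the printed reduction over the in-plane indices, the companion
    root is convenient for plotting on the same scale as the spread itself.
    """
    s_u = spread(ens)["u"]  # (nz, ny, nx)
    sq = (s_u**2).mean(axis=(1, 2))
    return sq, np.sqrt(sq)


def rmse_obs(mean_state: TissueState, obs: ObservationSet, grid: Grid3D) -> float:
    """RMS difference between observations and the mean state at the
    nearest grid nodes; restricted to whatever records are passed."""
    if len(obs) == 0:
        raise ValueError("rmse_obs requires a nonempty observation set")
    pred = observation_operator(mean_state, obs, grid)
    return float(np.sqrt(np.mean((obs.value - pred) ** 2)))


def crps(ens_values: np.ndarray, reference: np.ndarray) -> float:
    """Fair (ensemble-size adjusted) kernel CRPS with the 1-norm.

    ``ens_values`` is (M, L); ``reference`` is the length-L vector the
    ensemble is scored against (observations, or the analysis mean for the
    ensemble-consistency variant):

        sum_m ||x_m - y||_1 / M  -  sum_{m,m'} ||x_m - x_m'||_1 / (2 M (M-1))
    """
    ens_values = np.atleast_2d(np.asarray(ens_values, dtype=float))
    reference = np.asarray(reference, dtype=float).ravel()
    M = ens_values.shape[0]
    if M < 2:
        raise ValueError("the adjusted CRPS requires M >= 2")
    term1 = np.abs(ens_values - reference).sum(axis=1).mean()
    pair = 0.0
    for m in range(M):
        pair += np.abs(ens_values[m + 1 :] - ens_values[m]).sum()
    return float(term1 - pair / (M * (M - 1)))


def extract_apd_apa(
    times: np.ndarray,
    u: np.ndarray,
    u_thr: float = 0.1,
    min_samples: int = 3,
) -> list[tuple[float, float]]:
    """Action potential durations and amplitudes from a voltage trace.

    For each upward crossing of ``u_thr`` followed by a downward crossing,
    APD is the time between the (linearly interpolated) crossings and APA
    is the maximum voltage between them.  Incomplete terminal APs and APs
    spanning fewer than ``min_samples`` samples are dropped.  A trace with
    no crossings yields an empty list.
    """
    times = np.asarray(times, dtype=float)
    u = np.asarray(u, dtype=float)
    if times.shape != u.shape:
        raise ValueError("times and u must have equal length")
    above = u > u_thr
    out: list[tuple[float, float]] = []
    i_up = None
    t_up = None
    for i in range(1, len(u)):
        if above[i] and not above[i - 1]:
            frac = (u_thr - u[i - 1]) / (u[i] - u[i - 1])
            t_up = times[i - 1] + frac * (times[i] - times[i - 1])
            i_up = i
        elif i_up is not None and not above[i] and above[i - 1]:
            frac = (u[i - 1] - u_thr) / (u[i - 1] - u[i])
            t_down = times[i - 1] + frac * (times[i] - times[i - 1])
            if i - i_up >= min_samples - 1:
                apa = float(u[i_up:i].max())
                out.append((float(t_down - t_up), apa))
            i_up = None
    return out
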