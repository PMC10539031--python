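"""Local ensemble transform Kalman filter (LETKF) analysis.

The analysis is performed independently at every grid node in the
M-dimensional ensemble space.  For each node, the observations within the
localization cutoff contribute to a local solve

    P~a = [ (M-1) I / rho + Yb^T R~^-1 Yb ]^-1
    wbar = P~a Yb^T R~^-1 (yo - ybar)
    Wa   = [ (M-1) P~a ]^(1/2)            (symmetric square root)

where Yb holds the background ensemble deviations in observation space and
R~^-1 is the diagonal observation precision with the localization taper
applied as observation-error weighting (the standard LETKF realization of
covariance localization).  The node's analysis mean is xbar + X wbar and the
analysis deviations are X Wa, applied to u, v, and w ("strongly coupled":
voltage observations update the gates too).  Multiplicative inflation enters
through rho >= 1; with no local observations the solve reduces exactly to
wbar = 0, Wa = sqrt(rho) I.

Distances for localization are measured in grid units (multiples of hx).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .fk import FKParameters, Grid3D, TissueState
from .observations import ObservationSet, nearest_node_indices

__all__ = [
    "Ensemble",
    "AssimilationConfig",
    "localization_weight",
    "localization_cutoff",
    "gross_error_screen",
    "local_solve",
    "analysis_step",
    "bound_state",
    "initialize_ensemble",
]


# ---------------------------------------------------------------------------
# ensemble container
# ---------------------------------------------------------------------------


@dataclass
class Ensemble:
    """M tissue states sharing one grid, stacked as (M, nz, ny, nx) arrays."""

    t: float
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    member_params: Optional[list[FKParameters]] = None
    diagnostics: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.u.shape == self.v.shape == self.w.shape):
            raise ValueError("u, v, w stacks must share one shape")
        if self.u.shape[0] < 2:
            raise ValueError("ensemble size M must be >= 2")

    @property
    def M(self) -> int:
        return self.u.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.u.shape[1:]

    def mean_state(self) -> TissueState:
        return TissueState(
            self.t, self.u.mean(axis=0), self.v.mean(axis=0), self.w.mean(axis=0)
        )

    def member(self, m: int) -> TissueState:
        return TissueState(self.t, self.u[m], self.v[m], self.w[m])

    def deviations(self, var: str = "u") -> np.ndarray:
        arr = getattr(self, var)
        return arr - arr.mean(axis=0)

    def copy(self) -> "Ensemble":
        return Ensemble(
            self.t, self.u.copy(), self.v.copy(), self.w.copy(),
            None if self.member_params is None else list(self.member_params),
            dict(self.diagnostics),
        )

    @classmethod
    def from_states(cls, states: Sequence[TissueState]) -> "Ensemble":
        t = states[0].t
        return cls(
            t,
            np.stack([s.u for s in states]),
            np.stack([s.v for s in states]),
            np.stack([s.w for s in states]),
        )


@dataclass(frozen=True)
class AssimilationConfig:
    """Numerical controls of the LETKF analysis.

    rho: multiplicative inflation of the analysis deviations.
    sigma_o: localization scale in grid units; observations beyond
        2*sqrt(10/3)*sigma_o have zero weight.
    sigma_g: gross-error multiplier; innovations larger than sigma_g * eta
        are zeroed (the observation is rendered inert for that cycle).
    T_a: assimilation interval in ms.
    bounds: clipping intervals applied to the analysis members.
    coupling: "strong" lets voltage observations update v and w as well.
    """

    rho: float = 1.05
    sigma_o: float = 6.0
    sigma_g: float = 10.0
    T_a: float = 2.0
    u_bounds: tuple[float, float] = (-0.1, 1.5)
    v_bounds: tuple[float, float] = (0.0, 1.0)
    w_bounds: tuple[float, float] = (0.0, 1.0)
    coupling: str = "strong"
    free_run: bool = False

    def __post_init__(self) -> None:
        if self.rho < 1.0:
            raise ValueError("rho must be >= 1")
        if self.sigma_o <= 0 or self.sigma_g <= 0:
            raise ValueError("sigma_o and sigma_g must be > 0")
        for lo, hi in (self.u_bounds, self.v_bounds, self.w_bounds):
            if not lo < hi:
                raise ValueError("bound intervals must be nonempty")
        if self.coupling not in ("strong", "weak"):
            raise ValueError("coupling must be 'strong' or 'weak'")


# ---------------------------------------------------------------------------
# localization and screening
# ---------------------------------------------------------------------------


def localization_cutoff(sigma_o: float) -> float:
    """Total support radius 2 * sqrt(10/3) * sigma_o of the taper (grid units)."""
    return 2.0 * np.sqrt(10.0 / 3.0) * sigma_o


def localization_weight(distance, sigma_o: float):
    """Fifth-order compactly supported localization taper.

    The standard piecewise-rational correlation function with half-width
    c = sqrt(10/3) * sigma_o: weight 1 at distance 0, decaying monotonically
    and reaching exactly zero at 2c.
    """
    r = np.asarray(distance, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be >= 0")
    c = np.sqrt(10.0 / 3.0) * sigma_o
    a = r / c
    w = np.zeros_like(a)
    m1 = a <= 1.0
    a1 = a[m1]
    w[m1] = -0.25 * a1**5 + 0.5 * a1**4 + 0.625 * a1**3 - (5.0 / 3.0) * a1**2 + 1.0
    m2 = (a > 1.0) & (a < 2.0)
    a2 = a[m2]
    w[m2] = (
        (1.0 / 12.0) * a2**5
        - 0.5 * a2**4
        + 0.625 * a2**3
        + (5.0 / 3.0) * a2**2
        - 5.0 * a2
        + 4.0
        - (2.0 / 3.0) / a2
    )
    w = np.clip(w, 0.0, 1.0)
    return float(w) if w.ndim == 0 else w


def gross_error_screen(innovations, etas, sigma_g: float):
    """Zero out innovations whose magnitude exceeds sigma_g * eta.

    Returns (masked innovations, number screened).  Screened observations
    remain in the arrays but become inert in the analysis.
    """
    innovations = np.asarray(innovations, dtype=float)
    etas = np.asarray(etas, dtype=float)
    if innovations.shape != etas.shape:
        raise ValueError("innovations and etas must have equal length")
    bad = np.abs(innovations) > sigma_g * etas
    out = np.where(bad, 0.0, innovations)
    return out, int(bad.sum())


# ---------------------------------------------------------------------------
# local solve (reference implementation; the grid sweep uses the numba twin)
# ---------------------------------------------------------------------------


def local_solve(
    Yb_local: np.ndarray,
    ybar_local: np.ndarray,
    yo_local: np.ndarray,
    etas: np.ndarray,
    loc_weights: np.ndarray,
    rho: float,
    M: int,
):
    """One node's analysis weights from its local observations.

    Returns (wbar, Wa): the mean weight vector (length M) and the symmetric
    transform matrix (M x M).  With no observations this is wbar = 0,
    Wa = sqrt(rho) * I.  A non-finite solve falls back to the
    no-observation behavior.
    """
    Yb_local = np.atleast_2d(np.asarray(Yb_local, dtype=float))
    yo_local = np.atleast_1d(np.asarray(yo_local, dtype=float))
    ybar_local = np.atleast_1d(np.asarray(ybar_local, dtype=float))
    etas = np.atleast_1d(np.asarray(etas, dtype=float))
    loc_weights = np.atleast_1d(np.asarray(loc_weights, dtype=float))
    if np.any(etas <= 0):
        raise ValueError("every eta must be > 0")
    L = len(yo_local)
    if L == 0:
        return np.zeros(M), np.sqrt(rho) * np.eye(M)
    rinv = loc_weights / etas**2
    C = (M - 1.0) / rho * np.eye(M) + (Yb_local * rinv[:, None]).T @ Yb_local
    evals, evecs = np.linalg.eigh(C)
    evals = np.maximum(evals, 1e-12)
    Pa = (evecs / evals) @ evecs.T
    wbar = Pa @ (Yb_local.T @ (rinv * (yo_local - ybar_local)))
    Wa = (evecs * np.sqrt((M - 1.0) / evals)) @ evecs.T
    if not (np.all(np.isfinite(wbar)) and np.all(np.isfinite(Wa))):
        return np.zeros(M), np.sqrt(rho) * np.eye(M)
    return wbar, Wa


@njit(cache=True, fastmath=True)
def _analysis_kernel(
    xbar, X, Y, winno, inv_eta2, indptr, indices, wloc, rho, n_update
):  # pragma: no cover - exercised through analysis_step
    nvar, n = xbar.shape
    M = X.shape[2]
    fac = (M - 1.0) / rho
    sq = np.sqrt(rho)
    for nd in range(n):
        k0 = indptr[nd]
        k1 = indptr[nd + 1]
        if k1 == k0:
            for l in range(n_update):
                for m in range(M):
                    X[l, nd, m] *= sq
            continue
        C = np.zeros((M, M))
        b = np.zeros(M)
        for jj in range(k0, k1):
            i = indices[jj]
            wi = wloc[jj] * inv_eta2[i]
            di = wi * winno[i]
            for a in range(M):
                ya = Y[i, a]
                b[a] += di * ya
                wya = wi * ya
                for c in range(a, M):
                    C[a, c] += wya * Y[i, c]
        for a in range(M):
            C[a, a] += fac
            for c in range(a + 1, M):
                C[c, a] = C[a, c]
        evals, evecs = np.linalg.eigh(C)
        ok = True
        for a in range(M):
            if not np.isfinite(evals[a]):
                ok = False
        if not ok:
            for l in range(n_update):
                for m in range(M):
                    X[l, nd, m] *= sq
            continue
        tmp = evecs.T.copy() @ b
        for a in range(M):
            la = evals[a] if evals[a] > 1e-12 else 1e-12
            tmp[a] /= la
        wbar = evecs @ tmp
        D = np.empty(M)
        for a in range(M):
            la = evals[a] if evals[a] > 1e-12 else 1e-12
            D[a] = np.sqrt((M - 1.0) / la)
        Wa = (evecs * D) @ evecs.T.copy()
        for l in range(n_update):
            md = 0.0
            for m in range(M):
                md += X[l, nd, m] * wbar[m]
            newx = X[l, nd, :].copy() @ Wa
            xbar[l, nd] += md
            for m in range(M):
                X[l, nd, m] = newx[m]


# ---------------------------------------------------------------------------
# neighbor geometry (cached per layout)
# ---------------------------------------------------------------------------

_GEOMETRY_CACHE: dict[bytes, tuple] = {}


def _observation_geometry(grid: Grid3D, obs: ObservationSet, sigma_o: float):
    """Nearest-node indices plus per-node CSR neighbor lists and taper weights."""
    pos = obs.positions
    key = hashlib.md5(
        pos.tobytes()
        + np.array(grid.shape + (grid.hx, grid.hy, grid.hz, sigma_o)).tobytes()
    ).digest()
    hit = _GEOMETRY_CACHE.get(key)
    if hit is not None:
        return hit
    obs_nodes = nearest_node_indices(grid, pos)
    # physical coordinates expressed in grid units (multiples of hx), so
    # that sigma_o keeps one consistent meaning on anisotropic spacings
    nz, ny, nx = grid.shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz) * grid.hz, np.arange(ny) * grid.hy,
        np.arange(nx) * grid.hx, indexing="ij",
    )
    node_gu = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]) / grid.hx
    obs_gu = pos / grid.hx
    cutoff = localization_cutoff(sigma_o)
    indptr = np.zeros(len(node_gu) + 1, dtype=np.int64)
    idx_chunks = []
    w_chunks = []
    chunk = max(1, int(2e6 // max(1, len(obs_gu))))
    for start in range(0, len(node_gu), chunk):
        blk = node_gu[start : start + chunk]
        d = np.sqrt(((blk[:, None, :] - obs_gu[None, :, :]) ** 2).sum(axis=2))
        inside = d < cutoff
        counts = inside.sum(axis=1)
        indptr[start + 1 : start + 1 + len(blk)] = counts
        rows, cols = np.nonzero(inside)
        idx_chunks.append(cols.astype(np.int64))
        w_chunks.append(localization_weight(d[rows, cols], sigma_o))
    indptr = np.cumsum(indptr)
    indices = np.concatenate(idx_chunks) if idx_chunks else np.zeros(0, dtype=np.int64)
    weights = np.concatenate(w_chunks) if w_chunks else np.zeros(0)
    out = (obs_nodes, indptr, indices, weights)
    if len(_GEOMETRY_CACHE) > 8:
        _GEOMETRY_CACHE.clear()
    _GEOMETRY_CACHE[key] = out
    return out


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------


def bound_state(ens: Ensemble, cfg: AssimilationConfig) -> Ensemble:
    """Clip every member to the configured physical bounds (in place)."""
    np.clip(ens.u, *cfg.u_bounds, out=ens.u)
    np.clip(ens.v, *cfg.v_bounds, out=ens.v)
    np.clip(ens.w, *cfg.w_bounds, out=ens.w)
    return ens


def analysis_step(
    bg: Ensemble,
    obs: Optional[ObservationSet],
    cfg: AssimilationConfig,
    grid: Grid3D,
) -> Ensemble:
    """Transform the background ensemble into the analysis ensemble.

    In free-run mode (or with no observations) the mean is preserved
    bitwise and the deviations are inflated by sqrt(rho); otherwise every
    node runs its local solve on the observations within the localization
    cutoff at the current time.
    """
    M = bg.M
    if cfg.free_run or obs is None or len(obs) == 0:
        # the no-observation limit of the transform: mean untouched,
        # deviations inflated by sqrt(rho), members bounded.  The mean is
        # preserved exactly whenever the bounds are inactive.
        out = bg.copy()
        if cfg.rho > 1.0:
            sq = np.sqrt(cfg.rho)
            for name in ("u", "v", "w"):
                arr = getattr(out, name)
                mean = arr.mean(axis=0)
                arr -= mean
                arr *= sq
                arr += mean
            bound_state(out, cfg)
        out.diagnostics = {"n_obs": 0, "n_screened": 0}
        return out

    if abs(obs.t - bg.t) > 1e-6:
        raise ValueError(
            f"observation time {obs.t} ms does not match ensemble time {bg.t} ms"
        )

    obs_nodes, indptr, indices, wloc = _observation_geometry(grid, obs, cfg.sigma_o)

    n = grid.n_nodes
    u2 = bg.u.reshape(M, n)
    v2 = bg.v.reshape(M, n)
    w2 = bg.w.reshape(M, n)
    xbar = np.ascontiguousarray(
        np.stack([u2.mean(axis=0), v2.mean(axis=0), w2.mean(axis=0)])
    )
    X = np.empty((3, n, M))
    X[0] = (u2 - xbar[0]).T
    X[1] = (v2 - xbar[1]).T
    X[2] = (w2 - xbar[2]).T
    X = np.ascontiguousarray(X)

    # observation-space background: u at the node nearest each record
    yb = u2[:, obs_nodes]  # (M, O)
    ybar = yb.mean(axis=0)
    Y = np.ascontiguousarray((yb - ybar).T)  # (O, M)
    innov = obs.value - ybar
    winno, n_screened = gross_error_screen(innov, obs.eta, cfg.sigma_g)
    # a screened observation is inert for the whole update: it neither
    # moves the mean nor contracts the deviations
    inv_eta2 = 1.0 / obs.eta**2
    inv_eta2[np.abs(innov) > cfg.sigma_g * obs.eta] = 0.0

    n_update = 3 if cfg.coupling == "strong" else 1
    _analysis_kernel(
        xbar, X, Y, winno, inv_eta2, indptr, indices, wloc, cfg.rho, n_update
    )

    strong = cfg.coupling == "strong"
    out = Ensemble(
        t=bg.t,
        u=(xbar[0] + X[0].T).reshape(bg.u.shape).copy(),
        v=(xbar[1] + X[1].T).reshape(bg.v.shape).copy() if strong else bg.v.copy(),
        w=(xbar[2] + X[2].T).reshape(bg.w.shape).copy() if strong else bg.w.copy(),
        member_params=None if bg.member_params is None else list(bg.member_params),
    )
    bound_state(out, cfg)
    out.diagnostics = {"n_obs": len(obs), "n_screened": n_screened}
    return out


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def initialize_ensemble(
    grid: Grid3D,
    M: int,
    p: FKParameters,
    cfg: AssimilationConfig,
    rng: np.random.Generator,
    amplitude: float = 0.1,
) -> Ensemble:
    """Rest states plus spatially correlated Gaussian voltage perturbations.

    White noise is smoothed with a Gaussian of width sigma_o grid units and
    rescaled so every member's perturbation field has standard deviation
    ``amplitude``; gates start fully recovered (v = w = 1).  Deterministic
    under a fixed rng seed.
    """
    from scipy.ndimage import gaussian_filter

    if M < 2:
        raise ValueError("M must be >= 2")
    shape = (M,) + grid.shape
    u = np.zeros(shape)
    if amplitude > 0:
        noise = rng.standard_normal(shape)
        for m in range(M):
            sm = gaussian_filter(noise[m], sigma=cfg.sigma_o, mode="mirror")
            sd = sm.std()
            if sd > 0:
                u[m] = sm * (amplitude / sd)
        np.clip(u, *cfg.u_bounds, out=u)
    return Ensemble(t=0.0, u=u, v=np.ones(shape), w=np.ones(shape))
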