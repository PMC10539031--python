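"""Observation handling: sampling recordings, uncertainty models, and the
observation operator.

Observations are point measurements of the normalized transmembrane
potential ``u`` taken on the epicardial (z = 0) and endocardial (z = S)
surfaces, each carrying a standard-deviation uncertainty ``eta``.  Interior
"synthetic" observations may be appended at mid-depth by interpolating the
two surface values; they carry a deliberately large uncertainty so that
they only gently constrain the reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RectBivariateSpline

from .fk import Grid3D, TissueState

__all__ = [
    "Recording",
    "Observation",
    "ObservationSet",
    "UncertaintyModel",
    "sample_recording",
    "extract_surface_observations",
    "wavefront_uncertainty",
    "synthesize_middepth_observations",
    "observation_operator",
    "nearest_node_indices",
    "grid_layout",
    "recording_layout",
    "uniform_layout",
    "write_observations",
    "read_observations",
]

SURFACE = "surface"
SYNTHETIC_INTERIOR = "synthetic-interior"


@dataclass
class Recording:
    """A single-surface recording: frames (n_frames, ny, nx) at uniform times."""

    times: np.ndarray
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] != self.times.size:
            raise ValueError("frames must be (n_frames, ny, nx) matching times")
        self._spline_cache: dict[int, RectBivariateSpline] = {}

    def _spline(self, k: int) -> RectBivariateSpline:
        sp = self._spline_cache.get(k)
        if sp is None:
            sp = RectBivariateSpline(self.y, self.x, self.frames[k], kx=3, ky=3)
            self._spline_cache[k] = sp
        return sp


@dataclass(frozen=True)
class Observation:
    """One tagged, located, uncertainty-weighted point observation."""

    var: str
    x: float
    y: float
    z: float
    t: float
    value: float
    eta: float
    provenance: str = SURFACE

    def __post_init__(self) -> None:
        if not self.eta > 0:
            raise ValueError("eta must be > 0")
        if not np.isfinite(self.value):
            raise ValueError("value must be finite")


@dataclass
class ObservationSet:
    """All observations at one time, stored columnwise."""

    t: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    value: np.ndarray
    eta: np.ndarray
    provenance: np.ndarray
    var: str = "u"

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in ("y", "z", "value", "eta", "provenance"):
            if len(getattr(self, name)) != n:
                raise ValueError("observation columns must share one length")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        self.provenance = np.asarray(self.provenance, dtype=object)
        if np.any(self.eta <= 0):
            raise ValueError("every eta must be > 0")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])

    def surface_mask(self) -> np.ndarray:
        return self.provenance == SURFACE

    def select(self, mask: np.ndarray) -> "ObservationSet":
        return ObservationSet(
            self.t, self.x[mask], self.y[mask], self.z[mask],
            self.value[mask], self.eta[mask], self.provenance[mask], self.var,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_ms": self.t,
                "var": self.var,
                "x_cm": self.x,
                "y_cm": self.y,
                "z_cm": self.z,
                "value": self.value,
                "eta": self.eta,
                "provenance": self.provenance,
            }
        )


@dataclass(frozen=True)
class UncertaintyModel:
    """Observation uncertainty assignment.

    In ``constant`` mode every surface observation gets ``eta_lo``.  In
    ``wavefront`` mode the uncertainty is a scaled, truncated Gaussian of
    the observed value, peaking at ``eta_hi`` mid-upstroke (value 0.5) and
    falling back to ``eta_lo`` outside the (u_lo, u_hi) band: the blunted
    wavefronts of optically mapped data make intermediate voltages genuinely
    ambiguous, while clearly quiescent or clearly excited values are
    trusted.
    """

    eta_lo: float = 0.05
    eta_hi: float = 0.50
    u_lo: float = 0.1
    u_hi: float = 0.9
    k_eta: Optional[float] = None
    mode: str = "constant"

    def __post_init__(self) -> None:
        if not (0 < self.eta_lo <= self.eta_hi):
            raise ValueError("require 0 < eta_lo <= eta_hi")
        if not self.u_lo < self.u_hi:
            raise ValueError("require u_lo < u_hi")
        if self.mode not in ("constant", "wavefront"):
            raise ValueError(f"unknown uncertainty mode {self.mode!r}")
        if self.k_eta is None:
            # Gaussian term <= 1e-3 * (eta_hi - eta_lo) at the truncation
            # boundaries, so eta is continuous there to that tolerance.
            half = 0.5 * (self.u_hi - self.u_lo)
            object.__setattr__(self, "k_eta", np.sqrt(np.log(1e3)) / half)


def wavefront_uncertainty(value, um: UncertaintyModel):
    """Value-dependent uncertainty eta(y^o); scalar in, scalar out."""
    value = np.asarray(value, dtype=float)
    mid = 0.5 * (um.u_hi + um.u_lo)
    gauss = um.eta_lo + (um.eta_hi - um.eta_lo) * np.exp(
        -um.k_eta**2 * (value - mid) ** 2
    )
    inside = (value > um.u_lo) & (value < um.u_hi)
    out = np.where(inside, gauss, um.eta_lo)
    return float(out) if out.ndim == 0 else out


def sample_recording(
    recording: Recording, points: np.ndarray, t: float
) -> np.ndarray:
    """Sample a surface recording at (x, y) points and time t.

    Cubic spatial interpolation of the two temporally adjacent frames,
    blended linearly in time.  Points and times outside the recorded domain
    are rejected.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    times = recording.times
    if not (times[0] <= t <= times[-1]):
        raise ValueError(f"time {t} ms outside recorded span [{times[0]}, {times[-1]}]")
    for px, py in points:
        if not (recording.x[0] <= px <= recording.x[-1]) or not (
            recording.y[0] <= py <= recording.y[-1]
        ):
            raise ValueError(f"point ({px}, {py}) outside recorded area")
    k = int(np.searchsorted(times, t, side="right") - 1)
    if k == times.size - 1:
        k -= 1
    frac = (t - times[k]) / (times[k + 1] - times[k])
    v0 = recording._spline(k).ev(points[:, 1], points[:, 0])
    if frac == 0.0:
        return v0
    v1 = recording._spline(k + 1).ev(points[:, 1], points[:, 0])
    return (1.0 - frac) * v0 + frac * v1


def extract_surface_observations(
    epi: Recording,
    endo: Recording,
    points: np.ndarray,
    t: float,
    um: UncertaintyModel,
    depth: float,
) -> ObservationSet:
    """One observation per layout point per surface at time t.

    Values are clipped to [0, 1]; epicardial records sit at z = 0 and
    endocardial records at z = ``depth``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("empty observation layout")
    vals_epi = np.clip(sample_recording(epi, points, t), 0.0, 1.0)
    vals_endo = np.clip(sample_recording(endo, points, t), 0.0, 1.0)
    values = np.concatenate([vals_epi, vals_endo])
    x = np.concatenate([points[:, 0], points[:, 0]])
    y = np.concatenate([points[:, 1], points[:, 1]])
    z = np.concatenate([np.zeros(len(points)), np.full(len(points), depth)])
    if um.mode == "wavefront":
        eta = wavefront_uncertainty(values, um)
    else:
        eta = np.full(values.shape, um.eta_lo)
    return ObservationSet(
        t=t, x=x, y=y, z=z, value=values, eta=eta,
        provenance=np.array([SURFACE] * len(values), dtype=object),
    )


def synthesize_middepth_observations(
    obs: ObservationSet,
    grid: Grid3D,
    layout: np.ndarray,
    eta_interior: float = 0.50,
) -> ObservationSet:
    """Append interior observations at z = S/2 interpolated through depth.

    Each interior value is the linear-in-depth interpolation (at mid-depth,
    the average) of the two surface values at the projected (x, y),
    looked up from the nearest surface record on each surface.
    """
    layout = np.atleast_2d(np.asarray(layout, dtype=float))
    epi_mask = obs.surface_mask() & (obs.z == 0.0)
    endo_mask = obs.surface_mask() & (obs.z > 0.0)
    if not epi_mask.any() or not endo_mask.any():
        raise ValueError("mid-depth synthesis requires observations on both surfaces")

    def _nearest_values(mask):
        xs, ys, vs = obs.x[mask], obs.y[mask], obs.value[mask]
        d2 = (layout[:, 0:1] - xs[None, :]) ** 2 + (layout[:, 1:2] - ys[None, :]) ** 2
        return vs[np.argmin(d2, axis=1)]

    v_mid = 0.5 * (_nearest_values(epi_mask) + _nearest_values(endo_mask))
    n = len(layout)
    return ObservationSet(
        t=obs.t,
        x=np.concatenate([obs.x, layout[:, 0]]),
        y=np.concatenate([obs.y, layout[:, 1]]),
        z=np.concatenate([obs.z, np.full(n, grid.depth / 2.0)]),
        value=np.concatenate([obs.value, v_mid]),
        eta=np.concatenate([obs.eta, np.full(n, eta_interior)]),
        provenance=np.concatenate(
            [obs.provenance, np.array([SYNTHETIC_INTERIOR] * n, dtype=object)]
        ),
    )


def nearest_node_indices(grid: Grid3D, positions: np.ndarray) -> np.ndarray:
    """Flat (z, y, x)-order node index nearest each (x, y, z) position.

    Positions farther than half a cell from every node (i.e. outside the
    grid by more than h/2 in any direction) are rejected.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    idx = np.empty((len(positions), 3), dtype=np.int64)
    tol = 0.5 + 1e-9
    for a, (h, n) in enumerate(
        [(grid.hx, grid.nx), (grid.hy, grid.ny), (grid.hz, grid.nz)]
    ):
        frac = positions[:, a] / h
        i = np.rint(frac).astype(np.int64)
        bad = (np.abs(frac - i) > tol) | (i < 0) | (i >= n)
        if bad.any():
            j = int(np.argmax(bad))
            raise ValueError(
                f"observation position {tuple(positions[j])} is farther than half "
                "a cell from any grid node"
            )
        idx[:, a] = i
    # flat index in (z, y, x) order
    return (idx[:, 2] * grid.ny + idx[:, 1]) * grid.nx + idx[:, 0]


def observation_operator(
    state: TissueState, obs: ObservationSet, grid: Grid3D
) -> np.ndarray:
    """Map a state to observation space: u sampled at the nearest node,
    one predicted value per record, order-preserving."""
    flat = nearest_node_indices(grid, obs.positions)
    return state.u.reshape(-1)[flat]


# ---------------------------------------------------------------------------
# layouts and files
# ---------------------------------------------------------------------------


def grid_layout(grid: Grid3D, stride: int = 1) -> np.ndarray:
    """Node-aligned (x, y) sample points covering the surface every ``stride`` nodes."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    xs = grid.x[::stride]
    ys = grid.y[::stride]
    xx, yy = np.meshgrid(xs, ys, indexing="xy")
    return np.column_stack([xx.ravel(), yy.ravel()])


def recording_layout(rec: Recording, stride: int = 1) -> np.ndarray:
    """Node-aligned (x, y) sample points over a recording's own pixel grid."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    xx, yy = np.meshgrid(rec.x[::stride], rec.y[::stride], indexing="xy")
    return np.column_stack([xx.ravel(), yy.ravel()])


def uniform_layout(
    x_range: tuple[float, float], y_range: tuple[float, float], m: int
) -> np.ndarray:
    """m x m points distributed uniformly over a rectangular region."""
    xs = np.linspace(x_range[0], x_range[1], m)
    ys = np.linspace(y_range[0], y_range[1], m)
    xx, yy = np.meshgrid(xs, ys, indexing="xy")
    return np.column_stack([xx.ravel(), yy.ravel()])


def write_observations(sets: Sequence[ObservationSet], path) -> None:
    """Write observation sets as a delimited text table (one row per record)."""
    frames = [s.to_frame() for s in np.atleast_1d(sets)]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_observations(path) -> list[ObservationSet]:
    """Read a table written by :func:`write_observations`, grouped by time."""
    df = pd.read_csv(path, sep="\t")
    required = {"t_ms", "var", "x_cm", "y_cm", "z_cm", "value", "eta", "provenance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observation file missing columns: {sorted(missing)}")
    out = []
    for t, g in df.groupby("t_ms", sort=True):
        out.append(
            ObservationSet(
                t=float(t),
                x=g["x_cm"].to_numpy(),
                y=g["y_cm"].to_numpy(),
                z=g["z_cm"].to_numpy(),
                value=g["value"].to_numpy(),
                eta=g["eta"].to_numpy(),
                provenance=g["provenance"].to_numpy(dtype=object),
                var=str(g["var"].iloc[0]),
            )
        )
    return out
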