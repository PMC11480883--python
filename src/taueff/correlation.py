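"""From orientation time series to spectral-density models.

Forward pipeline: a unit-vector trajectory u(t) (e.g. an N–H bond
vector exported from MD) → second-order rotational correlation
function g(t) = ⟨P₂(u(t)·u(t+Δ))⟩ → multi-exponential fit → τ_eff and
Redfield rates.  A rotational-diffusion simulator generates synthetic
trajectories with a known answer (g(t) = exp(−6·D_r·t) for isotropic
diffusion), so every estimator in the package is testable without
external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.optimize import nnls
from scipy.signal import fftconvolve

from .relaxation_theory import SpectralDensityModel

__all__ = [
    "CorrelationFunction",
    "VectorTrajectory",
    "MultiExpFit",
    "AcfTauEstimate",
    "p2_autocorrelation",
    "simulate_rotational_diffusion",
    "fit_multiexponential",
    "tau_eff_from_acf",
    "read_vector_csv",
    "write_vector_csv",
    "read_acf_csv",
    "write_acf_csv",
]


@dataclass(frozen=True)
class CorrelationFunction:
    """Sampled second-order orientational correlation function g(t).

    ``lags`` are ascending time points in seconds starting at 0;
    ``values`` the (dimensionless) correlation, with g(0) = 1.
    """

    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if lags.ndim != 1 or lags.shape != values.shape or lags.size < 1:
            raise ValueError("lags and values must be equal-length 1-D arrays")
        if lags[0] != 0.0:
            raise ValueError("lags must start at 0")
        if lags.size > 1 and np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if abs(values[0] - 1.0) > 1e-9:
            raise ValueError(f"g(0) must equal 1 (got {values[0]!r})")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class VectorTrajectory:
    """Sequential unit vectors sampled every ``timestep`` seconds."""

    timestep: float
    vectors: np.ndarray   # shape (n_frames, 3)

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 2:
            raise ValueError("vectors must be an (n>=2, 3) array")
        if self.timestep <= 0 or not math.isfinite(self.timestep):
            raise ValueError("timestep must be positive and finite")
        norms = np.linalg.norm(v, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("all vectors must be unit-norm to 1e-6")
        object.__setattr__(self, "vectors", v)

    @property
    def n_frames(self) -> int:
        return int(self.vectors.shape[0])


def p2_autocorrelation(traj: VectorTrajectory,
                       max_lag: int) -> CorrelationFunction:
    """All-origins estimator of g(Δ) = ⟨P₂(u(t)·u(t+Δ))⟩.

    P₂(x) = (3x²−1)/2.  Uses the identity (u·u′)² = Σ_ab (u_a u_b)(u′_a u′_b)
    to compute the average over all time origins with FFT
    cross-correlations of the 6 unique component products — O(N log N)
    instead of O(N·max_lag).
    """
    if not (0 < max_lag < traj.n_frames):
        raise ValueError(
            f"max_lag must be in [1, n_frames-1] = [1, {traj.n_frames - 1}], "
            f"got {max_lag}"
        )
    v = traj.vectors
    n = traj.n_frames
    # products: xx, yy, zz (weight 1) and xy, xz, yz (weight 2)
    pairs = [(0, 0, 1.0), (1, 1, 1.0), (2, 2, 1.0),
             (0, 1, 2.0), (0, 2, 2.0), (1, 2, 2.0)]
    acc = np.zeros(max_lag + 1)
    for a, b, w in pairs:
        s = v[:, a] * v[:, b]
        corr = fftconvolve(s, s[::-1])[n - 1:n + max_lag]
        acc += w * corr
    counts = n - np.arange(max_lag + 1)
    dot2 = acc / counts                     # ⟨(u·u′)²⟩ per lag
    g = 1.5 * dot2 - 0.5
    g[0] = 1.0                              # exact at zero lag (unit norms)
    lags = np.arange(max_lag + 1) * traj.timestep
    return CorrelationFunction(lags=lags, values=g)


def simulate_rotational_diffusion(dr: float, dt: float, n_frames: int,
                                  seed: Union[int, np.random.Generator],
                                  u0: Optional[np.ndarray] = None
                                  ) -> VectorTrajectory:
    """Isotropic rotational diffusion of a unit vector on the sphere.

    Each step applies a random rotation with independent Gaussian
    angular displacements of variance 2·D_r·dt per axis, so for
    D_r·dt ≪ 1 the resulting P₂ correlation function decays as
    exp(−6·D_r·t).  Deterministic for a fixed seed.
    """
    if dr <= 0 or dt <= 0:
        raise ValueError("dr and dt must be positive")
    if dr * dt >= 0.05:
        raise ValueError(
            f"time step too coarse: require dr*dt < 0.05, got {dr * dt:g}"
        )
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    sigma = math.sqrt(2.0 * dr * dt)
    steps = rng.normal(0.0, sigma, size=(n_frames - 1, 3))
    out = np.empty((n_frames, 3))
    if u0 is None:
        ux, uy, uz = 0.0, 0.0, 1.0
    else:
        u0 = np.asarray(u0, dtype=float)
        nrm = float(np.linalg.norm(u0))
        if nrm == 0:
            raise ValueError("u0 must be non-zero")
        ux, uy, uz = (u0 / nrm).tolist()
    out[0] = (ux, uy, uz)
    for i in range(n_frames - 1):
        wx, wy, wz = steps[i]
        theta = math.sqrt(wx * wx + wy * wy + wz * wz)
        if theta > 0.0:
            ax, ay, az = wx / theta, wy / theta, wz / theta
            ct, st = math.cos(theta), math.sin(theta)
            dot = ax * ux + ay * uy + az * uz
            # Rodrigues rotation of u about axis (ax,ay,az) by theta
            cx = ay * uz - az * uy
            cy = az * ux - ax * uz
            cz = ax * uy - ay * ux
            ux = ux * ct + cx * st + ax * dot * (1.0 - ct)
            uy = uy * ct + cy * st + ay * dot * (1.0 - ct)
            uz = uz * ct + cz * st + az * dot * (1.0 - ct)
            nrm = math.sqrt(ux * ux + uy * uy + uz * uz)
            ux, uy, uz = ux / nrm, uy / nrm, uz / nrm
        out[i + 1] = (ux, uy, uz)
    return VectorTrajectory(timestep=dt, vectors=out)


@dataclass(frozen=True)
class MultiExpFit:
    """Result of a grid-based multi-exponential fit of g(t).

    ``model`` holds the renormalized weights; ``achieved_g0`` is the
    unnormalized weight sum actually fitted at t = 0; ``residual`` the
    RMS misfit; ``non_decaying`` flags input whose weight piles up at
    the longest grid timescale (g barely decays over the observed
    window, so timescales are not constrained by the data).
    """

    model: SpectralDensityModel
    achieved_g0: float
    residual: float
    non_decaying: bool


def fit_multiexponential(g: CorrelationFunction,
                         grid: Union[int, np.ndarray, None] = None,
                         tau_min: float = 1e-12,
                         tau_max: float = 1e-6) -> MultiExpFit:
    """Fit g(t) ≈ Σ wᵢ exp(−t/τᵢ) with non-negative least squares.

    The timescales live on a log-spaced grid (default 64 points, 1 ps
    up to the last observed lag, capped at 1 µs); only the
    non-negative weights are solved, which makes the fit convex and
    reproducible.  The grid is capped at the observation window
    because longer timescales are not identifiable from the data and,
    on noisy estimated correlation functions, would soak up tail noise
    and inflate τ_eff.  Individual components are not identifiable in
    general but τ_eff = Σαᵢτᵢ is.  Pass an explicit ``grid`` array to
    override.
    """
    if isinstance(grid, (int, np.integer)) or grid is None:
        n = 64 if grid is None else int(grid)
        if n < 2:
            raise ValueError("grid must have at least 2 timescales")
        upper = min(tau_max, float(g.lags[-1])) if g.lags.size else tau_max
        if upper <= tau_min:
            raise ValueError(
                f"observed lag window ({g.lags[-1]:g} s) is shorter than "
                f"the smallest grid timescale ({tau_min:g} s)"
            )
        taus = np.logspace(math.log10(tau_min), math.log10(upper), n)
    else:
        taus = np.asarray(grid, dtype=float)
        if taus.ndim != 1 or taus.size == 0 or np.any(taus <= 0):
            raise ValueError("grid timescales must be positive")
    if g.lags.size < 2:
        raise ValueError("correlation function must have at least 2 lags")
    design = np.exp(-g.lags[:, None] / taus[None, :])
    weights, rnorm = nnls(design, g.values)
    total = float(weights.sum())
    if total <= 0:
        raise ValueError("degenerate correlation function: all fitted "
                         "weights are zero")
    alphas = weights / total
    non_decaying = bool(alphas[-1] > 0.5)
    keep = alphas > 0
    model = SpectralDensityModel(weights=alphas[keep] / alphas[keep].sum(),
                                 timescales=taus[keep])
    residual = float(rnorm / math.sqrt(g.lags.size))
    return MultiExpFit(model=model, achieved_g0=total, residual=residual,
                       non_decaying=non_decaying)


@dataclass(frozen=True)
class AcfTauEstimate:
    """τ_eff from direct integration of g(t), with provenance.

    ``tail`` is the contribution extrapolated beyond the last observed
    lag (zero when truncated); ``flag`` marks degenerate input.
    """

    tau_eff: float
    tail: float
    flag: Optional[str] = None


def tau_eff_from_acf(g: CorrelationFunction,
                     tail_model: str = "exponential-extrapolation"
                     ) -> AcfTauEstimate:
    """τ_eff as the area under g(t).

    Trapezoidal integral over the observed lags plus a tail
    correction: an exponential is fitted to the last decade of lags
    and integrated to infinity (``exponential-extrapolation``), or the
    tail is assumed zero (``truncate``).
    """
    if tail_model not in ("exponential-extrapolation", "truncate"):
        raise ValueError(f"unknown tail model {tail_model!r}")
    if g.lags.size < 2:
        raise ValueError("correlation function must have at least 2 lags")
    area = float(np.trapezoid(g.values, g.lags))
    if tail_model == "truncate":
        return AcfTauEstimate(tau_eff=area, tail=0.0)
    g_end = float(g.values[-1])
    if g_end <= 0.0:
        # already fully decayed (or noise-negative): nothing to extrapolate
        return AcfTauEstimate(tau_eff=area, tail=0.0,
                              flag="fully-decayed" if g_end == 0 else None)
    sel = (g.lags >= g.lags[-1] / 10.0) & (g.values > 0)
    if sel.sum() < 2:
        return AcfTauEstimate(tau_eff=area, tail=0.0,
                              flag="tail-not-fittable")
    t_tail = g.lags[sel]
    log_g = np.log(g.values[sel])
    slope, _ = np.polyfit(t_tail, log_g, 1)
    if slope >= 0:
        return AcfTauEstimate(tau_eff=area, tail=0.0, flag="non-decaying")
    tau_tail = -1.0 / slope
    tail = g_end * tau_tail     # ∫_T^∞ g(T)·e^{−(t−T)/τ} dt
    return AcfTauEstimate(tau_eff=area + tail, tail=tail)


# ---------------------------------------------------------------------------
# plain-text interchange

def write_vector_csv(path, traj: VectorTrajectory) -> None:
    """Write a trajectory as CSV with columns t, x, y, z (t in seconds)."""
    t = np.arange(traj.n_frames) * traj.timestep
    data = np.column_stack([t, traj.vectors])
    np.savetxt(path, data, delimiter=",", header="t,x,y,z", comments="",
               fmt="%.12g")


def read_vector_csv(path) -> VectorTrajectory:
    """Read a t,x,y,z CSV written by :func:`write_vector_csv`."""
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.ndim != 2 or data.shape[1] < 4 or data.shape[0] < 2:
        raise ValueError(f"{path}: expected >=2 rows of t,x,y,z")
    dt = float(np.median(np.diff(data[:, 0])))
    vec = data[:, 1:4]
    vec = vec / np.linalg.norm(vec, axis=1, keepdims=True)
    return VectorTrajectory(timestep=dt, vectors=vec)


def write_acf_csv(path, g: CorrelationFunction) -> None:
    """Write a correlation function as two-column CSV (lag_s, g)."""
    np.savetxt(path, np.column_stack([g.lags, g.values]), delimiter=",",
               header="lag_s,g", comments="", fmt="%.12g")


def read_acf_csv(path) -> CorrelationFunction:
    """Read a lag_s,g CSV written by :func:`write_acf_csv`."""
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns lag_s,g")
    return CorrelationFunction(lags=data[:, 0], values=data[:, 1])
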