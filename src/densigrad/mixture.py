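"""Gaussian deconvolution of gradient profiles and dense-DNA quantification.

A DNA species at equilibrium in a caesium sulphate gradient forms a
Gaussian concentration profile along the RI axis: the mean is its buoyant
density (in RI units), the height is proportional to the amount of DNA,
and sigma shrinks with fragment size.  Profiles carrying bulk DNA plus a
denser sub-population are biphasic and are deconvolved by least squares
into two components; the proportion of dense DNA is the ratio of the
integrated DNA in an extended dense window of the secondary gradient to
the total integrated DNA of the primary gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import ParameterError, QuantificationError
from .gradient import GradientProfile

__all__ = [
    "GaussianComponent",
    "MixtureFit",
    "PoolingWindow",
    "DenseQuantification",
    "POOLING_WINDOWS",
    "fit_mixture",
    "select_window",
    "percent_dense",
    "peak_window_overlap_length",
]

SIGMA_BOUNDS = (1e-4, 1e-2)  # RI units; gradients span ~0.02 RI


@dataclass(frozen=True)
class GaussianComponent:
    """One DNA species: A·exp(−(ri−μ)²/(2σ²))."""

    mean: float  # RI units
    sigma: float  # RI units
    amplitude: float  # concentration units (peak height)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def __call__(self, ri) -> np.ndarray:
        ri = np.asarray(ri, dtype=float)
        return self.amplitude * np.exp(-((ri - self.mean) ** 2) / (2.0 * self.sigma**2))

    @property
    def area(self) -> float:
        """Integral over RI, A·σ·√(2π) — proportional to the amount of DNA."""
        return self.amplitude * self.sigma * np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class MixtureFit:
    """Best least-squares fit of 1–2 Gaussian components to a profile."""

    components: tuple[GaussianComponent, ...]
    sse: float
    n_points: int
    converged: bool

    def __post_init__(self) -> None:
        if not 1 <= len(self.components) <= 2:
            raise ValueError("1 or 2 components supported")
        means = [c.mean for c in self.components]
        if means != sorted(means):
            raise ValueError("components must be sorted by ascending mean")
        if self.sse < -1e-12:
            raise ValueError("sse must be non-negative")

    @property
    def dense_component(self) -> GaussianComponent:
        """The larger-mean (denser) component."""
        return self.components[-1]

    def predict(self, ri) -> np.ndarray:
        ri = np.asarray(ri, dtype=float)
        return sum((c(ri) for c in self.components), start=np.zeros_like(ri))


@dataclass(frozen=True)
class PoolingWindow:
    """Closed RI interval used to pool fractions of one DNA class."""

    name: str
    ri_lo: float
    ri_hi: float

    def __post_init__(self) -> None:
        if not self.ri_lo < self.ri_hi:
            raise ValueError("ri_lo must be < ri_hi")

    def contains(self, ri) -> np.ndarray:
        ri = np.asarray(ri, dtype=float)
        return (ri >= self.ri_lo) & (ri <= self.ri_hi)


#: Study pooling windows: bulk and dense/light shoulders on the primary
#: gradient, and the extended dense window used for quantification on the
#: secondary gradient.
POOLING_WINDOWS: dict[str, PoolingWindow] = {
    "bulk": PoolingWindow("bulk", 1.3670, 1.3682),
    "dense": PoolingWindow("dense", 1.3695, 1.3715),
    "light": PoolingWindow("light", 1.3630, 1.3660),
    "dense_extended": PoolingWindow("dense_extended", 1.3700, 1.3750),
}


@dataclass(frozen=True)
class DenseQuantification:
    """Percent dense DNA: window integral of secondary over total of primary."""

    dense_integral: float
    total_integral: float
    percent_dense: float


def _model(params: np.ndarray, ri: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros_like(ri)
    for j in range(k):
        mu, sig, amp = params[3 * j : 3 * j + 3]
        out += amp * np.exp(-((ri - mu) ** 2) / (2.0 * sig**2))
    return out


def _solve(ri, y, p0, k, bounds):
    p0 = np.clip(p0, bounds[0] + 1e-12, bounds[1] - 1e-12)
    return least_squares(
        lambda p: _model(p, ri, k) - y,
        p0,
        bounds=bounds,
        method="trf",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=2000,
    )


def _moment_init(ri: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    w = np.clip(y, 0.0, None)
    if w.sum() <= 0:
        return float(ri.mean()), float(ri.std() or 1e-3), 1e-6
    mu = float(np.average(ri, weights=w))
    sig = float(np.sqrt(np.average((ri - mu) ** 2, weights=w)))
    return mu, min(max(sig, SIGMA_BOUNDS[0]), SIGMA_BOUNDS[1]), float(y.max())


def fit_mixture(profile: GradientProfile, k: int = 1, init=None) -> MixtureFit:
    """Fit ``k`` Gaussian components to a (baseline-corrected) profile.

    Minimises the sum of squared differences between the per-fraction DNA
    concentrations and the Gaussian mixture over the RI axis, with bounded
    parameters (means within the data range, sigma in ``SIGMA_BOUNDS``,
    amplitudes non-negative) and multi-start initialisation: the
    two-component fit is seeded both from moments and from the
    one-component solution plus a second component at the dense-window
    centre, which makes its SSE nested below the one-component SSE.

    Parameters
    ----------
    profile
        Gradient with RI defined everywhere; corrected concentrations are
        used when present, raw readings otherwise.
    k
        Number of components (1 or 2).
    init
        Optional explicit starting components (list of
        :class:`GaussianComponent`), tried in addition to the defaults.
    """
    if k not in (1, 2):
        raise ParameterError(f"k must be 1 or 2, got {k}")
    ri = profile.ri
    if np.isnan(ri).any():
        raise ParameterError("profile needs RI on every fraction; run interpolate_ri first")
    y = profile.signal
    if len(ri) < 3 * k + 1:
        raise ParameterError(f"need at least {3 * k + 1} fractions for a k={k} fit")

    lo_mu, hi_mu = float(ri.min()), float(ri.max())
    amp_hi = max(2.0 * float(np.abs(y).max()), 1e-6)
    b1 = (np.array([lo_mu, SIGMA_BOUNDS[0], 0.0]), np.array([hi_mu, SIGMA_BOUNDS[1], amp_hi]))

    starts1 = [np.array(_moment_init(ri, y))]
    if init:
        starts1 = [np.array([init[0].mean, init[0].sigma, init[0].amplitude])] + starts1
    sols1 = [_solve(ri, y, p0, 1, b1) for p0 in starts1]
    best1 = min(sols1, key=lambda s: s.cost)

    if k == 1:
        params, res = best1.x, best1
    else:
        b2 = (np.tile(b1[0], 2), np.tile(b1[1], 2))
        mu1, sig1, amp1 = best1.x
        dense_mu = POOLING_WINDOWS["dense"].ri_lo + (
            POOLING_WINDOWS["dense"].ri_hi - POOLING_WINDOWS["dense"].ri_lo
        ) / 2.0
        dense_mu = min(max(dense_mu, lo_mu), hi_mu)
        starts2 = [
            # k=1 solution + dense-window component: guarantees SSE nesting
            np.array([mu1, sig1, amp1, dense_mu, 0.0013, 0.25 * max(amp1, 1e-6)]),
            np.array([mu1, sig1, amp1, dense_mu, 0.0013, 1e-9]),
            # symmetric split of the moment estimate
            np.array([mu1 - sig1, sig1, 0.6 * max(amp1, 1e-6), mu1 + sig1, sig1, 0.6 * max(amp1, 1e-6)]),
        ]
        if init and len(init) == 2:
            starts2.insert(0, np.array([p for c in init for p in (c.mean, c.sigma, c.amplitude)]))
        sols2 = [_solve(ri, y, p0, 2, b2) for p0 in starts2]
        res = min(sols2, key=lambda s: s.cost)
        params = res.x

    comps = sorted(
        (
            GaussianComponent(mean=float(params[3 * j]), sigma=float(params[3 * j + 1]), amplitude=float(params[3 * j + 2]))
            for j in range(k)
        ),
        key=lambda c: c.mean,
    )
    return MixtureFit(
        components=tuple(comps),
        sse=float(2.0 * res.cost),  # least_squares cost is 0.5·SSE
        n_points=len(ri),
        converged=bool(res.status > 0),
    )


def select_window(profile: GradientProfile, window: PoolingWindow) -> GradientProfile:
    """Sub-profile of fractions whose RI lies inside the closed window."""
    ri = profile.ri
    if np.isnan(ri).any():
        raise ParameterError("profile needs RI on every fraction")
    keep = window.contains(ri)
    if not keep.any():
        warnings.warn(f"window {window.name} [{window.ri_lo}, {window.ri_hi}] selects no fractions", stacklevel=2)
    fracs = [f for f, k_ in zip(profile.fractions, keep) if k_]
    return GradientProfile(fractions=fracs, label=profile.label, ri_fit=profile.ri_fit)


def _trapz_over_ri(ri: np.ndarray, conc: np.ndarray) -> float:
    order = np.argsort(ri)
    return float(np.trapezoid(conc[order], ri[order]))


def _window_integral(ri: np.ndarray, conc: np.ndarray, window: PoolingWindow) -> float:
    """Trapezoid of the piecewise-linear interpolant restricted to the window.

    Grid points at the exact window bounds are inserted by linear
    interpolation so the result is the integral of the interpolant over
    [ri_lo, ri_hi] rather than over whichever samples happen to fall inside.
    """
    order = np.argsort(ri)
    x, y = ri[order], conc[order]
    lo = max(window.ri_lo, float(x[0]))
    hi = min(window.ri_hi, float(x[-1]))
    if hi <= lo:
        return 0.0
    inner = (x > lo) & (x < hi)
    gx = np.concatenate(([lo], x[inner], [hi]))
    gy = np.interp(gx, x, y)
    return float(np.trapezoid(gy, gx))


def percent_dense(
    secondary: GradientProfile,
    primary: GradientProfile,
    dense_window: PoolingWindow = POOLING_WINDOWS["dense_extended"],
) -> DenseQuantification:
    """Percent dense DNA: integrated secondary signal in the extended dense
    window divided by the integrated total signal of the primary gradient.

    Both profiles must be baseline-corrected; integration is trapezoidal
    over RI (negative corrected readings contribute as-is).
    """
    for p in (secondary, primary):
        if np.isnan(p.ri).any():
            raise ParameterError("both profiles need RI on every fraction")
        if np.isnan(p.corrected).any():
            raise ParameterError("both profiles must be baseline-corrected before quantification")
    total = _trapz_over_ri(primary.ri, primary.corrected)
    if total <= 0:
        raise QuantificationError(f"non-positive total DNA integral ({total:g}) on the primary gradient")
    dense = _window_integral(secondary.ri, secondary.corrected, dense_window)
    return DenseQuantification(
        dense_integral=dense,
        total_integral=total,
        percent_dense=100.0 * dense / total,
    )


def peak_window_overlap_length(fit: MixtureFit, window: PoolingWindow) -> list[float]:
    """Per component, length of the overlap of its ±2σ extent with the window."""
    out = []
    for c in fit.components:
        lo = max(c.mean - 2.0 * c.sigma, window.ri_lo)
        hi = min(c.mean + 2.0 * c.sigma, window.ri_hi)
        out.append(max(0.0, hi - lo))
    return out
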