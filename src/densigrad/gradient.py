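"""Caesium-sulphate gradient profiles: calibration, RI interpolation, baseline correction.

A gradient is pumped bottom-to-top, so fraction 1 is the densest and the
refractive index (RI) decreases with fraction index.  RI is an optical
proxy for the local caesium sulphate concentration and converts linearly
to buoyant density; only odd-numbered fractions carry a measured RI, the
rest are filled in from a linear regression of RI against fraction index.

Raw per-fraction DNA concentrations (blanked spectrophotometer readings,
ng/µl, possibly negative) sit on a slight linear instrumental baseline.
The baseline is estimated by ordinary least squares over fractions that
contain no nucleic acid — by default those outside RI > 1.3780 and
RI in [1.365, 1.372] — and subtracted from every fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientBaselineError

__all__ = [
    "GradientFraction",
    "GradientProfile",
    "RICalibration",
    "BaselineFit",
    "DEFAULT_BASELINE_EXCLUSIONS",
    "PUBLISHED_CALIBRATION",
    "fit_ri_density_calibration",
    "ri_to_density",
    "interpolate_ri",
    "correct_baseline",
]

#: RI windows treated as signal-bearing and excluded from the baseline fit:
#: the RNA-containing bottom of the gradient (RI > 1.3780) and the DNA band
#: (RI 1.365–1.372).
DEFAULT_BASELINE_EXCLUSIONS: tuple[tuple[float, float], ...] = (
    (1.3780, math.inf),
    (1.365, 1.372),
)

_RI_MIN, _RI_MAX = 1.3300, 1.4000


@dataclass
class GradientFraction:
    """One fraction of an equilibrium gradient.

    ``index`` starts at 1 for the first (densest) fraction pumped.
    ``refractive_index`` is the RI at 20 °C used for computation; after
    :func:`interpolate_ri` it holds the fitted-line value and the original
    reading, when there was one, is kept in ``measured_refractive_index``.
    """

    index: int
    raw_concentration: float
    refractive_index: float | None = None
    measured_refractive_index: float | None = None
    density: float | None = None
    corrected_concentration: float | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"fraction index must be >= 1, got {self.index}")
        for ri in (self.refractive_index, self.measured_refractive_index):
            if ri is not None and not (_RI_MIN <= ri <= _RI_MAX):
                raise ValueError(f"refractive index {ri} outside plausible range [{_RI_MIN}, {_RI_MAX}]")
        if self.density is not None and not (1.0 < self.density < 2.0):
            raise ValueError(f"density {self.density} g/ml outside (1.0, 2.0)")


@dataclass
class GradientProfile:
    """Ordered fractions of one gradient plus optional RI-vs-index fit."""

    fractions: list[GradientFraction]
    label: str = ""
    ri_fit: tuple[float, float] | None = None  # (slope, intercept) of RI vs index

    def __post_init__(self) -> None:
        idx = [f.index for f in self.fractions]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("fraction indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.fractions)

    @property
    def indices(self) -> np.ndarray:
        return np.array([f.index for f in self.fractions], dtype=float)

    @property
    def ri(self) -> np.ndarray:
        """RI per fraction (NaN where undefined)."""
        return np.array(
            [f.refractive_index if f.refractive_index is not None else np.nan for f in self.fractions]
        )

    @property
    def raw(self) -> np.ndarray:
        return np.array([f.raw_concentration for f in self.fractions])

    @property
    def corrected(self) -> np.ndarray:
        """Baseline-corrected concentrations (NaN where not yet computed)."""
        return np.array(
            [
                f.corrected_concentration if f.corrected_concentration is not None else np.nan
                for f in self.fractions
            ]
        )

    @property
    def signal(self) -> np.ndarray:
        """Corrected concentrations when available, else raw readings."""
        corr = self.corrected
        return self.raw if np.isnan(corr).any() else corr

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "fraction_index": [f.index for f in self.fractions],
                "refractive_index": [f.refractive_index for f in self.fractions],
                "measured_refractive_index": [f.measured_refractive_index for f in self.fractions],
                "dna_concentration": [f.raw_concentration for f in self.fractions],
                "corrected_concentration": [f.corrected_concentration for f in self.fractions],
            }
        )


@dataclass(frozen=True)
class RICalibration:
    """Linear map from refractive index to buoyant density (g/ml)."""

    slope: float  # g/ml per RI unit
    intercept: float  # g/ml
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive (density rises with RI)")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")


#: Published calibration of the study's gravimetric density measurements:
#: D = 12.46 g/ml · RI − 15.62 g/ml (38 points, R² = 0.9945).
PUBLISHED_CALIBRATION = RICalibration(slope=12.46, intercept=-15.62, n_points=38, r_squared=0.9945)


@dataclass(frozen=True)
class BaselineFit:
    """OLS baseline of concentration against RI over signal-free fractions."""

    slope: float  # concentration per RI unit
    intercept: float  # concentration at RI = 0
    excluded_windows: tuple[tuple[float, float], ...]
    n_baseline_points: int
    abscissa: str = "refractive_index"

    def __post_init__(self) -> None:
        if self.n_baseline_points < 2:
            raise ValueError("baseline fit needs at least 2 points")
        if not self.excluded_windows:
            raise ValueError("excluded_windows must be non-empty")

    def predict(self, ri: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(ri, dtype=float) + self.intercept


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line through (x, y); returns (slope, intercept, r²)."""
    if len(np.unique(x)) < 2:
        raise DegenerateInputError("need at least 2 distinct abscissa values for a line fit")
    res = stats.linregress(x, y)
    # linregress leaves rvalue ill-defined when y is constant; a constant is
    # fit perfectly by the zero-slope line.
    r2 = 1.0 if np.allclose(y, y[0]) else float(res.rvalue) ** 2
    return float(res.slope), float(res.intercept), r2


def fit_ri_density_calibration(pairs) -> RICalibration:
    """Fit the RI→density line by ordinary least squares.

    Parameters
    ----------
    pairs
        Iterable of ``(refractive_index, density_g_per_ml)`` measurements;
        at least two distinct RI values are required.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise DegenerateInputError("calibration needs >= 2 (RI, density) pairs")
    slope, intercept, r2 = _ols(arr[:, 0], arr[:, 1])
    return RICalibration(slope=slope, intercept=intercept, n_points=arr.shape[0], r_squared=r2)


def ri_to_density(cal: RICalibration, ri: float | np.ndarray):
    """Convert refractive index to buoyant density via ``cal``."""
    out = cal.slope * np.asarray(ri, dtype=float) + cal.intercept
    return float(out) if out.ndim == 0 else out


def interpolate_ri(profile: GradientProfile) -> GradientProfile:
    """Fill every fraction's RI from a linear fit of measured RI against index.

    RIs are measured only for odd-numbered fractions; a single regression
    line through the measured values assigns an RI to every fraction
    (measured readings are retained in ``measured_refractive_index``).
    The fitted slope must be nonzero so that assigned RIs are strictly
    monotone in fraction index.
    """
    measured = [(f.index, f.refractive_index) for f in profile.fractions if f.refractive_index is not None]
    if len(measured) < 2:
        raise DegenerateInputError("RI interpolation needs >= 2 measured fractions")
    x = np.array([m[0] for m in measured], dtype=float)
    y = np.array([m[1] for m in measured], dtype=float)
    slope, intercept, _ = _ols(x, y)
    if slope == 0.0:
        raise DegenerateInputError("measured RIs are constant; fitted RI would not be monotone in index")
    new_fracs = [
        replace(
            f,
            refractive_index=slope * f.index + intercept,
            measured_refractive_index=(
                f.refractive_index if f.refractive_index is not None else f.measured_refractive_index
            ),
        )
        for f in profile.fractions
    ]
    return GradientProfile(fractions=new_fracs, label=profile.label, ri_fit=(slope, intercept))


def _in_windows(ri: np.ndarray, windows) -> np.ndarray:
    mask = np.zeros(ri.shape, dtype=bool)
    for lo, hi in windows:
        mask |= (ri >= lo) & (ri <= hi)
    return mask


def correct_baseline(
    profile: GradientProfile,
    signal_windows=DEFAULT_BASELINE_EXCLUSIONS,
) -> tuple[GradientProfile, BaselineFit]:
    """Subtract the linear instrumental baseline estimated from signal-free fractions.

    Fractions whose RI falls inside any of ``signal_windows`` are treated as
    nucleic-acid-bearing and excluded from the baseline regression of raw
    concentration against RI.  The fitted line is subtracted from *every*
    fraction, so refitting the baseline on the corrected profile yields slope
    and intercept of zero.  Negative corrected readings are kept as-is.
    """
    ri = profile.ri
    if np.isnan(ri).any():
        raise DegenerateInputError("all fractions need an RI before baseline correction; run interpolate_ri")
    baseline_mask = ~_in_windows(ri, signal_windows)
    if np.count_nonzero(baseline_mask) < 2 or len(np.unique(ri[baseline_mask])) < 2:
        raise InsufficientBaselineError(
            f"only {int(np.count_nonzero(baseline_mask))} baseline fraction(s) left after exclusion"
        )
    slope, intercept, _ = _ols(ri[baseline_mask], profile.raw[baseline_mask])
    fit = BaselineFit(
        slope=slope,
        intercept=intercept,
        excluded_windows=tuple((float(lo), float(hi)) for lo, hi in signal_windows),
        n_baseline_points=int(np.count_nonzero(baseline_mask)),
    )
    new_fracs = [
        replace(f, corrected_concentration=f.raw_concentration - (slope * f.refractive_index + intercept))
        for f in profile.fractions
    ]
    return GradientProfile(fractions=new_fracs, label=profile.label, ri_fit=profile.ri_fit), fit
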