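"""Independent reference implementations used to check the package.

Each oracle is deliberately naive (closed forms, exhaustive enumeration,
brute force) and shares no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def ols_normal_equations(x, y) -> tuple[float, float]:
    """Least-squares line via the normal equations, written out longhand."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def gaussian_sse(x, y, mu, sigma, amp) -> float:
    model = amp * np.exp(-((np.asarray(x) - mu) ** 2) / (2.0 * sigma**2))
    return float(((np.asarray(y) - model) ** 2).sum())


def grid_search_gaussian(x, y, n_mu=40, n_sigma=25, n_amp=25):
    """Best single-Gaussian SSE over an exhaustive coarse parameter grid."""
    best = math.inf
    for mu in np.linspace(min(x), max(x), n_mu):
        for sigma in np.linspace(1e-4, 1e-2, n_sigma):
            for amp in np.linspace(0.0, 2.0 * max(max(y), 1e-9), n_amp):
                best = min(best, gaussian_sse(x, y, mu, sigma, amp))
    return best


def gaussian_window_mass(mu, sigma, lo, hi) -> float:
    """∫ A·exp(−(x−μ)²/2σ²) over [lo, hi] divided by amplitude: σ√(2π)·ΔΦ."""
    phi = lambda z: 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
    return sigma * math.sqrt(2.0 * math.pi) * (phi((hi - mu) / sigma) - phi((lo - mu) / sigma))


def brute_force_a_in_b(a_rows, b_rows):
    """All-pairs overlap: indices of a-rows sharing ≥ 1 bp with any b-row.

    Rows are (chrom, start, end) triples, half-open coordinates.
    """
    hits = []
    for i, (ca, sa, ea) in enumerate(a_rows):
        for cb, sb, eb in b_rows:
            if ca == cb and sa < eb and sb < ea:
                hits.append(i)
                break
    return hits


def sliding_window_ccgg(seq: str):
    """Positions where seq[i:i+4] == 'CCGG', checked one by one."""
    return [i for i in range(len(seq) - 3) if seq[i : i + 4] == "CCGG"]


# Monoisotopic atomic masses, restated independently of the package.
_ATOMIC = {"C": 12.000000, "H": 1.0078250319, "N": 14.0030740052, "O": 15.9949146221}


def sum_formula_mass(counts: dict[str, int]) -> float:
    """Monoisotopic mass from explicit per-element atom counts."""
    return sum(_ATOMIC[el] * n for el, n in counts.items())
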