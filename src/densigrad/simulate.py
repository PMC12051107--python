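"""Forward models of every input the analysis stages consume.

Each generator is a pure function of its spec plus a seed: gradients as
1–2 Gaussian DNA components on a linear RI ramp with a linear baseline
tilt and heteroscedastic noise (RI "measured" only on odd fractions, as
with a hand refractometer); interval sets with a constructed overlap
fraction on a toy genome; LC-MS peak tables with H/Na adduct splitting
and bounded mass error; and i.i.d. random sequences of a target GC
content.  ``study_gradient_specs`` bundles the gradient scenarios of the
quiescent / late-G1 / S-phase experiments with their published component
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import PackingError, ParameterError
from .fragments import SequenceFragment
from .gradient import GradientFraction, GradientProfile
from .intervals import GenomicInterval, IntervalSet
from .mixture import GaussianComponent
from .nucleosides import MzPeak, NUCLEOSIDE_NAMES, expected_mz, load_references

__all__ = [
    "DEFAULT_TOY_GENOME",
    "GradientSimSpec",
    "PeakSetSimSpec",
    "MsSimSpec",
    "simulate_gradient",
    "simulate_calibration_pairs",
    "simulate_peak_sets",
    "simulate_ms_peaks",
    "simulate_fragment",
    "study_gradient_specs",
]

#: Small enough for brute-force oracles, large enough for shuffle statistics.
DEFAULT_TOY_GENOME: dict[str, int] = {"chr1": 1_000_000, "chr2": 500_000, "chr3": 200_000}


@dataclass(frozen=True)
class GradientSimSpec:
    """Synthetic gradient: components + linear baseline + noise on an RI ramp.

    The baseline is ``baseline_slope·RI + baseline_intercept`` (same
    abscissa the correction regresses against); the per-fraction noise
    s.d. is ``noise_cv·|clean signal| + noise_floor_sd``, mimicking
    blanked spectrophotometer readings that can dip below zero.
    """

    components: tuple[GaussianComponent, ...]
    n_fractions: int = 60
    ri_start: float = 1.3800  # fraction 1 (densest, pumped first)
    ri_end: float = 1.3600
    baseline_slope: float = 150.0  # ng/µl per RI unit
    baseline_intercept: float = -202.0  # ng/µl at RI = 0 (≈ 2–5 ng/µl across the ramp)
    noise_cv: float = 0.02
    noise_floor_sd: float = 0.05
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_fractions < 10:
            raise ParameterError("n_fractions must be >= 10")
        if not self.ri_start > self.ri_end:
            raise ParameterError("ri_start must exceed ri_end (dense fractions pumped first)")
        if self.noise_cv < 0 or self.noise_floor_sd < 0:
            raise ParameterError("noise parameters must be non-negative")
        if not self.components:
            raise ParameterError("at least one Gaussian component required")


@dataclass(frozen=True)
class PeakSetSimSpec:
    """Two interval sets with a constructed a-in-b overlap fraction."""

    n_a: int
    n_b: int
    overlap_fraction: float
    genome: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_TOY_GENOME))
    len_dist: tuple[int, int] = (200, 2000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ParameterError("overlap_fraction must be in [0, 1]")
        if self.n_a < 0 or self.n_b < 1:
            raise ParameterError("need n_a >= 0 and n_b >= 1")
        if not 1 <= self.len_dist[0] <= self.len_dist[1]:
            raise ParameterError("len_dist must satisfy 1 <= min <= max")


@dataclass(frozen=True)
class MsSimSpec:
    """LC-MS peak table for a known deoxycytidine composition."""

    composition: tuple[float, float, float, float, float]  # % (dC, 5me, 5hm, 5f, 5ca)
    total_intensity: float = 1_000_000.0
    adduct_split: float = 0.7  # fraction of each nucleoside's signal in the H adduct
    mass_error_sd: float = 0.005  # Da
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.composition) - 100.0) > 1e-9:
            raise ParameterError(f"composition must sum to 100, got {sum(self.composition)}")
        if any(c < 0 for c in self.composition):
            raise ParameterError("composition percentages must be non-negative")
        if not 0.0 <= self.adduct_split <= 1.0:
            raise ParameterError("adduct_split must be in [0, 1]")
        if self.mass_error_sd < 0:
            raise ParameterError("mass_error_sd must be >= 0")


def simulate_gradient(spec: GradientSimSpec) -> GradientProfile:
    """Draw one gradient; odd fractions carry measured RI, even are blank."""
    rng = np.random.default_rng(spec.seed)
    idx = np.arange(1, spec.n_fractions + 1)
    ri = spec.ri_start + (spec.ri_end - spec.ri_start) * (idx - 1) / (spec.n_fractions - 1)
    clean = spec.baseline_slope * ri + spec.baseline_intercept
    for comp in spec.components:
        clean = clean + comp(ri)
    sd = spec.noise_cv * np.abs(clean) + spec.noise_floor_sd
    conc = clean + rng.normal(0.0, 1.0, size=clean.shape) * sd
    fractions = [
        GradientFraction(
            index=int(i),
            raw_concentration=float(c),
            refractive_index=float(r) if i % 2 == 1 else None,
        )
        for i, r, c in zip(idx, ri, conc)
    ]
    return GradientProfile(fractions=fractions, label=spec.label)


def simulate_calibration_pairs(
    n: int,
    slope: float = 12.46,
    intercept: float = -15.62,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """(RI, density) pairs on a line over RI ∈ [1.360, 1.380] plus noise."""
    if n < 2:
        raise ParameterError("need n >= 2 calibration pairs")
    rng = np.random.default_rng(seed)
    ri = rng.uniform(1.360, 1.380, size=n)
    density = slope * ri + intercept + rng.normal(0.0, noise_sd, size=n)
    return list(zip(ri.tolist(), density.tolist()))


def _draw_placement(rng, genome, length_range, n, forbid=None, max_tries=10_000):
    """Uniform interval placements; rejection against `forbid` trees."""
    chroms = sorted(genome)
    weights = np.array([genome[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out = []
    for _ in range(n):
        for _ in range(max_tries):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            if length > genome[chrom]:
                continue
            start = int(rng.integers(0, genome[chrom] - length + 1))
            if forbid is not None and any(s < start + length and start < e for s, e in forbid.get(chrom, [])):
                continue
            out.append(GenomicInterval(chrom, start, start + length))
            break
        else:
            raise PackingError(chrom, "could not place interval within retry budget")
    return out


def simulate_peak_sets(spec: PeakSetSimSpec) -> tuple[IntervalSet, IntervalSet]:
    """Build (a, b): exactly ⌊overlap_fraction·n_a⌋ a-intervals overlap b.

    b is placed uniformly without self-overlap; the designated a-intervals
    are anchored to a random b-interval with ≥ 1 bp overlap, the remainder
    are rejection-sampled to avoid b entirely.
    """
    rng = np.random.default_rng(spec.seed)
    b_intervals: list[GenomicInterval] = []
    b_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in _draw_placement(rng, spec.genome, spec.len_dist, spec.n_b, forbid=b_by_chrom):
        b_intervals.append(iv)
        b_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    n_over = int(np.floor(spec.overlap_fraction * spec.n_a))
    a_intervals: list[GenomicInterval] = []
    for _ in range(n_over):
        anchor = b_intervals[int(rng.integers(0, len(b_intervals)))]
        length = int(rng.integers(spec.len_dist[0], spec.len_dist[1] + 1))
        chrom_len = spec.genome[anchor.chrom]
        length = min(length, chrom_len)
        lo = max(0, anchor.start - length + 1)
        hi = min(anchor.end - 1, chrom_len - length)
        start = int(rng.integers(lo, hi + 1))
        a_intervals.append(GenomicInterval(anchor.chrom, start, start + length))
    a_intervals.extend(
        _draw_placement(rng, spec.genome, spec.len_dist, spec.n_a - n_over, forbid=b_by_chrom)
    )
    genome = dict(spec.genome)
    return (
        IntervalSet(intervals=a_intervals, genome=genome).sorted(),
        IntervalSet(intervals=b_intervals, genome=dict(genome)).sorted(),
    )


def simulate_ms_peaks(spec: MsSimSpec) -> list[MzPeak]:
    """H and Na adduct peaks for every nucleoside with nonzero composition."""
    rng = np.random.default_rng(spec.seed)
    refs = {r.name: r for r in load_references()}
    peaks: list[MzPeak] = []
    for name, pct in zip(NUCLEOSIDE_NAMES, spec.composition):
        if pct == 0:
            continue
        nucleoside_total = spec.total_intensity * pct / 100.0
        for adduct, frac in (("H", spec.adduct_split), ("Na", 1.0 - spec.adduct_split)):
            mz = expected_mz(refs[name], adduct) + rng.normal(0.0, spec.mass_error_sd)
            peaks.append(MzPeak(mz=float(mz), intensity=nucleoside_total * frac))
    return sorted(peaks, key=lambda p: p.mz)


def simulate_fragment(length: int, gc_target: float, seed: int = 0, id: str = "synthetic") -> SequenceFragment:
    """i.i.d. bases with P(G or C) = ``gc_target``."""
    if length < 1:
        raise ParameterError("length must be >= 1")
    if not 0.0 <= gc_target <= 1.0:
        raise ParameterError("gc_target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
    return SequenceFragment(id=id, sequence=seq)


def study_gradient_specs(seed: int = 0, noise_cv: float = 0.02) -> dict[str, GradientSimSpec]:
    """Gradient scenarios at the component parameters reported for the study.

    Keys: ``quiescent_primary`` (bulk DNA, mean RI 1.3683, σ 0.00163),
    ``light_secondary`` (re-run light shoulder, 1.3672/0.0014),
    ``quiescent_secondary`` (biphasic: carried-over bulk 1.3685/0.0012 at
    ~3:1 amplitude over dense 1.3706/0.0013), ``g1_secondary`` (dense
    component at 1.3701/0.0009), ``s_phase_secondary`` (bulk only — no
    distinct dense population).
    """
    bulk_amp, dense_amp = 10.0, 10.0 / 3.0
    carried_bulk = GaussianComponent(mean=1.3685, sigma=0.0012, amplitude=bulk_amp)
    specs = {
        "quiescent_primary": (GaussianComponent(mean=1.3683, sigma=0.00163, amplitude=bulk_amp),),
        "light_secondary": (GaussianComponent(mean=1.3672, sigma=0.0014, amplitude=bulk_amp),),
        "quiescent_secondary": (carried_bulk, GaussianComponent(mean=1.3706, sigma=0.0013, amplitude=dense_amp)),
        "g1_secondary": (carried_bulk, GaussianComponent(mean=1.3701, sigma=0.0009, amplitude=dense_amp)),
        "s_phase_secondary": (GaussianComponent(mean=1.3685, sigma=0.0012, amplitude=bulk_amp),),
    }
    return {
        name: GradientSimSpec(components=comps, seed=seed, noise_cv=noise_cv, label=name)
        for name, comps in specs.items()
    }
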