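"""LC-MS nucleoside composition: adduct m/z matching and percent quantification.

Enzymatically digested DNA yields free 2'-deoxynucleosides that ionise in
positive mode mainly as [M+H]+ and [M+Na]+ adducts.  Observed peaks are
assigned to deoxycytidine and its four 5-position modification states
(5me, 5hm, 5f, 5ca) by nearest expected m/z within an absolute tolerance
(default 0.025 Da, < 0.01 % at these masses); H- and Na-adduct intensities
are combined per nucleoside and reported as percent of total
deoxycytidines.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

from .errors import ParameterError

__all__ = [
    "ATOMIC_MASSES",
    "ADDUCT_OFFSETS",
    "NUCLEOSIDE_NAMES",
    "NucleosideReference",
    "MzPeak",
    "PeakAssignment",
    "CompositionResult",
    "mass_from_formula",
    "load_references",
    "expected_mz",
    "match_peaks",
    "composition_percent",
]

#: Monoisotopic atomic masses (Da).
ATOMIC_MASSES = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052, "O": 15.9949146221}

#: Cation mass minus electron mass: [M+H]+ and [M+Na]+ offsets (Da).  The
#: instrument-software "+1 / +23" nominal shifts are shorthand for these.
ADDUCT_OFFSETS = {"H": 1.00728, "Na": 22.98922}

NUCLEOSIDE_NAMES = ("dC", "5me-dC", "5hm-dC", "5f-dC", "5ca-dC")

DEFAULT_TOLERANCE_DA = 0.025


def mass_from_formula(formula: str) -> float:
    """Monoisotopic mass of a CHNO molecular formula like ``C9H13N3O4``."""
    total = 0.0
    for element, count in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if not element:
            continue
        if element not in ATOMIC_MASSES:
            raise ParameterError(f"unsupported element {element!r} in formula {formula!r}")
        total += ATOMIC_MASSES[element] * int(count or 1)
    if total <= 0:
        raise ParameterError(f"could not parse formula {formula!r}")
    return total


@dataclass(frozen=True)
class NucleosideReference:
    """A deoxycytidine form with its neutral monoisotopic mass and adducts."""

    name: str
    formula: str
    neutral_mass: float  # Da
    adducts: dict[str, float] = field(default_factory=lambda: dict(ADDUCT_OFFSETS))

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError("neutral mass must be positive")
        if any(off <= 0 for off in self.adducts.values()):
            raise ValueError("adduct offsets must be positive")


@dataclass(frozen=True)
class MzPeak:
    mz: float  # Da
    intensity: float  # detector counts

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class PeakAssignment:
    peak: MzPeak
    nucleoside: str
    adduct: str
    delta_mz: float  # observed − expected, Da


@dataclass(frozen=True)
class CompositionResult:
    """Combined per-nucleoside intensities and their percent of total dC forms."""

    intensities: dict[str, float]
    percentages: dict[str, float] | None  # None when total intensity is 0
    unassigned: int
    total_intensity: float


def load_references() -> list[NucleosideReference]:
    """The five deoxycytidine forms shipped with the package."""
    refs = []
    with resources.files("densigrad").joinpath("data/nucleosides.tsv").open() as fh:
        header = fh.readline()
        assert header.split() == ["name", "formula", "neutral_mass"]
        for line in fh:
            name, formula, mass = line.split()
            refs.append(NucleosideReference(name=name, formula=formula, neutral_mass=float(mass)))
    return refs


def expected_mz(ref: NucleosideReference, adduct: str) -> float:
    """Expected m/z of the singly charged ``adduct`` ion of ``ref``."""
    if adduct not in ref.adducts:
        raise ParameterError(f"unknown adduct {adduct!r}; expected one of {sorted(ref.adducts)}")
    return ref.neutral_mass + ref.adducts[adduct]


def match_peaks(
    peaks: list[MzPeak],
    refs: list[NucleosideReference] | None = None,
    tol: float = DEFAULT_TOLERANCE_DA,
) -> tuple[list[PeakAssignment], list[MzPeak]]:
    """Assign peaks to (nucleoside, adduct) slots by nearest expected m/z.

    A peak is assigned when the nearest expected adduct m/z is within
    ``tol`` Da; otherwise it is returned among the unassigned peaks.
    Ambiguity (two candidates within ``tol``) resolves to the nearest,
    exact ties to the earlier reference in listing order with a warning.
    """
    if tol <= 0:
        raise ParameterError("tolerance must be positive")
    if refs is None:
        refs = load_references()
    candidates = [(ref.name, adduct, expected_mz(ref, adduct)) for ref in refs for adduct in ref.adducts]
    # warn once about reference windows that cannot be told apart at this tol
    for i, (n1, a1, m1) in enumerate(candidates):
        for n2, a2, m2 in candidates[i + 1 :]:
            if abs(m1 - m2) < 2 * tol:
                warnings.warn(
                    f"reference windows overlap at tol={tol}: {n1}+{a1} ({m1:.4f}) vs {n2}+{a2} ({m2:.4f})",
                    stacklevel=2,
                )
    assigned: list[PeakAssignment] = []
    unassigned: list[MzPeak] = []
    for peak in peaks:
        deltas = [abs(peak.mz - mz) for _, _, mz in candidates]
        best = min(range(len(candidates)), key=lambda i: deltas[i])
        ties = [i for i in range(len(candidates)) if deltas[i] == deltas[best] and i != best]
        if ties and deltas[best] <= tol:
            warnings.warn(f"peak {peak.mz:.4f} equidistant to multiple references; using listing order", stacklevel=2)
        if deltas[best] <= tol:
            name, adduct, mz = candidates[best]
            assigned.append(PeakAssignment(peak=peak, nucleoside=name, adduct=adduct, delta_mz=peak.mz - mz))
        else:
            unassigned.append(peak)
    return assigned, unassigned


def composition_percent(
    assignments: list[PeakAssignment],
    unassigned: list[MzPeak] | None = None,
) -> CompositionResult:
    """Combine H- and Na-adduct intensities per nucleoside; percent of total.

    Multiple peaks assigned to the same (nucleoside, adduct) slot are
    summed.  Percentages are over the five deoxycytidine forms; with zero
    total intensity they are undefined and reported as ``None``.
    """
    intensities = {name: 0.0 for name in NUCLEOSIDE_NAMES}
    for a in assignments:
        intensities.setdefault(a.nucleoside, 0.0)
        intensities[a.nucleoside] += a.peak.intensity
    total = sum(intensities.values())
    percentages = {name: 100.0 * v / total for name, v in intensities.items()} if total > 0 else None
    if percentages is None:
        warnings.warn("total assigned intensity is zero; percentages undefined", stacklevel=2)
    return CompositionResult(
        intensities=intensities,
        percentages=percentages,
        unassigned=len(unassigned or []),
        total_intensity=total,
    )
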