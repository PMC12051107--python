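"""Sequence-level accounting for modified DNA fragments.

PCR-synthesised duplexes in which dCTP is replaced entirely by a modified
analogue carry one modified cytosine per C on the substituted strand(s).
This module counts those residues, converts them into the extra molecular
mass a modification adds relative to unmodified dC, scans for MspI (CCGG)
restriction sites, and provides a small empirical regression linking mass
loading per base pair to the observed equilibrium RI shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "MODIFICATIONS",
    "MOD_MASS_DELTA_MONO",
    "MOD_MASS_DELTA_AVG",
    "SequenceFragment",
    "ModificationScheme",
    "MassLoading",
    "DensityShiftModel",
    "gc_fraction",
    "find_ccgg_sites",
    "modification_mass_loading",
    "fit_density_shift_model",
]

MODIFICATIONS = ("none", "5me", "5hm", "5f", "5ca")
MODES = ("full", "hemi_top", "hemi_bottom")

#: Monoisotopic mass added per modified residue relative to dC (Da):
#: 5me = +CH2, 5hm = +CH2O, 5f = +CO, 5ca = +CO2.
MOD_MASS_DELTA_MONO = {"none": 0.0, "5me": 14.015650, "5hm": 30.010565, "5f": 27.994915, "5ca": 43.989829}
#: Average-mass variants of the same deltas.
MOD_MASS_DELTA_AVG = {"none": 0.0, "5me": 14.0266, "5hm": 30.0260, "5f": 28.0101, "5ca": 44.0095}


@dataclass(frozen=True)
class SequenceFragment:
    """A double-stranded fragment given by its top-strand sequence (ACGT only)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence
        if len(seq) < 1:
            raise ValueError("sequence must be non-empty")
        if set(seq) - set("ACGT"):
            bad = sorted(set(seq) - set("ACGT"))
            raise ValueError(f"sequence restricted to A/C/G/T; found {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ModificationScheme:
    """Which cytosine analogue replaces dC, and on which strand(s).

    ``hemi_top`` / ``hemi_bottom`` model hemi-modified duplexes — as arise
    after one round of semiconservative replication — with exactly one
    fully unmodified strand.
    """

    modification: str = "none"
    mode: str = "full"

    def __post_init__(self) -> None:
        if self.modification not in MODIFICATIONS:
            raise ParameterError(f"modification must be one of {MODIFICATIONS}, got {self.modification!r}")
        if self.mode not in MODES:
            raise ParameterError(f"mode must be one of {MODES}, got {self.mode!r}")


@dataclass(frozen=True)
class MassLoading:
    """Extra mass a modification scheme adds to a duplex fragment."""

    n_dC_top: int
    n_dC_bottom: int
    modified_dC_count: int
    added_mass_total: float  # Da
    added_mass_per_bp: float  # Da / bp


def gc_fraction(frag: SequenceFragment) -> float:
    """(#G + #C) / length of the top strand (duplex GC content)."""
    seq = frag.sequence
    return (seq.count("G") + seq.count("C")) / len(seq)


def find_ccgg_sites(frag: SequenceFragment) -> list[int]:
    """0-based start positions of all (possibly overlapping) CCGG sites.

    CCGG is palindromic, so top-strand occurrences are the duplex sites;
    reverse-complement matches coincide and are not double-counted.
    """
    seq, sites, pos = frag.sequence, [], frag.sequence.find("CCGG")
    while pos != -1:
        sites.append(pos)
        pos = seq.find("CCGG", pos + 1)
    return sites


def modification_mass_loading(
    frag: SequenceFragment,
    scheme: ModificationScheme,
    monoisotopic: bool = True,
) -> MassLoading:
    """Count modified cytosines under ``scheme`` and their added mass.

    Every dC of a substituted strand is modified (PCR synthesis replaces
    dCTP entirely, CpG context plays no role).  Top-strand dC count is the
    number of C; bottom-strand dC count equals the number of G on the top
    strand (each pairs a bottom-strand C).
    """
    deltas = MOD_MASS_DELTA_MONO if monoisotopic else MOD_MASS_DELTA_AVG
    n_top = frag.sequence.count("C")
    n_bottom = frag.sequence.count("G")
    if scheme.modification == "none":
        count = 0
    elif scheme.mode == "full":
        count = n_top + n_bottom
    elif scheme.mode == "hemi_top":
        count = n_top
    else:
        count = n_bottom
    total = count * deltas[scheme.modification]
    return MassLoading(
        n_dC_top=n_top,
        n_dC_bottom=n_bottom,
        modified_dC_count=count,
        added_mass_total=total,
        added_mass_per_bp=total / len(frag),
    )


@dataclass(frozen=True)
class DensityShiftModel:
    """Empirical line relating added mass per bp to equilibrium mean RI."""

    slope: float  # RI per (Da/bp)
    intercept: float  # RI of the unmodified fragment
    r_squared: float

    def predict(self, added_mass_per_bp: float | np.ndarray):
        out = self.slope * np.asarray(added_mass_per_bp, dtype=float) + self.intercept
        return float(out) if out.ndim == 0 else out


def fit_density_shift_model(observations) -> DensityShiftModel:
    """Least-squares line of observed mean RI against added mass per bp.

    ``observations`` are ``(added_mass_per_bp, mean_ri)`` pairs from
    gradient runs of fragments with different modification loadings.
    """
    arr = np.asarray(list(observations), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or len(np.unique(arr[:, 0])) < 2:
        raise DegenerateInputError("need >= 2 observations with distinct mass loadings")
    res = stats.linregress(arr[:, 0], arr[:, 1])
    r2 = 1.0 if np.allclose(arr[:, 1], arr[0, 1]) else float(res.rvalue) ** 2
    return DensityShiftModel(slope=float(res.slope), intercept=float(res.intercept), r_squared=r2)
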