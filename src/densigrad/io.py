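"""Readers and writers for the plain-text formats the pipeline consumes.

Fraction tables and calibration pairs are delimited text (comma or tab,
chosen by extension); interval sets are BED3+ with a UCSC-style
chrom.sizes file; LC-MS peak tables are two-column delimited text;
fragments are FASTA.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fragments import SequenceFragment
from .gradient import GradientFraction, GradientProfile
from .intervals import GenomicInterval, IntervalSet
from .nucleosides import MzPeak

__all__ = [
    "read_fraction_table",
    "write_fraction_table",
    "read_calibration_pairs",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_peak_table",
    "read_fasta",
    "write_fasta",
    "write_json",
]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt", ".sizes")) else ","


def read_fraction_table(path, label: str | None = None) -> GradientProfile:
    """Read a per-fraction table: fraction_index, refractive_index, dna_concentration.

    The refractive_index cell may be blank (RI is typically measured only
    for odd fractions); a corrected_concentration column is honoured when
    present.
    """
    df = pd.read_csv(path, sep=_sep(path))
    required = {"fraction_index", "refractive_index", "dna_concentration"}
    if missing := required - set(df.columns):
        raise ValueError(f"fraction table {path} missing columns {sorted(missing)}")
    fractions = [
        GradientFraction(
            index=int(row.fraction_index),
            refractive_index=None if pd.isna(row.refractive_index) else float(row.refractive_index),
            raw_concentration=float(row.dna_concentration),
            corrected_concentration=(
                None
                if "corrected_concentration" not in df.columns or pd.isna(row.corrected_concentration)
                else float(row.corrected_concentration)
            ),
        )
        for row in df.itertuples()
    ]
    return GradientProfile(fractions=fractions, label=label or Path(path).stem)


def write_fraction_table(profile: GradientProfile, path) -> None:
    profile.to_frame().to_csv(path, sep=_sep(path), index=False)


def read_calibration_pairs(path) -> list[tuple[float, float]]:
    """Two-column delimited text: ri, density_g_per_ml."""
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] < 2:
        raise ValueError(f"calibration file {path} needs two columns (ri, density_g_per_ml)")
    return list(zip(df.iloc[:, 0].astype(float), df.iloc[:, 1].astype(float)))


def read_chrom_sizes(path) -> dict[str, int]:
    """UCSC chrom.sizes dialect: name<TAB>length."""
    genome: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, length = line.split()[:2]
        genome[name] = int(length)
    return genome


def read_bed(path, genome: dict[str, int]) -> IntervalSet:
    """BED3+ (tab-delimited, no header; track/browser lines ignored)."""
    intervals = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t")
        score = float(fields[4]) if len(fields) > 4 and fields[4] not in (".", "") else None
        intervals.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), score=score))
    return IntervalSet(intervals=intervals, genome=dict(genome))


def write_bed(s: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in s.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_peak_table(path) -> list[MzPeak]:
    """Delimited text with columns mz, intensity."""
    df = pd.read_csv(path, sep=_sep(path))
    if missing := {"mz", "intensity"} - set(df.columns):
        raise ValueError(f"peak table {path} missing columns {sorted(missing)}")
    return [MzPeak(mz=float(r.mz), intensity=float(r.intensity)) for r in df.itertuples()]


def write_peak_table(peaks: list[MzPeak], path) -> None:
    pd.DataFrame({"mz": [p.mz for p in peaks], "intensity": [p.intensity for p in peaks]}).to_csv(
        path, sep=_sep(path), index=False
    )


def read_fasta(path) -> list[SequenceFragment]:
    return [SequenceFragment(id=rec.id, sequence=str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(fragments: list[SequenceFragment], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(f.sequence), id=f.id, description="") for f in fragments],
        str(path),
        "fasta",
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
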