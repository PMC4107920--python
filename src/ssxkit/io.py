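"""Plain-text output formats: peak/reflection stream, hkl table,
quality report.

All intermediate artifacts are diff-able text.  The per-frame "stream"
format loosely mirrors the conventions of serial-crystallography stream
files: one block per frame with the refined cell, the orientation
matrix rows, and a reflection table ``h k l I sigma fast slow``.
Merged data are written as a TSV hkl table ``h k l I sigma n``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import TextIO

import pandas as pd

from .indexing import CrystalOrientation
from .integrate import ReflectionMeasurement
from .merge import MergedDataset, QualityReport
from .peakfind import DetectedPeak

__all__ = [
    "write_stream_frame",
    "write_hkl",
    "read_hkl",
    "format_quality_report",
]


def write_stream_frame(fh: TextIO, frame: int, peaks: list[DetectedPeak],
                       orientation: CrystalOrientation | None = None,
                       measurements: list[ReflectionMeasurement] | None = None) -> None:
    fh.write(f"----- Begin frame {frame} -----\n")
    fh.write(f"num_peaks = {len(peaks)}\n")
    fh.write("fast/px slow/px intensity\n")
    for p in peaks:
        fh.write(f"{p.fast:9.2f} {p.slow:9.2f} {p.intensity:12.2f}\n")
    if orientation is not None:
        c = orientation.cell
        fh.write(f"cell = {c.a:.4f} {c.b:.4f} {c.c:.4f} "
                 f"{c.alpha:.3f} {c.beta:.3f} {c.gamma:.3f}\n")
        for i, name in enumerate("abc"):
            row = orientation.rotation[i]
            fh.write(f"R{name} = {row[0]:+.7f} {row[1]:+.7f} {row[2]:+.7f}\n")
        fh.write(f"n_indexed = {orientation.n_indexed_peaks}\n")
    if measurements:
        fh.write("   h    k    l            I        sigma    fast    slow\n")
        for m in measurements:
            fh.write(f"{m.hkl[0]:4d} {m.hkl[1]:4d} {m.hkl[2]:4d} "
                     f"{m.intensity:12.2f} {m.sigma:12.2f} "
                     f"{m.fast:7.1f} {m.slow:7.1f}\n")
    fh.write(f"----- End frame {frame} -----\n")


def write_hkl(merged: MergedDataset, path: str | Path) -> None:
    """Merged unique reflections as TSV: h k l I sigma n."""
    merged.table[["h", "k", "l", "I", "sigma", "n"]].to_csv(
        path, sep="\t", index=False, float_format="%.4f")


def read_hkl(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _fmt(value: float, pct: bool = False, digits: int = 2) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "n/a"
    return f"{value * (100 if pct else 1):.{digits}f}"


def format_quality_report(report: QualityReport) -> str:
    """Human-readable data-collection statistics block, overall values
    with the outer shell in parentheses."""
    ov, sh = report.overall, report.shells[-1]
    lines = [
        "Data statistics (outer shell in parentheses)",
        f"Resolution range (Å)   {ov.d_max:.2f}-{ov.d_min:.2f} "
        f"({sh.d_max:.2f}-{sh.d_min:.2f})",
        f"Unique reflections     {ov.n_unique} ({sh.n_unique})",
        f"Completeness (%)       {_fmt(ov.completeness, digits=1)} ({_fmt(sh.completeness, digits=1)})",
        f"Redundancy             {_fmt(ov.redundancy, digits=1)} ({_fmt(sh.redundancy, digits=1)})",
        f"I/sigma(I)             {_fmt(ov.mean_i_over_sigma, digits=1)} ({_fmt(sh.mean_i_over_sigma, digits=1)})",
        f"R_split (%)            {_fmt(ov.r_split, pct=True)} ({_fmt(sh.r_split, pct=True)})",
        f"CC1/2                  {_fmt(ov.cc_half, digits=4)} ({_fmt(sh.cc_half, digits=4)})",
        f"CC*                    {_fmt(ov.cc_star, digits=4)} ({_fmt(sh.cc_star, digits=4)})",
    ]
    if report.wilson is not None:
        lines.append(f"Wilson B factor (Å²)   {report.wilson.b_factor:.1f}")
    lines.append(f"Patterns merged        {report.n_patterns}")
    header = ("shell  d_max  d_min  n_unique  compl%%  redund  I/sig  "
              "Rsplit%%  CC1/2  CC*")
    lines.append("")
    lines.append(header.replace("%%", "%"))
    for i, s in enumerate(report.shells):
        lines.append(
            f"{i + 1:5d}  {s.d_max:5.2f}  {s.d_min:5.2f}  {s.n_unique:8d}  "
            f"{_fmt(s.completeness, digits=1):>6}  {_fmt(s.redundancy, digits=1):>6}  "
            f"{_fmt(s.mean_i_over_sigma, digits=1):>5}  "
            f"{_fmt(s.r_split, pct=True, digits=1):>7}  "
            f"{_fmt(s.cc_half, digits=3):>5}  {_fmt(s.cc_star, digits=3):>4}")
    return "\n".join(lines)
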