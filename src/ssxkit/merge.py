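"""Monte Carlo merging and half-set data-quality statistics.

Snapshot serial crystallography measures each unique reflection many
times — different crystals, orientations, partialities, transit times —
and simply averages the unscaled measurements ("Monte Carlo"
integration): with enough snapshots the stochastic factors integrate
out into one common scale.  Per unique (ASU) reflection this module
reports the mean intensity, the standard error of the mean, and the
redundancy.

Internal consistency is judged by splitting the patterns (not the
individual measurements) into two random halves, merging each, and
comparing:

    R_split = 2^(−1/2) · Σ|I₁ − I₂| / (½ Σ(I₁ + I₂))
    CC½     = Pearson correlation of (I₁, I₂)
    CC*     = sqrt(2 CC½ / (1 + CC½))

CC* estimates the correlation of the merged data with the unknown
converged truth; it is defined for CC½ > −1/3 and maps 0 → 0, 1 → 1
monotonically.  All statistics are computed overall and in resolution
shells (equal reciprocal-volume by default), along with completeness,
redundancy, I/σ(I), and a Wilson-plot B-factor fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MergeParams
from .crystal import SymmetryInfo, UnitCell, generate_hkl

__all__ = [
    "MergedDataset",
    "ShellStatistics",
    "QualityReport",
    "WilsonFit",
    "map_to_asu",
    "monte_carlo_merge",
    "split_half",
    "r_split",
    "cc_half",
    "cc_star",
    "shell_statistics",
    "wilson_fit",
    "convergence_analysis",
    "theoretical_unique_count",
]

MEASUREMENT_COLUMNS = ["pattern", "h", "k", "l", "I", "sigma"]


def map_to_asu(hkl: np.ndarray, sym: SymmetryInfo) -> np.ndarray:
    """Canonical 4/mmm asymmetric-unit index (Friedel mates merged)."""
    return sym.map_to_asu(hkl)


@dataclass
class MergedDataset:
    """Unique-reflection intensity table.

    ``table`` columns: h, k, l (ASU), I (mean), sigma (sd/√n; NaN and
    flagged for n = 1), n (redundancy), d (Å).
    """

    table: pd.DataFrame
    cell: UnitCell
    sym: SymmetryInfo
    n_patterns: int

    def __len__(self) -> int:
        return len(self.table)


def _asu_frame(measurements: pd.DataFrame, sym: SymmetryInfo) -> pd.DataFrame:
    df = measurements.copy()
    asu = map_to_asu(df[["h", "k", "l"]].to_numpy(int), sym)
    df[["h", "k", "l"]] = asu
    return df


def monte_carlo_merge(measurements: pd.DataFrame, cell: UnitCell,
                      sym: SymmetryInfo) -> MergedDataset:
    """Average all measurements of each unique reflection, unscaled.

    σ(I) of a merged reflection is the standard error estimated from
    the scatter of its measurements, the quantity that makes I/σ(I)
    meaningful for Monte Carlo data.  Sorted-key grouping makes the
    result exactly permutation-invariant.
    """
    if len(measurements) == 0:
        raise ValueError("no measurements to merge")
    df = _asu_frame(measurements, sym)
    # sort for permutation invariance of the grouped sums
    df = df.sort_values(["h", "k", "l", "I"], kind="mergesort")
    g = df.groupby(["h", "k", "l"], sort=True)["I"]
    out = g.agg(I="mean", sd="std", n="size").reset_index()
    out["sigma"] = out["sd"] / np.sqrt(out["n"])
    out = out.drop(columns="sd")
    out["d"] = cell.d_spacing(out[["h", "k", "l"]].to_numpy(float))
    n_patterns = measurements["pattern"].nunique() if "pattern" in measurements else 0
    return MergedDataset(table=out, cell=cell, sym=sym, n_patterns=int(n_patterns))


def split_half(measurements: pd.DataFrame, cell: UnitCell, sym: SymmetryInfo,
               seed) -> tuple[MergedDataset, MergedDataset]:
    """Random pattern-level half split (all measurements of a frame stay
    together; half sizes differ by at most one frame), each half merged."""
    rng = np.random.default_rng(seed)
    patterns = np.array(sorted(measurements["pattern"].unique()))
    perm = rng.permutation(len(patterns))
    half_a = set(patterns[perm[: len(patterns) // 2]])
    in_a = measurements["pattern"].isin(half_a)
    return (monte_carlo_merge(measurements[~in_a], cell, sym),
            monte_carlo_merge(measurements[in_a], cell, sym))


def _common(half1: MergedDataset, half2: MergedDataset) -> pd.DataFrame:
    m = half1.table.merge(half2.table, on=["h", "k", "l"], suffixes=("1", "2"))
    return m


def r_split(half1: MergedDataset, half2: MergedDataset,
            shells: np.ndarray | None = None) -> float | pd.DataFrame:
    """Half-set R factor with the conventional 1/√2 factor correcting
    for each half holding only half the measurements.  With ``shells``
    (d-spacing bin edges, descending) returns a per-shell table."""
    m = _common(half1, half2)
    if shells is None:
        return _r_split_values(m["I1"].to_numpy(), m["I2"].to_numpy())
    return _per_shell(m, shells, lambda sub: _r_split_values(
        sub["I1"].to_numpy(), sub["I2"].to_numpy()), "r_split")


def _r_split_values(i1: np.ndarray, i2: np.ndarray) -> float:
    denom = 0.5 * (i1 + i2).sum()
    if len(i1) < 2 or denom == 0:
        return math.nan
    return float(np.abs(i1 - i2).sum() / denom / math.sqrt(2.0))


def _pearson(i1: np.ndarray, i2: np.ndarray) -> float:
    """Pearson correlation; NaN for <3 points or zero variance."""
    if len(i1) < 3 or np.std(i1) == 0 or np.std(i2) == 0:
        return math.nan
    return float(np.corrcoef(i1, i2)[0, 1])


def cc_half(half1: MergedDataset, half2: MergedDataset) -> float:
    """Pearson correlation of half-set intensities."""
    m = _common(half1, half2)
    return _pearson(m["I1"].to_numpy(), m["I2"].to_numpy())


def cc_star(cc: float) -> float:
    """CC* = sqrt(2·CC½/(1+CC½)), with the signed extension
    −sqrt(−2·CC½/(1+CC½)) for CC½ < 0 so the transform stays continuous
    and monotone on (−1/3, 1]; NaN for CC½ ≤ −1/3 (undefined)."""
    if not np.isfinite(cc) or cc <= -1.0 / 3.0:
        return math.nan
    return math.copysign(math.sqrt(abs(2.0 * cc / (1.0 + cc))), cc)


def shell_edges(params: MergeParams) -> np.ndarray:
    """Resolution bin edges in d (Å), descending, outermost = d_min.
    Default scheme: equal reciprocal-space volume (uniform in 1/d³)."""
    smin3, smax3 = params.d_max ** -3, params.d_min ** -3
    s3 = np.linspace(smin3, smax3, params.n_shells + 1)
    return s3 ** (-1.0 / 3.0)


def _per_shell(df: pd.DataFrame, edges: np.ndarray, fn, name: str) -> pd.DataFrame:
    rows = []
    dcol = "d1" if "d1" in df else "d"
    for i in range(len(edges) - 1):
        d_hi, d_lo = edges[i], edges[i + 1]
        sub = df[(df[dcol] <= d_hi) & (df[dcol] > d_lo)] if i < len(edges) - 2 \
            else df[(df[dcol] <= d_hi) & (df[dcol] >= d_lo)]
        rows.append({"d_max": d_hi, "d_min": d_lo, "n": len(sub),
                     name: fn(sub) if len(sub) else math.nan})
    return pd.DataFrame(rows)


@dataclass
class ShellStatistics:
    d_max: float
    d_min: float
    n_unique: int
    completeness: float  # %
    redundancy: float
    mean_i_over_sigma: float
    r_split: float       # fraction (multiply by 100 for %)
    cc_half: float
    cc_star: float


@dataclass
class WilsonFit:
    b_factor: float   # Å²
    scale: float
    d_range: tuple[float, float]
    n_shells_used: int


@dataclass
class QualityReport:
    """Overall and per-shell data-collection statistics."""

    shells: list[ShellStatistics]
    overall: ShellStatistics
    wilson: WilsonFit | None
    n_patterns: int


def theoretical_unique_count(cell: UnitCell, sym: SymmetryInfo,
                             d_min: float, d_max: float = np.inf,
                             include_lower: bool = True) -> int:
    """Number of theoretically observable unique (ASU, non-absent)
    reflections in the resolution range, by brute-force enumeration.
    The resolution of a unique reflection is that of its ASU
    representative (for a cell that is only approximately tetragonal,
    4/mmm mates differ slightly in d), matching the binning applied to
    merged tables; ``include_lower=False`` makes the d_min bound
    exclusive, the shell convention for all but the innermost shell."""
    hkl = generate_hkl(cell, d_min * 0.97, np.inf if np.isinf(d_max) else d_max * 1.03)
    hkl = hkl[~sym.is_absent(hkl)]
    uniq = np.unique(map_to_asu(hkl, sym), axis=0)
    d = cell.d_spacing(uniq)
    lower_ok = (d >= d_min) if include_lower else (d > d_min)
    return int((lower_ok & (d <= d_max)).sum())


def shell_statistics(merged: MergedDataset, half1: MergedDataset,
                     half2: MergedDataset,
                     params: MergeParams | None = None) -> QualityReport:
    """Per-shell and overall completeness, redundancy, I/σ, R_split,
    CC½ and CC* for a merged dataset and its random halves."""
    params = params or MergeParams()
    edges = shell_edges(params)
    # integration may extend beyond the statistics range (e.g. into the
    # detector corners); all statistics are confined to the shell range
    tbl = merged.table
    tbl = tbl[(tbl["d"] <= edges[0]) & (tbl["d"] >= edges[-1])]
    common = _common(half1, half2)
    common = common[(common["d1"] <= edges[0]) & (common["d1"] >= edges[-1])]
    shells: list[ShellStatistics] = []
    for i in range(len(edges) - 1):
        d_hi, d_lo = float(edges[i]), float(edges[i + 1])
        inc_low = i == len(edges) - 2
        sel = (tbl["d"] <= d_hi) & ((tbl["d"] >= d_lo) if inc_low else (tbl["d"] > d_lo))
        sub = tbl[sel]
        selc = (common["d1"] <= d_hi) & ((common["d1"] >= d_lo) if inc_low
                                         else (common["d1"] > d_lo))
        subc = common[selc]
        shells.append(_one_shell(sub, subc, merged, d_hi, d_lo,
                                 include_lower=inc_low))
    overall = _one_shell(tbl, common, merged, float(edges[0]), float(edges[-1]))
    wf = None
    try:
        wf = wilson_fit(merged, (params.d_max, params.d_min))
    except ValueError:
        pass
    return QualityReport(shells=shells, overall=overall, wilson=wf,
                         n_patterns=merged.n_patterns)


def _one_shell(sub: pd.DataFrame, subc: pd.DataFrame, merged: MergedDataset,
               d_hi: float, d_lo: float,
               include_lower: bool = True) -> ShellStatistics:
    theo = theoretical_unique_count(merged.cell, merged.sym, d_lo, d_hi,
                                    include_lower=include_lower)
    n_unique = len(sub)
    mult = sub[(sub["n"] >= 2) & (sub["sigma"] > 0)]
    ios = mult["I"] / mult["sigma"]
    cc = _pearson(subc["I1"].to_numpy(), subc["I2"].to_numpy())
    return ShellStatistics(
        d_max=d_hi, d_min=d_lo, n_unique=n_unique,
        completeness=100.0 * n_unique / theo if theo else math.nan,
        redundancy=float(sub["n"].mean()) if n_unique else math.nan,
        mean_i_over_sigma=float(ios.mean()) if len(ios) else math.nan,
        r_split=_r_split_values(subc["I1"].to_numpy(), subc["I2"].to_numpy()),
        cc_half=cc,
        cc_star=cc_star(cc),
    )


def wilson_fit(merged: MergedDataset, d_range: tuple[float, float] | None = None,
               n_shells: int = 15) -> WilsonFit:
    """Wilson-plot fit: straight line through ln⟨I⟩ versus s²/2
    (s = 1/d); the slope is −B.  Non-positive shell means are excluded
    (and counted out of the fit)."""
    tbl = merged.table
    if d_range is not None:
        d_hi, d_lo = max(d_range), min(d_range)
        tbl = tbl[(tbl["d"] <= d_hi) & (tbl["d"] >= d_lo)]
    if len(tbl) < 10:
        raise ValueError("too few reflections for a Wilson fit")
    s2 = 1.0 / tbl["d"].to_numpy() ** 2
    edges = np.linspace(s2.min(), s2.max(), n_shells + 1)
    idx = np.clip(np.digitize(s2, edges) - 1, 0, n_shells - 1)
    means, centers = [], []
    for i in range(n_shells):
        sel = idx == i
        if sel.sum() < 3:
            continue
        m = float(tbl["I"].to_numpy()[sel].mean())
        if m > 0:
            means.append(m)
            centers.append(float(s2[sel].mean()))
    if len(means) < 2:
        raise ValueError("not enough positive shell means for a Wilson fit")
    x = np.array(centers) / 2.0
    y = np.log(means)
    slope, intercept = np.polyfit(x, y, 1)
    return WilsonFit(b_factor=float(-slope), scale=float(np.exp(intercept)),
                     d_range=(float(tbl["d"].max()), float(tbl["d"].min())),
                     n_shells_used=len(means))


def convergence_analysis(measurements: pd.DataFrame, cell: UnitCell,
                         sym: SymmetryInfo, n_grid: list[int], seed,
                         params: MergeParams | None = None) -> pd.DataFrame:
    """Quality metrics versus number of merged patterns.

    For each n in ``n_grid`` a random pattern subset is drawn (seeded),
    split in half, and overall R_split / CC½ / CC* / mean I/σ computed.
    Returns a tidy DataFrame with one row per grid point.
    """
    params = params or MergeParams()
    rng = np.random.default_rng(seed)
    patterns = np.array(sorted(measurements["pattern"].unique()))
    rows = []
    for n in n_grid:
        if n > len(patterns):
            raise ValueError(f"requested {n} patterns, have {len(patterns)}")
        chosen = set(rng.choice(patterns, size=n, replace=False))
        sub = measurements[measurements["pattern"].isin(chosen)]
        h1, h2 = split_half(sub, cell, sym, rng.integers(2 ** 31))
        merged = monte_carlo_merge(sub, cell, sym)
        mult = merged.table[(merged.table["n"] >= 2) & (merged.table["sigma"] > 0)]
        cc = cc_half(h1, h2)
        rows.append({
            "n_patterns": n,
            "r_split": r_split(h1, h2),
            "cc_half": cc,
            "cc_star": cc_star(cc),
            "mean_i_over_sigma": float((mult["I"] / mult["sigma"]).mean())
            if len(mult) else math.nan,
        })
    return pd.DataFrame(rows)
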