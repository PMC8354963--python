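"""Cohort-level statistics of the four-protocol superimposition study.

Replicates the analysis applied to the 50-match / 50-mismatch design:

* per-group means and SDs of RMS, of the four |RMS difference| columns and
  of the three size differences, split by match status (table 1 analog);
* two-sided paired Student's t-tests between the reference-swapped groups,
  {B, C} and {A, D} for the registration swap, {A, B} and {C, D} for the
  distance-calculation swap (table 2 analog);
* Pearson correlations of each RMS delta against each size delta
  (table 3 analog), p-values via the t transform t = r sqrt((n-2)/(1-r^2));
* match/mismatch separability against the literature identification
  threshold of 0.96 mm.

Raw p-values are reported against the 0.05 and 0.001 flags with no
multiple-testing correction, matching standard practice in this
identification literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .protocols import ProtocolQuartet

__all__ = [
    "TTestResult",
    "PearsonResult",
    "Separation",
    "CohortTables",
    "paired_t_test",
    "pearson_r",
    "separability",
    "quartets_to_frame",
    "build_tables",
]

DEFAULT_THRESHOLD_MM = 0.96

_DELTA_COLS = ["delta_B-C", "delta_A-D", "delta_A-B", "delta_C-D"]
_SIZE_COLS = ["delta_breadth", "delta_height", "delta_volume"]
_RMS_COLS = ["rms_A", "rms_B", "rms_C", "rms_D"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False  # all differences identically zero


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class Separation:
    """Match/mismatch separability at a fixed RMS threshold."""

    max_match_rms: float
    min_mismatch_rms: float
    threshold_mm: float
    overlap: bool
    accuracy: float


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Classic paired Student's t-test (two-sided).

    t = mean(d) / (sd(d)/sqrt(n)) on the differences d = x - y, with n-1
    degrees of freedom. All-zero differences are the degenerate "identical
    samples" case (t = 0, p = 1, flagged); zero variance around a nonzero
    mean difference has no finite t and raises instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return TTestResult(t=0.0, p=1.0, df=n - 1, degenerate=True)
        raise ZeroDivisionError("differences have zero variance but nonzero mean")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * t_dist.sf(abs(t), df=n - 1)
    return TTestResult(t=float(t), p=float(p), df=n - 1)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Sample Pearson correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = (xd**2).sum()
    syy = (yd**2).sum()
    if sxx == 0 or syy == 0:
        raise ValueError("constant vector: correlation undefined")
    r = float(np.clip(xd @ yd / np.sqrt(sxx * syy), -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * t_dist.sf(abs(t), df=n - 2))
    return PearsonResult(r=r, p=p, n=n)


def separability(
    match_rms: Iterable[float],
    mismatch_rms: Iterable[float],
    threshold_mm: float = DEFAULT_THRESHOLD_MM,
) -> Separation:
    """Assess identification at the RMS threshold (match iff RMS < threshold)."""
    m = np.asarray(list(match_rms), dtype=float)
    mm = np.asarray(list(mismatch_rms), dtype=float)
    if m.size == 0 or mm.size == 0:
        raise ValueError("both groups must be nonempty")
    correct = int((m < threshold_mm).sum() + (mm >= threshold_mm).sum())
    return Separation(
        max_match_rms=float(m.max()),
        min_mismatch_rms=float(mm.min()),
        threshold_mm=threshold_mm,
        overlap=bool(m.max() >= mm.min()),
        accuracy=correct / (m.size + mm.size),
    )


def quartets_to_frame(quartets: Iterable[ProtocolQuartet]) -> pd.DataFrame:
    """One row per pair: RMS per group, the four deltas, the size deltas."""
    return pd.DataFrame([q.to_row() for q in quartets])


@dataclass
class CohortTables:
    """The three study tables plus the separability record.

    table1 : mean/SD of every column by match status.
    table2 : paired-t p-values for the four group contrasts by match status.
    table3 : Pearson r (p) of each RMS delta vs each size delta by status.
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    separation: Separation
    per_group_separation: dict[str, Separation] = field(default_factory=dict)

    def to_csv(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table1.to_csv(directory / "table1_summary.csv")
        self.table2.to_csv(directory / "table2_paired_t.csv")
        self.table3.to_csv(directory / "table3_correlations.csv")


def _summary_block(df: pd.DataFrame) -> pd.DataFrame:
    cols = _RMS_COLS + _DELTA_COLS + _SIZE_COLS
    return pd.DataFrame({"mean": df[cols].mean(), "sd": df[cols].std(ddof=1)}).T


def build_tables(
    quartets: Iterable[ProtocolQuartet] | pd.DataFrame,
    threshold_mm: float = DEFAULT_THRESHOLD_MM,
) -> CohortTables:
    """Assemble the three tables and the separation record from quartets."""
    df = quartets if isinstance(quartets, pd.DataFrame) else quartets_to_frame(quartets)
    matches = df[df["is_match"]]
    mismatches = df[~df["is_match"]]
    if len(matches) < 2 or len(mismatches) < 2:
        raise ValueError("need at least 2 matches and 2 mismatches")

    table1 = pd.concat(
        {"matches": _summary_block(matches), "mismatches": _summary_block(mismatches)},
        names=["group", "stat"],
    )

    contrasts = {
        ("registration", "B-C"): ("rms_B", "rms_C"),
        ("registration", "A-D"): ("rms_A", "rms_D"),
        ("rms_calculation", "A-B"): ("rms_A", "rms_B"),
        ("rms_calculation", "C-D"): ("rms_C", "rms_D"),
    }
    rows = {}
    for key, (a, b) in contrasts.items():
        rows[key] = {
            "matches": paired_t_test(matches[a], matches[b]).p,
            "mismatches": paired_t_test(mismatches[a], mismatches[b]).p,
        }
    table2 = pd.DataFrame(rows).T
    table2.index.names = ["step", "contrast"]

    rows3 = {}
    for status, sub in (("matches", matches), ("mismatches", mismatches)):
        for dcol in _DELTA_COLS:
            for scol in _SIZE_COLS:
                try:
                    res = pearson_r(sub[dcol], sub[scol])
                    cell = {"r": res.r, "p": res.p}
                except ValueError:  # constant column or fewer than 3 pairs
                    cell = {"r": float("nan"), "p": float("nan")}
                rows3[(status, dcol.removeprefix("delta_"), scol.removeprefix("delta_"))] = cell
    table3 = pd.DataFrame(rows3).T
    table3.index.names = ["group", "rms_delta", "size_delta"]

    match_rms = matches[_RMS_COLS].to_numpy().ravel()
    mismatch_rms = mismatches[_RMS_COLS].to_numpy().ravel()
    separation = separability(match_rms, mismatch_rms, threshold_mm)
    per_group = {
        g: separability(matches[f"rms_{g}"], mismatches[f"rms_{g}"], threshold_mm) for g in "ABCD"
    }
    return CohortTables(
        table1=table1,
        table2=table2,
        table3=table3,
        separation=separation,
        per_group_separation=per_group,
    )
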