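"""Polysome-to-monosome quantification from fractionation traces."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import find_peaks

from .io import provenance_line

BASELINE_MODES = ("none", "min", "linear")


@dataclass
class PolysomeTrace:
    """Absorbance vs position; positions strictly increasing."""

    position: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.position.shape != self.absorbance.shape or self.position.ndim != 1:
            raise ValueError("position and absorbance must be equal-length vectors")
        if not (np.diff(self.position) > 0).all():
            raise ValueError("positions must be strictly increasing")

    def to_tsv(self, path: str | Path, params: Mapping | None = None) -> None:
        df = pd.DataFrame({"position": self.position, "absorbance": self.absorbance})
        with open(path, "w") as fh:
            fh.write(provenance_line("trace", params) + "\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PolysomeTrace":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df["position"].to_numpy(), df["absorbance"].to_numpy())


def _region_auc(
    trace: PolysomeTrace, bounds: tuple[float, float], baseline_mode: str
) -> float:
    lo, hi = float(bounds[0]), float(bounds[1])
    x, y = trace.position, trace.absorbance
    if lo >= hi:
        raise ValueError(f"invalid bounds ({lo}, {hi})")
    if lo < x[0] or hi > x[-1]:
        raise ValueError(f"bounds ({lo}, {hi}) outside position range ({x[0]}, {x[-1]})")
    inner = (x > lo) & (x < hi)
    xs = np.concatenate(([lo], x[inner], [hi]))
    ys = np.concatenate(([np.interp(lo, x, y)], y[inner], [np.interp(hi, x, y)]))
    if baseline_mode == "none":
        base = np.zeros_like(xs)
    elif baseline_mode == "min":
        base = np.full_like(xs, y.min())
    elif baseline_mode == "linear":
        base = np.interp(xs, [xs[0], xs[-1]], [ys[0], ys[-1]])
    else:
        raise ValueError(f"baseline_mode must be one of {BASELINE_MODES}")
    return float(np.trapezoid(ys - base, xs))


def auc_ratio(
    trace: PolysomeTrace,
    monosome_bounds: tuple[float, float],
    polysome_bounds: tuple[float, float],
    baseline_mode: str = "linear",
) -> float:
    """Polysome AUC over monosome (80S) AUC, trapezoidal after baseline
    subtraction.  Regions must not overlap; a non-positive monosome AUC is
    an error."""
    if max(monosome_bounds[0], polysome_bounds[0]) < min(
        monosome_bounds[1], polysome_bounds[1]
    ):
        raise ValueError("monosome and polysome regions overlap")
    mono = _region_auc(trace, monosome_bounds, baseline_mode)
    poly = _region_auc(trace, polysome_bounds, baseline_mode)
    if mono <= 0:
        raise ValueError(
            f"monosome AUC is {mono:.4g} after baseline subtraction; "
            "check bounds and baseline mode"
        )
    return poly / mono


def suggest_region_bounds(
    trace: PolysomeTrace, prominence_frac: float = 0.1
) -> list[tuple[float, float]]:
    """Optional helper: local maxima with valley-to-valley bounds.  Never
    applied automatically — callers must pass bounds explicitly."""
    y = trace.absorbance
    peaks, _ = find_peaks(y, prominence=prominence_frac * (y.max() - y.min()))
    out = []
    for p in peaks:
        left = p
        while left > 0 and y[left - 1] < y[left]:
            left -= 1
        right = p
        while right < len(y) - 1 and y[right + 1] < y[right]:
            right += 1
        out.append((float(trace.position[left]), float(trace.position[right])))
    return out


def ratio_change_test(
    ko_ratios: Mapping[str, Sequence[float]],
    wt_ratios: Sequence[float],
) -> pd.DataFrame:
    """Per-clone fold change vs the WT median ratio and a one-sided Welch
    t-test (alternative: clone > WT).

    Returns columns ``clone, n, fold_change, t, pvalue``.
    """
    wt = np.asarray(wt_ratios, dtype=float)
    if wt.size < 2:
        raise ValueError("need >= 2 WT ratios for a t-test")
    wt_median = float(np.median(wt))
    if wt_median <= 0:
        raise ValueError("WT median ratio must be positive")
    rows = []
    for clone, values in ko_ratios.items():
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError(f"clone {clone!r} has {v.size} ratio(s); need >= 2")
        res = sps.ttest_ind(v, wt, equal_var=False, alternative="greater")
        rows.append((clone, v.size, float(v.mean() / wt_median), float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["clone", "n", "fold_change", "t", "pvalue"])
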