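"""Melting-temperature extraction from nanoDSF F350/F330 ratio curves.

A thermal-unfolding curve is the intrinsic-tryptophan fluorescence ratio
F350/F330 against temperature; each unfolding transition shows up as a
local maximum of the smoothed first derivative dR/dT, and the peak
position is the melting temperature Tm.  MHC class I samples typically
show two transitions: the heavy chain first (dipeptide-concentration
dependent) and β2-microglobulin near 62 °C.

Smoothing is a Savitzky-Golay local-polynomial derivative (default window
11 points, order 3); peak positions are refined to sub-grid precision with
a parabolic fit through the peak bin and its neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "MeltCurve",
    "TransitionResult",
    "derivative_curve",
    "find_transitions",
    "tm_vs_concentration",
    "MeltCurveModel",
    "MeltFitResult",
]


@dataclass
class MeltCurve:
    """One nanoDSF ratio curve: temperature (°C) vs F350/F330."""

    temperature: np.ndarray
    ratio: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float).ravel()
        self.ratio = np.asarray(self.ratio, dtype=float).ravel()
        if self.temperature.size != self.ratio.size:
            raise ValueError("temperature and ratio lengths differ")
        if self.temperature.size < 10:
            raise ValueError("melt curve needs at least 10 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    @classmethod
    def from_table(cls, source, label: str = "") -> "MeltCurve":
        """Build from a CSV/TSV file or DataFrame.

        Accepts columns ``temperature`` plus either ``ratio`` or the raw
        channels ``F350`` and ``F330`` (ratio computed as F350/F330).
        Column matching is case-insensitive.
        """
        if isinstance(source, (str, Path)):
            sep = "\t" if str(source).endswith((".tsv", ".txt")) else ","
            df = pd.read_csv(source, sep=sep)
        else:
            df = pd.DataFrame(source)
        cols = {c.lower(): c for c in df.columns}
        if "temperature" not in cols:
            raise ValueError("table needs a 'temperature' column")
        temp = df[cols["temperature"]].to_numpy(float)
        if "ratio" in cols:
            ratio = df[cols["ratio"]].to_numpy(float)
        elif "f350" in cols and "f330" in cols:
            ratio = df[cols["f350"]].to_numpy(float) / df[cols["f330"]].to_numpy(float)
        else:
            raise ValueError("table needs 'ratio' or 'F350'+'F330' columns")
        return cls(temperature=temp, ratio=ratio, label=label)

    def to_table(self, path) -> None:
        pd.DataFrame({"temperature": self.temperature,
                      "ratio": self.ratio}).to_csv(path, index=False)


@dataclass
class TransitionResult:
    """Detected unfolding transitions of one curve, ascending in Tm."""

    tm: list[float]                    # °C
    prominence: list[float]
    derivative_temperature: np.ndarray
    derivative: np.ndarray
    label: str = ""

    @property
    def n_transitions(self) -> int:
        return len(self.tm)


def derivative_curve(curve: MeltCurve, window: int = 11,
                     polyorder: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Savitzky-Golay smoothed first derivative dR/dT on the curve's grid.

    The temperature grid is assumed (approximately) uniform; the returned
    arrays are truncated by half a window at each edge, where the local
    polynomial fit is one-sided and unreliable.
    """
    n = curve.temperature.size
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window < polyorder + 2:
        raise ValueError("window must be at least polyorder + 2")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    dt = float(np.mean(np.diff(curve.temperature)))
    deriv = savgol_filter(curve.ratio, window, polyorder, deriv=1, delta=dt)
    half = window // 2
    return curve.temperature[half:n - half], deriv[half:n - half]


def _default_prominence(deriv: np.ndarray) -> float:
    """5x the median absolute derivative of the first 10 points (baseline noise)."""
    baseline = np.abs(deriv[:10])
    return max(5.0 * float(np.median(baseline)), 1e-12)


def _refine_peak(temps: np.ndarray, deriv: np.ndarray, i: int,
                 half: int = 5) -> float:
    """Sub-grid refinement of a derivative maximum.

    Least-squares parabola through the peak bin and up to ``half``
    neighbours each side; falls back to the grid position when the fitted
    curvature is not concave or the vertex leaves the neighbourhood.
    """
    lo, hi = max(0, i - half), min(deriv.size, i + half + 1)
    if hi - lo < 3:
        return float(temps[i])
    t = temps[lo:hi] - temps[i]
    coeff = np.polyfit(t, deriv[lo:hi], 2)
    if coeff[0] >= 0:
        return float(temps[i])
    vertex = -coeff[1] / (2 * coeff[0])
    if not (t[0] <= vertex <= t[-1]):
        return float(temps[i])
    return float(temps[i] + vertex)


def find_transitions(curve: MeltCurve, min_prominence: float | None = None,
                     max_transitions: int | None = None, window: int = 11,
                     polyorder: int = 3) -> TransitionResult:
    """Unfolding transitions as prominent maxima of the smoothed derivative.

    ``min_prominence`` defaults to 5x the median absolute derivative over
    the first 10 points, a baseline-noise proxy that makes the call
    invariant under rescaling the ratio.  When ``max_transitions`` is set,
    the most prominent peaks are kept.  Zero transitions is a valid result.
    """
    temps, deriv = derivative_curve(curve, window=window, polyorder=polyorder)
    if min_prominence is None:
        min_prominence = _default_prominence(deriv)
    peaks, props = find_peaks(deriv, prominence=min_prominence)
    proms = props["prominences"]
    if max_transitions is not None and peaks.size > max_transitions:
        keep = np.argsort(proms)[::-1][:max_transitions]
        peaks, proms = peaks[keep], proms[keep]
    order = np.argsort(temps[peaks]) if peaks.size else np.array([], dtype=int)
    tms = [_refine_peak(temps, deriv, int(i)) for i in peaks[order]]
    return TransitionResult(tm=tms, prominence=[float(p) for p in proms[order]],
                            derivative_temperature=temps, derivative=deriv,
                            label=curve.label)


def tm_vs_concentration(curves: Sequence[MeltCurve], transition_index: int = 0,
                        **kwargs) -> pd.DataFrame:
    """Tm of one chosen transition across a labelled curve series.

    Returns one row per curve (labels preserved, Tm in °C); a curve that
    does not show the requested transition is flagged rather than fatal.
    Index 0 is the lowest-temperature transition (the heavy chain in the
    two-event MHC layout; β2m is index 1).
    """
    rows = []
    for curve in curves:
        result = find_transitions(curve, **kwargs)
        ok = transition_index < result.n_transitions
        rows.append({
            "label": curve.label,
            "tm": result.tm[transition_index] if ok else np.nan,
            "n_transitions": result.n_transitions,
            "flagged": not ok,
        })
    return pd.DataFrame(rows, columns=["label", "tm", "n_transitions", "flagged"])


class MeltCurveModel:
    """Model-style wrapper: one curve in, a fitted transition set out."""

    def __init__(self, curve: MeltCurve, *, window: int = 11, polyorder: int = 3):
        self.curve = curve
        self.window = window
        self.polyorder = polyorder

    @classmethod
    def from_table(cls, source, label: str = "", **kwargs) -> "MeltCurveModel":
        return cls(MeltCurve.from_table(source, label=label), **kwargs)

    def fit(self, min_prominence: float | None = None,
            max_transitions: int | None = None) -> "MeltFitResult":
        res = find_transitions(self.curve, min_prominence=min_prominence,
                               max_transitions=max_transitions,
                               window=self.window, polyorder=self.polyorder)
        return MeltFitResult(model=self, transitions=res)


@dataclass
class MeltFitResult:
    model: MeltCurveModel
    transitions: TransitionResult

    @property
    def tm(self) -> list[float]:
        return self.transitions.tm

    def summary(self) -> str:
        curve = self.model.curve
        lines = [
            "nanoDSF melting-curve analysis",
            "=" * 34,
            f"curve label:    {curve.label or '(unlabelled)'}",
            f"points:         {curve.temperature.size} "
            f"({curve.temperature[0]:.1f}-{curve.temperature[-1]:.1f} °C)",
            f"smoothing:      Savitzky-Golay window {self.model.window}, "
            f"order {self.model.polyorder}",
            f"transitions:    {self.transitions.n_transitions}",
        ]
        names = ["heavy chain", "beta2m"]
        for i, (tm, prom) in enumerate(zip(self.transitions.tm,
                                           self.transitions.prominence)):
            tag = f" ({names[i]})" if i < len(names) and \
                self.transitions.n_transitions == 2 else ""
            lines.append(f"  Tm {i + 1}{tag}: {tm:6.2f} °C  "
                         f"(prominence {prom:.2e})")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        t = self.transitions
        ax.plot(t.derivative_temperature, t.derivative, color="k", lw=1.2)
        for tm in t.tm:
            ax.axvline(tm, color="crimson", ls="--", lw=0.8)
        ax.set_xlabel("temperature (°C)")
        ax.set_ylabel("d(F350/F330)/dT")
        return ax
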