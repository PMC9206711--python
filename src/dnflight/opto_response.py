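"""Scoring and regression analysis of optogenetic wingbeat-amplitude responses.

A session delivers brief light pulses to a tethered flying fly while a
machine-vision tracker reports left/right wingbeat amplitude (degrees) and a
photodetector reports wingbeat frequency (Hz).  Each pulse is scored as the
mean wingbeat amplitude over the half second starting at stimulus onset minus
the mean over the half second before onset (baseline subtraction, "BLS").
Per-trial scores are averaged within flies, summarised per driver line by
median and interquartile range, and regressed on the number of targeted
descending-neuron cell pairs to test a population code: more active cell
pairs, proportionally larger amplitude increase.

Window convention: half-open sample windows [onset - pre, onset) and
[onset, onset + post), so the onset sample is counted once, in the response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .aero_power import Morphometrics, mechanical_power

__all__ = [
    "TrialTrace",
    "TrialWindow",
    "TrialMetrics",
    "FlySummary",
    "LineSummary",
    "DoseResponseFit",
    "InteractionTest",
    "FreqCouplingFit",
    "segment_trials",
    "score_trial",
    "summarize_fly",
    "summarize_line",
    "rank_lines",
    "fit_dose_response",
    "compare_bls_slopes",
    "freq_change_regression",
    "amp_freq_trajectory",
]


@dataclass
class TrialTrace:
    """One fly's wingbeat time series with the optogenetic pulse schedule.

    ``t`` is uniformly sampled (s); amplitudes in degrees, frequency in Hz.
    """

    t: np.ndarray
    wba_left: np.ndarray
    wba_right: np.ndarray
    freq: np.ndarray
    pulse_onsets: np.ndarray
    fs: float
    fly_id: str = ""
    line_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.wba_left = np.asarray(self.wba_left, dtype=float)
        self.wba_right = np.asarray(self.wba_right, dtype=float)
        self.freq = np.asarray(self.freq, dtype=float)
        self.pulse_onsets = np.asarray(self.pulse_onsets, dtype=float)
        n = self.t.size
        if any(a.size != n for a in (self.wba_left, self.wba_right, self.freq)):
            raise ValueError("all series must have the same length as t")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def wba_mean(self) -> np.ndarray:
        """Mean of left and right wingbeat amplitude, (L+R)/2 (deg)."""
        return 0.5 * (self.wba_left + self.wba_right)


@dataclass
class TrialWindow:
    """One pulse-aligned window: samples in [onset - pre, onset + post)."""

    onset: float
    t: np.ndarray           # absolute time of samples
    wba_mean: np.ndarray
    freq: np.ndarray
    split: int              # index of the first sample with t >= onset

    @property
    def t_rel(self) -> np.ndarray:
        return self.t - self.onset


@dataclass(frozen=True)
class TrialMetrics:
    """Baseline/response means for one pulse (amplitude in deg, frequency in Hz)."""

    baseline_wba: float
    response_wba_raw: float
    delta_wba: float
    baseline_freq: float
    delta_freq: float


@dataclass(frozen=True)
class FlySummary:
    """Across-trial means for one fly (one measurement per individual)."""

    fly_id: str
    n_trials: int
    baseline_wba: float
    response_wba_raw: float
    delta_wba: float
    baseline_freq: float
    delta_freq: float


@dataclass
class LineSummary:
    """Per-driver-line summary: per-fly response values, median and IQR."""

    line_id: str
    n_pairs: int
    per_fly_values: np.ndarray
    median: float = field(init=False)
    q1: float = field(init=False)
    q3: float = field(init=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.per_fly_values, dtype=float)
        if vals.size == 0:
            raise ValueError("LineSummary needs at least one fly")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        self.per_fly_values = vals
        # Linear-interpolation quantiles (numpy default).
        self.q1, self.median, self.q3 = (float(q) for q in
                                         np.quantile(vals, [0.25, 0.5, 0.75]))


@dataclass(frozen=True)
class DoseResponseFit:
    """OLS fit of line response on number of targeted cell pairs."""

    slope: float          # deg per cell pair
    intercept: float      # deg
    r2: float
    n_points: int


@dataclass(frozen=True)
class InteractionTest:
    """Slopes with and without baseline subtraction and the interaction p-value."""

    slope_bls: float
    slope_raw: float
    p_interaction: float


@dataclass(frozen=True)
class FreqCouplingFit:
    """OLS of frequency change on baseline frequency, with zero-crossing."""

    slope: float
    intercept: float            # Hz
    zero_crossing: Optional[float]  # Hz; None when slope == 0
    r2: float


def segment_trials(trace: TrialTrace, pre_s: float = 0.5, post_s: float = 0.5
                   ) -> list[TrialWindow]:
    """Cut one window per pulse onset, spanning [onset - pre_s, onset + post_s).

    Raises if a window runs off either end of the trace or if consecutive
    windows overlap (they cannot with the standard 10 s interpulse interval).
    """
    if pre_s <= 0 or post_s <= 0:
        raise ValueError("pre_s and post_s must be > 0")
    onsets = np.sort(trace.pulse_onsets)
    if onsets.size == 0:
        raise ValueError("trace has no pulse onsets")
    t0, t_end = trace.t[0], trace.t[-1]
    bad = onsets[(onsets - pre_s < t0) | (onsets + post_s > t_end + 0.5 / trace.fs)]
    if bad.size:
        raise ValueError(f"windows exceed trace extent for onsets {bad.tolist()}")
    overlap = onsets[1:][np.diff(onsets) < pre_s + post_s]
    if overlap.size:
        raise ValueError(f"overlapping windows at onsets {overlap.tolist()}")
    wba = trace.wba_mean
    windows = []
    for onset in onsets:
        i0 = int(np.searchsorted(trace.t, onset - pre_s, side="left"))
        i_on = int(np.searchsorted(trace.t, onset, side="left"))
        i1 = int(np.searchsorted(trace.t, onset + post_s, side="left"))
        windows.append(TrialWindow(onset=float(onset), t=trace.t[i0:i1],
                                   wba_mean=wba[i0:i1], freq=trace.freq[i0:i1],
                                   split=i_on - i0))
    return windows


def score_trial(window: TrialWindow,
                metric: Literal["mean", "peak"] = "mean") -> TrialMetrics:
    """Score one pulse window.

    Baseline = mean over the pre-onset half; response = mean (default) or,
    with ``metric="peak"``, the maximum of the post-onset half.  The same
    windows are applied to the frequency channel (always window means there).
    """
    if not (np.all(np.isfinite(window.wba_mean)) and np.all(np.isfinite(window.freq))):
        raise ValueError("non-finite samples in trial window")
    if window.split <= 0 or window.split >= window.t.size:
        raise ValueError("window does not contain both baseline and response samples")
    pre = slice(None, window.split)
    post = slice(window.split, None)
    baseline = float(np.mean(window.wba_mean[pre]))
    if metric == "mean":
        response = float(np.mean(window.wba_mean[post]))
    elif metric == "peak":
        response = float(np.max(window.wba_mean[post]))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    baseline_freq = float(np.mean(window.freq[pre]))
    delta_freq = float(np.mean(window.freq[post])) - baseline_freq
    return TrialMetrics(
        baseline_wba=baseline,
        response_wba_raw=response,
        delta_wba=response - baseline,
        baseline_freq=baseline_freq,
        delta_freq=delta_freq,
    )


def summarize_fly(metrics: Sequence[TrialMetrics], fly_id: str = "") -> FlySummary:
    """Average all trials of one fly into a single measurement."""
    metrics = list(metrics)
    if not metrics:
        raise ValueError("no trials to summarise")
    mean = lambda attr: float(np.mean([getattr(m, attr) for m in metrics]))
    return FlySummary(
        fly_id=fly_id,
        n_trials=len(metrics),
        baseline_wba=mean("baseline_wba"),
        response_wba_raw=mean("response_wba_raw"),
        delta_wba=mean("delta_wba"),
        baseline_freq=mean("baseline_freq"),
        delta_freq=mean("delta_freq"),
    )


def summarize_line(flies: Sequence[FlySummary], line_id: str, n_pairs: int,
                   value: str = "delta_wba") -> LineSummary:
    """Median and interquartile range of per-fly response values for one line."""
    flies = list(flies)
    if not flies:
        raise ValueError("no flies to summarise")
    vals = np.array([getattr(f, value) for f in flies], dtype=float)
    return LineSummary(line_id=line_id, n_pairs=int(n_pairs), per_fly_values=vals)


def rank_lines(lines: Sequence[LineSummary]) -> pd.DataFrame:
    """Rank driver lines by the magnitude of their median response, descending.

    Ties are broken lexicographically by line_id.
    """
    lines = list(lines)
    if not lines:
        raise ValueError("no lines to rank")
    df = pd.DataFrame({
        "line_id": [l.line_id for l in lines],
        "n_pairs": [l.n_pairs for l in lines],
        "median": [l.median for l in lines],
        "q1": [l.q1 for l in lines],
        "q3": [l.q3 for l in lines],
        "n_flies": [l.per_fly_values.size for l in lines],
    })
    df = df.sort_values(["median", "line_id"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df.index.name = "rank"
    return df


def fit_dose_response(lines: Sequence[LineSummary], use_median: bool = True
                      ) -> DoseResponseFit:
    """OLS of line response on the number of targeted cell pairs.

    With ``use_median`` (default, as the screen figures are drawn) each line
    contributes its median; otherwise every fly contributes a point.  Several
    lines may share one ``n_pairs`` value.  r^2 is the squared Pearson
    correlation of observed and fitted values.
    """
    lines = list(lines)
    if use_median:
        x = np.array([l.n_pairs for l in lines], dtype=float)
        y = np.array([l.median for l in lines], dtype=float)
    else:
        x = np.concatenate([np.full(l.per_fly_values.size, l.n_pairs, dtype=float)
                            for l in lines])
        y = np.concatenate([l.per_fly_values for l in lines])
    if np.unique(x).size < 2:
        raise ValueError("all lines target the same number of cell pairs; slope unidentifiable")
    res = stats.linregress(x, y)
    return DoseResponseFit(slope=float(res.slope), intercept=float(res.intercept),
                           r2=float(res.rvalue**2), n_points=int(x.size))


def compare_bls_slopes(table: pd.DataFrame, value_col: str = "value") -> InteractionTest:
    """Test whether baseline subtraction changes the cell-count slope.

    ``table`` holds per-fly observations with columns ``n_pairs``, the response
    value, and ``mode`` in {"BLS", "RAW"}.  Fits
    ``value ~ n_pairs * mode`` by OLS and reports the two mode-specific slopes
    and the p-value of the interaction term (slope difference).
    """
    modes = set(table["mode"].unique())
    if modes != {"BLS", "RAW"}:
        raise ValueError(f"need both BLS and RAW observations, got modes {sorted(modes)}")
    df = table.rename(columns={value_col: "value"})
    model = smf.ols("value ~ n_pairs * C(mode, Treatment('BLS'))", data=df).fit()
    slope_bls = float(model.params["n_pairs"])
    inter_name = "n_pairs:C(mode, Treatment('BLS'))[T.RAW]"
    slope_raw = slope_bls + float(model.params[inter_name])
    return InteractionTest(slope_bls=slope_bls, slope_raw=slope_raw,
                           p_interaction=float(model.pvalues[inter_name]))


def freq_change_regression(baseline_freq: Sequence[float],
                           delta_freq: Sequence[float]) -> FreqCouplingFit:
    """OLS of per-fly frequency change on pre-stimulus baseline frequency.

    Under a muscle power cap the fit has negative slope: flies already beating
    fast must trade frequency away when activation raises amplitude.  The
    zero-crossing -intercept/slope estimates the baseline frequency above
    which activation lowers frequency (absent when the slope is zero).
    """
    x = np.asarray(baseline_freq, dtype=float)
    y = np.asarray(delta_freq, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 matched (baseline, delta) frequency pairs")
    if np.ptp(x) == 0:
        raise ValueError("baseline frequencies are all identical")
    res = stats.linregress(x, y)
    slope = float(res.slope)
    crossing = None if slope == 0.0 else float(-res.intercept / slope)
    return FreqCouplingFit(slope=slope, intercept=float(res.intercept),
                           zero_crossing=crossing, r2=float(res.rvalue**2))


def amp_freq_trajectory(window: TrialWindow, morph: Morphometrics) -> pd.DataFrame:
    """Per-sample kinematic states of a trial with attached mechanical power.

    Returns a frame with columns (time, phi_deg, n_hz, P_mech); feed the
    (n_hz, phi_deg) columns to :func:`dnflight.aero_power.bounding_power`.
    """
    if window.wba_mean.size != window.freq.size:
        raise ValueError("amplitude and frequency sample counts differ")
    P = mechanical_power(window.freq, window.wba_mean, morph, degrees=True).P_mech
    return pd.DataFrame({
        "time": window.t,
        "phi_deg": window.wba_mean,
        "n_hz": window.freq,
        "P_mech": np.asarray(P),
    })
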