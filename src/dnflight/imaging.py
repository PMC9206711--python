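"""Bilateral two-photon functional-imaging pipeline.

The recording has two channels over the same field of view: a GCaMP activity
channel and a tdTomato anatomical channel.  Processing order (fixed):

1. rigid registration of both channels to the time-averaged tdTomato image
   (integer-pixel cross-correlation peak);
2. ROI selection — the 20% most temporally variable GCaMP pixels in each
   half of the FOV — and background selection — the 20% dimmest pixels of
   the whole FOV on the temporal mean;
3. per-frame fluorescence F_t = mean(ROI) - mean(background), per channel;
4. ratiometric normalisation G/R to cancel z-motion;
5. baseline F_0 = mean of the lowest 10% of F_t, then
   dF/F = (F_t - F_0) / max(F_t - F_0), which spans [.., 1] with max exactly 1;
6. behaviour (32 Hz wingbeat amplitudes) corrected for the ~30 ms tracker
   delay and interpolated onto frame times;
7. stimulus-epoch averages with bootstrap CIs, equal-occupancy tuning curves
   on z-scored signals, and pixel-wise fluorescence-behaviour correlation maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.registration import phase_cross_correlation

__all__ = [
    "TwoChannelMovie",
    "RoiSet",
    "SideTrace",
    "BehaviorTrace",
    "StimulusProtocol",
    "EpochAverage",
    "TuningCurve",
    "PixelCorrMap",
    "PATTERN_CODES",
    "register_to_reference",
    "select_variable_rois",
    "select_background",
    "roi_fluorescence",
    "ratio_normalize",
    "baseline_f0",
    "normalized_dff",
    "lag_correct_behavior",
    "resample_behavior_to_frames",
    "extract_epochs",
    "bootstrap_mean_ci",
    "epoch_average",
    "tuning_curve",
    "pixel_correlation_map",
    "bilateral_summary",
]

# Visual pattern codes: pitch up/down, stripe oscillating left/right, yaw
# right/left, roll left/right, expansion left/right, regressive/progressive
# motion, closed-loop stripe fixation.
PATTERN_CODES = ("PU", "OL", "YR", "RL", "EL", "Re", "ER", "Pr",
                 "YL", "RR", "PD", "OR", "CL")


@dataclass
class TwoChannelMovie:
    """GCaMP + tdTomato frame stacks (T, H, W) with frame timing."""

    gcamp: np.ndarray
    tdtom: np.ndarray
    frame_rate: float
    frame_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.gcamp = np.asarray(self.gcamp, dtype=float)
        self.tdtom = np.asarray(self.tdtom, dtype=float)
        if self.gcamp.shape != self.tdtom.shape:
            raise ValueError("channel shape mismatch: "
                             f"{self.gcamp.shape} vs {self.tdtom.shape}")
        if self.gcamp.ndim != 3:
            raise ValueError("movies must be (T, H, W) stacks")
        if self.frame_times is None:
            self.frame_times = np.arange(self.gcamp.shape[0]) / self.frame_rate
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.gcamp.shape


@dataclass(frozen=True)
class RoiSet:
    """Boolean masks: left/right ROIs (one per FOV half) plus background."""

    left_mask: np.ndarray
    right_mask: np.ndarray
    background_mask: np.ndarray


@dataclass(frozen=True)
class SideTrace:
    """Per-hemisphere fluorescence trace: raw F_t, baseline F_0, normalised dF/F."""

    side: str
    F_t: np.ndarray
    F0: float
    dff: np.ndarray


@dataclass
class BehaviorTrace:
    """Wingbeat-amplitude time series from the 32 Hz video tracker."""

    t: np.ndarray
    wba_left: np.ndarray
    wba_right: np.ndarray
    fs: float = 32.0
    lag_corrected: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.wba_left = np.asarray(self.wba_left, dtype=float)
        self.wba_right = np.asarray(self.wba_right, dtype=float)
        if not (self.t.size == self.wba_left.size == self.wba_right.size):
            raise ValueError("behaviour series must share one time base")


@dataclass
class StimulusProtocol:
    """Ordered visual epochs: (pattern_id, onset_s, duration_s), gaps between."""

    epochs: pd.DataFrame  # columns: pattern_id, onset_s, duration_s

    def __post_init__(self) -> None:
        required = {"pattern_id", "onset_s", "duration_s"}
        if not required.issubset(self.epochs.columns):
            raise ValueError(f"protocol table needs columns {sorted(required)}")
        e = self.epochs.sort_values("onset_s").reset_index(drop=True)
        ends = e["onset_s"] + e["duration_s"]
        if np.any(e["onset_s"].values[1:] < ends.values[:-1]):
            raise ValueError("protocol epochs overlap")
        self.epochs = e

    def onsets_for(self, pattern_id: str) -> np.ndarray:
        sel = self.epochs[self.epochs["pattern_id"] == pattern_id]
        if sel.empty:
            raise ValueError(f"pattern {pattern_id!r} absent from protocol")
        return sel["onset_s"].to_numpy()


@dataclass(frozen=True)
class EpochAverage:
    """Stimulus-triggered mean with percentile-bootstrap 95% CI of the mean."""

    t_rel: np.ndarray
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n: int


@dataclass(frozen=True)
class TuningCurve:
    """Binned mean of z-scored wingbeat amplitude vs z-scored dF/F."""

    bin_center: np.ndarray
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_per_bin: np.ndarray


@dataclass(frozen=True)
class PixelCorrMap:
    """Per-pixel Pearson r of pixel signals vs left/right wingbeat amplitude."""

    r_left: np.ndarray
    r_right: np.ndarray
    valid: np.ndarray  # False where the pixel had zero temporal variance


# ---------------------------------------------------------------------------
# registration

def _integer_shift(img: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    """Shift a 2-D image by whole pixels, filling exposed edges with ``fill``."""
    out = np.full_like(img, fill)
    H, W = img.shape
    ys = slice(max(dy, 0), min(H + dy, H))
    xs = slice(max(dx, 0), min(W + dx, W))
    ys_src = slice(max(-dy, 0), min(H - dy, H))
    xs_src = slice(max(-dx, 0), min(W - dx, W))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def register_to_reference(movie: TwoChannelMovie
                          ) -> tuple[TwoChannelMovie, np.ndarray]:
    """Rigidly register each frame to the time-averaged tdTomato image.

    The per-frame shift is the integer-pixel peak of the 2-D cross-correlation
    between the frame's tdTomato image and the reference; the same shift is
    applied to both channels.  Exposed edge pixels are filled with the frame's
    median (a background estimate).  Returns the registered movie and the
    (T, 2) array of applied (dy, dx) shifts.
    """
    if movie.shape[0] < 2:
        raise ValueError("need at least 2 frames to register")
    reference = movie.tdtom.mean(axis=0)
    T = movie.shape[0]
    shifts = np.zeros((T, 2), dtype=int)
    g_out = np.empty_like(movie.gcamp)
    t_out = np.empty_like(movie.tdtom)
    for k in range(T):
        frame = movie.tdtom[k]
        if np.ptp(frame) == 0:
            warnings.warn(f"frame {k} has no contrast; zero shift applied", stacklevel=2)
            dy = dx = 0
        else:
            shift, _, _ = phase_cross_correlation(reference, frame,
                                                  normalization=None,
                                                  upsample_factor=1)
            dy, dx = int(round(shift[0])), int(round(shift[1]))
        shifts[k] = (dy, dx)
        t_out[k] = _integer_shift(frame, dy, dx, float(np.median(frame)))
        g_out[k] = _integer_shift(movie.gcamp[k], dy, dx, float(np.median(movie.gcamp[k])))
    registered = TwoChannelMovie(gcamp=g_out, tdtom=t_out,
                                 frame_rate=movie.frame_rate,
                                 frame_times=movie.frame_times.copy())
    return registered, shifts


# ---------------------------------------------------------------------------
# masks

def _top_k_mask(score: np.ndarray, k: int) -> np.ndarray:
    """Mask of the k highest-scoring pixels; ties broken by raster order."""
    flat = score.ravel()
    # stable sort on -score keeps raster order among ties
    order = np.argsort(-flat, kind="stable")
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(score.shape)


def select_variable_rois(gcamp_registered: np.ndarray,
                         fraction: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Select the most temporally variable GCaMP pixels in each FOV half.

    Returns boolean (H, W) masks for the left and right halves (split at
    W // 2), each containing floor(fraction * half-pixel-count) pixels.
    """
    stack = np.asarray(gcamp_registered, dtype=float)
    var = stack.var(axis=0)
    if np.all(var == 0):
        raise ValueError("stack has no temporal variability; cannot select ROIs")
    H, W = var.shape
    half = W // 2
    k = int(np.floor(fraction * H * half))
    if k < 1:
        raise ValueError("FOV too small for the requested ROI fraction")
    left = np.zeros((H, W), dtype=bool)
    right = np.zeros((H, W), dtype=bool)
    left[:, :half] = _top_k_mask(var[:, :half], k)
    right[:, half:] = _top_k_mask(var[:, half:], k)
    return left, right


def select_background(stack: np.ndarray, fraction: float = 0.2) -> np.ndarray:
    """The dimmest pixels of the whole FOV, ranked on the temporal-mean image."""
    stack = np.asarray(stack, dtype=float)
    mean_img = stack.mean(axis=0)
    k = int(np.floor(fraction * mean_img.size))
    return _top_k_mask(-mean_img, k)


# ---------------------------------------------------------------------------
# traces

def roi_fluorescence(stack: np.ndarray, roi_mask: np.ndarray,
                     background_mask: np.ndarray) -> np.ndarray:
    """Per-frame F_t = mean over the ROI minus mean over the background."""
    stack = np.asarray(stack, dtype=float)
    if not roi_mask.any() or not background_mask.any():
        raise ValueError("empty ROI or background mask")
    return stack[:, roi_mask].mean(axis=1) - stack[:, background_mask].mean(axis=1)


def ratio_normalize(F_gcamp: np.ndarray, F_tdtom: np.ndarray,
                    eps: float = 0.05) -> np.ndarray:
    """Divide the activity trace by the anatomical trace to cancel z-motion.

    A shared per-frame gain (z-drift) multiplies both channels and cancels in
    the ratio.  The denominator is floored at ``eps * median`` to avoid
    blow-up on dim frames.
    """
    G = np.asarray(F_gcamp, dtype=float)
    R = np.asarray(F_tdtom, dtype=float)
    if G.shape != R.shape:
        raise ValueError("channel traces must have equal length")
    med = np.median(R)
    if med <= 0:
        raise ValueError("tdTomato trace has non-positive median; cannot normalise")
    return G / np.maximum(R, eps * med)


def baseline_f0(F_t: np.ndarray, fraction: float = 0.1) -> float:
    """Baseline fluorescence: mean of the lowest ``fraction`` of F_t samples."""
    F = np.asarray(F_t, dtype=float)
    if F.size == 0:
        raise ValueError("empty trace")
    k = max(1, int(np.floor(fraction * F.size)))
    return float(np.mean(np.sort(F)[:k]))


def normalized_dff(F_t: np.ndarray, F0: float) -> np.ndarray:
    """dF/F normalised to the session maximum: (F_t - F_0) / max(F_t - F_0).

    The output's maximum is exactly 1 by construction, which standardises
    activity across individuals; invariant to positive affine transforms of
    the raw intensities.
    """
    d = np.asarray(F_t, dtype=float) - F0
    m = d.max()
    if m <= 0:
        raise ValueError("non-positive dynamic range; cannot normalise dF/F")
    return d / m


def extract_side_trace(movie: TwoChannelMovie, roi_mask: np.ndarray,
                       background_mask: np.ndarray, side: str,
                       eps: float = 0.05) -> SideTrace:
    """F_t -> ratio-normalised -> F_0 -> dF/F for one hemisphere."""
    Fg = roi_fluorescence(movie.gcamp, roi_mask, background_mask)
    Fr = roi_fluorescence(movie.tdtom, roi_mask, background_mask)
    F = ratio_normalize(Fg, Fr, eps=eps)
    F0 = baseline_f0(F)
    return SideTrace(side=side, F_t=F, F0=F0, dff=normalized_dff(F, F0))


# ---------------------------------------------------------------------------
# behaviour

def lag_correct_behavior(behavior: BehaviorTrace, lag_s: float = 0.030
                         ) -> BehaviorTrace:
    """Remove the video tracker's measurement delay.

    A value the tracker reports at time t reflects the wings at t - lag, so
    the corrected series at time t is the reported series evaluated at
    t + lag (linear interpolation, edge hold).  Refuses to correct twice.
    """
    if behavior.lag_corrected:
        raise ValueError("behaviour trace is already lag-corrected")
    if lag_s == 0:
        return replace(behavior, lag_corrected=True)
    t = behavior.t
    return BehaviorTrace(
        t=t.copy(),
        wba_left=np.interp(t + lag_s, t, behavior.wba_left),
        wba_right=np.interp(t + lag_s, t, behavior.wba_right),
        fs=behavior.fs,
        lag_corrected=True,
    )


def resample_behavior_to_frames(behavior: BehaviorTrace,
                                frame_times: np.ndarray) -> pd.DataFrame:
    """Linearly interpolate the 32 Hz behaviour onto imaging frame times."""
    return pd.DataFrame({
        "t": frame_times,
        "wba_left": np.interp(frame_times, behavior.t, behavior.wba_left),
        "wba_right": np.interp(frame_times, behavior.t, behavior.wba_right),
    })


# ---------------------------------------------------------------------------
# epoch averaging and bootstrap

def extract_epochs(signal: np.ndarray, times: np.ndarray,
                   protocol: StimulusProtocol, pattern_id: str,
                   pre_s: float = 1.0, post_s: float = 4.0,
                   baseline_subtract: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Cut pattern-aligned epochs out of a signal.

    Each row spans [onset - pre_s, onset + post_s) on the signal's own time
    base; with ``baseline_subtract`` the mean over the pre-onset second is
    removed per epoch.  Returns (epoch matrix, relative-time vector).
    """
    onsets = protocol.onsets_for(pattern_id)
    dt = float(np.median(np.diff(times)))
    n_pre = int(round(pre_s / dt))
    n_post = int(round(post_s / dt))
    rows = []
    for onset in onsets:
        i_on = int(np.searchsorted(times, onset, side="left"))
        i0, i1 = i_on - n_pre, i_on + n_post
        if i0 < 0 or i1 > signal.size:
            raise ValueError(f"epoch at onset {onset} exceeds recording extent")
        row = signal[i0:i1].astype(float)
        if baseline_subtract:
            row = row - row[:n_pre].mean()
        rows.append(row)
    t_rel = (np.arange(-n_pre, n_post)) * dt
    return np.vstack(rows), t_rel


def bootstrap_mean_ci(samples: np.ndarray, n_boot: int = 1000,
                      seed: Optional[int] = None,
                      ci: float = 0.95) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percentile bootstrap CI for the mean across rows of ``samples``.

    Rows are the resampling units (flies or epochs); columns are time points.
    Deterministic given (seed, n_boot).
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n = samples.shape[0]
    if n < 2:
        raise ValueError("need >= 2 resampling units for a bootstrap CI")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = samples[idx].mean(axis=1)       # (n_boot, n_t)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boot_means, [alpha, 1.0 - alpha], axis=0)
    return samples.mean(axis=0), lo, hi


def epoch_average(signal: np.ndarray, times: np.ndarray,
                  protocol: StimulusProtocol, pattern_id: str,
                  pre_s: float = 1.0, post_s: float = 4.0,
                  n_boot: int = 1000, seed: Optional[int] = None) -> EpochAverage:
    """Baseline-subtracted stimulus-triggered average with bootstrap 95% CI.

    Epochs of one session are the resampling units here; to average across
    flies, stack per-fly means and call :func:`bootstrap_mean_ci` directly.
    """
    epochs, t_rel = extract_epochs(signal, times, protocol, pattern_id,
                                   pre_s=pre_s, post_s=post_s)
    mean, lo, hi = bootstrap_mean_ci(epochs, n_boot=n_boot, seed=seed)
    return EpochAverage(t_rel=t_rel, mean=mean, ci_lo=lo, ci_hi=hi,
                        n=epochs.shape[0])


# ---------------------------------------------------------------------------
# tuning and correlation maps

def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("constant signal: z-score undefined")
    return (x - x.mean()) / sd


def tuning_curve(dff: np.ndarray, wba: np.ndarray, n_bins: int = 10,
                 n_boot: int = 1000, seed: Optional[int] = None) -> TuningCurve:
    """Binned mean of z-scored wingbeat amplitude against z-scored dF/F.

    dF/F is split into equal-occupancy bins (quantile edges); each bin
    reports the mean z-scored amplitude with a percentile-bootstrap 95% CI.
    """
    z_d = _zscore(dff)
    z_w = _zscore(wba)
    if z_d.size != z_w.size:
        raise ValueError("signals must be time-aligned and equal length")
    edges = np.quantile(z_d, np.linspace(0, 1, n_bins + 1))
    which = np.clip(np.searchsorted(edges, z_d, side="right") - 1, 0, n_bins - 1)
    rng = np.random.default_rng(seed)
    centers, means, lows, highs, counts = [], [], [], [], []
    for b in range(n_bins):
        sel = which == b
        vals = z_w[sel]
        if vals.size == 0:
            continue
        centers.append(z_d[sel].mean())
        means.append(vals.mean())
        boots = vals[rng.integers(0, vals.size, size=(n_boot, vals.size))].mean(axis=1)
        lo, hi = np.quantile(boots, [0.025, 0.975])
        lows.append(lo)
        highs.append(hi)
        counts.append(vals.size)
    return TuningCurve(bin_center=np.array(centers), mean=np.array(means),
                       ci_lo=np.array(lows), ci_hi=np.array(highs),
                       n_per_bin=np.array(counts))


def pixel_correlation_map(gcamp_registered: np.ndarray,
                          wba_left: np.ndarray, wba_right: np.ndarray,
                          bout: Optional[slice] = None) -> PixelCorrMap:
    """Per-pixel Pearson correlation of pixel signals with each wing's amplitude.

    ``wba_left``/``wba_right`` must already be resampled onto frame times.
    Zero-variance pixels get r = 0 and are flagged invalid.
    """
    stack = np.asarray(gcamp_registered, dtype=float)
    if bout is not None:
        stack = stack[bout]
        wba_left = wba_left[bout]
        wba_right = wba_right[bout]
    T = stack.shape[0]
    if wba_left.size != T or wba_right.size != T:
        raise ValueError("behaviour length must match frame count over the bout")
    pix = stack.reshape(T, -1)
    pix_c = pix - pix.mean(axis=0)
    sd = pix_c.std(axis=0)
    valid = sd > 0

    def corr_with(beh: np.ndarray) -> np.ndarray:
        z = _zscore(beh)
        r = np.zeros(pix.shape[1])
        r[valid] = (pix_c[:, valid] * z[:, None]).mean(axis=0) / sd[valid]
        return r.reshape(stack.shape[1:])

    H, W = stack.shape[1:]
    return PixelCorrMap(r_left=corr_with(wba_left), r_right=corr_with(wba_right),
                        valid=valid.reshape(H, W))


def bilateral_summary(left: SideTrace, right: SideTrace,
                      wba_left: np.ndarray, wba_right: np.ndarray) -> pd.DataFrame:
    """2x2 table of side-trace x wing correlations plus the L-R wing correlation.

    The wing amplitudes of the two sides are themselves negatively correlated
    during asymmetric behaviour, so the left-right amplitude correlation is
    reported alongside as a confound check.
    """
    for name, x in (("left dff", left.dff), ("right dff", right.dff),
                    ("left wba", wba_left), ("right wba", wba_right)):
        if np.std(x) == 0:
            raise ValueError(f"constant input: {name}")
    r = lambda a, b: float(np.corrcoef(a, b)[0, 1])
    rows = [
        {"signal": "dff_left", "wing": "left", "r": r(left.dff, wba_left), "relation": "ipsilateral"},
        {"signal": "dff_left", "wing": "right", "r": r(left.dff, wba_right), "relation": "contralateral"},
        {"signal": "dff_right", "wing": "left", "r": r(right.dff, wba_left), "relation": "contralateral"},
        {"signal": "dff_right", "wing": "right", "r": r(right.dff, wba_right), "relation": "ipsilateral"},
        {"signal": "wba_left", "wing": "right", "r": r(wba_left, wba_right), "relation": "left-right wba"},
    ]
    return pd.DataFrame(rows)
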