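"""Ground-truth generators for every pipeline stage.

Three generators emulate the study's recordings:

* :func:`simulate_wingbeat_session` — an optogenetic activation session in
  which each light pulse drives an exponential amplitude step whose frequency
  consequence is governed by the aerodynamic power model: frequency rises
  with amplitude until muscle-mass-specific power would exceed a cap, after
  which frequency follows the power isoline (the amplitude-frequency
  trade-off) downward.
* :func:`simulate_dose_response` — a screen of driver lines targeting
  different numbers of descending-neuron cell pairs, with per-fly Gaussian
  noise around a linear population-code response.
* :func:`simulate_imaging_session` — a two-channel movie with one Gaussian
  arbor per hemisphere whose activity is driven by a visual-pattern protocol,
  plus 32 Hz wingbeat behaviour coupled contralaterally (positive gain) and
  ipsilaterally (negative gain) to the latent activity, with in-plane motion
  jitter, shared z-drift gain, shot-like noise, and the tracker's 30 ms delay
  injected.

All generators are deterministic given their seed; every returned object
carries a GroundTruth sidecar with latent signals and the config echo.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .aero_power import (
    Morphometrics,
    drosophila_morphometrics,
    mechanical_power,
    solve_frequency_for_power,
)
from .imaging import PATTERN_CODES, BehaviorTrace, StimulusProtocol, TwoChannelMovie
from .opto_response import TrialTrace

__all__ = [
    "OptoSimConfig",
    "DoseSimConfig",
    "ImagingSimConfig",
    "OptoGroundTruth",
    "DoseGroundTruth",
    "ImagingGroundTruth",
    "make_stimulus_protocol",
    "simulate_wingbeat_session",
    "simulate_dose_response",
    "simulate_bls_raw_table",
    "simulate_imaging_session",
]


# ---------------------------------------------------------------------------
# optogenetic session

@dataclass(frozen=True)
class OptoSimConfig:
    """Study conditions for one optogenetic activation session.

    Defaults follow the experimental schedule (30 pulses of 100 ms at 10 s
    intervals) and plausible tethered-flight kinematics; ``saturation_amp``
    is the amplitude at which the muscle power cap starts to bind (about
    160 degrees in the data this emulates).  ``power_cap=None`` computes the
    cap from the morphometrics as the mechanical power at the saturation
    amplitude and its uncapped frequency, so the cap binds there exactly.
    """

    baseline_amp: float = 145.0      # deg
    baseline_freq: float = 200.0     # Hz
    response_gain: float = 25.0      # deg, asymptote of the amplitude step
    rise_tau: float = 0.05           # s
    hold_s: float = 0.5              # s at plateau before decay
    decay_tau: float = 0.3           # s
    freq_gain: float = 1.0           # Hz per deg of amplitude above baseline
    saturation_amp: float = 160.0    # deg
    power_cap: Optional[float] = None  # W/kg; None -> derived from morphometrics
    noise_sd_amp: float = 2.0        # deg
    noise_sd_freq: float = 3.0       # Hz
    asym_sd: float = 1.0             # deg, left-right half-difference noise
    n_trials: int = 30
    interpulse_s: float = 10.0
    pulse_ms: float = 100.0
    lead_in_s: float = 2.0
    fs: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_amp", "baseline_freq", "rise_tau", "hold_s",
                     "decay_tau", "interpulse_s", "pulse_ms", "fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"OptoSimConfig.{name} must be > 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class OptoGroundTruth:
    """Latent (noiseless) kinematics and the cap actually applied."""

    t: np.ndarray
    amp_latent: np.ndarray       # deg
    freq_latent: np.ndarray      # Hz
    freq_uncapped: np.ndarray    # Hz, before the power cap
    power_cap: float             # W/kg
    config: OptoSimConfig


def default_power_cap(cfg: OptoSimConfig, morph: Morphometrics) -> float:
    """Cap = P_mech at the saturation amplitude and its uncapped frequency."""
    n_sat = cfg.baseline_freq + cfg.freq_gain * (cfg.saturation_amp - cfg.baseline_amp)
    return float(mechanical_power(n_sat, cfg.saturation_amp, morph, degrees=True).P_mech)


def _pulse_response(t: np.ndarray, onsets: np.ndarray, cfg: OptoSimConfig) -> np.ndarray:
    """Unit-asymptote amplitude response: exponential rise, plateau, decay."""
    h = np.zeros_like(t)
    plateau = 1.0 - np.exp(-cfg.hold_s / cfg.rise_tau)
    for onset in onsets:
        d = t - onset
        rise = (d >= 0) & (d < cfg.hold_s)
        h[rise] += 1.0 - np.exp(-d[rise] / cfg.rise_tau)
        tail = d >= cfg.hold_s
        h[tail] += plateau * np.exp(-(d[tail] - cfg.hold_s) / cfg.decay_tau)
    return h


def simulate_wingbeat_session(cfg: OptoSimConfig,
                              morph: Optional[Morphometrics] = None,
                              seed: Optional[int] = None
                              ) -> tuple[TrialTrace, OptoGroundTruth]:
    """Simulate one fly's optogenetic session under a muscle power cap.

    The latent amplitude follows an exponential approach toward
    ``baseline_amp + response_gain`` after each pulse; the latent frequency
    rises linearly with amplitude until the mechanical power would exceed
    ``power_cap``, beyond which it is set to the isoline frequency solving
    P_mech(n, amp) = power_cap.  Seeded Gaussian noise is added to the
    observed amplitude and frequency channels.
    """
    morph = morph if morph is not None else drosophila_morphometrics()
    cap = cfg.power_cap if cfg.power_cap is not None else default_power_cap(cfg, morph)
    P_base = float(mechanical_power(cfg.baseline_freq, cfg.baseline_amp,
                                    morph, degrees=True).P_mech)
    if cap <= P_base:
        raise ValueError(
            f"power_cap {cap:.1f} W/kg is at or below baseline power {P_base:.1f} W/kg")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    duration = cfg.lead_in_s + cfg.n_trials * cfg.interpulse_s
    t = np.arange(int(round(duration * cfg.fs))) / cfg.fs
    onsets = cfg.lead_in_s + np.arange(cfg.n_trials) * cfg.interpulse_s

    amp = cfg.baseline_amp + cfg.response_gain * _pulse_response(t, onsets, cfg)
    freq_uncapped = cfg.baseline_freq + cfg.freq_gain * (amp - cfg.baseline_amp)
    P = np.asarray(mechanical_power(freq_uncapped, amp, morph, degrees=True).P_mech)
    freq = freq_uncapped.copy()
    over = P > cap
    if over.any():
        freq[over] = solve_frequency_for_power(amp[over], cap, morph, degrees=True)

    amp_obs = amp + rng.normal(0.0, cfg.noise_sd_amp, t.size)
    asym = rng.normal(0.0, cfg.asym_sd, t.size)
    freq_obs = freq + rng.normal(0.0, cfg.noise_sd_freq, t.size)

    trace = TrialTrace(t=t, wba_left=amp_obs + asym, wba_right=amp_obs - asym,
                       freq=freq_obs, pulse_onsets=onsets, fs=cfg.fs,
                       fly_id="sim", line_id="sim")
    truth = OptoGroundTruth(t=t, amp_latent=amp, freq_latent=freq,
                            freq_uncapped=freq_uncapped, power_cap=cap, config=cfg)
    return trace, truth


# ---------------------------------------------------------------------------
# dose-response screen

@dataclass(frozen=True)
class DoseSimConfig:
    """Linear population-code screen: response = intercept + slope * n_pairs."""

    true_slope: float = 2.77         # deg per cell pair
    intercept: float = 1.0           # deg
    n_pairs_list: tuple[int, ...] = tuple(range(1, 16))
    flies_per_line: int = 8
    per_fly_sd: float = 4.0          # deg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flies_per_line < 1 or not self.n_pairs_list:
            raise ValueError("need at least one line and one fly per line")
        if self.per_fly_sd < 0:
            raise ValueError("per_fly_sd must be >= 0")


@dataclass(frozen=True)
class DoseGroundTruth:
    true_slope: float
    intercept: float
    config: DoseSimConfig


def simulate_dose_response(cfg: DoseSimConfig, seed: Optional[int] = None
                           ) -> tuple[pd.DataFrame, DoseGroundTruth]:
    """Per-fly screen table: columns (line_id, fly_id, n_pairs, delta_wba)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    for i, n_pairs in enumerate(cfg.n_pairs_list):
        line_id = f"L{i + 1:02d}"
        for j in range(cfg.flies_per_line):
            delta = (cfg.intercept + cfg.true_slope * n_pairs
                     + rng.normal(0.0, cfg.per_fly_sd))
            rows.append({"line_id": line_id, "fly_id": f"{line_id}_f{j + 1}",
                         "n_pairs": int(n_pairs), "delta_wba": delta})
    truth = DoseGroundTruth(true_slope=cfg.true_slope, intercept=cfg.intercept,
                            config=cfg)
    return pd.DataFrame(rows), truth


def simulate_bls_raw_table(cfg: DoseSimConfig, slope_delta_raw: float = 0.0,
                           raw_offset: float = 150.0,
                           seed: Optional[int] = None) -> pd.DataFrame:
    """Per-fly observations under both scoring modes for the interaction test.

    BLS rows follow the config's linear model; RAW rows add the un-subtracted
    baseline level (``raw_offset``) and a slope difference of
    ``slope_delta_raw`` (zero under the null).  Observation noise is drawn
    independently per row, matching the iid-error assumption of the OLS
    interaction test.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    for mode, slope, offset in (("BLS", cfg.true_slope, 0.0),
                                ("RAW", cfg.true_slope + slope_delta_raw, raw_offset)):
        for i, n_pairs in enumerate(cfg.n_pairs_list):
            line_id = f"L{i + 1:02d}"
            for j in range(cfg.flies_per_line):
                value = (cfg.intercept + offset + slope * n_pairs
                         + rng.normal(0.0, cfg.per_fly_sd))
                rows.append({"line_id": line_id, "fly_id": f"{line_id}_f{j + 1}",
                             "n_pairs": int(n_pairs), "mode": mode, "value": value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stimulus protocol

def make_stimulus_protocol(seed: int = 0, n_blocks: int = 1,
                           start_s: float = 3.0, epoch_s: float = 3.0,
                           gap_s: float = 3.0) -> StimulusProtocol:
    """Shuffled blocks of the 13 visual patterns, 3 s epochs with 3 s gaps."""
    rng = np.random.default_rng(seed)
    rows = []
    t = start_s
    for _ in range(n_blocks):
        order = list(PATTERN_CODES)
        rng.shuffle(order)
        for pattern in order:
            rows.append({"pattern_id": pattern, "onset_s": t, "duration_s": epoch_s})
            t += epoch_s + gap_s
    return StimulusProtocol(epochs=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# imaging session

# Per-pattern (left, right) drive to the latent activity of each hemisphere's
# cells.  Invented, but with the study's qualitative structure: yaw to one
# side raises that side's cells and lowers the other's; regressive motion
# drives both strongly.  Units: arbitrary drive, filtered by a calcium kernel.
PATTERN_DRIVES: dict[str, tuple[float, float]] = {
    "YR": (-1.0, 1.0), "YL": (1.0, -1.0),
    "Re": (1.0, 1.0), "Pr": (-0.3, -0.3),
    "RL": (0.5, -0.5), "RR": (-0.5, 0.5),
    "PU": (0.4, 0.4), "PD": (-0.2, -0.2),
    "OL": (0.6, -0.2), "OR": (-0.2, 0.6),
    "EL": (-0.4, 0.2), "ER": (0.2, -0.4),
    "CL": (0.0, 0.0),
}


@dataclass(frozen=True)
class ImagingSimConfig:
    """Two-channel imaging session with bilateral activity-behaviour coupling.

    ``gain_contra`` couples each wing's amplitude positively to the opposite
    hemisphere's activity, ``gain_ipsi`` (non-positive) weakly negatively to
    its own side's, which also builds in the left-right amplitude
    anticorrelation during asymmetric epochs.
    """

    shape: tuple[int, int, int] = (1600, 64, 128)   # (T, H, W)
    frame_rate: float = 13.1
    behavior_fs: float = 32.0
    baseline_wba: float = 150.0      # deg
    gain_contra: float = 15.0        # deg per activity unit, > 0
    gain_ipsi: float = -5.0          # deg per activity unit, <= 0
    behavior_noise_sd: float = 1.0   # deg
    tracker_lag_s: float = 0.030
    activity_baseline: float = 0.25
    drive_gain: float = 0.8
    calcium_tau: float = 0.6         # s
    arbor_sigma: tuple[float, float] = (6.0, 9.0)   # (sy, sx) px
    gcamp_base: float = 30.0         # activity-independent GCaMP brightness
    gcamp_gain: float = 120.0        # GCaMP brightness per activity unit
    # The two arbors differ in anatomical brightness (real preparations are
    # never bilaterally identical); this also removes the half-FOV periodicity
    # that would make registration ambiguous.
    tdtom_peak_left: float = 150.0
    tdtom_peak_right: float = 100.0
    bg_level: float = 10.0
    photon_noise: float = 0.0        # Gaussian sd = photon_noise * sqrt(intensity)
    motion_jitter_px: int = 0        # max |integer shift| per axis
    z_drift_amp: float = 0.0         # fractional shared gain modulation
    z_drift_period_s: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_contra <= 0:
            raise ValueError("gain_contra must be > 0")
        if self.gain_ipsi > 0:
            raise ValueError("gain_ipsi must be <= 0")
        T, H, W = self.shape
        if min(T, H, W) < 4:
            raise ValueError("movie shape too small")
        sy, sx = self.arbor_sigma
        # Arbors sit at (H/2, W/4) and (H/2, 3W/4); require ~2 sigma clearance
        # inside each half so each arbor stays within its half-frame.
        if 2 * sx > W / 4 or 2 * sy > H / 2:
            raise ValueError("arbors would extend outside their half-frame")

    @classmethod
    def small_noiseless(cls, seed: int = 0) -> "ImagingSimConfig":
        """Two 13-pattern blocks at reduced FOV; no noise, jitter, or z-drift."""
        return cls(shape=(2100, 32, 64), arbor_sigma=(3.0, 4.5), seed=seed)

    @classmethod
    def small_moderate(cls, seed: int = 0) -> "ImagingSimConfig":
        """Moderate-noise preset: shot noise, +/-3 px jitter, 5% z-drift."""
        return cls(shape=(2100, 32, 64), arbor_sigma=(3.0, 4.5),
                   photon_noise=1.0, motion_jitter_px=3, z_drift_amp=0.05,
                   behavior_noise_sd=2.0, seed=seed)


@dataclass(frozen=True)
class ImagingGroundTruth:
    """Latent activity, injected shifts, and true (undelayed) behaviour."""

    t_behavior: np.ndarray
    activity_left: np.ndarray        # at behaviour times
    activity_right: np.ndarray
    activity_left_frames: np.ndarray  # at frame times
    activity_right_frames: np.ndarray
    wba_left_true: np.ndarray        # noiseless, undelayed, at behaviour times
    wba_right_true: np.ndarray
    shifts: np.ndarray               # (T, 2) injected (dy, dx)
    z_gain: np.ndarray               # per-frame shared gain
    config: ImagingSimConfig


def _zero_mean_jitter(rng: np.random.Generator, T: int, jmax: int) -> np.ndarray:
    """Integer in-plane jitter with exactly zero mean per axis.

    Shifts come in (s, -s) pairs that are then shuffled in time, so the
    trial-averaged reference image sits on the unshifted pixel grid and
    "recovered shift = -injected shift" is well defined frame by frame.
    """
    if jmax <= 0:
        return np.zeros((T, 2), dtype=int)
    half = rng.integers(-jmax, jmax + 1, size=(T // 2, 2))
    shifts = np.concatenate([half, -half], axis=0)
    if shifts.shape[0] < T:
        shifts = np.concatenate([shifts, np.zeros((1, 2), dtype=int)], axis=0)
    return shifts[rng.permutation(T)]


def _gaussian_arbor(H: int, W: int, cy: float, cx: float,
                    sy: float, sx: float) -> np.ndarray:
    y = np.arange(H)[:, None]
    x = np.arange(W)[None, :]
    return np.exp(-0.5 * (((y - cy) / sy) ** 2 + ((x - cx) / sx) ** 2))


def _exp_filter(drive: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """First-order low-pass (single-exponential calcium kernel)."""
    out = np.empty_like(drive)
    a = dt / tau
    acc = 0.0
    for k in range(drive.size):
        acc += a * (drive[k] - acc)
        out[k] = acc
    return out


def simulate_imaging_session(cfg: ImagingSimConfig,
                             protocol: Optional[StimulusProtocol] = None,
                             seed: Optional[int] = None
                             ) -> tuple[TwoChannelMovie, BehaviorTrace,
                                        StimulusProtocol, ImagingGroundTruth]:
    """Generate movie + behaviour + protocol + ground truth for one session."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    T, H, W = cfg.shape
    frame_times = np.arange(T) / cfg.frame_rate
    duration = frame_times[-1] + 1.0 / cfg.frame_rate
    if protocol is None:
        n_blocks = max(1, int(duration // (len(PATTERN_CODES) * 6.0)))
        protocol = make_stimulus_protocol(seed=seed, n_blocks=n_blocks)

    # latent activity on the behaviour grid
    t_beh = np.arange(int(np.ceil(duration * cfg.behavior_fs))) / cfg.behavior_fs
    drive_l = np.zeros_like(t_beh)
    drive_r = np.zeros_like(t_beh)
    for _, ep in protocol.epochs.iterrows():
        dl, dr = PATTERN_DRIVES[ep["pattern_id"]]
        on = (t_beh >= ep["onset_s"]) & (t_beh < ep["onset_s"] + ep["duration_s"])
        drive_l[on] += dl
        drive_r[on] += dr
    dt = 1.0 / cfg.behavior_fs
    act_l = np.clip(cfg.activity_baseline
                    + cfg.drive_gain * _exp_filter(drive_l, dt, cfg.calcium_tau), 0, None)
    act_r = np.clip(cfg.activity_baseline
                    + cfg.drive_gain * _exp_filter(drive_r, dt, cfg.calcium_tau), 0, None)

    # behaviour: contralateral-positive, ipsilateral-negative coupling
    wba_l_true = cfg.baseline_wba + cfg.gain_contra * act_r + cfg.gain_ipsi * act_l
    wba_r_true = cfg.baseline_wba + cfg.gain_contra * act_l + cfg.gain_ipsi * act_r
    # tracker delay: the value reported at t reflects the wings at t - lag
    rep_l = np.interp(t_beh - cfg.tracker_lag_s, t_beh, wba_l_true)
    rep_r = np.interp(t_beh - cfg.tracker_lag_s, t_beh, wba_r_true)
    rep_l = rep_l + rng.normal(0.0, cfg.behavior_noise_sd, t_beh.size)
    rep_r = rep_r + rng.normal(0.0, cfg.behavior_noise_sd, t_beh.size)
    behavior = BehaviorTrace(t=t_beh, wba_left=rep_l, wba_right=rep_r,
                             fs=cfg.behavior_fs, lag_corrected=False)

    # movie
    act_l_f = np.interp(frame_times, t_beh, act_l)
    act_r_f = np.interp(frame_times, t_beh, act_r)
    arbor_l = _gaussian_arbor(H, W, H / 2, W / 4, *cfg.arbor_sigma)
    arbor_r = _gaussian_arbor(H, W, H / 2, 3 * W / 4, *cfg.arbor_sigma)
    z_gain = 1.0 + cfg.z_drift_amp * np.sin(
        2 * np.pi * frame_times / cfg.z_drift_period_s)
    shifts = _zero_mean_jitter(rng, T, cfg.motion_jitter_px)

    from .imaging import _integer_shift  # shared shift kernel

    gcamp = np.empty((T, H, W))
    tdtom = np.empty((T, H, W))
    td_clean_base = (cfg.bg_level + cfg.tdtom_peak_left * arbor_l
                     + cfg.tdtom_peak_right * arbor_r)
    for k in range(T):
        g_clean = z_gain[k] * (cfg.bg_level
                               + (cfg.gcamp_base + cfg.gcamp_gain * act_l_f[k]) * arbor_l
                               + (cfg.gcamp_base + cfg.gcamp_gain * act_r_f[k]) * arbor_r)
        t_clean = z_gain[k] * td_clean_base
        dy, dx = int(shifts[k, 0]), int(shifts[k, 1])
        if dy or dx:
            g_clean = _integer_shift(g_clean, dy, dx, z_gain[k] * cfg.bg_level)
            t_clean = _integer_shift(t_clean, dy, dx, z_gain[k] * cfg.bg_level)
        if cfg.photon_noise > 0:
            g_clean = g_clean + rng.normal(0.0, 1.0, (H, W)) * cfg.photon_noise * np.sqrt(g_clean)
            t_clean = t_clean + rng.normal(0.0, 1.0, (H, W)) * cfg.photon_noise * np.sqrt(t_clean)
        gcamp[k] = np.clip(g_clean, 0, None)
        tdtom[k] = np.clip(t_clean, 0, None)

    movie = TwoChannelMovie(gcamp=gcamp, tdtom=tdtom, frame_rate=cfg.frame_rate,
                            frame_times=frame_times)
    truth = ImagingGroundTruth(
        t_behavior=t_beh, activity_left=act_l, activity_right=act_r,
        activity_left_frames=act_l_f, activity_right_frames=act_r_f,
        wba_left_true=wba_l_true, wba_right_true=wba_r_true,
        shifts=shifts, z_gain=z_gain, config=cfg)
    return movie, behavior, protocol, truth
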