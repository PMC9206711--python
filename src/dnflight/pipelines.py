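"""End-to-end drivers for the two study workflows.

``run_opto_pipeline`` chains trial segmentation -> scoring -> per-fly and
per-line aggregation -> dose-response fit -> frequency-coupling regression
-> amplitude-frequency trajectory and bounding power, writing tidy CSVs and
JSON reports.  ``run_imaging_pipeline`` chains registration -> ROI and
background selection -> per-side traces -> dF/F -> behaviour lag correction
-> epoch averages -> tuning curves -> pixel correlation maps.  Both are
deterministic given (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from . import io
from .aero_power import Morphometrics, bounding_power, drosophila_morphometrics
from .imaging import (
    BehaviorTrace,
    StimulusProtocol,
    TwoChannelMovie,
    bilateral_summary,
    epoch_average,
    extract_side_trace,
    lag_correct_behavior,
    pixel_correlation_map,
    register_to_reference,
    resample_behavior_to_frames,
    select_background,
    select_variable_rois,
    tuning_curve,
)
from .opto_response import (
    TrialTrace,
    amp_freq_trajectory,
    fit_dose_response,
    freq_change_regression,
    rank_lines,
    score_trial,
    segment_trials,
    summarize_fly,
    summarize_line,
)

__all__ = ["RunConfig", "RunReport", "run_opto_pipeline", "run_imaging_pipeline"]


@dataclass
class RunConfig:
    """Defaults are the study's documented analysis constants."""

    out_dir: Path = Path("results")
    seed: int = 0
    pre_s: float = 0.5            # baseline window before pulse onset
    post_s: float = 0.5           # response window after onset
    metric: str = "mean"          # trial scoring: "mean" or "peak"
    roi_fraction: float = 0.2     # most-variable pixels per half
    background_fraction: float = 0.2  # dimmest pixels of the FOV
    f0_fraction: float = 0.1      # lowest F_t entering the baseline
    tracker_lag_s: float = 0.030
    epoch_pre_s: float = 1.0
    epoch_post_s: float = 4.0
    n_boot: int = 1000
    tuning_bins: int = 10
    morphometrics: Optional[Morphometrics] = None

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.morphometrics is None:
            self.morphometrics = drosophila_morphometrics()


@dataclass
class RunReport:
    config: dict
    seed: int
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def _config_echo(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["out_dir"] = str(d["out_dir"])
    return d


def run_opto_pipeline(traces: list[TrialTrace],
                      catalogue: dict[str, int],
                      cfg: RunConfig) -> RunReport:
    """Score an optogenetic screen and write all per-stage tables.

    ``traces`` holds one TrialTrace per fly; ``catalogue`` maps line_id to
    the number of targeted cell pairs.
    """
    if not traces:
        raise ValueError("no trial traces supplied")
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=_config_echo(cfg), seed=cfg.seed)

    trial_rows, fly_summaries = [], []
    for trace in traces:
        windows = segment_trials(trace, pre_s=cfg.pre_s, post_s=cfg.post_s)
        metrics = [score_trial(w, metric=cfg.metric) for w in windows]
        for w, m in zip(windows, metrics):
            trial_rows.append({"fly_id": trace.fly_id, "line_id": trace.line_id,
                               "onset_s": w.onset, **dataclasses.asdict(m)})
        fly_summaries.append((trace.line_id, summarize_fly(metrics, trace.fly_id)))
    pd.DataFrame(trial_rows).to_csv(cfg.out_dir / "trial_metrics.csv", index=False)

    fly_df = pd.DataFrame([{"line_id": line, **dataclasses.asdict(f)}
                           for line, f in fly_summaries])
    fly_df.to_csv(cfg.out_dir / "fly_summaries.csv", index=False)

    lines = []
    for line_id, group in fly_df.groupby("line_id", sort=False):
        if line_id not in catalogue:
            raise ValueError(f"line {line_id!r} missing from the cell-count catalogue")
        flies = [f for l, f in fly_summaries if l == line_id]
        lines.append(summarize_line(flies, line_id, catalogue[line_id]))
    io.write_line_summaries(lines, cfg.out_dir / "line_summaries.csv")
    ranked = rank_lines(lines)
    ranked.to_csv(cfg.out_dir / "line_ranking.csv")

    stages = report.stages
    stages["n_flies"] = len(traces)
    stages["n_lines"] = len(lines)
    if len({l.n_pairs for l in lines}) >= 2:
        fit = fit_dose_response(lines)
        io.write_json_report(dataclasses.asdict(fit), cfg.out_dir / "dose_response.json")
        stages["dose_response"] = dataclasses.asdict(fit)
    else:
        report.warnings.append("dose-response fit skipped: <2 distinct cell counts")

    if len(fly_df) >= 3 and fly_df["baseline_freq"].nunique() > 1:
        freq_fit = freq_change_regression(fly_df["baseline_freq"],
                                          fly_df["delta_freq"])
        io.write_json_report(dataclasses.asdict(freq_fit),
                             cfg.out_dir / "freq_coupling.json")
        stages["freq_coupling"] = dataclasses.asdict(freq_fit)

    # amplitude-frequency trajectory + bounding power of the first fly
    windows = segment_trials(traces[0], pre_s=cfg.pre_s, post_s=cfg.post_s)
    traj = pd.concat([amp_freq_trajectory(w, cfg.morphometrics) for w in windows])
    traj.to_csv(cfg.out_dir / "amp_freq_trajectory.csv", index=False)
    level, idx = bounding_power((traj["n_hz"].to_numpy(), traj["phi_deg"].to_numpy()),
                                cfg.morphometrics, degrees=True)
    stages["bounding_power_w_per_kg"] = level
    stages["bounding_power_index"] = idx

    io.write_json_report(dataclasses.asdict(report), cfg.out_dir / "opto_report.json")
    return report


def run_imaging_pipeline(movie: TwoChannelMovie, behavior: BehaviorTrace,
                         protocol: StimulusProtocol, cfg: RunConfig) -> RunReport:
    """Run the full bilateral imaging analysis and write all outputs."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=_config_echo(cfg), seed=cfg.seed)
    stages = report.stages

    registered, shifts = register_to_reference(movie)
    np.savetxt(cfg.out_dir / "registration_shifts.csv", shifts, fmt="%d",
               delimiter=",", header="dy,dx", comments="")
    stages["max_abs_shift_px"] = int(np.abs(shifts).max())

    left_mask, right_mask = select_variable_rois(registered.gcamp, cfg.roi_fraction)
    bg_mask = select_background(registered.gcamp, cfg.background_fraction)
    sides = {
        "left": extract_side_trace(registered, left_mask, bg_mask, "left"),
        "right": extract_side_trace(registered, right_mask, bg_mask, "right"),
    }
    pd.DataFrame({
        "t": registered.frame_times,
        "F_left": sides["left"].F_t, "dff_left": sides["left"].dff,
        "F_right": sides["right"].F_t, "dff_right": sides["right"].dff,
    }).to_csv(cfg.out_dir / "side_traces.csv", index=False)
    stages["F0"] = {s: tr.F0 for s, tr in sides.items()}

    corrected = lag_correct_behavior(behavior, cfg.tracker_lag_s)
    beh_frames = resample_behavior_to_frames(corrected, registered.frame_times)

    epoch_rows = []
    for side, tr in sides.items():
        for pattern in protocol.epochs["pattern_id"].unique():
            if len(protocol.onsets_for(pattern)) < 2:
                if side == "left":
                    report.warnings.append(
                        f"pattern {pattern}: <2 epochs, no bootstrap CI")
                continue
            avg = epoch_average(tr.dff, registered.frame_times, protocol, pattern,
                                pre_s=cfg.epoch_pre_s, post_s=cfg.epoch_post_s,
                                n_boot=cfg.n_boot, seed=cfg.seed)
            for t_rel, m, lo, hi in zip(avg.t_rel, avg.mean, avg.ci_lo, avg.ci_hi):
                epoch_rows.append({"side": side, "pattern_id": pattern,
                                   "t_rel": t_rel, "mean": m,
                                   "ci_lo": lo, "ci_hi": hi, "n": avg.n})
    pd.DataFrame(epoch_rows).to_csv(cfg.out_dir / "epoch_averages.csv", index=False)

    tuning_rows = []
    for side, wing in (("left", "wba_right"), ("left", "wba_left"),
                       ("right", "wba_left"), ("right", "wba_right")):
        curve = tuning_curve(sides[side].dff, beh_frames[wing].to_numpy(),
                             n_bins=cfg.tuning_bins, n_boot=cfg.n_boot,
                             seed=cfg.seed)
        for c, m, lo, hi, n in zip(curve.bin_center, curve.mean,
                                   curve.ci_lo, curve.ci_hi, curve.n_per_bin):
            tuning_rows.append({"side": side, "wing": wing, "bin_center": c,
                                "mean": m, "ci_lo": lo, "ci_hi": hi, "n": n})
    pd.DataFrame(tuning_rows).to_csv(cfg.out_dir / "tuning_curves.csv", index=False)

    maps = pixel_correlation_map(registered.gcamp,
                                 beh_frames["wba_left"].to_numpy(),
                                 beh_frames["wba_right"].to_numpy())
    tifffile.imwrite(cfg.out_dir / "pixel_corr_left.tiff",
                     maps.r_left.astype(np.float32))
    tifffile.imwrite(cfg.out_dir / "pixel_corr_right.tiff",
                     maps.r_right.astype(np.float32))

    summary = bilateral_summary(sides["left"], sides["right"],
                                beh_frames["wba_left"].to_numpy(),
                                beh_frames["wba_right"].to_numpy())
    summary.to_csv(cfg.out_dir / "bilateral_summary.csv", index=False)
    stages["bilateral"] = {f"{r.signal}~{r.wing}": r.r for r in summary.itertuples()}

    io.write_json_report(dataclasses.asdict(report), cfg.out_dir / "imaging_report.json")
    return report
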