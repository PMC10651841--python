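"""End-to-end simulation sweep: configurations, estimators, metrics, report.

A run draws ``n_configs`` virtual marker configurations per segment,
drives all of them with the *same* gait kinematics, injects the *same*
quadrant-wise STA profiles into every configuration (the study condition
that makes the SVD-LS CM offset configuration-independent), runs the
requested estimators, evaluates all reconstruction-offset metrics on the
middle gait cycle, and writes long-format and summary CSVs plus a manifest
with every seed used.

Randomness is fully deterministic: each consumer derives a child seed from
the master seed and a structured key, so identical configs + seeds give
byte-identical metric CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as mx
from .core import eigendecompose, inertia_tensor
from .frustum import SpacingRules, build_frustum, sample_marker_configuration
from .io import write_trc
from .pct import PctConfig, pct_pose
from .pctpt import PctPtConfig, pctpt_pose
from .simulate import (
    GaitParameters,
    SimulatedTrial,
    generate_gait_kinematics,
    load_sta_profiles,
    simulate_trial,
    synthesize_sta,
)
from .svdls import PoseSeries, svdls_pose

__all__ = ["SimulationConfig", "RunResult", "load_config", "run_simulation", "child_rng"]

DISTANCE_METRICS_CM = ("TRO", "ALRO", "AFOO")  # reported in cm; internal unit is m


def child_rng(master_seed: int, *key) -> np.random.Generator:
    """Deterministic child generator from a master seed and a structured key."""
    tokens = [int(master_seed) & 0x7FFFFFFF]
    tokens += [zlib.crc32(str(k).encode()) for k in key]
    return np.random.default_rng(np.random.SeedSequence(tokens))


@dataclass
class SimulationConfig:
    """Configuration of a full simulation run."""

    seed: int = 0
    n_configs: int = 100
    segments: tuple[str, ...] = ("thigh", "shank")
    estimators: tuple[str, ...] = ("pct", "pctpt", "svdls")
    sta_mode: str = "synthetic"           # "synthetic" | "csv"
    sta_csv: dict | None = None           # segment -> path when sta_mode == "csv"
    sta_amplitude: dict = field(default_factory=lambda: {"thigh": 0.012, "shank": 0.005})
    sta_harmonics: int = 3
    gait: GaitParameters = field(default_factory=GaitParameters)
    spacing: SpacingRules = field(default_factory=SpacingRules)
    frustum_overrides: dict = field(default_factory=dict)  # segment -> kwargs
    d_max: float = 0.01
    output_dir: str | None = None
    save_trajectories: bool = False

    def __post_init__(self) -> None:
        if self.n_configs < 1:
            raise ValueError("n_configs must be >= 1")
        self.segments = tuple(self.segments)
        self.estimators = tuple(self.estimators)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "gait" in data and isinstance(data["gait"], dict):
            data["gait"] = GaitParameters(**data["gait"])
        if "spacing" in data and isinstance(data["spacing"], dict):
            data["spacing"] = SpacingRules(**data["spacing"])
        return cls(**data)


def load_config(path: str | Path) -> SimulationConfig:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return SimulationConfig.from_dict(data or {})


@dataclass
class SegmentEstimate:
    """One estimator's reconstruction for one (segment, configuration)."""

    method: str
    poses: PoseSeries
    continuous: bool
    failure: str = ""


@dataclass
class RunResult:
    config: SimulationConfig
    long: pd.DataFrame
    summary: pd.DataFrame
    continuous_counts: dict
    manifest: dict
    knee_curves: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# estimator execution
# ---------------------------------------------------------------------------


def _run_estimator(method: str, trial: SimulatedTrial, cfg: SimulationConfig) -> SegmentEstimate:
    cal = trial.calibration_markers
    noisy = trial.noisy_markers
    if method == "svdls":
        poses = svdls_pose(cal, noisy)
        return SegmentEstimate("svdls", poses, True)
    if method == "pct":
        poses, mass = pct_pose(cal, noisy, PctConfig())
        return SegmentEstimate("pct", poses, bool(np.all(mass.valid)))
    if method == "pctpt":
        poses, mass, cm, diag = pctpt_pose(cal, noisy, PctPtConfig(d_max=cfg.d_max))
        return SegmentEstimate("pctpt", poses, diag.valid)
    raise ValueError(f"unknown estimator {method!r}")


def _reference_pose(trial: SimulatedTrial) -> tuple[np.ndarray, np.ndarray]:
    """Pose series mapping calibration-global coordinates to time-t truth."""
    k = trial.calibration_frame
    r_cal = trial.true_rotations[k]
    t_cal = trial.true_translations[k]
    r_ref = np.einsum("tij,kj->tik", trial.true_rotations, r_cal)  # R_t R_calᵀ
    t_ref = trial.true_translations - np.einsum("tij,j->ti", r_ref, t_cal)
    return r_ref, t_ref


def _evaluation_window(gait) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample indices of the evaluation cycle plus its stance mask."""
    hs = gait.heel_strikes
    if len(hs) < 2:
        raise ValueError("need at least one full gait cycle")
    c = (len(hs) - 1) // 2  # middle cycle
    start, end = int(hs[c]), int(hs[c + 1])
    toe = int(gait.toe_offs[c])
    _, stance, _ = mx.phase_partition(start, toe, end)
    idx = np.arange(start, end)
    percent = gait.normalized_time[idx]
    return idx, stance, percent


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------


def run_simulation(config: SimulationConfig) -> RunResult:
    """Execute the full simulation sweep and return (and optionally write)
    the metric tables."""
    gait = generate_gait_kinematics(config.gait)
    idx, stance, percent = _evaluation_window(gait)

    rows: list[dict] = []
    knee_rows: list[dict] = []
    failures: list[dict] = []
    continuous_counts: dict[str, dict[str, int]] = {}
    seeds_used: dict[str, dict] = {"sta": {}, "configs": {}}

    frusta = {
        seg: build_frustum(seg, **config.frustum_overrides.get(seg, {}))
        for seg in config.segments
    }

    # one STA profile set per segment, shared by every configuration
    sta = {}
    for seg in config.segments:
        if config.sta_mode == "csv":
            if not config.sta_csv or seg not in config.sta_csv:
                raise ValueError(f"sta_mode='csv' requires an sta_csv path for {seg!r}")
            sta[seg] = load_sta_profiles(config.sta_csv[seg], gait.normalized_time)
        else:
            profiles = []
            for q in range(4):
                rng = child_rng(config.seed, "sta", seg, q)
                profiles.append(
                    synthesize_sta(
                        q, seg, gait,
                        amplitude=config.sta_amplitude.get(seg),
                        harmonics=config.sta_harmonics,
                        rng=rng,
                    )
                )
            sta[seg] = profiles
            seeds_used["sta"][seg] = [f"({config.seed},'sta',{seg!r},{q})" for q in range(4)]

    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        if config.save_trajectories:
            (out_dir / "trials").mkdir(exist_ok=True)

    # estimate every (segment, configuration); keep frames for the knee angles
    frames: dict[tuple[str, int, str], list[mx.AnatomicalFrame]] = {}
    true_frames: dict[tuple[str, int], list[mx.AnatomicalFrame]] = {}

    for seg in config.segments:
        frustum = frusta[seg]
        continuous_counts[seg] = {m: 0 for m in config.estimators}
        for ci in range(config.n_configs):
            rng = child_rng(config.seed, "config", seg, ci)
            marker_config = sample_marker_configuration(frustum, config.spacing, rng)
            trial = simulate_trial(frustum, marker_config, gait, sta[seg])
            if out_dir and config.save_trajectories:
                write_trc(out_dir / "trials" / f"{seg}_{ci:03d}_true.trc", trial.true_markers)
                write_trc(out_dir / "trials" / f"{seg}_{ci:03d}_noisy.trc", trial.noisy_markers)

            # ground-truth reference quantities on the evaluation window
            r_ref, t_ref = _reference_pose(trial)
            cal = trial.calibration_markers
            cal_cm = cal.mean(axis=0)
            cal_eig = eigendecompose(inertia_tensor(cal - cal_cm))
            t_true = np.einsum("tij,j->ti", r_ref, cal_cm) + t_ref
            cal_landmarks = {
                name: pos[trial.calibration_frame]
                for name, pos in trial.true_landmarks.items()
            }
            tf_true = [
                mx.anatomical_frame(
                    {n: trial.true_landmarks[n][i] for n in trial.true_landmarks}, seg
                )
                for i in idx
            ]
            true_frames[(seg, ci)] = tf_true

            for method in config.estimators:
                try:
                    est = _run_estimator(method, trial, config)
                except Exception as exc:  # isolate per-configuration failures
                    failures.append(
                        {"segment": seg, "config": ci, "method": method, "reason": str(exc)}
                    )
                    continue
                if est.continuous:
                    continuous_counts[seg][method] += 1
                rot, trans = est.poses.rotations, est.poses.translations
                t_rec = np.einsum("tij,j->ti", rot, cal_cm) + trans
                rec_landmarks = mx.reconstruct_landmarks(cal_landmarks, rot, trans)
                tf_rec = [
                    mx.anatomical_frame({n: rec_landmarks[n][i] for n in rec_landmarks}, seg)
                    for i in idx
                ]
                frames[(seg, ci, method)] = tf_rec

                series = [mx.tro(t_true[idx], t_rec[idx])]
                for n in (1, 2, 3):
                    e_cal = cal_eig.eigenvectors[:, n - 1]
                    e_ref = np.einsum("tij,j->ti", r_ref[idx], e_cal)
                    e_rec = np.einsum("tij,j->ti", rot[idx], e_cal)
                    series.append(mx.ero(e_ref, e_rec, n))
                for name in trial.true_landmarks:
                    series.append(
                        mx.alro(trial.true_landmarks[name][idx], rec_landmarks[name][idx], name)
                    )
                series.append(mx.afoo(tf_true, tf_rec))

                for s in series:
                    scale = 100.0 if s.units == "m" else 1.0
                    units = "cm" if s.units == "m" else s.units
                    for p, v in zip(percent, s.values * scale):
                        rows.append(
                            {
                                "method": method,
                                "segment": seg,
                                "config": ci,
                                "metric": s.name,
                                "percent_cycle": float(p),
                                "value": float(v),
                                "units": units,
                                "continuous": est.continuous,
                            }
                        )

    # knee angles need both segments per configuration index
    if {"thigh", "shank"}.issubset(config.segments):
        for ci in range(config.n_configs):
            tt, ts = true_frames[("thigh", ci)], true_frames[("shank", ci)]
            true_angles = mx.knee_angle_series(tt, ts)
            for method in config.estimators:
                key_t, key_s = ("thigh", ci, method), ("shank", ci, method)
                if key_t not in frames or key_s not in frames:
                    continue
                kao_series, _, rec_angles = mx.kao(tt, ts, frames[key_t], frames[key_s])
                for s in kao_series:
                    for p, v in zip(percent, s.values):
                        rows.append(
                            {
                                "method": method,
                                "segment": "knee",
                                "config": ci,
                                "metric": s.name,
                                "percent_cycle": float(p),
                                "value": float(v),
                                "units": "deg",
                                "continuous": True,
                            }
                        )
                for k, angle in enumerate(("FE", "AA", "IE")):
                    for j, p in enumerate(percent):
                        knee_rows.append(
                            {
                                "method": method,
                                "config": ci,
                                "angle": angle,
                                "percent_cycle": float(p),
                                "true_deg": float(true_angles[j, k]),
                                "rec_deg": float(rec_angles[j, k]),
                            }
                        )

    long_df = pd.DataFrame(rows)
    knee_df = pd.DataFrame(knee_rows) if knee_rows else None
    summary_df = _summarize(long_df, stance, config)

    manifest = {
        "package": "clusterpose",
        "config": config.to_dict(),
        "seed_scheme": "SeedSequence([seed & 0x7fffffff, crc32(token) ...])",
        "seeds": seeds_used,
        "continuous_counts": continuous_counts,
        "failures": failures,
        "n_evaluation_samples": int(idx.size),
    }

    if out_dir:
        long_df.to_csv(out_dir / "metrics_long.csv", index=False)
        summary_df.to_csv(out_dir / "summary.csv", index=False)
        if knee_df is not None:
            knee_df.to_csv(out_dir / "knee_angles.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return RunResult(config, long_df, summary_df, continuous_counts, manifest, knee_df)


def _summarize(long_df: pd.DataFrame, stance: np.ndarray, config: SimulationConfig) -> pd.DataFrame:
    """Tables-style pooled statistics per (segment, method, metric, phase).

    PCT rows pool only configurations whose whole time series passed the
    continuity screen; other estimators pool all configurations.  Both the
    pooled std and the across-configuration envelope std are exported.
    """
    out = []
    if long_df.empty:
        return pd.DataFrame(out)
    n_samples = stance.shape[0]
    for (seg, method, metric), grp in long_df.groupby(["segment", "method", "metric"]):
        sub = grp[grp["continuous"]] if method == "pct" else grp
        configs = sorted(sub["config"].unique())
        if not configs:
            continue
        mat = np.full((len(configs), n_samples), np.nan)
        for row_i, ci in enumerate(configs):
            vals = sub[sub["config"] == ci].sort_values("percent_cycle")["value"].to_numpy()
            mat[row_i, : vals.size] = vals
        pooled = mx.summarize(mat, stance)
        spread = mx.config_spread(mat, stance)
        for phase in ("GC", "StP", "SwP"):
            out.append(
                {
                    "segment": seg,
                    "method": method,
                    "metric": metric,
                    "phase": phase,
                    "mean": pooled.mean[phase],
                    "std": pooled.std[phase],
                    "config_std": spread.std[phase],
                    "units": grp["units"].iloc[0],
                    "n_configs": len(configs),
                }
            )
    return pd.DataFrame(out)
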