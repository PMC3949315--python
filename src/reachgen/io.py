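"""Configuration and on-disk schemas.

CSV with mandatory headers (UTF-8, '.' decimal) for tabular data, JSON for
nested fit results, YAML for run configuration.  Every writer/reader pair
round-trips at full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult, GeneralizationDataset, MixtureSpec
from .kinematics import ArmModel, Trajectory

__all__ = [
    "RunConfig",
    "read_config",
    "write_trajectories",
    "read_trajectories",
    "write_dataset",
    "read_dataset",
    "write_fit_result",
    "read_fit_result",
    "write_prediction_summary",
    "write_prediction_series",
]

TRAJECTORY_COLUMNS = ["trial_id", "t", "x", "y", "vx", "vy", "fx", "fy"]
DATASET_COLUMNS = ["subject_id", "movement_id", "adaptation"]

_KNOWN_KEYS = {
    "experiment",
    "arm",
    "field",
    "protocol",
    "models",
    "seed",
    "out_dir",
    "n_subjects",
    "ground_truth",
}
_ARM_KEYS = {"link_lengths", "shoulder_position"}
_FIELD_KEYS = {"kind", "B", "train_posture", "workspace"}


@dataclass
class RunConfig:
    """Validated run configuration for the command-line pipeline."""

    experiment: str = "1"
    arm: ArmModel = dc_field(default_factory=ArmModel)
    field_kind: str = "extrinsic"
    B: np.ndarray | None = None
    protocol: dict = dc_field(default_factory=dict)
    models: list[str] = dc_field(default_factory=lambda: ["J", "C", "O"])
    seed: int = 0
    n_subjects: int = 9
    out_dir: Path = Path("reachgen_out")
    ground_truth: dict = dc_field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw: dict = {}
        if "experiment" in raw:
            kw["experiment"] = str(raw["experiment"])
        if "arm" in raw:
            arm_raw = dict(raw["arm"])
            unknown = set(arm_raw) - _ARM_KEYS
            if unknown:
                raise ValueError(f"unknown arm keys: {sorted(unknown)}")
            if "link_lengths" not in arm_raw:
                raise ValueError("arm config requires link_lengths")
            kw["arm"] = ArmModel(
                link_lengths=tuple(arm_raw["link_lengths"]),
                shoulder_position=tuple(arm_raw.get("shoulder_position", (0.0, 0.0))),
            )
        if "field" in raw:
            f = dict(raw["field"])
            unknown = set(f) - _FIELD_KEYS
            if unknown:
                raise ValueError(f"unknown field keys: {sorted(unknown)}")
            kw["field_kind"] = f.get("kind", "extrinsic")
            if "B" in f:
                kw["B"] = np.asarray(f["B"], float)
        for key in ("protocol", "models", "seed", "n_subjects", "ground_truth"):
            if key in raw:
                kw[key] = raw[key]
        if "out_dir" in raw:
            kw["out_dir"] = Path(raw["out_dir"])
        return cls(**kw)


def read_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    return RunConfig.from_dict(raw)


# ---------------------------------------------------------------------------
# trajectories


def write_trajectories(path: str | Path, trajectories: list[Trajectory]) -> None:
    frames = []
    for k, traj in enumerate(trajectories):
        tid = traj.trial_id if traj.trial_id is not None else k
        force = traj.force if traj.force is not None else np.full_like(traj.pos, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": tid,
                    "t": traj.t,
                    "x": traj.pos[:, 0],
                    "y": traj.pos[:, 1],
                    "vx": traj.vel[:, 0],
                    "vy": traj.vel[:, 1],
                    "fx": force[:, 0],
                    "fy": force[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path: str | Path) -> list[Trajectory]:
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV {path} missing columns {sorted(missing)}")
    out = []
    for tid, grp in df.groupby("trial_id", sort=True):
        force = grp[["fx", "fy"]].to_numpy()
        out.append(
            Trajectory(
                t=grp["t"].to_numpy(),
                pos=grp[["x", "y"]].to_numpy(),
                vel=grp[["vx", "vy"]].to_numpy(),
                force=None if np.all(np.isnan(force)) else force,
                trial_id=int(tid),
            )
        )
    return out


# ---------------------------------------------------------------------------
# generalization datasets


def write_dataset(path: str | Path, dataset: GeneralizationDataset) -> None:
    long = dataset.values.stack().rename("adaptation").reset_index()
    long.columns = DATASET_COLUMNS
    long.to_csv(path, index=False)


def read_dataset(
    path: str | Path,
    predictions: pd.DataFrame,
    distances: pd.DataFrame,
) -> GeneralizationDataset:
    df = pd.read_csv(path)
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset CSV {path} missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"dataset CSV {path} is empty")
    wide = df.pivot(index="subject_id", columns="movement_id", values="adaptation")
    if wide.isna().any().any():
        bad = int(df.index[df.adaptation.isna()][0]) if df.adaptation.isna().any() else "?"
        raise ValueError(f"dataset CSV {path} has missing cells (e.g. row {bad})")
    return GeneralizationDataset(values=wide, predictions=predictions, distances=distances)


# ---------------------------------------------------------------------------
# fit results


def write_fit_result(path: str | Path, result: FitResult) -> None:
    payload = result.to_dict()
    payload = {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
               for k, v in payload.items()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def read_fit_result(path: str | Path) -> FitResult:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    spec = MixtureSpec(tuple(d["components"]), bool(d["decay"]))
    weights = {c: d[f"k_{c.lower()}"] for c in spec.components}
    decays = (
        {c: d[f"d_{c.lower()}"] for c in spec.components} if spec.decay else {}
    )
    return FitResult(
        spec=spec,
        weights=weights,
        decays=decays,
        mse=d["mse"],
        n=d["n"],
        converged=d.get("converged", True),
        seed=d.get("seed"),
        variance_explained=(
            np.asarray(d["variance_explained"]) if "variance_explained" in d else None
        ),
    )


# ---------------------------------------------------------------------------
# predictions


def write_prediction_summary(path: str | Path, normalized: pd.DataFrame) -> None:
    long = normalized.stack().rename("normalized_adaptation").reset_index()
    long.columns = ["movement_id", "model", "normalized_adaptation"]
    long.to_csv(path, index=False)


def write_prediction_series(path: str | Path, series: dict, dt: float = 0.001,
                            movements=None) -> None:
    frames = []
    normals = {m.movement_id: m.channel_normal for m in movements} if movements else {}
    for (model, mid), arr in series.items():
        arr = np.asarray(arr)
        f_perp = arr @ normals[mid] if mid in normals else np.linalg.norm(arr, axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "movement_id": mid,
                    "model": model,
                    "t": dt * np.arange(len(arr)),
                    "f_perp": f_perp,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
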