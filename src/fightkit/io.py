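"""Readers and writers for trajectories, ethograms and run configs.

Trajectory CSV schema: columns ``frame, fish_id, x_cm, y_cm`` with a
mandatory header, comma separated, '.' decimal, UTF-8, exactly two fish
ids.  Trajectory HDF5 layout: datasets ``/fish1/xy`` and ``/fish2/xy``
of shape (T, 2) plus root attributes ``frame_rate`` and the arena
geometry.  Ethogram CSV schema: ``frame, fish_id, attack_score,
attack_label, role`` ordered by (frame, fish_id).
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import ArenaConfig, Ethogram, FightRecording, ROLE_CODES, ROLE_NAMES
from .errors import FormatError, GapError

_TRAJ_COLUMNS = ("frame", "fish_id", "x_cm", "y_cm")

_ARENA_ATTRS = ("width", "height", "frame_rate", "wall_margin",
                "corner_margin", "body_length")


def _positions_from_long(df: pd.DataFrame) -> np.ndarray:
    """(T, 2, 2) array from a validated long-format trajectory table."""
    fish_ids = sorted(df["fish_id"].unique())
    if len(fish_ids) != 2:
        raise FormatError(
            f"expected exactly 2 fish ids, found {len(fish_ids)}")
    frames = np.sort(df["frame"].unique())
    full = np.arange(frames[0], frames[-1] + 1)
    missing = np.setdiff1d(full, frames)
    if missing.size:
        raise GapError(missing.tolist())
    n = full.size
    pos = np.full((n, 2, 2), np.nan)
    for k, fid in enumerate(fish_ids):
        sub = df[df["fish_id"] == fid].sort_values("frame")
        if sub.shape[0] != n or sub["frame"].duplicated().any():
            present = sub["frame"].to_numpy()
            raise GapError(np.setdiff1d(full, present).tolist())
        pos[:, k, 0] = sub["x_cm"].to_numpy()
        pos[:, k, 1] = sub["y_cm"].to_numpy()
    return pos


def read_trajectories(path, arena: ArenaConfig | None = None,
                      smooth_sigma: float = 0.0) -> FightRecording:
    """Read a trajectory CSV or HDF5 file into a validated recording.

    For CSV input ``arena`` is required; HDF5 files carry the arena in
    their attributes (an explicit ``arena`` overrides it).
    """
    path = os.fspath(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            if arena is None:
                try:
                    arena = ArenaConfig(
                        **{k: float(f.attrs[k]) for k in _ARENA_ATTRS})
                except KeyError as e:
                    raise FormatError(f"missing arena attribute: {e}")
            try:
                xy1 = np.asarray(f["fish1/xy"])
                xy2 = np.asarray(f["fish2/xy"])
            except KeyError as e:
                raise FormatError(f"missing dataset: {e}")
        if xy1.shape != xy2.shape:
            raise FormatError("fish datasets have different lengths")
        pos = np.stack([xy1, xy2], axis=1)
        return FightRecording(pos, arena, smooth_sigma)
    if arena is None:
        raise ValueError("arena is required for CSV input")
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise FormatError(str(e))
    missing_cols = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"missing columns: {missing_cols}")
    pos = _positions_from_long(df)
    return FightRecording(pos, arena, smooth_sigma)


def write_trajectories(rec: FightRecording, path) -> str:
    """Write a recording as CSV (long format) or HDF5, by extension."""
    path = os.fspath(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.create_dataset("fish1/xy", data=rec.positions[:, 0])
            f.create_dataset("fish2/xy", data=rec.positions[:, 1])
            for k in _ARENA_ATTRS:
                f.attrs[k] = getattr(rec.arena, k)
        return path
    n = rec.n_frames
    frames = np.repeat(np.arange(n), 2)
    fish = np.tile([1, 2], n)
    flat = rec.positions.reshape(n * 2, 2)
    pd.DataFrame({"frame": frames, "fish_id": fish,
                  "x_cm": flat[:, 0], "y_cm": flat[:, 1]}).to_csv(
        path, index=False)
    return path


def write_ethogram(eth: Ethogram, path) -> str:
    """Write an ethogram CSV ordered by (frame, fish_id)."""
    path = os.fspath(path)
    n = eth.n_frames
    frames = np.repeat(np.arange(n), 2)
    fish = np.tile([1, 2], n)
    scores = eth.scores.reshape(n * 2)
    labels = eth.labels.reshape(n * 2).astype(int)
    role = np.repeat([ROLE_NAMES[int(r)] for r in eth.role], 2)
    pd.DataFrame({"frame": frames, "fish_id": fish,
                  "attack_score": np.round(scores, 6),
                  "attack_label": labels, "role": role}).to_csv(
        path, index=False)
    return path


def read_ethogram(path, threshold: float = 0.5,
                  frame_rate: float = 20.0) -> Ethogram:
    df = pd.read_csv(path)
    required = ("frame", "fish_id", "attack_score", "attack_label", "role")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    if df.empty:
        return Ethogram(np.zeros((0, 2)), np.zeros((0, 2), bool),
                        np.zeros(0, np.int8), threshold, frame_rate)
    df = df.sort_values(["frame", "fish_id"])
    n = df["frame"].nunique()
    scores = df["attack_score"].to_numpy().reshape(n, 2)
    labels = df["attack_label"].to_numpy().astype(bool).reshape(n, 2)
    role = np.array([ROLE_CODES[r] for r in df["role"].to_numpy()[::2]],
                    dtype=np.int8)
    return Ethogram(scores, labels, role, threshold, frame_rate)


def load_config(path) -> dict:
    """Load a YAML run config into a plain dict."""
    with open(path, "r", encoding="utf-8") as f:
        cfg = yaml.safe_load(f)
    return cfg or {}


def arena_from_config(cfg: dict) -> ArenaConfig:
    """Build an ArenaConfig from the ``arena`` section of a run config."""
    return ArenaConfig(**cfg.get("arena", {}))
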