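"""File formats exchanged between pipeline stages.

* Transform CSV: one row per frame — ``frame`` then the 16 row-major entries
  of the 4x4 homogeneous matrix (``m00 ... m33``), header required.  This is
  the interchange format for every tracked pose sequence.
* Bead observation CSV: ``frame,view,bead_label,u,v,visible`` with detector
  coordinates in pixels relative to the principal point.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .transforms import RigidTransform

TRANSFORM_HEADER = ["frame"] + [f"m{i}{j}" for i in range(4) for j in range(4)]
OBS_HEADER = ["frame", "view", "bead_label", "u", "v", "visible"]

# %.17g round-trips IEEE doubles exactly, which keeps stage outputs
# byte-reproducible under a fixed seed.
_FLOAT_FMT = "%.17g"


def write_transform_csv(path, transforms, frames=None) -> None:
    """Write a pose sequence; ``frames`` defaults to 0..N-1."""
    transforms = list(transforms)
    if frames is None:
        frames = range(len(transforms))
    path = Path(path)
    with path.open("w") as fh:
        fh.write(",".join(TRANSFORM_HEADER) + "\n")
        for f, t in zip(frames, transforms):
            vals = t.as_matrix().reshape(16)
            fh.write(str(int(f)) + "," + ",".join(_FLOAT_FMT % v for v in vals) + "\n")


def read_transform_csv(path) -> tuple[list[int], list[RigidTransform]]:
    """Read a pose sequence CSV; returns (frame indices, transforms)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRANSFORM_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing transform CSV columns {missing}")
    frames = df["frame"].astype(int).tolist()
    mats = df[TRANSFORM_HEADER[1:]].to_numpy(float).reshape(-1, 4, 4)
    return frames, [RigidTransform.from_matrix(m) for m in mats]


def write_observation_csv(path, rows) -> None:
    """``rows``: iterable of (frame, view, bead_label, u, v, visible)."""
    with Path(path).open("w") as fh:
        fh.write(",".join(OBS_HEADER) + "\n")
        for frame, view, label, u, v, visible in rows:
            if visible:
                fh.write(
                    f"{int(frame)},{int(view)},{label},"
                    + (_FLOAT_FMT % u) + "," + (_FLOAT_FMT % v) + ",1\n"
                )
            else:
                fh.write(f"{int(frame)},{int(view)},{label},,,0\n")


def read_observation_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"bead_label": str}, float_precision="round_trip")
    missing = [c for c in OBS_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing observation CSV columns {missing}")
    df["visible"] = df["visible"].astype(bool)
    return df


def stack_matrices(transforms) -> np.ndarray:
    """(N, 4, 4) array view of a transform sequence (helper for vector ops)."""
    return np.stack([t.as_matrix() for t in transforms])
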