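"""Clip serialization.

Clips are written as JSON with a header (task, truth, fps, size,
eccentricity, noise_count, bbox, meta) and per-frame arrays of
``[x, y, diameter, provenance]`` records; positions are serialized at
full double precision, so a write/read round trip is bit exact.  A long
CSV export (frame, t, dot_id, x, y, diameter, provenance) is provided
for analysis tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clip import StimulusClip


class ClipFormatError(ValueError):
    """Raised when a clip file is malformed; names the offending record."""


def write_clip(clip: StimulusClip, path) -> None:
    frames = []
    for i in range(clip.n_frames):
        frames.append(
            [
                [float(x), float(y), float(d), str(p)]
                for (x, y), d, p in zip(clip.positions[i], clip.diameters, clip.provenance)
            ]
        )
    doc = {
        "task": clip.task,
        "truth": clip.truth,
        "fps": clip.fps,
        "size": clip.size,
        "eccentricity": clip.eccentricity,
        "noise_count": clip.noise_count,
        "bbox": list(clip.bbox),
        "meta": clip.meta,
        "frames": frames,
    }
    Path(path).write_text(json.dumps(doc))


def read_clip(path) -> StimulusClip:
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ClipFormatError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("task", "truth", "fps", "size", "eccentricity", "noise_count", "bbox", "frames"):
        if key not in doc:
            raise ClipFormatError(f"{path}: missing header field {key!r}")
    frames = doc["frames"]
    if not frames:
        raise ClipFormatError(f"{path}: clip has no frames")
    n_dots = len(frames[0])
    positions = np.empty((len(frames), n_dots, 2))
    diameters = np.empty(n_dots)
    provenance = np.empty(n_dots, dtype=object)
    for i, frame in enumerate(frames):
        if len(frame) != n_dots:
            raise ClipFormatError(
                f"{path}: frame {i} has {len(frame)} dot records, expected {n_dots}"
            )
        for k, rec in enumerate(frame):
            if len(rec) != 4:
                raise ClipFormatError(f"{path}: frame {i} dot {k}: malformed record {rec!r}")
            x, y, d, p = rec
            positions[i, k] = (x, y)
            if i == 0:
                diameters[k] = d
                provenance[k] = p
            elif d != diameters[k] or p != provenance[k]:
                raise ClipFormatError(
                    f"{path}: frame {i} dot {k}: diameter/provenance differs from frame 0"
                )
    try:
        return StimulusClip(
            task=doc["task"],
            truth=doc["truth"],
            fps=doc["fps"],
            size=doc["size"],
            eccentricity=doc["eccentricity"],
            bbox=tuple(doc["bbox"]),
            positions=positions,
            diameters=diameters,
            provenance=provenance,
            noise_count=doc["noise_count"],
            meta=doc.get("meta", {}),
        )
    except ValueError as exc:
        raise ClipFormatError(f"{path}: inconsistent clip header ({exc})") from exc


def clip_to_dataframe(clip: StimulusClip) -> pd.DataFrame:
    """Long-format view: one row per (frame, dot)."""
    n_f, n_d = clip.n_frames, clip.n_dots
    frame_idx = np.repeat(np.arange(n_f), n_d)
    return pd.DataFrame(
        {
            "frame": frame_idx,
            "t": frame_idx / clip.fps,
            "dot_id": np.tile(np.arange(n_d), n_f),
            "x": clip.positions[:, :, 0].ravel(),
            "y": clip.positions[:, :, 1].ravel(),
            "diameter": np.tile(clip.diameters, n_f),
            "provenance": np.tile(clip.provenance, n_f),
        }
    )


def write_clip_csv(clip: StimulusClip, path) -> None:
    clip_to_dataframe(clip).to_csv(path, index=False)
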