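"""File formats: multi-page 16-bit TIFF stacks, CSV seed/trace tables.

Stacks are written as two TIFFs (acquisition frames and background
frames) plus a YAML protocol descriptor; seeds and traces are tidy CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .protocol import StimulusProtocol
from .stackproc import ImageStack, NeuronTrack, RoiSeed


def write_stack(stack: ImageStack, directory: Path, name: str) -> None:
    """Write frames, background frames, and the protocol descriptor."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / f"{name}.tif", np.asarray(stack.frames))
    tifffile.imwrite(
        directory / f"{name}_background.tif", np.asarray(stack.background_frames)
    )
    proto = {
        "t_buffer_pre": stack.protocol.t_buffer_pre,
        "t_odor": stack.protocol.t_odor,
        "t_buffer_post": stack.protocol.t_buffer_post,
        "frame_rate": stack.protocol.frame_rate,
    }
    (directory / f"{name}_protocol.yaml").write_text(yaml.safe_dump(proto))


def read_stack(directory: Path, name: str) -> ImageStack:
    directory = Path(directory)
    frames = tifffile.imread(directory / f"{name}.tif")
    background = tifffile.imread(directory / f"{name}_background.tif")
    proto = yaml.safe_load((directory / f"{name}_protocol.yaml").read_text())
    return ImageStack(frames, background, StimulusProtocol(**proto))


def write_seeds(seeds: list[RoiSeed], path: Path) -> None:
    pd.DataFrame(
        [
            {
                "animal_id": s.animal_id,
                "row_min": s.row_min,
                "row_max": s.row_max,
                "col_min": s.col_min,
                "col_max": s.col_max,
                "seed_row": s.seed_row,
                "seed_col": s.seed_col,
                "reference_frame": s.reference_frame,
            }
            for s in seeds
        ]
    ).to_csv(path, index=False)


def read_seeds(path: Path) -> list[RoiSeed]:
    df = pd.read_csv(path)
    return [RoiSeed(**{k: (row[k] if k == "animal_id" else int(row[k])) for k in df.columns}) for _, row in df.iterrows()]


def write_traces(tracks: list[NeuronTrack], frame_rate: float, path: Path) -> None:
    """Tidy per-frame trace table: animal_id, frame, time_s, F, dff, viable."""
    parts = []
    for t in tracks:
        T = t.F.size
        parts.append(
            pd.DataFrame(
                {
                    "animal_id": t.animal_id,
                    "frame": np.arange(T),
                    "time_s": np.arange(T) / frame_rate,
                    "row": t.positions[:, 0],
                    "col": t.positions[:, 1],
                    "F": t.F,
                    "dff": t.dff if t.dff is not None else np.nan,
                    "viable": t.viable,
                }
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)
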