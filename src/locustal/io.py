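"""Reading and writing the pipeline's on-disk formats.

Movies travel as multi-page TIFF (one file per stimulus, one page per frame)
with a JSON sidecar ``{stimulus, onset_frame, frame_rate_hz}``; trajectories
as CSV (animal_id, frame, x_px, y_px); label maps as 16-bit TIFF; tables as
CSV; reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .synthetic import CalciumMovie

__all__ = [
    "write_movie",
    "read_movie",
    "write_label_map",
    "read_label_map",
    "write_json",
    "read_json",
]


def write_movie(movie: CalciumMovie, tiff_path, sidecar_path=None) -> None:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, movie.stack.astype(np.float32))
    sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "stimulus": movie.stimulus,
        "onset_frame": int(movie.onset_frame),
        "frame_rate_hz": float(movie.frame_rate),
    }, indent=2))


def read_movie(tiff_path, sidecar_path=None) -> CalciumMovie:
    tiff_path = Path(tiff_path)
    stack = np.asarray(tifffile.imread(tiff_path), dtype=float)
    sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    return CalciumMovie(stack, meta["stimulus"], int(meta["onset_frame"]),
                        float(meta["frame_rate_hz"]))


def write_label_map(labels: np.ndarray, path) -> None:
    if labels.max() >= 2 ** 16:
        raise ValueError("too many granules for a 16-bit label map")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_label_map(path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=np.int32)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder))


def read_json(path):
    return json.loads(Path(path).read_text())
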