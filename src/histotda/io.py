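"""Plain-text serialization of the pipeline's artefacts.

Persistence diagrams travel as CSV (``dim,birth,death,essential``, one row
per point); ranked-vector matrices as CSV with image id and label columns;
stain matrices and colour statistics as YAML; intensity surfaces as CSV
grids.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .features import IntensityDiagram
from .persistence import PersistenceDiagram
from .stain import ColorStats, StainMatrix

__all__ = [
    "write_diagram", "read_diagram",
    "write_ranked_vectors", "read_ranked_vectors",
    "write_stain_matrix", "read_stain_matrix",
    "write_color_stats", "read_color_stats",
    "write_intensity", "read_intensity",
    "write_image", "read_image",
    "write_manifest",
]


def write_diagram(diagram: PersistenceDiagram, path) -> None:
    pd.DataFrame({
        "dim": diagram.dims,
        "birth": diagram.births,
        "death": diagram.deaths,
        "essential": diagram.essential.astype(int),
    }).to_csv(path, index=False, float_format="%.17g")


def read_diagram(path) -> PersistenceDiagram:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"dim", "birth", "death", "essential"}
    if not required.issubset(df.columns):
        raise ValueError(f"diagram CSV must have columns {sorted(required)}")
    return PersistenceDiagram(df["dim"].to_numpy(), df["birth"].to_numpy(),
                              df["death"].to_numpy(),
                              df["essential"].to_numpy().astype(bool))


def write_ranked_vectors(matrix: np.ndarray, image_ids, labels, path) -> None:
    df = pd.DataFrame(matrix)
    df.columns = [f"f{i}" for i in range(matrix.shape[1])]
    df.insert(0, "label", list(labels))
    df.insert(0, "image_id", list(image_ids))
    df.to_csv(path, index=False)


def read_ranked_vectors(path) -> tuple[np.ndarray, list, list]:
    df = pd.read_csv(path)
    return (df.drop(columns=["image_id", "label"]).to_numpy(float),
            df["image_id"].tolist(), df["label"].tolist())


def write_stain_matrix(m: StainMatrix, path) -> None:
    Path(path).write_text(yaml.safe_dump({
        "hematoxylin": [float(v) for v in m.hematoxylin],
        "eosin": [float(v) for v in m.eosin],
    }))


def read_stain_matrix(path) -> StainMatrix:
    data = yaml.safe_load(Path(path).read_text())
    return StainMatrix(np.array([data["hematoxylin"], data["eosin"]]))


def write_color_stats(stats: ColorStats, path) -> None:
    Path(path).write_text(yaml.safe_dump({
        "space": stats.space,
        "means": [float(v) for v in stats.means],
        "sds": [float(v) for v in stats.sds],
    }))


def read_color_stats(path) -> ColorStats:
    data = yaml.safe_load(Path(path).read_text())
    return ColorStats(tuple(data["means"]), tuple(data["sds"]), data["space"])


def write_intensity(surface: IntensityDiagram, path) -> None:
    header = (f"# dim={surface.dim} sigma_smooth={surface.sigma_smooth} "
              f"x0={surface.xs[0]} x1={surface.xs[-1]}")
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, surface.values, delimiter=",")


def read_intensity(path) -> IntensityDiagram:
    with open(path) as fh:
        header = fh.readline().lstrip("#").split()
        meta = dict(kv.split("=") for kv in header)
        values = np.loadtxt(fh, delimiter=",")
    res = values.shape[0]
    xs = np.linspace(float(meta["x0"]), float(meta["x1"]), res)
    return IntensityDiagram(values, xs, xs.copy(), float(meta["sigma_smooth"]),
                            int(meta["dim"]))


def write_image(image: np.ndarray, path) -> None:
    """Write a [0,1] grayscale or uint8 RGB array as PNG/TIFF."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def read_image(path, gray: bool = False) -> np.ndarray:
    img = Image.open(path)
    if gray:
        return np.asarray(img.convert("L"), dtype=float) / 255.0
    return np.asarray(img.convert("RGB"))


def write_manifest(rows: list[dict], path) -> None:
    """Dataset manifest: filename, label, pattern, seed per image."""
    pd.DataFrame(rows, columns=["filename", "label", "pattern", "seed"]).to_csv(
        path, index=False)
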