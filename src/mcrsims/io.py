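"""File formats: peak lists, sample cubes, fitted models, score-image export.

Cubes are stored as delimited text (height*width rows x channels columns,
row-major) next to a JSON sidecar carrying the sample id, grid shape,
physical field size, polarity and the peak-list file.  Scores are exported
both losslessly (delimited text) and as 16-bit grayscale images min–max
scaled per component across ALL samples jointly, so relative intensities
between samples stay comparable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConsolidatedMatrix, MCRModel, PeakList, SampleCube, refold_scores

__all__ = [
    "save_peaklist",
    "load_peaklist",
    "save_cube",
    "load_cube",
    "load_dataset",
    "save_model",
    "load_model",
    "export_score_images",
    "export_loadings",
]


def save_peaklist(peaklist: PeakList, path) -> None:
    """CSV with header ``mz,label``, one row per channel, in channel order."""
    pd.DataFrame({"mz": peaklist.mz, "label": list(peaklist.labels)}).to_csv(
        path, index=False, float_format="%.17g"
    )


def load_peaklist(path, polarity: str = "positive") -> PeakList:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != ["mz", "label"]:
        raise ValueError(f"{path}: expected columns 'mz,label', got {list(df.columns)}")
    return PeakList(
        mz=df["mz"].to_numpy(float),
        labels=tuple(df["label"].astype(str)),
        polarity=polarity,
    )


def save_cube(cube: SampleCube, directory, peaklist_file: str = "peaklist.csv",
              polarity: str = "positive") -> Path:
    """Write ``<id>.cube.csv`` plus a ``<id>.json`` sidecar; returns the sidecar path."""
    directory = Path(directory)
    array_name = f"{cube.sample_id}.cube.csv"
    arr = cube.unfold()
    if np.allclose(arr, np.round(arr)):
        fmt = "%d"
        arr = np.round(arr).astype(np.int64)
    else:
        fmt = "%.17g"
    np.savetxt(directory / array_name, arr, delimiter=",", fmt=fmt)
    sidecar = {
        "sample_id": cube.sample_id,
        "height": cube.height,
        "width": cube.width,
        "field_size_um": list(cube.field_size_um),
        "polarity": polarity,
        "peaklist_file": peaklist_file,
        "array_file": array_name,
    }
    out = directory / f"{cube.sample_id}.json"
    out.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return out


def load_cube(sidecar_path) -> SampleCube:
    sidecar_path = Path(sidecar_path)
    try:
        meta = json.loads(sidecar_path.read_text())
        arr = np.loadtxt(
            sidecar_path.parent / meta.get("array_file", f"{meta['sample_id']}.cube.csv"),
            delimiter=",", dtype=float, ndmin=2,
        )
    except OSError as exc:
        raise OSError(f"failed loading cube from {sidecar_path}: {exc}") from exc
    h, w = int(meta["height"]), int(meta["width"])
    if arr.shape[0] != h * w:
        raise ValueError(
            f"{sidecar_path}: array has {arr.shape[0]} rows, sidecar promises {h}x{w}"
        )
    return SampleCube(
        sample_id=str(meta["sample_id"]),
        intensities=arr.reshape(h, w, arr.shape[1]),
        field_size_um=tuple(meta.get("field_size_um", (500.0, 500.0))),
    )


def load_dataset(directory) -> tuple[list[SampleCube], PeakList]:
    """Load every ``*.json`` cube sidecar in a directory plus its peak list.

    Cubes are ordered by sidecar filename so runs are reproducible.
    """
    directory = Path(directory)
    sidecars = sorted(
        p for p in directory.glob("*.json")
        if p.name not in ("phantom_spec.json", "run_meta.json", "model.json", "overfit.json")
    )
    if not sidecars:
        raise FileNotFoundError(f"no cube sidecars (*.json) found in {directory}")
    cubes = [load_cube(p) for p in sidecars]
    pl_files = {json.loads(p.read_text()).get("peaklist_file", "peaklist.csv") for p in sidecars}
    if len(pl_files) != 1:
        raise ValueError(f"cubes reference multiple peak lists: {sorted(pl_files)}")
    polarity = {json.loads(p.read_text()).get("polarity", "positive") for p in sidecars}
    peaklist = load_peaklist(directory / pl_files.pop(), polarity=polarity.pop())
    return cubes, peaklist


def save_model(model: MCRModel, directory, peaklist: PeakList | None = None) -> Path:
    """Serialize a fitted model: loadings CSV, scores binary array, JSON metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    export_loadings(model, peaklist, directory / "loadings.csv")
    np.save(directory / "scores.npy", model.scores)
    meta = {
        "k": model.k,
        "seed": model.seed,
        "n_iter": model.n_iter,
        "lof_percent": model.lof_percent,
        "converged": model.converged,
        "degenerate": model.degenerate,
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return directory


def load_model(directory) -> MCRModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    # round_trip parsing: %.17g text must reproduce the float64 bits exactly
    loadings = pd.read_csv(directory / "loadings.csv", index_col=0,
                           float_precision="round_trip").to_numpy(float)
    scores = np.load(directory / "scores.npy")
    return MCRModel(
        k=int(meta["k"]),
        scores=scores,
        loadings=loadings,
        lof_percent=float(meta["lof_percent"]),
        n_iter=int(meta["n_iter"]),
        converged=bool(meta["converged"]),
        seed=int(meta["seed"]),
        degenerate=bool(meta.get("degenerate", False)),
    )


def export_loadings(model: MCRModel, peaklist: PeakList | None, path) -> None:
    """Loadings CSV: one row per component, columns = peak labels (or ch###)."""
    cols = list(peaklist.labels) if peaklist is not None else [
        f"ch{i:03d}" for i in range(model.channels)
    ]
    df = pd.DataFrame(model.loadings, columns=cols)
    df.index = [f"component_{j + 1}" for j in range(model.k)]
    df.to_csv(path, float_format="%.17g")


def export_score_images(model: MCRModel, matrix: ConsolidatedMatrix, directory) -> list[Path]:
    """Per sample x component 16-bit grayscale PNGs plus lossless score text.

    Each component is min–max scaled jointly across all samples, so a pixel
    that is twice as bright in one sample as in another stays so in the
    images.
    """
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    images = refold_scores(model, matrix)
    written: list[Path] = []
    for j in range(model.k):
        col = model.scores[:, j]
        lo, hi = float(col.min()), float(col.max())
        span = hi - lo if hi > lo else 1.0
        for sid in matrix.sample_ids:
            img = images[sid][j]
            scaled = np.round((img - lo) / span * 65535.0).astype(np.uint16)
            out = directory / f"component_{j + 1:02d}_{sid}.png"
            iio.imwrite(out, scaled)
            written.append(out)
    np.savetxt(directory / "scores_raw.csv", model.scores, delimiter=",", fmt="%.17g")
    return written
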