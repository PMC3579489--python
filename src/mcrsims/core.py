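"""Domain containers for multi-sample hyperspectral image analysis.

A ToF-SIMS acquisition yields, per sample, a hyperspectral cube: a pixel
grid where every pixel carries a vector of peak-integrated ion intensities
(one channel per entry of a peak list).  For joint multivariate curve
resolution the cubes are *consolidated*: each cube is unfolded to a
(pixels x channels) block and the blocks are row-stacked into a single
matrix D, with a row map remembering which (sample, row, col) every matrix
row came from.  The bilinear MCR model D ~= C @ S + E then factorizes D
into non-negative concentration profiles C (scores) and pure-component
spectra S (loadings).

Intensities are carried through unchanged — no scaling, centring or
normalization is applied at consolidation.  Pixel ordering is fixed:
0-based, row-major, origin top-left, cubes in input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PeakList",
    "SampleCube",
    "ConsolidatedMatrix",
    "MCRModel",
    "AreaEquivalent",
    "consolidate",
    "refold_scores",
    "unfold_scores",
    "area_equivalent",
]


@dataclass(frozen=True)
class PeakList:
    """Ordered m/z channel axis: one (m/z centre, label) per intensity channel.

    Parameters
    ----------
    mz : array of float
        Peak centres in u; strictly increasing and positive.
    labels : tuple of str
        Ion labels such as ``"C2H5O+"``; unique and non-empty.
    polarity : {"positive", "negative"}
        Secondary-ion polarity of the acquisition the list belongs to.
    """

    mz: np.ndarray
    labels: tuple[str, ...]
    polarity: str = "positive"

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        object.__setattr__(self, "mz", mz)
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if mz.ndim != 1 or mz.size == 0:
            raise ValueError("peak list must be a non-empty 1-D m/z array")
        if not np.all(mz > 0):
            raise ValueError("all m/z centres must be positive")
        if not np.all(np.diff(mz) > 0):
            raise ValueError("m/z centres must be strictly increasing")
        if len(labels) != mz.size:
            raise ValueError("labels and m/z centres must have equal length")
        if any(not lab for lab in labels):
            raise ValueError("peak labels must be non-empty")
        if len(set(labels)) != len(labels):
            raise ValueError("peak labels must be unique")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class SampleCube:
    """One sample's hyperspectral image: (height, width, channels) intensities.

    ``field_size_um`` is the physical (width, height) of the rastered field
    in micrometres.  Intensities must be non-negative; negative values are
    rejected, never clipped.
    """

    sample_id: str
    intensities: np.ndarray
    field_size_um: tuple[float, float] = (500.0, 500.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "field_size_um", (float(self.field_size_um[0]), float(self.field_size_um[1])))
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if arr.ndim != 3:
            raise ValueError(f"cube {self.sample_id!r}: intensities must be 3-D (h, w, channels)")
        if min(arr.shape) < 1:
            raise ValueError(f"cube {self.sample_id!r}: all dimensions must be >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"cube {self.sample_id!r}: non-finite intensities")
        if np.any(arr < 0):
            raise ValueError(f"cube {self.sample_id!r}: negative intensities are not allowed")
        if self.field_size_um[0] <= 0 or self.field_size_um[1] <= 0:
            raise ValueError(f"cube {self.sample_id!r}: field size must be positive")

    @property
    def height(self) -> int:
        return self.intensities.shape[0]

    @property
    def width(self) -> int:
        return self.intensities.shape[1]

    @property
    def channels(self) -> int:
        return self.intensities.shape[2]

    def unfold(self) -> np.ndarray:
        """Row-major (height*width, channels) view of the cube."""
        return self.intensities.reshape(self.height * self.width, self.channels)


@dataclass(frozen=True)
class ConsolidatedMatrix:
    """Row-stacked unfolded cubes: the matrix D the factorization consumes.

    Rows follow cube input order, row-major within each cube (origin
    top-left).  ``sample_ids``/``shapes``/``offsets`` give O(1) access to any
    block; ``row_map`` materializes the full row -> (sample, row, col) list.
    """

    data: np.ndarray
    sample_ids: tuple[str, ...]
    shapes: tuple[tuple[int, int], ...]
    peaklist: PeakList

    def __post_init__(self) -> None:
        total = sum(h * w for h, w in self.shapes)
        if self.data.shape[0] != total:
            raise ValueError("data row count disagrees with cube shapes")
        if self.data.shape[1] != len(self.peaklist):
            raise ValueError("data channel count disagrees with peak list")

    @property
    def total_pixels(self) -> int:
        return int(self.data.shape[0])

    @property
    def channels(self) -> int:
        return int(self.data.shape[1])

    @property
    def offsets(self) -> tuple[int, ...]:
        off, acc = [], 0
        for h, w in self.shapes:
            off.append(acc)
            acc += h * w
        return tuple(off)

    @property
    def row_map(self) -> list[tuple[str, int, int]]:
        out: list[tuple[str, int, int]] = []
        for sid, (h, w) in zip(self.sample_ids, self.shapes):
            for r in range(h):
                for c in range(w):
                    out.append((sid, r, c))
        return out

    def row_of(self, sample_id: str, r: int, c: int) -> int:
        """Matrix row index of pixel (r, c) of ``sample_id``."""
        i = self.sample_ids.index(sample_id)
        h, w = self.shapes[i]
        if not (0 <= r < h and 0 <= c < w):
            raise IndexError(f"pixel ({r}, {c}) outside {sample_id!r} grid {h}x{w}")
        return self.offsets[i] + r * w + c

    def loc_of(self, row: int) -> tuple[str, int, int]:
        """(sample_id, row, col) of a matrix row index."""
        if not (0 <= row < self.total_pixels):
            raise IndexError(f"row {row} out of range")
        for sid, (h, w), off in zip(self.sample_ids, self.shapes, self.offsets):
            if row < off + h * w:
                k = row - off
                return (sid, k // w, k % w)
        raise AssertionError("unreachable")

    def block(self, sample_id: str) -> np.ndarray:
        """The (h*w, channels) block of one sample."""
        i = self.sample_ids.index(sample_id)
        h, w = self.shapes[i]
        off = self.offsets[i]
        return self.data[off : off + h * w]


@dataclass
class MCRModel:
    """Fitted bilinear MCR model D ~= C @ S + E.

    ``scores`` is C (total_pixels x k), ``loadings`` is S (k x channels);
    both non-negative.  Loading rows have unit Euclidean norm unless flagged
    degenerate (all-zero).  ``lof_percent`` is the lack of fit,
    100 * ||D - C S||_F / ||D||_F.
    """

    k: int
    scores: np.ndarray
    loadings: np.ndarray
    lof_percent: float
    n_iter: int
    converged: bool
    seed: int
    degenerate: bool = False
    lof_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.scores.shape[1] != self.k or self.loadings.shape[0] != self.k:
            raise ValueError("factor shapes disagree with k")
        if np.any(self.scores < 0) or np.any(self.loadings < 0):
            raise ValueError("scores and loadings must be non-negative")
        norms = np.linalg.norm(self.loadings, axis=1)
        unit = np.isclose(norms, 1.0, atol=1e-8)
        zero = norms == 0.0
        if not np.all(unit | zero):
            raise ValueError("loading rows must be unit-norm or all-zero (degenerate)")
        if zero.any() and not self.degenerate:
            raise ValueError("all-zero loading rows require the degenerate flag")
        if not (-1e-9 <= self.lof_percent <= 100.0 + 1e-9):
            raise ValueError("lack of fit must lie in [0, 100] for non-negative data")

    @property
    def channels(self) -> int:
        return int(self.loadings.shape[1])


def consolidate(cubes: Sequence[SampleCube], peaklist: PeakList) -> ConsolidatedMatrix:
    """Stack sample cubes into one analysis matrix, intensities unchanged.

    Cubes may differ in height/width; they must all match the peak list's
    channel count and carry unique sample ids.
    """
    if not cubes:
        raise ValueError("no cubes to consolidate")
    ids = [c.sample_id for c in cubes]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id(s): {dup}")
    n_chan = len(peaklist)
    for cube in cubes:
        if cube.channels != n_chan:
            raise ValueError(
                f"cube {cube.sample_id!r} has {cube.channels} channels but the "
                f"peak list defines {n_chan}"
            )
    data = np.vstack([c.unfold() for c in cubes])
    return ConsolidatedMatrix(
        data=data,
        sample_ids=tuple(ids),
        shapes=tuple((c.height, c.width) for c in cubes),
        peaklist=peaklist,
    )


def refold_scores(model: MCRModel, matrix: ConsolidatedMatrix) -> dict[str, np.ndarray]:
    """Fold score columns back onto each sample's pixel grid.

    Returns ``{sample_id: array (k, height, width)}`` with pixel (r, c) of
    component j equal to ``scores[row_of(sample, r, c), j]``.
    """
    if model.scores.shape[0] != matrix.total_pixels:
        raise ValueError(
            f"model has {model.scores.shape[0]} score rows but the matrix "
            f"has {matrix.total_pixels} pixels"
        )
    out: dict[str, np.ndarray] = {}
    for sid, (h, w), off in zip(matrix.sample_ids, matrix.shapes, matrix.offsets):
        block = model.scores[off : off + h * w]  # (h*w, k)
        out[sid] = np.moveaxis(block.reshape(h, w, model.k), 2, 0)
    return out


def unfold_scores(images: dict[str, np.ndarray], matrix: ConsolidatedMatrix) -> np.ndarray:
    """Inverse of :func:`refold_scores`: rebuild the (total_pixels, k) score matrix."""
    blocks = []
    for sid, (h, w) in zip(matrix.sample_ids, matrix.shapes):
        img = images[sid]
        if img.shape[1:] != (h, w):
            raise ValueError(f"image for {sid!r} has shape {img.shape[1:]}, expected {(h, w)}")
        blocks.append(np.moveaxis(img, 0, 2).reshape(h * w, img.shape[0]))
    return np.vstack(blocks)


@dataclass(frozen=True)
class AreaEquivalent:
    """Total analysed area and the equivalent single rectangle at equal pixel pitch."""

    area_mm2: float
    rect_mm: tuple[float, float]
    n_fields: int
    pixels_total: int


def area_equivalent(cubes: Sequence[SampleCube]) -> AreaEquivalent:
    """Total analysed area of homogeneous fields, as mm^2 and an equivalent rectangle.

    All cubes must share field size and resolution (the rectangle assumes one
    pixel pitch).  The rectangle tiles the n fields into the most nearly
    square a x b grid (a <= b, a*b = n), e.g. eight 500 x 500 um fields
    report as 1 mm x 2 mm.
    """
    if not cubes:
        raise ValueError("no cubes")
    fs = cubes[0].field_size_um
    res = (cubes[0].height, cubes[0].width)
    for c in cubes[1:]:
        if c.field_size_um != fs or (c.height, c.width) != res:
            raise ValueError(
                f"heterogeneous fields: {c.sample_id!r} has {c.field_size_um} um at "
                f"{c.height}x{c.width}, expected {fs} um at {res[0]}x{res[1]}"
            )
    n = len(cubes)
    area_mm2 = n * fs[0] * fs[1] / 1e6
    a = max(d for d in range(1, int(np.sqrt(n)) + 1) if n % d == 0)
    b = n // a
    rect = (a * fs[0] / 1000.0, b * fs[1] / 1000.0)
    return AreaEquivalent(
        area_mm2=float(area_mm2),
        rect_mm=(float(min(rect)), float(max(rect))),
        n_fields=n,
        pixels_total=n * res[0] * res[1],
    )
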