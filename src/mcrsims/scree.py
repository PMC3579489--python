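"""PCA scree evaluation of the consolidated matrix.

PCA is used here only as a precursor diagnostic: the eigenvalue spectrum of
the data cross-product bounds how many MCR components are worth fitting.
Mirroring the no-pre-treatment policy of the rest of the pipeline, the
decomposition is uncentred by default; column mean-centring is an explicit
flag.  The suggestion is a *range*, not a point, and is advisory only.

The elbow heuristic: walking down the sorted eigenvalues, the plateau is
taken to begin at the smallest index i where the drop ratio
lambda_i / lambda_{i+1} falls below 1.5 (eigenvalues at the numerical noise
floor count as plateau); the suggested range is (elbow - 2, elbow + 3),
clipped to [1, channels].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConsolidatedMatrix

__all__ = ["ScreeResult", "pca_scree", "plot_scree"]

_RATIO_PLATEAU = 1.5
_NOISE_FLOOR_REL = 1e-12
_MAX_CHANNELS = 10**6


@dataclass(frozen=True)
class ScreeResult:
    """Descending eigenvalues of the data covariance with an advisory component range."""

    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    suggested_range: tuple[int, int]
    centred: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(1, self.eigenvalues.size + 1),
                "eigenvalue": self.eigenvalues,
                "variance_fraction": self.variance_fraction,
            }
        )


def _elbow(eigenvalues: np.ndarray) -> int:
    """1-based index at which the scree plateau begins."""
    lam = eigenvalues
    floor = _NOISE_FLOOR_REL * lam[0]
    ratios = np.empty(lam.size - 1)
    for i in range(lam.size - 1):
        if lam[i + 1] <= floor:
            # both at the floor -> flat; a real value dropping to the floor -> cliff
            ratios[i] = 1.0 if lam[i] <= floor else np.inf
        else:
            ratios[i] = lam[i] / lam[i + 1]
    below = np.nonzero(ratios < _RATIO_PLATEAU)[0]
    return int(below[0]) + 1 if below.size else int(lam.size)


def pca_scree(matrix: ConsolidatedMatrix | np.ndarray, centred: bool = False) -> ScreeResult:
    """Eigenvalue scree of the consolidated data with a suggested component range.

    Eigenvalues are those of the (optionally column-mean-centred) data
    covariance ``X'X / (n_pixels - 1)``, computed on the channels x channels
    cross-product since channels << pixels.
    """
    X = matrix.data if isinstance(matrix, ConsolidatedMatrix) else np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("matrix must be non-empty and 2-D")
    n, m = X.shape
    if m > _MAX_CHANNELS:
        raise ValueError(f"{m} channels exceeds the supported maximum of {_MAX_CHANNELS}")
    if centred:
        X = X - X.mean(axis=0, keepdims=True)
    denom = max(n - 1, 1)
    cov = (X.T @ X) / denom
    lam = np.linalg.eigvalsh(cov)[::-1]
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total <= 0:
        raise ValueError("zero-variance matrix: scree undefined")
    elbow = _elbow(lam)
    low = max(1, elbow - 2)
    high = min(m, elbow + 3)
    return ScreeResult(
        eigenvalues=lam,
        variance_fraction=lam / total,
        suggested_range=(low, high),
        centred=centred,
    )


def plot_scree(result: ScreeResult, path) -> None:
    """Log-scale eigenvalue plot with the suggested component range shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lam = result.eigenvalues
    idx = np.arange(1, lam.size + 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    positive = lam > 0
    ax.semilogy(idx[positive], lam[positive], marker="o", ms=3, lw=1, color="tab:blue")
    lo, hi = result.suggested_range
    ax.axvspan(lo - 0.5, hi + 0.5, color="tab:orange", alpha=0.25,
               label=f"suggested components: {lo}–{hi}")
    ax.set_xlabel("component index")
    ax.set_ylabel("eigenvalue")
    ax.set_title("PCA scree" + (" (centred)" if result.centred else " (uncentred)"))
    ax.legend(loc="upper right")
    fig.tight_layout()
    try:
        fig.savefig(path, dpi=110, metadata={"Software": "mcrsims"})
    except OSError as exc:
        raise OSError(f"could not write scree plot to {path}: {exc}") from exc
    finally:
        plt.close(fig)
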