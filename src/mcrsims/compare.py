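"""Permutation-aware comparison of bilinear factorizations.

MCR solutions are determined only up to reordering (and, absent the
unit-norm convention, rescaling) of components, so any comparison between
two models — or between a model and ground truth — must first match
components.  Matching maximizes total pairwise cosine similarity of the
loading vectors via the Hungarian assignment.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["match_loadings", "loading_cosines"]


def _row_normalize(A: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(A, axis=1, keepdims=True)
    return A / np.where(norms > 0, norms, 1.0)


def match_loadings(reference: np.ndarray, estimate: np.ndarray) -> np.ndarray:
    """Permutation of estimate rows best matching the reference rows.

    Returns ``perm`` such that ``estimate[perm[i]]`` corresponds to
    ``reference[i]``; both inputs are (k, channels).
    """
    ref = _row_normalize(np.asarray(reference, dtype=float))
    est = _row_normalize(np.asarray(estimate, dtype=float))
    if ref.shape != est.shape:
        raise ValueError("reference and estimate must have equal shapes")
    cos = ref @ est.T
    _, cols = linear_sum_assignment(-cos)
    return cols


def loading_cosines(reference: np.ndarray, estimate: np.ndarray) -> np.ndarray:
    """Per-component cosine similarity after optimal matching, in reference order."""
    ref = _row_normalize(np.asarray(reference, dtype=float))
    est = _row_normalize(np.asarray(estimate, dtype=float))
    perm = match_loadings(ref, est)
    return np.einsum("ij,ij->i", ref, est[perm])
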