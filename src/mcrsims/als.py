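"""Non-negativity-constrained alternating least squares MCR.

One ALS run factorizes the consolidated matrix D (pixels x channels) as
D ~= C @ S with C, S >= 0, alternating exact constrained least-squares
solves for one factor with the other fixed.  Because each half-step is an
exact constrained minimizer (never clip-after-solve), the lack of fit is
non-increasing across iterations — a property the test suite asserts on
every fit.

After every loadings update the rows of S are rescaled to unit Euclidean
norm with the scale absorbed into the matching score columns; this fixes
the bilinear scale ambiguity and makes loadings from independent restarts
directly comparable for consensus clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConsolidatedMatrix, MCRModel
from .nnls import nnls_multi

__all__ = [
    "ALSConfig",
    "random_init",
    "update_scores",
    "update_loadings",
    "fit_mcr",
    "lack_of_fit",
]

#: lack-of-fit (percent) below which a fit is declared numerically exact
LOF_FLOOR = 1e-6


@dataclass(frozen=True)
class ALSConfig:
    """Settings for one ALS run.

    ``tol`` is the relative lack-of-fit change declaring convergence;
    ``scores_first`` controls which half-step opens each iteration.  The
    default (None -> True) solves scores from the initial loadings first:
    with consensus loadings supplied this is what lets them steer the fit,
    and with random starts it preserves the spectral diversity of the
    random loading directions — deriving loadings from i.i.d. random
    scores instead collapses every component's first estimate toward the
    global mean spectrum, which empirically strands most restarts in poor
    local minima.  Set False to open with the loadings half-step.
    """

    k: int
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    init_loadings: np.ndarray | None = None
    scores_first: bool | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if self.init_loadings is not None:
            S0 = np.asarray(self.init_loadings, dtype=float)
            if S0.shape[0] != self.k:
                raise ValueError("init_loadings row count must equal k")
            if np.any(S0 < 0) or not np.all(np.isfinite(S0)):
                raise ValueError("init_loadings must be finite and non-negative")
            object.__setattr__(self, "init_loadings", S0)


def random_init(
    k: int, channels: int, total_pixels: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Strictly positive random starting factors, loadings rows unit-norm.

    Entries are uniform on (0.1, 1.1) — bounded away from zero so no
    component starts degenerate — and fully reproducible from ``seed``.
    """
    if min(k, channels, total_pixels) < 1:
        raise ValueError("all dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    scores = rng.uniform(0.1, 1.1, size=(total_pixels, k))
    loadings = rng.uniform(0.1, 1.1, size=(k, channels))
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    return scores, loadings


def update_scores(data: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Exact NNLS solve for C given S: argmin_{C>=0} ||D - C S||_F.

    Each pixel's score vector is an independent k-variable subproblem; all
    pixels are solved jointly through the grouped active-set solver.
    """
    C, _ = _update_scores_ws(data, loadings, None)
    return C


def _update_scores_ws(
    data: np.ndarray, loadings: np.ndarray, warm: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Scores update carrying the active-set support for warm restarts."""
    StS = loadings @ loadings.T
    StD = loadings @ data.T
    X = nnls_multi(StS, StD, warm_start=warm)
    return X.T, X > 0


def update_loadings(data: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Exact NNLS solve for S given C, rows re-normalized to unit norm.

    The dropped row scales belong to the score columns; inside
    :func:`fit_mcr` they are absorbed there explicitly.  All-zero rows
    (degenerate components) are returned as zeros.
    """
    S, _, _ = _update_loadings_scaled(data, scores, None)
    return S


def _update_loadings_scaled(
    data: np.ndarray, scores: np.ndarray, warm: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    CtC = scores.T @ scores
    CtD = scores.T @ data
    S = nnls_multi(CtC, CtD, warm_start=warm)
    support = S > 0
    norms = np.linalg.norm(S, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return S / safe[:, None], norms, support


def lack_of_fit(data: np.ndarray | ConsolidatedMatrix, model_or_scores, loadings=None) -> float:
    """Lack of fit in percent: 100 * ||D - C S||_F / ||D||_F."""
    D = data.data if isinstance(data, ConsolidatedMatrix) else np.asarray(data, dtype=float)
    if loadings is None:
        C, S = model_or_scores.scores, model_or_scores.loadings
    else:
        C, S = model_or_scores, loadings
    denom = np.linalg.norm(D)
    if denom == 0:
        raise ValueError("lack of fit undefined for all-zero data")
    R = C @ S
    np.subtract(D, R, out=R)  # reuse the reconstruction buffer for the residual
    return float(100.0 * np.linalg.norm(R) / denom)


def _reinit_component(D: np.ndarray, C: np.ndarray, S: np.ndarray, j: int) -> None:
    """Reseed component j from the residual's dominant non-negative direction."""
    R = D - C @ S
    # a few power iterations on R'R give the top right-singular direction
    rng = np.random.default_rng(0)
    v = rng.random(D.shape[1])
    for _ in range(10):
        v = R.T @ (R @ v)
        nv = np.linalg.norm(v)
        if nv == 0:
            break
        v /= nv
    v = np.abs(v)
    nv = np.linalg.norm(v)
    S[j] = v / nv if nv > 0 else np.full(D.shape[1], D.shape[1] ** -0.5)
    C[:, j] = np.clip(R @ S[j], 0.0, None)


def fit_mcr(matrix: ConsolidatedMatrix | np.ndarray, config: ALSConfig) -> MCRModel:
    """One complete ALS-MCR run from a (possibly random) starting point.

    Alternates the two constrained half-steps until the relative change in
    lack of fit drops below ``config.tol``, the fit reaches the numerical
    floor, or ``config.max_iter`` is hit.  A component whose loading row or
    score column collapses to zero is reseeded once from the residual's
    dominant non-negative direction; a second collapse ends the run with
    ``converged=False`` and the degenerate flag set.
    """
    D = matrix.data if isinstance(matrix, ConsolidatedMatrix) else np.asarray(matrix, dtype=float)
    if D.ndim != 2 or D.size == 0:
        raise ValueError("data must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(D)):
        raise ValueError("data contains non-finite values")
    n, m = D.shape
    if config.k > min(n, m):
        raise ValueError(f"k={config.k} exceeds min(total_pixels, channels)={min(n, m)}")
    if np.linalg.norm(D) == 0:
        raise ValueError("all-zero data cannot be factorized")

    C, S = random_init(config.k, m, n, config.seed)
    if config.init_loadings is not None:
        if config.init_loadings.shape[1] != m:
            raise ValueError("init_loadings channel count disagrees with data")
        S = config.init_loadings.copy()
        norms = np.linalg.norm(S, axis=1)
        if np.any(norms == 0):
            raise ValueError("init_loadings contains an all-zero row")
        S /= norms[:, None]
    scores_first = True if config.scores_first is None else config.scores_first

    reinit_used = np.zeros(config.k, dtype=bool)
    degenerate = False
    converged = False
    trace: list[float] = []
    lof_prev = np.inf
    warm_C: np.ndarray | None = None  # active-set support carried across iterations
    warm_S: np.ndarray | None = None
    it = 0
    for it in range(1, config.max_iter + 1):
        if scores_first:
            C, warm_C = _update_scores_ws(D, S, warm_C)
            S, norms, warm_S = _update_loadings_scaled(D, C, warm_S)
            C = C * np.where(norms > 0, norms, 0.0)[None, :]
        else:
            S, norms, warm_S = _update_loadings_scaled(D, C, warm_S)
            C, warm_C = _update_scores_ws(D, S, warm_C)

        dead = (np.linalg.norm(S, axis=1) == 0) | (np.linalg.norm(C, axis=0) == 0)
        if dead.any():
            j = int(np.nonzero(dead)[0][0])
            if reinit_used[j]:
                degenerate = True
                S[dead] = 0.0
                C[:, dead] = 0.0
                trace.append(lack_of_fit(D, C, S))
                break
            reinit_used[j] = True
            _reinit_component(D, C, S, j)
            warm_C = warm_S = None  # stale supports after a reseed
            continue

        lof = lack_of_fit(D, C, S)
        trace.append(lof)
        if lof <= LOF_FLOOR:
            converged = True
            break
        if np.isfinite(lof_prev):
            rel = (lof_prev - lof) / max(lof_prev, np.finfo(float).tiny)
            if rel < config.tol:
                converged = True
                break
        lof_prev = lof

    # tidy: unit-norm or zero loading rows, scale into scores
    norms = np.linalg.norm(S, axis=1)
    pos = norms > 0
    S[pos] /= norms[pos, None]
    C[:, pos] *= norms[pos][None, :]
    np.clip(C, 0.0, None, out=C)
    np.clip(S, 0.0, None, out=S)
    return MCRModel(
        k=config.k,
        scores=C,
        loadings=S,
        lof_percent=lack_of_fit(D, C, S),
        n_iter=it,
        converged=converged,
        seed=config.seed,
        degenerate=degenerate,
        lof_trace=np.asarray(trace),
    )
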