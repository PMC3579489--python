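"""Repeat–cluster–refit consensus protocol for MCR-ALS.

ALS from random starting points converges to starting-point-dependent
local solutions.  The protocol here stabilizes the result: run the fit
several times (default ten) from independent random starts, pool the
resulting unit-norm loading vectors (n_repeats * k of them), k-means
cluster the pool into k groups, and use the renormalized cluster means as
the initial loadings for one final ALS round with fresh random scores.
The final model is the pipeline's headline result; cluster dispersion and
per-cluster repeat coverage are reported as stability diagnostics.

Repeats are seed-deterministic and order-independent: repeat i derives its
seed from (master_seed, i), so concurrent and sequential execution yield
bit-identical models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from joblib import Parallel, delayed
from sklearn.cluster import KMeans

from .als import ALSConfig, fit_mcr
from .core import ConsolidatedMatrix, MCRModel

__all__ = [
    "ConsensusResult",
    "ClusterStability",
    "derive_seed",
    "run_repeats",
    "cluster_loadings",
    "consensus_fit",
    "run_consensus",
]


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic per-repeat seed below 2**31."""
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class ClusterStability:
    """Per-cluster diagnostics of the pooled-loadings clustering."""

    mean_cosine: tuple[float, ...]  # members to their cluster mean
    coverage: tuple[int, ...]  # distinct repeats contributing to the cluster


@dataclass(frozen=True)
class ConsensusResult:
    """Everything the consensus protocol produced, including the headline model."""

    repeat_models: tuple[MCRModel, ...]
    cluster_assignment: np.ndarray  # label per pooled non-degenerate loading vector
    consensus_loadings: np.ndarray  # (k, channels), unit-norm rows
    final_model: MCRModel
    stability: ClusterStability
    master_seed: int

    @property
    def k(self) -> int:
        return self.final_model.k


def run_repeats(
    matrix: ConsolidatedMatrix | np.ndarray,
    k: int,
    n_repeats: int = 10,
    master_seed: int = 0,
    als_config: ALSConfig | None = None,
    n_jobs: int = 1,
) -> list[MCRModel]:
    """Independent random-start ALS fits, seed-derived and order-stable.

    A repeat that raises is recorded as a warning and dropped; the run
    fails only if fewer than two repeats survive.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    base = als_config if als_config is not None else ALSConfig(k=k)
    if base.k != k:
        base = replace(base, k=k)
    configs = [
        replace(base, seed=derive_seed(master_seed, i), init_loadings=None)
        for i in range(n_repeats)
    ]

    def _one(cfg: ALSConfig):
        try:
            return fit_mcr(matrix, cfg)
        except Exception as exc:  # noqa: BLE001 — repeat failures are non-fatal
            return exc

    if n_jobs == 1:
        results = [_one(c) for c in configs]
    else:
        results = Parallel(n_jobs=n_jobs, prefer="threads")(delayed(_one)(c) for c in configs)
    models: list[MCRModel] = []
    for i, res in enumerate(results):
        if isinstance(res, Exception):
            warnings.warn(f"repeat {i} (seed {configs[i].seed}) failed: {res}", stacklevel=2)
        else:
            models.append(res)
    if len(models) < 2:
        raise RuntimeError(f"only {len(models)} of {n_repeats} repeats succeeded")
    return models


def cluster_loadings(
    repeat_models: list[MCRModel], k: int, seed: int = 0, n_restarts: int = 10
) -> tuple[np.ndarray, np.ndarray, ClusterStability]:
    """k-means the pooled loading vectors; cluster means become the consensus.

    Euclidean k-means on unit-norm non-negative vectors is monotonically
    related to cosine distance, so clusters group spectrally similar
    components across repeats regardless of which repeat produced them.
    Unconverged repeats still contribute; degenerate (all-zero) loading
    rows carry no spectral information and are dropped from the pool.
    Only nothing-to-cluster cases (fewer distinct vectors than clusters)
    are refused.
    """
    ks = {m.k for m in repeat_models}
    chans = {m.channels for m in repeat_models}
    if len(ks) != 1 or len(chans) != 1:
        raise ValueError("repeat models must share k and channel count")
    pooled = np.vstack([m.loadings for m in repeat_models])
    repeat_of = np.repeat(np.arange(len(repeat_models)), repeat_models[0].k)
    nonzero = np.linalg.norm(pooled, axis=1) > 0
    pooled = pooled[nonzero]
    repeat_of = repeat_of[nonzero]
    n_distinct = np.unique(np.round(pooled, 12), axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(
            f"insufficient diversity: {n_distinct} distinct pooled loadings for k={k}"
        )
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(pooled)
    if np.unique(labels).size < k:  # pragma: no cover — sklearn relocates empty clusters
        raise RuntimeError("k-means produced an empty cluster despite restarts")
    centroids = np.clip(km.cluster_centers_, 0.0, None)  # shave float dust off the means
    norms = np.linalg.norm(centroids, axis=1)
    if np.any(norms == 0):
        raise RuntimeError("k-means produced a zero centroid")
    consensus = centroids / norms[:, None]
    mean_cos, coverage = [], []
    for c in range(k):
        members = pooled[labels == c]
        cos = members @ consensus[c] / np.maximum(np.linalg.norm(members, axis=1), 1e-300)
        mean_cos.append(float(np.clip(cos, 0.0, 1.0).mean()))
        coverage.append(int(np.unique(repeat_of[labels == c]).size))
    return labels, consensus, ClusterStability(tuple(mean_cos), tuple(coverage))


def consensus_fit(
    matrix: ConsolidatedMatrix | np.ndarray,
    consensus_loadings: np.ndarray,
    als_config: ALSConfig,
) -> MCRModel:
    """Final ALS round seeded with the consensus loadings and fresh random scores."""
    cfg = replace(als_config, init_loadings=np.asarray(consensus_loadings, dtype=float))
    return fit_mcr(matrix, cfg)


def run_consensus(
    matrix: ConsolidatedMatrix | np.ndarray,
    k: int,
    n_repeats: int = 10,
    master_seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_jobs: int = 1,
) -> ConsensusResult:
    """The full protocol: repeats, loading clustering, one consensus-seeded refit."""
    base = ALSConfig(k=k, tol=tol, max_iter=max_iter)
    models = run_repeats(matrix, k, n_repeats, master_seed, base, n_jobs=n_jobs)
    labels, consensus, stability = cluster_loadings(
        models, k, seed=derive_seed(master_seed, 10_000)
    )
    final = consensus_fit(
        matrix, consensus, replace(base, seed=derive_seed(master_seed, 20_000))
    )
    return ConsensusResult(
        repeat_models=tuple(models),
        cluster_assignment=labels,
        consensus_loadings=consensus,
        final_model=final,
        stability=stability,
        master_seed=master_seed,
    )
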