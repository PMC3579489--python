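"""Shared fixtures: phantoms at two scales and the heavy consensus runs.

The 64x64 eight-sample phantom is the study-scale object used by the
end-to-end tests; the 16x16 three-sample phantom keeps unit tests fast.
Heavy pipeline results are session-scoped so recovery, stability,
monotonicity and reporting tests all reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import mcrsims as M

STUDY_SEED = 7


def tiny_spec(seed: int = 11, noise: str = "none") -> M.PhantomSpec:
    """Three samples, 16x16, 12 channels, 3 chemistries — fast unit-test phantom."""
    comps = (
        M.ComponentSpec(role="background", present_in=(0, 1, 2), amplitude=100.0),
        M.ComponentSpec(role="spot", present_in=(0, 1), amplitude=80.0),
        M.ComponentSpec(role="spot", present_in=(2,), amplitude=60.0),
    )
    return M.PhantomSpec(
        n_samples=3, height=16, width=16, n_channels=12,
        components=comps, noise=noise, seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_truth() -> M.PhantomTruth:
    return M.generate_phantom(tiny_spec())


@pytest.fixture(scope="session")
def tiny_matrix(tiny_truth) -> M.ConsolidatedMatrix:
    return M.consolidate(tiny_truth.cubes, tiny_truth.peaklist)


@pytest.fixture(scope="session")
def study_truth() -> M.PhantomTruth:
    """Noiseless 8-sample, 64x64, 30-channel phantom with 5 chemistries."""
    return M.generate_phantom(M.default_spec(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def study_matrix(study_truth) -> M.ConsolidatedMatrix:
    return M.consolidate(study_truth.cubes, study_truth.peaklist)


@pytest.fixture(scope="session")
def study_consensus(study_matrix) -> M.ConsensusResult:
    """Full consensus pipeline (10 repeats, k=5) on the noiseless phantom."""
    return M.run_consensus(study_matrix, k=5, n_repeats=10, master_seed=STUDY_SEED)


@pytest.fixture(scope="session")
def poisson_truth() -> M.PhantomTruth:
    return M.generate_phantom(M.default_spec(seed=STUDY_SEED, noise="poisson"))


@pytest.fixture(scope="session")
def poisson_matrix(poisson_truth) -> M.ConsolidatedMatrix:
    return M.consolidate(poisson_truth.cubes, poisson_truth.peaklist)


@pytest.fixture(scope="session")
def poisson_consensus(poisson_matrix) -> M.ConsensusResult:
    return M.run_consensus(poisson_matrix, k=5, n_repeats=10, master_seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_scan(study_matrix) -> M.ScanResult:
    """Component-number scan k=3..8 with the full consensus protocol per k."""
    return M.scan_components(study_matrix, range(3, 9), n_repeats=10, master_seed=STUDY_SEED)


def make_cube(sample_id: str, h: int = 2, w: int = 2, c: int = 3,
              fill: float | None = None, seed: int = 0,
              field_um: tuple[float, float] = (500.0, 500.0)) -> M.SampleCube:
    if fill is None:
        arr = np.random.default_rng(seed).random((h, w, c)) * 10
    else:
        arr = np.full((h, w, c), float(fill))
    return M.SampleCube(sample_id=sample_id, intensities=arr, field_size_um=field_um)


def make_peaklist(n: int) -> M.PeakList:
    return M.PeakList(mz=10.0 + np.arange(n), labels=tuple(f"p{i}" for i in range(n)))
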