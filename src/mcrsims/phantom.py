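"""Synthetic multi-sample hyperspectral phantoms with known ground truth.

The generator emulates the structure of a polymer-microarray ToF-SIMS
study: several samples imaged over identical fields, all sharing a
substrate chemistry (background) that is strong outside a central printed
spot and suppressed inside it; spot chemistries appearing as smooth discs
in subsets of the samples; and an optional contamination overlay that both
adds its own spectrum and multiplicatively attenuates ("masks") the spot
chemistry underneath it.  Pure spectra are unit-norm, non-negative and
pairwise well separated, so every noiseless phantom is an exact low-rank
bilinear product whose factors are known — the ground truth every
downstream stage is tested against.

Spot edges are raised-cosine tapered rather than hard circles: printed
spots are not uniform, and smooth concentration gradients exercise the
factorization more realistically than binary masks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .core import PeakList, SampleCube

__all__ = [
    "ComponentSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "write_phantom",
    "default_spec",
    "acquisition_scale_spec",
]

#: background suppression depth inside a spot disc (1.0: the printed spot
#: fully covers the substrate where the disc profile is 1 — SIMS is
#: top-monolayer sensitive, so a covered substrate emits nothing)
_BG_SUPPRESSION = 1.0
#: fraction by which contamination attenuates a co-located spot chemistry
_MASK_STRENGTH = 0.8
#: raised-cosine edge half-width as a fraction of the spot radius
_EDGE_FRACTION = 0.3
#: pairwise cosine-similarity ceiling enforced on pure spectra
_MAX_SPECTRAL_COSINE = 0.95


@dataclass(frozen=True)
class ComponentSpec:
    """One chemistry of the phantom.

    ``role`` is ``background`` (substrate, present everywhere, high outside
    the spot discs), ``spot`` (a disc in each sample listed in
    ``present_in``) or ``contamination`` (a disc that masks co-located spot
    chemistries).  ``spectrum`` may be None, in which case a pure spectrum
    is drawn at generation time.  ``center`` is the disc centre as a
    (x, y) fraction of the field.
    """

    role: str
    present_in: tuple[int, ...]
    amplitude: float
    spot_radius_fraction: float = 0.35
    center: tuple[float, float] = (0.5, 0.5)
    spectrum: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.role not in ("background", "spot", "contamination"):
            raise ValueError(f"unknown component role {self.role!r}")
        if self.amplitude <= 0:
            raise ValueError("component amplitude must be > 0")
        if not 0 < self.spot_radius_fraction <= 0.7:
            raise ValueError("spot_radius_fraction must lie in (0, 0.7]")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a phantom study: geometry, components, noise, seed."""

    n_samples: int = 8
    height: int = 64
    width: int = 64
    n_channels: int = 30
    components: tuple[ComponentSpec, ...] = ()
    noise: str = "none"  # none | poisson | gaussian
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.height, self.width, self.n_channels) < 1:
            raise ValueError("all phantom dimensions must be >= 1")
        if self.noise not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise == "gaussian" and self.noise_sigma <= 0:
            raise ValueError("gaussian noise requires noise_sigma > 0")
        if not self.components:
            raise ValueError("phantom needs at least one component")
        if self.n_channels < len(self.components):
            raise ValueError(
                f"{len(self.components)} components need at least that many "
                f"channels; got {self.n_channels} (pure spectra under-determined)"
            )
        all_samples = tuple(range(self.n_samples))
        bg = [c for c in self.components if c.role == "background"]
        if len(bg) != 1 or tuple(sorted(bg[0].present_in)) != all_samples:
            raise ValueError("exactly one background component present in all samples is required")
        for c in self.components:
            if any(s < 0 or s >= self.n_samples for s in c.present_in):
                raise ValueError("present_in indices out of range")

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class PhantomTruth:
    """Generated cubes plus the exact factors they were built from."""

    cubes: tuple[SampleCube, ...]
    true_scores: dict[str, np.ndarray]  # sample_id -> (k, h, w), noiseless
    true_loadings: np.ndarray  # (k, channels), unit-norm rows
    peaklist: PeakList
    spec: PhantomSpec


def default_spec(seed: int = 0, noise: str = "none", *, n_samples: int = 8,
                 height: int = 64, width: int = 64, n_channels: int = 30) -> PhantomSpec:
    """The stock five-chemistry study layout.

    One substrate background in all samples; three spot chemistries shared
    across sample subsets (one chemistry in four samples, two in two
    samples each, every sample carrying exactly one spot); one
    contamination overlay in a single sample, sitting on the four-sample
    chemistry so masking is observable against uncontaminated peers.
    """
    if n_samples != 8:
        raise ValueError("the stock layout is defined for 8 samples")
    comps = (
        ComponentSpec(role="background", present_in=tuple(range(8)), amplitude=100.0),
        ComponentSpec(role="spot", present_in=(0, 1, 3, 7), amplitude=90.0),
        ComponentSpec(role="spot", present_in=(2, 6), amplitude=75.0),
        ComponentSpec(role="spot", present_in=(4, 5), amplitude=60.0),
        ComponentSpec(role="contamination", present_in=(3,), amplitude=80.0,
                      spot_radius_fraction=0.25, center=(0.58, 0.58)),
    )
    return PhantomSpec(
        n_samples=n_samples, height=height, width=width, n_channels=n_channels,
        components=comps, noise=noise, seed=seed,
    )


def acquisition_scale_spec(seed: int = 0, noise: str = "poisson") -> PhantomSpec:
    """Full acquisition-scale layout: 8 samples, 256x256 pixels, 461 channels.

    Nine chemistries: substrate background, seven spot chemistries spread
    over sample subsets, one contamination overlay — the component count a
    nine-component resolution should recover.
    """
    comps = (
        ComponentSpec(role="background", present_in=tuple(range(8)), amplitude=100.0),
        ComponentSpec(role="spot", present_in=(0, 1, 3, 7), amplitude=90.0),
        ComponentSpec(role="spot", present_in=(2, 6), amplitude=80.0),
        ComponentSpec(role="spot", present_in=(0, 4), amplitude=70.0, spot_radius_fraction=0.25),
        ComponentSpec(role="spot", present_in=(1, 5), amplitude=65.0, spot_radius_fraction=0.25,
                      center=(0.42, 0.42)),
        ComponentSpec(role="spot", present_in=(4,), amplitude=60.0, center=(0.6, 0.4),
                      spot_radius_fraction=0.2),
        ComponentSpec(role="spot", present_in=(5, 6), amplitude=55.0, center=(0.4, 0.6),
                      spot_radius_fraction=0.2),
        ComponentSpec(role="spot", present_in=(7,), amplitude=50.0, center=(0.6, 0.6),
                      spot_radius_fraction=0.2),
        ComponentSpec(role="contamination", present_in=(3,), amplitude=80.0,
                      spot_radius_fraction=0.25, center=(0.58, 0.58)),
    )
    return PhantomSpec(
        n_samples=8, height=256, width=256, n_channels=461,
        components=comps, noise=noise, seed=seed,
    )


def _disc_profile(h: int, w: int, center: tuple[float, float], radius_frac: float) -> np.ndarray:
    """Raised-cosine disc: 1 inside, cosine taper across the edge band, 0 outside."""
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = center[0] * w, center[1] * h
    r = np.hypot(xx - cx, yy - cy)
    r0 = radius_frac * w
    r_in = r0 * (1 - _EDGE_FRACTION)
    r_out = r0 * (1 + _EDGE_FRACTION)
    t = np.clip((r - r_in) / (r_out - r_in), 0.0, 1.0)
    return 0.5 * (1 + np.cos(np.pi * t))


def _draw_spectra(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Unit-norm pure spectra: disjoint dominant channels plus a sparse tail.

    Each chemistry emits a few characteristic ions strongly and a random
    ~30 % of the remaining channels weakly; the other channels are exactly
    zero, as in real peak-integrated SIMS spectra where most listed ions
    are absent from any one material.  The zero pattern is what makes the
    noiseless phantom's factorization unique (up to order), i.e. the
    ground truth recoverable.
    """
    k, m = spec.n_components, spec.n_channels
    n_dominant = max(1, min(3, m // k))
    order = rng.permutation(m)
    S = np.empty((k, m))
    for j, comp in enumerate(spec.components):
        if comp.spectrum is not None:
            s = np.asarray(comp.spectrum, dtype=float)
            if s.shape != (m,) or np.any(s < 0) or not s.any():
                raise ValueError(f"component {j}: invalid user spectrum")
        else:
            s = np.where(rng.random(m) < 0.3, rng.uniform(0.01, 0.08, size=m), 0.0)
            dom = order[j * n_dominant : (j + 1) * n_dominant]
            s[dom] = rng.uniform(0.5, 1.0, size=dom.size)
        S[j] = s / np.linalg.norm(s)
    gram = S @ S.T
    off = gram[~np.eye(k, dtype=bool)]
    if off.size and off.max() >= _MAX_SPECTRAL_COSINE:
        raise ValueError(
            f"pure spectra too similar (max cosine {off.max():.3f} >= {_MAX_SPECTRAL_COSINE})"
        )
    return S


def _synthetic_peaklist(n_channels: int) -> PeakList:
    mz = 23.0 + 2.5 * np.arange(n_channels)
    labels = tuple(f"ion{i:03d}" for i in range(n_channels))
    return PeakList(mz=mz, labels=labels, polarity="positive")


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Build cubes and exact ground-truth factors from a phantom description.

    Noiseless intensities are exactly ``sum_j scores_j * spectrum_j``.
    Poisson noise treats each noiseless intensity as a mean count; Gaussian
    noise adds N(0, sigma) and truncates at zero (intensities are counts
    and must stay non-negative).  The master seed deterministically derives
    the spectrum stream and one noise stream per sample.
    """
    ss = np.random.SeedSequence(spec.seed)
    child = ss.spawn(1 + spec.n_samples)
    rng_spectra = np.random.default_rng(child[0])
    loadings = _draw_spectra(spec, rng_spectra)
    peaklist = _synthetic_peaklist(spec.n_channels)

    h, w, k = spec.height, spec.width, spec.n_components
    profiles = [
        _disc_profile(h, w, c.center, c.spot_radius_fraction) for c in spec.components
    ]
    cubes = []
    true_scores: dict[str, np.ndarray] = {}
    for s_idx in range(spec.n_samples):
        maps = np.zeros((k, h, w))
        spot_union = np.zeros((h, w))
        for j, comp in enumerate(spec.components):
            if comp.role == "spot" and s_idx in comp.present_in:
                maps[j] = comp.amplitude * profiles[j]
                spot_union = np.maximum(spot_union, profiles[j])
        for j, comp in enumerate(spec.components):
            if comp.role == "contamination" and s_idx in comp.present_in:
                maps[j] = comp.amplitude * profiles[j]
                for jj, other in enumerate(spec.components):
                    if other.role == "spot" and s_idx in other.present_in:
                        maps[jj] = maps[jj] * (1.0 - _MASK_STRENGTH * profiles[j])
        for j, comp in enumerate(spec.components):
            if comp.role == "background":
                maps[j] = comp.amplitude * (1.0 - _BG_SUPPRESSION * spot_union)
        cube = np.einsum("khw,kc->hwc", maps, loadings)
        rng_noise = np.random.default_rng(child[1 + s_idx])
        if spec.noise == "poisson":
            cube = rng_noise.poisson(cube).astype(float)
        elif spec.noise == "gaussian":
            cube = np.clip(cube + rng_noise.normal(0.0, spec.noise_sigma, cube.shape), 0.0, None)
        sid = f"spot{s_idx + 1:02d}"
        cubes.append(SampleCube(sample_id=sid, intensities=cube))
        true_scores[sid] = maps
    return PhantomTruth(
        cubes=tuple(cubes),
        true_scores=true_scores,
        true_loadings=loadings,
        peaklist=peaklist,
        spec=spec,
    )


def _spec_to_jsonable(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    for comp in d["components"]:
        if comp["spectrum"] is not None:
            comp["spectrum"] = list(map(float, comp["spectrum"]))
    return d


def write_phantom(truth: PhantomTruth, directory) -> Path:
    """Write cubes, peak list and ground truth as plain-text files.

    Layout: ``peaklist.csv``, per sample ``<id>.cube.csv`` (h*w rows x
    channels, row-major) with a ``<id>.json`` sidecar, ground-truth
    ``truth_loadings.csv`` and ``truth_scores_<id>.csv``, and a
    ``phantom_spec.json`` echo (including the seed) for provenance.
    Noiseless integer intensities round-trip bit-exactly.
    """
    from . import io as _io

    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        _io.save_peaklist(truth.peaklist, directory / "peaklist.csv")
        for cube in truth.cubes:
            _io.save_cube(cube, directory, peaklist_file="peaklist.csv",
                          polarity=truth.peaklist.polarity)
        np.savetxt(directory / "truth_loadings.csv", truth.true_loadings,
                   delimiter=",", fmt="%.17g")
        for sid, maps in truth.true_scores.items():
            k = maps.shape[0]
            flat = maps.reshape(k, -1).T  # (h*w, k), row-major pixels
            np.savetxt(directory / f"truth_scores_{sid}.csv", flat,
                       delimiter=",", fmt="%.17g")
        (directory / "phantom_spec.json").write_text(
            json.dumps(_spec_to_jsonable(truth.spec), indent=2, sort_keys=True) + "\n"
        )
    except OSError as exc:
        raise OSError(f"failed writing phantom under {directory}: {exc}") from exc
    return directory
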