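"""Run-report bundle: score-image grids, tables and reproducibility metadata.

Everything a reader needs from one consensus run goes into one directory:

    out_dir/
      components/          per-component image grid (one panel per sample)
                           and per sample x component 16-bit PNGs
      loadings.csv         final loadings, columns = peak labels
      top_ions.csv         ranked most-loaded ions per component
      component_summary.csv  per-sample mean scores and role hints
      repeat_lof.csv       lack of fit of every random-start repeat
      consensus_loadings.csv
      overfit.json         pairwise similarity diagnostic
      stability.json       per-cluster dispersion and repeat coverage
      run_meta.json        seeds and settings for exact re-runs

Grids share one intensity scale per component across samples, so
inter-sample effects (e.g. contamination masking a spot) stay visible.
All text outputs are byte-deterministic for a given model.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .consensus import ConsensusResult
from .core import ConsolidatedMatrix, PeakList, refold_scores
from .diagnostics import component_reports, overfit_check
from .io import export_loadings, export_score_images

__all__ = ["render_report"]


def _component_grid(images: dict[str, np.ndarray], j: int, vmax: float, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sids = list(images)
    n = len(sids)
    ncol = min(4, n)
    nrow = -(-n // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.2 * ncol, 2.4 * nrow), squeeze=False)
    for ax in axes.ravel():
        ax.axis("off")
    for i, sid in enumerate(sids):
        ax = axes[i // ncol][i % ncol]
        ax.imshow(images[sid][j], cmap="inferno", vmin=0.0, vmax=vmax, origin="upper")
        ax.set_title(sid, fontsize=8)
        ax.axis("off")
    fig.suptitle(f"component {j + 1} scores", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=110, metadata={"Software": "mcrsims"})
    plt.close(fig)


def render_report(
    result: ConsensusResult,
    matrix: ConsolidatedMatrix,
    peaklist: PeakList,
    out_dir,
    n_top: int = 10,
    score_thresh: float = 0.9,
    loading_thresh: float = 0.9,
    extra_meta: dict | None = None,
) -> Path:
    """Write the full report bundle for one consensus run."""
    out_dir = Path(out_dir)
    comp_dir = out_dir / "components"
    try:
        comp_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {out_dir}: {exc}") from exc

    model = result.final_model
    diag = overfit_check(model, matrix, score_thresh, loading_thresh)
    reports = component_reports(model, matrix, peaklist, n_top, diag)

    export_loadings(model, peaklist, out_dir / "loadings.csv")
    export_score_images(model, matrix, comp_dir)
    images = refold_scores(model, matrix)
    for j in range(model.k):
        vmax = float(model.scores[:, j].max()) or 1.0
        _component_grid(images, j, vmax, comp_dir / f"component_{j + 1:02d}_grid.png")

    rows = [
        {"component": r.component_index, "rank": rank + 1, "ion": lab, "loading": val}
        for r in reports
        for rank, (lab, val) in enumerate(r.top_ions)
    ]
    pd.DataFrame(rows).to_csv(out_dir / "top_ions.csv", index=False, float_format="%.10g")

    summ = pd.DataFrame(
        [
            {"component": r.component_index, "role_hint": r.role_hint, **r.per_sample_mean_score}
            for r in reports
        ]
    )
    summ.to_csv(out_dir / "component_summary.csv", index=False, float_format="%.10g")

    pd.DataFrame(
        {
            "repeat": np.arange(len(result.repeat_models)),
            "seed": [m.seed for m in result.repeat_models],
            "lof_percent": [m.lof_percent for m in result.repeat_models],
            "n_iter": [m.n_iter for m in result.repeat_models],
            "converged": [m.converged for m in result.repeat_models],
        }
    ).to_csv(out_dir / "repeat_lof.csv", index=False, float_format="%.10g")

    np.savetxt(out_dir / "consensus_loadings.csv", result.consensus_loadings,
               delimiter=",", fmt="%.17g")

    flagged = diag.flagged
    (out_dir / "overfit.json").write_text(
        json.dumps(
            {
                "score_thresh": diag.score_thresh,
                "loading_thresh": diag.loading_thresh,
                "pairs": [
                    {"i": i, "j": j, "score_cosine": sc, "loading_cosine": lc, "flagged": f}
                    for i, j, sc, lc, f in diag.pairs
                ],
                "flagged": [list(p) for p in flagged] if flagged else "none",
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    (out_dir / "stability.json").write_text(
        json.dumps(
            {
                "mean_cosine": list(result.stability.mean_cosine),
                "repeat_coverage": list(result.stability.coverage),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    meta = {
        "software": {"name": "mcrsims", "version": _version},
        "k": model.k,
        "master_seed": result.master_seed,
        "final_seed": model.seed,
        "repeat_seeds": [m.seed for m in result.repeat_models],
        "n_repeats": len(result.repeat_models),
        "lof_percent": model.lof_percent,
        "converged": model.converged,
        "n_iter": model.n_iter,
        "samples": list(matrix.sample_ids),
        "score_thresh": score_thresh,
        "loading_thresh": loading_thresh,
    }
    if extra_meta:
        meta.update(extra_meta)
    (out_dir / "run_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return out_dir
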