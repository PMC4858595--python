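"""Rendering of report tables, plane/CEAC point files, figures and manifest."""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cea import QUADRANTS
from .scenarios import ReportBundle

__all__ = ["render_reports", "cea_table"]


def _slug(s) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", str(s)).strip("_")


def _round_pct(x: float) -> int:
    # half-up to integer, matching the style of published quadrant tables
    return int(np.floor(x * 100 + 0.5))


def _fmt_icer(icer) -> str:
    if isinstance(icer, str):
        return icer
    return f"{icer:.0f}"


def cea_table(results: dict, key_names: tuple) -> pd.DataFrame:
    """Flatten CEA result cells into one summary table.

    One row per arm per cell plus the incremental/ICER/quadrant columns on
    the intervention row, mirroring the usual published layout.
    """
    rows = []
    for key, res in results.items():
        est = res.estimator
        meta = dict(zip(key_names, key if isinstance(key, tuple) else (key,)))
        for arm in ("control", "intervention"):
            s = est.arm_summaries_[arm]
            row = {**meta, "scenario": res.scenario, "arm": arm, "n": s.n,
                   "mean_cost": round(s.mean_cost, 2),
                   "mean_effect": round(s.mean_effect, 2)}
            if arm == "intervention":
                row.update({
                    "delta_cost": round(est.delta_cost_, 2),
                    "delta_effect": round(est.delta_effect_, 2),
                    "point_icer": _fmt_icer(est.point_icer_),
                    "median_icer": _fmt_icer(est.median_icer_),
                })
                for q in QUADRANTS:
                    row[f"pct_{q}"] = _round_pct(est.quadrant_proportions_[q])
            rows.append(row)
    return pd.DataFrame(rows)


def _write_points(res, outdir: Path, stem: str):
    reps = res.distribution.replicates
    dc, de = reps[:, 0], reps[:, 1]
    quad = np.where(de > 0, np.where(dc > 0, "NE", "SE"),
                    np.where(dc > 0, "NW", "SW"))
    pd.DataFrame({"delta_cost": dc, "delta_effect": de, "quadrant": quad}
                 ).to_csv(outdir / f"plane_{stem}.csv", index=False)
    res.ceac.to_frame().to_csv(outdir / f"ceac_{stem}.csv", index=False)


def _plot_cell(res, outdir: Path, stem: str):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    reps = res.distribution.replicates
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].scatter(reps[:, 1], reps[:, 0], s=3, alpha=0.3)
    axes[0].axhline(0, lw=0.8, color="k")
    axes[0].axvline(0, lw=0.8, color="k")
    axes[0].set_xlabel("incremental effect")
    axes[0].set_ylabel("incremental cost (EUR)")
    axes[0].set_title(f"CE plane: {stem}")
    curve = res.ceac
    axes[1].plot(curve.wtp_grid, curve.probabilities)
    axes[1].set_ylim(0, 1)
    axes[1].set_xlabel("willingness to pay (EUR per unit effect)")
    axes[1].set_ylabel("P(cost-effective)")
    axes[1].set_title("CEAC")
    fig.tight_layout()
    fig.savefig(outdir / f"fig_{stem}.png", dpi=120)
    plt.close(fig)


def render_reports(bundle: ReportBundle, outdir, plots: bool = False) -> dict:
    """Write all report files; returns the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    bundle.analysis.flow.to_frame().to_csv(outdir / "flow.csv", index=False)
    (outdir / "flow.txt").write_text(bundle.analysis.flow.to_text() + "\n")
    bundle.baseline.to_csv(outdir / "baseline_table.csv", index=False)
    bundle.cost_summary.to_csv(outdir / "cost_summary.csv", index=False)

    sections = {}
    tables = {
        "base_case": cea_table(bundle.base_case, ("perspective", "outcome")),
        "sensitivity": cea_table(bundle.sensitivity,
                                 ("scenario_kind", "perspective", "outcome")),
        "subgroups": cea_table(bundle.subgroups,
                               ("variable", "level", "perspective", "outcome")),
    }
    for name, tab in tables.items():
        if tab.empty:
            sections[name] = "omitted (no cells)"
            continue
        tab.to_csv(outdir / f"cea_{name}.csv", index=False)
        sections[name] = f"cea_{name}.csv"

    for results in (bundle.base_case, bundle.sensitivity, bundle.subgroups):
        for key, res in results.items():
            stem = _slug("_".join(map(str, key if isinstance(key, tuple)
                                      else (key,))))
            _write_points(res, outdir, stem)
            if plots:
                _plot_cell(res, outdir, stem)

    cfg = asdict(bundle.config)
    cfg["subgroups"] = [{"variable": s.variable, "rule": s.rule}
                        for s in bundle.config.subgroups]
    cfg_json = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "package": "ceatrial",
        "version": __version__,
        "seed": bundle.config.seed,
        "n_reps": bundle.config.n_reps,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_analyzed": int(len(bundle.analysis.data)),
        "n_by_arm": bundle.analysis.data["arm"].value_counts().to_dict(),
        "sections": sections,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
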