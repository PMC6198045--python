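"""Tabular and file output for model runs.

Writers produce tidy CSV/JSON artefacts (cohort traces, base-case
cost/outcome tables, tornado tables, PSA scatters, CEAC curves) plus a
run manifest recording exactly what produced each output directory.
Optional matplotlib figures accompany the CSVs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .economics import ICERResult, classify_quadrant
from .sensitivity import CEACCurve, PSAScatter, TornadoTable, quadrant_shares
from .simulation import CohortTrace, SimulationResult
from .states import ARM_LABELS, STATE_LABELS, Arm, StateId

__all__ = ["basecase_table", "icer_report_dict", "write_manifest", "write_trace_csv",
           "write_tornado_csv", "write_scatter_csv", "write_ceac_csv",
           "plot_tornado", "plot_ce_plane", "plot_ceac"]

_COST_ROWS = [("Drug", "drug"), ("BPH", "bph"), ("AUR", "aur"), ("TURP", "turp"),
              ("Medical intervention", "medical")]
_EPISODE_ROWS = [("BPH", "bph_years"), ("AUR", "aur_episodes"),
                 ("TURP", "turp_procedures"), ("Death", "deaths")]


def basecase_table(icer: ICERResult) -> pd.DataFrame:
    """Cost-decomposition / episode / QALY table for both arms plus the
    difference column (layout of the published base-case results)."""
    rc, rm = icer.combination, icer.monotherapy
    rows = []
    for label, key in _COST_ROWS:
        a, b = rc.cost_breakdown[key], rm.cost_breakdown[key]
        rows.append(("Cost (US$ 2018)", label, a, b, a - b))
    fu = rc.cost_breakdown.get("recovery_followup", 0.0), rm.cost_breakdown.get("recovery_followup", 0.0)
    if any(fu):
        rows.append(("Cost (US$ 2018)", "Recovery follow-up", fu[0], fu[1], fu[0] - fu[1]))
    for label, key in _EPISODE_ROWS:
        a, b = rc.episodes[key], rm.episodes[key]
        rows.append(("Episodes", label, a, b, a - b))
    rows.append(("Outcome", "QALY", rc.total_qaly, rm.total_qaly, icer.delta_qaly))
    rows.append(("Outcome", "Total cost", rc.total_cost, rm.total_cost, icer.delta_cost))
    df = pd.DataFrame(rows, columns=["section", "row",
                                     ARM_LABELS[Arm.COMBINATION],
                                     ARM_LABELS[Arm.MONOTHERAPY],
                                     "Difference"])
    return df


def icer_report_dict(icer: ICERResult) -> dict:
    """JSON-ready ICER summary keyed like the base-case table rows."""
    rc, rm = icer.combination, icer.monotherapy
    return {
        "horizon_years": rc.horizon_years,
        "cost": {label: {"combination": rc.cost_breakdown[key],
                         "monotherapy": rm.cost_breakdown[key],
                         "difference": rc.cost_breakdown[key] - rm.cost_breakdown[key]}
                 for label, key in _COST_ROWS},
        "episodes": {label: {"combination": rc.episodes[key],
                             "monotherapy": rm.episodes[key],
                             "difference": rc.episodes[key] - rm.episodes[key]}
                     for label, key in _EPISODE_ROWS},
        "qaly": {"combination": rc.total_qaly, "monotherapy": rm.total_qaly,
                 "difference": icer.delta_qaly},
        "total_cost": {"combination": rc.total_cost, "monotherapy": rm.total_cost,
                       "difference": icer.delta_cost},
        "icer": icer.icer,
        "label": icer.label,
    }


def write_manifest(out_dir: Path, subcommand: str, config_text: str,
                   seed=None, horizon=None, n=None, engine=None) -> Path:
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": seed,
        "horizon": horizon,
        "n": n,
        "engine": engine,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "package_version": __version__,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def write_trace_csv(trace: CohortTrace, arm: Arm, path: Path) -> None:
    """Tidy per-cycle trace: cycle, state, occupancy (+ per-cycle
    discounted cost and QALY increments on the state rows)."""
    T = trace.occupancy.shape[0]
    rows = []
    for t in range(T):
        for s in StateId:
            rows.append({"cycle": t, "arm": ARM_LABELS[arm],
                         "state": STATE_LABELS[s],
                         "occupancy": trace.occupancy[t, s]})
    df = pd.DataFrame(rows)
    inc = pd.DataFrame({"cycle": range(T - 1),
                        "cost_increment": trace.cost_increments,
                        "qaly_increment": trace.qaly_increments})
    df = df.merge(inc, on="cycle", how="left")
    df.to_csv(path, index=False)


def write_tornado_csv(table: TornadoTable, path: Path) -> None:
    df = pd.DataFrame([{"parameter": e.parameter, "low": e.low, "high": e.high,
                        "icer_low": e.icer_at_low, "icer_high": e.icer_at_high,
                        "spread": e.spread} for e in table.entries])
    df.to_csv(path, index=False)


def write_scatter_csv(scatter: PSAScatter, path: Path) -> None:
    df = pd.DataFrame({
        "draw": np.arange(scatter.n),
        "delta_cost": scatter.delta_cost,
        "delta_qaly": scatter.delta_qaly,
        "quadrant": [classify_quadrant(c, e)
                     for c, e in zip(scatter.delta_cost, scatter.delta_qaly)],
    })
    df.to_csv(path, index=False)


def read_scatter_csv(path: Path) -> PSAScatter:
    df = pd.read_csv(path)
    return PSAScatter(delta_cost=df["delta_cost"].to_numpy(),
                      delta_qaly=df["delta_qaly"].to_numpy(),
                      seed=-1, horizon_years=0)


def write_ceac_csv(curve: CEACCurve, path: Path) -> None:
    pd.DataFrame({"wtp": curve.wtp, "probability": curve.probability}).to_csv(
        path, index=False)


def quadrant_summary_dict(scatter: PSAScatter) -> dict:
    shares = quadrant_shares(scatter)
    shares["n"] = scatter.n
    shares["n_resampled"] = scatter.n_resampled
    return shares


# --------------------------------------------------------------------------
# optional plots
# --------------------------------------------------------------------------

def _mpl():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_tornado(table: TornadoTable, path: Path, top: int = 15) -> None:
    plt = _mpl()
    entries = [e for e in table.entries if np.isfinite(e.spread)][:top][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(entries) + 1.5))
    for i, e in enumerate(entries):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(i, hi - lo, left=lo, color="#4878d0")
    ax.axvline(table.base_icer, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.parameter for e in entries], fontsize=8)
    ax.set_xlabel("ICER (US$/QALY)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ce_plane(scatter: PSAScatter, path: Path) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(scatter.delta_qaly, scatter.delta_cost, s=4, alpha=0.3)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (US$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: CEACCurve, path: Path) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp, curve.probability)
    ax.set_xlabel("Willingness to pay (US$/QALY)")
    ax.set_ylabel("P(combination cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
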