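"""Render the replicate-study summaries: error-bar panels, correlations, table.

One figure per noise level mirrors the study layout (rows = true model,
columns = dDIC / dMSE against the true model, symbols = fitted model), plus
one correlation figure and a markdown summary table. Every figure's plotted
numbers are also written as a CSV so the graphics regenerate exactly.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .experiment import delta_summaries, dic_mse_correlation

_MARKERS = {"M1": "o", "M2": "s", "M3": "^"}
_OFFSETS = {"M1": -0.12, "M2": 0.0, "M3": 0.12}


def _errorbar_panel(ax, summ: pd.DataFrame, true_model: str, metric: str) -> None:
    sub = summ[summ["true_model"] == true_model]
    if sub.empty:
        ax.text(0.5, 0.5, "insufficient replicates", ha="center", va="center",
                transform=ax.transAxes)
        return
    r_values = sorted(sub["r"].unique())
    pos = {r: i for i, r in enumerate(r_values)}
    for fit_model, grp in sub.groupby("fit_model"):
        x = [pos[r] + _OFFSETS[fit_model] for r in grp["r"]]
        ax.errorbar(
            x, grp[f"mean_d{metric}"], yerr=grp[f"sd_d{metric}"],
            fmt=_MARKERS[fit_model], capsize=3, label=fit_model, linestyle="none",
        )
    ax.axhline(0.0, linestyle="--", color="grey", linewidth=0.8)
    ax.set_xticks(range(len(r_values)), [f"r={r:g}" for r in r_values])
    ax.set_ylabel(f"Δ{metric} vs true")
    ax.set_title(f"true model {true_model}")


def render_report(records: pd.DataFrame, out_dir) -> list[Path]:
    """Write all figures, their data CSVs and a markdown summary table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summ = delta_summaries(records)
    corr = dic_mse_correlation(records)
    if summ.empty:
        raise ValueError("no summaries to render")
    written: list[Path] = []

    for p, df in (("delta_summaries.csv", summ), ("dic_mse_correlation.csv", corr)):
        path = out_dir / p
        df.to_csv(path, index=False)
        written.append(path)

    for level in summ["noise_level"].unique():
        sub = summ[summ["noise_level"] == level]
        true_models = sorted(sub["true_model"].unique())
        fig, axes = plt.subplots(
            len(true_models), 2, figsize=(9, 2.8 * len(true_models)), squeeze=False
        )
        for i, tm in enumerate(true_models):
            _errorbar_panel(axes[i][0], sub, tm, "DIC")
            _errorbar_panel(axes[i][1], sub, tm, "MSE")
        axes[0][0].legend(fontsize=8)
        fig.suptitle(f"{level} noise: differences against the true model")
        fig.tight_layout()
        path = out_dir / f"errorbars_{level}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    fig, ax = plt.subplots(figsize=(7, 4))
    for (tm, level), grp in corr.groupby(["true_model", "noise_level"]):
        grp = grp.sort_values("r")
        ax.plot(grp["r"], grp["rho"], marker=_MARKERS[tm], label=f"{tm}/{level}")
    ax.axhline(0.0, linestyle="--", color="grey", linewidth=0.8)
    ax.set_xlabel("r")
    ax.set_ylabel("DIC-MSE correlation")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    path = out_dir / "dic_mse_correlation.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    md = out_dir / "summary.md"
    with open(md, "w") as fh:
        fh.write("# Replicate-study summary\n\n## ΔDIC / ΔMSE vs true model\n\n")
        fh.write(summ.round(3).to_markdown(index=False))
        fh.write("\n\n## DIC-MSE correlation per generating condition\n\n")
        fh.write(corr.round(3).to_markdown(index=False))
        fh.write("\n")
    written.append(md)
    return written
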