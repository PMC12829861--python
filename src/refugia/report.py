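"""Plain-text (and optional plot) rendering of pipeline outputs.

Formatting only: every number in the report is computed upstream.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from .classify import SummaryTable

__all__ = ["render_report"]

_ARROW = {"positive": "+", "negative": "-", "none": "0"}


def _species_table(table: SummaryTable) -> str:
    header = f"{'Species':<26}{'Occupied':>9}{'At risk':>9}{'% risk':>8}{'In situ':>9}{'Ex situ':>9}"
    lines = [header, "-" * len(header)]
    for r in table.rows:
        pct = f"{r.pct_at_risk:.1f}" if r.pct_at_risk is not None else "--"
        lines.append(
            f"{r.species_id:<26}{r.n_occupied:>9}{r.n_at_risk:>9}{pct:>8}"
            f"{r.n_in_situ:>9}{r.n_ex_situ:>9}"
        )
    a = table.averages
    lines.append(
        f"{'Average':<26}{a['n_occupied']:>9}{a['n_at_risk']:>9}"
        f"{a['pct_at_risk']:>8}{a['n_in_situ']:>9}{a['n_ex_situ']:>9}"
    )
    lines.append("")
    lines.append(f"Ex situ share of refugia: {table.pct_ex_situ_of_refugia}%")
    lines.append(
        f"Retention of occupied PAs: mean {table.mean_retention_pct}% "
        f"(pooled {table.pooled_retention_pct}%)"
    )
    return "\n".join(lines)


def _model_section(name: str, res) -> str:
    title = f"Count model: species with {name.replace('_', ' ')} refugia per PA"
    if res is None:
        return f"{title}\n  not fitted (no refugia of this type)\n"
    summ = res.summary()
    lines = [title, "-" * len(title)]
    lines.append(
        f"{'Parameter':<22}{'Mean':>8}{'SD':>8}{'Lower':>8}{'Upper':>8}{'Rhat':>7}  Effect"
    )
    sig = res.significance_table()
    for pname, row in summ.iterrows():
        arrow = _ARROW.get(sig.get(str(pname), ""), " ")
        lines.append(
            f"{pname:<22}{row['mean']:>8.3f}{row['sd']:>8.3f}"
            f"{row['lower']:>8.3f}{row['upper']:>8.3f}{row['rhat']:>7.3f}  {arrow}"
        )
    if not res.converged:
        lines.append("  WARNING: split-Rhat > 1.05 for some parameters (not converged)")
    lines.append("")
    return "\n".join(lines)


def render_report(
    table: SummaryTable,
    results: Mapping[str, object],
    make_plots: bool = False,
    outdir: str | Path | None = None,
) -> str:
    """Human-readable summary of the classification and the two count models."""
    parts = [
        "Climate-refugia screening of protected areas",
        "=" * 44,
        "",
        _species_table(table),
        "",
    ]
    for mode in ("in_situ", "ex_situ"):
        parts.append(_model_section(mode, results.get(mode)))

    if make_plots and outdir is not None:
        _forest_plots(results, Path(outdir))
        parts.append("Forest plots written alongside this report.")
    return "\n".join(parts)


def _forest_plots(results: Mapping[str, object], outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for mode, res in results.items():
        if res is None:
            continue
        summ = res.summary().drop(index=["intercept", "gp_sigma", "gp_rho"], errors="ignore")
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ypos = range(len(summ))
        ax.errorbar(
            summ["mean"],
            list(ypos),
            xerr=[summ["mean"] - summ["lower"], summ["upper"] - summ["mean"]],
            fmt="o",
            capsize=3,
        )
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_yticks(list(ypos))
        ax.set_yticklabels(summ.index)
        ax.set_xlabel("posterior mean and 95% CI")
        ax.set_title(f"{mode.replace('_', ' ')} refugia count model")
        fig.tight_layout()
        fig.savefig(outdir / f"forest_{mode}.png", dpi=150)
        plt.close(fig)
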