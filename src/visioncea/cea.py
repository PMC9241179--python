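"""Incremental cost-effectiveness comparison of the two strategies.

The primary outcome is the ICER — incremental cost divided by incremental
QALYs — reported only when the comparison is a genuine trade-off; a strategy
that is cheaper and at least as effective dominates, one that is costlier
and no more effective is dominated.  Net monetary benefit at a
willingness-to-pay threshold λ is ``λ·ΔE − ΔC``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model_config import ValidationError
from .outcomes import StrategyResult

__all__ = ["CEAResult", "compare", "budget_impact", "run_comparison"]


@dataclass
class CEAResult:
    """Incremental results of gene therapy (VN) versus standard of care."""

    vn: StrategyResult
    soc: StrategyResult
    threshold: float
    incremental_cost: float
    incremental_cost_undiscounted: float
    incremental_qalys: float
    incremental_blindness_free_years: float
    status: str  # tradeoff | dominant | dominated | equivalent

    @property
    def icer(self) -> float | None:
        """CHF per QALY gained; None unless the comparison is a trade-off."""
        if self.status != "tradeoff":
            return None
        return self.incremental_cost / self.incremental_qalys

    @property
    def icer_per_blindness_free_year(self) -> float | None:
        if self.status != "tradeoff" or self.incremental_blindness_free_years == 0:
            return None
        return self.incremental_cost / self.incremental_blindness_free_years

    @property
    def net_monetary_benefit(self) -> float:
        return self.threshold * self.incremental_qalys - self.incremental_cost

    def summary_text(self) -> str:
        """Plain-text summary mirroring the per-patient results table layout."""
        lines = [
            f"Perspective: {self.vn.perspective}",
            f"{'':38s}{'SoC':>12s}{'VN':>12s}{'Difference':>12s}",
            _row("Blindness-free years",
                 self.soc.blindness_free_years, self.vn.blindness_free_years),
            _row("QALYs", self.soc.qalys, self.vn.qalys),
            _row("Total costs (CHF)",
                 self.soc.total_cost, self.vn.total_cost, money=True),
            f"Status: {self.status}",
        ]
        if self.status == "tradeoff":
            lines.append(f"ICER (CHF per QALY gained): {round(self.icer):,}")
            if self.icer_per_blindness_free_year is not None:
                lines.append(
                    "ICER (CHF per blindness-free year gained): "
                    f"{round(self.icer_per_blindness_free_year):,}"
                )
        lines.append(
            f"NMB at CHF {self.threshold:,.0f}/QALY: "
            f"{self.net_monetary_benefit:,.0f}"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "perspective": self.vn.perspective,
            "vn_cost": self.vn.total_cost,
            "soc_cost": self.soc.total_cost,
            "incremental_cost": self.incremental_cost,
            "incremental_cost_undiscounted": self.incremental_cost_undiscounted,
            "vn_qalys": self.vn.qalys,
            "soc_qalys": self.soc.qalys,
            "incremental_qalys": self.incremental_qalys,
            "incremental_blindness_free_years": self.incremental_blindness_free_years,
            "status": self.status,
            "icer": self.icer,
            "icer_per_blindness_free_year": self.icer_per_blindness_free_year,
            "nmb": self.net_monetary_benefit,
            "threshold": self.threshold,
        }


def _row(label: str, soc: float, vn: float, money: bool = False) -> str:
    fmt = (lambda x: f"{x:>12,.0f}") if money else (lambda x: f"{x:>12.2f}")
    return f"{label:38s}{fmt(soc)}{fmt(vn)}{fmt(vn - soc)}"


def compare(
    vn: StrategyResult, soc: StrategyResult, threshold: float = 100_000.0
) -> CEAResult:
    """Build the incremental comparison (increments are VN − SoC).

    Both results must come from the same settings and perspective.
    """
    if vn.perspective != soc.perspective:
        raise ValidationError("compare: results computed under different perspectives")
    d_cost = vn.total_cost - soc.total_cost
    d_cost_u = vn.total_cost_undiscounted - soc.total_cost_undiscounted
    d_e = vn.qalys - soc.qalys
    d_bfy = vn.blindness_free_years - soc.blindness_free_years
    if d_cost == 0 and d_e == 0:
        status = "equivalent"
    elif d_cost <= 0 and d_e >= 0:
        status = "dominant"
    elif d_cost >= 0 and d_e <= 0:
        status = "dominated"
    else:
        status = "tradeoff"
    return CEAResult(
        vn=vn,
        soc=soc,
        threshold=threshold,
        incremental_cost=d_cost,
        incremental_cost_undiscounted=d_cost_u,
        incremental_qalys=d_e,
        incremental_blindness_free_years=d_bfy,
        status=status,
    )


def budget_impact(per_patient_undiscounted_incremental: float, n_patients: int) -> float:
    """Lifetime budget impact: undiscounted incremental cost per patient
    times the number of eligible patients."""
    if n_patients < 0:
        raise ValidationError("budget_impact: n_patients must be >= 0")
    return per_patient_undiscounted_incremental * n_patients


def run_comparison(config, utilities=None) -> CEAResult:
    """Run both arms under ``config`` and compare them.

    Convenience wrapper used by scenarios, sensitivity analysis and the CLI;
    a shared matrix cache avoids recomputing the common long-term matrices.
    """
    from .markov_engine import run_trace
    from .outcomes import evaluate_strategy

    cache: dict = {}
    results = {}
    for strategy in ("VN", "SoC"):
        trace = run_trace(strategy, config, cache=cache)
        results[strategy] = evaluate_strategy(trace, config, utilities=utilities)
    return compare(
        results["VN"], results["SoC"], threshold=config.settings.wtp_threshold
    )


def results_frame(results: dict[str, CEAResult]) -> pd.DataFrame:
    """Tabulate named comparisons in results-table column order."""
    rows = []
    for name, r in results.items():
        rows.append(
            (
                name,
                r.vn.total_cost,
                r.soc.total_cost,
                r.incremental_cost,
                r.vn.qalys,
                r.soc.qalys,
                r.incremental_qalys,
                r.icer,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scenario", "vn_cost", "soc_cost", "incremental_cost",
            "vn_qalys", "soc_qalys", "incremental_qalys", "icer",
        ],
    )
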