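"""Multi-exposure MR screening with Bonferroni multiplicity control.

Drives the three study screens — the candidate-gene screen (single-
instrument Wald ratios permitted), the immune-cell-subset screen and the
metabolome-wide screen (both requiring at least three instruments) — and
assigns each exposure a tier: ``significant`` (below the Bonferroni
threshold α/n_tests over the feasible exposures), ``suggestive`` (nominal
only), ``null``, or ``infeasible``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .instruments import InstrumentConfig, LDMatrix, select_instruments
from .mr import MREstimate, SensitivityReport, ivw, sensitivity, wald_ratio
from .sumstats import SummaryDataset, retained


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class ScreenResult:
    exposure_label: str
    estimate: Optional[MREstimate]
    sensitivity: Optional[SensitivityReport]
    n_tests: int
    bonferroni_threshold: float
    tier: str  # significant | suggestive | null | infeasible


def _tier(pvalue: float, threshold: float, alpha: float) -> str:
    if pvalue < threshold:
        return "significant"
    if pvalue < alpha:
        return "suggestive"
    return "null"


def run_screen(
    exposures: Sequence[SummaryDataset],
    outcome: SummaryDataset,
    ld: LDMatrix,
    cfg: InstrumentConfig = InstrumentConfig(),
    alpha: float = 0.05,
    allow_wald: bool = True,
) -> list[ScreenResult]:
    """Screen many exposures against one outcome.

    Per exposure: significance filter → clump → F filter → harmonize (with
    proxies) → IVW (or single-instrument Wald ratio when ``allow_wald``) →
    sensitivity analysis when at least three instruments remain. The
    Bonferroni denominator counts feasible exposures only; an exposure is
    infeasible with fewer than ``cfg.min_instruments`` instruments (fewer
    than one under ``allow_wald``). Output ordering is deterministic:
    ascending p-value, then label.
    """
    if not exposures:
        raise ValueError("exposures must be nonempty")
    fitted: list[tuple[str, Optional[MREstimate], Optional[SensitivityReport]]] = []
    min_needed = 1 if allow_wald else cfg.min_instruments
    for exp in exposures:
        try:
            pairs = retained(select_instruments(exp, outcome, ld, cfg))
        except Exception:
            pairs = []
        if len(pairs) < min_needed:
            fitted.append((exp.trait_label, None, None))
            continue
        est = wald_ratio(pairs[0]) if len(pairs) == 1 else ivw(pairs)
        sens = sensitivity(pairs) if len(pairs) >= 3 else None
        fitted.append((exp.trait_label, est, sens))

    n_tests = sum(1 for _, est, _ in fitted if est is not None)
    threshold = bonferroni_threshold(alpha, max(n_tests, 1))
    results = []
    for label, est, sens in fitted:
        if est is None:
            results.append(ScreenResult(label, None, None, n_tests, threshold, "infeasible"))
        else:
            results.append(ScreenResult(label, est, sens, n_tests, threshold,
                                        _tier(est.pvalue, threshold, alpha)))
    results.sort(key=lambda r: (r.estimate.pvalue if r.estimate else float("inf"),
                                r.exposure_label))
    return results


def screen_to_frame(results: Sequence[ScreenResult], outcome_label: str = "outcome") -> pd.DataFrame:
    """Forest-plot-ready tidy table for a screen."""
    rows = []
    for r in results:
        e = r.estimate
        rows.append({
            "exposure": r.exposure_label,
            "outcome": outcome_label,
            "method": e.method if e else "",
            "nsnp": e.n_snp if e else 0,
            "beta": e.beta if e else float("nan"),
            "se": e.se if e else float("nan"),
            "or": e.or_value if e else float("nan"),
            "ci_low": e.ci_low if e else float("nan"),
            "ci_high": e.ci_high if e else float("nan"),
            "pvalue": e.pvalue if e else float("nan"),
            "n_tests": r.n_tests,
            "bonferroni_threshold": r.bonferroni_threshold,
            "tier": r.tier,
            "q_pvalue": r.sensitivity.q_pvalue if r.sensitivity else float("nan"),
            "egger_intercept_pvalue": (
                r.sensitivity.egger_intercept_pvalue if r.sensitivity else float("nan")
            ),
        })
    return pd.DataFrame(rows)
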