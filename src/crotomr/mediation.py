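"""Two-step summary-statistics mediation along exposure → mediator → disease.

Step 1 estimates the exposure→mediator effect (β1) by MR with the exposure's
instruments; step 2 estimates the mediator→outcome effect (β2) with the
mediator's own instruments. The indirect effect is β1·β2, its standard error
the first-order Delta approximation sqrt(β1²·SE2² + β2²·SE1²), and the
proportion mediated is the ratio of the indirect effect to the total
exposure→outcome IVW estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats as sps

from .instruments import InstrumentConfig, LDMatrix, select_instruments
from .mr import InsufficientInstrumentsError, MREstimate, ivw, wald_ratio
from .sumstats import SummaryDataset, retained


@dataclass
class MediationResult:
    beta1: float
    se1: float
    beta2: float
    se2: float
    indirect: float
    indirect_se: float
    z: float
    pvalue: float
    ci_low: float
    ci_high: float
    total: float
    proportion: Optional[float]
    flag: str = ""  # "", "sign-discordant", "total-zero", "infeasible"


def mediate(beta1: float, se1: float, beta2: float, se2: float,
            total: float, level: float = 0.95) -> MediationResult:
    """Product-of-coefficients mediation with first-order Delta inference.

    ``total`` is the exposure→outcome estimate; the mediated proportion is
    indirect/total, reported verbatim with a ``sign-discordant`` flag when
    the indirect and total effects oppose each other.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("leg standard errors must be > 0")
    indirect = beta1 * beta2
    indirect_se = math.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2)
    if indirect_se > 0:
        z = indirect / indirect_se
        pvalue = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    else:
        z, pvalue = 0.0, 1.0
    zq = sps.norm.ppf((1 + level) / 2)
    ci_low = indirect - zq * indirect_se
    ci_high = indirect + zq * indirect_se
    if total == 0:
        proportion, flag = None, "total-zero"
    else:
        proportion = indirect / total
        flag = "sign-discordant" if proportion < 0 else ""
    return MediationResult(beta1, se1, beta2, se2, indirect, indirect_se,
                           z, max(pvalue, 1e-300), ci_low, ci_high, total, proportion, flag)


def _leg_estimate(exposure: SummaryDataset, outcome: SummaryDataset,
                  ld: LDMatrix, cfg: InstrumentConfig) -> Optional[MREstimate]:
    """One MR leg: full selection chain then IVW (Wald ratio for a single
    instrument). None when no usable instrument survives."""
    pairs = retained(select_instruments(exposure, outcome, ld, cfg))
    if not pairs:
        return None
    if len(pairs) == 1:
        return wald_ratio(pairs[0])
    return ivw(pairs)


def mediation_screen(
    exposure: SummaryDataset,
    mediators: Sequence[SummaryDataset],
    outcome: SummaryDataset,
    ld: LDMatrix,
    cfg: InstrumentConfig = InstrumentConfig(),
) -> pd.DataFrame:
    """Two-step mediation over a panel of candidate mediators.

    Runs exposure→mediator (step 1) and mediator→outcome (step 2) per
    mediator, combines with the exposure→outcome total, and returns one row
    per mediator sorted by p-value. Legs with no usable instruments yield a
    row flagged ``infeasible`` rather than failing the screen.
    """
    total_est = _leg_estimate(exposure, outcome, ld, cfg)
    if total_est is None:
        raise InsufficientInstrumentsError("no instruments for the exposure→outcome total")
    rows = []
    for med in mediators:
        step1 = _leg_estimate(exposure, med, ld, cfg)
        step2 = _leg_estimate(med, outcome, ld, cfg)
        base = {"exposure": exposure.trait_label, "mediator": med.trait_label,
                "outcome": outcome.trait_label}
        if step1 is None or step2 is None:
            rows.append({**base, "beta1": float("nan"), "se1": float("nan"),
                         "beta2": float("nan"), "se2": float("nan"),
                         "indirect": float("nan"), "indirect_se": float("nan"),
                         "z": float("nan"), "pvalue": float("nan"),
                         "ci_low": float("nan"), "ci_high": float("nan"),
                         "total": total_est.beta, "proportion": float("nan"),
                         "flag": "infeasible"})
            continue
        res = mediate(step1.beta, step1.se, step2.beta, step2.se, total_est.beta)
        rows.append({**base, "beta1": res.beta1, "se1": res.se1,
                     "beta2": res.beta2, "se2": res.se2,
                     "indirect": res.indirect, "indirect_se": res.indirect_se,
                     "z": res.z, "pvalue": res.pvalue,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "total": res.total,
                     "proportion": res.proportion if res.proportion is not None else float("nan"),
                     "flag": res.flag})
    df = pd.DataFrame(rows)
    return df.sort_values("pvalue", na_position="last", kind="mergesort").reset_index(drop=True)
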