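"""Two-sample MR estimators and sensitivity statistics on harmonized pairs.

Estimators operate on per-variant ratio estimates theta_j = b_Yj / b_Xj with
first-order inverse-variance weights w_j = b_Xj² / s_Yj²:

* :func:`wald_ratio` — single-instrument estimate b_Y/b_X.
* :func:`ivw` — inverse-variance weighted mean of the ratios, equivalent to
  weighted regression of outcome on exposure effects through the origin;
  multiplicative random-effects by default (SE inflated by
  max(1, sqrt(Q/(k-1)))).
* :func:`egger` — weighted regression with a free intercept; the intercept is
  the directional-pleiotropy test.
* :func:`weighted_median` / :func:`weighted_mode` — pleiotropy-robust
  estimators with parametric-bootstrap standard errors.
* :func:`cochran_q`, :func:`leave_one_out` — heterogeneity and influence
  diagnostics.

The statsmodels-style facade :class:`MRModel` wraps the same functions:
``MRModel(pairs).fit(method="ivw")`` returns an :class:`MRResults` carrying
the estimate, its uncertainty, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import HarmonizedPair, retained

_PMIN = 1e-300  # p-values are reported in (0,1]


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the estimator requires."""


class UndefinedRatioError(ZeroDivisionError):
    """An exposure beta of zero makes the ratio estimate undefined."""


@dataclass(frozen=True)
class MREstimate:
    """A causal estimate on the log-odds scale plus its exponentiated form."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int
    or_value: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")


@dataclass
class SensitivityReport:
    """Heterogeneity, pleiotropy and influence diagnostics for one analysis."""

    q_statistic: float
    q_df: int
    q_pvalue: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pvalue: float
    leave_one_out: pd.DataFrame  # index: omitted variant_id


def _two_sided_normal_p(z: float) -> float:
    return max(_PMIN, min(1.0, 2.0 * sps.norm.sf(abs(z))))


def or_from_beta(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate into (OR, CI low, CI high)."""
    if se <= 0:
        raise ValueError("se must be > 0")
    if not (0 < level < 1):
        raise ValueError("level must be in (0,1)")
    z = sps.norm.ppf((1 + level) / 2)
    return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se)


def p_from_or_ci(
    or_value: float, ci_low: float, ci_high: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Recover (SE on the log scale, z, two-sided p) from a printed OR and CI."""
    if not (0 < ci_low <= or_value <= ci_high):
        raise ValueError("CI must bracket the OR with 0 < ci_low")
    z_q = sps.norm.ppf((1 + level) / 2)
    se_log = (math.log(ci_high) - math.log(ci_low)) / (2 * z_q)
    z = math.log(or_value) / se_log
    return se_log, z, _two_sided_normal_p(z)


def _estimate(method: str, beta: float, se: float, pvalue: float, n_snp: int,
              level: float = 0.95) -> MREstimate:
    orv, lo, hi = or_from_beta(beta, se, level) if se > 0 else (math.exp(beta),) * 3
    return MREstimate(method, beta, se, pvalue, n_snp, orv, lo, hi)


def _ratio_arrays(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant ratios and first-order inverse-variance weights."""
    kept = retained(pairs)
    bx = np.array([p.beta_exposure for p in kept])
    by = np.array([p.beta_outcome for p in kept])
    sy = np.array([p.se_outcome for p in kept])
    if np.any(bx == 0):
        raise UndefinedRatioError("beta_exposure = 0 makes the ratio undefined")
    return by / bx, bx**2 / sy**2


def wald_ratio(pair: HarmonizedPair, second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate b_Y / b_X.

    SE is the first-order approximation s_Y/|b_X|; ``second_order`` adds the
    b_Y²·s_X²/b_X⁴ term.
    """
    if pair.beta_exposure == 0:
        raise UndefinedRatioError("beta_exposure = 0")
    beta = pair.beta_outcome / pair.beta_exposure
    var = (pair.se_outcome / pair.beta_exposure) ** 2
    if second_order:
        var += pair.beta_outcome**2 * pair.se_exposure**2 / pair.beta_exposure**4
    se = math.sqrt(var)
    p = _two_sided_normal_p(beta / se)
    return _estimate("wald_ratio", beta, se, p, 1)


def ivw(pairs: Sequence[HarmonizedPair], random_effects: bool = True) -> MREstimate:
    """Inverse-variance weighted estimate over >= 2 instruments.

    Default is the multiplicative random-effects model: the fixed-effect SE
    1/sqrt(sum w_j) is inflated by max(1, sqrt(Q/(k-1))).
    """
    theta, w = _ratio_arrays(pairs)
    k = theta.size
    if k < 2:
        raise InsufficientInstrumentsError("ivw requires >= 2 instruments (use wald_ratio)")
    beta = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    if random_effects:
        q = float(np.sum(w * (theta - beta) ** 2))
        se *= max(1.0, math.sqrt(q / (k - 1)))
    p = _two_sided_normal_p(beta / se)
    return _estimate("ivw", beta, se, p, k)


def cochran_q(pairs: Sequence[HarmonizedPair], pooled: MREstimate) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic around a pooled estimate."""
    theta, w = _ratio_arrays(pairs)
    if theta.size < 2:
        raise InsufficientInstrumentsError("Q requires >= 2 instruments")
    q = float(np.sum(w * (theta - pooled.beta) ** 2))
    df = theta.size - 1
    return q, df, float(max(_PMIN, sps.chi2.sf(q, df)))


def egger(pairs: Sequence[HarmonizedPair]) -> tuple[MREstimate, float, float, float]:
    """MR-Egger weighted regression with a free intercept.

    Each pair is oriented so that b_X >= 0 (both betas flipped otherwise),
    then b_Y is regressed on b_X with weights 1/s_Y²; the slope is the causal
    estimate and the intercept, with its t(k-2) test, measures directional
    pleiotropy. Both SEs are inflated by max(1, sqrt(Q_egger/(k-2))).

    Returns (slope estimate, intercept, intercept SE, intercept p).
    """
    kept = retained(pairs)
    k = len(kept)
    if k < 3:
        raise InsufficientInstrumentsError("egger requires >= 3 instruments")
    bx = np.array([p.beta_exposure for p in kept])
    by = np.array([p.beta_outcome for p in kept])
    sy = np.array([p.se_outcome for p in kept])
    flip = np.where(bx < 0, -1.0, 1.0)
    x, y, w = bx * flip, by * flip, 1.0 / sy**2
    # weighted normal equations for y = a + b x
    sw, swx, swx2 = w.sum(), (w * x).sum(), (w * x * x).sum()
    swy, swxy = (w * y).sum(), (w * x * y).sum()
    det = sw * swx2 - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swx2 * swy - swx * swxy) / det
    resid = y - intercept - slope * x
    q_e = float(np.sum(w * resid**2))
    inflation = max(1.0, math.sqrt(q_e / (k - 2)))
    se_slope = math.sqrt(sw / det) * inflation
    se_int = math.sqrt(swx2 / det) * inflation
    p_slope = max(_PMIN, min(1.0, 2.0 * sps.t.sf(abs(slope / se_slope), k - 2)))
    p_int = max(_PMIN, min(1.0, 2.0 * sps.t.sf(abs(intercept / se_int), k - 2)))
    est = _estimate("egger", float(slope), float(se_slope), p_slope, k)
    return est, float(intercept), float(se_int), p_int


def _parametric_bootstrap_se(
    pairs: Sequence[HarmonizedPair],
    point_fn,
    n_boot: int,
    seed: int,
) -> float:
    """SD of the point estimate over resampled (b_X, b_Y) ~ N(b, s)."""
    kept = retained(pairs)
    rng = np.random.default_rng(seed)
    bx = np.array([p.beta_exposure for p in kept])
    sx = np.array([p.se_exposure for p in kept])
    by = np.array([p.beta_outcome for p in kept])
    sy = np.array([p.se_outcome for p in kept])
    draws = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0] = 1e-12
        draws[b] = point_fn(bys / bxs, bxs**2 / sy**2)
    return float(np.std(draws, ddof=1))


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    th, ws = theta[order], w[order]
    s = np.cumsum(ws)
    p = (s - ws / 2) / s[-1]
    return float(np.interp(0.5, p, th))


def weighted_median(
    pairs: Sequence[HarmonizedPair], n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator, consistent when >= 50% of weight is valid.

    Ratio estimates are sorted with inverse-variance weights; the estimate
    interpolates the cumulative weight fraction (S_j - w_j/2)/S_k at 0.5. SE
    by parametric bootstrap.
    """
    theta, w = _ratio_arrays(pairs)
    if theta.size < 3:
        raise InsufficientInstrumentsError("weighted_median requires >= 3 instruments")
    beta = _weighted_median_point(theta, w)
    se = _parametric_bootstrap_se(pairs, _weighted_median_point, n_boot, seed)
    p = _two_sided_normal_p(beta / se) if se > 0 else 1.0
    return _estimate("weighted_median", beta, se, p, theta.size)


def _mode_bandwidth(theta: np.ndarray, factor: float) -> float:
    sd = float(np.std(theta, ddof=1))
    iqr = float(np.subtract(*np.percentile(theta, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return factor * 0.9 * spread * theta.size ** (-1 / 5)


def _weighted_mode_point(theta: np.ndarray, w: np.ndarray,
                         factor: float = 1.0, n_grid: int = 512) -> float:
    h = _mode_bandwidth(theta, factor)
    if h == 0:
        return float(theta[0])
    grid = np.linspace(theta.min(), theta.max(), n_grid)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(
    pairs: Sequence[HarmonizedPair],
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-mode estimator: argmax of a weighted normal-kernel density
    over the ratio estimates, bandwidth 0.9·min(sd, iqr/1.34)·k^(-1/5) scaled
    by ``bandwidth_factor``, evaluated on a 512-point grid spanning the
    ratio range. SE by parametric bootstrap.
    """
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be > 0")
    theta, w = _ratio_arrays(pairs)
    if theta.size < 3:
        raise InsufficientInstrumentsError("weighted_mode requires >= 3 instruments")
    beta = _weighted_mode_point(theta, w, bandwidth_factor)
    se = _parametric_bootstrap_se(
        pairs, lambda t, wt: _weighted_mode_point(t, wt, bandwidth_factor), n_boot, seed
    )
    p = _two_sided_normal_p(beta / se) if se > 0 else 1.0
    return _estimate("weighted_mode", beta, se, p, theta.size)


def leave_one_out(pairs: Sequence[HarmonizedPair], random_effects: bool = True) -> pd.DataFrame:
    """IVW re-estimated omitting each instrument in turn.

    Flags omissions that change the sign of beta or push the estimate
    outside the all-instrument confidence interval.
    """
    kept = retained(pairs)
    if len(kept) < 3:
        raise InsufficientInstrumentsError("leave-one-out requires >= 3 instruments")
    full = ivw(kept, random_effects=random_effects)
    rows = []
    for i, omitted in enumerate(kept):
        sub = kept[:i] + kept[i + 1 :]
        est = ivw(sub, random_effects=random_effects) if len(sub) >= 2 else wald_ratio(sub[0])
        rows.append({
            "omitted": omitted.variant_id,
            "beta": est.beta, "se": est.se, "pvalue": est.pvalue,
            "or": est.or_value, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "sign_change": (est.beta * full.beta) < 0,
            "outside_full_ci": not (
                math.log(full.ci_low) <= est.beta <= math.log(full.ci_high)
            ),
        })
    return pd.DataFrame(rows).set_index("omitted")


def sensitivity(pairs: Sequence[HarmonizedPair]) -> SensitivityReport:
    """Cochran's Q, Egger intercept test and leave-one-out for one analysis."""
    pooled = ivw(pairs)
    q, df, qp = cochran_q(pairs, pooled)
    _, a, a_se, a_p = egger(pairs)
    return SensitivityReport(q, df, qp, a, a_se, a_p, leave_one_out(pairs))


# ---------------------------------------------------------------------------
# Model/Results facade


class MRModel:
    """Two-sample MR model over harmonized exposure/outcome pairs.

    Parameters
    ----------
    pairs
        Harmonized pairs; dropped pairs are excluded automatically.
    exposure, outcome
        Trait labels carried through to the results table.

    Examples
    --------
    >>> model = MRModel(pairs, exposure="DPF2", outcome="COAD")
    >>> res = model.fit()            # IVW (Wald ratio if a single instrument)
    >>> print(res.summary())
    """

    METHODS = ("wald_ratio", "ivw", "egger", "weighted_median", "weighted_mode")

    def __init__(self, pairs: Sequence[HarmonizedPair],
                 exposure: str = "exposure", outcome: str = "outcome"):
        self.pairs = retained(pairs)
        self.exposure = exposure
        self.outcome = outcome

    @classmethod
    def from_datasets(cls, exposure, outcome, ld, cfg=None, **kw) -> "MRModel":
        """Build a model straight from summary datasets via the full
        instrument-selection chain."""
        from .instruments import InstrumentConfig, select_instruments

        cfg = cfg or InstrumentConfig()
        pairs = select_instruments(exposure, outcome, ld, cfg, **kw)
        return cls(pairs, exposure=exposure.trait_label, outcome=outcome.trait_label)

    @property
    def n_snp(self) -> int:
        return len(self.pairs)

    def fit(self, method: str = "ivw", **kwargs) -> "MRResults":
        if method == "ivw" and self.n_snp == 1:
            method = "wald_ratio"
        if method == "wald_ratio":
            if self.n_snp != 1:
                raise InsufficientInstrumentsError("wald_ratio needs exactly 1 instrument")
            est, extra = wald_ratio(self.pairs[0], **kwargs), {}
        elif method == "ivw":
            est, extra = ivw(self.pairs, **kwargs), {}
        elif method == "egger":
            est, a, a_se, a_p = egger(self.pairs)
            extra = {"intercept": a, "intercept_se": a_se, "intercept_pvalue": a_p}
        elif method == "weighted_median":
            est, extra = weighted_median(self.pairs, **kwargs), {}
        elif method == "weighted_mode":
            est, extra = weighted_mode(self.pairs, **kwargs), {}
        else:
            raise ValueError(f"unknown method {method!r}")
        return MRResults(self, est, extra)

    def fit_all(self, seed: int = 0) -> pd.DataFrame:
        """All applicable estimators as one tidy table."""
        rows = []
        methods = ["ivw"] if self.n_snp >= 2 else ["wald_ratio"]
        if self.n_snp >= 3:
            methods += ["egger", "weighted_median", "weighted_mode"]
        for m in methods:
            kw = {"seed": seed} if m in ("weighted_median", "weighted_mode") else {}
            rows.append(self.fit(m, **kw).row())
        return pd.DataFrame(rows)

    def sensitivity(self) -> SensitivityReport:
        return sensitivity(self.pairs)


class MRResults:
    """Results container for one fitted MR estimator."""

    def __init__(self, model: MRModel, estimate: MREstimate, extra: dict):
        self.model = model
        self.estimate = estimate
        self.extra = extra

    method = property(lambda self: self.estimate.method)
    beta = property(lambda self: self.estimate.beta)
    se = property(lambda self: self.estimate.se)
    pvalue = property(lambda self: self.estimate.pvalue)
    n_snp = property(lambda self: self.estimate.n_snp)
    or_value = property(lambda self: self.estimate.or_value)

    def conf_int(self) -> tuple[float, float]:
        return self.estimate.ci_low, self.estimate.ci_high

    def row(self) -> dict:
        d = {
            "exposure": self.model.exposure, "outcome": self.model.outcome,
            "method": self.method, "nsnp": self.n_snp, "beta": self.beta,
            "se": self.se, "or": self.or_value,
            "ci_low": self.estimate.ci_low, "ci_high": self.estimate.ci_high,
            "pvalue": self.pvalue,
        }
        d.update(self.extra)
        return d

    def summary(self) -> str:
        e = self.estimate
        lines = [
            f"MR results: {self.model.exposure} -> {self.model.outcome}",
            f"  method   : {e.method} (nsnp = {e.n_snp})",
            f"  beta (SE): {e.beta:.4f} ({e.se:.4f})",
            f"  OR, 95% CI: {e.or_value:.3f} ({e.ci_low:.3f}-{e.ci_high:.3f})",
            f"  p-value  : {e.pvalue:.3g}",
        ]
        if "intercept" in self.extra:
            lines.append(
                f"  intercept: {self.extra['intercept']:.4f} "
                f"(SE {self.extra['intercept_se']:.4f}, "
                f"p {self.extra['intercept_pvalue']:.3g})"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return f"<MRResults {self.method} beta={self.beta:.4f} p={self.pvalue:.3g}>"
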