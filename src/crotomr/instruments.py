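"""Instrument selection: significance filtering, greedy LD clumping,
F-statistic filtering, and high-LD proxy substitution.

The selection chain mirrors standard two-sample MR practice: keep variants
below the genome-wide threshold, clump them to approximate independence
(r-squared below the cutoff within a genomic window, greedily by p-value),
drop weak instruments by the per-SNP F approximation, and — when an
instrument is missing from the outcome — fall back to the best high-LD proxy
present there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .sumstats import HarmonizedPair, SummaryDataset, VariantAssociation, harmonize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InstrumentConfig:
    """Thresholds governing instrument selection.

    Defaults follow the conventional pipeline: genome-wide significance
    5e-8, clumping at r² < 0.1 within a 10,000 kb window, F > 10 weak-
    instrument filter, proxies at r² > 0.8, and a minimum of three
    instruments for analyses that require sensitivity statistics.
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.1
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    proxy_r2: float = 0.8
    min_instruments: int = 3
    palindromic_maf: float = 0.42

    def __post_init__(self) -> None:
        if not (0 < self.clump_r2 < 1):
            raise ValueError("clump_r2 must be in (0,1)")
        if not (0 < self.proxy_r2 < 1):
            raise ValueError("proxy_r2 must be in (0,1)")
        if self.f_min < 0:
            raise ValueError("f_min must be >= 0")
        if self.min_instruments < 1:
            raise ValueError("min_instruments must be >= 1")


class LDLookupError(KeyError):
    """A variant required for an LD operation is absent from the matrix."""


@dataclass
class LDMatrix:
    """Squared-correlation matrix over an ordered set of variants."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 shape {self.r2.shape} != ({k},{k})")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0,1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def lookup(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise LDLookupError(f"variant {exc.args[0]!r} not in LD matrix") from exc

    @classmethod
    def read_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column variant ids differ")
        return cls(variant_ids=[str(v) for v in df.columns], r2=df.to_numpy(dtype=float))

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t", float_format="%.10g"
        )


def f_statistic(v: VariantAssociation) -> float:
    """Per-SNP instrument-strength approximation (beta/se)²."""
    if v.se <= 0:
        raise ValueError("se must be > 0")
    return (v.beta / v.se) ** 2


def filter_by_f(dataset: SummaryDataset, f_min: float = 10.0) -> SummaryDataset:
    """Retain variants with F strictly greater than ``f_min``."""
    keep = [r.variant_id for r in dataset.records if f_statistic(r) > f_min]
    return dataset.subset(keep)


def clump(dataset: SummaryDataset, ld: LDMatrix, cfg: InstrumentConfig) -> SummaryDataset:
    """Greedy p-value clumping.

    Among variants passing ``cfg.p_threshold``, repeatedly retain the
    remaining variant with the smallest p-value (ties broken by variant_id)
    and remove every remaining variant on the same chromosome within
    ``clump_window_kb`` of it having r² >= ``clump_r2`` with it. The globally
    smallest-p variant is therefore always retained. Significant variants
    absent from the LD matrix are ignored with a warning.
    """
    sig = [r for r in dataset.records if r.pvalue < cfg.p_threshold]
    usable = []
    for r in sig:
        if r.variant_id in ld:
            usable.append(r)
        else:
            logger.warning("clump: %s significant but absent from LD matrix; ignored", r.variant_id)
    remaining = sorted(usable, key=lambda r: (r.pvalue, r.variant_id))
    window_bp = cfg.clump_window_kb * 1000.0
    retained_ids: list[str] = []
    while remaining:
        index = remaining.pop(0)
        retained_ids.append(index.variant_id)
        survivors = []
        for r in remaining:
            same_chrom = r.chromosome == index.chromosome
            close = abs(r.position - index.position) <= window_bp
            if same_chrom and close and ld.lookup(index.variant_id, r.variant_id) >= cfg.clump_r2:
                continue
            survivors.append(r)
        remaining = survivors
    return dataset.subset(retained_ids)


def find_proxy(
    target: str,
    outcome: SummaryDataset,
    ld: LDMatrix,
    cfg: InstrumentConfig,
) -> Optional[str]:
    """Best high-LD proxy for ``target`` among outcome variants.

    Returns the outcome variant with maximal r² to the target among those
    with r² strictly above ``cfg.proxy_r2``; ``None`` when no candidate
    qualifies. Ties broken by lexicographic variant_id.
    """
    if target not in ld:
        raise LDLookupError(f"proxy target {target!r} not in LD matrix")
    best: Optional[tuple[float, str]] = None
    for rec in outcome.records:
        vid = rec.variant_id
        if vid == target or vid not in ld:
            continue
        r2 = ld.lookup(target, vid)
        if r2 <= cfg.proxy_r2:
            continue
        # maximise r2; break exact ties on the smaller id
        if best is None or r2 > best[0] or (r2 == best[0] and vid < best[1]):
            best = (r2, vid)
    return best[1] if best else None


def select_instruments(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDMatrix,
    cfg: InstrumentConfig = InstrumentConfig(),
    use_proxies: bool = True,
) -> list[HarmonizedPair]:
    """Full instrument-selection chain for one exposure/outcome analysis.

    Significance filter → clump → F filter → harmonize; instruments missing
    from the outcome are rescued through :func:`find_proxy` when possible,
    adopting the proxy's outcome beta/SE unchanged. Returns harmonized pairs
    (dropped pairs included, with reasons).
    """
    clumped = clump(exposure, ld, cfg)
    strong = filter_by_f(clumped, cfg.f_min)
    pairs = harmonize(strong, outcome, cfg.palindromic_maf)
    if not use_proxies:
        return pairs
    rescued: list[HarmonizedPair] = []
    for p in pairs:
        if p.action == "dropped" and p.drop_reason == "not_in_outcome" and p.variant_id in ld:
            proxy = find_proxy(p.variant_id, outcome, ld, cfg)
            if proxy is not None:
                out = outcome.get(proxy)
                rescued.append(HarmonizedPair(
                    variant_id=p.variant_id,
                    beta_exposure=p.beta_exposure,
                    se_exposure=p.se_exposure,
                    beta_outcome=out.beta,
                    se_outcome=out.se,
                    action="kept",
                    proxy_id=proxy,
                ))
                continue
        rescued.append(p)
    return rescued
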