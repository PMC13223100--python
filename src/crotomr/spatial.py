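"""Spot-level spatial-transcriptomics stage.

Each spot carries deconvolved cell-type fractions and a normalized target-
gene expression value. The stage assigns every spot its dominant cell type
(argmax fraction), partitions spots into malignant (tumor-cell fraction
strictly > 0) and non-malignant regions, and summarizes each section:
per-dominant-type mean expression with within-section z-scores, Mal/nMal
means with standard errors and a Wilcoxon rank-sum comparison, and spot-
level Spearman correlations of expression against every cell-type fraction
plus the pairwise correlation structure among fractions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import stats_kit

logger = logging.getLogger(__name__)

TUMOR_KEY = "TumorCells"
FRACTION_TOL = 1e-6


@dataclass(frozen=True)
class SpotRecord:
    spot_id: str
    section_id: str
    x: float
    y: float
    expression: float  # normalized target-gene expression, >= 0
    fractions: dict  # cell type -> fraction, summing to 1
    dominant_type: str = ""
    region: str = ""  # Mal | nMal

    def validate(self) -> None:
        if self.expression < 0 or not math.isfinite(self.expression):
            raise ValueError(f"{self.spot_id}: expression must be finite and >= 0")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > FRACTION_TOL:
            raise ValueError(f"{self.spot_id}: fractions sum to {total}, not 1")
        if any(f < -FRACTION_TOL or f > 1 + FRACTION_TOL for f in self.fractions.values()):
            raise ValueError(f"{self.spot_id}: fraction outside [0,1]")


@dataclass
class SectionSummary:
    section_id: str
    type_means: dict          # dominant type -> mean expression
    type_zscores: dict        # dominant type -> z-scored mean (population sd)
    mal_mean: float
    mal_sem: float
    nmal_mean: float
    nmal_sem: float
    wilcoxon_pvalue: Optional[float]   # None when a region is empty
    spearman: dict            # cell type -> (rho, pvalue) of expression vs fraction
    fraction_spearman: pd.DataFrame    # pairwise rho among fractions
    flags: list = field(default_factory=list)


def assign_dominant_type(spot: SpotRecord) -> str:
    """Cell type with the highest deconvolved fraction; ties broken
    lexicographically by type name."""
    if not spot.fractions:
        raise ValueError(f"{spot.spot_id}: empty fraction vector")
    return min(spot.fractions, key=lambda t: (-spot.fractions[t], t))


def partition_regions(spots: Sequence[SpotRecord]) -> list[SpotRecord]:
    """Label each spot Mal (tumor fraction strictly > 0) or nMal, and fill
    in its dominant type. A missing tumor-fraction key counts as 0 with a
    warning."""
    out = []
    warned = False
    for s in spots:
        s.validate()
        if TUMOR_KEY not in s.fractions and not warned:
            logger.warning("section %s: no %r key in fractions; treating as 0", s.section_id, TUMOR_KEY)
            warned = True
        tumor = s.fractions.get(TUMOR_KEY, 0.0)
        out.append(replace(s, dominant_type=assign_dominant_type(s),
                           region="Mal" if tumor > 0 else "nMal"))
    return out


def _sem(values: np.ndarray) -> float:
    return float(values.std(ddof=1) / math.sqrt(values.size)) if values.size > 1 else 0.0


def summarize_section(spots: Sequence[SpotRecord]) -> SectionSummary:
    """Section-level summary of expression against the deconvolution.

    Z-scores across dominant-type means use the population (n) standard
    deviation; with a single dominant type present the z-score is undefined
    and flagged. Spots with missing (NaN) expression are dropped with a
    logged count. The Mal/nMal Wilcoxon comparison is flagged infeasible
    when either region is empty.
    """
    if not spots:
        raise ValueError("summarize_section needs >= 1 spot")
    section_id = spots[0].section_id
    labelled = partition_regions(spots)
    n_before = len(labelled)
    labelled = [s for s in labelled if not math.isnan(s.expression)]
    flags: list[str] = []
    if len(labelled) < n_before:
        logger.info("section %s: dropped %d spots with missing expression",
                    section_id, n_before - len(labelled))

    expr = np.array([s.expression for s in labelled])
    types = sorted({s.dominant_type for s in labelled})
    type_means = {
        t: float(expr[[s.dominant_type == t for s in labelled]].mean()) for t in types
    }
    means = np.array([type_means[t] for t in types])
    if len(types) >= 2 and means.std() > 0:
        z = (means - means.mean()) / means.std()  # population sd
        type_z = dict(zip(types, z.tolist()))
    else:
        type_z = {t: 0.0 for t in types}
        flags.append("zscore-degenerate")

    mal = expr[[s.region == "Mal" for s in labelled]]
    nmal = expr[[s.region == "nMal" for s in labelled]]
    if mal.size and nmal.size:
        wilcoxon_p = stats_kit.wilcoxon_rank_sum(mal, nmal)
    else:
        wilcoxon_p = None
        flags.append("region-comparison-infeasible")

    all_types = sorted({t for s in labelled for t in s.fractions})
    frac_mat = np.array([[s.fractions.get(t, 0.0) for t in all_types] for s in labelled])
    spear: dict = {}
    for j, t in enumerate(all_types):
        try:
            rho, p = stats_kit.spearman(expr, frac_mat[:, j])
        except ValueError:
            rho, p = float("nan"), float("nan")
        if math.isnan(rho):
            flags.append(f"rho-undefined:{t}")
        spear[t] = (rho, p)
    pair = np.full((len(all_types), len(all_types)), np.nan)
    for i in range(len(all_types)):
        pair[i, i] = 1.0
        for j in range(i + 1, len(all_types)):
            try:
                rho, _ = stats_kit.spearman(frac_mat[:, i], frac_mat[:, j])
            except ValueError:
                rho = float("nan")
            pair[i, j] = pair[j, i] = rho
    frac_spear = pd.DataFrame(pair, index=all_types, columns=all_types)

    return SectionSummary(
        section_id=section_id,
        type_means=type_means,
        type_zscores=type_z,
        mal_mean=float(mal.mean()) if mal.size else float("nan"),
        mal_sem=_sem(mal),
        nmal_mean=float(nmal.mean()) if nmal.size else float("nan"),
        nmal_sem=_sem(nmal),
        wilcoxon_pvalue=wilcoxon_p,
        spearman=spear,
        fraction_spearman=frac_spear,
        flags=flags,
    )


def spots_to_frame(spots: Sequence[SpotRecord]) -> pd.DataFrame:
    """Tidy spot table: one ``frac_<Type>`` column per cell type."""
    types = sorted({t for s in spots for t in s.fractions})
    rows = []
    for s in spots:
        row = {"spot_id": s.spot_id, "section_id": s.section_id, "x": s.x, "y": s.y,
               "expression": s.expression, "dominant_type": s.dominant_type,
               "region": s.region}
        for t in types:
            row[f"frac_{t}"] = s.fractions.get(t, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def spots_from_frame(df: pd.DataFrame) -> list[SpotRecord]:
    frac_cols = [c for c in df.columns if c.startswith("frac_")]
    spots = []
    for _, row in df.iterrows():
        spots.append(SpotRecord(
            spot_id=str(row["spot_id"]), section_id=str(row["section_id"]),
            x=float(row["x"]), y=float(row["y"]),
            expression=float(row["expression"]),
            fractions={c[len("frac_"):]: float(row[c]) for c in frac_cols},
        ))
    return spots
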