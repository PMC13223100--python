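"""Summary-statistics data model, TSV readers/writers, and harmonization.

A :class:`SummaryDataset` is a trait-level collection of per-variant
association records (effect allele, other allele, frequency, beta, SE, p, N).
:func:`harmonize` aligns an exposure and an outcome dataset to a shared effect
allele — the unit every MR estimator consumes is the resulting
:class:`HarmonizedPair`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical on-disk column order
SUMSTATS_COLUMNS = [
    "variant_id", "chromosome", "position", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]


class SumstatsFormatError(ValueError):
    """A mandatory column is missing or the file cannot be parsed."""


class EmptyDatasetError(ValueError):
    """The file contains a header but no data rows."""


@dataclass(frozen=True)
class VariantAssociation:
    """One GWAS or eQTL association record.

    ``beta`` is the per-allele effect of ``effect_allele`` (log-odds for
    binary traits); ``eaf`` is the effect-allele frequency, ``None`` when the
    source does not report it.
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pvalue: float
    n: Optional[float] = None

    def validate(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.variant_id}: pvalue must be in (0,1], got {self.pvalue}")
        if self.effect_allele not in _BASES or self.other_allele not in _BASES:
            raise ValueError(
                f"{self.variant_id}: alleles must be single bases A/C/G/T "
                f"(got {self.effect_allele}/{self.other_allele})"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.variant_id}: eaf outside [0,1]: {self.eaf}")

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G variants — strand cannot be inferred from alleles alone."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class SummaryDataset:
    """A trait-level collection of :class:`VariantAssociation` records."""

    trait_label: str
    trait_type: str  # "continuous" | "binary"
    records: list[VariantAssociation] = field(default_factory=list)
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type}")
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({v for v in ids if ids.count(v) > 1})
            raise ValueError(f"duplicate variant_id values in {self.trait_label}: {dupes[:5]}")
        self._index = {r.variant_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def get(self, variant_id: str) -> Optional[VariantAssociation]:
        return self._index.get(variant_id)

    def subset(self, variant_ids: Iterable[str]) -> "SummaryDataset":
        keep = set(variant_ids)
        return SummaryDataset(
            trait_label=self.trait_label,
            trait_type=self.trait_type,
            records=[r for r in self.records if r.variant_id in keep],
            source_tag=self.source_tag,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant_id": r.variant_id, "chromosome": r.chromosome,
                "position": r.position, "effect_allele": r.effect_allele,
                "other_allele": r.other_allele, "eaf": r.eaf, "beta": r.beta,
                "se": r.se, "pvalue": r.pvalue, "n": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=SUMSTATS_COLUMNS)


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects aligned to a shared effect allele.

    ``action`` is ``kept``, ``flipped`` (outcome beta sign flipped because the
    outcome reported the opposite allele as effect allele) or ``dropped``;
    exactly the kept/flipped pairs enter estimation.
    """

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    action: str  # kept | flipped | dropped
    drop_reason: str = ""
    proxy_id: str = ""  # set when the outcome stats come from a high-LD proxy

    def __post_init__(self) -> None:
        if self.action not in ("kept", "flipped", "dropped"):
            raise ValueError(f"invalid action {self.action!r}")
        if self.action != "dropped" and (self.se_exposure <= 0 or self.se_outcome <= 0):
            raise ValueError(f"{self.variant_id}: non-positive SE in retained pair")


def _parse_field(value, caster, allow_missing=False):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "NA":
        if allow_missing:
            return None
        raise ValueError("missing mandatory value")
    return caster(value)


def read_sumstats(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    trait_label: str = "",
    trait_type: str = "continuous",
    source_tag: str = "",
) -> SummaryDataset:
    """Read a tab-separated summary-statistics table.

    ``column_map`` maps canonical field names (``variant_id``, ``beta``, ...)
    to the column names in the file; identity mapping by default. Rows failing
    record invariants (non-positive SE, p outside (0,1], multi-allelic or
    indel alleles, ...) are dropped and counted in the log.
    """
    column_map = dict(column_map or {})
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise EmptyDatasetError(f"{path}: no header/data") from exc
    mandatory = ["variant_id", "chromosome", "position", "effect_allele",
                 "other_allele", "beta", "se", "pvalue"]
    optional = ["eaf", "n"]
    colnames = {}
    for fieldname in mandatory + optional:
        col = column_map.get(fieldname, fieldname)
        if fieldname in mandatory and col not in df.columns:
            raise SumstatsFormatError(f"{path}: missing mandatory column {col!r}")
        colnames[fieldname] = col if col in df.columns else None
    if len(df) == 0:
        raise EmptyDatasetError(f"{path}: file has a header but no rows")

    records: list[VariantAssociation] = []
    n_rejected = 0
    for _, row in df.iterrows():
        try:
            rec = VariantAssociation(
                variant_id=_parse_field(row[colnames["variant_id"]], str),
                chromosome=_parse_field(row[colnames["chromosome"]], str),
                position=_parse_field(row[colnames["position"]], int),
                effect_allele=_parse_field(row[colnames["effect_allele"]], str),
                other_allele=_parse_field(row[colnames["other_allele"]], str),
                eaf=_parse_field(row[colnames["eaf"]], float, allow_missing=True)
                if colnames["eaf"] else None,
                beta=_parse_field(row[colnames["beta"]], float),
                se=_parse_field(row[colnames["se"]], float),
                pvalue=_parse_field(row[colnames["pvalue"]], float),
                n=_parse_field(row[colnames["n"]], float, allow_missing=True)
                if colnames["n"] else None,
            )
            rec.validate()
        except (ValueError, KeyError) as exc:
            n_rejected += 1
            logger.debug("rejected row: %s", exc)
            continue
        records.append(rec)
    if n_rejected:
        logger.info("read_sumstats(%s): dropped %d invalid rows", path, n_rejected)
    ds = SummaryDataset(
        trait_label=trait_label or str(path),
        trait_type=trait_type,
        records=records,
        source_tag=source_tag,
    )
    ds.n_rejected = n_rejected  # type: ignore[attr-defined]
    return ds


def write_sumstats(dataset: SummaryDataset, path) -> None:
    """Write the canonical tab-separated format; missing values as ``NA``."""
    df = dataset.to_frame()
    # repr-based float formatting keeps the round trip bit-for-bit
    for col in ("eaf", "beta", "se", "pvalue", "n"):
        df[col] = df[col].map(lambda v: "NA" if v is None or (isinstance(v, float) and math.isnan(v)) else repr(float(v)))
    df.to_csv(path, sep="\t", index=False)


def _alleles_match(exp: VariantAssociation, out: VariantAssociation) -> Optional[bool]:
    """Return False for same orientation, True when outcome alleles are
    swapped relative to the exposure, None when they cannot be reconciled."""
    if (out.effect_allele, out.other_allele) == (exp.effect_allele, exp.other_allele):
        return False
    if (out.effect_allele, out.other_allele) == (exp.other_allele, exp.effect_allele):
        return True
    return None


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindromic_maf: float = 0.42,
) -> list[HarmonizedPair]:
    """Align outcome effects to the exposure's effect allele.

    Variants are matched on ``variant_id``. When the outcome reports the
    opposite effect allele the outcome beta sign is flipped. Palindromic (A/T,
    C/G) variants are retained only when both allele frequencies are present
    and both fall on the same side of the ambiguity band — both below
    ``palindromic_maf`` or both above ``1 - palindromic_maf`` — so the strand
    can be inferred consistently; otherwise the pair is dropped with reason
    ``palindromic_ambiguous``. Variants absent from the outcome are dropped
    with reason ``not_in_outcome``.
    """
    if not (0 < palindromic_maf < 0.5):
        raise ValueError("palindromic_maf must be in (0, 0.5)")
    pairs: list[HarmonizedPair] = []
    for exp in exposure.records:
        out = outcome.get(exp.variant_id)
        if out is None:
            pairs.append(HarmonizedPair(exp.variant_id, exp.beta, exp.se, 0.0, 0.0,
                                        "dropped", "not_in_outcome"))
            continue
        if (out.chromosome != exp.chromosome) or (out.position != exp.position):
            # public sumstats disagree on builds; id identity wins
            logger.warning("%s: chromosome/position mismatch between datasets", exp.variant_id)
        swapped = _alleles_match(exp, out)
        if swapped is None:
            pairs.append(HarmonizedPair(exp.variant_id, exp.beta, exp.se, 0.0, 0.0,
                                        "dropped", "allele_mismatch"))
            continue
        if exp.is_palindromic:
            ok = (
                exp.eaf is not None and out.eaf is not None
                and (
                    (exp.eaf < palindromic_maf and out.eaf < palindromic_maf)
                    or (exp.eaf > 1 - palindromic_maf and out.eaf > 1 - palindromic_maf)
                )
            )
            if not ok:
                pairs.append(HarmonizedPair(exp.variant_id, exp.beta, exp.se, 0.0, 0.0,
                                            "dropped", "palindromic_ambiguous"))
                continue
        if swapped:
            pairs.append(HarmonizedPair(exp.variant_id, exp.beta, exp.se,
                                        -out.beta, out.se, "flipped"))
        else:
            pairs.append(HarmonizedPair(exp.variant_id, exp.beta, exp.se,
                                        out.beta, out.se, "kept"))
    return pairs


def retained(pairs: Sequence[HarmonizedPair]) -> list[HarmonizedPair]:
    """The kept/flipped pairs — exactly those entering estimation."""
    return [p for p in pairs if p.action != "dropped"]
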