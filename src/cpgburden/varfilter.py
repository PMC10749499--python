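"""Variant QC, rarity and pathogenicity classification.

Annotated germline variants (consequence, ClinVar assertions, gnomAD
population frequencies, SpliceAI splice-loss scores, exon/domain context and
QC flags are consumed as input annotations) pass through a three-stage
cascade:

1. :func:`prefilter` removes variants in blacklisted / low-mappability
   regions and variants flagged as technical artifacts in gnomAD
   (InbreedingCoeff, AC0, RF).
2. :func:`is_rare` keeps variants with MAF < 0.5% globally and in every
   annotated gnomAD subpopulation; variants absent from the reference
   frequency source are kept only if detected in <= 1% of samples in every
   study cohort.
3. :func:`classify_variant` assigns pathogenicity classes: protein-truncating
   variants (PTV: stop gain/loss, frameshift indel, splice site, or predicted
   splice loss > 0.8), excluding terminal-exon or domain-less truncations and
   ClinVar-benign assertions; and ClinVar-pathogenic variants (Pathogenic,
   Likely pathogenic, association, risk factor assertions).

Qualifying calls are collapsed per gene into a boolean carrier matrix
(:func:`build_carrier_matrix`), the unit of the downstream burden tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Consequence",
    "VariantRecord",
    "PathogenicCall",
    "CarrierMatrix",
    "prefilter",
    "is_rare",
    "classify_variant",
    "classify_variants",
    "build_carrier_matrix",
    "call_class_summary",
    "GNOMAD_SUBPOPULATIONS",
]

GNOMAD_SUBPOPULATIONS = ("AFR", "SAS", "EAS", "AMR", "NFE", "FIN", "ASJ", "OTH")

#: ClinVar assertions that veto a PTV call.
BENIGN_LABELS = frozenset({"Benign", "Likely benign"})
#: ClinVar assertions that make a variant ClinVar-pathogenic.
PATHOGENIC_LABELS = frozenset({"Pathogenic", "Likely pathogenic", "association", "risk factor"})

DEFAULT_MAF_THRESHOLD = 0.005
DEFAULT_COHORT_THRESHOLD = 0.01
DEFAULT_SPLICEAI_THRESHOLD = 0.8


class Consequence(str, Enum):
    """Canonical-transcript consequence of a protein-coding variant."""

    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    SPLICE_SITE = "splice_site"
    FRAMESHIFT_INDEL = "frameshift_indel"
    OTHER = "other"


#: Consequences counted as protein truncating before the exon/domain filter.
PTV_CONSEQUENCES = frozenset(
    {
        Consequence.STOP_GAIN,
        Consequence.STOP_LOSS,
        Consequence.SPLICE_SITE,
        Consequence.FRAMESHIFT_INDEL,
    }
)


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant.

    ``maf_global``/``maf_subpop`` hold reference (gnomAD-style) frequencies;
    both absent means the variant is missing from the reference source and
    rarity falls back to ``cohort_detection_freq``, the fraction of samples
    in which the variant was detected per study cohort.
    ``spliceai_loss_score`` is the max of the donor-loss and acceptor-loss
    deltas.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    consequence: Consequence
    clinvar_labels: frozenset = frozenset()
    maf_global: float | None = None
    maf_subpop: Mapping[str, float] = field(default_factory=dict)
    spliceai_loss_score: float | None = None
    in_terminal_exon: bool = False
    has_functional_domain: bool = True
    gnomad_qc_flags: frozenset = frozenset()
    region_flags: frozenset = frozenset()
    cohort_detection_freq: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, val in (("maf_global", self.maf_global), ("spliceai_loss_score", self.spliceai_loss_score)):
            if val is not None and not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        for pop, maf in self.maf_subpop.items():
            if not 0.0 <= maf <= 1.0:
                raise ValueError(f"maf_subpop[{pop}] out of [0, 1]: {maf}")
        if not isinstance(self.consequence, Consequence):
            object.__setattr__(self, "consequence", Consequence(self.consequence))

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class PathogenicCall:
    """A variant with at least one pathogenicity class flag."""

    variant: VariantRecord
    class_flags: frozenset  # subset of {"PTV", "ClinVarPathogenic"}

    def __post_init__(self) -> None:
        if not self.class_flags:
            raise ValueError("class_flags must be non-empty")
        extra = set(self.class_flags) - {"PTV", "ClinVarPathogenic"}
        if extra:
            raise ValueError(f"unknown class flags: {extra}")


def prefilter(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Drop variants with any region flag or gnomAD QC flag; order preserved."""
    return [v for v in variants if not v.region_flags and not v.gnomad_qc_flags]


def is_rare(
    v: VariantRecord,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    cohort_threshold: float = DEFAULT_COHORT_THRESHOLD,
) -> bool:
    """Rarity rule.

    Present in the reference source: rare iff global MAF and every annotated
    subpopulation MAF are strictly below ``maf_threshold``. Absent from the
    reference source: excluded only when detected in strictly more than
    ``cohort_threshold`` of samples in some study cohort. Subpopulations with
    no annotated frequency are not tested.
    """
    if maf_threshold < 0 or cohort_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    in_reference = v.maf_global is not None or bool(v.maf_subpop)
    if in_reference:
        if v.maf_global is not None and v.maf_global >= maf_threshold:
            return False
        return all(maf < maf_threshold for maf in v.maf_subpop.values())
    return all(freq <= cohort_threshold for freq in v.cohort_detection_freq.values())


def classify_variant(
    v: VariantRecord, spliceai_threshold: float = DEFAULT_SPLICEAI_THRESHOLD
) -> PathogenicCall | None:
    """Assign PTV / ClinVarPathogenic flags to a prefiltered rare variant.

    PTV requires a truncating consequence (or predicted splice loss above
    ``spliceai_threshold``), no benign ClinVar assertion, an internal exon and
    an annotated functional domain. ClinVarPathogenic requires a clinical
    pathogenicity assertion. Returns ``None`` when neither class applies.
    """
    flags = set()
    truncating = v.consequence in PTV_CONSEQUENCES or (
        v.spliceai_loss_score is not None and v.spliceai_loss_score > spliceai_threshold
    )
    if (
        truncating
        and not (set(v.clinvar_labels) & BENIGN_LABELS)
        and not (v.in_terminal_exon or not v.has_functional_domain)
    ):
        flags.add("PTV")
    if set(v.clinvar_labels) & PATHOGENIC_LABELS:
        flags.add("ClinVarPathogenic")
    if not flags:
        return None
    return PathogenicCall(variant=v, class_flags=frozenset(flags))


def classify_variants(
    variants: Iterable[VariantRecord],
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    cohort_threshold: float = DEFAULT_COHORT_THRESHOLD,
    spliceai_threshold: float = DEFAULT_SPLICEAI_THRESHOLD,
) -> list[PathogenicCall]:
    """Full cascade: prefilter, rarity, classification."""
    calls = []
    for v in prefilter(variants):
        if not is_rare(v, maf_threshold, cohort_threshold):
            continue
        call = classify_variant(v, spliceai_threshold)
        if call is not None:
            calls.append(call)
    return calls


@dataclass
class CarrierMatrix:
    """Gene x sample boolean indicator: carries >= 1 qualifying variant.

    ``data`` is a genes-by-samples boolean DataFrame; ``class_mode`` records
    which pathogenicity class the matrix collapses (PTV, ClinVar or union).
    """

    data: pd.DataFrame
    class_mode: str = "union"

    def __post_init__(self) -> None:
        if self.class_mode not in {"PTV", "ClinVar", "union"}:
            raise ValueError(f"unknown class_mode {self.class_mode!r}")
        self.data = self.data.astype(bool)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def carrier_counts(self) -> pd.Series:
        """Total carriers per gene."""
        return self.data.sum(axis=1)

    def frequency_report(self, sample_cohorts: pd.Series) -> pd.DataFrame:
        """Per-gene carrier count and percent frequency within each cohort.

        ``sample_cohorts`` maps sample id to cohort label (e.g. case/control).
        Percentages are reported to two decimals, the convention used for
        carrier frequencies throughout.
        """
        cohorts = sample_cohorts.loc[self.samples]
        rows = {}
        for label in cohorts.unique():
            cols = cohorts.index[cohorts == label]
            n = len(cols)
            counts = self.data[cols].sum(axis=1)
            rows[f"n_carriers_{label}"] = counts
            rows[f"pct_{label}"] = (100.0 * counts / n).round(2)
            rows[f"n_{label}"] = n
        return pd.DataFrame(rows)


def build_carrier_matrix(
    calls: Iterable[PathogenicCall],
    genotypes: Mapping[str, Iterable[str]],
    samples: Iterable[str],
    class_mode: str = "union",
    genes: Iterable[str] | None = None,
) -> CarrierMatrix:
    """Collapse qualifying calls into a gene x sample carrier matrix.

    ``genotypes`` maps variant id to the samples carrying the alternate
    allele (het or hom; zygosity is not modelled). ``class_mode`` selects
    which call flags qualify: ``"PTV"``, ``"ClinVar"`` or ``"union"``.
    ``genes`` optionally fixes the gene universe so zero-carrier genes are
    retained as all-false rows.
    """
    samples = list(samples)
    sample_set = set(samples)
    wanted = {"PTV": {"PTV"}, "ClinVar": {"ClinVarPathogenic"}, "union": {"PTV", "ClinVarPathogenic"}}
    try:
        match_flags = wanted[class_mode]
    except KeyError:
        raise ValueError(f"unknown class_mode {class_mode!r}") from None

    calls = list(calls)
    gene_ids = list(dict.fromkeys(genes)) if genes is not None else list(
        dict.fromkeys(c.variant.gene_id for c in calls)
    )
    data = pd.DataFrame(False, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    for call in calls:
        if not (set(call.class_flags) & match_flags):
            continue
        gene = call.variant.gene_id
        if gene not in data.index:
            continue
        for s in genotypes.get(call.variant.variant_id, ()):
            if s not in sample_set:
                raise KeyError(f"genotype sample {s!r} absent from sample list")
            data.loc[gene, s] = True
    return CarrierMatrix(data=data, class_mode=class_mode)


def call_class_summary(calls: Iterable[PathogenicCall]) -> pd.Series:
    """Bookkeeping over a call set: class counts and percentage shares.

    Shares are percentages of the union call count, reported to one decimal.
    """
    calls = list(calls)
    n = len(calls)
    n_ptv = sum("PTV" in c.class_flags for c in calls)
    n_clinvar = sum("ClinVarPathogenic" in c.class_flags for c in calls)
    n_both = sum(len(c.class_flags) == 2 for c in calls)
    out = {
        "n_union": n,
        "n_ptv": n_ptv,
        "n_clinvar": n_clinvar,
        "n_both": n_both,
    }
    if n:
        out["pct_ptv"] = round(100.0 * n_ptv / n, 1)
        out["pct_clinvar"] = round(100.0 * n_clinvar / n, 1)
        out["pct_both"] = round(100.0 * n_both / n, 1)
    return pd.Series(out)
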