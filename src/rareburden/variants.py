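"""Variant/sample data model, consequence-class taxonomy and rarity filters.

The unit of analysis is the *carrier event*: a sample carrying at least one
qualifying allele of a gene.  Variant classes are defined over the pair
(consequence, MPC score); both MPC thresholds (2 and 3) are strict, so a
missense variant with MPC exactly 2.0 belongs to no damaging class.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping, Optional

from .errors import DataError


class Consequence(str, Enum):
    """Collapsed functional consequence of an allele."""

    PTV = "ptv"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class ChromCategory(str, Enum):
    AUTOSOMAL_OR_PAR = "autosomal_or_PAR"
    X_NONPAR = "X_nonPAR"


class Phenotype(str, Enum):
    CASE = "case"
    CONTROL = "control"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class VariantClass(str, Enum):
    """Gene-test variant classes cut on the MPC missense score at 2 and 3."""

    PTV_ONLY = "ptv"
    PTV_MPC_GT3 = "ptv_mpc_gt3"
    PTV_MPC_GT2 = "ptv_mpc_gt2"
    MPC_GT2 = "mpc_gt2"
    SYNONYMOUS = "synonymous"
    MPC_2_3 = "mpc_2_3"


#: the four classes scanned in the primary gene-discovery analysis
DAMAGING_CLASSES = (
    VariantClass.PTV_ONLY,
    VariantClass.PTV_MPC_GT3,
    VariantClass.PTV_MPC_GT2,
    VariantClass.MPC_GT2,
)

#: gene annotation flag required for a class to be defined for a gene;
#: classes without an entry are defined for every gene
CLASS_POSSIBLE_FLAG: Mapping[VariantClass, str] = {
    VariantClass.PTV_MPC_GT3: "has_possible_mpc_gt3",
    VariantClass.PTV_MPC_GT2: "has_possible_mpc_gt2",
    VariantClass.MPC_GT2: "has_possible_mpc_gt2",
    VariantClass.MPC_2_3: "has_possible_mpc_gt2",
}


@dataclass
class VariantRecord:
    """One ultra-rare site (one alternate allele).

    ``mac_internal`` is the minor allele count over the full analysed cohort
    (all strata pooled); ``mac_reference`` the count in the external
    reference panel.  ``mpc`` may be absent only for non-missense alleles.
    """

    gene_id: str
    carrier_ids: frozenset
    consequence: Consequence
    mpc: Optional[float]
    chrom_category: ChromCategory = ChromCategory.AUTOSOMAL_OR_PAR
    mac_internal: int = 1
    mac_reference: int = 0

    def __post_init__(self) -> None:
        self.carrier_ids = frozenset(self.carrier_ids)
        self.consequence = Consequence(self.consequence)
        self.chrom_category = ChromCategory(self.chrom_category)
        if self.consequence is Consequence.MISSENSE and self.mpc is None:
            raise DataError(
                f"missense variant in {self.gene_id} with carriers "
                f"{sorted(self.carrier_ids)} lacks an MPC score"
            )
        if self.mpc is not None and self.mpc < 0:
            raise DataError(f"negative MPC {self.mpc} in {self.gene_id}")
        if self.mac_internal < 1:
            raise DataError(
                f"mac_internal must be >= 1, got {self.mac_internal} in {self.gene_id}"
            )
        if self.mac_reference < 0:
            raise DataError(
                f"negative mac_reference {self.mac_reference} in {self.gene_id}"
            )
        if self.mac_internal < len(self.carrier_ids):
            raise DataError(
                f"mac_internal {self.mac_internal} < {len(self.carrier_ids)} "
                f"carriers in {self.gene_id}"
            )


@dataclass
class SampleRecord:
    """Phenotype, stratum and nuisance covariates for one sample.

    ``covariates`` is an ordered vector: principal components first, the
    exome-wide rare-coding burden count last.
    """

    sample_id: str
    phenotype: Phenotype
    stratum: str
    sex: Sex
    covariates: tuple = ()

    def __post_init__(self) -> None:
        self.phenotype = Phenotype(self.phenotype)
        self.sex = Sex(self.sex)
        self.covariates = tuple(float(c) for c in self.covariates)
        if not self.stratum:
            raise DataError(f"sample {self.sample_id} has an empty stratum label")


@dataclass
class GeneAnnotation:
    """Per-gene constraint, possible-variant flags and de novo expectations."""

    gene_id: str
    pli: float = 0.0
    has_possible_mpc_gt3: bool = True
    has_possible_mpc_gt2: bool = True
    denovo_lambda: dict = field(default_factory=dict)
    chrom_category: ChromCategory = ChromCategory.AUTOSOMAL_OR_PAR
    excluded_clonal_haem: bool = False
    cnv_locus: Optional[str] = None

    def __post_init__(self) -> None:
        self.chrom_category = ChromCategory(self.chrom_category)
        if not 0.0 <= self.pli <= 1.0:
            raise DataError(f"pli for {self.gene_id} must be in [0,1], got {self.pli}")
        self.denovo_lambda = {
            VariantClass(k): float(v) for k, v in self.denovo_lambda.items()
        }
        for c, lam in self.denovo_lambda.items():
            if lam < 0:
                raise DataError(f"negative de novo rate {lam} for {self.gene_id}/{c.value}")

    @property
    def constrained(self) -> bool:
        return self.pli >= 0.9


def class_membership(v: VariantRecord, c: VariantClass) -> bool:
    """Return whether variant ``v`` belongs to test class ``c``.

    Membership is a total function over (consequence, mpc); MPC thresholds
    are strict, so mpc == 2.0 is not "> 2".
    """
    c = VariantClass(c)
    is_ptv = v.consequence is Consequence.PTV
    is_mis = v.consequence is Consequence.MISSENSE
    if is_mis and v.mpc is None:
        raise DataError(
            f"missense variant in {v.gene_id} with carriers "
            f"{sorted(v.carrier_ids)} lacks an MPC score"
        )
    if c is VariantClass.PTV_ONLY:
        return is_ptv
    if c is VariantClass.PTV_MPC_GT3:
        return is_ptv or (is_mis and v.mpc > 3)
    if c is VariantClass.PTV_MPC_GT2:
        return is_ptv or (is_mis and v.mpc > 2)
    if c is VariantClass.MPC_GT2:
        return is_mis and v.mpc > 2
    if c is VariantClass.SYNONYMOUS:
        return v.consequence is Consequence.SYNONYMOUS
    if c is VariantClass.MPC_2_3:
        return is_mis and 2 < v.mpc <= 3
    raise DataError(f"unknown variant class {c!r}")  # pragma: no cover


def passes_rare_filter(
    v: VariantRecord, mac_cap: int = 5, reference_cap: Optional[int] = None
) -> bool:
    """Ultra-rarity filter: MAC <= cap in the cohort *and* in the reference panel.

    ``reference_cap`` defaults to ``mac_cap``; both bounds are inclusive.
    """
    if mac_cap < 0:
        raise DataError(f"negative mac_cap {mac_cap}")
    if reference_cap is None:
        reference_cap = mac_cap
    return v.mac_internal <= mac_cap and v.mac_reference <= reference_cap


def is_singleton(v: VariantRecord) -> bool:
    """Singleton: MAC = 1 in the cohort and absent from the reference panel."""
    return v.mac_internal == 1 and v.mac_reference == 0


def exome_wide_burden(
    samples: Iterable[SampleRecord],
    variants: Iterable[VariantRecord],
    predicate: Optional[Callable[[VariantRecord], bool]] = None,
) -> dict:
    """Count, per sample, qualifying variant carriages across all genes.

    Every (variant, carrier) pair passing ``predicate`` contributes one count;
    the total over samples therefore equals the number of qualifying carriage
    events.  A carrier id absent from ``samples`` is a data error.
    """
    burden = {s.sample_id: 0 for s in samples}
    for v in variants:
        if predicate is not None and not predicate(v):
            continue
        for sid in v.carrier_ids:
            if sid not in burden:
                raise DataError(f"carrier {sid!r} of {v.gene_id} not in sample manifest")
            burden[sid] += 1
    return burden
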