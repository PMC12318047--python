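"""Stratified 2x2 carrier tables and the Cochran-Mantel-Haenszel burden test.

Per gene and variant class, each stratum contributes one 2x2 table of
case/control carriers versus non-carriers (X non-PAR genes additionally split
configured strata by sex, since carrier counts there are not comparable
between sexes).  The test statistic is the 1-df CMH chi-square with an
optional 0.5 continuity correction, the effect estimate the Mantel-Haenszel
common odds ratio with a Robins-Breslow-Greenland 95% CI.
"""
from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from scipy.stats import chi2

from .errors import ConfigError, DataError
from .variants import (
    CLASS_POSSIBLE_FLAG,
    ChromCategory,
    GeneAnnotation,
    Phenotype,
    SampleRecord,
    Sex,
    VariantClass,
    VariantRecord,
    class_membership,
    passes_rare_filter,
)

_Z975 = 1.959963984540054


@dataclass
class StratumTable:
    """One 2x2 case/control carrier table for one stratum."""

    stratum: str
    a: int  # case carriers
    b: int  # case non-carriers
    c: int  # control carriers
    d: int  # control non-carriers

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError(f"negative count in stratum {self.stratum!r}: {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def informative(self) -> bool:
        """A table with a zero margin on either axis carries no information."""
        return (
            self.a + self.b > 0
            and self.c + self.d > 0
            and self.a + self.c > 0
            and self.b + self.d > 0
        )

    @property
    def base_stratum(self) -> str:
        """Stratum label without any sex-split suffix."""
        return self.stratum.split(":", 1)[0]


@dataclass
class CmhResult:
    statistic: float
    p_two_sided: float
    or_mh: float
    ci95: tuple
    n_informative_strata: int
    testable: bool = True


class SampleIndex:
    """Prebuilt lookups over a sample manifest (stratum sizes, sample info)."""

    def __init__(self, samples: Sequence[SampleRecord]):
        self.by_id = {}
        self.strata: list = []
        self.n_cases = defaultdict(int)
        self.n_controls = defaultdict(int)
        seen = set()
        for s in samples:
            if s.sample_id in self.by_id:
                raise DataError(f"duplicate sample id {s.sample_id!r}")
            self.by_id[s.sample_id] = s
            if s.stratum not in seen:
                seen.add(s.stratum)
                self.strata.append(s.stratum)
            if s.phenotype is Phenotype.CASE:
                self.n_cases[s.stratum] += 1
            else:
                self.n_controls[s.stratum] += 1
            key = (s.stratum, s.sex)
            if s.phenotype is Phenotype.CASE:
                self.n_cases[key] += 1
            else:
                self.n_controls[key] += 1


def build_tables(
    gene_id: str,
    vclass: VariantClass,
    variants: Iterable[VariantRecord],
    samples: Sequence[SampleRecord],
    chrom_category: ChromCategory = ChromCategory.AUTOSOMAL_OR_PAR,
    sex_split_strata: Sequence[str] = (),
    carrier_mode: str = "carrier",
    index: Optional[SampleIndex] = None,
) -> list:
    """Build per-stratum 2x2 carrier tables for one gene x class test.

    A sample is a carrier if it carries >= 1 qualifying variant in the gene
    (counted once, ``carrier_mode="carrier"``); ``"allele"`` counts every
    carriage event instead.  ``variants`` are assumed pre-filtered for rarity.
    For X non-PAR genes, each stratum listed in ``sex_split_strata``
    contributes separate male and female tables (labelled ``stratum:sex``).
    """
    if carrier_mode not in ("carrier", "allele"):
        raise ConfigError(f"carrier_mode must be 'carrier' or 'allele', got {carrier_mode!r}")
    idx = index if index is not None else SampleIndex(samples)

    carriers: dict = defaultdict(int)
    seen_once: set = set()
    for v in variants:
        if v.gene_id != gene_id or not class_membership(v, vclass):
            continue
        for sid in v.carrier_ids:
            if sid not in idx.by_id:
                raise DataError(f"carrier {sid!r} of {gene_id} not in sample manifest")
            if carrier_mode == "carrier":
                if sid in seen_once:
                    continue
                seen_once.add(sid)
            carriers[sid] += 1

    split = set(sex_split_strata) if chrom_category is ChromCategory.X_NONPAR else set()
    # carrier counts per table key
    case_car: dict = defaultdict(int)
    ctl_car: dict = defaultdict(int)
    for sid, k in carriers.items():
        s = idx.by_id[sid]
        key = (s.stratum, s.sex) if s.stratum in split else s.stratum
        if s.phenotype is Phenotype.CASE:
            case_car[key] += k
        else:
            ctl_car[key] += k

    tables = []
    for stratum in idx.strata:
        keys = (
            [(stratum, Sex.MALE), (stratum, Sex.FEMALE)] if stratum in split else [stratum]
        )
        for key in keys:
            label = f"{stratum}:{key[1].value}" if isinstance(key, tuple) else stratum
            nca, nco = idx.n_cases[key], idx.n_controls[key]
            a, c = case_car[key], ctl_car[key]
            # allele mode can exceed the sample count in pathological inputs
            b = max(nca - a, 0) if carrier_mode == "allele" else nca - a
            d = max(nco - c, 0) if carrier_mode == "allele" else nco - c
            tables.append(StratumTable(label, a, b, c, d))
    return tables


def gene_is_testable(
    annotation: GeneAnnotation,
    vclass: VariantClass,
    tables: Sequence[StratumTable],
    largest_stratum: str,
) -> bool:
    """Gene-inclusion rule for one gene x class test.

    A gene is tested when it is not a clonal-haematopoiesis exclusion, the
    class's possible-variant flag holds, and carriers are observed in at
    least two strata or in the designated largest stratum.
    """
    base_strata = {t.base_stratum for t in tables}
    if largest_stratum not in base_strata:
        raise ConfigError(
            f"largest_stratum {largest_stratum!r} not among strata {sorted(base_strata)}"
        )
    if annotation.excluded_clonal_haem:
        return False
    flag = CLASS_POSSIBLE_FLAG.get(VariantClass(vclass))
    if flag is not None and not getattr(annotation, flag):
        return False
    with_carriers = {t.base_stratum for t in tables if t.a + t.c > 0}
    return len(with_carriers) >= 2 or largest_stratum in with_carriers


def cmh_test(tables: Sequence[StratumTable], continuity: bool = True) -> CmhResult:
    """Two-sided CMH chi-square (1 df) with MH odds ratio and RBG 95% CI.

    Strata with a zero margin on either axis are skipped.  With no
    informative stratum the result is flagged untestable rather than raising.
    The statistic is ``(|sum a - sum E| - 0.5)^2 / sum V`` (the 0.5 only with
    ``continuity``), with hypergeometric mean and variance per stratum.
    """
    info = [t for t in tables if t.informative]
    if not info:
        return CmhResult(math.nan, math.nan, math.nan, (math.nan, math.nan), 0, testable=False)

    sum_a = sum_e = sum_v = 0.0
    R = S = 0.0
    # RBG variance accumulators
    prr = pssr = qss = 0.0
    for t in info:
        n = t.n
        r1, r2 = t.a + t.b, t.c + t.d
        c1, c2 = t.a + t.c, t.b + t.d
        sum_a += t.a
        sum_e += r1 * c1 / n
        sum_v += r1 * r2 * c1 * c2 / (n * n * (n - 1))
        rk = t.a * t.d / n
        sk = t.b * t.c / n
        R += rk
        S += sk
        pk = (t.a + t.d) / n
        qk = (t.b + t.c) / n
        prr += pk * rk
        pssr += pk * sk + qk * rk
        qss += qk * sk

    num = abs(sum_a - sum_e)
    if continuity:
        num = max(num - 0.5, 0.0)
    statistic = num * num / sum_v if sum_v > 0 else 0.0
    p = float(chi2.sf(statistic, 1)) if sum_v > 0 else 1.0

    if S > 0 and R > 0:
        or_mh = R / S
        var_log = prr / (2 * R * R) + pssr / (2 * R * S) + qss / (2 * S * S)
        se = math.sqrt(var_log)
        ci = (or_mh * math.exp(-_Z975 * se), or_mh * math.exp(_Z975 * se))
    elif R > 0:  # all carriers in cases
        or_mh, ci = math.inf, (0.0, math.inf)
    elif S > 0:  # all carriers in controls
        or_mh, ci = 0.0, (0.0, math.inf)
    else:
        or_mh, ci = math.nan, (math.nan, math.nan)
    return CmhResult(statistic, p, or_mh, ci, len(info))


@dataclass
class BurdenResult:
    """One counted gene x class case-control test (testable or not)."""

    gene_id: str
    variant_class: VariantClass
    testable: bool
    cmh: Optional[CmhResult] = None
    tables: list = field(default_factory=list)

    @property
    def p_cc(self) -> float:
        if self.testable and self.cmh is not None and self.cmh.testable:
            return self.cmh.p_two_sided
        return math.nan


def run_burden_scan(
    variants: Sequence[VariantRecord],
    samples: Sequence[SampleRecord],
    genes: Sequence[GeneAnnotation],
    classes: Sequence[VariantClass] = None,
    mac_cap: int = 5,
    largest_stratum: Optional[str] = None,
    sex_split_strata: Sequence[str] = (),
    carrier_mode: str = "carrier",
    continuity: bool = True,
) -> list:
    """Scan every defined gene x class test; return one BurdenResult each.

    A class is *defined* for a gene when its possible-variant flag holds
    (PTV-only and synonymous tests are defined for every gene).  Untestable
    genes (inclusion rule, clonal-haematopoiesis exclusions) still produce a
    counted result with no p-value — they contribute to the multiplicity
    ledger downstream.
    """
    from .variants import DAMAGING_CLASSES

    if classes is None:
        classes = DAMAGING_CLASSES
    idx = SampleIndex(samples)
    if largest_stratum is None:
        largest_stratum = max(
            idx.strata, key=lambda s: idx.n_cases[s] + idx.n_controls[s]
        )
    rare = [v for v in variants if passes_rare_filter(v, mac_cap)]
    by_gene = defaultdict(list)
    for v in rare:
        by_gene[v.gene_id].append(v)

    results = []
    for ann in genes:
        gvars = by_gene.get(ann.gene_id, [])
        for c in classes:
            c = VariantClass(c)
            flag = CLASS_POSSIBLE_FLAG.get(c)
            if flag is not None and not getattr(ann, flag):
                continue  # test not defined for this gene
            tables = build_tables(
                ann.gene_id,
                c,
                gvars,
                samples,
                chrom_category=ann.chrom_category,
                sex_split_strata=sex_split_strata,
                carrier_mode=carrier_mode,
                index=idx,
            )
            testable = gene_is_testable(ann, c, tables, largest_stratum)
            res = cmh_test(tables, continuity=continuity) if testable else None
            if res is not None and not res.testable:
                testable = False
            results.append(BurdenResult(ann.gene_id, c, testable, res, tables))
    return results
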