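"""De novo Poisson enrichment, gated Fisher combination and multiplicity control.

Per gene x class the reported statistic is the minimum of (1) the
case-control CMH p-value and (2) — only when the case-control p passes the
gate (default 0.01) and a de novo expectation exists — the Fisher
combination of the case-control and de novo p-values.  Both test families
count toward the Bonferroni total regardless of whether the gate opened.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import chi2, poisson

from .errors import ConfigError, DataError
from .variants import VariantClass


@dataclass
class DenovoRecord:
    """Observed vs expected de novo count for one gene x class across all trios."""

    gene_id: str
    variant_class: VariantClass
    observed: int
    expected: float

    def __post_init__(self) -> None:
        self.variant_class = VariantClass(self.variant_class)
        if self.observed < 0:
            raise DataError(f"negative observed de novo count for {self.gene_id}")
        if not math.isfinite(self.expected) or self.expected < 0:
            raise DataError(f"invalid expected de novo count for {self.gene_id}")


@dataclass
class MultiplicityLedger:
    n_cc_tests: int
    n_meta_tests: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_cc_tests < 0 or self.n_meta_tests < 0:
            raise ConfigError("test counts must be non-negative")
        if self.n_total == 0:
            raise ConfigError("n_total is zero: nothing was tested")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")

    @property
    def n_total(self) -> int:
        return self.n_cc_tests + self.n_meta_tests

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.n_total


@dataclass
class GeneResult:
    """Final per gene x class result row."""

    gene_id: str
    variant_class: VariantClass
    testable: bool
    or_mh: float = math.nan
    ci95: tuple = (math.nan, math.nan)
    p_cc: float = math.nan
    p_denovo: Optional[float] = None
    p_meta: Optional[float] = None
    p_final: float = math.nan
    q_value: float = math.nan
    exome_wide_significant: bool = False
    fdr5_significant: bool = False
    n_informative_strata: int = 0
    denovo_observed: Optional[int] = None
    denovo_expected: Optional[float] = None


def poisson_denovo_test(observed: int, expected: float) -> float:
    """One-sided Poisson enrichment tail P(X >= observed | X ~ Poisson(expected)).

    ``expected == 0`` with ``observed == 0`` gives p = 1; with a positive
    observed count the rate ratio is undefined and NaN is returned (callers
    treat it as an absent de novo test).
    """
    if observed < 0:
        raise DataError(f"negative observed count {observed}")
    if not (expected >= 0):
        raise DataError(f"expected count must be >= 0, got {expected}")
    if expected == 0:
        return 1.0 if observed == 0 else math.nan
    return float(poisson.sf(observed - 1, expected))


def fisher_combine(p1: float, p2: float) -> float:
    """Fisher's combined probability of two p-values (chi-square, 4 df)."""
    for p in (p1, p2):
        if not (0 < p <= 1):
            raise DataError(f"p-value {p} outside (0, 1]")
    stat = -2.0 * (math.log(p1) + math.log(p2))
    return float(chi2.sf(stat, 4))


def final_gene_p(
    p_cc: float, denovo: Optional[DenovoRecord] = None, gate: float = 0.01
):
    """Gated min-P combination for one gene x class.

    Returns ``(p_denovo, p_meta, p_final)``.  The meta test runs only when
    ``p_cc < gate`` and a usable de novo record exists; otherwise
    ``p_final = p_cc`` (ties broken toward the case-control-only test).
    """
    if not (0 < p_cc <= 1):
        raise DataError(f"p_cc {p_cc} outside (0, 1]")
    if not 0 < gate < 1:
        raise ConfigError(f"meta gate must be in (0,1), got {gate}")
    if denovo is None or p_cc >= gate:
        return None, None, p_cc
    p_dn = poisson_denovo_test(denovo.observed, denovo.expected)
    if math.isnan(p_dn):  # undefined rate ratio: gate treated as closed
        return None, None, p_cc
    p_meta = fisher_combine(p_cc, p_dn)
    return p_dn, p_meta, min(p_cc, p_meta)


def build_ledger(
    n_cc_tests: int, n_meta_tests: int, alpha: float = 0.05
) -> MultiplicityLedger:
    """Total-test ledger and Bonferroni exome-wide threshold alpha / n_total."""
    return MultiplicityLedger(n_cc_tests, n_meta_tests, alpha)


def fdr_qvalues(p_finals: Sequence[float], m: Optional[int] = None) -> list:
    """Benjamini-Hochberg step-up q-values with denominator ``m``.

    ``m`` defaults to the list length (textbook BH); a larger ``m`` treats
    the listed p-values as the smallest of ``m`` performed tests.
    """
    p = np.asarray(p_finals, dtype=float)
    k = len(p)
    if m is None:
        m = k
    if m < k:
        raise ConfigError(f"BH denominator m={m} smaller than number of p-values {k}")
    if k == 0:
        return []
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(k)
    q[order] = q_sorted
    return q.tolist()


def subset_bonferroni(p_finals: Mapping[str, float], locus_genes: Sequence[str]) -> dict:
    """Bonferroni correction restricted to the gene tests at one locus."""
    if not locus_genes:
        raise ConfigError("locus_genes is empty")
    missing = [g for g in locus_genes if g not in p_finals]
    if missing:
        raise DataError(f"unknown genes in locus: {missing}")
    n = len(locus_genes)
    return {g: min(1.0, p_finals[g] * n) for g in locus_genes}


def denovo_lookup(
    records: Iterable[DenovoRecord], gene_id: str, vclass: VariantClass
) -> Optional[DenovoRecord]:
    """Match a case-control test class to its de novo counterpart.

    De novo counts are tabulated per gene for PTVs and for damaging missense
    (MPC > 2).  PTV-only tests use the PTV record, missense tests the
    missense record, and the combined PTV+missense classes pool the two
    (observed and expected both summed).
    """
    by_class = {}
    for r in records:
        if r.gene_id == gene_id:
            by_class[r.variant_class] = r
    return _match_denovo(by_class, gene_id, vclass)


def _match_denovo(by_class: Mapping[VariantClass, DenovoRecord], gene_id, vclass):
    vclass = VariantClass(vclass)
    ptv = by_class.get(VariantClass.PTV_ONLY)
    mis = by_class.get(VariantClass.MPC_GT2)
    if vclass is VariantClass.PTV_ONLY:
        return ptv
    if vclass in (VariantClass.MPC_GT2, VariantClass.MPC_2_3):
        return mis
    if vclass in (VariantClass.PTV_MPC_GT3, VariantClass.PTV_MPC_GT2):
        if ptv is None and mis is None:
            return None
        obs = (ptv.observed if ptv else 0) + (mis.observed if mis else 0)
        exp = (ptv.expected if ptv else 0.0) + (mis.expected if mis else 0.0)
        return DenovoRecord(gene_id, vclass, obs, exp)
    return None  # synonymous: no de novo test


def annotate_results(
    burden_results: Sequence,
    denovo: Sequence[DenovoRecord] = (),
    gate: float = 0.01,
    alpha: float = 0.05,
    fdr_denominator: str = "ledger_total",
):
    """Attach de novo / meta / final p-values, ledger, q-values and flags.

    Returns ``(list of GeneResult, MultiplicityLedger)``.  Every counted
    burden result (testable or not) contributes to ``n_cc_tests``; every
    actually-performed Fisher combination contributes to ``n_meta_tests``.
    """
    if fdr_denominator not in ("ledger_total", "tested_genes"):
        raise ConfigError(f"unknown fdr_denominator {fdr_denominator!r}")
    dn_by_gene: dict = {}
    for r in denovo:
        dn_by_gene.setdefault(r.gene_id, {})[r.variant_class] = r

    results = []
    n_meta = 0
    for br in burden_results:
        gr = GeneResult(br.gene_id, br.variant_class, br.testable)
        if br.testable and br.cmh is not None:
            gr.or_mh = br.cmh.or_mh
            gr.ci95 = br.cmh.ci95
            gr.p_cc = br.cmh.p_two_sided
            gr.n_informative_strata = br.cmh.n_informative_strata
            rec = _match_denovo(
                dn_by_gene.get(br.gene_id, {}), br.gene_id, br.variant_class
            )
            if rec is not None:
                gr.denovo_observed = rec.observed
                gr.denovo_expected = rec.expected
            gr.p_denovo, gr.p_meta, gr.p_final = final_gene_p(gr.p_cc, rec, gate)
            if gr.p_meta is not None:
                n_meta += 1
        results.append(gr)

    ledger = build_ledger(len(results), n_meta, alpha)
    tested = [gr for gr in results if gr.testable]
    if tested:
        m = ledger.n_total if fdr_denominator == "ledger_total" else len(tested)
        qs = fdr_qvalues([gr.p_final for gr in tested], m)
        for gr, q in zip(tested, qs):
            gr.q_value = q
            gr.exome_wide_significant = gr.p_final <= ledger.bonferroni_threshold
            gr.fdr5_significant = q <= 0.05
    return results, ledger
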