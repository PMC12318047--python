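"""End-to-end orchestration: filter, burden scan, meta-analysis, QQ check."""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import kstest

from .cmh import run_burden_scan
from .errors import ConfigError, DataError
from .meta import annotate_results
from .simulate import SyntheticStudy
from .variants import (
    DAMAGING_CLASSES,
    VariantClass,
    passes_rare_filter,
)

log = logging.getLogger("rareburden")


@dataclass
class StudyConfig:
    """Analysis thresholds; defaults mirror the study design."""

    mac_cap: int = 5
    meta_gate: float = 0.01
    alpha: float = 0.05
    largest_stratum: Optional[str] = None
    classes: tuple = DAMAGING_CLASSES
    carrier_mode: str = "carrier"
    fdr_denominator: str = "ledger_total"
    sex_split_strata: tuple = ()
    continuity: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mac_cap < 1:
            raise ConfigError(f"mac_cap must be >= 1, got {self.mac_cap}")
        if not 0 < self.meta_gate < 1:
            raise ConfigError(f"meta_gate must be in (0,1), got {self.meta_gate}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        self.classes = tuple(VariantClass(c) for c in self.classes)


@dataclass
class PipelineResult:
    gene_results: list
    ledger: object
    synonymous_pvalues: list = field(default_factory=list)
    geneset_results: list = field(default_factory=list)


def analyze_study(
    variants: Sequence,
    samples: Sequence,
    genes: Sequence,
    denovo: Sequence = (),
    cfg: Optional[StudyConfig] = None,
    with_synonymous_qq: bool = True,
) -> PipelineResult:
    """Run the case-control burden scan and de novo meta-analysis.

    Also computes the synonymous-class CMH p-values used for the null QQ
    check (these never enter the discovery scan or the multiplicity ledger).
    """
    if cfg is None:
        cfg = StudyConfig()
    if not samples or not genes:
        raise DataError("analyze_study needs a non-empty sample manifest and gene panel")
    n_in = len(variants)
    rare = [v for v in variants if passes_rare_filter(v, cfg.mac_cap)]
    log.info("variants in: %d; passing rarity filter (MAC<=%d): %d", n_in, cfg.mac_cap, len(rare))
    if not variants:
        log.warning("no variant records supplied: results will be empty of signal")

    burden = run_burden_scan(
        rare,
        samples,
        genes,
        classes=cfg.classes,
        mac_cap=cfg.mac_cap,
        largest_stratum=cfg.largest_stratum,
        sex_split_strata=cfg.sex_split_strata,
        carrier_mode=cfg.carrier_mode,
        continuity=cfg.continuity,
    )
    for c in cfg.classes:
        n_def = sum(1 for b in burden if b.variant_class == c)
        n_test = sum(1 for b in burden if b.variant_class == c and b.testable)
        log.info("class %s: %d counted tests, %d testable", c.value, n_def, n_test)
    results, ledger = annotate_results(
        burden,
        denovo,
        gate=cfg.meta_gate,
        alpha=cfg.alpha,
        fdr_denominator=cfg.fdr_denominator,
    )
    log.info(
        "ledger: %d case-control + %d meta = %d tests; Bonferroni threshold %.3g",
        ledger.n_cc_tests, ledger.n_meta_tests, ledger.n_total, ledger.bonferroni_threshold,
    )

    syn_p: list = []
    if with_synonymous_qq:
        syn = run_burden_scan(
            rare,
            samples,
            genes,
            classes=(VariantClass.SYNONYMOUS,),
            mac_cap=cfg.mac_cap,
            largest_stratum=cfg.largest_stratum,
            sex_split_strata=cfg.sex_split_strata,
            carrier_mode=cfg.carrier_mode,
            continuity=cfg.continuity,
        )
        syn_p = [b.p_cc for b in syn if b.testable and not math.isnan(b.p_cc)]
    return PipelineResult(results, ledger, syn_p)


def analyze_synthetic(study: SyntheticStudy, cfg: Optional[StudyConfig] = None, **kw) -> PipelineResult:
    return analyze_study(study.variants, study.samples, study.genes, study.denovo, cfg, **kw)


def qq_null_check(p_values: Sequence[float], alpha: float = 0.01):
    """Kolmogorov-Smirnov uniformity check of a p-value collection.

    Returns ``(ks_statistic, ks_pvalue, passed)`` where ``passed`` means the
    uniform null is not rejected at ``alpha``.  Requires >= 100 p-values.
    """
    p = np.asarray([x for x in p_values if not math.isnan(x)], dtype=float)
    if p.size < 100:
        raise DataError(f"qq_null_check needs >= 100 p-values, got {p.size}")
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    stat, ks_p = kstest(p, "uniform")
    return float(stat), float(ks_p), bool(ks_p >= alpha)
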