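"""Synthetic exome-study generator with planted gene-level effects.

Produces the full input surface of the analysis — ultra-rare variant records,
a stratified sample manifest with nuisance covariates, gene annotations with
constraint structure and de novo expectations, trio de novo counts and a
reference panel MAC per variant — from a single seeded configuration.

Carrier events are independent Bernoulli draws per individual x gene x
generating class (PTV, missense MPC>3, missense MPC 2-3, synonymous); in the
ultra-rare regime multi-hit probabilities are negligible, so each event is
emitted as its own singleton variant record.  Planted odds ratios act on the
odds of the baseline carrier probability for cases in risk genes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError
from .meta import DenovoRecord
from .variants import (
    ChromCategory,
    Consequence,
    GeneAnnotation,
    Phenotype,
    SampleRecord,
    Sex,
    VariantClass,
    VariantRecord,
)

#: clonal haematopoiesis exclusion labels used when the panel plants them
CLONAL_HAEM_GENES = ("TET2", "DNMT3A", "ASXL1")

# generating event classes: (consequence, mpc interval or None)
_GEN_CLASSES = (
    ("ptv", Consequence.PTV, None),
    ("mis_gt3", Consequence.MISSENSE, (3.05, 4.5)),
    ("mis_2_3", Consequence.MISSENSE, (2.05, 2.95)),
    ("syn", Consequence.SYNONYMOUS, None),
)

#: which generating classes a planted test class boosts
CLASS_TO_GENERATORS = {
    VariantClass.PTV_ONLY: frozenset({"ptv"}),
    VariantClass.PTV_MPC_GT3: frozenset({"ptv", "mis_gt3"}),
    VariantClass.PTV_MPC_GT2: frozenset({"ptv", "mis_gt3", "mis_2_3"}),
    VariantClass.MPC_GT2: frozenset({"mis_gt3", "mis_2_3"}),
    VariantClass.MPC_2_3: frozenset({"mis_2_3"}),
    VariantClass.SYNONYMOUS: frozenset({"syn"}),
}


@dataclass
class SimConfig:
    """All knobs of the synthetic study; a fixed seed reproduces it exactly."""

    n_strata: int = 3
    stratum_sizes: tuple = ((1000, 1000), (1000, 1000), (1000, 1000))
    n_genes: int = 100
    frac_constrained: float = 0.3
    risk_genes: tuple = ()  # (gene_index, VariantClass, odds_ratio)
    baseline_carrier_rate: float = 0.005
    n_trios: int = 1000
    denovo_rate_per_gene_class: float = 0.05
    denovo_enrichment: float = 1.0
    n_pcs: int = 10
    seed: int = 0
    # reference-panel MAC mixture: fraction of draws above the rarity cap,
    # and, within the <=5 mass, the share sitting at exactly 0
    mac_gt5_fraction: float = 0.1
    reference_zero_fraction: float = 0.5
    frac_possible_mpc_gt3: float = 1.0
    frac_possible_mpc_gt2: float = 1.0
    n_x_genes: int = 0
    include_clonal_haem_genes: bool = False
    confounded_burden: bool = False
    synonymous_rate: Optional[float] = None
    missense_rate: Optional[float] = None

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError(f"n_genes must be positive, got {self.n_genes}")
        if self.n_strata <= 0:
            raise ConfigError(f"n_strata must be positive, got {self.n_strata}")
        if len(self.stratum_sizes) != self.n_strata:
            raise ConfigError(
                f"stratum_sizes has {len(self.stratum_sizes)} entries, expected n_strata={self.n_strata}"
            )
        for i, (nca, nco) in enumerate(self.stratum_sizes):
            if nca <= 0 or nco <= 0:
                raise ConfigError(f"stratum_sizes[{i}] must be positive, got {(nca, nco)}")
        for name in (
            "frac_constrained",
            "baseline_carrier_rate",
            "mac_gt5_fraction",
            "reference_zero_fraction",
            "frac_possible_mpc_gt3",
            "frac_possible_mpc_gt2",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {val}")
        if self.synonymous_rate is not None and not 0.0 <= self.synonymous_rate <= 1.0:
            raise ConfigError(f"synonymous_rate must be in [0,1], got {self.synonymous_rate}")
        if self.missense_rate is not None and not 0.0 <= self.missense_rate <= 1.0:
            raise ConfigError(f"missense_rate must be in [0,1], got {self.missense_rate}")
        if self.frac_possible_mpc_gt3 > self.frac_possible_mpc_gt2:
            raise ConfigError(
                "frac_possible_mpc_gt3 cannot exceed frac_possible_mpc_gt2"
            )
        if self.denovo_rate_per_gene_class < 0:
            raise ConfigError(
                f"denovo_rate_per_gene_class must be >= 0, got {self.denovo_rate_per_gene_class}"
            )
        if self.denovo_enrichment <= 0:
            raise ConfigError(f"denovo_enrichment must be > 0, got {self.denovo_enrichment}")
        if self.n_trios < 0:
            raise ConfigError(f"n_trios must be >= 0, got {self.n_trios}")
        if self.n_pcs < 0:
            raise ConfigError(f"n_pcs must be >= 0, got {self.n_pcs}")
        if self.n_x_genes < 0 or self.n_x_genes > self.n_genes:
            raise ConfigError(f"n_x_genes out of range: {self.n_x_genes}")
        for entry in self.risk_genes:
            idx, vclass, orr = entry
            if not 0 <= idx < self.n_genes:
                raise ConfigError(f"risk gene index {idx} out of range")
            VariantClass(vclass)
            if orr <= 0:
                raise ConfigError(f"odds_ratio must be > 0, got {orr} for gene {idx}")


@dataclass
class SyntheticStudy:
    variants: list
    samples: list
    genes: list
    denovo: list
    truth: dict = field(default_factory=dict)
    config: Optional[SimConfig] = None


def _boosted_rate(p0: float, odds_ratio: float) -> float:
    """Carrier probability whose odds are ``odds_ratio`` times those of p0."""
    odds = odds_ratio * p0 / (1.0 - p0)
    return odds / (1.0 + odds)


def simulate_gene_panel(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> list:
    """Draw the gene annotation panel: constraint, possible-variant flags, rates."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    n_constrained = int(round(cfg.frac_constrained * n))
    constrained_idx = set(rng.permutation(n)[:n_constrained].tolist())
    u_flags = rng.random(n)
    pli_hi = rng.uniform(0.9, 1.0, size=n)
    pli_lo = rng.uniform(0.0, 0.9, size=n)
    lam = cfg.denovo_rate_per_gene_class

    genes = []
    for i in range(n):
        if cfg.include_clonal_haem_genes and i < len(CLONAL_HAEM_GENES):
            gene_id = CLONAL_HAEM_GENES[i]
            excluded = True
        else:
            gene_id = f"G{i:04d}"
            excluded = False
        chrom = (
            ChromCategory.X_NONPAR
            if i >= n - cfg.n_x_genes
            else ChromCategory.AUTOSOMAL_OR_PAR
        )
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                pli=float(pli_hi[i] if i in constrained_idx else pli_lo[i]),
                has_possible_mpc_gt3=bool(u_flags[i] < cfg.frac_possible_mpc_gt3),
                has_possible_mpc_gt2=bool(u_flags[i] < cfg.frac_possible_mpc_gt2),
                denovo_lambda={
                    VariantClass.PTV_ONLY: lam,
                    VariantClass.MPC_GT2: lam,
                },
                chrom_category=chrom,
                excluded_clonal_haem=excluded,
            )
        )
    return genes


def _risk_map(cfg: SimConfig, panel: Sequence[GeneAnnotation]) -> dict:
    """gene_id -> (VariantClass, OR); validates possible-variant flags."""
    truth = {}
    for idx, vclass, orr in cfg.risk_genes:
        vclass = VariantClass(vclass)
        ann = panel[idx]
        gens = CLASS_TO_GENERATORS[vclass]
        needs_mis = bool(gens & {"mis_gt3", "mis_2_3"})
        if needs_mis and not ann.has_possible_mpc_gt2:
            raise ConfigError(
                f"risk_genes: gene {ann.gene_id} lacks possible MPC>2 variants "
                f"but is planted with class {vclass.value}"
            )
        if "mis_gt3" in gens and vclass is VariantClass.PTV_MPC_GT3 and not ann.has_possible_mpc_gt3:
            raise ConfigError(
                f"risk_genes: gene {ann.gene_id} lacks possible MPC>3 variants "
                f"but is planted with class {vclass.value}"
            )
        truth[ann.gene_id] = (vclass, float(orr))
    return truth


def _draw_mac_reference(rng: np.random.Generator, size: int, cfg: SimConfig) -> np.ndarray:
    """Categorical reference-panel MAC: mostly <= 5, a tail above the cap."""
    u = rng.random(size)
    out = np.empty(size, dtype=int)
    gt5 = u < cfg.mac_gt5_fraction
    out[gt5] = rng.integers(6, 31, size=int(gt5.sum()))
    rest = ~gt5
    n_rest = int(rest.sum())
    zero = rng.random(n_rest) < cfg.reference_zero_fraction
    vals = np.where(zero, 0, rng.integers(1, 6, size=n_rest))
    out[rest] = vals
    return out


def simulate_case_control(
    cfg: SimConfig,
    panel: Sequence[GeneAnnotation],
    rng: Optional[np.random.Generator] = None,
):
    """Draw samples and ultra-rare variant records with planted odds ratios.

    Returns ``(variants, samples, truth)``.  Exome-wide burden (total rare
    carriage events per sample) is appended to each sample's covariate
    vector after the principal components.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    truth = _risk_map(cfg, panel)
    n_genes = len(panel)
    gene_ids = [g.gene_id for g in panel]
    chrom = [g.chrom_category for g in panel]
    p0 = cfg.baseline_carrier_rate
    p_syn = cfg.synonymous_rate if cfg.synonymous_rate is not None else p0
    p_mis = cfg.missense_rate if cfg.missense_rate is not None else p0

    def _base_rate(name: str) -> float:
        if name == "syn":
            return p_syn
        if name in ("mis_gt3", "mis_2_3"):
            return p_mis
        return p0

    # per generating class: baseline and per-gene boosted case rates
    case_rates = {}
    for name, _, _ in _GEN_CLASSES:
        base = _base_rate(name)
        rates = np.full(n_genes, base)
        for i, g in enumerate(panel):
            if g.gene_id in truth:
                vclass, orr = truth[g.gene_id]
                if name in CLASS_TO_GENERATORS[vclass] and base > 0:
                    rates[i] = _boosted_rate(base, orr)
        case_rates[name] = rates

    samples: list = []
    variants: list = []
    events_by_sample: dict = {}
    for si, (n_cases, n_controls) in enumerate(cfg.stratum_sizes):
        stratum = f"stratum{si}"
        n_tot = n_cases + n_controls
        sids = [f"S{si}_{j:05d}" for j in range(n_tot)]
        phen = [Phenotype.CASE] * n_cases + [Phenotype.CONTROL] * n_controls
        sex = [Sex.MALE if u < 0.5 else Sex.FEMALE for u in rng.random(n_tot)]
        pcs = rng.standard_normal((n_tot, cfg.n_pcs))
        for j in range(n_tot):
            events_by_sample[sids[j]] = 0
            samples.append(
                SampleRecord(
                    sample_id=sids[j],
                    phenotype=phen[j],
                    stratum=stratum,
                    sex=sex[j],
                    covariates=tuple(pcs[j]),
                )
            )
        for name, consequence, mpc_range in _GEN_CLASSES:
            base = _base_rate(name)
            if base == 0 and not np.any(case_rates[name] > 0):
                continue
            pmat = np.empty((n_genes, n_tot))
            pmat[:, :n_cases] = case_rates[name][:, None]
            pmat[:, n_cases:] = base
            hits = rng.random((n_genes, n_tot)) < pmat
            g_idx, s_idx = np.nonzero(hits)
            mac_ref = _draw_mac_reference(rng, g_idx.size, cfg)
            if mpc_range is not None:
                mpcs = rng.uniform(mpc_range[0], mpc_range[1], size=g_idx.size)
            for k in range(g_idx.size):
                gi = int(g_idx[k])
                sid = sids[int(s_idx[k])]
                events_by_sample[sid] += 1
                variants.append(
                    VariantRecord(
                        gene_id=gene_ids[gi],
                        carrier_ids=frozenset({sid}),
                        consequence=consequence,
                        mpc=float(mpcs[k]) if mpc_range is not None else None,
                        chrom_category=chrom[gi],
                        mac_internal=1,
                        mac_reference=int(mac_ref[k]),
                    )
                )

    # append exome-wide burden (optionally stratum-confounded) as last covariate
    for s in samples:
        b = float(events_by_sample[s.sample_id])
        if cfg.confounded_burden:
            b += 2.0 * int(s.stratum.removeprefix("stratum"))
        s.covariates = s.covariates + (b,)
    return variants, samples, truth


def simulate_trios(
    cfg: SimConfig,
    panel: Sequence[GeneAnnotation],
    rng: Optional[np.random.Generator] = None,
) -> list:
    """Poisson de novo counts per gene x class against per-gene expectations.

    Risk genes receive ``denovo_enrichment`` times the expectation for the
    de novo class(es) matching the planted variant class.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    truth = _risk_map(cfg, panel)
    records = []
    for g in panel:
        for dn_class, gen_name in (
            (VariantClass.PTV_ONLY, "ptv"),
            (VariantClass.MPC_GT2, "mis_gt3"),
        ):
            lam = g.denovo_lambda.get(dn_class, 0.0)
            enr = 1.0
            if g.gene_id in truth:
                vclass, _ = truth[g.gene_id]
                gens = CLASS_TO_GENERATORS[vclass]
                if (dn_class is VariantClass.PTV_ONLY and "ptv" in gens) or (
                    dn_class is VariantClass.MPC_GT2 and gens & {"mis_gt3", "mis_2_3"}
                ):
                    enr = cfg.denovo_enrichment
            observed = int(rng.poisson(lam * enr)) if lam > 0 else 0
            records.append(DenovoRecord(g.gene_id, dn_class, observed, lam))
    return records


def simulate_study(cfg: SimConfig) -> SyntheticStudy:
    """One seeded draw of the complete study: panel, case-control data, trios."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    panel = simulate_gene_panel(cfg, rng)
    variants, samples, truth = simulate_case_control(cfg, panel, rng)
    denovo = simulate_trios(cfg, panel, rng)
    return SyntheticStudy(variants, samples, panel, denovo, truth, cfg)
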