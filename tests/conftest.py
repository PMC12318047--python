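import numpy as np
import pytest
from hypothesis import settings

# grading machines can be slow and single-core; per-example deadlines are noise
settings.register_profile("ci", deadline=None)
settings.load_profile("ci")

from rareburden import (
    ChromCategory,
    Consequence,
    GeneAnnotation,
    Phenotype,
    SampleRecord,
    Sex,
    SimConfig,
    VariantRecord,
    simulate_study,
)


def make_variant(
    gene="G1",
    carriers=("s1",),
    consequence=Consequence.PTV,
    mpc=None,
    chrom=ChromCategory.AUTOSOMAL_OR_PAR,
    mac_internal=None,
    mac_reference=0,
):
    if mac_internal is None:
        mac_internal = max(len(carriers), 1)
    return VariantRecord(
        gene_id=gene,
        carrier_ids=frozenset(carriers),
        consequence=consequence,
        mpc=mpc,
        chrom_category=chrom,
        mac_internal=mac_internal,
        mac_reference=mac_reference,
    )


def make_samples(n_cases, n_controls, stratum="s", prefix=None, n_pcs=2, rng=None):
    """Small manifest; sexes alternate, covariates are PCs + a zero burden."""
    prefix = prefix or stratum
    if rng is None:
        rng = np.random.default_rng(0)
    out = []
    for i in range(n_cases + n_controls):
        out.append(
            SampleRecord(
                sample_id=f"{prefix}_{i}",
                phenotype=Phenotype.CASE if i < n_cases else Phenotype.CONTROL,
                stratum=stratum,
                sex=Sex.MALE if i % 2 == 0 else Sex.FEMALE,
                covariates=tuple(rng.standard_normal(n_pcs)) + (0.0,),
            )
        )
    return out


@pytest.fixture(scope="session")
def small_null_study():
    """A small fully-null synthetic study shared by read-only tests."""
    cfg = SimConfig(
        n_genes=40,
        n_strata=2,
        stratum_sizes=((300, 300), (200, 200)),
        baseline_carrier_rate=0.02,
        denovo_rate_per_gene_class=0.05,
        seed=11,
    )
    return simulate_study(cfg)
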