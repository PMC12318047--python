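"""Tab-separated readers/writers for the study's external interfaces.

All tables are headered TSV; absent values are written as ".".  Readers
validate row by row and name the offending line on failure.
"""
from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import DataError
from .geneset import GeneSetSpec
from .meta import DenovoRecord, GeneResult, MultiplicityLedger
from .variants import (
    ChromCategory,
    GeneAnnotation,
    SampleRecord,
    VariantClass,
    VariantRecord,
)

_NA = "."


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return _NA
    if isinstance(x, bool):
        return str(int(x))
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as e:
        raise DataError(f"{path}: cannot parse TSV: {e}") from e
    return df


def _row_error(path, i, exc) -> DataError:
    # +2: one for the header, one for 1-based numbering
    return DataError(f"{path}: line {i + 2}: {exc}")


def write_variants_tsv(variants: Iterable[VariantRecord], path) -> None:
    rows = [
        {
            "gene_id": v.gene_id,
            "sample_ids": ",".join(sorted(v.carrier_ids)),
            "consequence": v.consequence.value,
            "mpc": _fmt(v.mpc),
            "chrom_category": v.chrom_category.value,
            "mac_internal": v.mac_internal,
            "mac_reference": v.mac_reference,
        }
        for v in variants
    ]
    cols = [
        "gene_id", "sample_ids", "consequence", "mpc",
        "chrom_category", "mac_internal", "mac_reference",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list:
    df = _read_tsv(path)
    required = {
        "gene_id", "sample_ids", "consequence", "mpc",
        "chrom_category", "mac_internal", "mac_reference",
    }
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                VariantRecord(
                    gene_id=row.gene_id,
                    carrier_ids=frozenset(
                        s for s in str(row.sample_ids).split(",") if s
                    ),
                    consequence=row.consequence,
                    mpc=None if row.mpc == _NA else float(row.mpc),
                    chrom_category=row.chrom_category,
                    mac_internal=int(row.mac_internal),
                    mac_reference=int(row.mac_reference),
                )
            )
        except (ValueError, DataError) as e:
            raise _row_error(path, i, e) from e
    return out


def write_samples_tsv(samples: Sequence[SampleRecord], path) -> None:
    if samples:
        ncov = len(samples[0].covariates)
    else:
        ncov = 1
    n_pcs = max(ncov - 1, 0)
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "phenotype": s.phenotype.value,
            "stratum": s.stratum,
            "sex": s.sex.value,
        }
        for j in range(n_pcs):
            row[f"pc{j + 1}"] = _fmt(s.covariates[j])
        row["exome_burden"] = _fmt(s.covariates[-1]) if s.covariates else _NA
        rows.append(row)
    cols = ["sample_id", "phenotype", "stratum", "sex"]
    cols += [f"pc{j + 1}" for j in range(n_pcs)] + ["exome_burden"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_samples_tsv(path) -> list:
    df = _read_tsv(path)
    for col in ("sample_id", "phenotype", "stratum", "sex"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    pc_cols = sorted(
        (c for c in df.columns if c.startswith("pc") and c[2:].isdigit()),
        key=lambda c: int(c[2:]),
    )
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            cov = [float(getattr(row, c)) for c in pc_cols]
            if "exome_burden" in df.columns:
                cov.append(float(row.exome_burden))
            out.append(
                SampleRecord(
                    sample_id=row.sample_id,
                    phenotype=row.phenotype,
                    stratum=row.stratum,
                    sex=row.sex,
                    covariates=tuple(cov),
                )
            )
        except (ValueError, DataError) as e:
            raise _row_error(path, i, e) from e
    return out


def write_genes_tsv(genes: Sequence[GeneAnnotation], path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "pli": _fmt(g.pli),
            "has_possible_mpc_gt3": int(g.has_possible_mpc_gt3),
            "has_possible_mpc_gt2": int(g.has_possible_mpc_gt2),
            "lambda_ptv": _fmt(g.denovo_lambda.get(VariantClass.PTV_ONLY, 0.0)),
            "lambda_mis_gt2": _fmt(g.denovo_lambda.get(VariantClass.MPC_GT2, 0.0)),
            "chrom_category": g.chrom_category.value,
            "excluded_clonal_haem": int(g.excluded_clonal_haem),
            "cnv_locus": g.cnv_locus if g.cnv_locus else _NA,
        }
        for g in genes
    ]
    cols = [
        "gene_id", "pli", "has_possible_mpc_gt3", "has_possible_mpc_gt2",
        "lambda_ptv", "lambda_mis_gt2", "chrom_category",
        "excluded_clonal_haem", "cnv_locus",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_genes_tsv(path) -> list:
    df = _read_tsv(path)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                GeneAnnotation(
                    gene_id=row.gene_id,
                    pli=float(row.pli),
                    has_possible_mpc_gt3=bool(int(row.has_possible_mpc_gt3)),
                    has_possible_mpc_gt2=bool(int(row.has_possible_mpc_gt2)),
                    denovo_lambda={
                        VariantClass.PTV_ONLY: float(row.lambda_ptv),
                        VariantClass.MPC_GT2: float(row.lambda_mis_gt2),
                    },
                    chrom_category=row.chrom_category,
                    excluded_clonal_haem=bool(int(row.excluded_clonal_haem)),
                    cnv_locus=None if row.cnv_locus == _NA else row.cnv_locus,
                )
            )
        except (ValueError, DataError) as e:
            raise _row_error(path, i, e) from e
    return out


def write_denovo_tsv(records: Sequence[DenovoRecord], path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "variant_class": r.variant_class.value,
            "observed": r.observed,
            "expected": _fmt(r.expected),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["gene_id", "variant_class", "observed", "expected"]).to_csv(
        path, sep="\t", index=False
    )


def read_denovo_tsv(path) -> list:
    df = _read_tsv(path)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                DenovoRecord(
                    gene_id=row.gene_id,
                    variant_class=VariantClass(row.variant_class),
                    observed=int(row.observed),
                    expected=float(row.expected),
                )
            )
        except (ValueError, DataError) as e:
            raise _row_error(path, i, e) from e
    return out


def read_genesets_tsv(path) -> list:
    """Long-format gene sets: set_name, gene_id, variant_class, filter."""
    df = _read_tsv(path)
    specs = []
    for (name, vclass, filt), sub in df.groupby(
        ["set_name", "variant_class", "filter"], sort=False
    ):
        specs.append(
            GeneSetSpec(
                name=name,
                gene_ids=frozenset(sub["gene_id"]),
                variant_class=VariantClass(vclass),
                rarity=filt,
            )
        )
    return specs


def write_genesets_tsv(specs: Sequence[GeneSetSpec], path) -> None:
    rows = [
        {
            "set_name": s.name,
            "gene_id": g,
            "variant_class": s.variant_class.value,
            "filter": s.rarity if isinstance(s.rarity, str) else "custom",
        }
        for s in specs
        for g in sorted(s.gene_ids)
    ]
    pd.DataFrame(rows, columns=["set_name", "gene_id", "variant_class", "filter"]).to_csv(
        path, sep="\t", index=False
    )


def gene_results_frame(results: Sequence[GeneResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "gene_id": r.gene_id,
                "variant_class": r.variant_class.value,
                "testable": int(r.testable),
                "n_informative_strata": r.n_informative_strata,
                "or_mh": r.or_mh,
                "ci_lower": r.ci95[0],
                "ci_upper": r.ci95[1],
                "p_cc": r.p_cc,
                "denovo_observed": r.denovo_observed,
                "denovo_expected": r.denovo_expected,
                "p_denovo": r.p_denovo,
                "p_meta": r.p_meta,
                "p_final": r.p_final,
                "q_value": r.q_value,
                "exome_wide_significant": int(r.exome_wide_significant),
                "fdr5_significant": int(r.fdr5_significant),
            }
        )
    return pd.DataFrame(rows)


def write_gene_results_tsv(results: Sequence[GeneResult], path) -> None:
    gene_results_frame(results).to_csv(
        path, sep="\t", index=False, float_format="%.6g", na_rep=_NA
    )


def write_ledger_tsv(ledger: MultiplicityLedger, path) -> None:
    pd.DataFrame(
        [
            {
                "n_cc_tests": ledger.n_cc_tests,
                "n_meta_tests": ledger.n_meta_tests,
                "n_total": ledger.n_total,
                "alpha": ledger.alpha,
                "bonferroni_threshold": f"{ledger.bonferroni_threshold:.6g}",
            }
        ]
    ).to_csv(path, sep="\t", index=False)


def variants_from_vcf(path, reference_ac_key: str = "REF_AC") -> list:
    """Read variant records from a VCF annotated with GENE, CSQ_CLASS and MPC.

    One record per alternate allele; carriers are samples with a non-ref
    genotype, ``mac_internal`` is the alternate allele count over samples and
    ``mac_reference`` comes from the ``reference_ac_key`` INFO field
    (default 0 when absent).  Requires cyvcf2.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    sample_names = vcf.samples
    out = []
    for rec in vcf:
        gene = rec.INFO.get("GENE")
        csq = rec.INFO.get("CSQ_CLASS")
        if gene is None or csq is None:
            raise DataError(
                f"{path}: {rec.CHROM}:{rec.POS} lacks GENE/CSQ_CLASS INFO fields"
            )
        mpc = rec.INFO.get("MPC")
        carriers = set()
        mac = 0
        for name, gt in zip(sample_names, rec.genotypes):
            alleles = [a for a in gt[:-1] if a is not None and a >= 0]
            n_alt = sum(1 for a in alleles if a > 0)
            if n_alt:
                carriers.add(name)
                mac += n_alt
        if not carriers:
            continue
        chrom_cat = (
            ChromCategory.X_NONPAR
            if rec.CHROM in ("X", "chrX")
            else ChromCategory.AUTOSOMAL_OR_PAR
        )
        out.append(
            VariantRecord(
                gene_id=gene,
                carrier_ids=frozenset(carriers),
                consequence=str(csq),
                mpc=float(mpc) if mpc is not None else None,
                chrom_category=chrom_cat,
                mac_internal=mac,
                mac_reference=int(rec.INFO.get(reference_ac_key) or 0),
            )
        )
    return out
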