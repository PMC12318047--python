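"""Gene-set burden enrichment via Firth-penalized logistic regression.

Case/control status is regressed on the per-sample count of qualifying
variants within a gene set, adjusting for principal components, sex and the
exome-wide rare-coding burden.  The Jeffreys-prior penalty keeps estimates
finite under complete separation; the burden p-value comes from a penalized
likelihood-ratio test by default.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
from scipy.special import expit
from scipy.stats import chi2

from .errors import ConfigError, DataError
from .variants import (
    GeneAnnotation,
    Phenotype,
    SampleRecord,
    Sex,
    VariantClass,
    VariantRecord,
    class_membership,
    is_singleton,
    passes_rare_filter,
)

_Z975 = 1.959963984540054


@dataclass
class GeneSetSpec:
    """A named gene set tested for burden enrichment.

    ``rarity`` is ``"singleton"``, ``"mac5"`` (or ``"mac<k>"``) or a
    predicate over VariantRecord.
    """

    name: str
    gene_ids: frozenset
    variant_class: VariantClass = VariantClass.PTV_ONLY
    rarity: Union[str, Callable[[VariantRecord], bool]] = "mac5"

    def __post_init__(self) -> None:
        self.gene_ids = frozenset(self.gene_ids)
        self.variant_class = VariantClass(self.variant_class)
        if not self.gene_ids:
            raise ConfigError(f"gene set {self.name!r} is empty")

    def predicate(self) -> Callable[[VariantRecord], bool]:
        if callable(self.rarity):
            return self.rarity
        if self.rarity == "singleton":
            return is_singleton
        if self.rarity.startswith("mac"):
            cap = int(self.rarity[3:])
            return lambda v: passes_rare_filter(v, cap)
        raise ConfigError(f"unknown rarity filter {self.rarity!r} for set {self.name!r}")


@dataclass
class FirthFit:
    beta: np.ndarray
    se: np.ndarray
    or_burden: float
    ci95: tuple
    p_burden: float
    converged: bool
    n_iter: int
    loglik: float = math.nan


def set_burden_vector(
    samples: Sequence[SampleRecord],
    variants: Iterable[VariantRecord],
    spec: GeneSetSpec,
    panel: Optional[Sequence[GeneAnnotation]] = None,
) -> dict:
    """Per-sample count of qualifying variant carriages within the set's genes."""
    if panel is not None:
        known = {g.gene_id for g in panel}
        unknown = sorted(spec.gene_ids - known)
        if unknown:
            raise ConfigError(f"gene set {spec.name!r} names unknown genes: {unknown}")
    pred = spec.predicate()
    counts = {s.sample_id: 0 for s in samples}
    for v in variants:
        if v.gene_id not in spec.gene_ids:
            continue
        if not pred(v) or not class_membership(v, spec.variant_class):
            continue
        for sid in v.carrier_ids:
            if sid not in counts:
                raise DataError(f"carrier {sid!r} of {v.gene_id} not in sample manifest")
            counts[sid] += 1
    return counts


def _penalized_loglik(beta, y, X):
    eta = X @ beta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = expit(eta)
    w = p * (1.0 - p)
    info = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -math.inf
    return ll + 0.5 * logdet


def _firth_newton(y, X, free=None, max_iter=50, gtol=1e-6, lltol=1e-8, max_halving=10):
    """Newton iterations with Jeffreys-penalized score and step-halving.

    ``free`` marks the coefficients maximized over; the rest stay fixed at 0
    while the penalty keeps the *full* design's information determinant, so
    the constrained maximum is the profile penalized likelihood used by the
    penalized LRT.
    """
    n, k = X.shape
    if free is None:
        free = np.ones(k, dtype=bool)
    beta = np.zeros(k)
    pll = _penalized_loglik(beta, y, X)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        w = p * (1.0 - p)
        info = (X * w[:, None]).T @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as e:  # pragma: no cover
            raise DataError("information matrix is singular") from e
        # leverages of the weighted hat matrix of the full design
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - p + h * (0.5 - p))
        if np.max(np.abs(score[free])) <= gtol:
            converged = True
            break
        step = np.zeros(k)
        step[free] = np.linalg.solve(info[np.ix_(free, free)], score[free])
        new_pll = _penalized_loglik(beta + step, y, X)
        halved = 0
        while new_pll < pll and halved < max_halving:
            step *= 0.5
            halved += 1
            new_pll = _penalized_loglik(beta + step, y, X)
        beta = beta + step
        if abs(new_pll - pll) <= lltol * (abs(pll) + 1.0):
            pll = new_pll
            converged = True
            break
        pll = new_pll
    p = expit(X @ beta)
    w = p * (1.0 - p)
    info = (X * w[:, None]).T @ X
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se, _penalized_loglik(beta, y, X), converged, it


def firth_fit(
    y: Sequence[int],
    X: np.ndarray,
    burden_index: int = 1,
    pvalue_method: str = "plrt",
    max_iter: int = 50,
) -> FirthFit:
    """Fit a Firth-penalized logistic regression; test the burden coefficient.

    ``X`` must include the intercept column and have full column rank.  The
    burden p-value is a penalized likelihood-ratio test against the profile
    penalized likelihood at burden coefficient 0 (full-design penalty kept);
    ``pvalue_method="wald"`` uses the Wald chi-square instead.  CI is Wald on
    the log-odds scale, exponentiated.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.size:
        raise DataError("y and X have incompatible shapes")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise DataError("y must be binary 0/1")
    if y.min() == y.max():
        raise DataError("y is constant: no case/control contrast to fit")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("design matrix is rank-deficient")
    if pvalue_method not in ("plrt", "wald"):
        raise ConfigError(f"unknown pvalue_method {pvalue_method!r}")

    beta, se, pll_full, converged, n_iter = _firth_newton(y, X, max_iter=max_iter)
    b = beta[burden_index]
    s = se[burden_index]
    if pvalue_method == "wald":
        stat = (b / s) ** 2
    else:
        free = np.ones(X.shape[1], dtype=bool)
        free[burden_index] = False
        _, _, pll_null, conv0, _ = _firth_newton(y, X, free=free, max_iter=max_iter)
        converged = converged and conv0
        stat = max(2.0 * (pll_full - pll_null), 0.0)
    p = float(chi2.sf(stat, 1))
    ci = (math.exp(b - _Z975 * s), math.exp(b + _Z975 * s))
    return FirthFit(beta, se, math.exp(b), ci, p, converged, n_iter, pll_full)


@dataclass
class GeneSetResult:
    name: str
    or_burden: float
    ci95: tuple
    p_burden: float
    n_carriage_events: int
    fit: FirthFit = field(repr=False, default=None)


def geneset_test(
    samples: Sequence[SampleRecord],
    variants: Sequence[VariantRecord],
    spec: GeneSetSpec,
    panel: Optional[Sequence[GeneAnnotation]] = None,
    pvalue_method: str = "plrt",
) -> GeneSetResult:
    """Firth regression of phenotype on set burden with nuisance covariates.

    Design: intercept, set burden, the per-sample covariate vector (PCs then
    exome-wide burden) and sex coded 0/1.  Covariate vectors must be present
    and of equal length on every sample.
    """
    lens = {len(s.covariates) for s in samples}
    if len(lens) != 1:
        raise DataError("covariate vectors differ in length across samples")
    burden = set_burden_vector(samples, variants, spec, panel)
    y = np.array([1.0 if s.phenotype is Phenotype.CASE else 0.0 for s in samples])
    cols = [
        np.ones(len(samples)),
        np.array([float(burden[s.sample_id]) for s in samples]),
    ]
    ncov = lens.pop()
    for j in range(ncov):
        cols.append(np.array([s.covariates[j] for s in samples]))
    cols.append(np.array([1.0 if s.sex is Sex.MALE else 0.0 for s in samples]))
    X = np.column_stack(cols)
    # drop constant nuisance columns (e.g. single-sex studies) to keep full rank
    keep = [0, 1] + [
        j for j in range(2, X.shape[1]) if np.ptp(X[:, j]) > 0
    ]
    X = X[:, keep]
    fit = firth_fit(y, X, burden_index=1, pvalue_method=pvalue_method)
    return GeneSetResult(
        spec.name, fit.or_burden, fit.ci95, fit.p_burden, int(sum(burden.values())), fit
    )
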