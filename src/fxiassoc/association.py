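"""Covariate-adjusted single-variant linear association.

Each common variant is tested with OLS of the phenotype on
``[1, dosage, age, sex]``; the reported effect is per copy of the sample
minor allele (dosages are flipped when the ALT allele is the major one, so
the tested allele is always the minor allele). Family-wise error and FDR
control over the panel of tested variants is available through six
corrections: Bonferroni, Holm, Sidak single-step, Sidak step-down,
Benjamini-Hochberg and Benjamini-Yekutieli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .variants import GenotypeMatrix, VariantRecord, compute_maf

__all__ = [
    "AssociationResult",
    "NormalityReport",
    "MonomorphicVariantError",
    "ADJUST_METHODS",
    "fit_linear",
    "adjust_pvalues",
    "test_normality",
    "SingleVariantAssociation",
]


class MonomorphicVariantError(ValueError):
    """The dosage vector is constant after missing-data exclusion."""


@dataclass
class AssociationResult:
    variant_id: str
    tested_allele: str  # "alt" or "ref": whichever is the sample minor allele
    maf: float
    n: int
    beta: float
    se: float
    t_stat: float
    p: float
    adjusted_p: dict[str, float] | None = None


@dataclass(frozen=True)
class NormalityReport:
    W: float
    p: float
    n: int


# name -> statsmodels method string
ADJUST_METHODS = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "sidak_single_step": "sidak",
    "sidak_step_down": "holm-sidak",
    "bh": "fdr_bh",
    "by": "fdr_by",
}


def fit_linear(
    y: np.ndarray,
    g: np.ndarray,
    covariates: np.ndarray,
    variant_id: str = "",
    orient_minor: bool = True,
) -> AssociationResult:
    """OLS association of phenotype on minor-allele dosage plus covariates.

    Missing dosages drop the individual for this variant only
    (complete-case). The two-sided p-value comes from the t distribution
    of the dosage coefficient. With ``orient_minor`` (the reporting
    convention: the tested allele is the sample minor allele) the dosage is
    flipped when the ALT allele is the major one, which makes the result
    invariant to allele labelling; with ``orient_minor=False`` the raw ALT
    dosage is used and recoding ``d -> 2 - d`` flips the sign of beta while
    leaving the p-value unchanged.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != y.shape[0]:
        covariates = covariates.T
    mask = ~np.isnan(g)
    y, g, covariates = y[mask], g[mask], covariates[mask]
    n = y.shape[0]
    if np.ptp(g) == 0:
        raise MonomorphicVariantError(f"variant {variant_id or '<anon>'} is monomorphic")
    maf = compute_maf(g)
    alt_freq = g.sum() / (2 * n)
    if orient_minor and alt_freq > 0.5:
        g = 2.0 - g
        tested_allele = "ref"
    else:
        tested_allele = "alt"

    X = np.column_stack([np.ones(n), g, covariates])
    p_params = X.shape[1]
    if n <= p_params + 1:
        raise ValueError("too few individuals for the design")
    if np.linalg.matrix_rank(X) < p_params:
        raise ValueError("rank-deficient design matrix")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - p_params
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(coef[1])
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return AssociationResult(
        variant_id=variant_id,
        tested_allele=tested_allele,
        maf=maf,
        n=n,
        beta=beta,
        se=se,
        t_stat=float(t),
        p=float(p),
    )


def adjust_pvalues(
    pvals: np.ndarray, method: str, m: int | None = None
) -> np.ndarray:
    """Multiple-testing adjustment, returned in the input order.

    ``m`` overrides the number of tests for the single-step methods
    (Bonferroni and Sidak single-step), which is useful when adjusting a
    subset of a larger panel; the step methods require ``m == len(pvals)``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must be in [0, 1]")
    if method not in ADJUST_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(ADJUST_METHODS)}")
    if m is not None and m != p.size:
        if method == "bonferroni":
            return np.minimum(1.0, p * m)
        if method == "sidak_single_step":
            return 1.0 - (1.0 - p) ** m
        raise ValueError(f"explicit m is only supported for single-step methods, not {method}")
    if p.size == 0:
        return p.copy()
    _, adj, _, _ = multipletests(p, alpha=0.05, method=ADJUST_METHODS[method])
    return adj


def test_normality(y: np.ndarray) -> NormalityReport:
    """Shapiro-Wilk normality test (valid for 3 <= n <= 5000)."""
    y = np.asarray(y, dtype=float)
    if not 3 <= y.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {y.size}")
    W, p = stats.shapiro(y)
    return NormalityReport(W=float(W), p=float(p), n=int(y.size))


class SingleVariantAssociation(BaseEstimator):
    """Panel-wide covariate-adjusted linear association.

    Fits :func:`fit_linear` to every column of a dosage matrix and applies
    the requested multiple-testing corrections across the panel.

    Parameters
    ----------
    methods:
        Correction names (keys of :data:`ADJUST_METHODS`); all six by
        default.
    n_tests:
        Override for the single-step correction count; defaults to the
        number of testable (polymorphic) variants.

    Attributes
    ----------
    results_ : DataFrame with one row per testable variant
    skipped_ : list of (variant_id, reason) for untestable variants
    """

    def __init__(self, methods: tuple[str, ...] | None = None, n_tests: int | None = None):
        self.methods = methods
        self.n_tests = n_tests

    def fit(self, X, y, covariates=None, variant_ids=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if covariates is None:
            covariates = np.empty((y.size, 0))
        variant_ids = (
            [f"v{j}" for j in range(X.shape[1])] if variant_ids is None else list(variant_ids)
        )
        methods = tuple(self.methods) if self.methods is not None else tuple(ADJUST_METHODS)
        results: list[AssociationResult] = []
        skipped: list[tuple[str, str]] = []
        for j, vid in enumerate(variant_ids):
            try:
                results.append(fit_linear(y, X[:, j], covariates, variant_id=vid))
            except MonomorphicVariantError:
                skipped.append((vid, "monomorphic"))
        raw = np.array([r.p for r in results])
        m = self.n_tests if self.n_tests is not None else raw.size
        adj: dict[str, np.ndarray] = {}
        for method in methods:
            if m != raw.size and method not in ("bonferroni", "sidak_single_step"):
                adj[method] = adjust_pvalues(raw, method)
            else:
                adj[method] = adjust_pvalues(raw, method, m=m)
        rows = []
        for k, r in enumerate(results):
            r.adjusted_p = {method: float(adj[method][k]) for method in methods}
            row = {
                "variant_id": r.variant_id,
                "tested_allele": r.tested_allele,
                "maf": r.maf,
                "n": r.n,
                "beta": r.beta,
                "se": r.se,
                "t_stat": r.t_stat,
                "p": r.p,
            }
            row.update({f"p_{mth}": r.adjusted_p[mth] for mth in methods})
            rows.append(row)
        self.results_ = pd.DataFrame(rows)
        self.skipped_ = skipped
        self.n_tests_ = m
        return self

    def to_table(self, variants: list[VariantRecord] | None = None) -> pd.DataFrame:
        """Association table with annotation columns merged in."""
        df = self.results_.copy()
        if variants:
            ann = pd.DataFrame(
                {
                    "variant_id": [v.variant_id for v in variants],
                    "gene": [v.gene for v in variants],
                    "location": [f"{v.chrom}:{v.pos}" for v in variants],
                    "hgvs_c": [v.hgvs_c for v in variants],
                    "dbsnp_id": [v.dbsnp_id for v in variants],
                }
            )
            df = ann.merge(df, on="variant_id", how="right")
        return df
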