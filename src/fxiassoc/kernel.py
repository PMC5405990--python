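"""Sliding-window kernel score tests for low-frequency variants.

The set test is a variance-component score test for a quantitative trait:
with OLS residuals ``r`` from the covariate-only null model and a weighted
dosage submatrix ``Z = G W`` for the variants of one window, the statistic

    Q = r' Z Z' r = || Z' r ||^2

follows, under the null, a mixture of one-degree chi-squares
``sum_k lambda_k chi^2_1`` whose weights are the eigenvalues of
``sigma^2 * Z' P0 Z`` (``P0`` projects off the covariate space). Tail
probabilities are evaluated by Imhof's numerical inversion with the Liu
moment-matching approximation as fallback (and as the fast vectorised
route inside the permutation loop).

Windows are anchored at each successive low-frequency variant and span
``[anchor, anchor + 2000]`` bp (inclusive). Family-wise error over all
windows (both loci jointly) is controlled by a min-p phenotype-permutation
procedure; overlapping significant windows merge into regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats
from sklearn.base import BaseEstimator

from .variants import GenotypeMatrix, compute_maf

__all__ = [
    "VariantSet",
    "NullModel",
    "Region",
    "SkatResult",
    "build_windows",
    "fit_null_model",
    "weights_beta",
    "mixture_chi2_sf",
    "liu_sf",
    "imhof_sf",
    "skat_test",
    "permutation_fwer",
    "merge_regions",
    "SlidingWindowKernelTest",
]

WINDOW_WIDTH_BP = 2000


@dataclass
class VariantSet:
    """One 2-kb window of low-frequency variants and its test results."""

    chrom: str
    window_start: int
    window_end: int
    member_ids: list[str]
    member_idx: np.ndarray  # column indices into the low-frequency matrix
    Q: float | None = None
    eigenvalues: np.ndarray | None = None
    p: float | None = None
    empirical_p: float | None = None
    significant_fwer: bool | None = None
    tested: bool = True  # False when every member is monomorphic

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


@dataclass
class NullModel:
    """Covariate-only OLS fit used to residualise the phenotype."""

    coef: np.ndarray
    residuals: np.ndarray
    sigma2: float
    X: np.ndarray
    q_basis: np.ndarray  # orthonormal basis of the covariate column space

    def project_out(self, M: np.ndarray) -> np.ndarray:
        """Apply the residual-space projection P0 = I - X(X'X)^-1 X'."""
        return M - self.q_basis @ (self.q_basis.T @ M)


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    tier: str  # "nominal" | "fwer"
    n_sets: int


@dataclass
class SkatResult:
    Q: float
    eigenvalues: np.ndarray
    p: float
    tail_method: str
    tested: bool = True


def build_windows(
    variant_ids: list[str],
    chroms: list[str],
    positions: np.ndarray,
    width_bp: int = WINDOW_WIDTH_BP,
) -> list[VariantSet]:
    """One window per variant: ``[pos, pos + width_bp]`` on its chromosome,
    holding every listed variant inside the interval (right edge inclusive).
    Input must be position-sorted within chromosome."""
    positions = np.asarray(positions)
    sets: list[VariantSet] = []
    for a, anchor_pos in enumerate(positions):
        chrom = chroms[a]
        lo, hi = int(anchor_pos), int(anchor_pos) + width_bp
        idx = [
            j
            for j in range(len(positions))
            if chroms[j] == chrom and lo <= positions[j] <= hi
        ]
        sets.append(
            VariantSet(
                chrom=chrom,
                window_start=lo,
                window_end=hi,
                member_ids=[variant_ids[j] for j in idx],
                member_idx=np.asarray(idx, dtype=int),
            )
        )
    return sets


def fit_null_model(y: np.ndarray, covariates: np.ndarray | None) -> NullModel:
    """OLS of the phenotype on an intercept plus covariates."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if covariates is None or np.size(covariates) == 0:
        X = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        X = np.column_stack([np.ones(n), covariates])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient covariate design")
    q_basis, _ = np.linalg.qr(X)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / (n - rank)
    return NullModel(coef=coef, residuals=resid, sigma2=sigma2, X=X, q_basis=q_basis)


def weights_beta(maf: np.ndarray | float, a: float = 1.0, b: float = 25.0):
    """Beta-density variant weight; Beta(1, 25) up-weights rarer variants."""
    return stats.beta.pdf(np.asarray(maf, dtype=float), a, b)


def liu_sf(q, eigenvalues: np.ndarray):
    """Liu-Tang-Zhang moment-matching survival function of a positive
    mixture of chi^2_1 variables; accepts scalar or vector ``q``."""
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        return np.ones_like(np.asarray(q, dtype=float)) if np.ndim(q) else 1.0
    c1, c2, c3, c4 = (float((lam**k).sum()) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        ell = a**2 - 2 * delta
    else:
        delta = 0.0
        ell = c2**3 / c3**2
    mu_q, sigma_q = c1, np.sqrt(2 * c2)
    mu_x, sigma_x = ell + delta, np.sqrt(2) * np.sqrt(ell + 2 * delta)
    t = (np.asarray(q, dtype=float) - mu_q) / sigma_q
    x = t * sigma_x + mu_x
    if delta > 0:
        p = stats.ncx2.sf(x, ell, delta)
    else:
        p = stats.chi2.sf(x, ell)
    return p if np.ndim(q) else float(p)


def imhof_sf(q: float, eigenvalues: np.ndarray) -> float:
    """Imhof (1961) numerical inversion for P(sum_k lambda_k chi^2_1 > q).

    Returns NaN when the quadrature fails to produce a probability, so the
    caller can fall back to :func:`liu_sf`.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        return 1.0
    # the mixture is invariant under joint rescaling; normalise so the
    # integrand oscillates on an O(1) scale and quadrature can resolve it
    scale = lam.max()
    lam = lam / scale
    q = q / scale

    def integrand(u: float) -> float:
        theta = 0.5 * np.arctan(lam * u).sum() - 0.5 * q * u
        rho = np.exp(0.25 * np.log1p((lam * u) ** 2).sum())
        return np.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        try:
            val, err = integrate.quad(
                integrand, 0.0, np.inf, limit=2000, epsabs=1e-9, epsrel=1e-8
            )
        except Exception:
            return float("nan")
    p = 0.5 + val / np.pi
    if not np.isfinite(p) or err > 1e-4 or p < -1e-6 or p > 1 + 1e-6:
        return float("nan")
    return float(min(max(p, 0.0), 1.0))


def mixture_chi2_sf(
    q: float, eigenvalues: np.ndarray, method: str = "imhof"
) -> tuple[float, str]:
    """Tail probability of a chi-square mixture; returns (p, method used)."""
    if method == "liu":
        return float(liu_sf(q, eigenvalues)), "liu"
    if method != "imhof":
        raise ValueError(f"unknown tail method {method!r}")
    p = imhof_sf(q, eigenvalues)
    if np.isnan(p) or p == 0.0:
        # quadrature failed or underflowed in the extreme tail
        return float(liu_sf(q, eigenvalues)), "liu"
    return p, "imhof"


def _set_machinery(
    null: NullModel, G_set: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted, mean-imputed dosage matrix Z and base eigenvalues
    nu = eig(Z' P0 Z) (to be scaled by sigma^2)."""
    G = np.asarray(G_set, dtype=float)
    if np.isnan(G).any():
        means = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G = G.copy()
        G[idx] = means[idx[1]]
    Z = G * np.asarray(weights, dtype=float)[np.newaxis, :]
    Zp = null.project_out(Z)
    nu = np.linalg.eigvalsh(Zp.T @ Zp)
    nu = nu[nu > max(1e-10, 1e-10 * (nu.max() if nu.size else 0.0))]
    return Z, nu


def skat_test(
    null: NullModel,
    G_set: np.ndarray,
    weights: np.ndarray,
    tail_method: str = "imhof",
) -> SkatResult:
    """Variance-component score test of one variant set.

    A set whose members are all monomorphic carries no signal and returns
    the defined no-test result (Q = 0, p = 1, ``tested=False``).
    """
    if G_set.ndim != 2 or G_set.shape[1] == 0:
        raise ValueError("G_set must be a non-empty 2-d matrix")
    Z, nu = _set_machinery(null, G_set, weights)
    q_stat = float(((Z.T @ null.residuals) ** 2).sum())
    lam = nu * null.sigma2
    if lam.size == 0:
        return SkatResult(Q=q_stat, eigenvalues=lam, p=1.0, tail_method="none", tested=False)
    p, used = mixture_chi2_sf(q_stat, lam, method=tail_method)
    return SkatResult(Q=q_stat, eigenvalues=lam, p=p, tail_method=used)


def _liu_params(nu: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Scale-free Liu parameters from unscaled eigenvalues ``nu``: the
    standardisation (Q - sigma^2 C1)/(sigma^2 sqrt(2 C2)) leaves the
    matched chi-square unchanged under sigma^2 rescaling."""
    c1, c2, c3, c4 = (float((nu**k).sum()) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        ell = a**2 - 2 * delta
    else:
        delta = 0.0
        ell = c2**3 / c3**2
    mu_x, sigma_x = ell + delta, np.sqrt(2) * np.sqrt(ell + 2 * delta)
    return c1, c2, ell, delta, mu_x, sigma_x


def permutation_fwer(
    y: np.ndarray,
    covariates: np.ndarray | None,
    genotypes: np.ndarray,
    sets: list[VariantSet],
    weights: np.ndarray | None = None,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    tail_method: str = "liu",
    scheme: str = "phenotype",
) -> list[VariantSet]:
    """Min-p permutation adjustment of the set tests (Westfall-Young style).

    For each of ``B`` permutations the phenotype vector is shuffled across
    individuals (covariates stay attached to their individuals and the null
    model is refit), every set's analytic p is recomputed, and the minimum
    over sets is recorded. The empirical p of set ``s`` is
    ``(1 + #{b : min_b <= p_s}) / (B + 1)``; a set is family-wise
    significant when its empirical p is at or below ``alpha``.

    ``scheme="freedman_lane"`` permutes null-model residuals and adds them
    back to the fitted values instead of permuting the raw phenotype.

    Observed and permuted p-values all use the same tail method (Liu by
    default, vectorised across permutations) so the min-p comparison is
    internally consistent. The input ``sets`` are updated in place (fields
    ``Q``, ``eigenvalues``, ``p``, ``empirical_p``, ``significant_fwer``)
    and returned.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(y, dtype=float)
    n = y.size
    null = fit_null_model(y, covariates)
    G = np.asarray(genotypes, dtype=float)
    if weights is None:
        mafs = np.array([compute_maf(G[:, j]) if np.ptp(G[~np.isnan(G[:, j]), j]) > 0 else 0.0
                         for j in range(G.shape[1])])
        weights = weights_beta(np.maximum(mafs, 1e-12))

    rng = np.random.default_rng(seed)
    # permutation matrix of phenotypes: column 0 = observed
    Y = np.empty((n, B + 1))
    if scheme == "phenotype":
        Y[:, 0] = y
        for b in range(1, B + 1):
            Y[:, b] = y[rng.permutation(n)]
    elif scheme == "freedman_lane":
        fitted = null.X @ null.coef
        Y[:, 0] = y
        for b in range(1, B + 1):
            Y[:, b] = fitted + null.residuals[rng.permutation(n)]
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    P0Y = Y - null.q_basis @ (null.q_basis.T @ Y)
    dof = n - null.X.shape[1]
    sigma2 = (P0Y**2).sum(axis=0) / dof  # per permutation

    # per-set machinery
    blocks: list[np.ndarray] = []
    nus: list[np.ndarray] = []
    for s in sets:
        Z, nu = _set_machinery(null, G[:, s.member_idx], weights[s.member_idx])
        blocks.append(Z)
        nus.append(nu)

    S = len(sets)
    pmat = np.ones((S, B + 1))
    qmat = np.zeros((S, B + 1))
    if S:
        Zall = np.hstack(blocks)
        M = Zall.T @ P0Y  # Z' P0 y_b = Z' r_b
        offset = 0
        for si, (s, nu) in enumerate(zip(sets, nus)):
            m = s.n_members
            qs = (M[offset : offset + m, :] ** 2).sum(axis=0)
            qmat[si] = qs
            offset += m
            if nu.size == 0:
                s.tested = False
                continue
            if tail_method == "liu":
                c1, c2, ell, delta, mu_x, sigma_x = _liu_params(nu)
                t = (qs / sigma2 - c1) / np.sqrt(2 * c2)
                x = t * sigma_x + mu_x
                pmat[si] = (
                    stats.ncx2.sf(x, ell, delta) if delta > 0 else stats.chi2.sf(x, ell)
                )
            elif tail_method == "imhof":
                for b in range(B + 1):
                    pmat[si, b], _ = mixture_chi2_sf(qs[b], nu * sigma2[b], "imhof")
            else:
                raise ValueError(f"unknown tail method {tail_method!r}")

    min_p = pmat[:, 1:].min(axis=0) if S else np.array([])
    for si, s in enumerate(sets):
        s.Q = float(qmat[si, 0])
        s.eigenvalues = nus[si] * sigma2[0]
        s.p = float(pmat[si, 0])
        s.empirical_p = float((1 + (min_p <= pmat[si, 0]).sum()) / (B + 1))
        s.significant_fwer = bool(s.empirical_p <= alpha)
    return sets


def merge_regions(
    sets: list[VariantSet], alpha: float = 0.05, tier: str = "nominal"
) -> list[Region]:
    """Union the intervals of the selected sets into maximal disjoint
    regions (position sweep per chromosome; output sorted).

    ``tier="nominal"`` selects sets with analytic p < alpha;
    ``tier="fwer"`` selects sets flagged significant by the permutation
    procedure.
    """
    if tier == "nominal":
        chosen = [s for s in sets if s.p is not None and s.p < alpha]
    elif tier == "fwer":
        chosen = [s for s in sets if s.significant_fwer]
    else:
        raise ValueError(f"unknown tier {tier!r}")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in chosen:
        by_chrom.setdefault(s.chrom, []).append((s.window_start, s.window_end))
    regions: list[Region] = []
    for chrom in sorted(by_chrom):
        ivals = sorted(by_chrom[chrom])
        cur_start, cur_end = ivals[0]
        count = 1
        for start, end in ivals[1:]:
            if start <= cur_end:  # overlap (>= 1 shared bp)
                cur_end = max(cur_end, end)
                count += 1
            else:
                regions.append(Region(chrom, cur_start, cur_end, tier, count))
                cur_start, cur_end, count = start, end, 1
        regions.append(Region(chrom, cur_start, cur_end, tier, count))
    return regions


class SlidingWindowKernelTest(BaseEstimator):
    """End-to-end sliding-window kernel association with permutation FWER.

    ``fit`` selects the polymorphic low-frequency columns of a dosage
    matrix (sample MAF below ``maf_threshold``), builds one 2-kb window
    per such variant, runs the kernel score test per window and the min-p
    permutation adjustment across all windows jointly.

    Attributes
    ----------
    sets_ : list of VariantSet with all statistics filled
    results_ : tidy per-window DataFrame
    regions_nominal_, regions_fwer_ : merged regions at each tier
    """

    def __init__(
        self,
        maf_threshold: float = 0.10,
        width_bp: int = WINDOW_WIDTH_BP,
        weight_beta_a: float = 1.0,
        weight_beta_b: float = 25.0,
        flat_weights: bool = False,
        B: int = 1000,
        alpha: float = 0.05,
        tail_method: str = "liu",
        scheme: str = "phenotype",
        random_state: int = 0,
    ) -> None:
        self.maf_threshold = maf_threshold
        self.width_bp = width_bp
        self.weight_beta_a = weight_beta_a
        self.weight_beta_b = weight_beta_b
        self.flat_weights = flat_weights
        self.B = B
        self.alpha = alpha
        self.tail_method = tail_method
        self.scheme = scheme
        self.random_state = random_state

    def fit(self, X, y, positions=None, chroms=None, covariates=None, variant_ids=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, m = X.shape
        if positions is None:
            raise ValueError("positions are required to build windows")
        positions = np.asarray(positions)
        chroms = ["chr0"] * m if chroms is None else list(chroms)
        variant_ids = (
            [f"v{j}" for j in range(m)] if variant_ids is None else list(variant_ids)
        )
        mafs = np.array(
            [
                compute_maf(X[:, j]) if (~np.isnan(X[:, j])).any() else 0.0
                for j in range(m)
            ]
        )
        poly = np.array(
            [np.ptp(X[~np.isnan(X[:, j]), j]) > 0 for j in range(m)]
        )
        low = np.where((mafs < self.maf_threshold) & poly)[0]
        # keep position order within chromosome
        low = low[np.lexsort((positions[low], np.array(chroms, dtype=object)[low]))]
        G = X[:, low]
        self.low_frequency_ids_ = [variant_ids[j] for j in low]
        self.low_frequency_mafs_ = mafs[low]
        sets = build_windows(
            self.low_frequency_ids_,
            [chroms[j] for j in low],
            positions[low],
            width_bp=self.width_bp,
        )
        if self.flat_weights:
            w = np.ones(G.shape[1])
        else:
            w = weights_beta(
                np.maximum(self.low_frequency_mafs_, 1e-12),
                self.weight_beta_a,
                self.weight_beta_b,
            )
        permutation_fwer(
            y,
            covariates,
            G,
            sets,
            weights=w,
            B=self.B,
            alpha=self.alpha,
            seed=self.random_state,
            tail_method=self.tail_method,
            scheme=self.scheme,
        )
        self.sets_ = sets
        self.results_ = pd.DataFrame(
            {
                "chrom": [s.chrom for s in sets],
                "window_start": [s.window_start for s in sets],
                "window_end": [s.window_end for s in sets],
                "n_members": [s.n_members for s in sets],
                "Q": [s.Q for s in sets],
                "p": [s.p for s in sets],
                "empirical_p": [s.empirical_p for s in sets],
                "significant_fwer": [s.significant_fwer for s in sets],
            }
        )
        self.regions_nominal_ = merge_regions(sets, alpha=self.alpha, tier="nominal")
        self.regions_fwer_ = merge_regions(sets, alpha=self.alpha, tier="fwer")
        return self
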