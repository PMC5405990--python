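"""LD-aware variant pruning and clumping.

``VIFPruner`` removes multi-collinear variants with the sliding-window
variance-inflation-factor criterion: within each window of ``window_size``
position-sorted variants (advancing ``shift`` variants per step), every
variant's VIF = 1/(1 - R^2) is computed from regressing its dosages on all
other retained variants in the window, and the worst offender is removed
until the maximum VIF is at or below the threshold. A VIF threshold of 2
corresponds to R^2 = 0.5. Sweeps repeat until a fixed point, which makes
pruning idempotent and guarantees the post-hoc window audit.

``clump`` groups nominally associated variants around index variants by
r^2 and distance, to count independent association signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .variants import GenotypeMatrix, compute_maf

__all__ = [
    "PruneParams",
    "ClumpParams",
    "Clump",
    "VIFPruner",
    "genotype_r2",
    "vif_prune",
    "window_vifs",
    "clump",
]


@dataclass(frozen=True)
class PruneParams:
    window_size: int = 30
    shift: int = 3
    vif_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.shift < 1 or self.window_size < 2:
            raise ValueError("need window_size >= 2 and shift >= 1")
        if self.shift > self.window_size:
            raise ValueError("shift must not exceed window_size")
        if self.vif_threshold <= 1:
            raise ValueError("vif_threshold must be > 1")


@dataclass(frozen=True)
class ClumpParams:
    index_p_threshold: float = 1e-4
    member_p_threshold: float = 0.05
    r2_threshold: float = 0.5
    distance_kb: float = 250.0

    def __post_init__(self) -> None:
        if self.index_p_threshold > self.member_p_threshold:
            raise ValueError("index_p_threshold must be <= member_p_threshold")
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in [0, 1]")


@dataclass
class Clump:
    index_variant: str
    index_p: float
    members: list[str] = field(default_factory=list)  # excludes the index
    member_r2: dict[str, float] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return 1 + len(self.members)


def genotype_r2(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors, computed on
    their shared non-missing individuals."""
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    mask = ~(np.isnan(g_i) | np.isnan(g_j))
    if mask.sum() < 3:
        raise ValueError("need >= 3 shared non-missing individuals")
    x, y = g_i[mask], g_j[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("r^2 undefined for a constant dosage vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _mean_impute(mat: np.ndarray) -> np.ndarray:
    if not np.isnan(mat).any():
        return mat
    out = mat.copy()
    means = np.nanmean(out, axis=0)
    idx = np.where(np.isnan(out))
    out[idx] = means[idx[1]]
    return out


def _vif_one(mat: np.ndarray, j: int) -> float:
    """VIF of column j against the other columns (mean-imputed, centered)."""
    y = mat[:, j]
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return 1.0  # constant column carries no collinearity signal
    X = np.delete(mat, j, axis=1)
    X = X - X.mean(axis=0)
    yc = y - y.mean()
    coef, *_ = np.linalg.lstsq(X, yc, rcond=None)
    sse = float(((yc - X @ coef) ** 2).sum())
    r2 = max(0.0, 1.0 - sse / sst)
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def window_vifs(mat: np.ndarray) -> np.ndarray:
    """VIF of every column of a (mean-imputed) window dosage matrix."""
    mat = _mean_impute(np.asarray(mat, dtype=float))
    if mat.shape[1] < 2:
        return np.ones(mat.shape[1])
    return np.array([_vif_one(mat, j) for j in range(mat.shape[1])])


class VIFPruner(BaseEstimator, TransformerMixin):
    """Sliding-window VIF pruning as a feature-selection transformer.

    Parameters follow the printed analysis settings: 30-variant windows,
    a shift of 3 variants, VIF threshold 2. Columns must already be sorted
    by genomic position (chromosome-wise); positions are only used for the
    removal tie-break.

    Attributes (after :meth:`fit`)
    ------------------------------
    support_ : boolean mask of retained columns
    removal_log_ : DataFrame with one row per removed variant
    n_sweeps_ : sweeps needed to reach the fixed point
    """

    def __init__(
        self,
        window_size: int = 30,
        shift: int = 3,
        vif_threshold: float = 2.0,
    ) -> None:
        self.window_size = window_size
        self.shift = shift
        self.vif_threshold = vif_threshold

    def _params(self) -> PruneParams:
        return PruneParams(self.window_size, self.shift, self.vif_threshold)

    def fit(self, X, y=None, positions=None):
        params = self._params()
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        positions = (
            np.arange(m) if positions is None else np.asarray(positions)
        )
        mafs = np.array([compute_maf(X[:, j]) for j in range(m)])
        retained = list(range(m))
        log_rows: list[dict] = []
        sweeps = 0
        while True:
            sweeps += 1
            removed_this_sweep = False
            start = 0
            while start < len(retained):
                window = retained[start : start + params.window_size]
                while len(window) >= 2:
                    vifs = window_vifs(X[:, window])
                    worst = np.max(vifs)
                    if worst <= params.vif_threshold:
                        break
                    # drop the max-VIF variant; ties -> lower MAF, then later position
                    cand = np.where(vifs >= worst * (1 - 1e-12))[0]
                    drop_local = min(
                        cand, key=lambda k: (mafs[window[k]], -positions[window[k]])
                    )
                    victim = window[drop_local]
                    log_rows.append(
                        {
                            "column": victim,
                            "position": positions[victim],
                            "vif_at_removal": float(vifs[drop_local]),
                            "window_start": start,
                            "sweep": sweeps,
                        }
                    )
                    window.remove(victim)
                    retained.remove(victim)
                    removed_this_sweep = True
                if start + params.window_size >= len(retained):
                    break
                start += params.shift
            if not removed_this_sweep:
                break
        self.support_ = np.zeros(m, dtype=bool)
        self.support_[retained] = True
        self.removal_log_ = pd.DataFrame(
            log_rows,
            columns=["column", "position", "vif_at_removal", "window_start", "sweep"],
        )
        self.n_sweeps_ = sweeps
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.support_]


def vif_prune(
    genotypes: GenotypeMatrix,
    order: list[str] | None = None,
    params: PruneParams = PruneParams(),
) -> tuple[list[str], pd.DataFrame]:
    """Prune a genotype matrix; returns (retained variant ids, removal log).

    ``order`` gives the position-sorted variant ids to consider (defaults
    to the matrix's column order). Fewer than 2 variants are returned
    unchanged.
    """
    ids = list(order) if order is not None else list(genotypes.variant_ids)
    if len(ids) < 2:
        return ids, pd.DataFrame(
            columns=["variant_id", "position", "vif_at_removal", "window_start", "sweep"]
        )
    sub = genotypes.subset_variants(ids)
    pruner = VIFPruner(params.window_size, params.shift, params.vif_threshold)
    pruner.fit(sub.dosages)
    retained = [v for v, keep in zip(ids, pruner.support_) if keep]
    log = pruner.removal_log_.copy()
    log.insert(0, "variant_id", [ids[c] for c in log["column"]])
    log = log.drop(columns=["column"])
    return retained, log


def clump(
    assoc: pd.DataFrame,
    genotypes: GenotypeMatrix,
    params: ClumpParams = ClumpParams(),
) -> list[Clump]:
    """Greedy clumping of association results.

    ``assoc`` needs columns ``variant_id``, ``position``, ``p``. Repeatedly
    the unassigned variant with the smallest p <= index_p_threshold becomes
    an index; unassigned variants with p <= member_p_threshold, r^2 >=
    r2_threshold with the index and within ``distance_kb`` are absorbed.
    """
    if ((assoc["p"] < 0) | (assoc["p"] > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    df = assoc.sort_values(["p", "position"]).reset_index(drop=True)
    unassigned = set(df["variant_id"])
    clumps: list[Clump] = []
    for _, row in df.iterrows():
        vid, pos, p = row["variant_id"], row["position"], row["p"]
        if vid not in unassigned or p > params.index_p_threshold:
            continue
        unassigned.discard(vid)
        c = Clump(index_variant=vid, index_p=float(p))
        g_index = genotypes.column(vid)
        for _, other in df.iterrows():
            ovid = other["variant_id"]
            if ovid not in unassigned or other["p"] > params.member_p_threshold:
                continue
            if abs(other["position"] - pos) > params.distance_kb * 1000:
                continue
            try:
                r2 = genotype_r2(g_index, genotypes.column(ovid))
            except ValueError:
                continue
            if r2 >= params.r2_threshold:
                c.members.append(ovid)
                c.member_r2[ovid] = r2
                unassigned.discard(ovid)
        clumps.append(c)
    # variants not absorbed and not index-eligible remain unclumped singletons
    for _, row in df.iterrows():
        vid = row["variant_id"]
        if vid in unassigned and row["p"] <= params.member_p_threshold:
            clumps.append(Clump(index_variant=vid, index_p=float(row["p"])))
            unassigned.discard(vid)
    return clumps
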