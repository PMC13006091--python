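"""Fold-nested locus selection: GBDT importance, linear-SVR weights, GWAS+LD.

All selectors operate on training-fold rows only. When a selector is given a
declared fold membership (``allowed_ids``) it refuses, with a hard
:class:`LeakageError`, any sample outside it. The returned marker subsets are
always in genomic (map) order because downstream patching tokenizes "the
sequence of selected SNPs" and interpretability maps patches back to
chromosome positions.

The GBDT selector retains every marker with split-gain importance > 0; the
two baselines take a caller-supplied ``k`` so ablations can match the GBDT
count exactly (fixed-k contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ConfigError, EmptySelectionError, LeakageError
from .genotype_io import GenotypeMatrix, MarkerMap


@dataclass
class SelectionResult:
    strategy: str                 # gbdt | linear_svr | gwas_ld
    selected: np.ndarray          # marker indices, genomic order
    scores: np.ndarray            # per-selected score (gain, |w|, -log10 p)
    k: int
    trained_on: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.selected.size != self.k or self.k < 1:
            raise ConfigError("selection must contain exactly k >= 1 markers")
        if len(set(self.selected.tolist())) != self.selected.size:
            raise ConfigError("duplicate selected markers")


def _check_fold(g_train: GenotypeMatrix, allowed_ids: Sequence[str] | None) -> None:
    if allowed_ids is None:
        return
    outside = set(g_train.sample_ids) - set(allowed_ids)
    if outside:
        raise LeakageError(
            f"selector given samples outside the declared training fold: "
            f"{sorted(outside)[:5]}"
        )


def _mean_fill(X: np.ndarray) -> np.ndarray:
    X = X.copy()
    mean = np.nanmean(X, axis=0)
    mean = np.where(np.isfinite(mean), mean, 0.0)
    nan_r, nan_c = np.where(~np.isfinite(X))
    X[nan_r, nan_c] = mean[nan_c]
    return X


def _genomic_order(idx: np.ndarray, mmap: MarkerMap) -> np.ndarray:
    """Order marker indices by (chromosome block, position, index)."""
    # chromosomes keep their first-appearance order in the map
    chrom_rank = {c: r for r, c in enumerate(dict.fromkeys(mmap.chromosomes))}
    keys = [(chrom_rank[mmap.chromosomes[i]], int(mmap.positions[i]), int(i)) for i in idx]
    return np.array([i for _, _, i in sorted(keys)], dtype=int)


def select_gbdt(
    g_train: GenotypeMatrix,
    y_train: np.ndarray,
    seed: int = 0,
    allowed_ids: Sequence[str] | None = None,
    n_estimators: int = 500,
    num_leaves: int = 31,
    learning_rate: float = 0.05,
    feature_fraction: float = 0.8,
    bagging_fraction: float = 0.8,
    min_child_samples: int = 5,
) -> SelectionResult:
    """LightGBM regressor on raw dosages; keep markers with split gain > 0.

    ``min_child_samples`` defaults below the LightGBM default so the selector
    still splits on small cohorts.
    """
    _check_fold(g_train, allowed_ids)
    import lightgbm as lgb

    X = _mean_fill(g_train.dosages)
    model = lgb.LGBMRegressor(
        n_estimators=n_estimators,
        num_leaves=num_leaves,
        learning_rate=learning_rate,
        feature_fraction=feature_fraction,
        bagging_fraction=bagging_fraction,
        min_child_samples=min_child_samples,
        bagging_freq=1,
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )
    model.fit(X, np.asarray(y_train, dtype=float))
    gain = model.booster_.feature_importance(importance_type="gain")
    keep = np.where(gain > 0)[0]
    if keep.size == 0:
        raise EmptySelectionError(
            "no marker attained positive importance; increase n_estimators"
        )
    order = _genomic_order(keep, g_train.markers)
    return SelectionResult(
        strategy="gbdt",
        selected=order,
        scores=gain[order],
        k=order.size,
        trained_on=list(g_train.sample_ids),
        seed=seed,
    )


def select_linear_svr(
    g_train: GenotypeMatrix,
    y_train: np.ndarray,
    k: int,
    seed: int = 0,
    allowed_ids: Sequence[str] | None = None,
    C: float = 1.0,
) -> SelectionResult:
    """Linear-kernel SVR on standardized dosages; top-k by |coefficient|.

    Ties in |coefficient| break toward the smaller marker index.
    """
    _check_fold(g_train, allowed_ids)
    if k < 1 or k > g_train.n_markers:
        raise ConfigError(f"k={k} outside [1, {g_train.n_markers}]")
    from sklearn.svm import LinearSVR

    X = _mean_fill(g_train.dosages)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    model = LinearSVR(C=C, random_state=seed, max_iter=10000, tol=1e-5)
    model.fit(Xs, np.asarray(y_train, dtype=float))
    w = np.abs(model.coef_.ravel())
    # stable sort on (-|w|, index): smaller index wins ties
    top = np.lexsort((np.arange(w.size), -w))[:k]
    order = _genomic_order(top, g_train.markers)
    return SelectionResult(
        strategy="linear_svr",
        selected=order,
        scores=w[order],
        k=k,
        trained_on=list(g_train.sample_ids),
        seed=seed,
    )


def gwas_single_marker(
    g_train: GenotypeMatrix,
    y_train: np.ndarray,
    allowed_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Per-marker simple linear regression y ~ dosage; two-sided slope t-test.

    Missing dosages are excluded marker-wise. Constant-dosage markers get
    p = 1 by convention. Vectorized over the complete-data markers via the
    correlation form t = r sqrt((n-2)/(1-r^2)).
    """
    _check_fold(g_train, allowed_ids)
    y = np.asarray(y_train, dtype=float)
    n, m = g_train.dosages.shape
    if n < 3:
        raise ConfigError("GWAS needs >= 3 training samples")
    pvals = np.ones(m)
    X = g_train.dosages
    for j in range(m):
        col = X[:, j]
        obs = np.isfinite(col)
        xj, yj = col[obs], y[obs]
        nj = xj.size
        if nj < 3 or np.ptp(xj) == 0 or np.ptp(yj) == 0:
            continue
        r = np.corrcoef(xj, yj)[0, 1]
        r = float(np.clip(r, -1.0, 1.0))
        if abs(r) >= 1.0:
            pvals[j] = 0.0
            continue
        t = r * np.sqrt((nj - 2) / (1.0 - r * r))
        pvals[j] = 2.0 * stats.t.sf(abs(t), df=nj - 2)
    return pvals


def _column_maf(col: np.ndarray) -> float:
    obs = col[np.isfinite(col)]
    if obs.size == 0:
        return 0.0
    p = obs.sum() / (2.0 * obs.size)
    return float(min(p, 1.0 - p))


def ld_prune(
    g_train: GenotypeMatrix,
    mmap: MarkerMap | None = None,
    window_bp: int = 200_000,
    step: int = 1,
    r2_max: float = 0.5,
) -> np.ndarray:
    """Greedy within-chromosome LD pruning on squared dosage correlation.

    Scanning left to right (windows advance by ``step`` markers), for every
    ordered pair within ``window_bp`` whose r^2 exceeds ``r2_max`` the
    lower-MAF member is removed (tie: the later-position marker). Returns the
    surviving marker indices in genomic order.
    """
    mmap = mmap or g_train.markers
    X = _mean_fill(g_train.dosages)
    m = X.shape[1]
    alive = np.ones(m, dtype=bool)
    mafs = np.array([_column_maf(g_train.dosages[:, j]) for j in range(m)])
    sd = X.std(axis=0)

    chrom_rank = {c: r for r, c in enumerate(dict.fromkeys(mmap.chromosomes))}
    order = sorted(
        range(m),
        key=lambda j: (chrom_rank[mmap.chromosomes[j]], int(mmap.positions[j]), j),
    )
    for a_pos in range(0, len(order), max(1, step)):
        i = order[a_pos]
        if not alive[i]:
            continue
        for b_pos in range(a_pos + 1, len(order)):
            j = order[b_pos]
            if mmap.chromosomes[j] != mmap.chromosomes[i]:
                break
            if mmap.positions[j] - mmap.positions[i] > window_bp:
                break
            if not alive[j] or not alive[i]:
                if not alive[i]:
                    break
                continue
            if sd[i] == 0 or sd[j] == 0:
                continue
            r = np.corrcoef(X[:, i], X[:, j])[0, 1]
            if r * r > r2_max:
                if mafs[i] < mafs[j]:
                    alive[i] = False
                elif mafs[j] < mafs[i]:
                    alive[j] = False
                else:  # tie: drop the later-position marker
                    alive[j] = False
    survivors = [j for j in order if alive[j]]
    return np.array(survivors, dtype=int)


def select_gwas_ld(
    g_train: GenotypeMatrix,
    y_train: np.ndarray,
    k: int,
    allowed_ids: Sequence[str] | None = None,
    window_bp: int = 200_000,
    step: int = 1,
    r2_max: float = 0.5,
) -> SelectionResult:
    """LD-prune first, then the k smallest GWAS p-values among survivors."""
    _check_fold(g_train, allowed_ids)
    survivors = ld_prune(g_train, window_bp=window_bp, step=step, r2_max=r2_max)
    if k < 1 or k > survivors.size:
        raise ConfigError(
            f"k={k} exceeds the {survivors.size} post-pruning survivors"
        )
    pvals = gwas_single_marker(g_train, y_train)
    p_surv = pvals[survivors]
    top = survivors[np.lexsort((survivors, p_surv))[:k]]
    order = _genomic_order(top, g_train.markers)
    with np.errstate(divide="ignore"):
        scores = -np.log10(np.maximum(pvals[order], 1e-300))
    return SelectionResult(
        strategy="gwas_ld",
        selected=order,
        scores=scores,
        k=k,
        trained_on=list(g_train.sample_ids),
    )
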