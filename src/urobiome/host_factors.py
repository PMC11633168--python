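"""Host-factor effects on community composition.

Univariable distance-based redundancy analysis (dbRDA) with permutation
ANOVA, BH screening, Spearman collinearity pruning, category-wise variation
partitioning with Ezekiel-adjusted R², and feature-phenotype correlation
tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community_metrics import DistanceMatrix, pcoa

logger = logging.getLogger(__name__)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _design_matrix(covariate, sample_ids=None) -> tuple[np.ndarray, np.ndarray]:
    """Column(s) for one covariate: numeric as-is, categorical dummy-coded
    (first level dropped). Returns (X, complete-case mask)."""
    ser = pd.Series(covariate)
    if ser.dtype == object or isinstance(ser.dtype, pd.CategoricalDtype) or ser.dtype == bool:
        mask = ser.notna().to_numpy()
        dummies = pd.get_dummies(ser[mask].astype(str), drop_first=True)
        return dummies.to_numpy(dtype=float), mask
    vals = ser.to_numpy(dtype=float)
    mask = np.isfinite(vals)
    return vals[mask][:, None], mask


def _dbrda_r2(coords: np.ndarray, x: np.ndarray) -> float:
    """R² = tr(Y'HY)/tr(Y'Y) with H the hat matrix of [1, X]."""
    n = coords.shape[0]
    y = coords - coords.mean(axis=0)
    xd = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(xd, y, rcond=None)
    fitted = xd @ beta
    ss_fit = float((fitted**2).sum())
    ss_tot = float((y**2).sum())
    return ss_fit / ss_tot if ss_tot > 0 else 0.0


@dataclass
class FactorEffect:
    covariate: str
    r_squared: float
    adj_r_squared: float
    p_value: float
    n: int
    n_perm: int
    category: str = "other"
    q_value: float | None = None
    retained_after_pruning: bool | None = None


def ezekiel_adjust(r2: float, n: int, p: int) -> float:
    """Ezekiel adjusted R² = 1 - (1-R²)(n-1)/(n-p-1)."""
    if n - p - 1 <= 0:
        raise ValueError("over-parameterized: p >= n - 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def univariable_dbrda(
    dist: DistanceMatrix,
    covariate,
    name: str = "covariate",
    n_perm: int = 999,
    seed: int | None = None,
    category: str = "other",
) -> FactorEffect:
    """Variance in composition explained by one covariate.

    The distance matrix is embedded by PCoA (positive axes); R² is the
    share of total inertia captured by the covariate's hat matrix, with
    significance from permuting covariate rows (pseudo-F ordering, counted
    as in PERMANOVA). Samples with missing covariate values are dropped.
    """
    x, mask = _design_matrix(covariate)
    if x.shape[1] == 0 or np.all(np.ptp(x, axis=0) == 0):
        raise ValueError(f"constant covariate: {name}")
    if not mask.all():
        logger.info("%s: dropping %d samples with missing values", name, (~mask).sum())
        ids = [s for s, m in zip(dist.sample_ids, mask) if m]
        dist = dist.subset(ids)
    coords = pcoa(dist).coordinates
    n, p = coords.shape[0], x.shape[1]
    r2 = _dbrda_r2(coords, x)
    df2 = n - p - 1
    f_obs = (r2 / p) / ((1.0 - r2) / df2) if df2 > 0 else np.inf

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        xp = x[rng.permutation(n)]
        r2p = _dbrda_r2(coords, xp)
        f_p = (r2p / p) / ((1.0 - r2p) / df2) if df2 > 0 else np.inf
        if f_p >= f_obs - 1e-12:
            count += 1
    p_value = (1 + count) / (1 + n_perm)
    return FactorEffect(
        covariate=name,
        r_squared=float(r2),
        adj_r_squared=float(ezekiel_adjust(r2, n, p)),
        p_value=float(p_value),
        n=n,
        n_perm=n_perm,
        category=category,
    )


def screen_factors(
    dist: DistanceMatrix,
    covariates: pd.DataFrame,
    categories: dict[str, str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    fdr: float = 0.05,
) -> list[FactorEffect]:
    """Univariable dbRDA per covariate + BH adjustment across covariates."""
    effects = []
    for i, col in enumerate(covariates.columns):
        try:
            eff = univariable_dbrda(
                dist,
                covariates[col],
                name=col,
                n_perm=n_perm,
                seed=None if seed is None else seed + i,
                category=(categories or {}).get(col, "other"),
            )
        except ValueError as exc:
            logger.warning("skipping %s: %s", col, exc)
            continue
        effects.append(eff)
    qs = bh_adjust([e.p_value for e in effects])
    for e, q in zip(effects, qs):
        e.q_value = float(q)
    return effects


def prune_collinear(
    covariates: pd.DataFrame,
    priority: list[str] | None = None,
    threshold: float = 0.6,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy Spearman pruning in priority order.

    A covariate is kept iff |Spearman r| <= threshold against every
    already-kept covariate. Priority defaults to column order (callers
    pass univariable-R²-descending order); ties upstream are expected to
    be broken lexicographically.
    """
    cols = priority if priority is not None else list(covariates.columns)
    num = {}
    for c in cols:
        ser = covariates[c]
        if ser.dtype == object or ser.dtype == bool:
            ser = pd.Series(pd.factorize(ser)[0], index=ser.index).replace(-1, np.nan)
        num[c] = ser.to_numpy(dtype=float)
    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for c in cols:
        clash = None
        for k in kept:
            mask = np.isfinite(num[c]) & np.isfinite(num[k])
            if mask.sum() < 3:
                continue
            rho = stats.spearmanr(num[c][mask], num[k][mask]).statistic
            if np.isfinite(rho) and abs(rho) > threshold:
                clash = (k, float(rho))
                break
        if clash is None:
            kept.append(c)
        else:
            dropped.append((c, clash[0], clash[1]))
    return kept, dropped


@dataclass
class VariancePartition:
    per_category: dict  # category -> adjusted R²
    per_category_r2: dict  # category -> raw R²
    n_covariates: dict  # category -> count
    total_adj_r_squared: float
    total_r_squared: float
    n: int


def variation_partition(
    dist: DistanceMatrix,
    covariates: pd.DataFrame,
    category_map: dict[str, str],
) -> VariancePartition:
    """Per-category and total (Ezekiel-adjusted) dbRDA R².

    Each category's value is the adjusted R² of a dbRDA on that category's
    covariates alone; the total uses all covariates jointly. Complete-case
    over all covariates so the embeddings agree.
    """
    missing = set(covariates.columns) - set(category_map)
    if missing:
        raise ValueError(f"covariates without category: {sorted(missing)}")
    masks = [_design_matrix(covariates[col])[1] for col in covariates.columns]
    cc = np.logical_and.reduce(masks)
    ids = [s for s, m in zip(dist.sample_ids, cc) if m]
    coords = pcoa(dist.subset(ids)).coordinates
    n = coords.shape[0]

    def block_x(cols: list[str]) -> np.ndarray:
        return np.column_stack(
            [_design_matrix(covariates[col][cc])[0] for col in cols]
        )

    per_cat_adj, per_cat_r2, n_cov = {}, {}, {}
    for cat in sorted(set(category_map.values())):
        cols = [c for c in covariates.columns if category_map[c] == cat]
        x = block_x(cols)
        p = x.shape[1]
        if p >= n - 1:
            raise ValueError(f"category {cat} over-parameterized (p={p}, n={n})")
        r2 = _dbrda_r2(coords, x)
        per_cat_r2[cat] = float(r2)
        per_cat_adj[cat] = float(ezekiel_adjust(r2, n, p))
        n_cov[cat] = len(cols)
    x_all = block_x(list(covariates.columns))
    p_all = x_all.shape[1]
    if p_all >= n - 1:
        raise ValueError(f"joint model over-parameterized (p={p_all}, n={n})")
    r2_all = _dbrda_r2(coords, x_all)
    return VariancePartition(
        per_category=per_cat_adj,
        per_category_r2=per_cat_r2,
        n_covariates=n_cov,
        total_adj_r_squared=float(ezekiel_adjust(r2_all, n, p_all)),
        total_r_squared=float(r2_all),
        n=n,
    )


def correlate_features(
    feature_matrix: pd.DataFrame,
    phenotype_matrix: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """All feature x phenotype correlations with two-sided P and BH q.

    Binary indicator features (e.g. urotype membership) are accepted.
    Constant columns are skipped with a log message.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method: {method}")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for f in feature_matrix.columns:
        fv = feature_matrix[f].to_numpy(dtype=float)
        for ph in phenotype_matrix.columns:
            pv = pd.to_numeric(phenotype_matrix[ph], errors="coerce").to_numpy(dtype=float)
            mask = np.isfinite(fv) & np.isfinite(pv)
            if mask.sum() < 3:
                continue
            if np.ptp(fv[mask]) == 0 or np.ptp(pv[mask]) == 0:
                logger.info("skipping constant pair (%s, %s)", f, ph)
                continue
            res = corr(fv[mask], pv[mask])
            rows.append(
                {
                    "feature": f,
                    "phenotype": ph,
                    "estimate": float(res.statistic),
                    "p": float(res.pvalue),
                    "n": int(mask.sum()),
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def top_associations(corr_table: pd.DataFrame, n: int = 20, by: str = "feature") -> pd.DataFrame:
    """Top-N associations per feature by |estimate| among q < 0.05."""
    sig = corr_table[corr_table["q"] < 0.05].copy()
    sig["abs_est"] = sig["estimate"].abs()
    out = (
        sig.sort_values("abs_est", ascending=False)
        .groupby(by, group_keys=False)
        .head(n)
        .drop(columns="abs_est")
    )
    return out.reset_index(drop=True)
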