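"""Diversity indices, community distances, ordination and PERMANOVA."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .cohort_io import TaxonProfileTable

logger = logging.getLogger(__name__)

JSD_MAX = float(np.sqrt(np.log(2.0)))


def alpha_diversity(profile: np.ndarray, index: str = "shannon") -> float:
    """Shannon (natural log) or Simpson (1 - sum p^2) of one profile.

    The vector is normalized internally; an all-zero vector raises.
    """
    p = np.asarray(profile, dtype=float)
    if np.any(p < 0) or np.any(~np.isfinite(p)):
        raise ValueError("profile must be finite and non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero profile")
    p = p / total
    p = p[p > 0]
    if index == "shannon":
        return float(-(p * np.log(p)).sum())
    if index == "simpson":
        return float(1.0 - (p**2).sum())
    raise ValueError(f"unknown index: {index}")


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(
            sample_ids=list(sample_ids),
            values=self.values[np.ix_(idx, idx)],
            metric=self.metric,
        )


def _bray_curtis(x: np.ndarray) -> np.ndarray:
    # sum|xi - yi| / sum(xi + yi), vectorized over all pairs
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        num = np.abs(x[i] - x).sum(axis=1)
        den = (x[i] + x).sum(axis=1)
        out[i] = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def _jsd_root(x: np.ndarray, pseudocount: float) -> np.ndarray:
    p = x + pseudocount
    p = p / p.sum(axis=1, keepdims=True)
    logp = np.log(p)
    h = -(p * logp).sum(axis=1)  # Shannon entropy per row (nats)
    n = p.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        m = 0.5 * (p[i] + p)
        h_m = -(m * np.log(m)).sum(axis=1)
        jsd = h_m - 0.5 * (h[i] + h)
        out[i] = np.sqrt(np.maximum(jsd, 0.0))
    np.fill_diagonal(out, 0.0)
    return out


def beta_distance(
    table: TaxonProfileTable | np.ndarray,
    metric: str = "bray_curtis",
    pseudocount: float = 1e-10,
    sample_ids: list[str] | None = None,
) -> DistanceMatrix:
    """All-pairs Bray-Curtis or root-JSD (natural log) distances.

    jsd_root adds ``pseudocount`` to every entry and renormalizes before
    computing sqrt(JSD); its range is [0, sqrt(ln 2)].
    """
    if isinstance(table, TaxonProfileTable):
        x = table.relabund
        ids = list(table.sample_ids)
    else:
        x = np.asarray(table, dtype=float)
        ids = sample_ids or [f"S{i}" for i in range(x.shape[0])]
    if np.any(~np.isfinite(x)):
        raise ValueError("non-finite abundance")
    if metric == "bray_curtis":
        vals = _bray_curtis(x)
    elif metric == "jsd_root":
        vals = _jsd_root(x, pseudocount)
    else:
        raise ValueError(f"unknown metric: {metric}")
    vals = 0.5 * (vals + vals.T)  # enforce exact symmetry
    return DistanceMatrix(sample_ids=ids, values=vals, metric=metric)


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues
    sample_ids: list[str]


def pcoa(dist: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates: Gower-center -0.5 D^2 and eigendecompose.

    Axes with negative eigenvalues are reported in ``eigenvalues`` but
    carry no coordinates.
    """
    d2 = dist.values**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    g = 0.5 * (g + g.T)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-10 if len(vals) else 0.0
    pos = vals > tol
    n_pos = int(pos.sum())
    if n_axes is None:
        n_axes = n_pos
    if n_axes > n_pos:
        logger.warning(
            "requested %d axes but only %d positive eigenvalues", n_axes, n_pos
        )
        n_axes = n_pos
    coords = vecs[:, :n_axes] * np.sqrt(vals[:n_axes])
    prop = (
        vals[:n_pos] / vals[:n_pos].sum() if n_pos else np.array([])
    )
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=vals,
        proportion_explained=prop,
        sample_ids=list(dist.sample_ids),
    )


@dataclass
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int | None = None


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_within, SS_total) from squared distances via the Gower identity."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.where(labels == g)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_within, ss_total


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, k: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_w, ss_t = _permanova_ss(d2, labels)
    ss_b = ss_t - ss_w
    f = (ss_b / (k - 1)) / (ss_w / (n - k)) if ss_w > 0 else np.inf
    r2 = ss_b / ss_t if ss_t > 0 else 0.0
    return f, r2


def permanova(
    dist: DistanceMatrix,
    labels,
    n_perm: int = 9999,
    seed: int | None = None,
    method: str = "sample",
) -> PermanovaResult:
    """One-factor PERMANOVA with free label permutation.

    ``method='exact'`` enumerates all distinct label arrangements instead
    of sampling; the identity arrangement plays the role of the +1 in
    P = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if np.any(counts < 2):
        raise ValueError("each group needs at least 2 samples")
    if n_perm < 99 and method == "sample":
        logger.warning("n_perm=%d is low; p-values will be coarse", n_perm)
    d2 = dist.values**2
    k = len(uniq)
    f_obs, r2 = _pseudo_f(d2, labels, k)

    if method == "exact":
        perms = _distinct_label_arrangements(labels)
        n_perm_eff = len(perms) - 1  # excluding the identity
        count = 0
        for perm in perms:
            if np.array_equal(perm, labels):
                continue
            f_p, _ = _pseudo_f(d2, perm, k)
            if f_p >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm_eff)
        return PermanovaResult(r2, f_obs, p, n_perm_eff, seed)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = labels[rng.permutation(len(labels))]
        f_p, _ = _pseudo_f(d2, perm, k)
        if f_p >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(r2, f_obs, p, n_perm, seed)


def _distinct_label_arrangements(labels: np.ndarray) -> list[np.ndarray]:
    """All distinct permutations of a label multiset (small n only)."""
    n = len(labels)
    if n > 10:
        raise ValueError("exact enumeration limited to n <= 10")
    seen = set()
    out = []
    for perm in itertools.permutations(range(n)):
        arr = tuple(labels[list(perm)])
        if arr not in seen:
            seen.add(arr)
            out.append(np.asarray(arr))
    return out


def pairwise_permanova(
    dist: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
) -> list[dict]:
    """All group pairs, BH-adjusted across pairs."""
    from .host_factors import bh_adjust

    labels = np.asarray(labels)
    ids = np.asarray(dist.sample_ids)
    results = []
    for a, b in itertools.combinations(np.unique(labels), 2):
        mask = np.isin(labels, [a, b])
        sub = dist.subset(list(ids[mask]))
        res = permanova(sub, labels[mask], n_perm=n_perm, seed=seed)
        results.append({"group_a": a, "group_b": b, "result": res})
    qs = bh_adjust([r["result"].p_value for r in results])
    for r, q in zip(results, qs):
        r["q_value"] = q
    return results
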