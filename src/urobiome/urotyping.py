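"""Urotype discovery: PAM clustering on root-JSD distances, cluster-number
selection by the Calinski-Harabasz index, and LDA-effect-size marker ranking.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort_io import TaxonProfileTable
from .community_metrics import DistanceMatrix, beta_distance, pcoa

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PAM (k-medoids): BUILD initialization + SWAP local search
# ---------------------------------------------------------------------------

def pam_cluster(
    dist: DistanceMatrix, k: int, seed: int | None = None
) -> tuple[np.ndarray, list[str]]:
    """Partition around medoids on a precomputed distance matrix.

    BUILD greedily seeds k medoids, SWAP exhaustively tries all
    (medoid, non-medoid) exchanges until no swap lowers the total cost
    sum_i d(i, nearest medoid). Ties break toward the lowest sample index,
    so the result is deterministic (``seed`` is accepted for API symmetry).

    Returns 1-based assignments (cluster c = c-th medoid in index order)
    and the medoid sample ids.
    """
    d = dist.values
    n = d.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n:
        raise ValueError("k must be < number of samples")

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        cur = d[:, medoids].min(axis=1)
        # gain of adding candidate c = sum of improvements
        gains = np.maximum(cur[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    medoids = sorted(medoids)
    cost = d[:, medoids].min(axis=1).sum()

    # SWAP: best-improvement steps
    while True:
        best = (0.0, None, None)  # (delta, medoid_out, candidate_in)
        med_arr = np.asarray(medoids)
        non_med = np.setdiff1d(np.arange(n), med_arr)
        dm = d[:, med_arr]  # n x k
        for mi, m in enumerate(medoids):
            others = np.delete(dm, mi, axis=1)
            base = others.min(axis=1) if others.shape[1] else np.full(n, np.inf)
            # new cost for each candidate h: sum_i min(base_i, d[i, h])
            new_costs = np.minimum(base[:, None], d[:, non_med]).sum(axis=0)
            j = int(np.argmin(new_costs))
            delta = new_costs[j] - cost
            if delta < best[0] - 1e-12 or (
                best[1] is not None
                and abs(delta - best[0]) <= 1e-12
                and (m, int(non_med[j])) < (best[1], best[2])
            ):
                best = (delta, m, int(non_med[j]))
        if best[1] is None or best[0] >= -1e-12:
            break
        medoids.remove(best[1])
        medoids.append(best[2])
        medoids = sorted(medoids)
        cost = d[:, medoids].min(axis=1).sum()

    med_arr = np.asarray(medoids)
    # nearest medoid, ties toward the lowest medoid index
    assignments = np.argmin(d[:, med_arr], axis=1) + 1
    medoid_ids = [dist.sample_ids[m] for m in medoids]
    return assignments.astype(int), medoid_ids


def pam_exhaustive(dist: DistanceMatrix, k: int) -> tuple[np.ndarray, list[int]]:
    """Globally optimal medoid set by brute force (small n only)."""
    d = dist.values
    n = d.shape[0]
    if n > 12:
        raise ValueError("exhaustive PAM limited to n <= 12")
    best_cost, best_set = np.inf, None
    for combo in itertools.combinations(range(n), k):
        cost = d[:, combo].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost, best_set = cost, combo
    assignments = np.argmin(d[:, list(best_set)], axis=1) + 1
    return assignments.astype(int), list(best_set)


# ---------------------------------------------------------------------------
# Calinski-Harabasz index, distance-only form
# ---------------------------------------------------------------------------

def ch_index(dist: DistanceMatrix, assignments: np.ndarray) -> float:
    """Distance-based CH: B/(k-1) over W/(n-k) with W, T from squared
    distances (W = sum_c (1/|c|) sum_{i<j in c} d^2; T likewise over all).

    Equals the centroid-based CH in full PCoA space for Euclidean-
    embeddable matrices. W = 0 returns +inf.
    """
    d2 = dist.values**2
    n = d2.shape[0]
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("need >= 2 clusters")
    t = d2[np.triu_indices(n, 1)].sum() / n
    w = 0.0
    for c in uniq:
        idx = np.where(labels == c)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    b = t - w
    if w <= 0:
        return float("inf")
    return float((b / (k - 1)) / (w / (n - k)))


def ch_index_centroid(coords: np.ndarray, assignments: np.ndarray) -> float:
    """Centroid-form CH in Euclidean coordinates (equivalence oracle)."""
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    n, k = coords.shape[0], len(uniq)
    grand = coords.mean(axis=0)
    b = w = 0.0
    for c in uniq:
        sub = coords[labels == c]
        cen = sub.mean(axis=0)
        b += len(sub) * ((cen - grand) ** 2).sum()
        w += ((sub - cen) ** 2).sum()
    if w <= 0:
        return float("inf")
    return float((b / (k - 1)) / (w / (n - k)))


def select_k(
    dist: DistanceMatrix,
    k_range: range = range(2, 11),
    seed: int | None = None,
) -> tuple[int, dict[int, float], bool]:
    """Scan k over ``k_range``, return (argmax-CH k, CH curve, weak flag).

    Ties resolve to the smallest k. The weak-structure flag is raised when
    max CH < 1.2 x median CH over the scanned curve.
    """
    ks = [k for k in k_range if 2 <= k < dist.n]
    if not ks:
        raise ValueError("empty k range")
    if len(ks) == 1:
        logger.warning("k range has a single value; no selection performed")
    curve: dict[int, float] = {}
    for k in ks:
        assignments, _ = pam_cluster(dist, k, seed=seed)
        curve[k] = ch_index(dist, assignments)
    finite = {k: v for k, v in curve.items() if np.isfinite(v)}
    pool = finite or curve
    best_val = max(pool.values())
    best_k = min(k for k, v in pool.items() if v >= best_val - 1e-12)
    vals = np.asarray(list(pool.values()))
    weak = bool(best_val < 1.2 * np.median(vals)) if len(vals) > 1 else False
    return best_k, curve, weak


# ---------------------------------------------------------------------------
# LDA effect-size marker ranking
# ---------------------------------------------------------------------------

@dataclass
class Marker:
    taxon_id: str
    class_label: object
    lda_score: float
    kw_p: float


def _fisher_lda_direction(
    x0: np.ndarray, x1: np.ndarray, ridge_scale: float = 1e-6
) -> np.ndarray:
    """Unit-norm Fisher discriminant of two classes with ridge shrinkage."""
    p = x0.shape[1]
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    n0, n1 = len(x0), len(x1)
    s0 = np.cov(x0, rowvar=False, bias=False) if n0 > 1 else np.zeros((p, p))
    s1 = np.cov(x1, rowvar=False, bias=False) if n1 > 1 else np.zeros((p, p))
    sw = ((n0 - 1) * np.atleast_2d(s0) + (n1 - 1) * np.atleast_2d(s1)) / max(
        n0 + n1 - 2, 1
    )
    tr = np.trace(sw)
    eps = ridge_scale * (tr / p if tr > 0 else 1.0)
    sw = sw + eps * np.eye(p)
    w = np.linalg.solve(sw, mu1 - mu0)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def lda_effect_scores(
    table: TaxonProfileTable | np.ndarray,
    class_labels,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    seed: int = 0,
    feature_ids: list[str] | None = None,
) -> list[Marker]:
    """Kruskal-Wallis screen + bootstrapped LDA effect sizes, LEfSe-style.

    Features are rescaled to parts-per-million. Per retained feature j and
    class c (one-vs-rest), each bootstrap round subsamples 2/3 of each
    class, fits a two-class Fisher LDA over all retained features, and
    takes effect_j = 0.5 * (|w_hat_j * (w_hat . dmu)| + |dmu_j|) where dmu
    is the class-mean difference; the score is log10 of the mean effect
    over rounds. Markers with score >= ``lda_threshold`` are returned
    sorted by score, labeled with the class whose mean is higher.
    """
    if isinstance(table, TaxonProfileTable):
        x = table.relabund
        names = table.taxon_ids
    else:
        x = np.asarray(table, dtype=float)
        names = feature_ids or [f"f{j}" for j in range(x.shape[1])]
    labels = np.asarray(class_labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    for c in classes:
        if (labels == c).sum() < 3:
            raise ValueError(f"class {c!r} has fewer than 3 samples")

    x = x * 1e6  # per-million scale
    nonconst = np.ptp(x, axis=0) > 0
    kw_p = np.ones(x.shape[1])
    for j in np.where(nonconst)[0]:
        groups = [x[labels == c, j] for c in classes]
        try:
            kw_p[j] = stats.kruskal(*groups).pvalue
        except ValueError:  # all values identical
            kw_p[j] = 1.0
    retained = np.where(nonconst & (kw_p < alpha))[0]
    if retained.size == 0:
        return []

    xr = x[:, retained]
    rng = np.random.default_rng(seed)
    markers: list[Marker] = []
    for c in classes:
        in_c = labels == c
        idx0 = np.where(~in_c)[0]
        idx1 = np.where(in_c)[0]
        effects = np.zeros((n_boot, retained.size))
        for b in range(n_boot):
            s0 = rng.choice(idx0, size=max(2, int(np.ceil(2 * len(idx0) / 3))), replace=False)
            s1 = rng.choice(idx1, size=max(2, int(np.ceil(2 * len(idx1) / 3))), replace=False)
            x0, x1 = xr[s0], xr[s1]
            dmu = x1.mean(axis=0) - x0.mean(axis=0)
            w_hat = _fisher_lda_direction(x0, x1)
            proj = float(w_hat @ dmu)
            effects[b] = 0.5 * (np.abs(w_hat * proj) + np.abs(dmu))
        mean_eff = effects.mean(axis=0)
        dmu_full = xr[idx1].mean(axis=0) - xr[idx0].mean(axis=0)
        with np.errstate(divide="ignore"):
            scores = np.where(mean_eff > 0, np.log10(mean_eff), -np.inf)
        for jj, j in enumerate(retained):
            if scores[jj] >= lda_threshold and dmu_full[jj] > 0:
                markers.append(
                    Marker(
                        taxon_id=names[j],
                        class_label=c,
                        lda_score=float(scores[jj]),
                        kw_p=float(kw_p[j]),
                    )
                )
    markers.sort(key=lambda m: -m.lda_score)
    return markers


# ---------------------------------------------------------------------------
# full urotyping pipeline
# ---------------------------------------------------------------------------

@dataclass
class UrotypeModel:
    k: int
    assignments: dict  # sample_id -> 1..k
    medoid_ids: list[str]
    ch_curve: dict  # k -> CH
    markers: dict  # cluster -> ranked list of Marker
    dominant_taxon: dict  # cluster -> taxon_id
    weak_structure: bool = False
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "assignments": self.assignments,
                "medoid_ids": self.medoid_ids,
                "ch_curve": {str(k): v for k, v in self.ch_curve.items()},
                "markers": {
                    str(c): [
                        {
                            "taxon_id": m.taxon_id,
                            "lda_score": m.lda_score,
                            "kw_p": m.kw_p,
                        }
                        for m in ms
                    ]
                    for c, ms in self.markers.items()
                },
                "dominant_taxon": {str(c): t for c, t in self.dominant_taxon.items()},
                "weak_structure": self.weak_structure,
                "seed": self.seed,
            },
            indent=1,
        )


def assign_urotypes(
    table: TaxonProfileTable,
    k_override: int | None = None,
    k_range: range = range(2, 11),
    lda_threshold: float = 2.0,
    alpha: float = 0.05,
    n_boot: int = 30,
    seed: int = 0,
) -> UrotypeModel:
    """jsd_root -> select_k -> PAM -> per-cluster LDA markers -> dominants.

    The dominant taxon of a cluster is its rank-1 marker; when no marker
    clears the threshold the threshold is ignored for that cluster (the
    best-scoring enriched taxon is still reported).
    """
    dist = beta_distance(table, metric="jsd_root")
    ch_curve: dict[int, float] = {}
    weak = False
    if k_override is not None:
        k = k_override
        assignments, medoid_ids = pam_cluster(dist, k, seed=seed)
        ch_curve[k] = ch_index(dist, assignments)
    else:
        k, ch_curve, weak = select_k(dist, k_range=k_range, seed=seed)
        assignments, medoid_ids = pam_cluster(dist, k, seed=seed)

    markers_all = lda_effect_scores(
        table,
        assignments,
        alpha=alpha,
        lda_threshold=-np.inf,  # keep everything, filter per cluster below
        n_boot=n_boot,
        seed=seed,
    )
    markers: dict[int, list[Marker]] = {c: [] for c in range(1, k + 1)}
    for m in markers_all:
        markers[int(m.class_label)].append(m)
    dominant: dict[int, str] = {}
    reported: dict[int, list[Marker]] = {}
    for c in range(1, k + 1):
        ranked = sorted(markers[c], key=lambda m: -m.lda_score)
        if ranked:
            dominant[c] = ranked[0].taxon_id
        above = [m for m in ranked if m.lda_score >= lda_threshold]
        reported[c] = above if above else ranked[:1]
    return UrotypeModel(
        k=k,
        assignments={s: int(a) for s, a in zip(table.sample_ids, assignments)},
        medoid_ids=medoid_ids,
        ch_curve=ch_curve,
        markers=reported,
        dominant_taxon=dominant,
        weak_structure=weak,
        seed=seed,
    )


def dominant_enrichment_tests(
    table: TaxonProfileTable, model: UrotypeModel
) -> list[dict]:
    """Welch t-test of each cluster's dominant taxon, cluster vs rest,
    BH-adjusted across clusters."""
    from .host_factors import bh_adjust

    labels = np.asarray([model.assignments[s] for s in table.sample_ids])
    rows = []
    for c, taxon_id in sorted(model.dominant_taxon.items()):
        j = table.taxon_index(taxon_id)
        in_c = table.relabund[labels == c, j]
        out_c = table.relabund[labels != c, j]
        if np.ptp(in_c) == 0 and np.ptp(out_c) == 0:
            rows.append(
                {"cluster": c, "taxon_id": taxon_id, "t": 0.0, "p": 1.0,
                 "degenerate": True}
            )
            continue
        t, p = stats.ttest_ind(in_c, out_c, equal_var=False)
        rows.append(
            {"cluster": c, "taxon_id": taxon_id, "t": float(t), "p": float(p),
             "degenerate": False}
        )
    qs = bh_adjust([r["p"] for r in rows])
    for r, q in zip(rows, qs):
        r["q"] = float(q)
    return rows
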