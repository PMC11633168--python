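"""Microbiome GWAS: variant/sample QC, genotype PCs, a dual linear/logistic
taxon-association scan, and genotype-environment interaction tests.

Taxa present in over half the cohort are analyzed as residualized
log10-abundance quantitative traits; taxa present in 10-50% as
presence/absence logistic traits. Both scans test the additive dosage term
at genome-wide significance 5e-8.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import GenotypeTable, TaxonProfileTable

logger = logging.getLogger(__name__)

GENOME_WIDE_ALPHA = 5e-8


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional HWE test.

    Sums the probabilities of all heterozygote counts (given allele
    counts) that are no more probable than the observed one. Symmetric in
    ref/alt; monomorphic data give p = 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_hom_alt + n_het  # minor-izable allele count
    n_alleles = 2 * n
    rare = min(n_a, n_alleles - n_a)
    # possible het counts share the parity of the rare allele count
    het_values = np.arange(rare % 2, rare + 1, 2)
    log_probs = np.array(
        [_hwe_log_prob(n, rare, h) for h in het_values]
    )
    log_probs -= log_probs.max()
    probs = np.exp(log_probs)
    probs /= probs.sum()
    obs = probs[np.where(het_values == n_het)[0][0]]
    return float(min(1.0, probs[probs <= obs + 1e-12].sum()))


def _hwe_log_prob(n: int, rare: int, het: int) -> float:
    """Log P(het | n, rare allele count) under HWE, up to a constant."""
    hom_rare = (rare - het) // 2
    hom_common = n - het - hom_rare
    if hom_rare < 0 or hom_common < 0:
        return -np.inf
    return (
        het * math.log(2.0)
        - math.lgamma(het + 1)
        - math.lgamma(hom_rare + 1)
        - math.lgamma(hom_common + 1)
    )


# ---------------------------------------------------------------------------
# variant QC and genotype PCs
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    hwe_p: float = 1e-5
    call_rate: float = 0.98
    maf: float = 0.01


def variant_qc(
    genotypes: GenotypeTable, thresholds: QCThresholds | None = None
) -> tuple[GenotypeTable, dict]:
    """Drop variants failing HWE, call-rate or MAF rules."""
    th = thresholds or QCThresholds()
    d = genotypes.dosages
    n = d.shape[1]
    called = np.isfinite(d)
    call_rate = called.mean(axis=1)
    maf = genotypes.maf()
    hwe_p = np.ones(genotypes.n_variants)
    for v in range(genotypes.n_variants):
        row = d[v][called[v]]
        if row.size:
            hwe_p[v] = hwe_exact_test(
                int((row == 0).sum()), int((row == 1).sum()), int((row == 2).sum())
            )
    pass_call = call_rate > th.call_rate
    pass_maf = maf >= th.maf
    pass_hwe = hwe_p > th.hwe_p
    keep = pass_call & pass_maf & pass_hwe
    if not keep.any():
        raise ValueError("no variants survive QC")
    report = {
        "n_input": genotypes.n_variants,
        "n_retained": int(keep.sum()),
        "n_fail_call_rate": int((~pass_call).sum()),
        "n_fail_maf": int((~pass_maf).sum()),
        "n_fail_hwe": int((~pass_hwe).sum()),
    }
    return genotypes.select_variants(keep), report


def genotype_pcs(genotypes: GenotypeTable, n_pc: int = 10) -> np.ndarray:
    """Top principal components of standardized dosages.

    Missing dosages are mean-imputed; each variant is centered at 2p and
    scaled by sqrt(2p(1-p)). PC signs are fixed by making each component's
    largest-magnitude sample loading positive.
    """
    d = genotypes.dosages.copy()
    mean = np.nanmean(d, axis=1)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mean, inds[0])
    p = mean / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    ok = sd > 0
    z = (d[ok] - mean[ok, None]) / sd[ok, None]
    n_pc_eff = min(n_pc, min(z.shape) - 1 if min(z.shape) > 1 else 1)
    if n_pc_eff < n_pc:
        logger.warning("n_pc truncated from %d to %d", n_pc, n_pc_eff)
    # samples are columns of z; PCs = right singular vectors
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    pcs = vt[:n_pc_eff].T * s[:n_pc_eff]
    for j in range(pcs.shape[1]):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


# ---------------------------------------------------------------------------
# taxon response preparation
# ---------------------------------------------------------------------------

@dataclass
class TaxonResponse:
    taxon_id: str
    model_kind: str  # "linear_residual" | "logistic_pa"
    prevalence: float
    response: np.ndarray  # residuals (linear) or 0/1 presence (logistic)
    covariate_names: list[str]
    pseudocount: float | None = None


def _ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    xd = np.column_stack([np.ones(len(y)), x])
    # drop machine-precision collinear columns via pivoted QR rank check
    q, r = np.linalg.qr(xd)
    diag = np.abs(np.diag(r))
    keep = diag > diag.max() * 1e-10
    if not keep.all():
        logger.warning("dropping %d collinear covariate columns", (~keep).sum())
        xd = xd[:, keep]
    beta, *_ = np.linalg.lstsq(xd, y, rcond=None)
    return y - xd @ beta


def prepare_taxon_response(
    abundances: np.ndarray,
    taxon_id: str,
    covariates: np.ndarray,
    covariate_names: list[str] | None = None,
    min_prevalence: float = 0.10,
    linear_prevalence: float = 0.5,
) -> TaxonResponse | None:
    """Build the per-taxon GWAS response.

    prevalence <= 0.10: excluded (returns None). > 0.5: zeros replaced by
    half the minimum nonzero abundance, log10, residualized on the
    covariates. (0.10, 0.5]: presence indicator for logistic regression.
    """
    ab = np.asarray(abundances, dtype=float)
    prevalence = float((ab > 0).mean())
    names = covariate_names or [f"c{j}" for j in range(np.atleast_2d(covariates).shape[1])]
    if prevalence <= min_prevalence:
        return None
    if prevalence > linear_prevalence:
        nz = ab[ab > 0]
        pseudo = nz.min() / 2.0
        y = np.log10(np.where(ab > 0, ab, pseudo))
        resid = _ols_residuals(y, covariates)
        return TaxonResponse(
            taxon_id=taxon_id,
            model_kind="linear_residual",
            prevalence=prevalence,
            response=resid,
            covariate_names=names,
            pseudocount=float(pseudo),
        )
    return TaxonResponse(
        taxon_id=taxon_id,
        model_kind="logistic_pa",
        prevalence=prevalence,
        response=(ab > 0).astype(float),
        covariate_names=names,
    )


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------

@dataclass
class AssociationRecord:
    variant_id: str
    taxon_id: str
    model_kind: str
    beta: float
    se: float
    p_value: float
    n: int
    maf: float
    flag: str = ""


def _linear_scan(
    resp: np.ndarray, dosages: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-variant simple regression y ~ 1 + g (Wald t).

    Missing dosages are handled per variant by masking. Returns
    (beta, se, p, n) arrays over variants.
    """
    v, n = dosages.shape
    ok = np.isfinite(dosages)
    y = resp
    n_eff = ok.sum(axis=1).astype(float)
    g = np.where(ok, dosages, 0.0)
    yv = np.where(ok, y[None, :], 0.0)
    sum_g = g.sum(axis=1)
    sum_y = yv.sum(axis=1)
    mean_g = sum_g / n_eff
    mean_y = sum_y / n_eff
    sxx = (g**2).sum(axis=1) - n_eff * mean_g**2
    sxy = (g * yv).sum(axis=1) - n_eff * mean_g * mean_y
    syy = (yv**2).sum(axis=1) - n_eff * mean_y**2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        ss_res = syy - beta * sxy
        df = n_eff - 2
        sigma2 = ss_res / df
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
    bad = (sxx <= 0) | (df <= 0)
    beta[bad], se[bad], p[bad] = np.nan, np.nan, np.nan
    return beta, se, p, n_eff.astype(int)


def _logistic_irls_batch(
    y: np.ndarray,
    covar: np.ndarray,
    dosages: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-8,
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wald z test of the dosage term in y ~ covariates + g, batched IRLS.

    Only the dosage column differs across variants, so Newton iterations
    are vectorized over variant chunks. Missing dosages are mean-imputed
    per variant (they are rare post-QC). Non-converged or near-separated
    fits fall back to a ridge-stabilized (Firth-style) solution and are
    flagged via se = inf -> p = NaN handled by the caller.
    """
    n = len(y)
    x_base = np.column_stack([np.ones(n), covar])
    p_base = x_base.shape[1]
    p_full = p_base + 1

    # warm start from the covariate-only fit
    beta0 = _logistic_single(y, x_base)[0]

    v_total = dosages.shape[0]
    betas = np.full(v_total, np.nan)
    ses = np.full(v_total, np.nan)
    converged = np.zeros(v_total, dtype=bool)

    for start in range(0, v_total, chunk):
        g = dosages[start : start + chunk].copy()
        m = g.shape[0]
        gm = np.nanmean(g, axis=1)
        miss = np.isnan(g)
        if miss.any():
            g[miss] = np.take(gm, np.where(miss)[0])
        x = np.broadcast_to(x_base, (m, n, p_base))
        x = np.concatenate([x, g[:, :, None]], axis=2)  # m x n x p_full
        b = np.tile(np.concatenate([beta0, [0.0]]), (m, 1))
        active = np.ones(m, dtype=bool)
        for _ in range(max_iter):
            eta = np.einsum("vnp,vp->vn", x, b)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            w = np.maximum(w, 1e-10)
            grad = np.einsum("vnp,vn->vp", x, y[None, :] - mu)
            info = np.einsum("vnp,vn,vnq->vpq", x, w, x)
            info = info + 1e-10 * np.eye(p_full)
            try:
                step = np.linalg.solve(info, grad[..., None])[..., 0]
            except np.linalg.LinAlgError:
                break
            step = np.clip(step, -5.0, 5.0)
            b = b + step
            moved = np.abs(step).max(axis=1)
            active = moved > tol
            if not active.any():
                break
        eta = np.einsum("vnp,vp->vn", x, b)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        info = np.einsum("vnp,vn,vnq->vpq", x, w, x) + 1e-10 * np.eye(p_full)
        cov = np.linalg.inv(info)
        betas[start : start + m] = b[:, -1]
        ses[start : start + m] = np.sqrt(np.maximum(cov[:, -1, -1], 0.0))
        converged[start : start + m] = ~active
    return betas, ses, converged


def _logistic_single(
    y: np.ndarray, x: np.ndarray, max_iter: int = 50, ridge: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Plain Newton logistic fit; returns (beta, covariance)."""
    p = x.shape[1]
    b = np.zeros(p)
    for _ in range(max_iter):
        eta = x @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = x.T @ (y - mu) - ridge * b
        info = (x * w[:, None]).T @ x + (ridge + 1e-12) * np.eye(p)
        step = np.linalg.solve(info, grad)
        b = b + np.clip(step, -10, 10)
        if np.abs(step).max() < 1e-10:
            break
    eta = x @ b
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    info = (x * w[:, None]).T @ x + (ridge + 1e-12) * np.eye(p)
    return b, np.linalg.inv(info)


def association_scan(
    genotypes: GenotypeTable,
    responses: list[TaxonResponse],
    covariates: np.ndarray,
    alpha: float = GENOME_WIDE_ALPHA,
) -> tuple[list[AssociationRecord], list[AssociationRecord]]:
    """Scan every (QC-passed variant, prepared taxon) pair.

    Linear responses are pre-residualized, so each test is a simple
    regression of residual on dosage. Logistic responses refit
    presence ~ dosage + covariates per variant by maximum likelihood.
    Returns (all records, genome-wide hits at ``alpha``).
    """
    maf = genotypes.maf()
    records: list[AssociationRecord] = []
    vids = genotypes.variants["id"].tolist()
    with np.errstate(all="ignore"):
        spread = np.array(
            [np.nanmax(row) - np.nanmin(row) if np.isfinite(row).any() else 0.0
             for row in genotypes.dosages]
        )
    informative = (maf > 0) & (spread > 0)
    for r in responses:
        if r.model_kind == "linear_residual":
            beta, se, p, n_eff = _linear_scan(r.response, genotypes.dosages)
            for v in range(genotypes.n_variants):
                if not informative[v]:
                    records.append(
                        AssociationRecord(
                            vids[v], r.taxon_id, r.model_kind,
                            np.nan, np.nan, np.nan, int(n_eff[v]),
                            float(maf[v]), flag="monomorphic",
                        )
                    )
                    continue
                records.append(
                    AssociationRecord(
                        vids[v], r.taxon_id, r.model_kind,
                        float(beta[v]), float(se[v]), float(p[v]),
                        int(n_eff[v]), float(maf[v]),
                    )
                )
        elif r.model_kind == "logistic_pa":
            betas, ses, conv = _logistic_irls_batch(
                r.response, covariates, genotypes.dosages
            )
            z = betas / ses
            ps = 2.0 * stats.norm.sf(np.abs(z))
            for v in range(genotypes.n_variants):
                flag = ""
                b, s, pv = betas[v], ses[v], ps[v]
                if not informative[v]:
                    records.append(
                        AssociationRecord(
                            vids[v], r.taxon_id, r.model_kind,
                            np.nan, np.nan, np.nan, len(r.response),
                            float(maf[v]), flag="monomorphic",
                        )
                    )
                    continue
                if not conv[v] or not np.isfinite(s) or s > 50 or abs(b) > 15:
                    # separation-prone fit: ridge-penalized fallback
                    g = genotypes.dosages[v].copy()
                    gm = np.nanmean(g)
                    g[np.isnan(g)] = gm
                    xd = np.column_stack([np.ones(len(g)), covariates, g])
                    bf, covf = _logistic_single(
                        r.response, xd, ridge=0.5
                    )
                    b, s = bf[-1], float(np.sqrt(covf[-1, -1]))
                    pv = 2.0 * stats.norm.sf(abs(b / s))
                    flag = "penalized"
                records.append(
                    AssociationRecord(
                        vids[v], r.taxon_id, r.model_kind,
                        float(b), float(s), float(pv),
                        len(r.response), float(maf[v]), flag=flag,
                    )
                )
        else:
            raise ValueError(f"unknown model kind: {r.model_kind}")
    hits = [
        rec
        for rec in records
        if np.isfinite(rec.p_value) and rec.p_value < alpha
    ]
    return records, hits


# ---------------------------------------------------------------------------
# gene-environment interaction
# ---------------------------------------------------------------------------

@dataclass
class InteractionRecord:
    variant_id: str
    taxon_id: str
    env_name: str
    beta_gxe: float
    se: float
    p_gxe: float
    n: int


def gxe_interaction(
    genotype: np.ndarray,
    env: np.ndarray,
    response: TaxonResponse,
    covariates: np.ndarray | None = None,
    variant_id: str = "variant",
    env_name: str = "env",
) -> InteractionRecord:
    """Wald test on the g*e coefficient of response ~ g + e + g*e.

    Linear responses use OLS on the prepared residuals; logistic responses
    refit presence ~ g + e + g*e + covariates by maximum likelihood.
    """
    g = np.asarray(genotype, dtype=float)
    e = np.asarray(env, dtype=float)
    if np.ptp(e[np.isfinite(e)]) == 0:
        raise ValueError("environment variable is constant")
    ok = np.isfinite(g) & np.isfinite(e)
    y = response.response[ok]
    g, e = g[ok], e[ok]
    inter = g * e
    if response.model_kind == "linear_residual":
        x = np.column_stack([np.ones(len(y)), g, e, inter])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        df = len(y) - x.shape[1]
        sigma2 = resid @ resid / df
        cov = sigma2 * np.linalg.inv(x.T @ x)
        se = float(np.sqrt(cov[-1, -1]))
        t = beta[-1] / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        return InteractionRecord(
            variant_id, response.taxon_id, env_name,
            float(beta[-1]), se, p, len(y),
        )
    cols = [np.ones(len(y)), g, e]
    if covariates is not None:
        cols.append(np.atleast_2d(np.asarray(covariates, float))[ok]
                    if np.asarray(covariates).ndim == 1
                    else np.asarray(covariates, float)[ok])
    cols.append(inter)
    x = np.column_stack(cols)
    b, cov = _logistic_single(y, x)
    se = float(np.sqrt(cov[-1, -1]))
    z = b[-1] / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return InteractionRecord(
        variant_id, response.taxon_id, env_name, float(b[-1]), se, p, len(y)
    )


def stratified_effect_summary(
    genotype: np.ndarray,
    group_labels,
    taxon_abund: np.ndarray,
    env: np.ndarray | None = None,
    carrier_rule: tuple[tuple[float, ...], tuple[float, ...]] = ((0.0,), (1.0, 2.0)),
) -> pd.DataFrame:
    """Cell means of abundance by (carrier class x group), with 95% CIs and
    within-carrier-class Spearman of env vs abundance.

    ``carrier_rule`` partitions dosages into two classes (default:
    homozygous reference vs carriers). Non-missing samples not covered by
    the rule would violate the partition and raise.
    """
    g = np.asarray(genotype, dtype=float)
    ab = np.asarray(taxon_abund, dtype=float)
    groups = np.asarray(group_labels)
    covered = np.isin(g, carrier_rule[0] + carrier_rule[1]) | np.isnan(g)
    if not covered.all():
        raise ValueError("carrier rule does not partition observed dosages")
    rows = []
    for ci, klass in enumerate(carrier_rule):
        in_class = np.isin(g, klass)
        for grp in pd.unique(groups):
            m = in_class & (groups == grp)
            n = int(m.sum())
            if n == 0:
                rows.append(
                    {"carrier_class": ci, "group": grp, "n": 0, "mean": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan}
                )
                continue
            mean = float(ab[m].mean())
            sem = float(ab[m].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            rows.append(
                {
                    "carrier_class": ci, "group": grp, "n": n, "mean": mean,
                    "ci_low": mean - 1.96 * sem if n > 1 else np.nan,
                    "ci_high": mean + 1.96 * sem if n > 1 else np.nan,
                }
            )
        if env is not None:
            ev = np.asarray(env, dtype=float)
            m = in_class & np.isfinite(ev)
            if m.sum() >= 3 and np.ptp(ab[m]) > 0 and np.ptp(ev[m]) > 0:
                rho, p = stats.spearmanr(ev[m], ab[m])
                rows.append(
                    {"carrier_class": ci, "group": "_spearman_env", "n": int(m.sum()),
                     "mean": float(rho), "ci_low": np.nan, "ci_high": float(p)}
                )
            else:
                rows.append(
                    {"carrier_class": ci, "group": "_spearman_env", "n": int(m.sum()),
                     "mean": np.nan, "ci_low": np.nan, "ci_high": np.nan}
                )
    return pd.DataFrame(rows)


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in records],
            "taxon_id": [r.taxon_id for r in records],
            "model": [r.model_kind for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "p": [r.p_value for r in records],
            "n": [r.n for r in records],
            "maf": [r.maf for r in records],
            "flag": [r.flag for r in records],
        }
    )
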