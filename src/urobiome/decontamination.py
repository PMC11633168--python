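"""Three-step contaminant removal for low-biomass profiles.

Step 1 flags cohort-wide contaminants by any of four criteria (PCR-
concentration correlation, frequency-model p-value / rarity, presence in
mock controls beyond the expected species, low total reads). Step 2 flags
plate-specific contaminants from each plate's mock control. Step 3 removes
flagged and non-bacterial taxa and renormalizes, reporting the per-sample
fraction of reads removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import SampleSheet, TaxonProfileTable
from .synthetic_cohort import MOCK_EXPECTED_SPECIES

logger = logging.getLogger(__name__)

REASONS = (
    "CORR_PCR",
    "PFREQ",
    "OCCURRENCE",
    "MOCK_COHORT",
    "READS",
    "PLATE_MOCK",
    "NON_BACTERIAL",
)


@dataclass
class DecontamParams:
    p_spearman: float = 0.05
    spearman_direction: str = "two-sided"  # or "negative"
    p_freq_threshold: float = 0.3
    min_occurrence: int = 4
    mock_mean_threshold: float = 1e-4
    min_reads: int = 1000
    per_sample_reads: bool = False  # alternative reading of the reads rule
    min_pfreq_samples: int = 5
    expected_species: tuple[str, ...] = MOCK_EXPECTED_SPECIES


@dataclass
class ContaminantFlag:
    taxon_id: str
    flagged: bool
    reasons: list[str] = field(default_factory=list)
    scope: str = "cohort"
    p_freq: float | None = None
    spearman_rho: float | None = None
    spearman_p: float | None = None
    occurrence: int = 0
    total_reads: int = 0

    def __post_init__(self) -> None:
        self.flagged = bool(self.reasons)


@dataclass
class DecontamReport:
    per_sample_contaminated_fraction: dict  # sample_id -> fraction
    n_taxa_removed_by_reason: dict
    n_taxa_retained: int
    empty_samples: list[str] = field(default_factory=list)

    @property
    def summary(self) -> dict:
        vals = np.asarray(list(self.per_sample_contaminated_fraction.values()))
        if vals.size == 0:
            return {"mean": 0.0, "median": 0.0, "q95": 0.0}
        return {
            "mean": float(vals.mean()),
            "median": float(np.median(vals)),
            "q95": float(np.quantile(vals, 0.95)),
        }


def freq_contaminant_pvalue(
    freqs: np.ndarray,
    conc: np.ndarray,
    min_samples: int = 5,
    eps: float = 1e-12,
) -> float | None:
    """Frequency-model contaminant p-value on one taxon.

    On samples with positive frequency and concentration, compares the
    least-squares fit of log10(freq) on log10(conc) under a contaminant
    model (slope fixed at -1, free intercept) against a non-contaminant
    model (slope 0, free intercept). The statistic is the residual
    sum-of-squares ratio lambda = SS_contaminant / SS_non, referred to an
    F(n-1, n-1) distribution; small values are contaminant-like.

    Returns None when fewer than ``min_samples`` usable samples exist.
    """
    freqs = np.asarray(freqs, dtype=float)
    conc = np.asarray(conc, dtype=float)
    m = (freqs > 0) & (conc > 0) & np.isfinite(freqs) & np.isfinite(conc)
    n = int(m.sum())
    if n < min_samples:
        return None
    y = np.log10(freqs[m])
    x = np.log10(conc[m])
    resid_c = (y + x) - (y + x).mean()  # y = -x + b
    resid_n = y - y.mean()  # y = b
    ss_c = float(resid_c @ resid_c)
    ss_n = float(resid_n @ resid_n)
    lam = (ss_c + eps) / (ss_n + eps)
    return float(stats.f.cdf(lam, n - 1, n - 1))


def _occurrence(relabund: np.ndarray) -> np.ndarray:
    return (relabund > 0).sum(axis=0)


def flag_cohort_contaminants(
    table: TaxonProfileTable,
    sheet: SampleSheet,
    params: DecontamParams | None = None,
) -> list[ContaminantFlag]:
    """Step 1: cohort-wide flags, OR-combined across four criteria.

    (a) CORR_PCR  — Spearman of relative abundance vs PCR concentration
                    significant at ``p_spearman`` (two-sided by default);
    (b) PFREQ     — frequency-model p < threshold, or OCCURRENCE in fewer
                    than ``min_occurrence`` study samples;
    (c) MOCK_COHORT — non-expected species with mean relative abundance
                    above ``mock_mean_threshold`` across all mock controls;
    (d) READS     — taxon reads summed over study samples < ``min_reads``.
    """
    params = params or DecontamParams()
    study_ids = sheet.study_ids
    mock_ids = [s for s in sheet.mock_ids if s in table.sample_ids]
    study = table.select_samples([s for s in study_ids if s in table.sample_ids])

    conc = None
    if "pcr_concentration" in sheet.data.columns:
        conc = sheet.column("pcr_concentration", study.sample_ids).to_numpy(float)
        if not np.isfinite(conc).any() or np.nanmax(conc) <= 0:
            conc = None
    if conc is None:
        logger.warning("no PCR concentrations: criteria (a) and (b: p_freq) skipped")

    mocks = table.select_samples(mock_ids) if mock_ids else None
    if mocks is None:
        logger.warning("no mock controls: criterion (c) skipped")

    if study.read_counts is not None:
        reads = study.read_counts
    else:
        tot = study.total_reads
        if tot is None:
            tot = np.full(study.n_samples, 1_000_000)
            logger.warning("no read counts; approximating reads from fractions")
        reads = np.rint(study.relabund * tot[:, None]).astype(np.int64)

    occ = _occurrence(study.relabund)
    expected = set(params.expected_species)
    flags: list[ContaminantFlag] = []
    for j, taxon in enumerate(table.taxa):
        reasons: list[str] = []
        rho = p_sp = pfreq = None
        freqs = study.relabund[:, j]
        if conc is not None:
            usable = np.isfinite(conc) & (conc > 0)
            if usable.sum() >= 3 and np.ptp(freqs[usable]) > 0:
                rho, p_sp = stats.spearmanr(freqs[usable], conc[usable])
                rho, p_sp = float(rho), float(p_sp)
                hit = p_sp < params.p_spearman
                if params.spearman_direction == "negative":
                    hit = hit and rho < 0
                if hit:
                    reasons.append("CORR_PCR")
            pfreq = freq_contaminant_pvalue(
                freqs, np.where(np.isfinite(conc), conc, 0.0),
                min_samples=params.min_pfreq_samples,
            )
            if pfreq is not None and pfreq < params.p_freq_threshold:
                reasons.append("PFREQ")
        if occ[j] < params.min_occurrence:
            reasons.append("OCCURRENCE")
        if mocks is not None and taxon.taxon_id not in expected:
            if mocks.relabund[:, j].mean() > params.mock_mean_threshold:
                reasons.append("MOCK_COHORT")
        total_reads_j = int(reads[:, j].sum())
        if params.per_sample_reads:
            if np.any((reads[:, j] > 0) & (reads[:, j] < params.min_reads)):
                reasons.append("READS")
        elif total_reads_j < params.min_reads:
            reasons.append("READS")
        flags.append(
            ContaminantFlag(
                taxon_id=taxon.taxon_id,
                flagged=bool(reasons),
                reasons=reasons,
                scope="cohort",
                p_freq=pfreq,
                spearman_rho=rho,
                spearman_p=p_sp,
                occurrence=int(occ[j]),
                total_reads=total_reads_j,
            )
        )
    return flags


def flag_plate_contaminants(
    table: TaxonProfileTable,
    sheet: SampleSheet,
    params: DecontamParams | None = None,
    cohort_flags: list[ContaminantFlag] | None = None,
) -> list[ContaminantFlag]:
    """Step 2: plate-scoped flags from each plate's mock control.

    Runs on taxa surviving Step 1: any non-expected species above the
    abundance threshold in a plate's mock is flagged for that plate only.
    """
    params = params or DecontamParams()
    removed = {
        f.taxon_id for f in (cohort_flags or []) if f.flagged
    }
    expected = set(params.expected_species)
    mock_df = sheet.data[sheet.data["role"].isin(["mock_extraction", "mock_library"])]
    flags: list[ContaminantFlag] = []
    plates_with_mocks = set()
    for plate_id, grp in mock_df.groupby("plate_id"):
        mids = [s for s in grp["sample_id"] if s in table.sample_ids]
        if not mids:
            continue
        plates_with_mocks.add(plate_id)
        mocks = table.select_samples(mids)
        mean_ab = mocks.relabund.mean(axis=0)
        for j, taxon in enumerate(table.taxa):
            if taxon.taxon_id in removed or taxon.taxon_id in expected:
                continue
            if mean_ab[j] > params.mock_mean_threshold:
                flags.append(
                    ContaminantFlag(
                        taxon_id=taxon.taxon_id,
                        flagged=True,
                        reasons=["PLATE_MOCK"],
                        scope=f"plate:{plate_id}",
                    )
                )
    study_plates = set(
        sheet.data.loc[sheet.data["role"] == "study", "plate_id"].dropna()
    )
    for plate in study_plates - plates_with_mocks:
        logger.warning("plate %s has no mock control; Step 2 skipped for it", plate)
    return flags


def apply_decontamination(
    table: TaxonProfileTable,
    flags: list[ContaminantFlag],
    sheet: SampleSheet | None = None,
    keep_domains: tuple[str, ...] = ("bacteria",),
) -> tuple[TaxonProfileTable, DecontamReport]:
    """Step 3: zero flagged taxa per scope, drop non-bacteria, renormalize.

    The per-sample contaminated fraction (reads removed / total reads) is
    computed before renormalization. Samples losing all reads are marked
    empty and excluded from the returned table.
    """
    out = table.copy()
    n_samples, n_taxa = out.relabund.shape
    plate_of: dict[str, str] = {}
    if sheet is not None and "plate_id" in sheet.data.columns:
        plate_of = dict(zip(sheet.data["sample_id"], sheet.data["plate_id"]))

    remove = np.zeros((n_samples, n_taxa), dtype=bool)
    tindex = {t.taxon_id: j for j, t in enumerate(out.taxa)}
    reason_counts: dict[str, int] = {}
    flagged_taxa: set[str] = set()
    for f in flags:
        if not f.flagged or f.taxon_id not in tindex:
            continue
        j = tindex[f.taxon_id]
        if f.scope == "cohort":
            remove[:, j] = True
        elif f.scope.startswith("plate:"):
            plate = f.scope.split(":", 1)[1]
            rows = [
                i for i, s in enumerate(out.sample_ids) if plate_of.get(s) == plate
            ]
            remove[rows, j] = True
        flagged_taxa.add(f.taxon_id)
        for r in f.reasons:
            reason_counts[r] = reason_counts.get(r, 0) + 1

    non_bact = np.array([t.domain not in keep_domains for t in out.taxa])
    if non_bact.any():
        remove[:, non_bact] = True
        reason_counts["NON_BACTERIAL"] = int(non_bact.sum())

    removed_mass = np.where(remove, out.relabund, 0.0).sum(axis=1)
    row_sums = out.relabund.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(row_sums > 0, removed_mass / row_sums, 0.0)

    new_rel = np.where(remove, 0.0, out.relabund)
    new_counts = None
    if out.read_counts is not None:
        new_counts = np.where(remove, 0, out.read_counts)
        tot = out.total_reads.astype(float)
        removed_reads = np.where(remove, out.read_counts, 0).sum(axis=1)
        frac = np.where(tot > 0, removed_reads / tot, 0.0)

    keep_sample = new_rel.sum(axis=1) > 0
    empty = [s for s, k in zip(out.sample_ids, keep_sample) if not k]
    for s in empty:
        logger.warning("sample %s lost all reads during decontamination", s)

    sums = new_rel.sum(axis=1, keepdims=True)
    new_rel = new_rel / np.where(sums > 0, sums, 1.0)

    # drop fully-removed taxa (cohort scope or non-bacterial)
    cohort_removed = ~(new_rel[keep_sample] > 0).any(axis=0) & (
        np.array([t.taxon_id in flagged_taxa for t in out.taxa]) | non_bact
    )
    keep_taxa = ~cohort_removed
    cleaned = TaxonProfileTable(
        sample_ids=[s for s, k in zip(out.sample_ids, keep_sample) if k],
        taxa=[t for t, k in zip(out.taxa, keep_taxa) if k],
        relabund=new_rel[np.ix_(keep_sample, keep_taxa)],
        read_counts=(
            None if new_counts is None else new_counts[np.ix_(keep_sample, keep_taxa)]
        ),
        total_reads=None,
        normalized=True,
    )
    # renormalize after dropping taxa columns that were zeroed per-plate only
    cleaned = cleaned.renormalized()
    report_ids = out.sample_ids
    if sheet is not None:
        study = set(sheet.study_ids)
        report_ids = [s for s in out.sample_ids if s in study]
    frac_of = dict(zip(out.sample_ids, frac))
    report = DecontamReport(
        per_sample_contaminated_fraction={
            s: float(frac_of[s]) for s in report_ids
        },
        n_taxa_removed_by_reason=reason_counts,
        n_taxa_retained=cleaned.n_taxa,
        empty_samples=empty,
    )
    return cleaned, report


def decontaminate(
    table: TaxonProfileTable,
    sheet: SampleSheet,
    params: DecontamParams | None = None,
) -> tuple[TaxonProfileTable, list[ContaminantFlag], DecontamReport]:
    """Run Steps 1-3 in order and return the cleaned table, flags, report."""
    params = params or DecontamParams()
    cohort = flag_cohort_contaminants(table, sheet, params)
    plate = flag_plate_contaminants(table, sheet, params, cohort_flags=cohort)
    cleaned, report = apply_decontamination(table, cohort + plate, sheet=sheet)
    return cleaned, cohort + plate, report


def feature_filter(
    table: TaxonProfileTable,
    min_prevalence: float = 0.10,
    min_mean_relabund: float = 1e-4,
) -> TaxonProfileTable:
    """Keep taxa present in more than ``min_prevalence`` of samples with
    mean relative abundance above ``min_mean_relabund``.

    No renormalization is applied (downstream use is ratio-preserving);
    the result is flagged unnormalized. Zero thresholds are identity.
    """
    prev = (table.relabund > 0).mean(axis=0)
    mean_ab = table.relabund.mean(axis=0)
    keep = np.ones(table.n_taxa, dtype=bool)
    if min_prevalence > 0:
        keep &= prev > min_prevalence
    if min_mean_relabund > 0:
        keep &= mean_ab > min_mean_relabund
    if not keep.any():
        raise ValueError(
            f"feature filter removed all taxa (max prevalence {prev.max():.3f}, "
            f"max mean abundance {mean_ab.max():.2e})"
        )
    if keep.all():
        out = table.copy()
        return out
    return table.select_taxa([t.taxon_id for t, k in zip(table.taxa, keep) if k])


def flags_to_frame(flags: list[ContaminantFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon_id": [f.taxon_id for f in flags],
            "flagged": [f.flagged for f in flags],
            "reasons": [";".join(f.reasons) for f in flags],
            "scope": [f.scope for f in flags],
            "p_freq": [f.p_freq for f in flags],
            "spearman_rho": [f.spearman_rho for f in flags],
            "spearman_p": [f.spearman_p for f in flags],
            "occurrence": [f.occurrence for f in flags],
            "total_reads": [f.total_reads for f in flags],
        }
    )
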