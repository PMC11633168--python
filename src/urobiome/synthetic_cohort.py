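"""Synthetic cohorts with the structure every downstream stage assumes.

Counts are simulated first (Dirichlet-multinomial per latent community
type) and fractions derived from them, so read-count filters are
exercisable. Contaminants, mock controls, genotypes and planted genetic
effects are layered on top, with every planted signal recorded in a
:class:`SimulationTruth` object for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import (
    GenotypeTable,
    SampleSheet,
    TaxonProfileTable,
    taxon_record,
)

# Ten equimolar pseudo-species standing in for a commercial mock community.
MOCK_EXPECTED_SPECIES: tuple[str, ...] = tuple(
    f"k__Bacteria|p__MockPhylum|c__MockClass|o__MockOrder|"
    f"f__MockFamily|g__Mockgenus|s__Mock_species_{i:02d}"
    for i in range(1, 11)
)


@dataclass
class SimulationConfig:
    """Knobs for :func:`generate_profiles`."""

    n_study: int = 600
    n_taxa: int = 100
    n_clusters: int = 5
    dominant_share: float = 0.30
    concentration: float = 50.0  # Dirichlet total mass per cluster
    # fraction of females overall, and per-cluster log-odds shift toward
    # females (positive = female-enriched); length n_clusters or scalar 0
    female_fraction: float = 0.5
    sex_bias: tuple[float, ...] | float = (1.5, -1.0, 1.5, -1.0, -1.0)
    n_sex_taxa: int = 0
    sex_effect_log10: float = 0.4
    # per-taxon prevalence: dominant taxa always present, the rest drawn
    # uniformly from this range (1, 1 = fully dense table)
    prevalence_range: tuple[float, float] = (1.0, 1.0)
    plate_capacity: int = 96
    mean_depth: float = 1e5
    depth_log_sd: float = 0.25
    phenotype_links: tuple[tuple[str, int, float], ...] = ()
    # hormone-like phenotypes keyed by sex: name -> (female mean, male mean, log sd)
    hormones: dict = field(
        default_factory=lambda: {
            "testosterone": (0.8, 18.0, 0.35),
            "estradiol": (110.0, 25.0, 0.35),
        }
    )


@dataclass
class ContaminantSpec:
    """Knobs for :func:`spike_contaminants`."""

    n_cohort: int = 16
    n_plate_specific: int = 4
    # expected contaminant read share for sample i is load_scale/pcr_i,
    # truncated at max_share
    load_scale: float = 0.08
    max_share: float = 0.5
    pcr_log_mean: float = 0.7  # ln ng/uL
    pcr_log_sd: float = 0.5
    mock_contaminant_share: float = 5e-4
    mock_depth: float = 5e4
    expected_species: tuple[str, ...] = MOCK_EXPECTED_SPECIES
    emit_negatives: bool = False


@dataclass
class SimulationTruth:
    """Ground truth of a generated cohort; grows as layers are added."""

    seed: int
    config: dict = field(default_factory=dict)
    cluster_labels: dict = field(default_factory=dict)  # sample_id -> 1..K
    dominant_taxon: dict = field(default_factory=dict)  # cluster -> taxon_id
    contaminant_taxa: dict = field(default_factory=dict)  # taxon_id -> scope
    contaminated_fraction: dict = field(default_factory=dict)  # sample -> frac
    sex_effect_taxa: list = field(default_factory=list)  # (taxon_id, signed log10)
    planted_effects: list = field(default_factory=list)
    phenotype_links: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _taxon_lineage(j: int) -> str:
    return (
        f"k__Bacteria|p__Phylum{j % 7}|c__Class{j % 11}|o__Order{j % 13}|"
        f"f__Family{j % 17}|g__Genus{j % 23}|s__Taxon_{j:03d}"
    )


def generate_profiles(
    config: SimulationConfig, seed: int
) -> tuple[TaxonProfileTable, SampleSheet, SimulationTruth]:
    """Draw a study cohort of Dirichlet-multinomial community profiles.

    Each sample belongs to one of K latent community types, each dominated
    by a distinct taxon with expected share ``dominant_share``; cluster
    priors are sex-biased via per-cluster log-odds shifts.
    """
    cfg = config
    if cfg.n_clusters > cfg.n_taxa:
        raise ValueError("more clusters than taxa")
    rng = np.random.default_rng(seed)

    lineages = [_taxon_lineage(j) for j in range(cfg.n_taxa)]
    taxa = [taxon_record(lin) for lin in lineages]
    dominant_idx = list(range(cfg.n_clusters))  # taxon j dominates cluster j+1

    # sex, then cluster given sex
    sex = np.where(rng.random(cfg.n_study) < cfg.female_fraction, "female", "male")
    bias = np.asarray(
        cfg.sex_bias
        if not np.isscalar(cfg.sex_bias)
        else [cfg.sex_bias] * cfg.n_clusters,
        dtype=float,
    )
    if bias.shape != (cfg.n_clusters,):
        raise ValueError("sex_bias length must equal n_clusters")
    logit_f = bias / 2.0
    w_female = np.exp(logit_f) / np.exp(logit_f).sum()
    w_male = np.exp(-logit_f) / np.exp(-logit_f).sum()
    clusters = np.empty(cfg.n_study, dtype=int)
    for i in range(cfg.n_study):
        w = w_female if sex[i] == "female" else w_male
        clusters[i] = rng.choice(cfg.n_clusters, p=w) + 1

    # per-cluster Dirichlet concentration: dominant taxon holds
    # dominant_share of the mass
    alphas = np.full(
        (cfg.n_clusters, cfg.n_taxa),
        cfg.concentration * (1.0 - cfg.dominant_share) / (cfg.n_taxa - 1),
    )
    for c in range(cfg.n_clusters):
        alphas[c, dominant_idx[c]] = cfg.concentration * cfg.dominant_share

    # sparsity layer: per-taxon prevalence, dominants always present
    lo, hi = cfg.prevalence_range
    prevalence = rng.uniform(lo, hi, size=cfg.n_taxa)
    prevalence[dominant_idx] = 1.0

    # sex-shifted taxa (never the dominants)
    sex_taxa: list[tuple[str, float]] = []
    if cfg.n_sex_taxa:
        candidates = [j for j in range(cfg.n_taxa) if j not in dominant_idx]
        chosen = rng.choice(candidates, size=cfg.n_sex_taxa, replace=False)
        signs = rng.choice([-1.0, 1.0], size=cfg.n_sex_taxa)
        sex_taxa = [
            (lineages[j], float(s * cfg.sex_effect_log10))
            for j, s in zip(chosen, signs)
        ]

    depths = np.maximum(
        rng.lognormal(np.log(cfg.mean_depth), cfg.depth_log_sd, cfg.n_study), 1000
    ).astype(np.int64)

    # hormone-like phenotypes and demographics
    pheno = {"age": np.round(rng.normal(29, 5, cfg.n_study), 1)}
    pheno["bmi"] = np.round(rng.normal(22.5, 3, cfg.n_study), 2)
    for name, (f_mean, m_mean, lsd) in cfg.hormones.items():
        mean = np.where(sex == "female", f_mean, m_mean)
        pheno[name] = rng.lognormal(np.log(mean), lsd)

    counts = np.zeros((cfg.n_study, cfg.n_taxa), dtype=np.int64)
    sex_idx = {lin: i for i, lin in enumerate(lineages)}
    for i in range(cfg.n_study):
        present = rng.random(cfg.n_taxa) < prevalence
        a = alphas[clusters[i] - 1] * present
        p = np.zeros(cfg.n_taxa)
        nz = a > 0
        p[nz] = rng.dirichlet(a[nz])
        # sex-taxon multiplicative shifts on the composition
        if sex_taxa:
            mult = np.ones(cfg.n_taxa)
            for lin, eff in sex_taxa:
                j = sex_idx[lin]
                mult[j] = 10.0 ** (eff if sex[i] == "female" else -eff)
            p = p * mult
            p = p / p.sum()
        for pname, j, eff in cfg.phenotype_links:
            z = (pheno[pname][i] - np.mean(pheno[pname])) / (np.std(pheno[pname]) + 1e-12)
            p[j] *= 10.0 ** (eff * z)
            p = p / p.sum()
        counts[i] = rng.multinomial(depths[i], p)

    sample_ids = [f"S{i:04d}" for i in range(cfg.n_study)]
    n_plates = int(np.ceil(cfg.n_study / cfg.plate_capacity))
    plate_ids = [f"P{i // cfg.plate_capacity + 1:02d}" for i in range(cfg.n_study)]

    table = TaxonProfileTable(
        sample_ids=sample_ids,
        taxa=taxa,
        relabund=counts / depths[:, None],
        read_counts=counts,
        total_reads=depths,
    )
    sheet_df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "role": "study",
            "plate_id": plate_ids,
            "pcr_concentration": np.nan,
            "sex": sex,
            "age": pheno["age"],
            "bmi": pheno["bmi"],
            "total_read_count": depths,
            **{k: v for k, v in pheno.items() if k not in ("age", "bmi")},
        }
    )
    truth = SimulationTruth(
        seed=seed,
        config=dataclasses.asdict(cfg),
        cluster_labels={s: int(c) for s, c in zip(sample_ids, clusters)},
        dominant_taxon={c + 1: lineages[dominant_idx[c]] for c in range(cfg.n_clusters)},
        sex_effect_taxa=sex_taxa,
        phenotype_links=[
            (pname, lineages[j], eff) for pname, j, eff in cfg.phenotype_links
        ],
    )
    return table, SampleSheet(sheet_df), truth


def spike_contaminants(
    table: TaxonProfileTable,
    sheet: SampleSheet,
    truth: SimulationTruth,
    spec: ContaminantSpec,
    seed: int,
) -> tuple[TaxonProfileTable, SampleSheet, SimulationTruth]:
    """Mix contaminant reads into study samples and emit mock controls.

    Per-sample contaminant load is inversely proportional to a log-normal
    PCR concentration; mock controls carry the 10 expected species
    (equimolar) plus the contaminants active on their plate.
    """
    rng = np.random.default_rng(seed)
    n_study = table.n_samples
    plates = sheet.column("plate_id", table.sample_ids).tolist()
    plate_list = sorted(set(plates))

    n_contam = spec.n_cohort + spec.n_plate_specific
    if n_contam == 0 and not spec.expected_species:
        return table, sheet, truth

    contam_lineages = [
        f"k__Bacteria|p__ContamPhylum|c__ContamClass|o__ContamOrder|"
        f"f__ContamFamily|g__Contamgenus|s__Contaminant_{j:02d}"
        for j in range(n_contam)
    ]
    scopes = ["cohort"] * spec.n_cohort
    if spec.n_plate_specific:
        assigned = [
            plate_list[j % len(plate_list)] for j in range(spec.n_plate_specific)
        ]
        scopes += [f"plate:{p}" for p in assigned]

    new_taxa = list(table.taxa)
    new_taxa += [taxon_record(lin) for lin in contam_lineages]
    new_taxa += [taxon_record(lin) for lin in spec.expected_species]
    n_old = table.n_taxa
    n_total = len(new_taxa)
    i_contam = np.arange(n_old, n_old + n_contam)
    i_mock = np.arange(n_old + n_contam, n_total)

    pcr = rng.lognormal(spec.pcr_log_mean, spec.pcr_log_sd, n_study)
    shares = spec.load_scale / pcr
    if np.any(shares >= 1.0):
        raise ValueError("contaminant share >= 1; re-parameterize load_scale")
    shares = np.minimum(shares, spec.max_share)

    # relative mix among contaminants (cohort-wide); plate-specific ones are
    # only active on their plate
    base_w = rng.dirichlet(np.full(n_contam, 5.0)) if n_contam else np.array([])

    depths = table.total_reads.astype(np.int64)
    counts = np.zeros((n_study, n_total), dtype=np.int64)
    contam_frac = np.zeros(n_study)
    old_rel = table.relabund
    for i in range(n_study):
        active = np.array(
            [s == "cohort" or s == f"plate:{plates[i]}" for s in scopes], dtype=bool
        )
        w = base_w * active
        wsum = w.sum()
        p = np.zeros(n_total)
        if wsum > 0 and n_contam:
            p[i_contam] = shares[i] * w / wsum
            p[:n_old] = (1.0 - shares[i]) * old_rel[i]
        else:
            p[:n_old] = old_rel[i]
        counts[i] = rng.multinomial(depths[i], p / p.sum())
        contam_frac[i] = counts[i, i_contam].sum() / depths[i]

    sample_ids = list(table.sample_ids)
    rows = [sheet.data.set_index("sample_id").loc[sample_ids].reset_index()]
    rows[0]["pcr_concentration"] = pcr

    # one extraction mock per plate
    mock_rows, mock_counts, mock_ids = [], [], []
    for p_id in plate_list:
        active = np.array(
            [s == "cohort" or s == f"plate:{p_id}" for s in scopes], dtype=bool
        )
        w = base_w * active
        comp = np.zeros(n_total)
        c_share = spec.mock_contaminant_share * active.sum()
        if active.sum():
            comp[i_contam] = spec.mock_contaminant_share * active
        comp[i_mock] = (1.0 - c_share) / len(i_mock)
        depth = int(spec.mock_depth)
        mock_counts.append(rng.multinomial(depth, comp / comp.sum()))
        mid = f"MOCK_{p_id}"
        mock_ids.append(mid)
        mock_rows.append(
            {
                "sample_id": mid,
                "role": "mock_extraction",
                "plate_id": p_id,
                "pcr_concentration": float(rng.lognormal(0.3, 0.2)),
                "sex": np.nan,
                "age": np.nan,
                "bmi": np.nan,
                "total_read_count": depth,
            }
        )

    all_ids = sample_ids + mock_ids
    all_counts = np.vstack([counts] + [np.asarray(mock_counts, dtype=np.int64)])
    all_depths = all_counts.sum(axis=1)
    new_table = TaxonProfileTable(
        sample_ids=all_ids,
        taxa=new_taxa,
        relabund=all_counts / all_depths[:, None],
        read_counts=all_counts,
        total_reads=all_depths,
    )
    mock_df = pd.DataFrame(mock_rows)
    new_sheet = SampleSheet(
        pd.concat([rows[0], mock_df], ignore_index=True)
    )
    truth.contaminant_taxa = dict(zip(contam_lineages, scopes))
    truth.contaminated_fraction = {
        s: float(f) for s, f in zip(sample_ids, contam_frac)
    }
    return new_table, new_sheet, truth


def generate_genotypes(
    n_samples: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> GenotypeTable:
    """I.i.d. biallelic dosages, Binomial(2, maf); HWE by construction."""
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie in (0, 0.5]")
    if not (0 <= missing_rate <= 0.1):
        raise ValueError("missing_rate must lie in [0, 0.1]")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, n_variants)
    dosages = rng.binomial(2, mafs[:, None], size=(n_variants, n_samples)).astype(float)
    if missing_rate > 0:
        miss = rng.random(dosages.shape) < missing_rate
        dosages[miss] = np.nan
    variants = pd.DataFrame(
        {
            "chrom": ["1"] * n_variants,
            "pos": np.arange(1, n_variants + 1) * 100,
            "id": [f"rs{v:06d}" for v in range(n_variants)],
            "ref": "A",
            "alt": "G",
        }
    )
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    return GenotypeTable(variants=variants, dosages=dosages, sample_ids=sample_ids)


@dataclass
class PlantedEffect:
    variant_id: str
    taxon_id: str
    mode: str  # "abundance" | "presence"
    beta: float
    gxe_env: str | None = None  # sheet column name, e.g. "sex"
    beta_gxe: float = 0.0
    presence_alpha: float = 0.0


def plant_associations(
    genotypes: GenotypeTable,
    table: TaxonProfileTable,
    truth: SimulationTruth,
    effects: list[PlantedEffect],
    seed: int,
    sheet: SampleSheet | None = None,
) -> tuple[TaxonProfileTable, SimulationTruth]:
    """Inject additive genetic effects on taxon abundance or presence.

    Abundance mode shifts log10 relative abundance by ``beta * dosage``
    (plus ``beta_gxe * dosage * env`` when an interaction is planted)
    before renormalization; presence mode redraws the detection indicator
    from logit(P) = alpha + beta * dosage. Read counts are redrawn from
    the adjusted composition so count/fraction consistency is preserved.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    vid_index = {v: i for i, v in enumerate(genotypes.variants["id"])}
    gsample = {s: i for i, s in enumerate(genotypes.sample_ids)}
    rel = out.relabund.copy()

    for eff in effects:
        j = out.taxon_index(eff.taxon_id)
        v = vid_index[eff.variant_id]
        dose_full = genotypes.dosages[v]
        env = None
        if eff.gxe_env is not None:
            if sheet is None:
                raise ValueError("planting a GxE effect requires the sample sheet")
            env_ser = sheet.column(eff.gxe_env, table.sample_ids)
            env = (
                (env_ser == "female").astype(float).to_numpy()
                if env_ser.dtype == object
                else env_ser.to_numpy(dtype=float)
            )
        for i, sid in enumerate(out.sample_ids):
            gi = gsample.get(sid)
            if gi is None or np.isnan(dose_full[gi]):
                continue
            d = dose_full[gi]
            if eff.mode == "abundance":
                shift = eff.beta * d
                if env is not None:
                    shift += eff.beta_gxe * d * env[i]
                rel[i, j] *= 10.0 ** shift
            elif eff.mode == "presence":
                logit = eff.presence_alpha + eff.beta * d
                if env is not None:
                    logit += eff.beta_gxe * d * env[i]
                p_present = 1.0 / (1.0 + np.exp(-logit))
                present = rng.random() < p_present
                if present and rel[i, j] == 0:
                    nz = rel[:, j][rel[:, j] > 0]
                    rel[i, j] = np.median(nz) if nz.size else 1e-4
                elif not present:
                    rel[i, j] = 0.0
            else:
                raise ValueError(f"unknown mode: {eff.mode}")
        truth.planted_effects.append(
            (eff.variant_id, eff.taxon_id, eff.mode, eff.beta, eff.beta_gxe)
        )

    rel = rel / rel.sum(axis=1, keepdims=True)
    out.relabund = rel
    if out.total_reads is not None:
        counts = np.vstack(
            [
                rng.multinomial(int(out.total_reads[i]), rel[i])
                for i in range(out.n_samples)
            ]
        )
        out.read_counts = counts
        out.relabund = counts / out.total_reads[:, None]
    return out, truth
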