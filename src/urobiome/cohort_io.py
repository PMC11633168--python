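"""Shared data model and readers/writers for external formats.

Three currencies flow through the pipeline: a samples × taxa relative
abundance table (MetaPhlAn-style TSV on disk), a per-sample metadata sheet
(TSV), and diploid genotypes (VCF). Taxon identity is the full rank-prefixed
lineage string; display names are the last rank token.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANK_PREFIXES = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}
_PREFIX_TO_RANK = {v: k for k, v in RANK_PREFIXES.items()}

SAMPLE_ROLES = ("study", "mock_extraction", "mock_library", "negative")

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TaxonRecord:
    """One taxon: identity is the full lineage string."""

    taxon_id: str
    rank: str
    lineage: str
    domain: str  # "bacteria" | "non-bacteria"

    @property
    def name(self) -> str:
        """Display name: last rank token, prefix stripped."""
        token = self.lineage.split("|")[-1]
        return token[3:] if len(token) > 3 and token[1:3] == "__" else token


def lineage_rank(lineage: str) -> str:
    """Rank of a rank-prefixed lineage = rank of its last token."""
    token = lineage.split("|")[-1]
    prefix = token[:3]
    return _PREFIX_TO_RANK.get(prefix, "species")


def lineage_domain(lineage: str) -> str:
    first = lineage.split("|")[0]
    if first.lower() in ("k__bacteria", "d__bacteria", "k__bacteria_unclassified"):
        return "bacteria"
    if not first.startswith(("k__", "d__")):
        # plain taxon names carry no domain information; assume bacterial
        return "bacteria"
    return "non-bacteria"


def taxon_record(lineage: str) -> TaxonRecord:
    return TaxonRecord(
        taxon_id=lineage,
        rank=lineage_rank(lineage),
        lineage=lineage,
        domain=lineage_domain(lineage),
    )


@dataclass
class TaxonProfileTable:
    """Samples × taxa relative abundances, optionally backed by read counts.

    ``relabund[i, j]`` is the relative abundance of taxon ``j`` in sample
    ``i``; rows sum to 1 when ``normalized`` is True. When ``read_counts``
    is present, ``relabund = read_counts / total_reads`` row-wise.
    """

    sample_ids: list[str]
    taxa: list[TaxonRecord]
    relabund: np.ndarray
    read_counts: np.ndarray | None = None
    total_reads: np.ndarray | None = None
    normalized: bool = True

    def __post_init__(self) -> None:
        self.relabund = np.asarray(self.relabund, dtype=float)
        if self.relabund.shape != (len(self.sample_ids), len(self.taxa)):
            raise ValueError(
                f"relabund shape {self.relabund.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxa)} taxa"
            )
        ids = [t.taxon_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate taxon_id")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_id")
        if np.any(self.relabund < 0):
            raise ValueError("negative relative abundance")
        if self.read_counts is not None:
            self.read_counts = np.asarray(self.read_counts)
            if self.total_reads is None:
                self.total_reads = self.read_counts.sum(axis=1)
        if self.total_reads is not None:
            self.total_reads = np.asarray(self.total_reads)

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def taxon_ids(self) -> list[str]:
        return [t.taxon_id for t in self.taxa]

    def taxon_index(self, taxon_id: str) -> int:
        try:
            return self.taxon_ids.index(taxon_id)
        except ValueError:
            raise KeyError(f"taxon not in table: {taxon_id}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample not in table: {sample_id}") from None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.relabund, index=self.sample_ids, columns=self.taxon_ids
        )

    def copy(self) -> "TaxonProfileTable":
        return TaxonProfileTable(
            sample_ids=list(self.sample_ids),
            taxa=list(self.taxa),
            relabund=self.relabund.copy(),
            read_counts=None if self.read_counts is None else self.read_counts.copy(),
            total_reads=None if self.total_reads is None else self.total_reads.copy(),
            normalized=self.normalized,
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "TaxonProfileTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return TaxonProfileTable(
            sample_ids=list(sample_ids),
            taxa=list(self.taxa),
            relabund=self.relabund[idx],
            read_counts=None if self.read_counts is None else self.read_counts[idx],
            total_reads=None if self.total_reads is None else self.total_reads[idx],
            normalized=self.normalized,
        )

    def select_taxa(self, taxon_ids: Sequence[str]) -> "TaxonProfileTable":
        idx = [self.taxon_index(t) for t in taxon_ids]
        return TaxonProfileTable(
            sample_ids=list(self.sample_ids),
            taxa=[self.taxa[j] for j in idx],
            relabund=self.relabund[:, idx],
            read_counts=(
                None if self.read_counts is None else self.read_counts[:, idx]
            ),
            total_reads=None if self.total_reads is None else self.total_reads.copy(),
            normalized=False,
        )

    def renormalized(self) -> "TaxonProfileTable":
        """Rescale each row to sum to 1; all-zero rows stay zero."""
        sums = self.relabund.sum(axis=1, keepdims=True)
        safe = np.where(sums > 0, sums, 1.0)
        out = self.copy()
        out.relabund = self.relabund / safe
        out.normalized = True
        return out

    def validate(self) -> None:
        """Assert the row-sum and count-consistency invariants."""
        if self.normalized:
            sums = self.relabund.sum(axis=1)
            nonempty = sums > 0
            if not np.allclose(sums[nonempty], 1.0, atol=_SUM_TOL):
                raise AssertionError("normalized rows must sum to 1")
        if self.read_counts is not None and self.total_reads is not None:
            tot = np.where(self.total_reads > 0, self.total_reads, 1)
            frac = self.read_counts / tot[:, None]
            if self.normalized and not np.allclose(
                frac, self.relabund, atol=1e-9
            ):
                raise AssertionError("relabund inconsistent with read_counts")


@dataclass
class SampleSheet:
    """Per-sample roles, plate layout and phenotypes, backed by a DataFrame.

    Required columns: sample_id, role. Study samples additionally carry
    plate_id; pcr_concentration, sex, age, bmi, total_read_count and any
    further phenotype columns are optional.
    """

    data: pd.DataFrame

    CORE_COLUMNS = (
        "sample_id",
        "role",
        "plate_id",
        "pcr_concentration",
        "sex",
        "age",
        "bmi",
        "total_read_count",
    )

    def __post_init__(self) -> None:
        df = self.data
        if "sample_id" not in df.columns or "role" not in df.columns:
            raise ValueError("sample sheet needs sample_id and role columns")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id: {dup}")
        bad_roles = set(df["role"]) - set(SAMPLE_ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")
        study = df[df["role"] == "study"]
        if "plate_id" in df.columns:
            if study["plate_id"].isna().any():
                missing = study.loc[study["plate_id"].isna(), "sample_id"].iloc[0]
                raise ValueError(f"study sample missing plate_id: {missing}")
        elif len(study):
            raise ValueError("study samples present but no plate_id column")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def ids_with_role(self, *roles: str) -> list[str]:
        return self.data.loc[self.data["role"].isin(roles), "sample_id"].tolist()

    @property
    def study_ids(self) -> list[str]:
        return self.ids_with_role("study")

    @property
    def mock_ids(self) -> list[str]:
        return self.ids_with_role("mock_extraction", "mock_library")

    def column(self, name: str, sample_ids: Sequence[str] | None = None) -> pd.Series:
        df = self.data.set_index("sample_id")
        if sample_ids is not None:
            df = df.loc[list(sample_ids)]
        return df[name]

    @property
    def phenotype_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.CORE_COLUMNS]

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        df = self.data.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleSheet(df)


@dataclass
class GenotypeTable:
    """Biallelic variants × samples, additive dosage coding.

    ``dosages[v, i]`` counts alt alleles (0/1/2) of variant ``v`` in sample
    ``i``; missing genotypes are NaN.
    """

    variants: pd.DataFrame  # columns: chrom, pos, id, ref, alt
    dosages: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.variants), len(self.sample_ids)):
            raise ValueError("dosage shape mismatch")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0/1/2 or missing")
        if (self.variants["pos"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def select_variants(self, mask: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            variants=self.variants.loc[np.asarray(mask)].reset_index(drop=True),
            dosages=self.dosages[np.asarray(mask)],
            sample_ids=list(self.sample_ids),
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "GenotypeTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return GenotypeTable(
            variants=self.variants.copy(),
            dosages=self.dosages[:, idx],
            sample_ids=list(sample_ids),
        )

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant over non-missing dosages."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=1) / 2.0
        return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _output_header(seed: int | None = None, config_hash: str | None = None) -> str:
    from . import __version__

    parts = [f"# urobiome v{__version__}"]
    if config_hash is not None:
        parts.append(f"config_hash={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts)


def read_profile_table(
    path: str | Path, expected_rank: str = "species"
) -> TaxonProfileTable:
    """Read a MetaPhlAn-style TSV (lineages in column 1, samples across).

    Rows are restricted to ``expected_rank``; percent tables (median column
    sum > 2) are rescaled to fractions and every retained row renormalized
    to sum 1. Read counts are attached when a paired ``.counts.tsv`` exists
    next to ``path``.
    """
    if expected_rank not in RANK_PREFIXES:
        raise ValueError(f"unknown rank: {expected_rank}")
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValueError(f"duplicated taxon_id: {df.index[df.index.duplicated()][0]}")
    mat = df.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("negative abundance in profile table")

    keep = [i for i, lin in enumerate(df.index) if lineage_rank(lin) == expected_rank]
    df = df.iloc[keep]
    mat = mat[keep]

    col_sums = mat.sum(axis=0)
    # percent vs fraction dialect: median column sum > 2 means percent
    if len(col_sums) and np.median(col_sums) > 2.0:
        mat = mat / 100.0
        col_sums = col_sums / 100.0
    empty = col_sums <= 0
    for sid in np.asarray(df.columns)[empty]:
        logger.warning("sample %s has zero total abundance; flagged empty", sid)
    safe = np.where(col_sums > 0, col_sums, 1.0)
    mat = mat / safe  # renormalize within the retained rank

    taxa = [taxon_record(lin) for lin in df.index]
    table = TaxonProfileTable(
        sample_ids=[str(c) for c in df.columns],
        taxa=taxa,
        relabund=mat.T,
    )

    counts_path = Path(str(path) + ".counts.tsv")
    if counts_path.exists():
        cdf = pd.read_csv(counts_path, sep="\t", comment="#", index_col=0)
        cdf = cdf.loc[[t.taxon_id for t in taxa], table.sample_ids]
        table.read_counts = cdf.to_numpy(dtype=np.int64).T
        table.total_reads = table.read_counts.sum(axis=1)
    return table


def write_profile_table(
    table: TaxonProfileTable,
    path: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    """Write fractional abundances as a lineage-by-sample TSV."""
    path = Path(path)
    df = pd.DataFrame(
        table.relabund.T, index=table.taxon_ids, columns=table.sample_ids
    )
    df.index.name = "clade_name"
    with open(path, "w") as fh:
        fh.write(_output_header(seed, config_hash) + "\n")
        df.to_csv(fh, sep="\t", float_format="%.12g")
    if table.read_counts is not None:
        cdf = pd.DataFrame(
            table.read_counts.T, index=table.taxon_ids, columns=table.sample_ids
        )
        cdf.index.name = "clade_name"
        with open(Path(str(path) + ".counts.tsv"), "w") as fh:
            fh.write(_output_header(seed, config_hash) + "\n")
            cdf.to_csv(fh, sep="\t")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["sample_id"] = df["sample_id"].astype(str)
    if "pcr_concentration" in df.columns:
        n_missing = df["pcr_concentration"].isna().sum()
        if n_missing:
            logger.warning("%d samples missing pcr_concentration", n_missing)
    return SampleSheet(df)


def write_sample_sheet(
    sheet: SampleSheet, path: str | Path, seed: int | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_output_header(seed) + "\n")
        sheet.data.to_csv(fh, sep="\t", index=False)


def read_genotypes(path: str | Path, strict: bool = False) -> GenotypeTable:
    """Read biallelic GT records from a VCF into additive dosages.

    Multiallelic records are skipped (counted in a warning) unless
    ``strict`` is set, in which case they raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, dosage_rows = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            if strict:
                raise ValueError(
                    f"multiallelic record at {rec.CHROM}:{rec.POS}"
                )
            n_multi += 1
            continue
        # gt_types: 0=hom ref, 1=het, 2=missing, 3=hom alt
        gt = rec.gt_types
        dose = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
        dosage_rows.append(dose)
    vcf.close()
    if n_multi:
        logger.warning("skipped %d multiallelic records", n_multi)
    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "id", "ref", "alt"]
    )
    dosages = (
        np.asarray(dosage_rows, dtype=float)
        if dosage_rows
        else np.empty((0, len(sample_ids)))
    )
    return GenotypeTable(variants=variants, dosages=dosages, sample_ids=sample_ids)


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    """Write dosages back to an uncompressed VCF (GT field, unphased)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=urobiome\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(table.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_ids)
            + "\n"
        )
        for v, row in enumerate(table.variants.itertuples(index=False)):
            calls = [
                gt_map.get(d, "./.") if not np.isnan(d) else "./."
                for d in table.dosages[v]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )
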