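import numpy as np
import pandas as pd
import pytest
from scipy import stats

from urobiome.cohort_io import SampleSheet
from urobiome.decontamination import (
    DecontamParams,
    apply_decontamination,
    decontaminate,
    feature_filter,
    flag_cohort_contaminants,
    flag_plate_contaminants,
    freq_contaminant_pvalue,
)

from conftest import make_table


class TestFreqContaminantPvalue:
    def test_perfect_inverse_relation_is_contaminant_like(self, rng):
        conc = rng.lognormal(0.5, 0.6, 10)
        freqs = 0.01 / conc
        assert freq_contaminant_pvalue(freqs, conc) < 0.01

    def test_constant_frequency_is_non_contaminant(self, rng):
        conc = rng.lognormal(0.5, 0.6, 10)
        freqs = np.full(10, 3e-4)
        assert freq_contaminant_pvalue(freqs, conc) > 0.5

    def test_invariant_to_concentration_rescaling(self, rng):
        conc = rng.lognormal(0.5, 0.6, 20)
        freqs = 10 ** (-np.log10(conc) - 3 + rng.normal(0, 0.3, 20))
        p1 = freq_contaminant_pvalue(freqs, conc)
        p2 = freq_contaminant_pvalue(freqs, conc * 7.3)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_too_few_samples_is_undefined(self):
        assert freq_contaminant_pvalue([0.1, 0.2, 0, 0], [1, 2, 3, 4]) is None

    def test_zero_frequencies_excluded_from_fit(self, rng):
        conc = rng.lognormal(0.5, 0.6, 20)
        freqs = 0.01 / conc
        freqs[:5] = 0.0  # excluded; still >= 5 usable
        assert freq_contaminant_pvalue(freqs, conc) < 0.01

    def test_calibration_slope_neg_below_slope_zero(self, rng):
        p_neg, p_zero = [], []
        for _ in range(200):
            logc = rng.normal(0.5, 0.5, 50)
            conc = 10**logc
            p_neg.append(
                freq_contaminant_pvalue(
                    10 ** (-logc - 3 + rng.normal(0, 0.3, 50)), conc
                )
            )
            p_zero.append(
                freq_contaminant_pvalue(10 ** (-3 + rng.normal(0, 0.3, 50)), conc)
            )
        assert np.median(p_neg) < np.median(p_zero)


def small_sheet(n_study=8, n_mock=2, pcr=True):
    ids = [f"S{i}" for i in range(n_study)] + [f"M{i}" for i in range(n_mock)]
    df = pd.DataFrame(
        {
            "sample_id": ids,
            "role": ["study"] * n_study + ["mock_extraction"] * n_mock,
            "plate_id": ["P1"] * (n_study // 2) + ["P2"] * (n_study - n_study // 2)
            + ["P1", "P2"][:n_mock],
            "pcr_concentration": (
                list(np.linspace(1, 8, n_study)) + [1.5] * n_mock if pcr
                else [np.nan] * (n_study + n_mock)
            ),
            "total_read_count": [10_000] * (n_study + n_mock),
        }
    )
    return SampleSheet(df)


class TestFlagCohortContaminants:
    def test_low_occurrence_flagged(self):
        rel = np.full((8, 2), 0.5)
        rel[3:, 1] = 0.0  # taxon 1 occurs in 3 study samples
        rel = rel / rel.sum(axis=1, keepdims=True)
        mock = np.tile([0.5, 0.5], (2, 1))
        table = make_table(
            np.vstack([rel, mock]),
            sample_ids=[f"S{i}" for i in range(8)] + ["M0", "M1"],
        )
        flags = flag_cohort_contaminants(table, small_sheet())
        assert "OCCURRENCE" in flags[1].reasons
        assert "OCCURRENCE" not in flags[0].reasons

    def test_low_total_reads_flagged(self):
        counts = np.zeros((8, 2), dtype=np.int64)
        counts[:, 0] = 10_000
        counts[:, 1] = [999, 0, 0, 0, 0, 0, 0, 0]  # cohort sum 999
        rel = counts / counts.sum(axis=1, keepdims=True)
        mock_counts = np.tile([5000, 0], (2, 1))
        table = make_table(
            np.vstack([rel, mock_counts / 5000]),
            sample_ids=[f"S{i}" for i in range(8)] + ["M0", "M1"],
            read_counts=np.vstack([counts, mock_counts]),
        )
        flags = flag_cohort_contaminants(table, small_sheet())
        assert "READS" in flags[1].reasons
        assert "READS" not in flags[0].reasons

    def test_mock_presence_flags_non_expected_only(self):
        expected = ("k__Bacteria|p__P|c__C|o__O|f__F|g__G|s__Expected_0",)
        lineages = [
            "k__Bacteria|p__P|c__C|o__O|f__F|g__G|s__Species_0",
            "k__Bacteria|p__P|c__C|o__O|f__F|g__G|s__Species_1",
            expected[0],
        ]
        study = np.tile([0.5, 0.5, 0.0], (8, 1))
        mock = np.tile([2e-4, 5e-5, 1 - 2.5e-4], (2, 1))
        table = make_table(
            np.vstack([study, mock]),
            lineages=lineages,
            sample_ids=[f"S{i}" for i in range(8)] + ["M0", "M1"],
        )
        params = DecontamParams(expected_species=expected)
        flags = flag_cohort_contaminants(table, small_sheet(), params)
        assert "MOCK_COHORT" in flags[0].reasons  # 2e-4 > 1e-4
        assert "MOCK_COHORT" not in flags[1].reasons  # below threshold
        assert "MOCK_COHORT" not in flags[2].reasons  # expected species

    def test_no_concentrations_skips_criteria_a_b(self):
        rel = np.tile([0.6, 0.4], (10, 1))
        table = make_table(
            rel, sample_ids=[f"S{i}" for i in range(8)] + ["M0", "M1"]
        )
        flags = flag_cohort_contaminants(table, small_sheet(pcr=False))
        for f in flags:
            assert f.spearman_p is None
            assert f.p_freq is None

    def test_or_semantics_monotone(self, contaminated_cohort):
        table, sheet, _ = contaminated_cohort
        full = flag_cohort_contaminants(table, sheet, DecontamParams())
        reduced = flag_cohort_contaminants(
            table, sheet, DecontamParams(min_occurrence=0, min_reads=0)
        )
        flagged_full = {f.taxon_id for f in full if f.flagged}
        flagged_reduced = {f.taxon_id for f in reduced if f.flagged}
        assert flagged_reduced <= flagged_full


class TestFlagPlateContaminants:
    EXPECTED = ("k__Bacteria|p__P|c__C|o__O|f__F|g__G|s__Expected_0",)

    def make_plate_table(self, p1_level):
        lineages = [
            "k__Bacteria|p__P|c__C|o__O|f__F|g__G|s__Species_0",
            "k__Bacteria|p__P|c__C|o__O|f__F|g__G|s__Species_1",
            self.EXPECTED[0],
        ]
        study = np.tile([0.7, 0.3, 0.0], (8, 1))
        m1 = [0.0, p1_level, 1 - p1_level]  # plate P1 mock
        m2 = [0.0, 0.0, 1.0]  # plate P2 mock
        return make_table(
            np.vstack([study, m1, m2]),
            lineages=lineages,
            sample_ids=[f"S{i}" for i in range(8)] + ["M0", "M1"],
        )

    def test_plate_scoped_flag(self):
        table = self.make_plate_table(2e-4)
        params = DecontamParams(expected_species=self.EXPECTED)
        flags = flag_plate_contaminants(table, small_sheet(), params)
        scopes = {(f.taxon_id, f.scope) for f in flags}
        assert scopes == {(table.taxon_ids[1], "plate:P1")}

    def test_below_threshold_not_flagged(self):
        table = self.make_plate_table(5e-5)
        flags = flag_plate_contaminants(
            table, small_sheet(), DecontamParams(expected_species=self.EXPECTED)
        )
        assert flags == []

    def test_step1_survivors_only(self):
        table = self.make_plate_table(2e-4)
        from urobiome.decontamination import ContaminantFlag

        step1 = [ContaminantFlag(table.taxon_ids[1], True, ["READS"])]
        flags = flag_plate_contaminants(
            table, small_sheet(), DecontamParams(expected_species=self.EXPECTED),
            cohort_flags=step1,
        )
        assert flags == []


class TestApplyDecontamination:
    def test_fraction_arithmetic(self):
        from urobiome.decontamination import ContaminantFlag

        rel = np.tile([0.9, 0.1], (4, 1))
        table = make_table(rel, sample_ids=[f"S{i}" for i in range(4)])
        flags = [ContaminantFlag(table.taxon_ids[1], True, ["READS"])]
        cleaned, report = apply_decontamination(table, flags)
        fracs = list(report.per_sample_contaminated_fraction.values())
        assert fracs == pytest.approx([0.1] * 4)
        assert np.allclose(cleaned.relabund.sum(axis=1), 1.0)
        assert cleaned.n_taxa == 1

    def test_no_flags_is_identity(self):
        rel = np.tile([0.25, 0.75], (3, 1))
        table = make_table(rel)
        cleaned, report = apply_decontamination(table, [])
        assert np.array_equal(cleaned.relabund, rel)
        assert all(
            v == 0.0 for v in report.per_sample_contaminated_fraction.values()
        )

    def test_non_bacterial_removed(self):
        lineages = [
            "k__Bacteria|p__P|c__C|o__O|f__F|g__G|s__Species_0",
            "k__Viruses|p__P|c__C|o__O|f__F|g__G|s__Virus_0",
        ]
        rel = np.tile([0.8, 0.2], (3, 1))
        table = make_table(rel, lineages=lineages)
        cleaned, report = apply_decontamination(table, [])
        assert cleaned.n_taxa == 1
        assert list(report.per_sample_contaminated_fraction.values()) == pytest.approx(
            [0.2] * 3
        )

    def test_sample_losing_everything_marked_empty(self):
        from urobiome.decontamination import ContaminantFlag

        rel = np.array([[1.0, 0.0], [0.5, 0.5]])
        table = make_table(rel)
        flags = [ContaminantFlag(table.taxon_ids[0], True, ["READS"])]
        cleaned, report = apply_decontamination(table, flags)
        assert report.empty_samples == ["S0"]
        assert cleaned.sample_ids == ["S1"]

    def test_idempotent(self, contaminated_cohort):
        table, sheet, _ = contaminated_cohort
        params = DecontamParams(spearman_direction="negative")
        cohort = flag_cohort_contaminants(table, sheet, params)
        plate = flag_plate_contaminants(table, sheet, params, cohort_flags=cohort)
        cleaned, _ = apply_decontamination(table, cohort + plate, sheet=sheet)
        again, report2 = apply_decontamination(cleaned, cohort + plate, sheet=sheet)
        assert np.abs(again.relabund - cleaned.relabund).max() < 1e-12
        assert all(
            v == 0.0 for v in report2.per_sample_contaminated_fraction.values()
        )

    def test_fraction_invariant_to_taxon_order(self, contaminated_cohort, rng):
        table, sheet, _ = contaminated_cohort
        params = DecontamParams(spearman_direction="negative")
        flags = flag_cohort_contaminants(table, sheet, params)
        _, rep1 = apply_decontamination(table, flags, sheet=sheet)
        perm = rng.permutation(table.n_taxa)
        shuffled = table.select_taxa([table.taxon_ids[j] for j in perm])
        shuffled.normalized = True
        shuffled.read_counts = (
            None if table.read_counts is None else table.read_counts[:, perm]
        )
        shuffled.total_reads = table.total_reads
        _, rep2 = apply_decontamination(shuffled, flags, sheet=sheet)
        assert rep1.per_sample_contaminated_fraction == pytest.approx(
            rep2.per_sample_contaminated_fraction
        )

    def test_end_to_end_recovers_truth(self, contaminated_cohort):
        table, sheet, truth = contaminated_cohort
        cleaned, flags, report = decontaminate(
            table, sheet, DecontamParams(spearman_direction="negative")
        )
        flagged = {f.taxon_id for f in flags if f.flagged}
        assert set(truth.contaminant_taxa) <= flagged
        mean_truth = np.mean(list(truth.contaminated_fraction.values()))
        assert abs(report.summary["mean"] - mean_truth) < 0.02


class TestFeatureFilter:
    def test_prevalence_rule(self):
        n = 100
        rel = np.zeros((n, 3))
        rel[:, 0] = 0.5
        rel[:9, 1] = 0.2  # 9% prevalence
        rel[:11, 2] = 0.2  # 11% prevalence, mean 0.022
        rel = rel / rel.sum(axis=1, keepdims=True)
        table = make_table(rel)
        table.normalized = True
        out = feature_filter(table)
        names = out.taxon_ids
        assert table.taxon_ids[1] not in names
        assert table.taxon_ids[2] in names

    def test_mean_abundance_rule(self):
        n = 100
        rel = np.zeros((n, 2))
        rel[:, 0] = 1.0
        rel[:50, 1] = 1e-4  # mean 5e-5 at 50% prevalence
        table = make_table(rel / rel.sum(axis=1, keepdims=True))
        table.normalized = True
        out = feature_filter(table)
        assert out.n_taxa == 1

    def test_zero_thresholds_identity(self, contaminated_cohort):
        table, _, _ = contaminated_cohort
        out = feature_filter(table, min_prevalence=0, min_mean_relabund=0)
        assert out.taxon_ids == table.taxon_ids
        assert np.array_equal(out.relabund, table.relabund)

    def test_empty_result_errors(self):
        rel = np.zeros((10, 2))
        rel[0, 0] = 1.0
        rel[1, 1] = 1.0
        table = make_table(rel)
        table.normalized = False
        with pytest.raises(ValueError, match="removed all taxa"):
            feature_filter(table, min_prevalence=0.5)

    def test_no_renormalization(self):
        n = 50
        rel = np.column_stack(
            [np.full(n, 0.89), np.full(n, 0.1), np.full(n, 0.01)]
        )
        table = make_table(rel)
        out = feature_filter(table, min_prevalence=0.1, min_mean_relabund=0.05)
        assert out.n_taxa == 2
        assert out.relabund.sum(axis=1) == pytest.approx([0.99] * n)
        assert not out.normalized
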