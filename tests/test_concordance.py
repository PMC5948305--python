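"""Concordance statistics: fold differences and culture comparison."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from quant16s.concordance import (
    ANAEROBIC_TAXON,
    ConfusionCounts,
    anaerobe_share,
    detection_table,
    fold_difference,
    genus_concordance,
    is_aerobic,
    sample_level_detection,
    saureus_genomes_to_16s,
    summarize_folds,
)
from quant16s.errors import PipelineError
from quant16s.io import CultureObservation
from quant16s.pipeline import SampleResult


class TestFoldDifference:
    def test_ratio_definition(self):
        assert fold_difference(13_000, 10_000) == pytest.approx(1.3)

    def test_identity(self):
        assert fold_difference(42.0, 42.0) == pytest.approx(1.0)

    @given(
        a=st.floats(min_value=1e-6, max_value=1e9),
        b=st.floats(min_value=1e-6, max_value=1e9),
    )
    def test_symmetric_and_at_least_one(self, a, b):
        f = fold_difference(a, b)
        assert f == fold_difference(b, a)
        assert f >= 1.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(PipelineError):
            fold_difference(0.0, 1.0)


class TestGenomeConversion:
    @pytest.mark.parametrize("genomes,copies", [(1000, 6000), (0, 0), (10_000, 60_000)])
    def test_six_16s_operons_per_genome(self, genomes, copies):
        assert saureus_genomes_to_16s(genomes) == pytest.approx(copies)


class TestSummarizeFolds:
    def test_median_with_mad(self):
        center, spread = summarize_folds([1.1, 1.3, 1.5], mode="median")
        assert center == pytest.approx(1.3)
        assert spread == pytest.approx(0.2)

    def test_single_element_has_zero_spread(self):
        assert summarize_folds([1.7]) == (pytest.approx(1.7), pytest.approx(0.0))

    def test_mean_with_sample_sd(self):
        center, spread = summarize_folds([1.0, 2.0], mode="mean")
        assert center == pytest.approx(1.5)
        assert spread == pytest.approx(math.sqrt(0.5))

    def test_empty_list_rejected(self):
        with pytest.raises(PipelineError):
            summarize_folds([])


class TestGenusConcordance:
    def test_detected_and_missed_genera_counted(self):
        culture, results = detection_table(
            {"Staphylococcus": (2, 1), "Proteus": (1, 1)}
        )
        out = genus_concordance(culture, results)
        staph = out.per_taxon["Staphylococcus"]
        assert (staph.tp, staph.fn) == (1, 1)
        assert out.per_taxon["Proteus"].tp == 1
        assert out.pooled.sensitivity == pytest.approx(2 / 3)

    def test_commensal_flora_counts_as_aerobic_detection_signal(self):
        culture, results = detection_table({}, commensal=(3, 2))
        out = genus_concordance(culture, results)
        commensal = out.per_taxon["commensal_flora"]
        assert (commensal.tp, commensal.fn) == (2, 1)

    def test_anaerobic_culture_matched_by_any_obligate_anaerobe(self):
        culture, results = detection_table({}, anaerobic=(3, 3))
        out = genus_concordance(culture, results)
        assert out.per_taxon[ANAEROBIC_TAXON].sensitivity == pytest.approx(1.0)

    def test_family_fallback_label_scores_and_classifies_as_aerobic(self):
        culture, results = detection_table({"Enterobacteriaceae*": (2, 2)})
        out = genus_concordance(culture, results)
        assert out.per_taxon["Enterobacteriaceae*"].tp == 2
        assert is_aerobic("Enterobacteriaceae*")
        assert not is_aerobic("Prevotella")

    def test_unmatched_sample_id_is_hard_error(self):
        culture = [CultureObservation("S1", "genus:Proteus")]
        results = [SampleResult("S2", {}, {}, {}, [])]
        with pytest.raises(PipelineError, match="S1"):
            genus_concordance(culture, results)

    def test_per_taxon_counts_sum_to_pooled_over_random_tables(self):
        rng = np.random.default_rng(17)
        genera = ["Staphylococcus", "Streptococcus", "Proteus", "Pseudomonas"]
        for _ in range(20):
            table = {}
            for g in genera:
                cultured = int(rng.integers(0, 5))
                if cultured:
                    table[g] = (cultured, int(rng.integers(0, cultured + 1)))
            if not table:
                continue
            n_an = int(rng.integers(0, 4))
            culture, results = detection_table(
                table, anaerobic=(n_an, int(rng.integers(0, n_an + 1)))
            )
            out = genus_concordance(culture, results)
            summed = ConfusionCounts()
            for counts in out.per_taxon.values():
                summed = summed + counts
            assert summed == out.pooled


class TestSampleLevelDetection:
    def test_all_positive_samples_detected_is_full_sensitivity(self):
        culture, results = detection_table({"Staphylococcus": (5, 5)})
        counts = sample_level_detection(culture, results)
        assert counts.sensitivity == pytest.approx(1.0)

    def test_negative_sample_with_empty_result_is_true_negative(self):
        culture, results = detection_table({}, negative=(1, 0))
        counts = sample_level_detection(culture, results)
        assert (counts.tn, counts.fp) == (1, 0)

    def test_specificity_arithmetic(self):
        culture, results = detection_table({"Proteus": (3, 3)}, negative=(10, 2))
        counts = sample_level_detection(culture, results)
        assert counts.specificity == pytest.approx(0.8)

    def test_empty_inputs_rejected(self):
        with pytest.raises(PipelineError):
            sample_level_detection([], [])


class TestAnaerobeShare:
    def test_fraction_of_detected_otus(self):
        labels = ["Prevotella"] * 3 + ["Staphylococcus"] * 1
        assert anaerobe_share(labels) == pytest.approx(0.75)

    def test_empty_detection_list_rejected(self):
        with pytest.raises(PipelineError):
            anaerobe_share([])


class TestConfusionCounts:
    def test_rates_undefined_without_denominator(self):
        counts = ConfusionCounts(tp=3, fn=1)
        assert counts.specificity is None
        assert counts.sensitivity == pytest.approx(0.75)

    def test_negative_counts_rejected(self):
        with pytest.raises(PipelineError):
            ConfusionCounts(tp=-1)
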