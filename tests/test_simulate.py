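"""Synthetic experiment generator: sampling model, determinism, file tree."""

from __future__ import annotations

import json
import math

import numpy as np
import pytest

from quant16s.errors import PipelineError
from quant16s.simulate import SimConfig, simulate_replicate, simulate_study


class TestSimulateReplicate:
    def test_read_total_equals_configured_depth(self):
        config = SimConfig(read_depth=12_345, seed=1)
        profile, _ = simulate_replicate(config, "sample", seed=1)
        assert profile.total_reads == 12_345

    def test_deterministic_per_seed(self):
        config = SimConfig(seed=5)
        a, _ = simulate_replicate(config, "sample", seed=99)
        b, _ = simulate_replicate(config, "sample", seed=99)
        assert a == b

    def test_nec_without_contamination_contains_only_ic(self):
        config = SimConfig(contamination=(), read_depth=5_000)
        profile, truth = simulate_replicate(config, "nec", seed=2)
        assert profile.counts == {"Otu_Synechococcus": 5_000}
        assert truth.true_copies == {}
        assert truth.ic_copies == pytest.approx(100.0)

    def test_pc_ic_reads_match_multinomial_expectation(self):
        # PC composition: 4 x 10,000 copies + 1000 IC copies at depth 44,000
        # gives expected IC reads 44,000 * 1000/41,000 = 1073.17...; the
        # empirical mean over 500 seeds must sit within 3 standard errors.
        config = SimConfig(contamination=(), read_depth=44_000)
        n_seeds = 500
        ic_reads = []
        for s in range(n_seeds):
            profile, _ = simulate_replicate(config, "pc", seed=s)
            ic_reads.append(profile.counts.get("Otu_Synechococcus", 0))
        p = 1000.0 / 41_000.0
        expected = 44_000 * p
        se_mean = math.sqrt(44_000 * p * (1 - p) / n_seeds)
        assert abs(np.mean(ic_reads) - expected) < 3 * se_mean

    def test_doubling_depth_doubles_expected_reads(self):
        base = SimConfig(contamination=(), read_depth=10_000)
        double = SimConfig(contamination=(), read_depth=20_000)
        n_seeds = 200
        mean_at = {}
        for config in (base, double):
            reads = [
                simulate_replicate(config, "sample", seed=s)[0].counts[
                    "Otu_Staphylococcus"
                ]
                for s in range(n_seeds)
            ]
            mean_at[config.read_depth] = float(np.mean(reads))
        ratio = mean_at[20_000] / mean_at[10_000]
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_expected_fractions_sum_to_one(self):
        for kind in ("sample", "nec", "pc"):
            _, truth = simulate_replicate(SimConfig(), kind, seed=0)
            assert sum(truth.expected_fractions.values()) == pytest.approx(1.0)

    def test_reads_only_for_taxa_in_truth_support(self):
        config = SimConfig(seed=3)
        profile, truth = simulate_replicate(config, "sample", seed=3)
        support = (
            set(truth.true_copies) | set(truth.contamination) | {"Synechococcus"}
        )
        for obs in profile.observations:
            assert obs.lineage.genus in support

    def test_all_zero_composition_rejected(self):
        config = SimConfig(taxa=(), contamination=(), ic_initial_copies=1.0)
        with pytest.raises(PipelineError):
            # NEC kind keeps the IC; zero out everything via efficiency
            simulate_replicate(
                SimConfig(taxa=(), contamination=(),
                          efficiency={"Synechococcus": 0.0}),
                "nec",
                seed=0,
            )

    def test_unknown_kind_rejected(self):
        with pytest.raises(PipelineError, match="kind"):
            simulate_replicate(SimConfig(), "blank", seed=0)


class TestSimulateStudy:
    def _configs(self, n, seed=0):
        return {
            f"S{i + 1:02d}": SimConfig(read_depth=2_000, seed=seed + i)
            for i in range(n)
        }

    def test_file_tree_for_two_samples(self, tmp_path):
        out = tmp_path / "study"
        simulate_study(self._configs(2), out)
        tsvs = sorted(p.name for p in out.glob("*.tsv"))
        assert len([n for n in tsvs if n.startswith("S")]) == 6
        assert len([n for n in tsvs if n.startswith("NEC")]) == 3
        assert len([n for n in tsvs if n.startswith("PC")]) == 3
        assert (out / "truth.json").exists()

    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_study(self._configs(1, seed=9), a)
        simulate_study(self._configs(1, seed=9), b)
        for pa in sorted(a.iterdir()):
            assert pa.read_bytes() == (b / pa.name).read_bytes()

    def test_existing_directory_requires_force(self, tmp_path):
        out = tmp_path / "study"
        simulate_study(self._configs(1), out)
        with pytest.raises(PipelineError, match="force"):
            simulate_study(self._configs(1), out)
        simulate_study(self._configs(1), out, force=True)  # succeeds

    def test_truth_and_tsvs_are_mutually_consistent(self, tmp_path):
        from quant16s.io import read_generic_tsv

        out = tmp_path / "study"
        simulate_study(self._configs(2), out)
        truth = json.loads((out / "truth.json").read_text())
        for sid, doc in truth["samples"].items():
            support = (
                set(doc["true_copies"]) | set(doc["contamination"]) | {"Synechococcus"}
            )
            for rep in (1, 2, 3):
                profile = read_generic_tsv(out / f"{sid}_{rep}.tsv")
                for obs in profile.observations:
                    assert obs.lineage.genus in support
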