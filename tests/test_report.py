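"""Report bundle assembly, sunburst hierarchy, HTML rendering."""

from __future__ import annotations

import numpy as np
import pytest

from quant16s.io import TaxonomyLineage
from quant16s.pipeline import CalibrationConfig, QcRecord, SampleResult
from quant16s.report import (
    build_report_bundle,
    build_sunburst,
    parse_report,
    render_report,
)
from quant16s.simulate import lineage_for


def make_result(copies: dict[str, float], genera: dict[str, str]) -> SampleResult:
    lineages = {otu: lineage_for(genus) for otu, genus in genera.items()}
    provenance = {
        otu: {"rep1": c, "rep2": c, "rep3": c} for otu, c in copies.items()
    }
    qc = [QcRecord("lod_filter", len(copies) + 1, len(copies), "threshold 25")]
    return SampleResult(
        "S1", copies, lineages, provenance, qc, config=CalibrationConfig()
    )


class TestSunburst:
    def test_sibling_genera_aggregate_at_family(self):
        # Staphylococcus sits alone; two Enterobacteriaceae-like genera
        # share every upper rank, so the shared family node sums them.
        lin_a = TaxonomyLineage(
            ranks=("Bacteria", "Proteobacteria", "Gamma", "Enterobacteriales",
                   "Enterobacteriaceae", "Escherichia")
        )
        lin_b = TaxonomyLineage(
            ranks=("Bacteria", "Proteobacteria", "Gamma", "Enterobacteriales",
                   "Enterobacteriaceae", "Proteus")
        )
        tree = build_sunburst(
            {"O1": 100.0, "O2": 50.0}, {"O1": lin_a, "O2": lin_b}
        )
        node = tree
        for label in ("Bacteria", "Proteobacteria", "Gamma",
                      "Enterobacteriales", "Enterobacteriaceae"):
            node = next(c for c in node["children"] if c["name"] == label)
        assert node["value"] == pytest.approx(150.0)
        assert {c["name"] for c in node["children"]} == {"Escherichia", "Proteus"}

    def test_root_total_equals_input_sum_for_random_profiles(self):
        rng = np.random.default_rng(23)
        genera = ["Staphylococcus", "Streptococcus", "Prevotella",
                  "Anaerococcus", "Pseudomonas"]
        for _ in range(20):
            picked = rng.choice(genera, size=int(rng.integers(1, 6)), replace=False)
            copies = {
                f"O{i}": float(rng.uniform(25, 5000)) for i in range(len(picked))
            }
            lineages = {f"O{i}": lineage_for(g) for i, g in enumerate(picked)}
            tree = build_sunburst(copies, lineages)
            assert tree["value"] == pytest.approx(sum(copies.values()))

    def test_empty_profile_is_flagged(self):
        tree = build_sunburst({}, {})
        assert tree["empty"] is True
        assert tree["children"] == []

    def test_children_ordered_by_copies_then_name(self):
        copies = {"O1": 50.0, "O2": 100.0, "O3": 50.0}
        lineages = {
            "O1": lineage_for("Prevotella"),
            "O2": lineage_for("Staphylococcus"),
            "O3": lineage_for("Anaerococcus"),
        }
        tree = build_sunburst(copies, lineages)
        names = [c["name"] for c in tree["children"][0]["children"]]
        # phyla under Bacteria: Firmicutes (100+50) before Bacteroidetes (50)
        assert names == ["Firmicutes", "Bacteroidetes"]


class TestBundle:
    def test_sunburst_total_matches_genus_table_total(self):
        result = make_result(
            {"O1": 400.0, "O2": 75.5},
            {"O1": "Staphylococcus", "O2": "Prevotella"},
        )
        bundle = build_report_bundle(result)
        assert bundle.sunburst["value"] == pytest.approx(bundle.total_copies)

    def test_diversity_computed_on_rounded_copies(self):
        result = make_result(
            {"O1": 400.0, "O2": 100.0},
            {"O1": "Staphylococcus", "O2": "Prevotella"},
        )
        bundle = build_report_bundle(result)
        assert bundle.diversity is not None
        assert bundle.diversity["sobs"] == 2

    def test_empty_result_has_no_diversity_and_flagged_tree(self):
        bundle = build_report_bundle(SampleResult("S1", {}, {}, {}, []))
        assert bundle.diversity is None
        assert bundle.sunburst["empty"] is True


class TestRenderedHtml:
    @pytest.fixture
    def bundle(self):
        return build_report_bundle(
            make_result(
                {"O1": 1999.6, "O2": 100.0, "O3": 50.0},
                {"O1": "Staphylococcus", "O2": "Prevotella", "O3": "Streptococcus"},
            )
        )

    def test_contains_genus_rows_with_integer_copies(self, bundle, tmp_path):
        path = render_report(bundle, tmp_path / "r.html")
        text = path.read_text()
        for genus in ("Staphylococcus", "Prevotella", "Streptococcus"):
            assert genus in text
        assert "<td>2000</td>" in text  # 1999.6 rounded half-up

    def test_bundle_round_trips_through_embedded_json(self, bundle, tmp_path):
        path = render_report(bundle, tmp_path / "r.html")
        again = parse_report(path)
        assert again.to_dict() == bundle.to_dict()

    def test_rendering_is_deterministic(self, bundle, tmp_path):
        a = render_report(bundle, tmp_path / "a.html").read_bytes()
        b = render_report(bundle, tmp_path / "b.html").read_bytes()
        assert a == b

    def test_empty_sample_states_absence_of_16s_copies(self, tmp_path):
        bundle = build_report_bundle(SampleResult("S1", {}, {}, {}, []))
        text = render_report(bundle, tmp_path / "empty.html").read_text()
        assert "No 16S rRNA gene copies detected" in text

    def test_report_stays_small_for_a_thousand_otus(self, tmp_path):
        genera = ["Staphylococcus", "Prevotella", "Streptococcus", "Pseudomonas"]
        copies = {f"O{i}": 25.0 + i for i in range(1000)}
        lineages = {f"O{i}": lineage_for(genera[i % 4]) for i in range(1000)}
        result = SampleResult(
            "S1", copies, lineages,
            {otu: {"rep1": c} for otu, c in copies.items()}, [],
        )
        path = render_report(build_report_bundle(result), tmp_path / "big.html")
        assert path.stat().st_size < 10 * 1024 * 1024
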