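"""Shared fixtures and profile builders for the test suite."""

from __future__ import annotations

import pytest

from quant16s.io import OtuObservation, ReplicateProfile, TaxonomyLineage
from quant16s.simulate import lineage_for


def profile_from_genus_counts(
    counts: dict[str, int], sample_id: str = "S1", replicate_index: int = 1
) -> ReplicateProfile:
    """Build a replicate where each key is a genus with one OTU
    (``Otu_<genus>``), using the simulator's lineage table."""
    observations = tuple(
        OtuObservation(f"Otu_{genus}", lineage_for(genus), reads)
        for genus, reads in counts.items()
    )
    return ReplicateProfile(sample_id, replicate_index, observations)


@pytest.fixture
def simple_profile() -> ReplicateProfile:
    """A small sample replicate: one dominant taxon plus the calibrator."""
    return profile_from_genus_counts(
        {"Staphylococcus": 500, "Synechococcus": 250}
    )


@pytest.fixture
def lineage_staph() -> TaxonomyLineage:
    return lineage_for("Staphylococcus")
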