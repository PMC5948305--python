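"""Synthetic micPCR/NGS experiment generator with known ground truth.

Emulates the quantitative behaviour of emulsion (micelle) PCR followed by
amplicon sequencing: because templates are clonally amplified in separate
micelles, read counts are proportional to input 16S gene copies, so a
replicate is modelled as a single multinomial draw at the configured depth
with probabilities proportional to (true copies + contamination copies +
calibrator copies).  An optional per-taxon efficiency multiplier is
available to emulate the amplification bias of conventional bulk PCR for
contrast experiments; it defaults to off.

Negative extraction controls (NEC) share the contamination composition of
the samples — the same reagent lots — which is exactly the assumption the
downstream NEC subtraction relies on.  Positive-control replicates contain
the four-species synthetic community at 10,000 copies each.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np

from .errors import PipelineError
from .io import (
    OtuObservation,
    ReplicateProfile,
    TaxonomyLineage,
    write_generic_tsv,
)

#: Full six-rank lineages for the genera the simulator uses by default.
KNOWN_LINEAGES: dict[str, TaxonomyLineage] = {
    name: TaxonomyLineage(ranks=ranks)
    for name, ranks in {
        "Synechococcus": (
            "Bacteria", "Cyanobacteria", "Cyanophyceae", "Synechococcales",
            "Synechococcaceae", "Synechococcus",
        ),
        "Moraxella": (
            "Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales",
            "Moraxellaceae", "Moraxella",
        ),
        "Staphylococcus": (
            "Bacteria", "Firmicutes", "Bacilli", "Bacillales",
            "Staphylococcaceae", "Staphylococcus",
        ),
        "Haemophilus": (
            "Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pasteurellales",
            "Pasteurellaceae", "Haemophilus",
        ),
        "Clostridium": (
            "Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
            "Clostridiaceae", "Clostridium",
        ),
        "Streptococcus": (
            "Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
            "Streptococcaceae", "Streptococcus",
        ),
        "Pseudomonas": (
            "Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales",
            "Pseudomonadaceae", "Pseudomonas",
        ),
        "Anaerococcus": (
            "Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
            "Peptoniphilaceae", "Anaerococcus",
        ),
        "Prevotella": (
            "Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
            "Prevotellaceae", "Prevotella",
        ),
        "Ralstonia": (
            "Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales",
            "Burkholderiaceae", "Ralstonia",
        ),
        "Bradyrhizobium": (
            "Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhizobiales",
            "Bradyrhizobiaceae", "Bradyrhizobium",
        ),
        "Kingella": (
            "Bacteria", "Proteobacteria", "Betaproteobacteria", "Neisseriales",
            "Neisseriaceae", "Kingella",
        ),
    }.items()
}

#: The four-species synthetic community run as positive control:
#: 10,000 16S copies of each species per extract.
PC_COMMUNITY: tuple[tuple[str, float], ...] = (
    ("Moraxella", 10_000.0),
    ("Staphylococcus", 10_000.0),
    ("Haemophilus", 10_000.0),
    ("Clostridium", 10_000.0),
)

#: Reagent-contamination profile used by default (copies per extract);
#: typical low-level kit contaminants.
DEFAULT_CONTAMINATION: tuple[tuple[str, float], ...] = (
    ("Ralstonia", 300.0),
    ("Bradyrhizobium", 150.0),
)


def lineage_for(name: str) -> TaxonomyLineage:
    """Lineage for a genus name (known table, or a genus-only lineage) or a
    full semicolon-separated lineage string."""
    if ";" in name:
        return TaxonomyLineage.from_string(name)
    if name in KNOWN_LINEAGES:
        return KNOWN_LINEAGES[name]
    return TaxonomyLineage.from_genus(name)


@dataclass(frozen=True)
class SimConfig:
    """Composition and sequencing parameters of one simulated sample.

    ``taxa`` lists (genus or lineage string, true 16S copies per extract);
    ``contamination`` is shared between samples and the NEC.  IC spike
    amounts default to the normalized-extract convention: 1000 copies into
    samples, 100 into the NEC.
    """

    taxa: tuple[tuple[str, float], ...] = (("Staphylococcus", 10_000.0),)
    contamination: tuple[tuple[str, float], ...] = DEFAULT_CONTAMINATION
    ic_initial_copies: float = 1000.0
    nec_ic_copies: float = 100.0
    read_depth: int = 20_000
    replicates: int = 3
    seed: int = 0
    efficiency: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.read_depth <= 0:
            raise PipelineError("read depth must be positive")
        if not (1 <= self.replicates <= 3):
            raise PipelineError("replicates must be 1..3")
        for name, c in tuple(self.taxa) + tuple(self.contamination):
            if c < 0:
                raise PipelineError(f"negative copies for {name}")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth accompanying one simulated replicate."""

    sample_id: str
    kind: str
    true_copies: Mapping[str, float]          # genus -> biological copies
    contamination: Mapping[str, float]        # genus -> contaminant copies
    ic_copies: float
    expected_fractions: Mapping[str, float]   # genus -> expected read fraction

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "kind": self.kind,
            "true_copies": dict(self.true_copies),
            "contamination": dict(self.contamination),
            "ic_copies": self.ic_copies,
            "expected_fractions": dict(self.expected_fractions),
        }


def _composition(config: SimConfig, kind: str) -> dict[str, float]:
    """Total 16S copies per genus entering the emulsion for one replicate."""
    comp: dict[str, float] = {}

    def add(name: str, copies: float) -> None:
        if copies > 0:
            comp[name] = comp.get(name, 0.0) + copies

    if kind == "sample":
        for name, c in config.taxa:
            add(name, c)
        for name, c in config.contamination:
            add(name, c)
        add("Synechococcus", config.ic_initial_copies)
    elif kind == "nec":
        for name, c in config.contamination:
            add(name, c)
        add("Synechococcus", config.nec_ic_copies)
    elif kind == "pc":
        for name, c in PC_COMMUNITY:
            add(name, c)
        for name, c in config.contamination:
            add(name, c)
        add("Synechococcus", config.ic_initial_copies)
    else:
        raise PipelineError(f"unknown replicate kind {kind!r}")
    if not comp:
        raise PipelineError("all-zero composition: nothing to sequence")
    return comp


def simulate_replicate(
    config: SimConfig,
    kind: str,
    seed: int,
    sample_id: str = "SIM",
    replicate_index: int = 1,
) -> tuple[ReplicateProfile, SimTruth]:
    """Draw one technical replicate at the configured depth.

    Reads are a multinomial draw with probabilities proportional to input
    copies (times the optional per-taxon efficiency multiplier).  Genera
    drawn to zero reads are omitted from the profile.  Deterministic per
    seed.
    """
    comp = _composition(config, kind)
    names = sorted(comp)
    weights = np.array(
        [
            comp[n] * (config.efficiency.get(n, 1.0) if config.efficiency else 1.0)
            for n in names
        ],
        dtype=float,
    )
    if weights.sum() <= 0:
        raise PipelineError("all-zero composition: nothing to sequence")
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    reads = rng.multinomial(config.read_depth, probs)
    # OTU ids are keyed by genus so they are stable across every replicate,
    # NEC and PC of a study (joint OTU clustering would do the same); NEC
    # subtraction downstream matches contaminant OTUs by id.
    observations = tuple(
        OtuObservation(f"Otu_{name}", lineage_for(name), int(k))
        for name, k in zip(names, reads)
        if k > 0
    )
    profile = ReplicateProfile(sample_id, replicate_index, observations)

    if kind == "sample":
        true_copies = {n: c for n, c in config.taxa if c > 0}
        ic = config.ic_initial_copies
    elif kind == "pc":
        true_copies = {n: c for n, c in PC_COMMUNITY}
        ic = config.ic_initial_copies
    else:
        true_copies = {}
        ic = config.nec_ic_copies
    truth = SimTruth(
        sample_id=sample_id,
        kind=kind,
        true_copies=true_copies,
        contamination={n: c for n, c in config.contamination if c > 0},
        ic_copies=ic,
        expected_fractions={n: float(p) for n, p in zip(names, probs)},
    )
    return profile, truth


def simulate_sample_set(
    config: SimConfig, kind: str, sample_id: str, seed: Optional[int] = None
) -> tuple[list[ReplicateProfile], SimTruth]:
    """All technical replicates of one sample/NEC/PC, with shared truth."""
    base = config.seed if seed is None else seed
    seeds = np.random.SeedSequence(base).generate_state(config.replicates)
    profiles = []
    truth = None
    for i, s in enumerate(seeds, start=1):
        profile, truth = simulate_replicate(
            config, kind, int(s) % (2**31), sample_id=sample_id, replicate_index=i
        )
        profiles.append(profile)
    assert truth is not None
    return profiles, truth


def simulate_study(
    configs: Mapping[str, SimConfig],
    out_dir: Union[str, Path],
    include_pc: bool = True,
    force: bool = False,
) -> dict:
    """Write a full simulated study to ``out_dir``.

    Emits triplicate generic TSVs per sample, triplicate NEC TSVs, one PC
    replicate set (if requested) and ``truth.json``.  NEC and PC use the
    first config's contamination/depth settings.  Refuses to overwrite an
    existing directory unless ``force``.
    """
    if not configs:
        raise PipelineError("at least one sample config required")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not force:
            raise PipelineError(
                f"output directory {out_dir} exists; pass force=True to overwrite"
            )
        shutil.rmtree(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    truth_doc: dict = {"samples": {}, "nec": None, "pc": None}
    first = next(iter(configs.values()))

    # Derive disjoint per-set seeds from each config's own seed so a study
    # is reproducible from the config alone.
    for offset, (sample_id, config) in enumerate(sorted(configs.items())):
        profiles, truth = simulate_sample_set(
            config, "sample", sample_id, seed=config.seed + offset
        )
        for p in profiles:
            write_generic_tsv(p, out_dir / f"{sample_id}_{p.replicate_index}.tsv")
        truth_doc["samples"][sample_id] = truth.to_dict()

    nec_profiles, nec_truth = simulate_sample_set(
        first, "nec", "NEC", seed=first.seed + 10_007
    )
    for p in nec_profiles:
        write_generic_tsv(p, out_dir / f"NEC_{p.replicate_index}.tsv")
    truth_doc["nec"] = nec_truth.to_dict()

    if include_pc:
        pc_profiles, pc_truth = simulate_sample_set(
            first, "pc", "PC", seed=first.seed + 20_011
        )
        for p in pc_profiles:
            write_generic_tsv(p, out_dir / f"PC_{p.replicate_index}.tsv")
        truth_doc["pc"] = pc_truth.to_dict()

    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth_doc, sort_keys=True, indent=1))
    return truth_doc
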