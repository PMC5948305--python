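"""Core quantification pipeline: reads -> absolute 16S rRNA gene copies.

Stages, in order, for one sample processed in technical triplicate:

1. optional seeded subsampling of each replicate (without replacement),
2. calibration of each replicate against the spiked internal calibrator
   (IC): ``copies = reads * ic_initial_copies / ic_reads``,
3. consensus over replicates (intersection + arithmetic mean by default),
4. subtraction of the negative-extraction-control (NEC) consensus,
   clamped at zero,
5. limit-of-detection filter (default: retain >= 25 copies per OTU).

Every filtering stage appends a :class:`QcRecord` so the final
:class:`SampleResult` carries a complete audit trail.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import IcDropoutError, PipelineError
from .io import OtuObservation, ReplicateProfile, TaxonomyLineage

#: Default limit of detection, in 16S rRNA gene copies per OTU.
DEFAULT_LOD_COPIES = 25.0

#: Default genus label of the spiked internal calibrator.
DEFAULT_IC_TAXON = "Synechococcus"


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties away from zero (reports print
    integer copy numbers; banker's rounding would be surprising there)."""
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CalibrationConfig:
    """Run parameters of the quantification pipeline.

    ``ic_initial_copies`` is the number of calibrator 16S copies spiked into
    each sample extract (1000 for extracts normalized to 10,000 copies/uL,
    100 for low-biomass extracts); ``nec_ic_initial_copies`` is the spike
    into the negative extraction control (100 by convention).
    """

    ic_taxon_label: str = DEFAULT_IC_TAXON
    ic_initial_copies: float = 1000.0
    nec_ic_initial_copies: float = 100.0
    lod_copies: float = DEFAULT_LOD_COPIES
    subsample_depth: Optional[int] = None
    replicate_policy: str = "all"  # "all" = intersection, "any" = union
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ic_initial_copies <= 0 or self.nec_ic_initial_copies <= 0:
            raise PipelineError("ic_initial_copies must be positive")
        if self.lod_copies <= 0:
            raise PipelineError("lod_copies must be positive")
        if self.subsample_depth is not None and self.subsample_depth <= 0:
            raise PipelineError("subsample_depth must be positive")
        if self.replicate_policy not in ("all", "any"):
            raise PipelineError(f"unknown replicate policy {self.replicate_policy!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class QcRecord:
    """One quality-control ledger entry: what a stage did to the data."""

    stage: str
    units_in: int
    units_out: int
    detail: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CalibratedProfile:
    """Per-OTU absolute 16S gene copies for one replicate.

    The IC OTU(s) are excluded from ``copies``; by construction calibrating
    the IC against itself returns exactly ``ic_initial_copies``, which is
    checked before exclusion.
    """

    sample_id: str
    replicate_index: int
    copies: Mapping[str, float]
    lineages: Mapping[str, TaxonomyLineage]
    ic_reads: int
    correction_factor: float


@dataclass
class SampleResult:
    """Triplicate-consensus, NEC-corrected, LOD-filtered profile of one
    sample, with full per-replicate provenance and QC trail."""

    sample_id: str
    consensus_copies: dict[str, float]
    lineages: dict[str, TaxonomyLineage]
    provenance: dict[str, dict[str, float]]  # otu -> replicate label -> copies
    qc: list[QcRecord]
    config: Optional[CalibrationConfig] = None

    @property
    def total_copies(self) -> float:
        return float(sum(self.consensus_copies.values()))

    @property
    def detected_genera(self) -> set[str]:
        return {
            self.lineages[otu].genus_label for otu in self.consensus_copies
        }

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "consensus_copies": dict(sorted(self.consensus_copies.items())),
            "lineages": {
                otu: lin.to_string(with_confidence=True)
                for otu, lin in sorted(self.lineages.items())
            },
            "provenance": {
                otu: dict(sorted(reps.items()))
                for otu, reps in sorted(self.provenance.items())
            },
            "qc": [r.to_dict() for r in self.qc],
            "config": self.config.to_dict() if self.config else None,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "SampleResult":
        config = CalibrationConfig(**d["config"]) if d.get("config") else None
        return cls(
            sample_id=d["sample_id"],
            consensus_copies=dict(d["consensus_copies"]),
            lineages={
                otu: TaxonomyLineage.from_string(s) for otu, s in d["lineages"].items()
            },
            provenance={otu: dict(v) for otu, v in d["provenance"].items()},
            qc=[QcRecord(**r) for r in d["qc"]],
            config=config,
        )

    @classmethod
    def from_json(cls, text: str) -> "SampleResult":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Stage operations


def subsample_replicate(
    profile: ReplicateProfile,
    depth: int,
    seed: int,
    qc: Optional[list[QcRecord]] = None,
) -> ReplicateProfile:
    """Draw exactly ``depth`` reads without replacement from a replicate.

    The draw is multivariate hypergeometric over the multiset of reads, so
    expectations are proportional to the original counts.  OTUs reduced to
    zero are dropped.  Deterministic for a fixed seed.
    """
    total = profile.total_reads
    if depth > total:
        raise PipelineError(
            f"subsample depth {depth} exceeds replicate total {total}; "
            "skip subsampling for this replicate"
        )
    rng = np.random.default_rng(seed)
    counts = np.array([o.reads for o in profile.observations], dtype=np.int64)
    drawn = rng.multivariate_hypergeometric(counts, depth)
    observations = tuple(
        OtuObservation(o.otu_id, o.lineage, int(k))
        for o, k in zip(profile.observations, drawn)
        if k > 0
    )
    out = ReplicateProfile(profile.sample_id, profile.replicate_index, observations)
    if qc is not None:
        qc.append(
            QcRecord(
                stage="subsample",
                units_in=total,
                units_out=depth,
                detail=(
                    f"{profile.sample_id} rep {profile.replicate_index}: "
                    f"{total} -> {depth} reads, "
                    f"{len(profile.observations) - len(observations)} OTU(s) lost"
                ),
            )
        )
    return out


def find_ic_reads(
    profile: ReplicateProfile, ic_taxon_label: str = DEFAULT_IC_TAXON
) -> tuple[int, frozenset[str]]:
    """Locate the internal-calibrator OTU(s) by genus label.

    Matching is case-insensitive at the genus rank.  Multiple matching OTUs
    (the calibrator split across clusters) are summed.  Zero matching OTUs
    or zero total reads is an IC dropout: calibration is impossible.
    """
    label = ic_taxon_label.lower()
    ic_ids = frozenset(
        o.otu_id for o in profile.observations if o.lineage.genus.lower() == label
    )
    ic_reads = sum(o.reads for o in profile.observations if o.otu_id in ic_ids)
    if not ic_ids or ic_reads == 0:
        raise IcDropoutError(
            f"IC dropout: no reads for calibrator taxon {ic_taxon_label!r} in "
            f"{profile.sample_id} replicate {profile.replicate_index}"
        )
    return ic_reads, ic_ids


def calibrate(
    profile: ReplicateProfile,
    config: CalibrationConfig,
    ic_initial_copies: Optional[float] = None,
    qc: Optional[list[QcRecord]] = None,
) -> CalibratedProfile:
    """Convert a replicate's read counts to absolute 16S gene copies.

    ``copies = reads * (ic_initial_copies / ic_reads)`` for every non-IC
    OTU.  The IC OTU(s) are excluded from the output.  No detection limit
    is applied here.
    """
    initial = config.ic_initial_copies if ic_initial_copies is None else ic_initial_copies
    ic_reads, ic_ids = find_ic_reads(profile, config.ic_taxon_label)
    factor = initial / ic_reads
    # IC self-consistency: the calibrator must map back onto its own spike.
    assert abs(ic_reads * factor - initial) <= 1e-9 * initial
    copies = {
        o.otu_id: o.reads * factor
        for o in profile.observations
        if o.otu_id not in ic_ids
    }
    lineages = {
        o.otu_id: o.lineage for o in profile.observations if o.otu_id not in ic_ids
    }
    if qc is not None:
        qc.append(
            QcRecord(
                stage="calibrate",
                units_in=len(profile.observations),
                units_out=len(copies),
                detail=(
                    f"{profile.sample_id} rep {profile.replicate_index}: "
                    f"IC reads={ic_reads}, correction factor={factor:.6g}"
                ),
            )
        )
    return CalibratedProfile(
        sample_id=profile.sample_id,
        replicate_index=profile.replicate_index,
        copies=copies,
        lineages=lineages,
        ic_reads=ic_reads,
        correction_factor=factor,
    )


def consensus_over_replicates(
    replicates: Sequence[CalibratedProfile],
    policy: str = "all",
    qc: Optional[list[QcRecord]] = None,
) -> dict[str, float]:
    """Average calibrated copies over technical replicates.

    Under the default ``"all"`` policy an OTU is retained only if it has
    positive copies in every replicate (technical replication as an
    accuracy/contamination filter); retained copies are the arithmetic mean.
    Under ``"any"`` the union is retained and absences enter the mean as
    zero.
    """
    if len(replicates) < 2:
        raise PipelineError("consensus requires at least 2 replicates")
    sample_ids = {r.sample_id for r in replicates}
    if len(sample_ids) != 1:
        raise PipelineError(
            f"replicates from different samples: {sorted(sample_ids)}"
        )
    if policy not in ("all", "any"):
        raise PipelineError(f"unknown replicate policy {policy!r}")
    union: set[str] = set()
    for r in replicates:
        union.update(otu for otu, c in r.copies.items() if c > 0)
    n = len(replicates)
    consensus: dict[str, float] = {}
    for otu in union:
        values = [r.copies.get(otu, 0.0) for r in replicates]
        if policy == "all" and any(v <= 0 for v in values):
            continue
        consensus[otu] = sum(values) / n
    if qc is not None:
        qc.append(
            QcRecord(
                stage="consensus",
                units_in=len(union),
                units_out=len(consensus),
                detail=(
                    f"policy={policy}, {n} replicates of "
                    f"{replicates[0].sample_id}"
                ),
            )
        )
    return consensus


def subtract_nec(
    sample_copies: Mapping[str, float],
    nec_copies: Mapping[str, float],
    qc: Optional[list[QcRecord]] = None,
) -> dict[str, float]:
    """Subtract the NEC consensus (contamination estimate) per OTU.

    Result is ``max(0, sample - NEC)``; OTUs absent from the NEC pass
    through unchanged; OTUs reduced to zero are dropped.  An empty NEC is a
    no-op.
    """
    out: dict[str, float] = {}
    subtracted_total = 0.0
    for otu, copies in sample_copies.items():
        removed = min(copies, nec_copies.get(otu, 0.0))
        subtracted_total += removed
        remaining = copies - removed
        if remaining > 0:
            out[otu] = remaining
    if qc is not None:
        qc.append(
            QcRecord(
                stage="nec_subtraction",
                units_in=len(sample_copies),
                units_out=len(out),
                detail=f"subtracted {subtracted_total:.3f} contaminant copies "
                f"across {len(nec_copies)} NEC OTU(s)",
            )
        )
    return out


def apply_lod(
    copies_map: Mapping[str, float],
    lod_copies: float = DEFAULT_LOD_COPIES,
    qc: Optional[list[QcRecord]] = None,
) -> dict[str, float]:
    """Limit-of-detection filter: retain OTUs with copies >= ``lod_copies``.

    The boundary is inclusive (the LOD is the smallest detectable value)
    and the operation is idempotent.
    """
    out = {otu: c for otu, c in copies_map.items() if c >= lod_copies}
    if qc is not None:
        qc.append(
            QcRecord(
                stage="lod_filter",
                units_in=len(copies_map),
                units_out=len(out),
                detail=f"threshold {lod_copies:g} copies per OTU",
            )
        )
    return out


def run_sample(
    replicates: Sequence[ReplicateProfile],
    nec_replicates: Sequence[ReplicateProfile],
    config: CalibrationConfig,
) -> SampleResult:
    """Run the full quantification pipeline for one sample.

    Stages: optional subsampling, IC calibration per replicate, replicate
    consensus (sample and NEC independently; the NEC is calibrated against
    its own spike amount), NEC subtraction on the consensus maps, LOD
    filter.  Deterministic for a fixed config seed.
    """
    if not replicates:
        raise PipelineError("no sample replicates given")
    qc: list[QcRecord] = []
    sample_id = replicates[0].sample_id

    seeds = np.random.SeedSequence(config.seed).generate_state(
        len(replicates) + len(nec_replicates)
    )

    def maybe_subsample(profile: ReplicateProfile, seed: int) -> ReplicateProfile:
        if config.subsample_depth is None:
            return profile
        if config.subsample_depth > profile.total_reads:
            qc.append(
                QcRecord(
                    stage="subsample",
                    units_in=profile.total_reads,
                    units_out=profile.total_reads,
                    detail=(
                        f"{profile.sample_id} rep {profile.replicate_index}: depth "
                        f"{config.subsample_depth} exceeds total, skipped"
                    ),
                )
            )
            return profile
        return subsample_replicate(profile, config.subsample_depth, seed, qc=qc)

    prepared = [
        maybe_subsample(p, int(s) % (2**31)) for p, s in zip(replicates, seeds)
    ]
    nec_prepared = [
        maybe_subsample(p, int(s) % (2**31))
        for p, s in zip(nec_replicates, seeds[len(replicates):])
    ]

    calibrated = [calibrate(p, config, qc=qc) for p in prepared]
    consensus = consensus_over_replicates(
        calibrated, policy=config.replicate_policy, qc=qc
    )

    nec_consensus: dict[str, float] = {}
    if nec_replicates:
        nec_calibrated = [
            calibrate(p, config, ic_initial_copies=config.nec_ic_initial_copies, qc=qc)
            for p in nec_prepared
        ]
        if len(nec_calibrated) >= 2:
            nec_consensus = consensus_over_replicates(
                nec_calibrated, policy=config.replicate_policy, qc=qc
            )
        else:
            nec_consensus = {
                otu: c for otu, c in nec_calibrated[0].copies.items() if c > 0
            }

    after_nec = subtract_nec(consensus, nec_consensus, qc=qc)
    final = apply_lod(after_nec, config.lod_copies, qc=qc)

    lineages: dict[str, TaxonomyLineage] = {}
    for cal in calibrated:
        lineages.update(cal.lineages)
    provenance: dict[str, dict[str, float]] = {}
    all_otus = set().union(*(cal.copies.keys() for cal in calibrated))
    for otu in all_otus:
        provenance[otu] = {
            f"rep{cal.replicate_index}": float(cal.copies.get(otu, 0.0))
            for cal in calibrated
        }

    return SampleResult(
        sample_id=sample_id,
        consensus_copies=final,
        lineages={otu: lin for otu, lin in lineages.items() if otu in provenance},
        provenance=provenance,
        qc=qc,
        config=config,
    )


def aggregate_by_genus(
    copies: Mapping[str, float], lineages: Mapping[str, TaxonomyLineage]
) -> dict[str, float]:
    """Sum copies over OTUs sharing a genus label.

    OTUs with an unresolved genus aggregate at the deepest resolved rank
    with a ``*`` marker (e.g. ``Enterobacteriaceae*``).
    """
    out: dict[str, float] = {}
    for otu, c in copies.items():
        label = lineages[otu].genus_label
        out[label] = out.get(label, 0.0) + c
    return out


def write_result_table(result: SampleResult, path) -> None:
    """Write the per-OTU output table: otu_id, lineage, consensus copies,
    per-replicate calibrated copies, and pass/fail flags."""
    rep_labels = sorted(
        {lab for reps in result.provenance.values() for lab in reps}
    )
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["otu_id", "lineage", "copies_mean"] + [
            f"copies_{lab}" for lab in rep_labels
        ] + ["flags"]
        fh.write("\t".join(cols) + "\n")
        for otu in sorted(result.provenance):
            mean = result.consensus_copies.get(otu)
            flags = "pass" if mean is not None else "filtered"
            row = [
                otu,
                result.lineages[otu].to_string(),
                f"{mean:.3f}" if mean is not None else "",
            ]
            row += [
                f"{result.provenance[otu].get(lab, 0.0):.3f}" for lab in rep_labels
            ]
            row.append(flags)
            fh.write("\t".join(row) + "\n")
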