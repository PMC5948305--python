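"""Concordance statistics against qPCR and routine bacterial culture.

Two families of validation statistics for the quantification pipeline:

* fold-difference agreement between two biomass estimates of the same
  quantity (pipeline vs qPCR, or pipeline vs a known spike), and
* genus-level and sample-level detection concordance against
  semi-quantitative culture, expressed as sensitivity/specificity from
  confusion counts.

Culture scoring follows clinical convention: ``commensal_flora`` culture
results count as a positive signal for any aerobic OTU detection, and a
positive anaerobic culture counts as detected when any obligate-anaerobe
genus is found.  Aerobe/anaerobe status is a configurable lookup keyed by
genus label (clinical knowledge, not derivable from the data).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .errors import PipelineError
from .io import (  # noqa: F401  (re-export)
    UNCLASSIFIED,
    CultureObservation,
    QpcrResult,
    TaxonomyLineage,
)
from .pipeline import SampleResult

#: Genera treated as aerobic / facultative by default.  Everything not in
#: this set (and not matching an aerobic family fallback) is treated as an
#: obligate anaerobe for concordance scoring.  Extend or replace per site.
DEFAULT_AEROBIC_GENERA = frozenset(
    {
        "Acinetobacter",
        "Aerococcus",
        "Alcaligenes",
        "Bacillus",
        "Brevibacterium",
        "Citrobacter",
        "Corynebacterium",
        "Dermabacter",
        "Enterobacter",
        "Enterococcus",
        "Escherichia",
        "Haemophilus",
        "Kingella",
        "Klebsiella",
        "Kocuria",
        "Micrococcus",
        "Moraxella",
        "Morganella",
        "Neisseria",
        "Pantoea",
        "Pasteurella",
        "Proteus",
        "Providencia",
        "Pseudomonas",
        "Ralstonia",
        "Rothia",
        "Serratia",
        "Staphylococcus",
        "Stenotrophomonas",
        "Streptococcus",
        "Synechococcus",
    }
)

#: Family-level fallback labels (``Family*``) that denote aerobic taxa which
#: could not be split at the genus rank.
DEFAULT_AEROBIC_FAMILIES = frozenset({"Enterobacteriaceae", "Dermabacteraceae"})


def is_aerobic(
    genus_label: str,
    aerobic_genera: frozenset[str] = DEFAULT_AEROBIC_GENERA,
    aerobic_families: frozenset[str] = DEFAULT_AEROBIC_FAMILIES,
) -> bool:
    """Classify a genus-level reporting label as aerobic/facultative.

    Labels ending in ``*`` are family-level fallbacks and are looked up in
    the aerobic-family set instead.
    """
    if genus_label.endswith("*"):
        return genus_label[:-1] in aerobic_families
    return genus_label in aerobic_genera


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 detection confusion counts with derived rates."""

    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise PipelineError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fn + other.fn,
            self.tn + other.tn,
            self.fp + other.fp,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity(self) -> Optional[float]:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def specificity(self) -> Optional[float]:
        denom = self.tn + self.fp
        return self.tn / denom if denom else None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def fold_difference(a: float, b: float) -> float:
    """Fold difference ``max(a,b)/min(a,b)`` between two positive biomass
    estimates; symmetric in its arguments and always >= 1."""
    if a <= 0 or b <= 0:
        raise PipelineError("fold difference requires positive values")
    return max(a, b) / min(a, b)


def saureus_genomes_to_16s(genome_copies: float) -> float:
    """Convert *S. aureus* genome copies (single-copy Martineau-fragment
    qPCR) to 16S rRNA gene copies: six 16S operons per genome."""
    if genome_copies < 0:
        raise PipelineError("genome copies must be non-negative")
    return genome_copies * 6.0


def summarize_folds(
    folds: Sequence[float], mode: str = "median"
) -> tuple[float, float]:
    """Summarize a set of fold differences as (center, spread).

    ``median`` mode pairs the median with the median absolute deviation;
    ``mean`` mode pairs the mean with the sample standard deviation.  A
    single value has spread 0.
    """
    if not folds:
        raise PipelineError("no fold differences to summarize")
    if any(f < 1 for f in folds):
        raise PipelineError("fold differences must be >= 1")
    if mode == "median":
        center = statistics.median(folds)
        spread = statistics.median(abs(f - center) for f in folds)
    elif mode == "mean":
        center = statistics.fmean(folds)
        spread = statistics.stdev(folds) if len(folds) > 1 else 0.0
    else:
        raise PipelineError(f"unknown summary mode {mode!r}")
    return center, spread


ANAEROBIC_TAXON = "anaerobic_bacteria"
COMMENSAL_TAXON = "commensal_flora"


@dataclass(frozen=True)
class GenusConcordance:
    """Per-taxon and pooled confusion counts against culture."""

    per_taxon: Mapping[str, ConfusionCounts]
    pooled: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "per_taxon": {t: c.to_dict() for t, c in sorted(self.per_taxon.items())},
            "pooled": self.pooled.to_dict(),
        }


def _detected_labels(result: SampleResult) -> set[str]:
    return result.detected_genera


def genus_concordance(
    culture: Sequence[CultureObservation],
    results: Sequence[SampleResult],
    aerobic_genera: frozenset[str] = DEFAULT_AEROBIC_GENERA,
    aerobic_families: frozenset[str] = DEFAULT_AEROBIC_FAMILIES,
) -> GenusConcordance:
    """Genus-level detection concordance against culture.

    For every cultured genus: TP when the pipeline detects that genus in
    the same sample, FN otherwise; per-genus negatives are the samples
    without that cultured genus (commensal-flora samples excluded, since
    any aerobic detection there is explained by the commensal growth), FP
    when the genus is nonetheless detected.  Anaerobic cultures are scored
    as one pooled taxon: positive when any obligate-anaerobe genus is
    detected.  Commensal-flora rows score TP when any aerobic OTU is
    detected.  Pooled counts are the sums over taxa.
    """
    if not culture or not results:
        raise PipelineError("empty culture or result set")
    by_sample = {r.sample_id: r for r in results}
    missing = sorted({c.sample_id for c in culture} - by_sample.keys())
    if missing:
        raise PipelineError(f"no pipeline result for sample(s): {', '.join(missing)}")

    def aerobic(label: str) -> bool:
        return is_aerobic(label, aerobic_genera, aerobic_families)

    detected: dict[str, set[str]] = {
        sid: _detected_labels(r) for sid, r in by_sample.items()
    }
    cultured_by_sample: dict[str, list[CultureObservation]] = {}
    for row in culture:
        cultured_by_sample.setdefault(row.sample_id, []).append(row)

    evaluated_samples = sorted(cultured_by_sample)
    genera = sorted({row.genus for row in culture if row.genus is not None})
    has_anaerobic_rows = any(c.category == "anaerobic_positive" for c in culture)
    commensal_samples = {
        c.sample_id for c in culture if c.category == COMMENSAL_TAXON
    }

    per_taxon: dict[str, ConfusionCounts] = {}

    for genus in genera:
        tp = fn = tn = fp = 0
        positive_samples = {
            c.sample_id for c in culture if c.genus == genus
        }
        for sid in evaluated_samples:
            found = genus in detected[sid]
            if sid in positive_samples:
                if found:
                    tp += 1
                else:
                    fn += 1
            elif sid in commensal_samples and aerobic(genus):
                continue  # detection explained by commensal growth
            else:
                if found:
                    fp += 1
                else:
                    tn += 1
        per_taxon[genus] = ConfusionCounts(tp, fn, tn, fp)

    if has_anaerobic_rows:
        tp = fn = tn = fp = 0
        positive_samples = {
            c.sample_id for c in culture if c.category == "anaerobic_positive"
        }
        for sid in evaluated_samples:
            found = any(not aerobic(lab) for lab in detected[sid])
            if sid in positive_samples:
                if found:
                    tp += 1
                else:
                    fn += 1
            else:
                if found:
                    fp += 1
                else:
                    tn += 1
        per_taxon[ANAEROBIC_TAXON] = ConfusionCounts(tp, fn, tn, fp)

    if commensal_samples:
        tp = fn = 0
        for sid in sorted(commensal_samples):
            if any(aerobic(lab) for lab in detected[sid]):
                tp += 1
            else:
                fn += 1
        per_taxon[COMMENSAL_TAXON] = ConfusionCounts(tp, fn, 0, 0)

    pooled = ConfusionCounts()
    for counts in per_taxon.values():
        pooled = pooled + counts
    return GenusConcordance(per_taxon=per_taxon, pooled=pooled)


def sample_level_detection(
    culture: Sequence[CultureObservation],
    results: Sequence[SampleResult],
) -> ConfusionCounts:
    """Sample-level detection concordance: did the pipeline find *any*
    bacterial DNA in culture-positive samples, and none in culture-negative
    ones?"""
    if not culture or not results:
        raise PipelineError("empty culture or result set")
    by_sample = {r.sample_id: r for r in results}
    cats: dict[str, set[str]] = {}
    for row in culture:
        cats.setdefault(row.sample_id, set()).add(row.category)
    missing = sorted(cats.keys() - by_sample.keys())
    if missing:
        raise PipelineError(f"no pipeline result for sample(s): {', '.join(missing)}")
    tp = fn = tn = fp = 0
    for sid, categories in sorted(cats.items()):
        culture_positive = any(c != "negative" for c in categories)
        pipeline_positive = bool(by_sample[sid].consensus_copies)
        if culture_positive and pipeline_positive:
            tp += 1
        elif culture_positive:
            fn += 1
        elif pipeline_positive:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fn, tn, fp)


def anaerobe_share(
    lineage_labels: Iterable[str],
    aerobic_genera: frozenset[str] = DEFAULT_AEROBIC_GENERA,
    aerobic_families: frozenset[str] = DEFAULT_AEROBIC_FAMILIES,
) -> float:
    """Fraction of detected OTU genus labels classified as obligate
    anaerobes (one entry per detected OTU, not per unique genus)."""
    labels = list(lineage_labels)
    if not labels:
        raise PipelineError("no detections to classify")
    anaerobic = sum(
        0 if is_aerobic(lab, aerobic_genera, aerobic_families) else 1 for lab in labels
    )
    return anaerobic / len(labels)


def detection_table(
    aerobic: Mapping[str, tuple[int, int]],
    anaerobic: tuple[int, int] = (0, 0),
    commensal: tuple[int, int] = (0, 0),
    negative: tuple[int, int] = (0, 0),
    copies: float = 1000.0,
) -> tuple[list[CultureObservation], list[SampleResult]]:
    """Build a synthetic culture/detection study from summary counts.

    This is a synthetic reconstruction used for testing concordance
    arithmetic from published-style summary counts, not real study data.
    Each taxon entry maps to ``(n_cultured_samples, n_detected_of_those)``;
    ``anaerobic`` and ``commensal`` behave likewise; ``negative`` is
    ``(n_culture_negative_samples, n_of_those_with_any_detection)``.  One
    sample is created per culture row; detected samples carry a single OTU
    of the relevant genus at ``copies`` 16S copies.
    """
    culture: list[CultureObservation] = []
    results: list[SampleResult] = []
    counter = 0

    def make_result(sid: str, genus: Optional[str]) -> SampleResult:
        if genus is None:
            return SampleResult(sid, {}, {}, {}, [])
        if genus.endswith("*"):
            # family-level fallback label: family resolved, genus not
            lin = TaxonomyLineage(
                ranks=(
                    "Bacteria",
                    UNCLASSIFIED,
                    UNCLASSIFIED,
                    UNCLASSIFIED,
                    genus[:-1],
                    UNCLASSIFIED,
                )
            )
        else:
            lin = TaxonomyLineage.from_genus(genus)
        return SampleResult(
            sid,
            {"Otu001": copies},
            {"Otu001": lin},
            {"Otu001": {"rep1": copies, "rep2": copies, "rep3": copies}},
            [],
        )

    for genus, (n_cultured, n_detected) in sorted(aerobic.items()):
        if n_detected > n_cultured:
            raise PipelineError(f"{genus}: detected exceeds cultured")
        for i in range(n_cultured):
            counter += 1
            sid = f"SYN{counter:03d}"
            culture.append(CultureObservation(sid, f"genus:{genus}"))
            results.append(make_result(sid, genus if i < n_detected else None))

    n_anaerobic, n_anaerobic_detected = anaerobic
    for i in range(n_anaerobic):
        counter += 1
        sid = f"SYN{counter:03d}"
        culture.append(CultureObservation(sid, "anaerobic_positive"))
        results.append(
            make_result(sid, "Anaerococcus" if i < n_anaerobic_detected else None)
        )

    n_commensal, n_commensal_detected = commensal
    for i in range(n_commensal):
        counter += 1
        sid = f"SYN{counter:03d}"
        culture.append(CultureObservation(sid, "commensal_flora", "2+"))
        results.append(
            make_result(sid, "Corynebacterium" if i < n_commensal_detected else None)
        )

    n_negative, n_negative_detected = negative
    for i in range(n_negative):
        counter += 1
        sid = f"SYN{counter:03d}"
        culture.append(CultureObservation(sid, "negative"))
        results.append(
            make_result(sid, "Kingella" if i < n_negative_detected else None)
        )

    return culture, results
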