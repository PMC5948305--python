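"""Readers and writers for the tabular formats the pipeline touches.

Supported inputs are the mothur ``.shared`` / ``.cons.taxonomy`` pair, a
generic per-replicate TSV (columns ``otu_id``, ``lineage``, ``reads``) and
CSV tables of culture and qPCR comparator records.  All readers validate
into the domain types defined here; parse failures are hard errors, never
silent coercions.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .errors import FormatError

#: Taxonomic ranks carried by every lineage, domain down to genus.
RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

#: Sentinel label for a rank the classifier could not resolve.
UNCLASSIFIED = "unclassified"

_CONF_RE = re.compile(r"^(?P<label>.*?)\((?P<conf>\d+(?:\.\d+)?)\)$")


@dataclass(frozen=True)
class TaxonomyLineage:
    """Six-rank taxonomic lineage (domain..genus) with optional confidences.

    Unresolved ranks carry the sentinel ``"unclassified"``.  Confidences are
    fractions in [0, 1]; ``None`` means the input carried no confidence for
    that rank (which is distinct from a confidence of zero).
    """

    ranks: tuple[str, ...]
    confidence: tuple[Optional[float], ...] = (None,) * len(RANKS)

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise FormatError(
                f"lineage must have {len(RANKS)} ranks, got {len(self.ranks)}"
            )
        if len(self.confidence) != len(RANKS):
            raise FormatError("confidence tuple length must match rank count")
        if self.ranks[0] == UNCLASSIFIED:
            raise FormatError("domain rank must be resolved (non-sentinel)")
        for label in self.ranks:
            if "\t" in label or ";" in label or not label:
                raise FormatError(f"illegal characters in rank label {label!r}")
        for c in self.confidence:
            if c is not None and not (0.0 <= c <= 1.0):
                raise FormatError(f"confidence {c} outside [0, 1]")

    @property
    def domain(self) -> str:
        return self.ranks[0]

    @property
    def family(self) -> str:
        return self.ranks[4]

    @property
    def genus(self) -> str:
        return self.ranks[5]

    @property
    def genus_label(self) -> str:
        """Reporting label at genus resolution.

        OTUs whose genus is unresolved fall back to the deepest resolved
        rank marked with ``*`` (e.g. ``Enterobacteriaceae*``), so that taxa
        which cannot be separated at 97% identity still aggregate stably.
        """
        if self.genus != UNCLASSIFIED:
            return self.genus
        for label in reversed(self.ranks[:-1]):
            if label != UNCLASSIFIED:
                return label + "*"
        return self.ranks[0] + "*"

    @classmethod
    def from_string(cls, text: str) -> "TaxonomyLineage":
        """Parse a semicolon-separated lineage cell.

        Accepts mothur-style confidence suffixes, e.g.
        ``Bacteria(100);...;Synechococcus(99);``.  Integer confidences are
        interpreted as percentages; values already in [0, 1] are taken as
        fractions.  Lineages shorter than six ranks are right-padded with
        the sentinel.
        """
        parts = [p.strip() for p in text.strip().rstrip(";").split(";")]
        if parts == [""]:
            raise FormatError("empty lineage cell")
        labels: list[str] = []
        confs: list[Optional[float]] = []
        for part in parts:
            m = _CONF_RE.match(part)
            if m:
                label = m.group("label")
                raw = float(m.group("conf"))
                confs.append(raw / 100.0 if raw > 1.0 else raw)
            else:
                label = part
                confs.append(None)
            labels.append(label if label else UNCLASSIFIED)
        labels = labels[: len(RANKS)]
        confs = confs[: len(RANKS)]
        while len(labels) < len(RANKS):
            labels.append(UNCLASSIFIED)
            confs.append(None)
        return cls(ranks=tuple(labels), confidence=tuple(confs))

    def to_string(self, with_confidence: bool = False) -> str:
        if not with_confidence:
            return ";".join(self.ranks)
        cells = []
        for label, conf in zip(self.ranks, self.confidence):
            if conf is None:
                cells.append(label)
            else:
                cells.append(f"{label}({conf * 100:g})")
        return ";".join(cells)

    @classmethod
    def from_genus(cls, genus: str, family: str = UNCLASSIFIED) -> "TaxonomyLineage":
        """Convenience constructor: a lineage resolved only at genus (and
        optionally family), domain fixed to Bacteria."""
        return cls(
            ranks=("Bacteria", UNCLASSIFIED, UNCLASSIFIED, UNCLASSIFIED, family, genus)
        )


@dataclass(frozen=True)
class OtuObservation:
    """One OTU's read count within a single technical replicate."""

    otu_id: str
    lineage: TaxonomyLineage
    reads: int

    def __post_init__(self) -> None:
        if not isinstance(self.reads, int) or isinstance(self.reads, bool):
            raise FormatError(f"reads must be an integer, got {self.reads!r}")
        if self.reads < 0:
            raise FormatError(f"negative read count {self.reads} for {self.otu_id}")


@dataclass(frozen=True)
class ReplicateProfile:
    """OTU read counts of one technical replicate of one sample."""

    sample_id: str
    replicate_index: int
    observations: tuple[OtuObservation, ...]

    def __post_init__(self) -> None:
        if self.replicate_index not in (1, 2, 3):
            raise FormatError(
                f"replicate_index must be 1..3, got {self.replicate_index}"
            )
        ids = [o.otu_id for o in self.observations]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate otu_id(s) in profile: {', '.join(dupes)}")

    @property
    def total_reads(self) -> int:
        return sum(o.reads for o in self.observations)

    @property
    def counts(self) -> dict[str, int]:
        return {o.otu_id: o.reads for o in self.observations}

    @property
    def lineages(self) -> dict[str, TaxonomyLineage]:
        return {o.otu_id: o.lineage for o in self.observations}


# Comparator records (consumed by the concordance module but parsed here).

VALID_CULTURE_CATEGORIES = ("commensal_flora", "anaerobic_positive", "negative")
VALID_GRADES = ("1+", "2+", "3+", "4+")


@dataclass(frozen=True)
class CultureObservation:
    """One routine-culture finding for one sample.

    ``category`` is ``genus:<Name>`` for a potentially relevant aerobic
    isolate, ``commensal_flora`` for growth judged clinically non-relevant,
    ``anaerobic_positive`` for a positive anaerobic culture, or
    ``negative``.  ``grade`` is the semi-quantitative 1+..4+ plate scale.
    """

    sample_id: str
    category: str
    grade: Optional[str] = None

    def __post_init__(self) -> None:
        if not (
            self.category in VALID_CULTURE_CATEGORIES
            or (self.category.startswith("genus:") and len(self.category) > 6)
        ):
            raise FormatError(f"unknown culture category {self.category!r}")
        if self.grade is not None and self.grade not in VALID_GRADES:
            raise FormatError(f"unknown culture grade {self.grade!r}")

    @property
    def genus(self) -> Optional[str]:
        if self.category.startswith("genus:"):
            return self.category.split(":", 1)[1]
        return None


@dataclass(frozen=True)
class QpcrResult:
    """qPCR comparator measurements for one sample."""

    sample_id: str
    total_16s_copies: float
    saureus_genome_copies: Optional[float] = None

    def __post_init__(self) -> None:
        if self.total_16s_copies < 0:
            raise FormatError("total_16s_copies must be non-negative")
        if self.saureus_genome_copies is not None and self.saureus_genome_copies < 0:
            raise FormatError("saureus_genome_copies must be non-negative")


# ---------------------------------------------------------------------------
# Parsing helpers


def _parse_count(token: str, context: str) -> int:
    """Parse a read count; fractional or non-numeric input is a hard error
    (it signals a corrupted file, not something to round away)."""
    try:
        value = int(token)
    except ValueError:
        try:
            f = float(token)
        except ValueError:
            raise FormatError(f"malformed count {token!r} at {context}") from None
        if f != int(f):
            raise FormatError(f"fractional count {token!r} at {context}") from None
        value = int(f)
    if value < 0:
        raise FormatError(f"negative count {token!r} at {context}")
    return value


_GROUP_RE = re.compile(r"^(?P<sample>.+?)[._-](?:rep)?(?P<rep>[123])$")


def split_group_name(group: str) -> tuple[str, int]:
    """Split a mothur group name into (sample_id, replicate_index).

    Group names like ``S01_2``, ``NEC-1`` or ``PC.rep3`` carry the replicate
    suffix; a bare name is replicate 1.
    """
    m = _GROUP_RE.match(group)
    if m:
        return m.group("sample"), int(m.group("rep"))
    return group, 1


def read_taxonomy_file(path: Union[str, Path]) -> dict[str, TaxonomyLineage]:
    """Read a mothur ``.cons.taxonomy`` file into otu_id -> lineage."""
    path = Path(path)
    lineages: dict[str, TaxonomyLineage] = {}
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty taxonomy file")
        cols = header.split()
        has_header = cols and cols[0].lower() in ("otu", "otu_id", "otulabel")
        rows = fh if has_header else [header] + list(fh)
        for lineno, line in enumerate(rows, start=2 if has_header else 1):
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected otu and taxonomy columns")
            otu_id = fields[0].strip()
            taxonomy_cell = fields[-1].strip()
            lineages[otu_id] = TaxonomyLineage.from_string(taxonomy_cell)
    return lineages


def read_shared_file(
    path: Union[str, Path], taxonomy_path: Union[str, Path]
) -> list[ReplicateProfile]:
    """Read a mothur ``.shared`` OTU table plus its taxonomy file.

    Returns one :class:`ReplicateProfile` per group row.  OTUs with zero
    reads in a group are omitted from that group's profile.  The three meta
    columns (``label``, ``group``, ``numOtus``) are located by name so
    column order and tab/space mixtures are both tolerated.
    """
    path = Path(path)
    lineages = read_taxonomy_file(taxonomy_path)
    profiles: list[ReplicateProfile] = []
    with path.open() as fh:
        header = fh.readline().split()
        if not header:
            raise FormatError(f"{path}: empty shared file")
        lower = [h.lower() for h in header]
        meta = {}
        for name in ("label", "group", "numotus"):
            if name in lower:
                meta[name] = lower.index(name)
        if "group" not in meta:
            raise FormatError(f"{path}: shared header lacks a 'group' column")
        otu_cols = [
            (i, h) for i, h in enumerate(header) if i not in set(meta.values())
        ]
        for otu_id in (h for _, h in otu_cols):
            if otu_id not in lineages:
                raise FormatError(
                    f"{path}: OTU {otu_id!r} missing from taxonomy file"
                )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
                )
            group = fields[meta["group"]]
            sample_id, rep = split_group_name(group)
            observations = []
            for col, otu_id in otu_cols:
                reads = _parse_count(fields[col], f"{path}:{lineno}")
                if reads > 0:
                    observations.append(
                        OtuObservation(otu_id, lineages[otu_id], reads)
                    )
            profiles.append(ReplicateProfile(sample_id, rep, tuple(observations)))
    return profiles


def read_generic_tsv(path: Union[str, Path]) -> ReplicateProfile:
    """Read one replicate from the generic TSV format.

    Columns: ``otu_id``, ``lineage``, ``reads`` (tab-separated, UTF-8).
    Leading ``# key=value`` comment lines may carry ``sample_id`` and
    ``replicate_index``; otherwise they are inferred from the file name
    (``<sample>_<rep>.tsv``).
    """
    path = Path(path)
    sample_id: Optional[str] = None
    replicate_index: Optional[int] = None
    observations: list[OtuObservation] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            m = re.match(r"#\s*(\w+)\s*=\s*(\S+)", line)
            if m:
                key, value = m.groups()
                if key == "sample_id":
                    sample_id = value
                elif key == "replicate_index":
                    replicate_index = int(value)
        else:
            break
    if sample_id is None or replicate_index is None:
        inferred_sample, inferred_rep = split_group_name(path.stem)
        sample_id = sample_id or inferred_sample
        replicate_index = replicate_index or inferred_rep

    body = [l for l in lines[body_start:] if l.strip()]
    if body:
        header = body[0].rstrip("\n").split("\t")
        expected = ["otu_id", "lineage", "reads"]
        if [h.strip().lower() for h in header] != expected:
            raise FormatError(
                f"{path}: expected header {expected}, got {header}"
            )
        for lineno, line in enumerate(body[1:], start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            otu_id, lineage_cell, reads_cell = (f.strip() for f in fields)
            if otu_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate otu_id {otu_id!r}")
            seen.add(otu_id)
            reads = _parse_count(reads_cell, f"{path}:{lineno}")
            observations.append(
                OtuObservation(otu_id, TaxonomyLineage.from_string(lineage_cell), reads)
            )
    return ReplicateProfile(sample_id, replicate_index, tuple(observations))


def write_generic_tsv(profile: ReplicateProfile, path: Union[str, Path]) -> None:
    """Write a replicate profile in the generic TSV format (round-trips
    through :func:`read_generic_tsv`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# sample_id={profile.sample_id}\n")
        fh.write(f"# replicate_index={profile.replicate_index}\n")
        fh.write("otu_id\tlineage\treads\n")
        for obs in profile.observations:
            fh.write(
                f"{obs.otu_id}\t{obs.lineage.to_string(with_confidence=True)}\t{obs.reads}\n"
            )


def read_culture_table(path: Union[str, Path]) -> list[CultureObservation]:
    """Read culture comparator records from CSV.

    Columns: ``sample_id``, ``category``, ``grade``.  A sample may have
    several ``genus:`` rows; the grade ``NA`` (or blank) means no grade.
    """
    path = Path(path)
    records: list[CultureObservation] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "category", "grade"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path}: culture CSV needs columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            grade = (row["grade"] or "").strip()
            records.append(
                CultureObservation(
                    sample_id=row["sample_id"].strip(),
                    category=row["category"].strip(),
                    grade=None if grade in ("", "NA") else grade,
                )
            )
    by_sample: dict[str, list[str]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r.category)
    for sid, cats in by_sample.items():
        if "negative" in cats and len(cats) > 1:
            raise FormatError(
                f"{path}: sample {sid} marked culture-negative but has other rows"
            )
    return records


def read_qpcr_table(path: Union[str, Path]) -> list[QpcrResult]:
    """Read qPCR comparator records from CSV.

    Columns: ``sample_id``, ``total_16s_copies``, optional
    ``saureus_genome_copies`` (blank or NA when the assay was not run).
    """
    path = Path(path)
    records: list[QpcrResult] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "total_16s_copies" not in reader.fieldnames:
            raise FormatError(f"{path}: qPCR CSV needs a total_16s_copies column")
        for row in reader:
            sa = (row.get("saureus_genome_copies") or "").strip()
            records.append(
                QpcrResult(
                    sample_id=row["sample_id"].strip(),
                    total_16s_copies=float(row["total_16s_copies"]),
                    saureus_genome_copies=None if sa in ("", "NA") else float(sa),
                )
            )
    return records
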