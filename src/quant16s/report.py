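"""Archivable single-file HTML report: taxonomy, diversity and QC tabs.

The report is a self-contained static HTML document (no network resources,
no external runtime): a genus-level copy table and a static sunburst
hierarchy on the taxonomy tab, the alpha-diversity summary on the diversity
tab, and the ordered QC trail on the quality-control tab.  The full bundle
is embedded verbatim as machine-readable JSON so the rendered file remains
the complete, parseable record of the analysis.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

from . import __version__ as _version
from .diversity import summarize
from .errors import PipelineError
from .io import TaxonomyLineage, UNCLASSIFIED
from .pipeline import SampleResult, aggregate_by_genus, round_half_up


def build_sunburst(
    copies: Mapping[str, float], lineages: Mapping[str, TaxonomyLineage]
) -> dict:
    """Build the nested rank hierarchy for a static sunburst plot.

    Nodes are keyed by taxonomy ranks down to the deepest resolved rank of
    each OTU; every node's value is the sum of its descendants' copies.
    Children are ordered by copies descending, then name, so output is
    deterministic.  An empty profile yields a flagged empty tree.
    """
    root: dict = {"name": "root", "value": 0.0, "children": []}
    if not copies:
        root["empty"] = True
        root["note"] = "no bacterial DNA detected"
        return root

    def child(node: dict, name: str) -> dict:
        for c in node["children"]:
            if c["name"] == name:
                return c
        c = {"name": name, "value": 0.0, "children": []}
        node["children"].append(c)
        return c

    for otu, value in copies.items():
        lineage = lineages[otu]
        labels = [r for r in lineage.ranks if r != UNCLASSIFIED]
        if not labels:
            labels = [lineage.ranks[0]]
        node = root
        root["value"] += value
        for label in labels:
            node = child(node, label)
            node["value"] += value

    def sort_tree(node: dict) -> None:
        node["children"].sort(key=lambda c: (-c["value"], c["name"]))
        for c in node["children"]:
            sort_tree(c)

    sort_tree(root)
    return root


@dataclass
class ReportBundle:
    """Everything one report renders, as a JSON-serializable document."""

    sample_id: str
    genus_table: list[dict]          # {genus, copies, copies_int}
    sunburst: dict
    diversity: Optional[dict]        # DiversitySummary dict, None if empty
    qc: list[dict]                   # ordered QcRecord dicts
    config: Optional[dict]
    version: str = _version
    schema_version: int = 1
    timestamp: Optional[str] = None  # pinnable; omitted by default

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "sample_id": self.sample_id,
            "genus_table": self.genus_table,
            "sunburst": self.sunburst,
            "diversity": self.diversity,
            "qc": self.qc,
            "config": self.config,
            "version": self.version,
            "timestamp": self.timestamp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReportBundle":
        return cls(
            sample_id=d["sample_id"],
            genus_table=d["genus_table"],
            sunburst=d["sunburst"],
            diversity=d["diversity"],
            qc=d["qc"],
            config=d["config"],
            version=d["version"],
            schema_version=d["schema_version"],
            timestamp=d.get("timestamp"),
        )

    @property
    def total_copies(self) -> float:
        return sum(row["copies"] for row in self.genus_table)


def build_report_bundle(
    result: SampleResult, timestamp: Optional[str] = None
) -> ReportBundle:
    """Assemble the report bundle from a finished :class:`SampleResult`.

    Diversity is computed on the integer-rounded consensus copies (the
    community the report presents); an empty result yields a flagged empty
    taxonomy tree and no diversity summary.
    """
    genus_copies = aggregate_by_genus(result.consensus_copies, result.lineages)
    genus_table = [
        {"genus": g, "copies": c, "copies_int": round_half_up(c)}
        for g, c in sorted(genus_copies.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    rounded = {
        otu: round_half_up(c)
        for otu, c in result.consensus_copies.items()
        if round_half_up(c) > 0
    }
    diversity = None
    if rounded and sum(rounded.values()) >= 2:
        diversity = summarize(rounded).to_dict()
    return ReportBundle(
        sample_id=result.sample_id,
        genus_table=genus_table,
        sunburst=build_sunburst(result.consensus_copies, result.lineages),
        diversity=diversity,
        qc=[r.to_dict() for r in result.qc],
        config=result.config.to_dict() if result.config else None,
        timestamp=timestamp,
    )


_CSS = """
body { font-family: sans-serif; margin: 1.5em; color: #222; }
h1 { font-size: 1.3em; }
table { border-collapse: collapse; margin: 0.8em 0; }
th, td { border: 1px solid #bbb; padding: 0.3em 0.7em; text-align: left; }
th { background: #eef; }
.tabs input[type=radio] { display: none; }
.tabs label { display: inline-block; padding: 0.4em 1em; border: 1px solid #99a;
  border-bottom: none; cursor: pointer; background: #dde; border-radius: 4px 4px 0 0; }
.tabs .panel { display: none; border: 1px solid #99a; padding: 1em; }
#tab1:checked ~ .panel-1, #tab2:checked ~ .panel-2, #tab3:checked ~ .panel-3 { display: block; }
#tab1:checked ~ label[for=tab1], #tab2:checked ~ label[for=tab2],
#tab3:checked ~ label[for=tab3] { background: #fff; font-weight: bold; }
ul.sunburst { list-style: none; }
.note { color: #a33; font-weight: bold; }
.muted { color: #666; font-size: 0.9em; }
"""


def _sunburst_html(node: dict, depth: int = 0) -> str:
    if node.get("empty"):
        return '<p class="note">No bacterial DNA detected.</p>'
    label = html.escape(str(node["name"]))
    value = round_half_up(node["value"])
    out = f"<li><b>{label}</b> — {value} copies"
    if node["children"]:
        out += '<ul class="sunburst">'
        out += "".join(_sunburst_html(c, depth + 1) for c in node["children"])
        out += "</ul>"
    return out + "</li>"


def render_report(bundle: ReportBundle, out_path: Union[str, Path]) -> Path:
    """Render the bundle to one self-contained HTML file.

    Output is deterministic for an identical bundle (the timestamp is a
    bundle field, pinnable or omitted).  The bundle JSON is embedded in a
    ``<script type="application/json" id="bundle-data">`` block so the
    report round-trips back into a :class:`ReportBundle`.
    """
    out_path = Path(out_path)
    empty = not bundle.genus_table

    genus_rows = "".join(
        f"<tr><td>{html.escape(row['genus'])}</td>"
        f"<td>{row['copies_int']}</td></tr>"
        for row in bundle.genus_table
    )
    taxonomy_tab = (
        '<p class="note">No 16S rRNA gene copies detected in this sample '
        "after contamination subtraction and the detection limit.</p>"
        if empty
        else (
            "<table><tr><th>Genus</th><th>16S rRNA gene copies</th></tr>"
            f"{genus_rows}</table>"
            '<h3>Taxonomic hierarchy</h3><ul class="sunburst">'
            f"{_sunburst_html(bundle.sunburst)}</ul>"
        )
    )

    if bundle.diversity:
        d = bundle.diversity
        diversity_tab = (
            "<table><tr><th>Index</th><th>Value</th></tr>"
            f"<tr><td>Observed OTUs</td><td>{d['sobs']}</td></tr>"
            f"<tr><td>Chao1</td><td>{d['chao1']:.4f}</td></tr>"
            f"<tr><td>Shannon (ln)</td><td>{d['shannon']:.4f}</td></tr>"
            f"<tr><td>Simpson dominance</td><td>{d['simpson']:.4f}</td></tr>"
            f"<tr><td>Simpson diversity (1-D)</td><td>{d['simpson_complement']:.4f}</td></tr>"
            "</table>"
        )
    else:
        diversity_tab = '<p class="note">Diversity undefined: no OTUs detected.</p>'

    qc_rows = "".join(
        f"<tr><td>{i}</td><td>{html.escape(r['stage'])}</td>"
        f"<td>{r['units_in']}</td><td>{r['units_out']}</td>"
        f"<td>{html.escape(r['detail'])}</td></tr>"
        for i, r in enumerate(bundle.qc, start=1)
    )
    qc_tab = (
        "<table><tr><th>#</th><th>Stage</th><th>Units in</th>"
        f"<th>Units out</th><th>Detail</th></tr>{qc_rows}</table>"
        if bundle.qc
        else "<p>No QC records.</p>"
    )

    bundle_json = json.dumps(bundle.to_dict(), sort_keys=True)
    meta = f"quant16s {html.escape(bundle.version)}"
    if bundle.timestamp:
        meta += f" — {html.escape(bundle.timestamp)}"

    doc = f"""<!DOCTYPE html>
<html lang="en"><head><meta charset="utf-8">
<title>Microbiota report — {html.escape(bundle.sample_id)}</title>
<style>{_CSS}</style></head>
<body>
<h1>Quantitative microbiota report: {html.escape(bundle.sample_id)}</h1>
<p class="muted">{meta}. Copy numbers are absolute 16S rRNA gene copies per
extract, calibrated against the internal spike-in, contamination-corrected
and filtered at the detection limit. Displayed copies are rounded; exact
values are in the embedded JSON.</p>
<div class="tabs">
<input type="radio" name="tabs" id="tab1" checked>
<input type="radio" name="tabs" id="tab2">
<input type="radio" name="tabs" id="tab3">
<label for="tab1">Taxonomy</label>
<label for="tab2">Diversity</label>
<label for="tab3">Quality control</label>
<div class="panel panel-1"><h2>Taxonomy</h2>{taxonomy_tab}</div>
<div class="panel panel-2"><h2>Diversity</h2>{diversity_tab}</div>
<div class="panel panel-3"><h2>Quality control</h2>{qc_tab}</div>
</div>
<script type="application/json" id="bundle-data">{bundle_json}</script>
</body></html>
"""
    try:
        out_path.write_text(doc, encoding="utf-8")
    except OSError as exc:
        raise PipelineError(f"cannot write report to {out_path}: {exc}") from exc
    return out_path


def parse_report(path: Union[str, Path]) -> ReportBundle:
    """Recover the bundle from a rendered report's embedded JSON block."""
    text = Path(path).read_text(encoding="utf-8")
    marker = '<script type="application/json" id="bundle-data">'
    start = text.index(marker) + len(marker)
    end = text.index("</script>", start)
    return ReportBundle.from_dict(json.loads(text[start:end]))
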