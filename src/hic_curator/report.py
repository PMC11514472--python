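"""Assembly QC report: contiguity statistics, quality ratios, JSON + HTML.

The four-section report mirrors standard curation summaries: (1) summary
statistics of the corrected assembly, (2) the adjusting result with the
global contact images before and after correction, (3) the error adjustment
gallery with up to five exhibits per error category, (4) additional
information with per-iteration error counts and chromosome length
proportions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import jinja2

from .errors import ParameterError

NX_FRACTIONS = (10, 30, 50, 70, 90)

REPORT_SCHEMA_VERSION = 1


def contiguity_stats(lengths: Sequence[int]) -> dict[str, int]:
    """Nx/Lx table for x in {10, 30, 50, 70, 90}.

    Nx is the length of the smallest piece in the minimal descending-sorted
    prefix whose sum reaches x% of the total; Lx is that prefix's size.
    """
    if not lengths:
        raise ParameterError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ParameterError("lengths must be positive")
    srt = sorted(lengths, reverse=True)
    total = sum(srt)
    out: dict[str, int] = {}
    for x in NX_FRACTIONS:
        threshold = total * x / 100.0
        acc = 0
        for i, ln in enumerate(srt, start=1):
            acc += ln
            if acc >= threshold:
                out[f"N{x}"] = ln
                out[f"L{x}"] = i
                break
    return out


def gc_content(sequences: Mapping[str, str] | Sequence[str]) -> float:
    """GC fraction over unambiguous ACGT bases only."""
    seqs = sequences.values() if isinstance(sequences, Mapping) else sequences
    gc = total = 0
    for seq in seqs:
        up = seq.upper()
        gc += up.count("G") + up.count("C")
        total += sum(up.count(b) for b in "ACGT")
    if total == 0:
        raise ParameterError("no unambiguous bases")
    return gc / total


@dataclass
class QualityRatios:
    """Scaffold/chromosome agreement and structural error rates.

    The primary rates share one denominator (the corrected genome length,
    redundant sequence excluded) so that ``r_error`` decomposes exactly into
    ``r_translocation + r_inversion``; the variants computed against the
    uncorrected genome size are reported separately with their denominator
    labelled.
    """

    n_scaffolds: int
    n_chromosomes: int
    cc_ratio: float
    r_error: float
    r_translocation: float
    r_inversion: float
    anchor_rate_pct: float
    denominator_bp: int
    r_translocation_uncorrected: float | None = None
    r_inversion_uncorrected: float | None = None
    uncorrected_denominator_bp: int | None = None


def quality_ratios(
    n_scaffolds: int,
    n_chromosomes: int,
    translocation_lengths: Sequence[int],
    inversion_lengths: Sequence[int],
    genome_length: int,
    l_contig: int,
    uncorrected_length: int | None = None,
) -> QualityRatios:
    """CC ratio, structural error rates and the Hi-C anchor rate.

    ``cc_ratio = n_scaffolds / n_chromosomes``; ``r_error`` is the summed
    translocation and inversion length divided by ``genome_length``; the
    anchor rate is ``l_contig / genome_length * 100``.
    """
    if n_chromosomes <= 0:
        raise ParameterError("n_chromosomes must be positive")
    if genome_length <= 0:
        raise ParameterError("genome_length must be positive")
    t_sum = sum(translocation_lengths)
    i_sum = sum(inversion_lengths)
    out = QualityRatios(
        n_scaffolds=n_scaffolds,
        n_chromosomes=n_chromosomes,
        cc_ratio=n_scaffolds / n_chromosomes,
        r_error=(t_sum + i_sum) / genome_length,
        r_translocation=t_sum / genome_length,
        r_inversion=i_sum / genome_length,
        anchor_rate_pct=l_contig / genome_length * 100.0,
        denominator_bp=genome_length,
    )
    if uncorrected_length:
        out.r_translocation_uncorrected = t_sum / uncorrected_length
        out.r_inversion_uncorrected = i_sum / uncorrected_length
        out.uncorrected_denominator_bp = uncorrected_length
    return out


@dataclass
class Exhibit:
    """One displayed error instance: its call plus an optional image path."""

    category: str
    x_start: int
    x_end: int
    length: int
    score: float
    image: str | None = None


@dataclass
class ReportData:
    """Everything the renderer needs; serialises losslessly to JSON."""

    schema_version: int
    summary: dict
    adjusting: dict  # {"before_image": path|None, "after_image": path|None}
    exhibits: dict[str, list[dict]]  # category -> up to five exhibit dicts
    additional: dict  # per-iteration counts, chromosome proportions, ...


MAX_EXHIBITS = 5

_TEMPLATE = jinja2.Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Assembly curation report</title>
<style>
 body { font-family: sans-serif; margin: 2em; }
 section { margin-bottom: 2em; }
 table { border-collapse: collapse; }
 td, th { border: 1px solid #999; padding: 0.3em 0.8em; }
 .warn { color: #b00; }
 img { max-width: 45%; }
</style></head><body>
<h1>Assembly curation report</h1>

<section><h2>1. Summary</h2>
<table>
{% for key, value in data.summary.items() %}
 <tr><th>{{ key }}</th><td>{{ value }}</td></tr>
{% endfor %}
</table></section>

<section><h2>2. Adjusting result</h2>
{% for label, img in [("before", data.adjusting.get("before_image")),
                      ("after", data.adjusting.get("after_image"))] %}
 {% if img %}<figure><img src="{{ img }}" alt="{{ label }}"><figcaption>{{ label }} correction</figcaption></figure>
 {% else %}<p class="warn">missing {{ label }}-correction image</p>{% endif %}
{% endfor %}
</section>

<section><h2>3. Error adjustment</h2>
{% for category, items in data.exhibits.items() %}
 <h3>{{ category }} ({{ items|length }})</h3>
 {% if items %}
 <table><tr><th>start</th><th>end</th><th>length</th><th>score</th></tr>
 {% for ex in items %}
  <tr><td>{{ ex.x_start }}</td><td>{{ ex.x_end }}</td><td>{{ ex.length }}</td><td>{{ ex.score }}</td></tr>
 {% endfor %}
 </table>
 {% else %}<p>none detected</p>{% endif %}
{% endfor %}
</section>

<section><h2>4. Additional information</h2>
<h3>Errors per iteration</h3>
<table><tr><th>iteration</th><th>translocation</th><th>inversion</th><th>debris</th></tr>
{% for row in data.additional.get("iteration_counts", []) %}
 <tr><td>{{ row.iteration }}</td><td>{{ row.translocation }}</td><td>{{ row.inversion }}</td><td>{{ row.debris }}</td></tr>
{% endfor %}
</table>
<h3>Chromosome length proportions</h3>
<table><tr><th>name</th><th>proportion</th></tr>
{% for name, frac in data.additional.get("chromosome_proportions", {}).items() %}
 <tr><td>{{ name }}</td><td>{{ "%.4f"|format(frac) }}</td></tr>
{% endfor %}
</table>
</section>
</body></html>
"""
)


def build_report_data(
    metrics: Mapping,
    calls: Sequence = (),
    iteration_counts: Sequence[Mapping] = (),
    chromosome_proportions: Mapping[str, float] | None = None,
    before_image: str | None = None,
    after_image: str | None = None,
) -> ReportData:
    """Assemble the four report sections from computed pieces.

    ``calls`` supplies the error-adjustment gallery; the five longest calls
    per category are exhibited (all of them when fewer than five exist).
    """
    exhibits: dict[str, list[dict]] = {"translocation": [], "inversion": [], "debris": []}
    for category in exhibits:
        cat_calls = sorted(
            (c for c in calls if c.category == category),
            key=lambda c: c.x_end - c.x_start,
            reverse=True,
        )[:MAX_EXHIBITS]
        exhibits[category] = [
            asdict(
                Exhibit(
                    category=c.category,
                    x_start=c.x_start,
                    x_end=c.x_end,
                    length=c.x_end - c.x_start,
                    score=c.score,
                )
            )
            for c in cat_calls
        ]
    return ReportData(
        schema_version=REPORT_SCHEMA_VERSION,
        summary=dict(metrics),
        adjusting={"before_image": before_image, "after_image": after_image},
        exhibits=exhibits,
        additional={
            "iteration_counts": [dict(r) for r in iteration_counts],
            "chromosome_proportions": dict(chromosome_proportions or {}),
        },
    )


def render_json(data: ReportData) -> str:
    return json.dumps(asdict(data), indent=1, sort_keys=True)


def parse_json(text: str) -> ReportData:
    raw = json.loads(text)
    return ReportData(**raw)


def render_html(data: ReportData) -> str:
    return _TEMPLATE.render(data=data)


def render_report(data: ReportData, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.json`` and ``<prefix>.html``; returns both paths."""
    out_prefix = Path(out_prefix)
    json_path = out_prefix.with_suffix(".json")
    html_path = out_prefix.with_suffix(".html")
    json_path.write_text(render_json(data))
    html_path.write_text(render_html(data))
    return json_path, html_path
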