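"""Synthetic misassembled genomes with matched Hi-C contact maps.

The generator emulates the conditions a curation pipeline faces: contigs are
cut into 10–50 kb pieces, 60% of the pieces are randomly moved (translocation)
or flipped in place (inversion), and a distance-decay contact matrix is built
whose bin permutation carries the corresponding off-diagonal band and
"butterfly" signatures. Expected contacts follow the standard power law

    E[c(p, q)] = s0 * (1 + d(p, q))^(-alpha)

where ``d`` is the separation in bins between the TRUE genomic positions of
the two bins, attenuated by a constant factor for between-chromosome pairs;
optional Poisson sampling adds counting noise. The ground-truth record powers
an oracle detector so the whole detect→correct→assign loop is testable
without a trained model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .assembly_model import AssemblyDoc, Fragment, parse_provenance
from .contact_store import ContactStore, Tile, n_bins
from .detection import Box
from .errors import ParameterError

DEFAULT_PIECE_RANGE = (10_000, 50_000)
DEFAULT_SHUFFLE_FRAC = 0.6


@dataclass
class ContactModel:
    """Distance-decay contact model parameters."""

    alpha: float = 1.0
    s0: float = 100.0
    noise: str = "none"  # none | poisson
    inter_chromosome: float = 0.1
    debris_factor: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0 or self.s0 <= 0:
            raise ParameterError("alpha and s0 must be positive")
        if self.noise not in ("none", "poisson"):
            raise ParameterError(f"unknown noise mode {self.noise!r}")


@dataclass(frozen=True)
class Event:
    """One planted misassembly, in final (shuffled) assembly coordinates."""

    category: str
    start: int
    end: int
    insertion: int | None = None  # true insertion boundary, translocations only
    fragment_name: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GroundTruth:
    """Simulator record: events, true layout and coordinate frame."""

    events: list[Event]
    doc: AssemblyDoc
    contig_lengths: dict[str, int]
    original_layout: list[int]  # signed ids of doc fragments in true order
    chromosome_spans: list[tuple[int, int]]  # true genomic contig spans

    @property
    def genome_length(self) -> int:
        return sum(self.contig_lengths.values())

    def bin_permutation(self, resolution: int) -> np.ndarray:
        """Rank permutation of assembly bins by true genomic position."""
        tp, _ = bin_true_positions(self.doc, self.contig_lengths, resolution)
        return np.argsort(np.argsort(tp, kind="stable"), kind="stable")


def contig_offsets(contig_lengths: Mapping[str, int]) -> dict[str, int]:
    """True genomic offset of each contig under concatenation in given order."""
    out, pos = {}, 0
    for name, ln in contig_lengths.items():
        out[name] = pos
        pos += ln
    return out


def make_genome(
    n_contigs: int = 3,
    length_range: tuple[int, int] = (100_000, 200_000),
    gc: float = 0.5,
    seed: int | None = None,
) -> tuple[dict[str, str], AssemblyDoc]:
    """Random contigs plus the matching single-scaffold assembly document."""
    if n_contigs <= 0:
        raise ParameterError("n_contigs must be positive")
    lo, hi = length_range
    if not 0 < lo <= hi:
        raise ParameterError("invalid length range")
    if not 0.0 <= gc <= 1.0:
        raise ParameterError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    contigs: dict[str, str] = {}
    fragments: list[Fragment] = []
    for i in range(n_contigs):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list("AGCT"), size=length, p=p))
        name = f"contig_{i + 1}"
        contigs[name] = seq
        fragments.append(Fragment(f"{name}:0-{length}", i + 1, length))
    doc = AssemblyDoc(fragments, [[f.id for f in fragments]])
    return contigs, doc


def fragment_and_shuffle(
    doc: AssemblyDoc,
    contig_lengths: Mapping[str, int] | None = None,
    piece_range: tuple[int, int] = DEFAULT_PIECE_RANGE,
    shuffle_frac: float = DEFAULT_SHUFFLE_FRAC,
    seed: int | None = None,
    n_events: int | None = None,
    categories: Sequence[str] = ("translocation", "inversion"),
) -> tuple[AssemblyDoc, GroundTruth]:
    """Cut contigs into pieces and randomly displace or flip a fraction of them.

    Piece lengths are uniform in ``piece_range`` (the last piece of each
    contig may be shorter). ``round(shuffle_frac * n_pieces)`` pieces are
    drawn without replacement; each independently receives one operation
    chosen equiprobably from ``categories``: moved to a uniformly chosen
    foreign boundary (translocation), sign-flipped in place (inversion), or
    marked as signal dropout (debris, left in place).
    """
    if not 0.0 <= shuffle_frac <= 1.0:
        raise ParameterError("shuffle_frac must lie in [0, 1]")
    lo, hi = piece_range
    if not 0 < lo <= hi:
        raise ParameterError("invalid piece range")
    rng = np.random.default_rng(seed)

    # 1. cut every fragment of the input document into pieces (true order)
    pieces: list[tuple[str, int]] = []  # (provenance name, length)
    for row in doc.layout:
        for sid in row:
            if sid < 0:
                raise ParameterError("input document must be all forward-oriented")
            frag = doc.fragment_by_id(sid)
            contig, a, b = parse_provenance(frag.name)
            pos = a
            while pos < b:
                ln = min(int(rng.integers(lo, hi + 1)), b - pos)
                pieces.append((f"{contig}:{pos}-{pos + ln}", ln))
                pos += ln
    n = len(pieces)
    k = int(n_events) if n_events is not None else round(shuffle_frac * n)
    if k > n:
        raise ParameterError(f"cannot plant {k} events with only {n} pieces")
    selected = rng.choice(n, size=k, replace=False)
    ops = {int(j): str(rng.choice(list(categories))) for j in selected}

    # 2. build the shuffled layout in piece-index space
    order = list(range(n))
    signs = {j: 1 for j in range(n)}
    for j, op in ops.items():
        if op == "inversion":
            signs[j] = -1
        elif op == "translocation":
            p = order.index(j)
            order.pop(p)
            slots = [s for s in range(len(order) + 1) if s != p]
            order.insert(int(rng.choice(slots)), j)
        elif op == "debris":
            pass
        else:
            raise ParameterError(f"unknown event category {op!r}")

    fragments = [Fragment(name, i + 1, ln) for i, (name, ln) in enumerate(pieces)]
    layout = [[signs[j] * (j + 1) for j in order]]
    shuffled = AssemblyDoc(fragments, layout)

    # 3. final assembly coordinates of every piece
    start_of: dict[int, int] = {}
    pos = 0
    for j in order:
        start_of[j] = pos
        pos += pieces[j][1]

    events: list[Event] = []
    for j, op in sorted(ops.items()):
        s = start_of[j]
        e = s + pieces[j][1]
        insertion = None
        if op == "translocation":
            if j > 0:
                insertion = start_of[j - 1] + pieces[j - 1][1]
            else:
                insertion = start_of[j + 1]
        events.append(Event(op, s, e, insertion, pieces[j][0]))
    events.sort(key=lambda ev: ev.start)

    if contig_lengths is None:
        contig_lengths = {}
        for row in doc.layout:
            for sid in row:
                contig, a, b = parse_provenance(doc.fragment_by_id(sid).name)
                contig_lengths[contig] = contig_lengths.get(contig, 0) + (b - a)
    spans, off = [], 0
    for ln in contig_lengths.values():
        spans.append((off, off + ln))
        off += ln
    truth = GroundTruth(
        events=events,
        doc=shuffled,
        contig_lengths=dict(contig_lengths),
        original_layout=[i + 1 for i in range(n)],
        chromosome_spans=spans,
    )
    return shuffled, truth


# ---------------------------------------------------------------------------
# Contact-map synthesis


def bin_true_positions(
    doc: AssemblyDoc,
    contig_lengths: Mapping[str, int],
    resolution: int,
) -> tuple[np.ndarray, np.ndarray]:
    """True genomic position and chromosome id of each assembly bin's centre."""
    L = doc.total_length
    offsets = contig_offsets(contig_lengths)
    chrom_index = {name: i for i, name in enumerate(contig_lengths)}
    nb = n_bins(L, resolution)
    centers = np.minimum(np.arange(nb) * resolution + resolution // 2, L - 1)
    tp = np.empty(nb, dtype=np.int64)
    chrom = np.empty(nb, dtype=np.int64)
    for si, ei, sid, start, end in doc.entries():
        mask = (centers >= start) & (centers < end)
        if not mask.any():
            continue
        frag = doc.fragment_by_id(abs(sid))
        contig, a, b = parse_provenance(frag.name)
        t = centers[mask] - start
        tp[mask] = offsets[contig] + (a + t if sid > 0 else (b - 1) - t)
        chrom[mask] = chrom_index[contig]
    return tp, chrom


def synth_contact_map(
    truth_or_doc: GroundTruth | AssemblyDoc,
    resolutions: Sequence[int],
    model: ContactModel | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> ContactStore:
    """Build a multi-resolution distance-decay contact store for an assembly.

    Given a :class:`GroundTruth`, debris events additionally attenuate their
    rows/columns by ``model.debris_factor`` (signal dropout).
    """
    model = model or ContactModel()
    if isinstance(truth_or_doc, GroundTruth):
        doc = truth_or_doc.doc
        contig_lengths = truth_or_doc.contig_lengths
        debris = [
            (ev.start, ev.end)
            for ev in truth_or_doc.events
            if ev.category == "debris"
        ]
    else:
        doc = truth_or_doc
        if contig_lengths is None:
            raise ParameterError("contig_lengths required when passing a bare document")
        debris = []
    L = doc.total_length
    resolutions = sorted(int(r) for r in resolutions)
    if n_bins(L, resolutions[-1]) < 10:
        raise ParameterError("coarsest resolution yields fewer than 10 bins")
    matrices = {}
    for res in resolutions:
        tp, chrom = bin_true_positions(doc, contig_lengths, res)
        d = np.abs(tp[:, None] - tp[None, :]) / res
        mat = model.s0 * np.power(1.0 + d, -model.alpha)
        inter = chrom[:, None] != chrom[None, :]
        mat[inter] *= model.inter_chromosome
        if debris:
            centers = np.minimum(np.arange(len(tp)) * res + res // 2, L - 1)
            drop = np.zeros(len(tp), dtype=bool)
            for s, e in debris:
                drop |= (centers >= s) & (centers < e)
            mat[drop, :] *= model.debris_factor
            mat[:, drop] *= model.debris_factor
        if model.noise == "poisson":
            rng = np.random.default_rng([model.seed, res])
            upper = rng.poisson(np.triu(mat)).astype(np.float64)
            mat = upper + np.triu(upper, 1).T
        matrices[res] = mat
    return ContactStore(L, matrices)


class SyntheticMapProvider:
    """Regenerates a contact store from any edited assembly document.

    Fulfils the ``map_provider`` contract of the iterative correction loop:
    the provenance carried in fragment names fixes every bin's true genomic
    position, so the map after an edit is exactly the map a re-alignment
    would have produced under the same contact model.
    """

    def __init__(
        self,
        contig_lengths: Mapping[str, int],
        resolutions: Sequence[int],
        model: ContactModel | None = None,
    ):
        self.contig_lengths = dict(contig_lengths)
        self.resolutions = [int(r) for r in resolutions]
        self.model = model or ContactModel()

    def __call__(self, doc: AssemblyDoc) -> ContactStore:
        return synth_contact_map(
            doc, self.resolutions, self.model, contig_lengths=self.contig_lengths
        )


# ---------------------------------------------------------------------------
# Oracle detector


def _genome_interval_to_pixels(
    s: int, e: int, win_start: int, win_end: int, n_px: int
) -> tuple[float, float] | None:
    """Exact inverse of the pixel→genome interpolation, clipped to the tile."""
    cs, ce = max(s, win_start), min(e, win_end)
    if cs >= ce:
        return None
    scale = n_px / (win_end - win_start)
    # clamp against float round-off at the tile's far edge
    return (
        max(0.0, (cs - win_start) * scale),
        min(float(n_px), (ce - win_start) * scale),
    )


def oracle_detect(
    tile: Tile,
    events: Sequence[Event],
    chromosome_spans: Sequence[tuple[int, int]] = (),
) -> list[Box]:
    """Emit one perfect box per event (and chromosome span) visible in the tile."""
    boxes: list[Box] = []
    for ev in events:
        px = _genome_interval_to_pixels(ev.start, ev.end, tile.x_start, tile.x_end, tile.width)
        py = _genome_interval_to_pixels(ev.start, ev.end, tile.y_start, tile.y_end, tile.height)
        if px is None or py is None:
            continue
        boxes.append(Box(ev.category, px[0], py[0], px[1], py[1], score=1.0))
    for s, e in chromosome_spans:
        px = _genome_interval_to_pixels(s, e, tile.x_start, tile.x_end, tile.width)
        py = _genome_interval_to_pixels(s, e, tile.y_start, tile.y_end, tile.height)
        if px is None or py is None:
            continue
        boxes.append(Box("chromosome", px[0], py[0], px[1], py[1], score=1.0))
    return boxes


def _longest_increasing(values: Sequence[float], eligible: Sequence[bool]) -> set[int]:
    """Indices of one longest strictly-increasing subsequence over eligible slots."""
    n = len(values)
    best_len = [0] * n
    prev = [-1] * n
    for i in range(n):
        if not eligible[i]:
            continue
        best_len[i] = 1
        for j in range(i):
            if eligible[j] and values[j] < values[i] and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    if not any(best_len):
        return set()
    i = max(range(n), key=lambda x: best_len[x])
    out = set()
    while i != -1:
        out.add(i)
        i = prev[i]
    return out


def diff_events(
    doc: AssemblyDoc,
    contig_lengths: Mapping[str, int],
) -> list[Event]:
    """Misassembly events implied by comparing a document to the true genome.

    Fragments are anchored by the longest strictly-increasing subsequence of
    true start positions over forward-oriented entries; every non-anchor
    fragment is an error: an inversion when only its orientation is wrong
    (its position fits between the neighbouring anchors), otherwise a
    translocation. Adjacent error fragments that are contiguous in true
    coordinates collapse into a single event.
    """
    offsets = contig_offsets(contig_lengths)
    recs = []  # (assembly start, end, true start, true end, forward?, name)
    for si, ei, sid, start, end in doc.entries():
        frag = doc.fragment_by_id(abs(sid))
        contig, a, b = parse_provenance(frag.name)
        recs.append(
            (start, end, offsets[contig] + a, offsets[contig] + b, sid > 0, frag.name)
        )
    anchors = _longest_increasing([r[2] for r in recs], [r[4] for r in recs])

    events: list[Event] = []
    for i, (s, e, ts, te, fwd, name) in enumerate(recs):
        if i in anchors:
            continue
        lo = max((recs[j][3] for j in anchors if j < i), default=0)
        hi = min((recs[j][2] for j in anchors if j > i), default=None)
        in_position = ts >= lo and (hi is None or te <= hi)
        cat = "inversion" if (not fwd and in_position) else "translocation"
        events.append(Event(cat, s, e, None, name))

    # collapse assembly-adjacent, true-contiguous error fragments
    merged: list[Event] = []
    for ev in sorted(events, key=lambda ev: ev.start):
        if merged and merged[-1].category == ev.category and merged[-1].end == ev.start:
            last = merged[-1]
            merged[-1] = Event(last.category, last.start, ev.end, None, last.fragment_name)
        else:
            merged.append(ev)
    return merged


def chromosome_runs(doc: AssemblyDoc, contig_lengths: Mapping[str, int]) -> list[tuple[int, int]]:
    """Maximal same-contig runs along the assembly axis (territory spans)."""
    runs: list[tuple[int, int, str]] = []
    for si, ei, sid, start, end in doc.entries():
        contig, _a, _b = parse_provenance(doc.fragment_by_id(abs(sid)).name)
        if runs and runs[-1][2] == contig and runs[-1][1] == start:
            runs[-1] = (runs[-1][0], end, contig)
        else:
            runs.append((start, end, contig))
    return [(s, e) for s, e, _c in runs]


class OracleDetector:
    """Ground-truth-backed detector fulfilling the Detector contract.

    Emits perfect boxes for every misassembly (and chromosome territory)
    visible in a tile. ``refresh`` re-derives the event list from the current
    document, so the detector stays truthful across correction iterations.
    """

    def __init__(self, truth: GroundTruth):
        self.contig_lengths = dict(truth.contig_lengths)
        self.events: list[Event] = list(truth.events)
        self.spans: list[tuple[int, int]] = chromosome_runs(truth.doc, self.contig_lengths)

    @classmethod
    def from_state(
        cls,
        events: Sequence[Event],
        spans: Sequence[tuple[int, int]],
        contig_lengths: Mapping[str, int],
    ) -> "OracleDetector":
        out = cls.__new__(cls)
        out.contig_lengths = dict(contig_lengths)
        out.events = list(events)
        out.spans = [tuple(s) for s in spans]
        return out

    def refresh(self, doc: AssemblyDoc) -> None:
        self.events = diff_events(doc, self.contig_lengths)
        self.spans = chromosome_runs(doc, self.contig_lengths)

    def __call__(self, tile: Tile) -> list[Box]:
        return oracle_detect(tile, self.events, self.spans)


# ---------------------------------------------------------------------------
# Ground-truth (de)serialisation for the CLI


def truth_to_json(truth: GroundTruth) -> str:
    import json

    return json.dumps(
        {
            "events": [
                {
                    "category": ev.category,
                    "start": ev.start,
                    "end": ev.end,
                    "insertion": ev.insertion,
                    "fragment_name": ev.fragment_name,
                }
                for ev in truth.events
            ],
            "contig_lengths": truth.contig_lengths,
            "chromosome_spans": truth.chromosome_spans,
            "original_layout": truth.original_layout,
        },
        indent=1,
    )


def truth_from_json(text: str, doc: AssemblyDoc) -> GroundTruth:
    import json

    raw = json.loads(text)
    return GroundTruth(
        events=[Event(**ev) for ev in raw["events"]],
        doc=doc,
        contig_lengths={k: int(v) for k, v in raw["contig_lengths"].items()},
        original_layout=[int(i) for i in raw["original_layout"]],
        chromosome_spans=[tuple(s) for s in raw["chromosome_spans"]],
    )
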