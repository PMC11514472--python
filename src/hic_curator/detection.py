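"""Detector contract, pixel→genome coordinate mapping and call bookkeeping.

A detector is any callable that maps a rendered :class:`~hic_curator.contact_store.Tile`
to bounding boxes in that tile's pixel space. Boxes are converted to genomic
error calls by linear interpolation between the tile's genomic footprint and
its pixel dimensions; equal pixel and genomic spans make the map exact.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Protocol, Sequence, runtime_checkable

import pandas as pd

from .contact_store import Tile
from .errors import ParameterError

CATEGORIES = ("translocation", "inversion", "debris", "chromosome")


@dataclass(frozen=True)
class Box:
    """Detector output in tile pixel space (top-left origin, corner encoded)."""

    category: str
    x1: float
    y1: float
    x2: float
    y2: float
    score: float = 1.0

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ParameterError(f"unknown category {self.category!r}")
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ParameterError("box corners must satisfy x1<x2 and y1<y2")
        if not 0.0 <= self.score <= 1.0:
            raise ParameterError("score must lie in [0, 1]")

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)


@dataclass
class ErrorCall:
    """A detector box mapped onto the genome.

    Correction acts on the x-axis interval; the y-axis interval is kept for
    diagnostics.
    """

    category: str
    x_start: int
    x_end: int
    y_start: int
    y_end: int
    resolution: int
    score: float
    tile_id: str = ""
    status: str = "pending"  # pending | corrected | skipped

    @property
    def length(self) -> int:
        return self.x_end - self.x_start

    @property
    def rect_area(self) -> int:
        return (self.x_end - self.x_start) * (self.y_end - self.y_start)


@runtime_checkable
class Detector(Protocol):
    def __call__(self, tile: Tile) -> list[Box]: ...


def box_to_genome(box: Box, tile: Tile) -> ErrorCall:
    """Map pixel corners onto the tile's genomic windows (nearest-bp rounding)."""
    if box.x2 > tile.width or box.y2 > tile.height or box.x1 < 0 or box.y1 < 0:
        raise ParameterError("box exceeds tile pixel bounds")
    x_scale = (tile.x_end - tile.x_start) / tile.width
    y_scale = (tile.y_end - tile.y_start) / tile.height
    xs = round(box.x1 * x_scale + tile.x_start)
    xe = round(box.x2 * x_scale + tile.x_start)
    ys = round(box.y1 * y_scale + tile.y_start)
    ye = round(box.y2 * y_scale + tile.y_start)
    return ErrorCall(
        category=box.category,
        x_start=int(xs),
        x_end=int(xe),
        y_start=int(ys),
        y_end=int(ye),
        resolution=tile.resolution,
        score=box.score,
        tile_id=tile.tile_id,
    )


def filter_calls(
    calls: Sequence[ErrorCall],
    min_len: int = 50_000,
    max_len: int | None = None,
) -> list[ErrorCall]:
    """Keep calls whose x-interval length lies within ``[min_len, max_len]``.

    Chromosome-category boxes are structural, not errors, and pass through
    untouched.
    """
    if min_len < 0 or (max_len is not None and max_len < min_len):
        raise ParameterError("require 0 <= min_len <= max_len")
    hi = float("inf") if max_len is None else max_len
    return [
        c
        for c in calls
        if c.category == "chromosome" or min_len <= c.length <= hi
    ]


def _rect_iou(a: ErrorCall, b: ErrorCall) -> float:
    ix = max(0, min(a.x_end, b.x_end) - max(a.x_start, b.x_start))
    iy = max(0, min(a.y_end, b.y_end) - max(a.y_start, b.y_start))
    inter = ix * iy
    union = a.rect_area + b.rect_area - inter
    return inter / union if union > 0 else 0.0


def merge_calls(calls: Sequence[ErrorCall], iou_min: float = 0.5) -> list[ErrorCall]:
    """Deduplicate same-category calls re-detected across windows/resolutions.

    Calls whose genomic rectangles reach ``iou_min`` overlap are clustered
    transitively; each cluster keeps a single survivor — highest score, ties
    broken by larger area then smaller x_start. Deterministic and idempotent.
    """
    if not 0.0 <= iou_min <= 1.0:
        raise ParameterError("iou_min must lie in [0, 1]")
    n = len(calls)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if calls[i].category != calls[j].category:
                continue
            if _rect_iou(calls[i], calls[j]) >= iou_min:
                parent[find(i)] = find(j)
    clusters: dict[int, list[ErrorCall]] = {}
    for i, c in enumerate(calls):
        clusters.setdefault(find(i), []).append(c)
    survivors = [
        max(group, key=lambda c: (c.score, c.rect_area, -c.x_start))
        for group in clusters.values()
    ]
    survivors.sort(key=lambda c: (c.x_start, c.y_start, c.category))
    return survivors


def select_best_candidate(candidates: Sequence[Sequence[ErrorCall]]) -> int:
    """Index of the candidate with the fewest translocation+inversion calls.

    Debris and chromosome calls do not count; ties go to the smaller index.
    """
    if not candidates:
        raise ParameterError("no candidates")
    costs = [
        sum(1 for c in calls if c.category in ("translocation", "inversion"))
        for calls in candidates
    ]
    return min(range(len(costs)), key=lambda i: (costs[i], i))


def count_by_type(calls: Iterable[ErrorCall]) -> dict[str, int]:
    counts = Counter(c.category for c in calls)
    return {cat: counts.get(cat, 0) for cat in CATEGORIES}


# ---------------------------------------------------------------------------
# Tabular I/O (detector plugin contract + error-call tables)

CALL_COLUMNS = [
    "iteration",
    "category",
    "x_start",
    "x_end",
    "y_start",
    "y_end",
    "resolution",
    "score",
    "tile_id",
    "status",
]


def calls_to_frame(calls: Sequence[ErrorCall], iteration: int = 1) -> pd.DataFrame:
    rows = [
        {
            "iteration": iteration,
            "category": c.category,
            "x_start": c.x_start,
            "x_end": c.x_end,
            "y_start": c.y_start,
            "y_end": c.y_end,
            "resolution": c.resolution,
            "score": c.score,
            "tile_id": c.tile_id,
            "status": c.status,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_calls(calls: Sequence[ErrorCall], path: str | Path, iteration: int = 1) -> None:
    calls_to_frame(calls, iteration).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[ErrorCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        ErrorCall(
            category=row.category,
            x_start=int(row.x_start),
            x_end=int(row.x_end),
            y_start=int(row.y_start),
            y_end=int(row.y_end),
            resolution=int(row.resolution),
            score=float(row.score),
            tile_id="" if pd.isna(row.tile_id) else str(row.tile_id),
            status=str(row.status),
        )
        for row in df.itertuples()
    ]


def write_boxes(boxes: Sequence[Box], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "category": b.category,
                "x1": b.x1,
                "y1": b.y1,
                "x2": b.x2,
                "y2": b.y2,
                "score": b.score,
            }
            for b in boxes
        ],
        columns=["category", "x1", "y1", "x2", "y2", "score"],
    ).to_csv(path, sep="\t", index=False)


def read_boxes(path: str | Path) -> list[Box]:
    df = pd.read_csv(path, sep="\t")
    return [
        Box(row.category, float(row.x1), float(row.y1), float(row.x2), float(row.y2), float(row.score))
        for row in df.itertuples()
    ]
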