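"""Translocation insertion-site search and the iterative correction loop.

The insertion site of a translocated block is found from the contact map
itself: at the resolution closest to a third of the error length, every
error-bin contact profile across the whole genome is scanned for peaks at
least as high as the 95th percentile of the extracted strip, separated by at
least the error's width in bins. Peak indices falling inside the error's own
(padded) bin interval are discarded and the most frequent remaining genome
bin wins; its coordinate ``i * resolution`` is the insertion site.

The loop alternates detection over all resolutions/windows with batched
correction, regenerating the contact store between iterations through a
``map_provider`` callable.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .assembly_model import (
    AssemblyDoc,
    invert_block,
    move_block,
    relegate_debris,
    split_at,
)
from .contact_store import (
    ContactStore,
    fetch_region,
    plan_windows,
    quantile_threshold,
    render_tile,
)
from .detection import (
    Detector,
    ErrorCall,
    box_to_genome,
    count_by_type,
    filter_calls,
    merge_calls,
)
from .errors import CorrectionStalled, NoInsertionSiteError, ParameterError


@dataclass
class CorrectionConfig:
    """User-facing knobs of the detect→correct loop."""

    max_iterations: int = 5
    stall_patience: int = 2
    debris_mode: str = "skip"  # skip | adjust
    error_min_len: int = 50_000
    error_max_len: int | None = None
    gap_len: int = 500
    iou_min: float = 0.5
    quantile: float = 0.95
    exclusion_pad: int = 2  # bins added around the error when vetoing peaks
    snap_tol_bins: int = 2  # insertion snaps to a fragment boundary this close
    seed: int = 0

    def __post_init__(self):
        if self.debris_mode not in ("skip", "adjust"):
            raise ParameterError(f"unknown debris_mode {self.debris_mode!r}")


@dataclass(frozen=True)
class EditRecord:
    iteration: int
    category: str
    x_start: int
    x_end: int
    insertion: int | None
    action: str  # move | invert | relegate | skip


@dataclass
class IterationLog:
    iteration: int
    counts: dict[str, int]
    edits: list[EditRecord] = field(default_factory=list)
    skipped: list[tuple[ErrorCall, str]] = field(default_factory=list)


def best_resolution(error_len: int, resolutions: Sequence[int]) -> int:
    """Resolution minimising ``|error_len/3 - R|``; ties go to the smaller R."""
    if not resolutions:
        raise ParameterError("empty resolution list")
    if error_len <= 0:
        raise ParameterError("error length must be positive")
    target = error_len / 3
    return int(min(sorted(resolutions), key=lambda r: abs(target - r)))


def _peak_vote(
    store: ContactStore,
    err_start: int,
    err_end: int,
    res: int,
    quantile: float,
    exclusion_pad: int,
) -> int | None:
    strip = fetch_region(store, res, (0, store.genome_length), (err_start, err_end)).values
    peak95 = quantile_threshold(strip, quantile)
    lo_bin = err_start // res
    hi_bin = err_end // res
    distance = max(1, hi_bin - lo_bin)
    votes: Counter[int] = Counter()
    n_rows = strip.shape[0]
    for c in range(strip.shape[1]):
        col = strip[:, c]
        idx = list(find_peaks(col, height=peak95, distance=distance)[0])
        # scipy never reports the endpoints; admit a genome-edge bin when it
        # strictly dominates its inward neighbour (insertion at a terminus)
        if n_rows > 1 and col[0] >= peak95 and col[0] > col[1]:
            if all(abs(i) >= distance for i in idx):
                idx.append(0)
        if n_rows > 1 and col[-1] >= peak95 and col[-1] > col[-2]:
            if all(abs(i - (n_rows - 1)) >= distance for i in idx):
                idx.append(n_rows - 1)
        votes.update(int(i) for i in idx)
    for b in range(lo_bin - exclusion_pad, hi_bin + exclusion_pad + 1):
        votes.pop(b, None)
    if not votes:
        return None
    row_mass = strip.sum(axis=1)
    top = max(votes.items(), key=lambda kv: (kv[1], row_mass[kv[0]], -kv[0]))
    return top[0] * res


def _find_insertion_site_ex(
    store: ContactStore,
    error: tuple[int, int],
    quantile: float,
    exclusion_pad: int,
) -> tuple[int, int]:
    err_start, err_end = map(int, error)
    Lg = store.genome_length
    if not (0 <= err_start < err_end <= Lg):
        raise ParameterError(f"error interval [{err_start}, {err_end}) outside genome")
    res_best = best_resolution(err_end - err_start, store.resolutions)
    cascade = [res_best] + [r for r in sorted(store.resolutions) if r != res_best]
    finest = min(store.resolutions)
    for res in cascade:
        site = _peak_vote(store, err_start, err_end, res, quantile, exclusion_pad)
        if site is None:
            continue
        if res > finest:
            # multi-resolution refinement: a coarse bin can hold more than one
            # fragment boundary, so re-vote at the finest resolution and keep
            # the refined site when it confirms the coarse neighbourhood
            refined = _peak_vote(store, err_start, err_end, finest, quantile, exclusion_pad)
            if refined is not None and abs(
                (refined + finest / 2) - (site + res / 2)
            ) <= res:
                return refined, finest
        return site, res
    raise NoInsertionSiteError(
        f"no candidate insertion peaks for error [{err_start}, {err_end}) "
        f"at any of {store.resolutions}"
    )


def find_insertion_site(
    store: ContactStore,
    error: tuple[int, int],
    quantile: float = 0.95,
    exclusion_pad: int = 2,
) -> int:
    """Peak-vote the genome bin where a translocated block belongs.

    The search runs at the resolution closest to a third of the error
    length. When every candidate falls inside the error's own padded bin
    interval — typical for a block displaced by only a few bins, where the
    exclusion band covers its true home — the remaining resolutions are
    tried from finest to coarsest, since the band's bp width shrinks with
    the bin size. Raises :class:`NoInsertionSiteError` when no resolution
    yields a surviving peak (the caller skips the call).
    """
    site, _res = _find_insertion_site_ex(store, error, quantile, exclusion_pad)
    return site


def _snap_to_boundary(doc: AssemblyDoc, site: int, res: int, tol: int) -> int:
    """Snap a bin-quantised site to the nearest fragment boundary.

    The peak algorithm returns the START of the winning bin; the true
    boundary may sit anywhere inside it, so distance is measured against the
    whole bin interval ``[site, site + res)`` — a boundary inside the bin is
    always preferred.
    """

    def dist(b: int) -> int:
        if site <= b < site + res:
            return 0
        return min(abs(b - site), abs(b - (site + res)))

    nearest = min(doc.boundaries(), key=dist)
    return nearest if dist(nearest) <= tol else site


def apply_correction(
    doc: AssemblyDoc,
    call: ErrorCall,
    store: ContactStore | None,
    config: CorrectionConfig | None = None,
    insertion: int | None = None,
    iteration: int = 1,
) -> tuple[AssemblyDoc, EditRecord]:
    """Apply one error call to the document; never mutates ``doc``.

    Translocations cut at both call boundaries and at the insertion site
    (computed from ``store`` unless supplied) and move the block there;
    inversions cut and flip; debris is relegated to the leftover scaffold
    only under ``debris_mode="adjust"`` and is skipped by default.
    """
    config = config or CorrectionConfig()
    if call.status != "pending":
        raise ParameterError(f"call already {call.status}")
    xs, xe = call.x_start, call.x_end
    if call.category == "translocation":
        if insertion is None:
            if store is None:
                raise ParameterError("need a contact store or an explicit insertion")
            insertion, res = _find_insertion_site_ex(
                store, (xs, xe), config.quantile, config.exclusion_pad
            )
            insertion = _snap_to_boundary(doc, insertion, res, config.snap_tol_bins * res)
        if xs < insertion < xe:
            call.status = "skipped"
            return doc, EditRecord(iteration, call.category, xs, xe, insertion, "skip")
        out = split_at(split_at(split_at(doc, xs), xe), insertion)
        out = move_block(out, (xs, xe), insertion)
        call.status = "corrected"
        return out, EditRecord(iteration, call.category, xs, xe, insertion, "move")
    if call.category == "inversion":
        out = invert_block(split_at(split_at(doc, xs), xe), (xs, xe))
        call.status = "corrected"
        return out, EditRecord(iteration, call.category, xs, xe, None, "invert")
    if call.category == "debris":
        if config.debris_mode != "adjust":
            call.status = "skipped"
            return doc, EditRecord(iteration, call.category, xs, xe, None, "skip")
        out = relegate_debris(split_at(split_at(doc, xs), xe), (xs, xe))
        call.status = "corrected"
        return out, EditRecord(iteration, call.category, xs, xe, None, "relegate")
    raise ParameterError(f"cannot correct category {call.category!r}")


# ---------------------------------------------------------------------------
# Detection sweep over all resolutions and windows


def detect_errors(
    store: ContactStore,
    detector: Detector,
    config: CorrectionConfig | None = None,
) -> list[ErrorCall]:
    """Tile the map at every resolution, run the detector, map/filter/merge.

    Boxes clipped by an interior tile edge are dropped: the 300-bin window
    overlap guarantees a neighbouring tile sees the same error whole.
    """
    config = config or CorrectionConfig()
    Lg = store.genome_length
    calls: list[ErrorCall] = []
    eps = 1e-9
    for res in store.resolutions:
        for w in plan_windows(Lg, res):
            region = fetch_region(store, res, (w.start, w.end), (w.start, w.end))
            ceiling = quantile_threshold(region.values, config.quantile)
            if ceiling <= 0:
                ceiling = max(float(region.values.max()), 1.0)
            tile = render_tile(region, ceiling, tile_id=f"res{res}_w{w.index}")
            for box in detector(tile):
                if box.category == "chromosome":
                    continue
                clipped_left = box.x1 <= eps and tile.x_start > 0
                clipped_right = box.x2 >= tile.width - eps and tile.x_end < Lg
                if clipped_left or clipped_right:
                    continue
                calls.append(box_to_genome(box, tile))
    calls = filter_calls(calls, config.error_min_len, config.error_max_len)
    return merge_calls(calls, config.iou_min)


# ---------------------------------------------------------------------------
# Coordinate remapping between edits of one batch


def _move_maps(s0: int, s1: int, ins: int):
    """Interval- and boundary-remap closures for moving [s0, s1) to ``ins``."""
    length = s1 - s0

    def interval(iv: tuple[int, int]) -> tuple[int, int]:
        a, b = iv
        m = (a + b) / 2
        if ins <= s0:
            if s0 <= m < s1:
                off = ins - s0
            elif ins <= m < s0:
                off = length
            else:
                off = 0
        else:
            if s0 <= m < s1:
                off = (ins - length) - s0
            elif s1 <= m < ins:
                off = -length
            else:
                off = 0
        return a + off, b + off

    def boundary(p: int) -> int:
        if ins <= s0:
            if ins < p <= s0:
                return p + length
            if s0 < p < s1:
                return ins + (p - s0)
            return p
        if s0 < p < s1:
            return (ins - length) + (p - s0)
        if s1 <= p < ins:
            return p - length
        return p

    return interval, boundary


def _invert_maps(b0: int, b1: int):
    def interval(iv: tuple[int, int]) -> tuple[int, int]:
        a, b = iv
        m = (a + b) / 2
        if b0 <= m < b1:
            return b0 + b1 - b, b0 + b1 - a
        return a, b

    def boundary(p: int) -> int:
        if b0 < p < b1:
            return b0 + b1 - p
        return p

    return interval, boundary


def run_iterations(
    doc: AssemblyDoc,
    detector: Detector,
    map_provider: Callable[[AssemblyDoc], ContactStore],
    config: CorrectionConfig | None = None,
) -> tuple[AssemblyDoc, list[IterationLog]]:
    """Iterate detect→correct until no translocation/inversion calls remain.

    All of an iteration's edits are planned against the iteration-start map:
    translocation insertion sites are computed first, then each applied edit
    remaps the coordinates of the calls still waiting in the batch. The loop
    stops at ``max_iterations`` and aborts with :class:`CorrectionStalled`
    when the error count fails to drop ``stall_patience`` times in a row.
    """
    config = config or CorrectionConfig()
    logs: list[IterationLog] = []
    if config.max_iterations <= 0:
        return doc, logs
    store = map_provider(doc)
    prev_cost = math.inf
    stall = 0
    for iteration in range(1, config.max_iterations + 1):
        if hasattr(detector, "refresh"):
            detector.refresh(doc)
        calls = detect_errors(store, detector, config)
        log = IterationLog(iteration, count_by_type(calls))
        logs.append(log)
        cost = log.counts["translocation"] + log.counts["inversion"]
        if cost == 0:
            break
        if cost >= prev_cost:
            stall += 1
            if stall >= config.stall_patience:
                raise CorrectionStalled(
                    f"{cost} errors remaining after {iteration} iterations "
                    f"with no progress for {stall} iterations"
                )
        else:
            stall = 0
        prev_cost = cost

        # phase A: plan every edit against the iteration-start store
        plans: list[tuple[ErrorCall, int | None]] = []
        for call in sorted(calls, key=lambda c: c.x_start):
            if call.category == "translocation":
                try:
                    ins, res = _find_insertion_site_ex(
                        store,
                        (call.x_start, call.x_end),
                        config.quantile,
                        config.exclusion_pad,
                    )
                except NoInsertionSiteError:
                    call.status = "skipped"
                    log.skipped.append((call, "no-insertion-site"))
                    continue
                ins = _snap_to_boundary(doc, ins, res, config.snap_tol_bins * res)
                plans.append((call, ins))
            elif call.category == "inversion":
                plans.append((call, None))
            elif call.category == "debris":
                if config.debris_mode == "adjust":
                    plans.append((call, None))
                else:
                    call.status = "skipped"
                    log.skipped.append((call, "debris-not-adjusted"))

        # phase B: apply in order, remapping the rest through each edit
        maps: list[tuple] = []
        for call, ins in plans:
            a, b = call.x_start, call.x_end
            for interval_map, boundary_map in maps:
                a, b = interval_map((a, b))
                if ins is not None:
                    ins = boundary_map(ins)
            current = replace(call, x_start=int(a), x_end=int(b))
            doc, record = apply_correction(
                doc, current, None, config, insertion=ins, iteration=iteration
            )
            call.status = current.status
            log.edits.append(record)
            if record.action == "move":
                maps.append(_move_maps(int(a), int(b), int(ins)))
            elif record.action == "invert":
                maps.append(_invert_maps(int(a), int(b)))
            elif record.action == "relegate":
                maps.append(_move_maps(int(a), int(b), doc.total_length))
        store = map_provider(doc)
    return doc, logs
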