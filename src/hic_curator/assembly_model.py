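"""3D-DNA-dialect ``.assembly`` documents: parse, edit, serialise, build FASTA.

An assembly document lists draft fragments (``>name id length``) followed by
one line per scaffold of signed fragment ids; the sign encodes orientation.
Assembly coordinates used throughout are the gapless concatenation of the
fragments in layout order (zero-based, half-open, bp) — gaps exist only in
FASTA output.

Fragment names carry provenance as ``contig:start-end`` (zero-based,
half-open native coordinates), maintained across splits so any fragment can
be resolved back to a slice of the input contigs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import BoundsError, FormatError, ParameterError, ReferenceResolutionError


@dataclass(frozen=True)
class Fragment:
    name: str
    id: int
    length: int


@dataclass
class AssemblyDoc:
    fragments: list[Fragment]
    layout: list[list[int]]
    # True when the final scaffold is the "leftover" bin for unplaced or
    # debris sequence; not representable in .assembly text, so not compared.
    has_leftover: bool = field(default=False, compare=False)

    def __post_init__(self):
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        ids = [f.id for f in self.fragments]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate fragment id")
        if any(f.length <= 0 for f in self.fragments):
            raise FormatError("fragment with non-positive length")
        known = set(ids)
        seen: set[int] = set()
        for row in self.layout:
            for sid in row:
                fid = abs(sid)
                if fid not in known:
                    raise FormatError(f"layout references unknown fragment id {fid}")
                if fid in seen:
                    raise FormatError(f"fragment id {fid} appears twice in layout")
                seen.add(fid)
        missing = known - seen
        if missing:
            raise FormatError(f"fragment ids missing from layout: {sorted(missing)}")

    def fragment_by_id(self, fid: int) -> Fragment:
        for f in self.fragments:
            if f.id == fid:
                return f
        raise ParameterError(f"no fragment with id {fid}")

    @property
    def total_length(self) -> int:
        return sum(f.length for f in self.fragments)

    def entries(self) -> list[tuple[int, int, int, int, int]]:
        """Flattened layout: (scaffold_idx, entry_idx, signed_id, start, end)."""
        out = []
        pos = 0
        for si, row in enumerate(self.layout):
            for ei, sid in enumerate(row):
                ln = self.fragment_by_id(abs(sid)).length
                out.append((si, ei, sid, pos, pos + ln))
                pos += ln
        return out

    def boundaries(self) -> list[int]:
        """Assembly coordinates of all fragment boundaries, 0 and total included."""
        bounds = [0]
        for *_x, end in self.entries():
            bounds.append(end)
        return bounds


def locate(doc: AssemblyDoc, g: int) -> tuple[int, int, int, int]:
    """Resolve assembly coordinate ``g`` to (scaffold, position, fragment id, offset).

    The offset is measured on the assembly axis, so for a −oriented fragment
    it runs opposite to the fragment's native axis.
    """
    if not 0 <= g < doc.total_length:
        raise BoundsError(f"position {g} outside assembly [0, {doc.total_length})")
    for si, ei, sid, start, end in doc.entries():
        if start <= g < end:
            return si, ei, abs(sid), g - start
    raise AssertionError("unreachable")


# -- serialisation ----------------------------------------------------------

_HEADER_RE = re.compile(r"^>(\S+)\s+(\d+)\s+(\d+)\s*$")


def read_assembly(text: str) -> AssemblyDoc:
    fragments: list[Fragment] = []
    layout: list[list[int]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            m = _HEADER_RE.match(line)
            if not m:
                raise FormatError(f"line {lineno}: malformed fragment header {raw!r}")
            fragments.append(Fragment(m.group(1), int(m.group(2)), int(m.group(3))))
        else:
            try:
                row = [int(tok) for tok in line.split()]
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer id in layout") from None
            if any(sid == 0 for sid in row):
                raise FormatError(f"line {lineno}: fragment id 0 is not allowed")
            layout.append(row)
    try:
        return AssemblyDoc(fragments, layout)
    except FormatError as exc:
        raise FormatError(str(exc)) from None


def write_assembly(doc: AssemblyDoc) -> str:
    lines = [f">{f.name} {f.id} {f.length}" for f in doc.fragments]
    lines += [" ".join(str(sid) for sid in row) for row in doc.layout]
    return "\n".join(lines) + "\n"


def load_assembly(path: str | Path) -> AssemblyDoc:
    return read_assembly(Path(path).read_text())


def save_assembly(doc: AssemblyDoc, path: str | Path) -> None:
    Path(path).write_text(write_assembly(doc))


# -- provenance -------------------------------------------------------------

_PROV_RE = re.compile(r"^(?P<contig>.+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_provenance(name: str) -> tuple[str, int, int]:
    m = _PROV_RE.match(name)
    if not m:
        raise ReferenceResolutionError(
            f"fragment name {name!r} lacks contig:start-end provenance"
        )
    return m.group("contig"), int(m.group("start")), int(m.group("end"))


def _renumbered(named: list[tuple[str, int]], layout_names: list[list[tuple[str, int]]],
                has_leftover: bool) -> AssemblyDoc:
    """Rebuild a doc from (name, length) records and a layout of signed refs.

    ``layout_names`` rows contain (index into named, sign) pairs.
    """
    fragments = [Fragment(name, i + 1, ln) for i, (name, ln) in enumerate(named)]
    layout = [[sign * (idx + 1) for idx, sign in row] for row in layout_names]
    return AssemblyDoc(fragments, layout, has_leftover=has_leftover)


def _decompose(doc: AssemblyDoc) -> tuple[list[tuple[str, int]], list[list[tuple[int, int]]]]:
    named = [(f.name, f.length) for f in doc.fragments]
    index_of = {f.id: i for i, f in enumerate(doc.fragments)}
    layout = [[(index_of[abs(sid)], 1 if sid > 0 else -1) for sid in row] for row in doc.layout]
    return named, layout


# -- editing operations (pure: each returns a new document) -----------------


def split_at(doc: AssemblyDoc, g: int) -> AssemblyDoc:
    """Cut the fragment containing assembly coordinate ``g`` into two.

    A ``g`` on an existing fragment boundary is a documented no-op. For a
    −oriented fragment the native cut point is ``length − offset``, so the
    assembly-axis position of the cut is preserved.
    """
    if g == doc.total_length:
        return doc
    si, ei, fid, offset = locate(doc, g)
    if offset == 0:
        return doc
    frag = doc.fragment_by_id(fid)
    sign = 1 if doc.layout[si][ei] > 0 else -1
    cut = offset if sign > 0 else frag.length - offset
    try:
        contig, a, b = parse_provenance(frag.name)
        name_l, name_r = f"{contig}:{a}-{a + cut}", f"{contig}:{a + cut}-{b}"
    except ReferenceResolutionError:
        name_l, name_r = f"{frag.name}:::fragment_1", f"{frag.name}:::fragment_2"
    named, layout = _decompose(doc)
    fidx = next(i for i, f in enumerate(doc.fragments) if f.id == fid)
    named[fidx: fidx + 1] = [(name_l, cut), (name_r, frag.length - cut)]
    # shift indices ≥ fidx by one, then expand the split entry
    new_layout: list[list[tuple[int, int]]] = []
    for row in layout:
        new_row: list[tuple[int, int]] = []
        for idx, sgn in row:
            if idx == fidx:
                if sgn > 0:
                    new_row += [(fidx, 1), (fidx + 1, 1)]
                else:
                    new_row += [(fidx + 1, -1), (fidx, -1)]
            else:
                new_row.append((idx + 1 if idx > fidx else idx, sgn))
        new_layout.append(new_row)
    return _renumbered(named, new_layout, doc.has_leftover)


def _run_for_block(doc: AssemblyDoc, block: tuple[int, int]) -> tuple[int, int, int]:
    """(scaffold index, first entry, last entry+1) for a fragment-aligned block."""
    b0, b1 = block
    if not (0 <= b0 < b1 <= doc.total_length):
        raise BoundsError(f"block [{b0}, {b1}) outside assembly")
    entries = doc.entries()
    first = last = None
    si_set = set()
    covered = 0
    for si, ei, sid, start, end in entries:
        if start >= b0 and end <= b1:
            if first is None:
                first, f_si = ei, si
            last = ei
            si_set.add(si)
            covered += end - start
        elif start < b1 and end > b0:
            raise ParameterError(
                f"block boundary inside fragment [{start}, {end}); split first"
            )
    if first is None or covered != b1 - b0:
        raise ParameterError("block boundaries do not align with fragment boundaries")
    if len(si_set) > 1:
        raise ParameterError("block spans multiple scaffolds")
    return f_si, first, last + 1


def _boundary_target(doc: AssemblyDoc, g: int) -> tuple[int, int]:
    """(scaffold, entry position) where inserting at coordinate ``g`` lands.

    At a junction between scaffolds the insertion goes to the start of the
    following scaffold; ``g == total`` appends to the last scaffold.
    """
    if g == 0:
        return 0, 0
    if g == doc.total_length:
        return len(doc.layout) - 1, len(doc.layout[-1])
    pos = 0
    for si, row in enumerate(doc.layout):
        row_start = pos
        for ei, sid in enumerate(row):
            if pos == g:
                return (si, ei) if pos > row_start else (si, 0)
            pos += doc.fragment_by_id(abs(sid)).length
        if pos == g:
            # junction: attach to the start of the next scaffold
            if si + 1 < len(doc.layout):
                return si + 1, 0
            return si, len(row)
    raise ParameterError(f"insertion point {g} is not a fragment boundary")


def move_block(doc: AssemblyDoc, block: tuple[int, int], insertion: int) -> AssemblyDoc:
    """Relocate a fragment-aligned block to a fragment-boundary insertion point."""
    b0, b1 = block
    if b0 < insertion < b1:
        raise ParameterError("insertion point lies inside the block")
    si, e0, e1 = _run_for_block(doc, block)
    sj, pj = _boundary_target(doc, insertion)
    named, layout = _decompose(doc)
    segment = layout[si][e0:e1]
    del layout[si][e0:e1]
    if sj == si and pj >= e1:
        pj -= e1 - e0
    layout[sj][pj:pj] = segment
    layout = [row for row in layout if row]
    return _renumbered(named, layout, doc.has_leftover)


def invert_block(doc: AssemblyDoc, block: tuple[int, int]) -> AssemblyDoc:
    """Reverse fragment order within the block and flip every orientation."""
    if block[0] == block[1]:
        return doc
    si, e0, e1 = _run_for_block(doc, block)
    named, layout = _decompose(doc)
    layout[si][e0:e1] = [(idx, -sgn) for idx, sgn in reversed(layout[si][e0:e1])]
    return _renumbered(named, layout, doc.has_leftover)


def relegate_debris(doc: AssemblyDoc, block: tuple[int, int]) -> AssemblyDoc:
    """Append the block's fragments to a trailing leftover scaffold.

    A block already forming the tail of the final scaffold is left in place
    (it already sits at the genome's extremity); the leftover flag is set.
    """
    si, e0, e1 = _run_for_block(doc, block)
    last = len(doc.layout) - 1
    if si == last and e1 == len(doc.layout[last]):
        # already the tail of the final scaffold: nothing to relocate
        return AssemblyDoc(
            list(doc.fragments), [list(r) for r in doc.layout], has_leftover=True
        )
    named, layout = _decompose(doc)
    segment = layout[si][e0:e1]
    del layout[si][e0:e1]
    if doc.has_leftover and layout and layout[-1]:
        layout[-1].extend(segment)
    else:
        layout = [row for row in layout if row]
        layout.append(segment)
    layout = [row for row in layout if row]
    return _renumbered(named, layout, True)


# -- FASTA ------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def build_fasta(
    doc: AssemblyDoc,
    contigs: Mapping[str, str],
    gap_len: int = 500,
    scaffold_names: Sequence[str] | None = None,
) -> dict[str, str]:
    """Assemble scaffold sequences from provenance-named fragments.

    Fragments are resolved to contig slices via their ``contig:start-end``
    names, reverse-complemented when −oriented, and joined with ``gap_len``
    Ns inside each scaffold.
    """
    if gap_len < 0:
        raise ParameterError("gap_len must be non-negative")
    out: dict[str, str] = {}
    for si, row in enumerate(doc.layout):
        pieces = []
        for sid in row:
            frag = doc.fragment_by_id(abs(sid))
            contig, a, b = parse_provenance(frag.name)
            if contig not in contigs:
                raise ReferenceResolutionError(f"unknown contig {contig!r}")
            seq = contigs[contig][a:b]
            if len(seq) != frag.length:
                raise ReferenceResolutionError(
                    f"fragment {frag.name}: contig slice length {len(seq)} "
                    f"!= declared length {frag.length}"
                )
            pieces.append(seq if sid > 0 else reverse_complement(seq))
        if scaffold_names is not None:
            name = scaffold_names[si]
        elif doc.has_leftover and si == len(doc.layout) - 1:
            name = "leftover"
        else:
            name = f"scaffold_{si + 1}"
        out[name] = ("N" * gap_len).join(pieces)
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
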