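"""Mutant-clone spectrum analysis.

Sanger-style mutant clone sequences are aligned globally to the plasmid
reference; differences are called as substitution / insertion / deletion
events; deletions are assigned a size class (small < 50 bp, medium
50-100 bp, large > 100 bp) and a junction microhomology length.  A clone
set is then summarized into the one-class-per-clone spectrum used for
pie-chart style reporting.

Breakpoint conventions
----------------------
A deletion junction flanked by a short repeat can be placed at several
equivalent positions; events are reported left-aligned (smallest proximal
coordinate).  The microhomology length of a deletion is the total slide
slack of its junction: the number of alternative placements of the same-
size deletion that reconstruct the identical mutant sequence.  It is
therefore independent of which equivalent placement is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
from Bio import Align

from hdnakit.plasmid import PlasmidMap

#: Alignment scoring defaults (affine backend); caller-adjustable.
DEFAULT_SCORING = {
    "match": 1.0,
    "mismatch": -2.0,
    "gap_open": -5.0,
    "gap_extend": -0.5,
}

#: Minimum run of exact match columns treated as an alignment anchor when
#: grouping difference columns into events.  Shorter match runs between
#: gap-containing blocks are spurious junction micro-matches (the aligner
#: threading a de novo insertion through the deleted segment) and are
#: absorbed into a single deletion-with-insertion event.
DEFAULT_MIN_ANCHOR = 10

DEFAULT_IDENTITY_FLOOR = 0.5

SPECTRUM_CLASSES = (
    "large_deletion",
    "medium_deletion",
    "small_deletion",
    "insertion",
    "point_mutation",
)


class UnalignableCloneError(ValueError):
    """Raised when a clone's best alignment identity falls below the floor."""


@dataclass
class CloneRecord:
    clone_id: str
    sequence: str
    group: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"clone {self.clone_id!r}: empty sequence")
        self.sequence = self.sequence.upper()


@dataclass
class MutationEvent:
    """One called difference between a clone and the reference.

    ``proximal``/``distal`` are 1-based inclusive reference breakpoints:
    for deletions, the deleted interval; for substitutions, the single
    changed position (proximal == distal); for insertions, the reference
    position immediately 5' of the inserted material.  ``inserted_seq``
    holds the clone-side sequence of the event (the new base for a
    substitution, the inserted material for insertions and for deletions
    with a junction de novo insert).
    """

    type: str  # substitution | insertion | deletion
    proximal: int
    distal: int
    inserted_seq: str = ""
    size: int = 0
    microhomology: int | None = None
    size_class: str = "n/a"


@dataclass
class SpectrumSummary:
    counts: dict[str, int]
    percent: dict[str, int]
    n_clones: int
    unalignable: list[str] = field(default_factory=list)
    unchanged: list[str] = field(default_factory=list)
    per_clone: dict[str, str] = field(default_factory=dict)

    @property
    def deletion_percent(self) -> int:
        """Rounded percentage of clones whose dominant event is any deletion."""
        n_del = sum(self.counts[c] for c in
                    ("large_deletion", "medium_deletion", "small_deletion"))
        n = sum(self.counts.values())
        return round(100 * n_del / n) if n else 0


@dataclass
class CloneAlignment:
    """A global pairwise alignment of a clone against (part of) the reference."""

    clone_id: str
    ref_aligned: str
    clone_aligned: str
    ref_offset: int  # 1-based reference position of the first reference column
    identity: float


def size_class(deletion_size: int) -> str:
    """Deletion size class: <50 small, 50-100 medium, >100 large."""
    if deletion_size < 1:
        raise ValueError(f"deletion size must be positive, got {deletion_size}")
    if deletion_size < 50:
        return "small"
    if deletion_size <= 100:
        return "medium"
    return "large"


def microhomology_length(pmap: PlasmidMap, proximal: int, distal: int) -> int:
    """Junction microhomology of the deleted interval [proximal, distal].

    Counts how many positions the deletion can slide (left plus right)
    while reconstructing the same mutant sequence; equivalently the length
    of the repeat shared between the deleted segment's margin and the
    flanking sequence.  Placement-invariant: every equivalent placement of
    the deletion returns the same value.
    """
    length = pmap.length
    size = (distal - proximal) % length + 1
    if size >= length:
        raise ValueError("deletion cannot span the entire circle")
    cap = length - size  # remaining sequence length bounds the slide
    k_right = 0
    while k_right < cap and pmap.base(proximal + k_right) == pmap.base(distal + 1 + k_right):
        k_right += 1
    k_left = 0
    while (k_left + k_right) < cap and pmap.base(proximal - 1 - k_left) == pmap.base(distal - k_left):
        k_left += 1
    return k_left + k_right


def align_clone(
    clone: CloneRecord,
    pmap: PlasmidMap,
    region: tuple[int, int] | None = None,
    scoring: dict | None = None,
    backend: str = "affine",
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
) -> CloneAlignment:
    """Globally align a clone to the reference (or a reference region).

    The default backend is an affine-gap global aligner (match 1,
    mismatch -2, gap open -5, gap extend -0.5).  ``backend='edlib'``
    selects a unit-cost edit-distance aligner, much faster on long clones;
    downstream event calling normalizes either backend's gap placement.
    """
    if len(clone.sequence) < 30:
        raise ValueError(f"clone {clone.clone_id!r}: sequence shorter than 30 nt")
    from hdnakit.plasmid import circular_substring

    if region is None:
        ref_seq = pmap.sequence
        offset = 1
    else:
        ref_seq = circular_substring(pmap, region[0], region[1])
        offset = region[0]

    if backend == "affine":
        sc = dict(DEFAULT_SCORING, **(scoring or {}))
        aligner = Align.PairwiseAligner(
            mode="global",
            match_score=sc["match"],
            mismatch_score=sc["mismatch"],
            open_gap_score=sc["gap_open"],
            extend_gap_score=sc["gap_extend"],
        )
        aln = aligner.align(ref_seq, clone.sequence)[0]
        ref_gapped, clone_gapped = str(aln[0]), str(aln[1])
    elif backend == "edlib":
        res = edlib.align(clone.sequence, ref_seq, task="path", mode="NW")
        nice = edlib.getNiceAlignment(res, clone.sequence, ref_seq)
        ref_gapped, clone_gapped = nice["target_aligned"], nice["query_aligned"]
    else:
        raise ValueError(f"unknown alignment backend {backend!r}")

    matches = sum(a == b for a, b in zip(ref_gapped, clone_gapped))
    identity = matches / len(ref_gapped)
    if identity < identity_floor:
        raise UnalignableCloneError(
            f"clone {clone.clone_id!r}: alignment identity {identity:.2f} "
            f"below floor {identity_floor:.2f}"
        )
    return CloneAlignment(clone.clone_id, ref_gapped, clone_gapped, offset, identity)


def _blocks(ref_g: str, clone_g: str) -> list[tuple[int, int]]:
    """Maximal runs of non-identical alignment columns, as [start, end) pairs."""
    blocks = []
    in_block = False
    for i, (a, b) in enumerate(zip(ref_g, clone_g)):
        if a != b:
            if not in_block:
                blocks.append([i, i + 1])
                in_block = True
            else:
                blocks[-1][1] = i + 1
        else:
            in_block = False
    return [tuple(b) for b in blocks]


def _merge_junction_blocks(
    blocks: list[tuple[int, int]], ref_g: str, clone_g: str, min_anchor: int
) -> list[tuple[int, int]]:
    """Merge difference blocks separated by match runs shorter than the anchor.

    Merging applies only when at least one of the two blocks contains a gap
    column, so neighbouring substitutions are never lumped together.
    """
    if not blocks:
        return blocks

    def has_gap(b: tuple[int, int]) -> bool:
        return "-" in ref_g[b[0]:b[1]] or "-" in clone_g[b[0]:b[1]]

    merged = [blocks[0]]
    for blk in blocks[1:]:
        prev = merged[-1]
        if blk[0] - prev[1] < min_anchor and (has_gap(prev) or has_gap(blk)):
            merged[-1] = (prev[0], blk[1])
        else:
            merged.append(blk)
    return merged


def canonicalize_replacement(
    pmap: PlasmidMap, prox: int, dist: int, ins: str
) -> tuple[int, int, str]:
    """Minimal representation of replacing ``ref[prox..dist]`` with ``ins``.

    Bases shared between the margins of the deleted segment and the
    replacement are trimmed (common suffix first, then common prefix), the
    parsimony convention for indel representation.  Aligners with
    degenerate gap placement can thread retained clone bases through a
    deleted segment; trimming collapses all such representations of the
    same mutant onto one.  May return an empty interval (``dist < prox``:
    a pure insertion after ``dist``) or an empty ``ins`` (pure deletion).
    """
    seg = list(pmap.sequence[prox - 1 : dist])
    ins_l = list(ins)
    while seg and ins_l and seg[-1] == ins_l[-1]:
        seg.pop()
        ins_l.pop()
        dist -= 1
    while seg and ins_l and seg[0] == ins_l[0]:
        seg.pop(0)
        ins_l.pop(0)
        prox += 1
    return prox, dist, "".join(ins_l)


def _slide_left(pmap: PlasmidMap, prox: int, dist: int, ins: str, floor: int) -> tuple[int, int, str]:
    """Left-align a deletion (optionally with a junction insert)."""
    while prox - 1 > floor:
        left = pmap.base(prox - 1)
        if ins:
            if left + ins != ins + pmap.base(dist):
                break
            ins = left + ins[:-1]
        elif left != pmap.base(dist):
            break
        prox -= 1
        dist -= 1
    return prox, dist, ins


def call_events(
    alignment: CloneAlignment,
    pmap: PlasmidMap,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> list[MutationEvent]:
    """Call mutation events from a clone alignment.

    Difference columns are grouped into blocks (junction micro-matches
    merged, see :data:`DEFAULT_MIN_ANCHOR`); each block becomes a deletion,
    an insertion, a deletion-with-insert, or per-column substitutions.
    Deletions are left-aligned and carry microhomology and size class.
    """
    ref_g, clone_g = alignment.ref_aligned, alignment.clone_aligned
    length = pmap.length
    # reference position (1-based) of each column's ref base; gap columns
    # carry the position of the preceding ref base.
    ref_pos = []
    pos = alignment.ref_offset - 1
    for ch in ref_g:
        if ch != "-":
            pos += 1
        ref_pos.append(((pos - 1) % length) + 1 if pos >= 1 else 0)

    blocks = _merge_junction_blocks(_blocks(ref_g, clone_g), ref_g, clone_g, min_anchor)
    events: list[MutationEvent] = []
    prev_dist = 0
    for b0, b1 in blocks:
        ref_bases = ref_g[b0:b1].replace("-", "")
        clone_bases = clone_g[b0:b1].replace("-", "")
        if not ref_bases:  # pure insertion
            prox = ref_pos[b0 - 1] if b0 > 0 else 0
            ins = clone_bases
            while prox - 1 > prev_dist and ins and pmap.base(prox) == ins[-1]:
                ins = pmap.base(prox) + ins[:-1]
                prox -= 1
            events.append(MutationEvent(
                type="insertion", proximal=prox, distal=prox,
                inserted_seq=ins, size=len(ins),
            ))
            prev_dist = prox
            continue
        # first/last reference positions covered by the block
        first = next(i for i in range(b0, b1) if ref_g[i] != "-")
        last = next(i for i in range(b1 - 1, b0 - 1, -1) if ref_g[i] != "-")
        prox, dist = ref_pos[first], ref_pos[last]
        if len(clone_bases) == len(ref_bases) and "-" not in ref_g[b0:b1] + clone_g[b0:b1]:
            for i in range(b0, b1):
                events.append(MutationEvent(
                    type="substitution", proximal=ref_pos[i], distal=ref_pos[i],
                    inserted_seq=clone_g[i], size=1,
                ))
            prev_dist = dist
            continue
        # replacement block: reduce to its minimal representation first
        prox, dist, ins = canonicalize_replacement(pmap, prox, dist, clone_bases)
        if dist < prox:  # segment fully trimmed: a pure insertion after `dist`
            if not ins:
                continue
            ipos = dist
            while ipos - 1 > prev_dist and pmap.base(ipos) == ins[-1]:
                ins = pmap.base(ipos) + ins[:-1]
                ipos -= 1
            events.append(MutationEvent(
                type="insertion", proximal=ipos, distal=ipos,
                inserted_seq=ins, size=len(ins),
            ))
            prev_dist = ipos
            continue
        if ins and dist - prox + 1 == len(ins):  # same-length replacement
            for off, (rb, cb) in enumerate(zip(pmap.sequence[prox - 1 : dist], ins)):
                if rb != cb:
                    events.append(MutationEvent(
                        type="substitution", proximal=prox + off,
                        distal=prox + off, inserted_seq=cb, size=1,
                    ))
            prev_dist = dist
            continue
        # deletion, possibly with a junction de novo insert
        prox, dist, ins = _slide_left(pmap, prox, dist, ins, prev_dist)
        span = (dist - prox) % length + 1
        events.append(MutationEvent(
            type="deletion", proximal=prox, distal=dist, inserted_seq=ins,
            size=span, microhomology=microhomology_length(pmap, prox, dist),
            size_class=size_class(span),
        ))
        prev_dist = dist
    return events


def apply_events(pmap: PlasmidMap, events: list[MutationEvent]) -> str:
    """Reconstruct the mutant sequence from reference plus called events.

    Events must be sorted by proximal coordinate and non-overlapping, and
    must not wrap the circle's origin (the clone is taken as linearized at
    reference position 1).
    """
    seq = pmap.sequence
    parts: list[str] = []
    cursor = 1  # next reference position to emit
    for ev in sorted(events, key=lambda e: e.proximal):
        if ev.type == "insertion":
            parts.append(seq[cursor - 1 : ev.proximal])
            parts.append(ev.inserted_seq)
            cursor = ev.proximal + 1
        else:  # substitution or deletion replace [proximal, distal]
            parts.append(seq[cursor - 1 : ev.proximal - 1])
            parts.append(ev.inserted_seq)
            cursor = ev.distal + 1
    parts.append(seq[cursor - 1 :])
    return "".join(parts)


def classify_clone(events: list[MutationEvent]) -> str | None:
    """Dominant-event class of a clone: largest deletion > insertion > point."""
    deletions = [e for e in events if e.type == "deletion"]
    if deletions:
        biggest = max(deletions, key=lambda e: e.size)
        return f"{biggest.size_class}_deletion"
    if any(e.type == "insertion" for e in events):
        return "insertion"
    if any(e.type == "substitution" for e in events):
        return "point_mutation"
    return None


def summarize_spectrum(
    clones: list[CloneRecord],
    pmap: PlasmidMap,
    backend: str = "affine",
    scoring: dict | None = None,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> SpectrumSummary:
    """Classify each clone by its dominant event and tabulate the spectrum.

    Unalignable clones (identity below the floor) and clones with no
    called events are reported separately and excluded from percentages.
    Percentages are rounded to integers and may not sum to exactly 100.
    """
    if not clones:
        raise ValueError("at least one clone is required")
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    unalignable: list[str] = []
    unchanged: list[str] = []
    per_clone: dict[str, str] = {}
    for clone in clones:
        try:
            aln = align_clone(clone, pmap, backend=backend, scoring=scoring)
        except UnalignableCloneError:
            unalignable.append(clone.clone_id)
            per_clone[clone.clone_id] = "unalignable"
            continue
        cls = classify_clone(call_events(aln, pmap, min_anchor=min_anchor))
        if cls is None:
            unchanged.append(clone.clone_id)
            per_clone[clone.clone_id] = "no_change"
        else:
            counts[cls] += 1
            per_clone[clone.clone_id] = cls
    n_classified = sum(counts.values())
    percent = {
        c: (round(100 * k / n_classified) if n_classified else 0)
        for c, k in counts.items()
    }
    return SpectrumSummary(
        counts=counts, percent=percent, n_clones=len(clones),
        unalignable=unalignable, unchanged=unchanged, per_clone=per_clone,
    )
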