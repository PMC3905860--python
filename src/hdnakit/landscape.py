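"""Plasmid deep-sequencing variant landscape.

Short reads are end-trimmed, mapped onto the circular reference, and
mismatching bases are counted per reference position (forward and reverse
contributions combined).  Per-position variant counts are normalized by
relative coverage (coverage divided by the plasmid-wide mean), summed over
sliding windows of 50 consecutive bp anchored at every start position, and
segmented into hotspots where the windowed signal exceeds a fold of the
plasmid-wide median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pysam

from hdnakit.motifs import reverse_complement
from hdnakit.plasmid import PlasmidMap

DEFAULT_TRIM = 20
DEFAULT_WINDOW = 50
DEFAULT_FOLD_THRESHOLD = 5.0
DEFAULT_SEED_K = 20


@dataclass
class AlignedRead:
    read_id: str
    ref_start: int  # 1-based; footprint may wrap past position `length`
    orientation: str  # forward | reverse
    aligned_length: int
    mismatch_positions: list[int] = field(default_factory=list)


@dataclass
class LandscapeTrack:
    """Per-position landscape arrays over the circular reference axis."""

    coverage: np.ndarray
    variant_count: np.ndarray
    normalized: np.ndarray
    window_size: int
    windowed: np.ndarray  # one value per window start position
    circular: bool = True

    @property
    def length(self) -> int:
        return len(self.coverage)


@dataclass
class Hotspot:
    start: int  # 1-based inclusive footprint of the peak (start of first window)
    end: int    # end of the region covered by the last above-threshold window
    max_windowed: float


def trim_read(seq: str, qualities: str | None = None, n: int = DEFAULT_TRIM):
    """Remove the less reliable first and last ``n`` bases of a read.

    Returns the trimmed sequence (and qualities, when given) or ``None``
    when nothing informative remains (length <= 2n).
    """
    if n < 0:
        raise ValueError("trim length must be >= 0")
    if len(seq) <= 2 * n:
        return None
    trimmed = seq[n : len(seq) - n] if n else seq
    if qualities is None:
        return trimmed
    return trimmed, (qualities[n : len(qualities) - n] if n else qualities)


def _seed_candidates(doubled: str, read: str, seed_k: int) -> set[int]:
    """Candidate 0-based offsets in the doubled sequence from exact k-mer seeds."""
    offs: set[int] = set()
    length = len(doubled) // 2
    for anchor in {0, max(0, len(read) // 2 - seed_k // 2), len(read) - seed_k}:
        seed = read[anchor : anchor + seed_k]
        start = 0
        while True:
            i = doubled.find(seed, start)
            if i == -1:
                break
            offs.add((i - anchor) % length)
            start = i + 1
    return offs


def map_read(
    read_id: str,
    seq: str,
    pmap: PlasmidMap,
    seed_k: int = DEFAULT_SEED_K,
) -> AlignedRead | None:
    """Place a read on the circular reference by k-mer seeding + ungapped check.

    Both orientations are tried against the doubled reference sequence
    (so footprints may wrap the origin).  The placement with the fewest
    mismatches wins; distinct placements tied for best are treated as
    ambiguous and the read is reported unmapped (``None``).  Reference N
    positions never count as mismatches.
    """
    if len(seq) < seed_k:
        return None
    if len(seq) >= pmap.length:
        raise ValueError("read length must be below the reference length")
    doubled = pmap.sequence + pmap.sequence
    length = pmap.length
    best: list[tuple[int, str, list[int]]] = []  # (offset, orientation, mismatches)
    best_score = None
    for orient, oriented in (("forward", seq.upper()),
                             ("reverse", reverse_complement(seq.upper()))):
        for off in sorted(_seed_candidates(doubled, oriented, seed_k)):
            window = doubled[off : off + len(oriented)]
            mism = [
                (off + i) % length + 1
                for i, (a, b) in enumerate(zip(window, oriented))
                if a != b and a != "N"
            ]
            score = len(mism)
            if best_score is None or score < best_score:
                best_score = score
                best = [(off, orient, mism)]
            elif score == best_score and all(
                (off % length, orient) != (b[0] % length, b[1]) for b in best
            ):
                best.append((off, orient, mism))
    if len(best) != 1:
        return None  # unmapped or ambiguous
    off, orient, mism = best[0]
    return AlignedRead(
        read_id=read_id,
        ref_start=off + 1,
        orientation=orient,
        aligned_length=len(seq),
        mismatch_positions=mism,
    )


def count_variants(
    alignments: list[AlignedRead], pmap: PlasmidMap
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position coverage and mismatch (base-variant) counts.

    Coverage counts every read overlapping a position; variant counts
    every read mismatching the reference there.  Forward and reverse
    reads contribute identically.
    """
    length = pmap.length
    coverage = np.zeros(length, dtype=np.int64)
    variants = np.zeros(length, dtype=np.int64)
    for ar in alignments:
        start0 = ar.ref_start - 1
        end0 = start0 + ar.aligned_length
        if end0 <= length:
            coverage[start0:end0] += 1
        else:  # wraps the origin
            coverage[start0:] += 1
            coverage[: end0 - length] += 1
        for pos in ar.mismatch_positions:
            variants[pos - 1] += 1
    if np.any(variants > coverage):
        raise ValueError("variant count exceeds coverage; alignments inconsistent")
    return coverage, variants


def read_sam(path, pmap: PlasmidMap) -> list[AlignedRead]:
    """Ingest pre-computed alignments from a SAM file.

    Mismatches are recomputed against the reference sequence rather than
    trusted from tags, so the reference map remains the single source of
    truth.  Secondary/supplementary and unmapped records are skipped.
    """
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            pairs = rec.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            query = rec.query_sequence.upper()
            mism = []
            ref_positions = [r for _, r in pairs]
            for q, r in pairs:
                ref_base = pmap.sequence[r]
                if ref_base != "N" and query[q] != ref_base:
                    mism.append(r + 1)
            start = min(ref_positions)
            span = max(ref_positions) - start + 1
            out.append(AlignedRead(
                read_id=rec.query_name,
                ref_start=start + 1,
                orientation="reverse" if rec.is_reverse else "forward",
                aligned_length=span,
                mismatch_positions=mism,
            ))
    return out


def normalize_and_window(
    coverage: np.ndarray,
    variant_count: np.ndarray,
    window_size: int = DEFAULT_WINDOW,
    circular: bool = True,
) -> LandscapeTrack:
    """Coverage-normalize variant counts and compute sliding-window sums.

    ``normalized[i] = variant_count[i] / (coverage[i] / mean_coverage)``,
    i.e. the variant count each position would show at the plasmid-wide
    mean coverage; zero-coverage positions yield 0.  Windowed values sum
    ``normalized`` over ``window_size`` consecutive positions anchored at
    every start position, wrapping the origin when ``circular``.
    """
    coverage = np.asarray(coverage, dtype=float)
    variant_count = np.asarray(variant_count, dtype=float)
    length = len(coverage)
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if window_size > length:
        raise ValueError(
            f"window_size {window_size} exceeds reference length {length}"
        )
    covered = coverage > 0
    if covered.mean() < 0.9:
        warnings.warn(
            f"only {100 * covered.mean():.1f}% of positions have coverage; "
            "normalization is unreliable", stacklevel=2,
        )
    mean_cov = coverage.mean()
    normalized = np.zeros(length)
    if mean_cov > 0:
        normalized[covered] = variant_count[covered] / (coverage[covered] / mean_cov)
    if circular:
        ext = np.concatenate([normalized, normalized[: window_size - 1]])
        cs = np.concatenate([[0.0], np.cumsum(ext)])
        windowed = cs[window_size:] - cs[:length]
    else:
        cs = np.concatenate([[0.0], np.cumsum(normalized)])
        windowed = cs[window_size:] - cs[: length - window_size + 1]
    return LandscapeTrack(
        coverage=coverage, variant_count=variant_count, normalized=normalized,
        window_size=window_size, windowed=windowed, circular=circular,
    )


def call_hotspots(
    track: LandscapeTrack, fold_threshold: float = DEFAULT_FOLD_THRESHOLD
) -> list[Hotspot]:
    """Segment the windowed track into peaks above a fold of the median.

    A hotspot is a maximal run of window start positions whose windowed
    value exceeds ``fold_threshold`` times the plasmid-wide median
    windowed value; runs separated by fewer than ``window_size`` start
    positions are merged.  The reported interval covers the footprint of
    the above-threshold windows (last window start + window_size - 1).
    """
    if fold_threshold < 1:
        raise ValueError("fold_threshold must be >= 1")
    w = track.windowed
    if not np.any(w > 0):
        return []
    threshold = fold_threshold * float(np.median(w))
    above = np.flatnonzero(w > threshold)
    if above.size == 0:
        return []
    runs: list[list[int]] = [[int(above[0]), int(above[0])]]
    for i in above[1:]:
        if i - runs[-1][1] < track.window_size:
            runs[-1][1] = int(i)
        else:
            runs.append([int(i), int(i)])
    # merge a run touching the end with one at the start (circular axis)
    if track.circular and len(runs) > 1:
        first, last = runs[0], runs[-1]
        if (track.length - 1 - last[1]) + first[0] + 1 < track.window_size:
            last[1] = first[1]  # wrapped run; report once anchored at the tail
            runs = runs[1:]
    peaks = []
    for a, b in runs:
        if b >= a:
            idx = np.arange(a, b + 1)
        else:  # wrapped run
            idx = np.concatenate([np.arange(a, track.length), np.arange(0, b + 1)])
        peaks.append(Hotspot(
            start=a + 1,
            end=((b + track.window_size - 1) % track.length) + 1,
            max_windowed=float(w[idx].max()),
        ))
    return peaks


def region_variant_sum(track: LandscapeTrack, start: int, end: int) -> float:
    """Sum of normalized variants over the inclusive range [start, end].

    The range may wrap the origin on a circular track.
    """
    length = track.length
    for pos in (start, end):
        if not 1 <= pos <= length:
            raise ValueError(f"position {pos} outside [1, {length}]")
    if start <= end:
        return float(track.normalized[start - 1 : end].sum())
    if not track.circular:
        raise ValueError("range wraps the origin of a non-circular track")
    return float(track.normalized[start - 1 :].sum() + track.normalized[:end].sum())


def write_track_tsv(track: LandscapeTrack, path, params: dict | None = None) -> None:
    """Write the landscape as TSV (position, coverage, variants, normalized, windowed)."""
    with open(path, "w") as fh:
        fh.write("# variant landscape; coordinates=1-based-inclusive\n")
        if params:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in sorted(params.items())) + "\n")
        fh.write("position\tcoverage\tvariant_count\tnormalized\twindowed\n")
        n_win = len(track.windowed)
        for i in range(track.length):
            win = f"{track.windowed[i]:.4f}" if i < n_win else ""
            fh.write(
                f"{i + 1}\t{int(track.coverage[i])}\t{int(track.variant_count[i])}\t"
                f"{track.normalized[i]:.4f}\t{win}\n"
            )


def write_peaks_tsv(peaks: list[Hotspot], path, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("# variant hotspots; coordinates=1-based-inclusive\n")
        if params:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in sorted(params.items())) + "\n")
        fh.write("start\tend\tmax_windowed\n")
        for p in peaks:
            fh.write(f"{p.start}\t{p.end}\t{p.max_windowed:.4f}\n")
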