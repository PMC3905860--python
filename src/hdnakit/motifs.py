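"""H-DNA candidate detection: mirror-symmetric purine/pyrimidine tracts.

Intramolecular triplex DNA (H-DNA) forms at poly(Pu.Py) tracts with mirror
repeat symmetry: half of the tract unpairs and one strand folds back to
pair with the purine-rich strand of the other half.  A candidate is
therefore a tract ``arm + spacer + reversed(arm)`` whose composition is
strongly purine-biased on one strand.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Default scanner thresholds.  The scale matches a ~23-bp promoter-derived
#: mirror-repeat tract; all three are caller-adjustable.
DEFAULT_MIN_ARM = 8
DEFAULT_MAX_SPACER = 8
DEFAULT_MIN_PURITY = 0.9


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def purine_fraction(seq: str) -> float:
    """Fraction of purines (A or G) in the sequence, case-insensitive."""
    if not seq:
        raise ValueError("empty sequence")
    up = seq.upper()
    return (up.count("A") + up.count("G")) / len(up)


def is_self_complementary(seq: str) -> bool:
    """True iff the sequence equals its own reverse complement.

    Such an oligonucleotide can fold into an intramolecular hairpin or
    anneal with a second copy into perfect duplex DNA.  Odd-length
    sequences are never self-complementary.
    """
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) % 2 == 1:
        return False
    return seq.upper() == reverse_complement(seq).upper()


@dataclass(frozen=True)
class MotifHit:
    """One H-DNA candidate tract (1-based inclusive, no wrap).

    ``end - start + 1 == 2 * arm_length + spacer_length``.  ``strand`` is
    the purine-richer strand and ``purine_fraction`` is evaluated on it.
    """

    start: int
    end: int
    arm_length: int
    spacer_length: int
    purine_fraction: float
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _tract_purity(seq: str) -> tuple[float, str]:
    """Purine fraction on the purine-richer strand, and that strand."""
    pf = purine_fraction(seq)
    if pf >= 0.5:
        return pf, "+"
    return 1.0 - pf, "-"


def find_mirror_repeats(
    seq: str,
    min_arm: int = DEFAULT_MIN_ARM,
    max_spacer: int = DEFAULT_MAX_SPACER,
    min_purity: float = DEFAULT_MIN_PURITY,
) -> list[MotifHit]:
    """Scan a sequence for mirror-repeat Pu.Py tracts (H-DNA candidates).

    A candidate is a triple (start, arm, spacer) with ``arm >= min_arm``,
    ``spacer <= max_spacer``, the second arm equal to the reverse of the
    first, and purine fraction of the whole tract on its richer strand at
    least ``min_purity``.  Candidates whose tract interval is strictly
    contained within another reported tract are pruned, so only maximal
    hits are returned, ordered by (start, end).

    N bases never participate in a tract.
    """
    if min_arm < 4:
        raise ValueError("min_arm must be >= 4")
    if max_spacer < 0:
        raise ValueError("max_spacer must be >= 0")
    up = seq.upper()
    n = len(up)
    candidates: list[MotifHit] = []
    # For each spacer placement, grow the arm outward from the centre; every
    # arm length from min_arm up to the maximal expansion is a candidate
    # (shorter arms can survive pruning when the maximal tract fails purity).
    for spacer in range(0, max_spacer + 1):
        for centre in range(min_arm, n - min_arm - spacer + 1):
            # arm1 ends at index centre-1; arm2 starts at centre+spacer (0-based)
            max_arm = 0
            while True:
                i = centre - 1 - max_arm
                j = centre + spacer + max_arm
                if i < 0 or j >= n or up[i] != up[j] or up[i] == "N":
                    break
                max_arm += 1
            for arm in range(min_arm, max_arm + 1):
                start0 = centre - arm
                end0 = centre + spacer + arm - 1
                tract = up[start0 : end0 + 1]
                purity, strand = _tract_purity(tract)
                if purity >= min_purity:
                    candidates.append(
                        MotifHit(
                            start=start0 + 1,
                            end=end0 + 1,
                            arm_length=arm,
                            spacer_length=spacer,
                            purine_fraction=purity,
                            strand=strand,
                        )
                    )
    return prune_contained(candidates)


def prune_contained(candidates: list[MotifHit]) -> list[MotifHit]:
    """Keep only hits not strictly contained in another kept hit.

    Hits are considered longest-first (ties: leftmost start, then longer
    arm), so the surviving set is deterministic.
    """
    ordered = sorted(candidates, key=lambda h: (-(h.length), h.start, -h.arm_length))
    kept: list[MotifHit] = []
    for hit in ordered:
        contained = any(
            k.start <= hit.start and hit.end <= k.end and
            (k.start, k.end) != (hit.start, hit.end)
            for k in kept
        )
        duplicate_interval = any((k.start, k.end) == (hit.start, hit.end) for k in kept)
        if not contained and not duplicate_interval:
            kept.append(hit)
    return sorted(kept, key=lambda h: (h.start, h.end))


def write_hits_tsv(hits: list[MotifHit], path, params: dict | None = None) -> None:
    """Write scanner hits as a BED-like TSV (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("# mirror-repeat Pu.Py tract hits; coordinates=1-based-inclusive\n")
        if params:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in sorted(params.items())) + "\n")
        fh.write("start\tend\tarm_length\tspacer_length\tpurine_fraction\tstrand\n")
        for h in hits:
            fh.write(
                f"{h.start}\t{h.end}\t{h.arm_length}\t{h.spacer_length}\t"
                f"{h.purine_fraction:.4f}\t{h.strand}\n"
            )
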