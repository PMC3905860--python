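"""Synthetic inputs with known ground truth.

Every pipeline stage has a matching generator here: a surrogate circular
reporter plasmid carrying either an H-DNA-forming (mirror-repeat Pu.Py)
or a composition-matched control insert, mutant clone sets drawn from a
mutation-class spectrum with engineered junction microhomologies,
short-read sets with planted high-variant regions, and binomial colony
screens.  All randomness flows from one explicit seed per call; there is
no global random state.

The surrogate plasmid backbone is a seeded random sequence: the toolkit
is exercised on plasmids whose published coordinates (insert at nt
1022-1044, reporter within nt 1040-1111, total ~5 kb) are reproduced,
while the backbone base sequence itself is synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hdnakit.plasmid import Feature, PlasmidMap
from hdnakit.spectrum import (
    CloneRecord,
    canonicalize_replacement,
    microhomology_length,
    size_class,
)
from hdnakit.stats import ColonyCount

DEFAULT_LENGTH = 5010  # 2.96 kb vector backbone + 2.05 kb insert-bearing fragment

#: Mirror-repeat Pu.Py tract for the H-DNA variant insert (23 bp:
#: 11-bp arm, 1-bp spacer, reflected arm; all purines on the top strand).
_HDNA_ARM = "GGAAGGGGAGG"
HDNA_INSERT = _HDNA_ARM + "G" + _HDNA_ARM[::-1]
#: Control insert: same length, mixed composition, no mirror symmetry.
CONTROL_INSERT = "ACGTTAGCATGCATCGGATCCTA"

INSERT_START, INSERT_END = 1022, 1044
REPORTER_START, REPORTER_END = 1040, 1111

DEFAULT_BACKBONE = {
    # label: (start, end, strand, kind)
    "marker_promoter": (1900, 1980, "+", "promoter"),
    "bacterial_origin": (2800, 2880, "+", "origin"),
    "viral_promoter": (3700, 3780, "+", "promoter"),
    "viral_origin": (4500, 4580, "+", "origin"),
}

#: Mutation elevation in H-DNA plasmids extends into the insert's flanks;
#: this is the hotspot footprint used when planting elevated variant rates.
HDNA_REGION_START, HDNA_REGION_END = 960, 1044

_CLASS_ORDER = (
    "large_deletion", "medium_deletion", "small_deletion",
    "insertion", "point_mutation",
)

#: Deletion size ranges per class (bp).  Only the class bounds (<50,
#: 50-100, >100) are fixed by the classification; within-class lengths are
#: uniform, with large deletions capped at 1500 bp.
DELETION_RANGES = {
    "large_deletion": (101, 1500),
    "medium_deletion": (50, 100),
    "small_deletion": (1, 49),
}


@dataclass
class SpectrumSpec:
    """Generating distribution for a mutant-clone set.

    Defaults emulate the observed junction anatomy of H-DNA-induced
    deletions: ~65% of deletion junctions carry a 1-6 bp microhomology,
    and ~12% carry a short (8-16 bp) de novo insert.
    """

    class_probs: dict[str, float]
    deletion_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DELETION_RANGES))
    microhomology_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.35, **{k: 0.65 / 6 for k in range(1, 7)}})
    junction_insertion_prob: float = 2 / 17
    junction_insertion_range: tuple[int, int] = (8, 16)
    insertion_length_range: tuple[int, int] = (1, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_probs.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"class probabilities sum to {total}, expected 1")
        for cls, (lo, hi) in self.deletion_ranges.items():
            blo, bhi = DELETION_RANGES[cls]
            if lo < blo or hi > bhi:
                raise ValueError(
                    f"{cls} length range ({lo}, {hi}) violates class bounds "
                    f"({blo}, {bhi})")
        if not np.isclose(sum(self.microhomology_probs.values()), 1.0, atol=1e-6):
            raise ValueError("microhomology probabilities must sum to 1")
        if not set(self.microhomology_probs) <= set(range(0, 7)):
            raise ValueError("microhomology support is 0-6 bp")


@dataclass
class ReadSimSpec:
    """Generating distribution for a short-read set over the plasmid."""

    read_length: int = 100
    n_reads: int = 2000
    base_error_rate: float = 0.002
    region_rates: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        for _, rate in self.region_rates + [("base", self.base_error_rate)]:
            if not 0 <= rate <= 1:
                raise ValueError(f"rate {rate} outside [0, 1]")


#: Class compositions of the four study arms.  The wild-type H-DNA
#: spectrum (40/33/13/7/7) and the control-plasmid point-mutation fraction
#: (87% wild-type, 73% depleted) and the depleted-cell large-deletion
#: fraction (60%) are fixed by the study design; the remaining splits are
#: chosen to complete each distribution.
_PRESETS = {
    "pMEXr_wt": {"large_deletion": 0.40, "medium_deletion": 0.33,
                 "small_deletion": 0.13, "insertion": 0.07, "point_mutation": 0.07},
    "pMEXr_dhx9kd": {"large_deletion": 0.60, "medium_deletion": 0.13,
                     "small_deletion": 0.13, "insertion": 0.07, "point_mutation": 0.07},
    "pCEX_wt": {"large_deletion": 0.0, "medium_deletion": 0.0,
                "small_deletion": 0.13, "insertion": 0.0, "point_mutation": 0.87},
    "pCEX_dhx9kd": {"large_deletion": 0.0, "medium_deletion": 0.13,
                    "small_deletion": 0.14, "insertion": 0.0, "point_mutation": 0.73},
}


def preset_spectra(name: str, seed: int = 0) -> SpectrumSpec:
    """Named class compositions for the four plasmid-by-depletion study arms."""
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; valid names: {sorted(_PRESETS)}")
    probs = _PRESETS[name]
    total = sum(probs.values())
    return SpectrumSpec(
        class_probs={k: v / total for k, v in probs.items()}, seed=seed)


def build_surrogate_map(
    variant: str,
    seed: int = 0,
    length: int = DEFAULT_LENGTH,
    backbone: dict | None = None,
) -> PlasmidMap:
    """A circular surrogate reporter plasmid with a structured insert.

    ``variant='hdna'`` embeds a 23-bp mirror-repeat Pu.Py tract at
    nt 1022-1044; ``variant='control'`` embeds a composition-mixed,
    non-mirror sequence of the same length at the same coordinates.  Both
    variants share length and feature coordinates, so results are directly
    comparable.
    """
    if variant not in ("hdna", "control"):
        raise ValueError("variant must be 'hdna' or 'control'")
    if length < 2 * REPORTER_END:
        raise ValueError(f"length {length} too short for the feature layout")
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=length)
    insert = HDNA_INSERT if variant == "hdna" else CONTROL_INSERT
    seq[INSERT_START - 1 : INSERT_END] = list(insert)
    sequence = "".join(seq)
    features = [
        Feature("insert", INSERT_START, INSERT_END, "+", "insert"),
        Feature("reporter", REPORTER_START, REPORTER_END, "+", "reporter"),
        Feature("hdna_region", HDNA_REGION_START, HDNA_REGION_END, "+", "other"),
    ]
    for label, (start, end, strand, kind) in (backbone or DEFAULT_BACKBONE).items():
        features.append(Feature(label, start, end, strand, kind))
    name = "pMEXr_surrogate" if variant == "hdna" else "pCEX_surrogate"
    return PlasmidMap(name=name, sequence=sequence, circular=True, features=features)


def _left_align(pmap: PlasmidMap, prox: int, dist: int, ins: str) -> tuple[int, int, str]:
    """Smallest-proximal-coordinate placement of a deletion (+ optional insert)."""
    while prox > 1:
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


def _place_deletion(
    pmap: PlasmidMap, rng: np.random.Generator,
    size_range: tuple[int, int], target_mh: int, margin: int,
) -> tuple[int, int]:
    """Find a deletion interval of the requested size class and microhomology.

    Searches random placements for one whose junction slide slack equals
    the target; if none is found the target is relaxed to whatever a
    random placement yields (the truth table always records the realized
    microhomology).
    """
    lo, hi = size_range
    hi = min(hi, pmap.length - 2 * margin - 1)
    for _ in range(40):
        size = int(rng.integers(lo, hi + 1))
        candidates = rng.permutation(np.arange(margin, pmap.length - margin - size))
        for p in candidates[:500]:
            p = int(p)
            if microhomology_length(pmap, p, p + size - 1) == target_mh:
                return p, p + size - 1
    size = int(rng.integers(lo, hi + 1))
    p = int(rng.integers(margin, pmap.length - margin - size))
    return p, p + size - 1


def simulate_clone_set(
    pmap: PlasmidMap,
    spec: SpectrumSpec,
    n: int,
    seed: int | None = None,
    exact_counts: dict[str, int] | None = None,
    group: str = "",
    margin: int = 60,
) -> tuple[list[CloneRecord], pd.DataFrame]:
    """Mutant clones, each the reference with one sampled event applied.

    Events are kept ``margin`` bp away from the circle's origin so clones
    remain colinear with the linearized reference.  Returns the clone
    records plus a truth table of every event (left-aligned coordinates,
    realized microhomology, junction insert).  ``exact_counts`` pins the
    per-class composition instead of multinomial sampling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if exact_counts is not None:
        if sum(exact_counts.values()) != n:
            raise ValueError("exact_counts must sum to n")
        classes = [c for c in _CLASS_ORDER for _ in range(exact_counts.get(c, 0))]
    else:
        probs = [spec.class_probs.get(c, 0.0) for c in _CLASS_ORDER]
        classes = list(rng.choice(_CLASS_ORDER, size=n, p=probs))
    mh_support = sorted(spec.microhomology_probs)
    mh_probs = [spec.microhomology_probs[k] for k in mh_support]
    clones: list[CloneRecord] = []
    rows = []
    ref = pmap.sequence
    for i, cls in enumerate(classes):
        clone_id = f"clone{i + 1:03d}"
        if cls == "point_mutation":
            pos = int(rng.integers(margin, pmap.length - margin))
            old = ref[pos - 1]
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            seq = ref[: pos - 1] + new + ref[pos:]
            rows.append((clone_id, cls, "substitution", pos, pos, 1, None, new))
        elif cls == "insertion":
            lo, hi = spec.insertion_length_range
            ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(lo, hi + 1))))
            pos = int(rng.integers(margin, pmap.length - margin))
            # left-normalize the inserted copy the way the caller will report it
            while pos > 1 and pmap.base(pos) == ins[-1]:
                ins = pmap.base(pos) + ins[:-1]
                pos -= 1
            seq = ref[:pos] + ins + ref[pos:]
            rows.append((clone_id, cls, "insertion", pos, pos, len(ins), None, ins))
        else:
            target_mh = int(rng.choice(mh_support, p=mh_probs))
            prox, dist = _place_deletion(
                pmap, rng, spec.deletion_ranges[cls], target_mh, margin)
            ins = ""
            if rng.random() < spec.junction_insertion_prob:
                ilen = int(rng.integers(spec.junction_insertion_range[0],
                                        spec.junction_insertion_range[1] + 1))
                ins = "".join(rng.choice(list("ACGT"), size=ilen))
                # the truth must be the minimal representation of the event
                prox, dist, ins = canonicalize_replacement(pmap, prox, dist, ins)
            prox, dist, ins = _left_align(pmap, prox, dist, ins)
            size = dist - prox + 1
            seq = ref[: prox - 1] + ins + ref[dist:]
            rows.append((
                clone_id, f"{size_class(size)}_deletion", "deletion", prox, dist,
                size, microhomology_length(pmap, prox, dist), ins,
            ))
        clones.append(CloneRecord(clone_id, seq, group=group))
    truth = pd.DataFrame(
        rows,
        columns=["clone_id", "class", "type", "proximal", "distal",
                 "size", "microhomology", "inserted_seq"],
    )
    return clones, truth


def region_rate_array(pmap: PlasmidMap, spec: ReadSimSpec) -> np.ndarray:
    """Per-position substitution rate: base rate, elevated inside listed features."""
    rates = np.full(pmap.length, spec.base_error_rate)
    by_label = {f.label: f for f in pmap.features}
    for label, rate in spec.region_rates:
        feat = by_label.get(label)
        if feat is None:
            raise ValueError(f"no feature labelled {label!r} on {pmap.name}")
        if feat.start <= feat.end:
            rates[feat.start - 1 : feat.end] = rate
        else:
            rates[feat.start - 1 :] = rate
            rates[: feat.end] = rate
    return rates


def simulate_reads(
    pmap: PlasmidMap, spec: ReadSimSpec
) -> tuple[list[tuple[str, str, str]], np.ndarray]:
    """Uniform circular shotgun reads with per-position substitution rates.

    Read start positions and orientations are uniform over the circle;
    each covered base substitutes to a random different base with the
    per-position probability from :func:`region_rate_array`.  Qualities
    are a constant placeholder.  Returns ``(reads, rate_array)`` where
    each read is ``(read_id, sequence, qualities)``.
    """
    if spec.read_length >= pmap.length:
        raise ValueError("read length must be below the reference length")
    rng = np.random.default_rng(spec.seed)
    rates = region_rate_array(pmap, spec)
    doubled = pmap.sequence + pmap.sequence
    qual = "I" * spec.read_length
    reads = []
    bases = np.array(list("ACGT"))
    for i in range(spec.n_reads):
        start0 = int(rng.integers(0, pmap.length))
        template = list(doubled[start0 : start0 + spec.read_length])
        footprint = (start0 + np.arange(spec.read_length)) % pmap.length
        hits = np.flatnonzero(rng.random(spec.read_length) < rates[footprint])
        for j in hits:
            alt = [b for b in "ACGT" if b != template[j]]
            template[j] = str(rng.choice(alt))
        seq = "".join(template)
        if rng.random() < 0.5:
            from hdnakit.motifs import reverse_complement
            seq = reverse_complement(seq)
            orient = "rev"
        else:
            orient = "fwd"
        reads.append((f"read{i + 1:05d}_{orient}", seq, qual))
    return reads, rates


def simulate_colony_assay(
    true_freq: float, n_colonies: int, seed: int = 0
) -> ColonyCount:
    """A blue/white colony screen: white ~ Binomial(n_colonies, true_freq)."""
    if not 0 <= true_freq <= 1:
        raise ValueError("true_freq must lie in [0, 1]")
    if n_colonies < 0:
        raise ValueError("n_colonies must be non-negative")
    rng = np.random.default_rng(seed)
    white = int(rng.binomial(n_colonies, true_freq))
    return ColonyCount(white=white, blue=n_colonies - white)


def write_clones_fasta(clones: list[CloneRecord], path) -> None:
    with open(path, "w") as fh:
        for c in clones:
            header = f">{c.clone_id}" + (f" group={c.group}" if c.group else "")
            fh.write(header + "\n")
            for i in range(0, len(c.sequence), 70):
                fh.write(c.sequence[i : i + 70] + "\n")


def read_clones_fasta(path) -> list[CloneRecord]:
    from Bio import SeqIO

    clones = []
    for rec in SeqIO.parse(str(path), "fasta"):
        group = ""
        for token in rec.description.split():
            if token.startswith("group="):
                group = token[len("group="):]
        clones.append(CloneRecord(rec.id, str(rec.seq), group=group))
    return clones


def write_fastq(reads: list[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
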