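"""Circular plasmid reference model and coordinate arithmetic.

Coordinates are 1-based inclusive everywhere in this package; an interval
whose start exceeds its end wraps through the origin of the circle.  The
reference is the coordinate authority for every downstream stage (motif
scanning, clone-spectrum calling, the variant landscape).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

FEATURE_KINDS = ("insert", "reporter", "origin", "promoter", "marker", "other")

_VALID_BASES = re.compile(r"^[ACGTN]+$")

# GenBank feature types mapped onto our coarse feature kinds.
_GENBANK_KIND = {
    "rep_origin": "origin",
    "promoter": "promoter",
    "misc_feature": "other",
    "gene": "other",
    "CDS": "other",
}
_KIND_GENBANK = {
    "origin": "rep_origin",
    "promoter": "promoter",
    "reporter": "gene",
    "insert": "misc_feature",
    "marker": "gene",
    "other": "misc_feature",
}


@dataclass
class Feature:
    """An annotated element on the plasmid (1-based inclusive coordinates).

    A feature with ``start > end`` wraps through the circle's origin.
    """

    label: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "other"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"feature {self.label!r}: positions must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.label!r}: strand must be '+' or '-'")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(
                f"feature {self.label!r}: unknown kind {self.kind!r}; "
                f"expected one of {FEATURE_KINDS}"
            )

    def span(self, length: int) -> int:
        """Length in bp of the feature on a circle of the given length."""
        if self.start <= self.end:
            return self.end - self.start + 1
        return length - self.start + 1 + self.end


@dataclass
class PlasmidMap:
    """A circular (or linear) plasmid reference with annotated features."""

    name: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("plasmid sequence must be non-empty")
        if not _VALID_BASES.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"non-nucleotide symbol(s) in sequence: {bad}")
        for feat in self.features:
            if feat.start > self.length or feat.end > self.length:
                raise ValueError(
                    f"feature {feat.label!r} ({feat.start}..{feat.end}) exceeds "
                    f"plasmid length {self.length}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at a 1-based position, wrapping on a circular map."""
        if self.circular:
            return self.sequence[(pos - 1) % self.length]
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} outside [1, {self.length}]")
        return self.sequence[pos - 1]


def load_reference(path: str | Path) -> PlasmidMap:
    """Read a single-record FASTA or GenBank file into a :class:`PlasmidMap`.

    The format is sniffed from the first non-blank character ('>' means
    FASTA, anything else GenBank).  GenBank features are mapped onto
    :class:`Feature` records; a FASTA record yields an empty feature list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.read(1024).lstrip()
    fmt = "fasta" if first.startswith(">") else "genbank"
    records = list(SeqIO.parse(path, fmt))
    if len(records) != 1:
        raise ValueError(
            f"{path}: expected exactly one record, found {len(records)}"
        )
    rec = records[0]
    circular = rec.annotations.get("topology", "circular") == "circular"
    features: list[Feature] = []
    if fmt == "genbank":
        for sf in rec.features:
            if sf.type == "source":
                continue
            start = int(sf.location.start) + 1
            end = int(sf.location.end)
            strand = "-" if sf.location.strand == -1 else "+"
            label = sf.qualifiers.get("label", [sf.type])[0]
            note = sf.qualifiers.get("note", [""])[0]
            kind = note if note in FEATURE_KINDS else _GENBANK_KIND.get(sf.type, "other")
            features.append(Feature(label, start, end, strand, kind))
    return PlasmidMap(
        name=rec.id or path.stem,
        sequence=str(rec.seq).upper(),
        circular=circular,
        features=features,
    )


def write_reference(pmap: PlasmidMap, path: str | Path, fmt: str = "genbank") -> None:
    """Write a map as GenBank (features preserved) or FASTA (sequence only)."""
    rec = SeqRecord(
        Seq(pmap.sequence),
        id=pmap.name,
        name=pmap.name[:16],
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if pmap.circular else "linear",
        },
    )
    for feat in pmap.features:
        loc = FeatureLocation(feat.start - 1, feat.end, strand=1 if feat.strand == "+" else -1)
        rec.features.append(
            SeqFeature(
                loc,
                type=_KIND_GENBANK[feat.kind],
                qualifiers={"label": [feat.label], "note": [feat.kind]},
            )
        )
    SeqIO.write([rec], str(path), fmt)


def write_feature_table(pmap: PlasmidMap, path: str | Path) -> None:
    """Write the feature annotation as a TSV table (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write(f"# plasmid={pmap.name} length={pmap.length} "
                 f"circular={pmap.circular} coordinates=1-based-inclusive\n")
        fh.write("label\tstart\tend\tstrand\tkind\n")
        for feat in pmap.features:
            fh.write(f"{feat.label}\t{feat.start}\t{feat.end}\t{feat.strand}\t{feat.kind}\n")


def circular_substring(pmap: PlasmidMap, start: int, end: int) -> str:
    """Sequence from ``start`` to ``end`` inclusive, wrapping when start > end.

    ``(k, k)`` returns the single base at k; ``(1, length)`` returns the full
    sequence.
    """
    length = pmap.length
    for pos in (start, end):
        if not 1 <= pos <= length:
            raise ValueError(f"position {pos} outside [1, {length}]")
    if start <= end:
        return pmap.sequence[start - 1 : end]
    if not pmap.circular:
        raise ValueError("interval wraps the origin of a non-circular map")
    return pmap.sequence[start - 1 :] + pmap.sequence[:end]


def digest_fragments(pmap: PlasmidMap, cut_positions: list[int]) -> list[int]:
    """Fragment lengths from restriction cuts on a circular map.

    ``n`` cuts on a circle yield ``n`` fragments whose lengths sum to the
    plasmid length.  A cut at position ``p`` severs the backbone between
    positions ``p`` and ``p + 1``.
    """
    if not pmap.circular:
        raise ValueError("digest_fragments requires a circular map")
    cuts = sorted(set(cut_positions))
    if not cuts:
        raise ValueError("at least one cut is required to linearize the circle")
    for cut in cuts:
        if not 1 <= cut <= pmap.length:
            raise ValueError(f"cut position {cut} outside [1, {pmap.length}]")
    if len(cuts) == 1:
        return [pmap.length]
    frags = [b - a for a, b in zip(cuts, cuts[1:])]
    frags.append(pmap.length - cuts[-1] + cuts[0])
    return frags
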