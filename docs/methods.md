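# Methods

This note documents the models, conventions and numerical choices behind
`hdnakit`, and what the synthetic-data generator does and does not
emulate.

## Coordinate model

All coordinates are 1-based inclusive. The reference is a circle: an
interval with `start > end` wraps through the origin, and features are
stored as single records with `start > end` rather than split in two,
preserving single-record integrity on the circular axis. Restriction
cuts on a circle produce as many fragments as cuts, and fragment lengths
always sum to the plasmid length. `N` bases are accepted in references;
they participate in coordinates but are masked wherever bases are
compared (motif arms, read mismatches), a conservative treatment of
ambiguity.

## Mirror-repeat (H-DNA candidate) scanner

An H-DNA candidate is a tract `arm + spacer + reversed(arm)` — a textual
mirror repeat — whose purine fraction on the purine-richer strand meets a
threshold. Defaults are arm ≥ 8 bp, spacer ≤ 8 bp, purity ≥ 0.9. These
thresholds are this package's choice: they match the scale of the ~23-bp
promoter-derived tract used in the reporter construct, but the underlying
assays define no numeric cutoff, and natural H-DNA-forming elements often
tolerate interruptions of the mirror that this exact-mirror-plus-spacer
model does not. Every arm length from the minimum up to the maximal
symmetric expansion is considered a candidate (a shorter arm can pass
purity when the maximal tract fails it); candidates strictly contained in
a reported tract are pruned, longest-first with ties broken by leftmost
start, so output is deterministic. Purity is evaluated on whichever
strand is purine-richer because the triplex-forming requirement is
strand-symmetric.

## Clone-spectrum pipeline

**Alignment.** Clones are aligned globally against the full reference
with affine gap scoring (match +1, mismatch −2, gap open −5, gap extend
−0.5; all config-exposed). A unit-cost edit-distance backend (`edlib`)
is offered for large simulated clone sets; both backends feed the same
event normalization, so calls agree on clean single-event clones while
the edlib backend is roughly two orders of magnitude faster on ~5 kb
sequences. Alignments below 50% identity raise an "unalignable clone"
error; such clones are reported separately and excluded from spectrum
percentages.

**Event calling.** Columns that are not exact matches are grouped into
blocks. Match runs shorter than 10 bp flanked by gap-containing blocks
are treated as spurious junction micro-matches — degenerate-gap aligners
thread retained clone bases through a deleted segment — and absorbed, so
a deletion carrying a de novo junction insert is called as one event
rather than a deletion/insertion pair. Each block is then reduced to its
minimal (parsimony) representation by trimming bases shared between the
margins of the deleted segment and the replacement, and finally
left-aligned (smallest proximal coordinate), the standard indel
normalization. The same canonicalization is applied to the generator's
truth tables, so recovery comparisons are representation-independent.

**Microhomology.** The microhomology of a deletion is defined as its
junction slide slack: the number of alternative placements of the
same-size deletion that reconstruct the identical mutant sequence,
equivalently the length of the repeat shared between the deleted
segment's margin and the flanking sequence. This definition is invariant
to which equivalent placement is reported, and is checked against a
brute-force slide oracle in the tests.

**Classification.** Deletions are small (< 50 bp), medium (50–100 bp,
inclusive on both ends) or large (> 100 bp). A clone's class is its
dominant event — largest deletion, else insertion, else point mutation —
mirroring one-class-per-clone pie-chart reporting. Percentages are
rounded to integers and may not sum to exactly 100.

## Variant landscape

Reads lose their first and last 20 bases (the less reliable cycle ends);
reads with ≤ 2×20 bases are discarded. The built-in mapper seeds three
exact 20-mers (both orientations) against the doubled reference so
footprints wrap the origin, extends ungapped, and drops reads whose best
placement is tied (no multi-mapping, which would double-count variants).
SAM input is accepted as an alternative; mismatches are recomputed
against the reference rather than trusted from tags so the reference
map stays the single source of truth.

Per-position variant counts (forward and reverse reads combined) are
normalized by relative coverage: `normalized[i] = variants[i] /
(coverage[i] / mean coverage)`, i.e. the count the position would show
at the plasmid-wide mean coverage. This reading of
coverage-normalization preserves the count scale while removing
coverage bias; zero-coverage positions yield 0 and a warning fires when
fewer than 90% of positions are covered. Windowed values sum the
normalized track over 50 consecutive bp at every start position,
wrapping the origin (a linear mode exists for plot parity); window sums
therefore conserve mass: Σ windowed = window × Σ normalized.

Hotspots are maximal runs of window starts exceeding `fold_threshold`
(default 5) times the plasmid-wide median windowed value, with runs
separated by less than one window merged. Both the normalization formula
and the peak criterion are package choices exposed in the configuration,
not claims about any particular published analysis.

## Assay statistics

Mutation frequency is white/(white+blue) with a Wilson 95% score
interval (cross-checked against Clopper–Pearson in the tests); when
replicate-level frequencies are supplied, mean ± s.d. style summaries
can be computed from them directly. Fold changes report the ratio and
its nearest-integer label. The Holm–Šidák step-down adjustment uses
`p̃₍ᵢ₎ = 1 − (1 − p₍ᵢ₎)^(m−i+1)` on ascending p-values with a running
maximum; because colony screens are binomial counts rather than Gaussian
group means, the omnibus comparison is realized as pairwise
two-proportion z-tests followed by this adjustment (a replicate-level
Welch-t mode is also provided). Densitometry reductions are exact
arithmetic: percent unwinding `100·(OC+L)/(OC+L+CC)`, net cleavage
`F = f_s − f_c` with `f_c` the mean over no-enzyme control lanes, and
ChIP percent IP `100·IP/input`. An optional background-frequency
subtraction exists but is off by default; uncorrected frequencies are
the primary output.

## Synthetic data: what it emulates, and what it does not

The surrogate plasmid is 5,010 bp (matching the 2.96 + 2.05 kb fragment
arithmetic of the real construct) with the structured insert at nt
1022–1044, the reporter within nt 1040–1111, and four backbone elements
(marker promoter, bacterial origin, viral promoter, viral origin) at
fixed, configurable positions. The true vector sequence is not public in
this form, so the backbone is a seeded uniform random sequence patched
with the engineered insert — the H-DNA variant carries an 11-bp-arm
pure-purine mirror repeat, the control a composition-mixed non-mirror
sequence of identical length and position. A `hdna_region` feature (nt
960–1044) records the hotspot footprint: instability in such constructs
extends into the insert's flanks, and planted rate elevations use this
wider region.

Clone sets apply exactly one event per clone, kept 60 bp away from the
linearization origin. Class compositions come from named presets; the
wild-type H-DNA preset is 40/33/13/7/7 (large/medium/small deletion/
insertion/point), the control presets are point-mutation-dominated
(87% / 73%), and the depleted-cell H-DNA preset has 60% large deletions.
Where a composition is only partially constrained by the study design,
the remaining mass is split evenly and recorded here. Within-class
deletion lengths are uniform (large capped at 1,500 bp) — the true
length distribution is unknown, and this choice is config-exposed.
Junction microhomologies are drawn on support 0–6 bp (35% none, the
rest uniform, echoing 11/17 junctions with homology) and realized by
searching the fixed reference for an interval whose slide slack equals
the target; when no placement exists the truth table records the
realized value, so ground truth is always exact. About 12% of deletions
carry an 8–16 bp de novo junction insert.

Reads are uniform circular shotgun with per-base substitution at a base
rate (default 0.002) elevated inside listed feature regions; no indels,
quality profiles, PCR duplicates or chimeras are modeled, and qualities
are a constant placeholder. Colony screens are direct binomial draws.
Consequently, passing recovery tests demonstrates the pipeline's
correctness under clean single-event clones and uniform substitution
noise; they do not certify behavior on real chromatograms, mixed clones,
or structured sequencing error.

The deterministic fixture `wildtype_spectrum_fixture` (seed 1022) is the integer
realization at n = 15 of the wild-type H-DNA composition — 6/5/2/1/1 —
and classifies to 87% deletions and 40% large deletions; it is generated
programmatically rather than shipped as data so it can never drift from
the generator.

## Problem sizes and determinism

Every generator takes one explicit seed and derives all randomness from
it; re-runs are byte-identical. The test suite and acceptance script use
desk-scale sizes chosen as this package's defaults: 15-clone fixtures
and 100–500-clone recovery sets for the spectrum stage, 2,000 reads of
100 bp (~24× mean coverage after trimming) for the landscape stage —
enough for 10× rate elevations to exceed the 5× median threshold with
wide margin, while binomial noise keeps background windows far below it.

## Known limitations

- The scanner requires exact mirror symmetry within the spacer model;
  interrupted natural elements may be fragmented or missed.
- The landscape counts base variants only (no indel calling from short
  reads), and the mapper is exact-seed based — it is intended for
  simulated or high-identity plasmid reads, not a general aligner.
- Deletions spanning the linearization origin are supported by the
  circular span arithmetic but not generated by the simulator, so that
  path is exercised only by unit tests.
- Spectrum percentages are integer-rounded per class and may not total
  100, matching the reporting convention they emulate.
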