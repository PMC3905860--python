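"""Frozen deterministic fixtures.

``wildtype_spectrum_fixture`` is the 15-clone integer realization of the wild-type
H-DNA-plasmid mutation spectrum (40/33/13/7/7 percent across large /
medium / small deletions, insertions and point mutations): 6 large, 5
medium and 2 small deletions, 1 insertion and 1 point mutation.  Its seed
is fixed so the clone set, and everything computed from it, is byte-stable
across runs and machines.
"""

from __future__ import annotations

import pandas as pd

from hdnakit.plasmid import PlasmidMap
from hdnakit.simulate import build_surrogate_map, preset_spectra, simulate_clone_set
from hdnakit.spectrum import CloneRecord

FIXTURE_SEED = 1022  # position of the structured insert; an arbitrary frozen seed

WT15_CLASS_COUNTS = {
    "large_deletion": 6,
    "medium_deletion": 5,
    "small_deletion": 2,
    "insertion": 1,
    "point_mutation": 1,
}


def wildtype_spectrum_fixture() -> tuple[PlasmidMap, list[CloneRecord], pd.DataFrame]:
    """The deterministic 15-clone wild-type H-DNA spectrum fixture.

    Returns ``(reference map, clones, truth table)``.
    """
    pmap = build_surrogate_map("hdna", seed=FIXTURE_SEED)
    spec = preset_spectra("pMEXr_wt", seed=FIXTURE_SEED)
    clones, truth = simulate_clone_set(
        pmap, spec, n=15, seed=FIXTURE_SEED,
        exact_counts=WT15_CLASS_COUNTS, group="pMEXr_wt",
    )
    return pmap, clones, truth
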