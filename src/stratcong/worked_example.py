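"""Reconstruction of the classic five-taxon worked example.

The standard textbook illustration of these indices uses five taxa whose FO
dates sit on unit stratigraphic intervals 1-8, chosen so that the
irreversible age character has minimum possible length Lm = 5 (the steps
between the oldest and youngest intervals) and optimized length Lo = 9 on
the depicted tree, with Gmax = 14 — making MSM* = Lm/Lo = 5/9 and
GER = 1 - (9-5)/(14-5) coincide at 0.556.  This module brute-forces a
(topology, FO table) fixture satisfying exactly those constraints from
first principles, as an end-to-end check of the whole index stack.
"""

from __future__ import annotations

import itertools

import numpy as np

from .congruence import TopologyArrays, sankoff_irreversible_length
from .stratigraphy import FOTable
from .trees import Cladogram, enumerate_topologies

__all__ = ["find_five_taxon_fixture"]


def find_five_taxon_fixture(
    lm: float = 5,
    lo: float = 9,
    g_max: float = 14,
    intervals: tuple[int, int] = (1, 8),
) -> tuple[Cladogram, FOTable]:
    """Brute-force a five-taxon fixture with the stated character lengths.

    Searches all 105 rooted binary five-taxon topologies crossed with all FO
    multisets on the unit intervals whose span equals ``lm`` and whose
    worst-case ghost-range sum equals ``g_max``, and returns the first pair
    whose optimized irreversible age character has length ``lo`` (verified
    with the independent Sankoff dynamic program).
    """
    labels = list("ABCDE")
    topologies = [(t, TopologyArrays(t)) for t in enumerate_topologies(labels)]
    low, high = intervals
    for combo in itertools.combinations_with_replacement(range(low, high + 1), 5):
        ages = np.asarray(combo, dtype=float)
        if ages.max() - ages.min() != lm:
            continue
        if (ages.max() - ages).sum() != g_max:
            continue
        for perm in sorted(set(itertools.permutations(ages))):
            vec = np.asarray(perm)
            for tree, arrays in topologies:
                if arrays.mig(vec) == lo:
                    fo = FOTable.from_ages(dict(zip(arrays.tip_labels, vec)))
                    # cross-check with the independent DP before accepting
                    if sankoff_irreversible_length(tree, fo) == lo:
                        return tree, fo
    raise ValueError("no fixture satisfies the stated constraints")
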