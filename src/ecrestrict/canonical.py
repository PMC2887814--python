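"""Published fold-change inputs for canonical endothelial-restricted
marker genes.

Each entry carries the two measured inputs of the composite rank score
for a well-known endothelial marker transcript: ``fc``, the
endothelial/non-endothelial mean-signal ratio from a primary cultured
cell panel, and ``ref_fold``, the same ratio measured in the public
REFEXA primary-cell compendium. The rank score itself is never stored —
it is recomputed by :func:`ecrestrict.specificity.rank_score`.

These rows serve as worked examples and as fixed inputs for regression
checks of the ranking operation.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MarkerFoldChanges:
    probe: str
    gene: str
    fc: float
    ref_fold: float


CANONICAL_MARKERS: tuple[MarkerFoldChanges, ...] = (
    MarkerFoldChanges("205612_at", "MMRN1", 172.65, 64.625),
    MarkerFoldChanges("204482_at", "CLDN5", 124.75, 47.5625),
    MarkerFoldChanges("202112_at", "VWF", 61.15, 78.05172414),
    MarkerFoldChanges("227779_at", "ECSCR", 53.73, 12.03448276),
    MarkerFoldChanges("238036_at", "SHE", 3.06, 3.219512195),
)
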