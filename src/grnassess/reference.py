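"""Published ensemble-bound sizes for the DREAM 4 in silico subchallenges.

The DREAM 4 In Silico Network Challenge used five 10-gene and five 100-gene
gold-standard networks (GeneNetWeaver extractions from E. coli and yeast
regulatory networks, auto-regulation removed).  The table below records, for
each network, the published edge counts of the gold standard (``P``), the
ensemble lower bound (``G_L``), the ensemble upper bound / transitive
closure (``G_U``) and the non-inferable set (``Ē``) under a complete
single-gene KO/KD design.

These are literature values kept for consistency checks and reporting; the
gold-standard files themselves are distributed by the DREAM project and are
not bundled here.  Running ``grnassess bounds`` on a downloaded gold
standard recomputes the same three bound columns from scratch.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = ["BoundSizes", "DREAM4_REPORTED_BOUND_SIZES"]


class BoundSizes(NamedTuple):
    gold: int
    lower: int
    upper: int
    non_inferable: int


#: (subchallenge size, network index) -> published edge counts.
DREAM4_REPORTED_BOUND_SIZES: dict[tuple[int, int], BoundSizes] = {
    (10, 1): BoundSizes(15, 5, 21, 16),
    (10, 2): BoundSizes(16, 2, 47, 45),
    (10, 3): BoundSizes(15, 1, 59, 58),
    (10, 4): BoundSizes(13, 3, 40, 37),
    (10, 5): BoundSizes(12, 5, 33, 28),
    (100, 1): BoundSizes(176, 93, 639, 546),
    (100, 2): BoundSizes(249, 60, 667, 607),
    (100, 3): BoundSizes(195, 35, 2375, 2340),
    (100, 4): BoundSizes(211, 38, 2316, 2278),
    (100, 5): BoundSizes(193, 60, 953, 893),
}
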