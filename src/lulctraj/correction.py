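"""Temporal-consistency correction of disallowed transitions.

Over the gaps between observations a pixel cannot plausibly return from
cleared land (NF) or regrowth (SF) to mature forest (MF): such a label
sequence is a classification error, not a land-cover change. The correction
relabels the offending MF as SF — never as NF, since spectral confusion
between NF and MF is unlikely while older regrowth is easily confused with
mature forest.

The scan is a single chronological pass in which each corrected date feeds
the comparison for the next one, so corrections propagate forward; this is
equivalent to rescanning until fixpoint (property-tested exhaustively for
short sequences).
"""

from __future__ import annotations

import pandas as pd

from .codes import MF, NF, NODATA, SF
from .core import ClassifiedStack, format_date


def correct_disallowed_transitions(
    stack: ClassifiedStack,
) -> tuple[ClassifiedStack, pd.DataFrame]:
    """Relabel MF that follows SF or NF as SF, scanning dates in order.

    NODATA dates are transparent: the comparison for each date uses the most
    recent non-NODATA label of the pixel, so cloud gaps do not break run
    logic. WATER and NODATA cells themselves are never altered.

    Returns the corrected stack and a per-date table of correction counts
    (the first date can never be corrected and is reported as 0).
    """
    grids = stack.grids()
    # last non-NODATA label seen per pixel (NODATA where nothing seen yet)
    prev = grids[0].copy()
    counts = [0]
    for k in range(1, stack.n_dates):
        g = grids[k]
        bad = ((prev == SF) | (prev == NF)) & (g == MF)
        g[bad] = SF
        counts.append(int(bad.sum()))
        observed = g != NODATA
        prev[observed] = g[observed]
    corrected = stack.with_grids(grids)
    table = pd.DataFrame(
        {
            "date": [format_date(d) for d in stack.dates],
            "n_corrected": counts,
            "area_corrected_ha": [c * stack.pixel_area_ha for c in counts],
        }
    )
    return corrected, table
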