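"""Category codes for the land-cover alphabet.

The three thematic classes are mature (primary) forest MF, non-forest NF
(crops, pasture, bare ground) and secondary (regenerating) forest SF.
WATER is a permanent common mask; NODATA marks per-date gaps (cloud).
Codes are fixed small integers so map files round-trip bit-exactly.
"""

from __future__ import annotations

import numpy as np

WATER: int = 0
MF: int = 1
NF: int = 2
SF: int = 3
NODATA: int = 255

#: the classes that participate in change analysis, in canonical order
THEMATIC: tuple[int, ...] = (MF, NF, SF)
THEMATIC_LABELS: tuple[str, ...] = ("MF", "NF", "SF")

ALL_CODES: frozenset[int] = frozenset({WATER, MF, NF, SF, NODATA})

CODE_TO_LABEL: dict[int, str] = {
    WATER: "WATER",
    MF: "MF",
    NF: "NF",
    SF: "SF",
    NODATA: "NODATA",
}
LABEL_TO_CODE: dict[str, int] = {v: k for k, v in CODE_TO_LABEL.items()}

GRID_DTYPE = np.uint8


def validate_codes(grid: np.ndarray) -> None:
    """Raise ``ValueError`` naming any code outside the 5-code alphabet."""
    values = np.unique(grid)
    bad = [int(v) for v in values if int(v) not in ALL_CODES]
    if bad:
        raise ValueError(
            f"unknown land-cover codes {bad}; allowed codes are "
            f"{sorted(ALL_CODES)} ({CODE_TO_LABEL})"
        )
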