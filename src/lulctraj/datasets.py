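"""Bundled example data: published accuracy and land-cover tables.

These small tables come from a published multi-decade Landsat land-cover
study of three Brazilian Amazon sites — north of Manaus (Amazonas), south of
Santarem (Para) and Machadinho d'Oeste (Rondonia) — whose maps distinguish
mature forest (MF), non-forest (NF) and secondary forest (SF). They serve as
worked-example inputs: validation error matrices (200 reference points per
class, sampled from polygons larger than 6 ha), per-year class proportions,
crop-overlay areas, and the acquisition calendars of the three time-series.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .accuracy import ErrorMatrix

SITES = ("manaus", "santarem", "machadinho")

#: validation error matrices, rows = reference (MF, NF, SF), cols = classified
ERROR_MATRICES: dict[str, ErrorMatrix] = {
    "manaus": ErrorMatrix(np.array([[186, 4, 10], [8, 185, 7], [11, 2, 187]])),
    "santarem": ErrorMatrix(np.array([[196, 0, 4], [0, 198, 2], [23, 11, 166]])),
    "machadinho": ErrorMatrix(np.array([[200, 0, 0], [0, 197, 3], [19, 37, 144]])),
}

#: per-year land-cover proportions (%), columns MF/NF/SF
_PROPORTIONS = {
    "manaus": [
        (1973, 91, 4, 5), (1977, 90, 4, 5), (1978, 90, 5, 5), (1979, 89, 6, 5),
        (1983, 88, 7, 5), (1985, 83, 8, 8), (1988, 81, 8, 11), (1989, 79, 9, 12),
        (1991, 79, 8, 13), (1992, 78, 8, 13), (1994, 78, 8, 14), (1995, 78, 7, 15),
        (1996, 78, 5, 17), (1999, 77, 7, 16), (2001, 77, 7, 16), (2002, 76, 8, 16),
        (2003, 74, 7, 20), (2006, 73, 8, 19), (2007, 72, 8, 19), (2008, 72, 8, 20),
        (2009, 72, 9, 19), (2010, 72, 9, 19), (2011, 72, 9, 19),
    ],
    "santarem": [
        (1984, 79, 2, 19), (1985, 78, 4, 18), (1986, 76, 6, 19), (1987, 75, 2, 23),
        (1988, 72, 12, 16), (1989, 72, 4, 24), (1990, 71, 4, 25), (1991, 71, 5, 24),
        (1993, 65, 10, 26), (1995, 64, 6, 30), (1996, 63, 10, 27), (1997, 62, 6, 32),
        (1998, 53, 15, 32), (1999, 52, 16, 33), (2000, 51, 9, 40), (2001, 51, 7, 42),
        (2003, 50, 13, 37), (2005, 48, 16, 36), (2006, 47, 15, 38), (2007, 47, 10, 43),
        (2008, 47, 14, 40), (2009, 46, 11, 43), (2010, 46, 10, 44),
    ],
    "machadinho": [
        (1984, 91, 1, 9), (1986, 84, 7, 9), (1987, 82, 5, 13), (1989, 79, 6, 14),
        (1990, 77, 5, 18), (1991, 74, 11, 14), (1994, 68, 12, 20), (1995, 63, 16, 20),
        (1996, 60, 12, 28), (1997, 57, 17, 26), (1998, 55, 16, 29), (1999, 51, 18, 30),
        (2001, 48, 23, 29), (2003, 43, 21, 36), (2005, 38, 27, 34), (2006, 35, 28, 37),
        (2007, 34, 31, 35), (2008, 33, 38, 29), (2009, 32, 36, 32), (2010, 32, 33, 35),
        (2011, 32, 33, 36),
    ],
}


def landcover_proportions(site: str) -> pd.DataFrame:
    """Published per-year MF/NF/SF proportions (%) for a site."""
    return pd.DataFrame(_PROPORTIONS[site], columns=["year", "MF", "NF", "SF"])


#: crop-overlay areas (ha): crop polygon area intersecting each mapped class,
#: and the total mapped class area implied by the published relative
#: incidences (SF of Manaus tree crops: RI 4.4 % of 96,295 ha of SF in 2007)
MANAUS_TREE_CROPS = {
    "overlap_ha": {"MF": 139.0, "NF": 398.0, "SF": 4237.0},
    "total_ha": 4774.0,
    "class_area_ha": {"SF": 96295.0, "NF": 39800.0},
}

#: acquisition calendars (yyyymmdd)
ACQUISITION_DATES: dict[str, tuple[int, ...]] = {
    "manaus": (
        19730707, 19770731, 19780822, 19790703, 19830709, 19850604, 19880815,
        19890802, 19910808, 19920607, 19941019, 19950920, 19960720, 19990713,
        20010827, 20020830, 20030809, 20060716, 20070804, 20080806, 20090910,
        20100727, 20110831,
    ),
    "santarem": (
        19840824, 19850726, 19860729, 19870716, 19880803, 19890822, 19900809,
        19910711, 19931020, 19951010, 19960825, 19970727, 19980815, 19990903,
        20000905, 20010916, 20030829, 20050701, 20060805, 20070621, 20081130,
        20090712, 20100629,
    ),
    "machadinho": (
        19840617, 19860810, 19870712, 19890717, 19900618, 19910925, 19940816,
        19950803, 19960704, 19970723, 19980624, 19990729, 20010803, 20030724,
        20050713, 20060716, 20070703, 20080806, 20090809, 20100625, 20110612,
    ),
}
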