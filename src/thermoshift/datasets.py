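"""Small built-in worked-example data.

The shift-statistic worked example carries the published class tallies of
a 13-year butterfly resurvey of a Mediterranean protected area (Dadia
National Park, NE Greece; baseline 1998, resurvey 2011): numbers of low-
and high-altitude species observed each year and their summed abundances,
with widespread species excluded.  It exercises ``t_sp`` / ``t_ab``
without any raw transect data.
"""

from __future__ import annotations

from .shift import ShiftCounts


def dadia_shift_counts() -> ShiftCounts:
    """Published low/high-altitude tallies, 1998 vs 2011.

    25 low- and 40 high-altitude species in 1998 (913 and 1557
    individuals); 31 and 40 species in 2011 (1657 and 1161 individuals).
    T_sp evaluates to 0.052 and T_ab to 0.218 on these inputs.
    """
    return ShiftCounts(L1=25, H1=40, L2=31, H2=40,
                       l1=913, h1=1557, l2=1657, h2=1161)
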