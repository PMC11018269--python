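"""Practice-effect loadings for repeated cognitive testing.

Retest gains are modeled through a latent practice factor whose loading at
each visit is fixed at the square root of the number of previous test
administrations: 0 at baseline, 1 at the second visit, sqrt(2) at the
third.  A one-decimal rounding mode reproduces the conventional fixed
loading of 1.4 at the third occasion.
"""

from __future__ import annotations

import math


def practice_loading(visit_order: int, rounding: str = "exact") -> float:
    """Loading of the practice factor at a 0-based visit order.

    Parameters
    ----------
    visit_order:
        Number of previous testing occasions (0 for baseline).
    rounding:
        ``"exact"`` returns sqrt(visit_order); ``"one-decimal"`` rounds the
        loading to one decimal place (giving 1.4 at the third visit).
    """
    if visit_order < 0:
        raise ValueError("visit_order must be non-negative")
    if rounding not in ("exact", "one-decimal"):
        raise ValueError("rounding must be 'exact' or 'one-decimal'")
    val = math.sqrt(visit_order)
    return round(val, 1) if rounding == "one-decimal" else val


# internal alias used by the design builder
practice_loading_value = practice_loading
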