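"""Trial-arithmetic utilities for whole-mouth clinical index endpoints.

Covers the two pieces of plain trial arithmetic used around the clinical
indices (Modified Gingival Index, Turesky Plaque Index, Expanded Bleeding
Index): the percent difference of a treatment arm's adjusted mean versus the
control arm, and inflation of a required sample size for an anticipated
drop-out rate.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

#: Valid score ranges of the whole-mouth clinical indices.
ENDPOINT_RANGES = {"MGI": (0.0, 4.0), "TPI": (0.0, 5.0), "EBI": (0.0, 2.0)}


def percent_difference(treatment_mean: float, control_mean: float) -> float:
    """Percent difference of a treatment mean versus the control mean.

    100 x (treatment - control) / control, rounded to one decimal with
    half-away-from-zero ties (the printed-table convention).  Requires a
    strictly positive control mean.
    """
    if control_mean <= 0:
        raise ValueError(f"control mean must be > 0, got {control_mean}")
    pct = float(100.0 * (treatment_mean - control_mean) / control_mean)
    return float(Decimal(repr(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def dropout_inflation(required_n: int, dropout_rate: float) -> int:
    """Smallest n whose expected completer count n(1 - rate) meets required_n."""
    if not 0 <= dropout_rate < 1:
        raise ValueError(f"dropout rate must be in [0, 1), got {dropout_rate}")
    if required_n < 1:
        raise ValueError(f"required n must be >= 1, got {required_n}")
    # exact rational arithmetic so boundary cases like n * (1 - r) == required
    # are not lost to float rounding
    retention = 1 - Fraction(repr(dropout_rate))
    n = -(-required_n // retention)  # ceil(required_n / retention)
    return int(n)
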