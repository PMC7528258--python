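"""Shared test helpers: comparison at printed precision.

Published tables print rounded values computed from rounded inputs, so
tests compare at the precision actually printed: half a unit in the
last printed digit, capped at three significant figures.
"""

from decimal import Decimal

import pytest


def approx_printed(printed: str):
    """pytest.approx matcher for a number as printed in a table.

    Tolerance is half a unit in the last printed digit; values printed
    with more than three significant figures are compared at three.
    """
    d = Decimal(printed)
    digits, exponent = d.as_tuple().digits, d.as_tuple().exponent
    n_sig = len(digits)
    if n_sig > 3:
        exponent += n_sig - 3
    return pytest.approx(float(d), abs=0.5 * 10.0 ** exponent)
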