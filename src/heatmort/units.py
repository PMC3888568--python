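"""Temperature unit conversions. All internal computation is in °C."""

from __future__ import annotations

import numpy as np


def c_to_f(temp_c):
    """Celsius to Fahrenheit."""
    return np.asarray(temp_c, dtype=float) * 9.0 / 5.0 + 32.0


def f_to_c(temp_f):
    """Fahrenheit to Celsius."""
    return (np.asarray(temp_f, dtype=float) - 32.0) * 5.0 / 9.0
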