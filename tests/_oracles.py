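"""Independent brute-force oracles, deliberately written with plain ``math``
and the textbook formulas so they share no code path with the package."""

import math

Z = 1.959963984540054


def prr_oracle(a, b, c, d):
    point = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return point, math.exp(math.log(point) - Z * se), math.exp(math.log(point) + Z * se)


def ror_oracle(a, b, c, d):
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return point, math.exp(math.log(point) - Z * se), math.exp(math.log(point) + Z * se)


def chi2_oracle(a, b, c, d, yates=False):
    n = a + b + c + d
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    return n * diff * diff / ((a + b) * (c + d) * (a + c) * (b + d))
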