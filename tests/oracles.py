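"""Independent reference computations used to check the library's results."""

from fractions import Fraction
from math import comb


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Works in exact rational arithmetic: with row margin r1 = a+b, column
    margin c1 = a+c and total n, every table consistent with the margins is
    enumerated and the probabilities of those no more probable than the
    observed table are summed.
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    denom = comb(n, c1)
    k_min = max(0, c1 - (n - r1))
    k_max = min(r1, c1)
    p_obs = Fraction(comb(r1, a) * comb(n - r1, c1 - a), denom)
    total = Fraction(0)
    for k in range(k_min, k_max + 1):
        p_k = Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return float(total)
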