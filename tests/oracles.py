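"""Independent brute-force oracles used to check the statistics kernel.

These deliberately avoid the implementation's code paths: exact rational
arithmetic over binomial coefficients for the hypergeometric model, and
the closed-form pooled t formula for the mean comparison.
"""

from fractions import Fraction
from math import comb
from typing import Dict, Tuple


def hypergeom_pmf_exact(a: int, b: int, c: int, d: int) -> Dict[int, Fraction]:
    """Exact point probabilities over the full support, conditioning on margins."""
    big_n, big_k, n = a + b + c + d, a + c, a + b
    lo, hi = max(0, n - (big_n - big_k)), min(n, big_k)
    denom = comb(big_n, n)
    return {
        k: Fraction(comb(big_k, k) * comb(big_n - big_k, n - k), denom)
        for k in range(lo, hi + 1)
    }


def fisher_oracle(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """(one-sided enrichment, two-sided) Fisher p by full enumeration."""
    pmf = hypergeom_pmf_exact(a, b, c, d)
    one_sided = sum(p for k, p in pmf.items() if k >= a)
    observed = pmf[a]
    cutoff = observed + observed * Fraction(1, 10**7)
    two_sided = sum(p for p in pmf.values() if p <= cutoff)
    return float(min(one_sided, 1)), float(min(two_sided, 1))
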