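"""Independent exact-arithmetic oracles used across the test suite.

Everything here is computed with integer/Fraction arithmetic and direct
summation — deliberately naive and slow, sharing no code path with the
package implementation.
"""

from fractions import Fraction
from math import comb


def binom_mass_exact(y: int, t: int, q: Fraction) -> Fraction:
    """Binomial(t, q) probability mass at y, exact."""
    return comb(t, y) * q**y * (1 - q) ** (t - y)


def binom_lower_tail_exact(y: int, t: int, q: Fraction) -> Fraction:
    """P(Y <= y), exact, by direct summation."""
    return sum(binom_mass_exact(k, t, q) for k in range(0, y + 1))


def binom_upper_tail_exact(y: int, t: int, q: Fraction) -> Fraction:
    """P(Y >= y), exact, by direct summation."""
    return sum(binom_mass_exact(k, t, q) for k in range(y, t + 1))


def two_library_pvalue_exact(
    x: int, y: int, n_a: int, n_b: int, two_sided: bool = True
) -> Fraction:
    """Min-tail (optionally doubled, capped at 1) conditional p-value."""
    t = x + y
    if t == 0:
        return Fraction(1)
    q = Fraction(n_b, n_a + n_b)
    smaller = min(binom_lower_tail_exact(y, t, q), binom_upper_tail_exact(y, t, q))
    if not two_sided:
        return smaller
    return min(Fraction(1), 2 * smaller)


def ddct_rq_by_hand(
    ct_target: float, ct_reference: float, calibrator_dct: float, efficiency: float = 2.0
) -> float:
    return efficiency ** (-((ct_target - ct_reference) - calibrator_dct))


def pooled_t_by_hand(a, b):
    """Pooled two-sample t statistic computed from first principles."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (ma - mb) / (sp2 * (1 / na + 1 / nb)) ** 0.5
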