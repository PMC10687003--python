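"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: exact rational
arithmetic for discrete tail probabilities, transitive-closure merging,
and the textbook pooled-variance t formula.
"""

from fractions import Fraction
from math import comb, sqrt


def conditional_binomial_twosided(s1: int, t: int, n1: int, n2: int) -> float:
    """Two-sided (doubled smaller tail, capped) conditional binomial p-value
    for observing group-1 sum s1 of total t with group sizes n1, n2,
    computed by exhaustive enumeration in exact rational arithmetic."""
    q = Fraction(n1, n1 + n2)
    pmf = [Fraction(comb(t, y)) * q**y * (1 - q) ** (t - y) for y in range(t + 1)]
    lo = sum(pmf[: s1 + 1])
    hi = sum(pmf[s1:])
    return float(min(Fraction(1), 2 * min(lo, hi)))


def hypergeom_pmf(k: int, M: int, n: int, N: int) -> Fraction:
    """P(X = k) drawing N from M with n successes."""
    if k < max(0, N - (M - n)) or k > min(n, N):
        return Fraction(0)
    return Fraction(comb(n, k) * comb(M - n, N - k), comb(M, N))


def fisher_twosided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for table [[a,b],[c,d]]: sum of all tables
    with the same margins whose probability does not exceed the observed."""
    M, n, N = a + b + c + d, a + b, a + c
    obs = hypergeom_pmf(a, M, n, N)
    total = Fraction(0)
    for k in range(max(0, N - (M - n)), min(n, N) + 1):
        p = hypergeom_pmf(k, M, n, N)
        if p <= obs:
            total += p
    return float(min(total, Fraction(1)))


def binomial_tail(k: int, n: int, p_num: int, p_den: int) -> float:
    """P(X >= k), X ~ Binomial(n, p_num/p_den), by exact summation."""
    p = Fraction(p_num, p_den)
    return float(
        sum(Fraction(comb(n, i)) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))
    )


def merge_transitive_closure(positions, is_dm, gap: int):
    """Brute-force DM-site merging: two DM sites belong to one candidate iff
    they are linked by a chain of DM sites with consecutive distances < gap.
    Returns sorted lists of DM positions per candidate."""
    dm = sorted(p for p, flag in zip(positions, is_dm) if flag)
    groups = []
    for p in dm:
        placed = False
        for g in groups:
            if any(abs(p - q) < gap for q in g):
                g.append(p)
                placed = True
        if not placed:
            groups.append([p])
    # transitive closure: merge groups sharing proximity
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(abs(p - q) < gap for p in groups[i] for q in groups[j]):
                    groups[i] += groups[j]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(sorted(g) for g in groups)


def pooled_ttest(a, b):
    """Textbook pooled-variance two-sample t statistic and two-sided p."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    return t, 2 * tdist.sf(abs(t), df)
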