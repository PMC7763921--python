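"""Independent brute-force oracles: literal nested-loop implementations
of the entropy definitions, kept free of any shared code with the
package internals."""

import math


def _windows(x, length, count):
    return [list(x[i : i + length]) for i in range(count)]


def _cheb(u, v):
    return max(abs(a - b) for a, b in zip(u, v))


def naive_apen(x, m, r):
    x = [float(v) for v in x]
    n = len(x)

    def phi(length, count):
        vecs = _windows(x, length, count)
        logs = []
        for vi in vecs:
            matches = sum(1 for vj in vecs if _cheb(vi, vj) <= r)  # self included
            logs.append(math.log(matches / count))
        return sum(logs) / count

    return phi(m, n - m + 1) - phi(m + 1, n - m)


def naive_sampen(x, m, r):
    x = [float(v) for v in x]
    n = len(x)
    count = n - m

    def phi(length):
        vecs = _windows(x, length, count)
        fracs = []
        for i, vi in enumerate(vecs):
            matches = sum(
                1 for j, vj in enumerate(vecs) if j != i and _cheb(vi, vj) <= r
            )
            fracs.append(matches / (count - 1))
        return sum(fracs) / count

    phi_m, phi_m1 = phi(m), phi(m + 1)
    if phi_m == 0 or phi_m1 == 0:
        return float("nan")
    return math.log(phi_m / phi_m1)


def naive_fuzzyen(x, m, r):
    x = [float(v) for v in x]
    n = len(x)
    count = n - m

    def phi(length):
        vecs = _windows(x, length, count)
        sims = []
        for i, vi in enumerate(vecs):
            total = sum(
                math.exp(-((_cheb(vi, vj) / r) ** 2))
                for j, vj in enumerate(vecs)
                if j != i
            )
            sims.append(total / (count - 1))
        return sum(sims) / count

    return math.log(phi(m) / phi(m + 1))


def naive_auc(a, b):
    score = 0.0
    for x in a:
        for y in b:
            if x > y:
                score += 1.0
            elif x == y:
                score += 0.5
    return score / (len(a) * len(b))
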