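"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions with explicit Python loops,
deliberately sharing no code with the package.
"""

import math


def oracle_quantities(counts, l):
    """(p_l, q_l, r_l, s_l) for class l by explicit summation."""
    L = len(counts)
    p = counts[l][l]
    q = sum(counts[i][j] for i in range(L) for j in range(L) if i != l and j != l)
    r = sum(counts[i][l] for i in range(L) if i != l)
    s = sum(counts[l][j] for j in range(L) if j != l)
    return p, q, r, s


def oracle_overall_se(counts):
    L = len(counts)
    total = sum(counts[i][j] for i in range(L) for j in range(L))
    return sum(counts[l][l] for l in range(L)) / total


def oracle_aggregate_mcc(counts):
    """Aggregate multiclass MCC from summed p, q, r, s."""
    L = len(counts)
    p = q = r = s = 0
    for l in range(L):
        pl, ql, rl, sl = oracle_quantities(counts, l)
        p, q, r, s = p + pl, q + ql, r + rl, s + sl
    denom = (p + r) * (p + s) * (q + r) * (q + s)
    if denom == 0:
        return 0.0
    return (p * q - r * s) / math.sqrt(denom)


def oracle_binary_mcc(tp, tn, fp, fn):
    """The textbook binary Matthews correlation coefficient."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def oracle_per_class_mcc(counts, l):
    p, q, r, s = oracle_quantities(counts, l)
    return oracle_binary_mcc(tp=p, tn=q, fp=r, fn=s)


def oracle_aa_tally(sequence, alphabet):
    """Letter-frequency tally over ``alphabet`` only."""
    counts = [sequence.count(a) for a in alphabet]
    total = sum(counts)
    if total == 0:
        return [0.0] * len(alphabet)
    return [c / total for c in counts]


def oracle_dimer_tally(sequence, alphabet):
    """Sliding-window dimer frequencies over the 2-letter words of ``alphabet``."""
    words = [a + b for a in alphabet for b in alphabet]
    counts = {w: 0 for w in words}
    for i in range(len(sequence) - 1):
        w = sequence[i : i + 2]
        if w in counts:
            counts[w] += 1
    total = sum(counts.values())
    if total == 0:
        return [0.0] * len(words)
    return [counts[w] / total for w in words]


def oracle_gaussian(X, Y, gamma):
    """Element-wise exp(-gamma * squared distance)."""
    out = []
    for x in X:
        row = []
        for y in Y:
            d2 = sum((a - b) ** 2 for a, b in zip(x, y))
            row.append(math.exp(-gamma * d2))
        out.append(row)
    return out
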