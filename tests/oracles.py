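"""Independent brute-force oracles used to cross-check the implementation.

Nothing here shares code with the package's matching or statistics paths:
approximate matching is checked by explicit neighborhood enumeration and a
plain dynamic program, rank statistics by literal rank construction, BH by
the textbook step-up loop, and the hypergeometric tail by enumeration of
binomial coefficients.
"""

from __future__ import annotations

from math import comb

RNA = "ACGU"


def edit1_neighborhood(seq: str):
    """All sequences within edit distance 1 of ``seq`` (including itself)."""
    out = {seq}
    for i in range(len(seq)):
        for b in RNA:
            out.add(seq[:i] + b + seq[i + 1 :])  # substitution
        out.add(seq[:i] + seq[i + 1 :])  # deletion
    for i in range(len(seq) + 1):
        for b in RNA:
            out.add(seq[:i] + b + seq[i:])  # insertion
    return out


def matches_within_one_edit(pattern: str, text: str) -> bool:
    """Pattern occurs inside text within 1 edit, by neighborhood enumeration."""
    return any(v and v in text for v in edit1_neighborhood(pattern))


def infix_edit_distance_dp(pattern: str, text: str) -> int:
    """Minimal edit distance of pattern to any substring of text (full DP)."""
    m, n = len(pattern), len(text)
    prev = [0] * (n + 1)  # free start anywhere in the text
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if pattern[i - 1] == text[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)


def spearman_bruteforce(x, y) -> float:
    """Spearman rho via literal mean-rank construction and the Pearson
    formula on ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mean_rank = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = mean_rank
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def bh_stepup(pvalues):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvalues[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted


def hypergeom_upper_tail(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for a hypergeometric(M, K, n), by direct enumeration."""
    total = comb(M, n)
    return sum(
        comb(K, x) * comb(M - K, n - x)
        for x in range(k, min(K, n) + 1)
        if n - x <= M - K
    ) / total
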