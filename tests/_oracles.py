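"""Independent brute-force reference implementations used only by tests.

Each oracle is written directly from the defining rule, with naive data
structures and elementwise comparisons, deliberately sharing no code with
the package implementations it checks.
"""

import math


def lz76_oracle(s: str) -> int:
    """Exhaustive-history component count by elementwise copy search.

    A component s[i:j] is reproducible if it can be copied symbol by
    symbol starting from some position p < i (the copy may run into the
    component itself).
    """

    def reproducible(i: int, j: int) -> bool:
        for p in range(i):
            if all(s[p + t] == s[i + t] for t in range(j - i)):
                return True
        return False

    n = len(s)
    count = 0
    i = 0
    while i < n:
        j = i + 1
        while j <= n and reproducible(i, j):
            j += 1
        count += 1
        i = j
    return count


def lz78_oracle(s: str) -> int:
    """Incremental parse counting phrases with a plain list re-scan."""
    phrases = []
    count = 0
    i = 0
    n = len(s)
    while i < n:
        j = i + 1
        while j <= n and any(s[i:j] == p for p in phrases):
            j += 1
        count += 1
        if j <= n:
            phrases.append(s[i:j])
        i = j
    return count


def titchener_oracle(s: str) -> float:
    """Naive T-decomposition on explicit string tokens.

    Level pattern = first token; its leading run length k contributes
    log2(k+1); remaining tokens absorb runs of the pattern into the next
    token; a trailing pattern run collapses to a single token.
    """
    if len(s) < 2:
        return 0.0
    toks = list(s)
    total = 0.0
    while len(toks) > 1:
        p = toks[0]
        k = 1
        while k < len(toks) - 1 and toks[k] == p:
            k += 1
        total += math.log2(k + 1)
        new = []
        buf = ""
        for t in toks[k:]:
            if t == p:
                buf += t
            else:
                new.append(buf + t)
                buf = ""
        if buf:
            new.append(buf)
        toks = new
    return total


def two_means_oracle(values) -> list:
    """Optimal 1-D two-cluster split by trying every threshold.

    Enumerates all splits of the sorted values, scores each split by the
    total squared distance to the two cluster means, and returns the 0/1
    assignment (lower cluster -> 0) of the best split.
    """
    vals = list(values)
    order = sorted(range(len(vals)), key=lambda i: vals[i])
    svals = [vals[i] for i in order]
    n = len(svals)
    best_cost, best_split = None, None
    for split in range(1, n):
        lo, hi = svals[:split], svals[split:]
        mlo = sum(lo) / len(lo)
        mhi = sum(hi) / len(hi)
        cost = sum((v - mlo) ** 2 for v in lo) + sum((v - mhi) ** 2 for v in hi)
        if best_cost is None or cost < best_cost:
            best_cost, best_split = cost, split
    bits = [0] * n
    assignment = [0] * n
    for rank, idx in enumerate(order):
        assignment[idx] = 0 if rank < best_split else 1
    return assignment


def all_binary_strings(max_len: int):
    for length in range(1, max_len + 1):
        for v in range(2**length):
            yield format(v, f"0{length}b")
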