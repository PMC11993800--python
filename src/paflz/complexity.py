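"""Binary-string complexity measures: LZ76, LZ78 and Titchener T-complexity.

All three operate on strings over the alphabet {0, 1} produced by coarse
graining an ECG lead.  Raw scores grow with string length, so values are
normalized by n / log2(n) before they are compared across sampling
frequencies; for the Lempel–Ziv measures this maps asymptotically random
strings towards 1.  Normalized values are deliberately not clipped to
[0, 1] — for T-complexity the unit bound does not hold universally, and we
record whatever the normalization yields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "lz76",
    "lz78",
    "titchener",
    "normalize",
    "ComplexityFeature",
    "COMPLEXITY_ALGORITHMS",
]


def _check_binary(s: str) -> None:
    if not s:
        raise ValueError("complexity requires a non-empty binary string")
    # set() is O(n) and cheap relative to the parses below
    extra = set(s) - {"0", "1"}
    if extra:
        raise ValueError(f"non-binary symbols in input: {sorted(extra)!r}")


def lz76(s: str) -> int:
    """Number of components in the exhaustive production history of ``s``.

    Scanning left to right, the current component is extended while the
    extended component can be reproduced from the history seen so far
    (self-overlap allowed); the symbol that breaks reproducibility closes
    the component.  A trailing component that never stops being
    reproducible still counts as one (Kaspar–Schuster convention).
    """
    _check_binary(s)
    n = len(s)
    c = 0
    i = 0
    while i < n:
        j = i + 1
        # extend while s[i:j] occurs in s[:j-1] (copy source may overlap
        # into the component itself)
        while j <= n and s[i:j] in s[: j - 1]:
            j += 1
        # if j > n the final component was reproducible to the end
        c += 1
        i = min(j, n)
    return c


def lz78(s: str) -> int:
    """Number of phrases in the LZ78 incremental parse of ``s``.

    Each phrase is the shortest prefix of the remainder not already in the
    phrase dictionary; an incomplete final phrase (still in the dictionary
    when the input ends) counts as one phrase.
    """
    _check_binary(s)
    phrases: set[str] = set()
    count = 0
    i = 0
    n = len(s)
    while i < n:
        j = i + 1
        while j <= n and s[i:j] in phrases:
            j += 1
        if j > n:
            # incomplete final phrase, already known
            count += 1
            break
        phrases.add(s[i:j])
        count += 1
        i = j
    return count


def titchener(s: str) -> float:
    """T-complexity of ``s`` via deterministic T-decomposition.

    The string is tokenized into single symbols and repeatedly reduced:
    at each level the leading token ``p`` is taken as the copy pattern,
    its leading run length ``k`` contributes ``log2(k + 1)``, and the
    remaining tokens are re-tokenized by absorbing runs of ``p`` into the
    following token (``p^j t`` becomes one token).  The recursion ends
    when a single token — the terminal codeword — remains.

    Returns 0.0 for strings of length < 2 (no augmentation step).
    """
    _check_binary(s)
    n = len(s)
    if n < 2:
        return 0.0
    # tokens are contiguous spans (start, end) into s
    toks: list[tuple[int, int]] = [(i, i + 1) for i in range(n)]
    total = 0.0
    while len(toks) > 1:
        pi, pj = toks[0]
        p = s[pi:pj]
        m = len(toks)
        # leading run of tokens equal to p; must leave a terminal token
        k = 1
        while k < m - 1 and s[toks[k][0] : toks[k][1]] == p:
            k += 1
        total += math.log2(k + 1)
        # re-tokenize the remainder: absorb runs of p into the next token
        new_toks: list[tuple[int, int]] = []
        start = None
        for a, b in toks[k:]:
            if s[a:b] == p:
                if start is None:
                    start = a
                continue
            new_toks.append((a if start is None else start, b))
            start = None
        if start is not None:
            # trailing run of p with no terminator collapses to one token
            new_toks.append((start, toks[-1][1]))
        toks = new_toks
    return total


def normalize(c: float, n: int) -> float:
    """Divide a raw complexity by n / log2(n); exact, never clipped."""
    if n < 2:
        raise ValueError("normalization requires string length n >= 2")
    if c < 0:
        raise ValueError("complexity must be non-negative")
    return c * math.log2(n) / n


_ALGORITHMS = {"LZ76": lz76, "LZ78": lz78, "Ti": titchener}
COMPLEXITY_ALGORITHMS = tuple(_ALGORITHMS)


def score(s: str, algorithm: str, normalized: bool = True) -> float:
    """Score a binary string with a named algorithm (LZ76, LZ78 or Ti)."""
    try:
        fn = _ALGORITHMS[algorithm]
    except KeyError:
        raise ValueError(
            f"unknown complexity algorithm {algorithm!r}; "
            f"choose from {COMPLEXITY_ALGORITHMS}"
        ) from None
    raw = float(fn(s))
    return normalize(raw, len(s)) if normalized else raw


@dataclass(frozen=True)
class ComplexityFeature:
    """One normalized complexity value and its full provenance."""

    raw: float
    n: int
    coarse_graining: str  # TC, KM, FD or BD
    algorithm: str  # LZ76, LZ78 or Ti
    lead: str
    fs: int

    @property
    def normalized(self) -> float:
        return normalize(self.raw, self.n)
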