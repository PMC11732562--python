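"""Brute-force CpG-island oracle, independent of the package implementation.

Definition (mirrored from the package's documented contract, computed here
with naive incremental counting instead of prefix-sum vectorization):
qualifying substring = length >= 200, no N, GC >= 0.50, CpG obs/exp >= 0.6;
islands = maximal intervals of the union of all qualifying substrings,
with any merged interval that fails the criteria refined into its longest
(leftmost-on-ties) qualifying substrings.
"""
from __future__ import annotations

MIN_LEN = 200
MIN_GC = 0.50
MIN_OE = 0.6


def _qualifies(seq: str) -> bool:
    L = len(seq)
    if L < MIN_LEN or "N" in seq:
        return False
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c + n_g < MIN_GC * L:
        return False
    return seq.count("CG") * L >= MIN_OE * n_c * n_g


def oracle_islands(sequence: str) -> list[tuple[int, int]]:
    seq = sequence.upper()
    n = len(seq)
    covered = [False] * n
    for s in range(0, n - MIN_LEN + 1):
        # incremental counts while extending the end
        n_c = seq.count("C", s, s + MIN_LEN - 1)
        n_g = seq.count("G", s, s + MIN_LEN - 1)
        n_n = seq.count("N", s, s + MIN_LEN - 1)
        n_cpg = seq.count("CG", s, s + MIN_LEN - 1)
        max_e = None
        for e in range(s + MIN_LEN, n + 1):
            base = seq[e - 1]
            if base == "C":
                n_c += 1
            elif base == "G":
                n_g += 1
                if seq[e - 2] == "C":
                    n_cpg += 1
            elif base not in "AT":
                n_n += 1
            L = e - s
            if (
                n_n == 0
                and n_c + n_g >= MIN_GC * L
                and n_cpg * L >= MIN_OE * n_c * n_g
            ):
                max_e = e
        if max_e is not None:
            for i in range(s, max_e):
                covered[i] = True
    merged: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j < n and covered[j]:
                j += 1
            merged.append((i, j))
            i = j
        else:
            i += 1
    out: list[tuple[int, int]] = []
    stack = list(merged)
    while stack:
        a, b = stack.pop()
        if b - a < MIN_LEN:
            continue
        if _qualifies(seq[a:b]):
            out.append((a, b))
            continue
        found = None
        for lam in range(b - a, MIN_LEN - 1, -1):
            for s in range(a, b - lam + 1):
                if _qualifies(seq[s : s + lam]):
                    found = (s, s + lam)
                    break
            if found:
                break
        if found:
            out.append(found)
            stack.append((a, found[0]))
            stack.append((found[1], b))
    return sorted(out)
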