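"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: alignment scores come
from exhaustive enumeration of every gapped alignment, components from a
plain union-find, conserved blocks from an all-substrings scan.
"""

from __future__ import annotations


def score_alignment_columns(cols, pair_score, gap_open, gap_extend) -> int:
    """Score a fully specified alignment (list of column tuples); a gap run
    of length L costs gap_open + L*gap_extend."""
    total = 0
    state = None
    for x, y in cols:
        if x == "-":
            total -= gap_extend + (gap_open if state != "y" else 0)
            state = "y"
        elif y == "-":
            total -= gap_extend + (gap_open if state != "x" else 0)
            state = "x"
        else:
            total += pair_score(x, y)
            state = "m"
    return total


def bruteforce_global_score(a: str, b: str, pair_score, gap_open, gap_extend) -> int:
    """Maximum score over every global alignment of a and b, enumerated."""
    best = [None]

    def rec(i: int, j: int, cols: list) -> None:
        if i == len(a) and j == len(b):
            s = score_alignment_columns(cols, pair_score, gap_open, gap_extend)
            if best[0] is None or s > best[0]:
                best[0] = s
            return
        if i < len(a) and j < len(b):
            cols.append((a[i], b[j]))
            rec(i + 1, j + 1, cols)
            cols.pop()
        if i < len(a):
            cols.append((a[i], "-"))
            rec(i + 1, j, cols)
            cols.pop()
        if j < len(b):
            cols.append(("-", b[j]))
            rec(i, j + 1, cols)
            cols.pop()

    rec(0, 0, [])
    return best[0]


def bruteforce_local_score(a: str, b: str, pair_score, gap_open, gap_extend) -> int:
    """Maximum over the empty alignment (0) and every global alignment of
    every substring pair."""
    best = 0
    for i in range(len(a)):
        for k in range(i + 1, len(a) + 1):
            for j in range(len(b)):
                for l in range(j + 1, len(b) + 1):
                    s = bruteforce_global_score(
                        a[i:k], b[j:l], pair_score, gap_open, gap_extend
                    )
                    if s > best:
                        best = s
    return best


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def partition(self) -> set[frozenset]:
        groups: dict = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return {frozenset(g) for g in groups.values()}


def bruteforce_conserved_block(fa: list[str], fb: list[str]) -> int:
    """Longest run of consecutive labels in fa appearing consecutively, in
    order or fully reversed, in fb."""

    def contains(hay: list[str], needle: list[str]) -> bool:
        n = len(needle)
        return any(hay[i : i + n] == needle for i in range(len(hay) - n + 1))

    best = 0
    for i in range(len(fa)):
        for k in range(i + 1, len(fa) + 1):
            run = fa[i:k]
            if contains(fb, run) or contains(fb, run[::-1]):
                best = max(best, k - i)
    return best
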