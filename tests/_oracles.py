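"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

NEG = float("-inf")

# Standard monoisotopic amino-acid residue masses (independent of the
# package's mass backend).
RESIDUE_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.010565


def peptide_mono_mass(sequence: str) -> float:
    return sum(RESIDUE_MONO[c] for c in sequence) + WATER


def sw_affine_brute(a: str, b: str, score_fn, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Quadratic-space three-matrix local affine-gap DP (gap of length L
    costs gap_open + L*gap_extend)."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - first, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - first, F[i][j - 1] - gap_extend)
            H[i][j] = max(0, H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1]), E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self) -> list[frozenset[int]]:
        groups: dict[int, set[int]] = {}
        for i in range(len(self.parent)):
            groups.setdefault(self.find(i), set()).add(i)
        return [frozenset(g) for g in groups.values()]
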