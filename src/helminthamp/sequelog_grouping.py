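"""All-vs-all local alignment, bit scoring and sequelog group construction.

Pairs of peptides whose optimal Smith–Waterman local alignment converts to a
Karlin–Altschul bit score at or above a threshold (default ≥100 bits) are
"sequelogs"; groups are the connected components of that threshold graph.
Components that are singletons, or whose members all come from a single
genome assembly, are discarded.  A known-AMP exclusion filter removes
candidates similar to previously characterised AMPs before grouping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from numba import njit

from helminthamp.types import STANDARD_AA, SequelogGroup

logger = logging.getLogger(__name__)

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}


def _blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a dense int64 matrix over the 20-letter alphabet."""
    b = substitution_matrices.load("BLOSUM62")
    m = np.zeros((20, 20), dtype=np.int64)
    for i, a in enumerate(_ALPHABET):
        for j, c in enumerate(_ALPHABET):
            m[i, j] = int(b[a, c])
    return m


_BLOSUM62 = _blosum62_matrix()


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for local alignment and bit-score conversion.

    A gap of length L costs ``gap_open + L·gap_extend`` (BLAST convention,
    default 11 + L).  ``lam``/``karlin_k`` are the standard gapped
    BLOSUM62/11/1 Karlin–Altschul constants used to express raw scores in
    bits.
    """

    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    karlin_k: float = 0.041
    matrix: np.ndarray = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.matrix is None:
            object.__setattr__(self, "matrix", _BLOSUM62)
        if self.lam <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin–Altschul constants must be positive")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")


DEFAULT_PARAMS = AlignmentParams()
DEFAULT_GROUP_MIN_BITS = 100.0
DEFAULT_EXCLUDE_MIN_BITS = 50.0


def encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in sequence], dtype=np.int64)
    except KeyError:
        for pos, c in enumerate(sequence, 1):
            if c not in _AA_INDEX:
                raise ValueError(f"non-standard residue {c!r} at position {pos}") from None
        raise  # pragma: no cover


@njit(cache=True)
def _sw_kernel(a: np.ndarray, b: np.ndarray, score: np.ndarray, gap_open: int, gap_extend: int) -> int:
    """Affine-gap Smith–Waterman best score, linear space (Gotoh)."""
    n, m = a.shape[0], b.shape[0]
    neg = -(1 << 60)
    h_prev = np.zeros(m + 1, dtype=np.int64)
    h_cur = np.zeros(m + 1, dtype=np.int64)
    e = np.full(m + 1, neg, dtype=np.int64)  # gap in b (vertical)
    first_gap = gap_open + gap_extend
    best = 0
    for i in range(1, n + 1):
        h_cur[0] = 0
        f = neg  # gap in a (horizontal)
        h_diag = h_prev[0]
        for j in range(1, m + 1):
            ev = h_prev[j] - first_gap
            if e[j] - gap_extend > ev:
                ev = e[j] - gap_extend
            e[j] = ev
            fv = h_cur[j - 1] - first_gap
            if f - gap_extend > fv:
                fv = f - gap_extend
            f = fv
            h = h_diag + score[a[i - 1], b[j - 1]]
            if ev > h:
                h = ev
            if fv > h:
                h = fv
            if h < 0:
                h = 0
            h_diag = h_prev[j]
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, h_cur = h_cur, h_prev
    return best


def smith_waterman(a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS) -> int:
    """Optimal local-alignment raw score under affine gaps.

    Symmetric in its arguments; 0 for sequences with no positively scoring
    local alignment (the empty alignment).
    """
    if not a or not b:
        return 0
    return int(_sw_kernel(encode(a), encode(b), params.matrix, params.gap_open, params.gap_extend))


def bit_score(raw: float, params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """Karlin–Altschul normalised score: (λ·S − ln K) / ln 2."""
    if raw < 0:
        raise ValueError("raw score must be ≥ 0")
    return (params.lam * raw - math.log(params.karlin_k)) / math.log(2)


def min_raw_for_bits(bits: float, params: AlignmentParams = DEFAULT_PARAMS) -> int:
    """Smallest integer raw score whose bit score reaches ``bits``."""
    return math.ceil((bits * math.log(2) + math.log(params.karlin_k)) / params.lam)


# ---------------------------------------------------------------------------
# Known-AMP exclusion
# ---------------------------------------------------------------------------

def exclusion_filter(
    items: Sequence,
    known_amps: Sequence,
    min_bits: float = DEFAULT_EXCLUDE_MIN_BITS,
    params: AlignmentParams = DEFAULT_PARAMS,
    key: Callable = lambda it: it.sequence,
) -> tuple[list, list[dict]]:
    """Remove items similar to a previously characterised AMP library.

    An item is removed when its sequence scores ≥ ``min_bits`` against any
    library entry.  Returns (survivors, removal log); each log entry names
    the best library hit.  An empty library is the identity.
    """
    kept, removed = [], []
    lib = [(getattr(k, "protein_id", None) or getattr(k, "peptide_id", str(i)), k.sequence)
           for i, k in enumerate(known_amps)]
    for it in items:
        seq = key(it)
        best_hit, best_bits = None, -math.inf
        for lid, lseq in lib:
            bits = bit_score(smith_waterman(seq, lseq, params), params)
            if bits > best_bits:
                best_hit, best_bits = lid, bits
        if lib and best_bits >= min_bits:
            removed.append({
                "peptide_id": getattr(it, "peptide_id", seq),
                "best_hit": best_hit,
                "bits": round(best_bits, 1),
            })
        else:
            kept.append(it)
    if removed:
        logger.info("exclusion_filter: removed %d known-AMP match(es)", len(removed))
    return kept, removed


# ---------------------------------------------------------------------------
# Group construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupingItem:
    """What the grouping stage needs to know about one candidate."""

    peptide_id: str
    genome_id: str
    sequence: str


def pairwise_bits(
    items: Sequence[GroupingItem],
    params: AlignmentParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Symmetric matrix of pairwise bit scores (diagonal set to 0)."""
    n = len(items)
    enc = [encode(it.sequence) for it in items]
    out = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            raw = _sw_kernel(enc[i], enc[j], params.matrix, params.gap_open, params.gap_extend)
            out[i, j] = out[j, i] = bit_score(raw, params)
    return out


def build_groups(
    items: Sequence[GroupingItem],
    params: AlignmentParams = DEFAULT_PARAMS,
    min_bits: float = DEFAULT_GROUP_MIN_BITS,
) -> list[SequelogGroup]:
    """Connected-component sequelog groups over the bit-score threshold graph.

    Self-hits are excluded.  Singleton components and components confined to
    a single genome are discarded.  Group ids are deterministic: descending
    component size, then lexicographically smallest member id.
    """
    if not items:
        raise ValueError("need at least one item to group")
    bits = pairwise_bits(items, params)
    g = nx.Graph()
    g.add_nodes_from(range(len(items)))
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if bits[i, j] >= min_bits:
                g.add_edge(i, j)

    comps = []
    for comp in nx.connected_components(g):
        members = sorted(items[i].peptide_id for i in comp)
        genomes = frozenset(items[i].genome_id for i in comp)
        if len(members) < 2:
            continue  # no sequelogs
        if len(genomes) < 2:
            continue  # single genome assembly
        comps.append((members, genomes))
    comps.sort(key=lambda c: (-len(c[0]), c[0][0]))
    return [
        SequelogGroup(group_id=k, members=tuple(m), genomes=g_)
        for k, (m, g_) in enumerate(comps, 1)
    ]


# ---------------------------------------------------------------------------
# Consensus and representative (center-star)
# ---------------------------------------------------------------------------

def _make_global_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # Biopython charges open for the first gap position and extend thereafter;
    # open = gap_open + gap_extend reproduces the 11 + L convention.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _merge_into_star(
    master: list[str],
    rows: dict[str, list[str]],
    center_aln: str,
    member_aln: str,
    member_id: str,
) -> tuple[list[str], dict[str, list[str]]]:
    """Merge one center↔member pairwise alignment into the star alignment."""
    new_master: list[str] = []
    new_rows: dict[str, list[str]] = {k: [] for k in rows}
    new_member: list[str] = []
    i = j = 0
    while i < len(master) or j < len(center_aln):
        mc = master[i] if i < len(master) else None
        cc = center_aln[j] if j < len(center_aln) else None
        if mc == "-" and cc != "-":
            new_master.append("-")
            for k in rows:
                new_rows[k].append(rows[k][i])
            new_member.append("-")
            i += 1
        elif cc == "-" and mc != "-":
            new_master.append("-")
            for k in rows:
                new_rows[k].append("-")
            new_member.append(member_aln[j])
            j += 1
        else:  # both residues (equal) or both gaps
            new_master.append(mc if mc is not None else "-")
            for k in rows:
                new_rows[k].append(rows[k][i] if i < len(master) else "-")
            new_member.append(member_aln[j] if j < len(center_aln) else "-")
            i += 1
            j += 1
    new_rows[member_id] = new_member
    return new_master, new_rows


def _percent_identity(a: str, b: str, aligner: Align.PairwiseAligner) -> float:
    if a == b:
        return 100.0
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(sa, sb))
    return 100.0 * matches / max(len(a), len(b))


def consensus_and_representative(
    group: SequelogGroup,
    member_sequences: Mapping[str, str],
    params: AlignmentParams = DEFAULT_PARAMS,
) -> tuple[str, str]:
    """Center-star consensus and the most representative member.

    The center is the member maximising its summed pairwise bit score.  All
    members are merged into a star multiple alignment around it; the
    consensus takes the modal residue per column (ties alphabetical),
    dropping gap-majority columns.  The representative is the member with
    the highest percent identity to the consensus (ties: greater length,
    then lexicographically smallest id).
    """
    ids = list(group.members)
    if len(ids) < 2:
        raise ValueError("consensus requires a group of ≥ 2 members")
    seqs = {i: member_sequences[i] for i in ids}

    sums = {}
    for i in ids:
        sums[i] = sum(
            bit_score(smith_waterman(seqs[i], seqs[j], params), params)
            for j in ids if j != i
        )
    center = max(ids, key=lambda i: (sums[i], -ids.index(i)))

    aligner = _make_global_aligner(params)
    master = list(seqs[center])
    rows: dict[str, list[str]] = {center: list(seqs[center])}
    for mid in ids:
        if mid == center:
            continue
        aln = aligner.align(seqs[center], seqs[mid])[0]
        master, rows = _merge_into_star(master, rows, str(aln[0]), str(aln[1]), mid)

    n_rows = len(rows)
    consensus_chars = []
    for col in range(len(master)):
        column = [rows[i][col] for i in ids]
        n_gaps = column.count("-")
        if n_gaps * 2 > n_rows:
            continue  # gap-majority column dropped
        counts: dict[str, int] = {}
        for c in column:
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        consensus_chars.append(max(sorted(counts), key=lambda c: counts[c]))
    consensus = "".join(consensus_chars)

    identity = {i: _percent_identity(seqs[i], consensus, aligner) for i in ids}
    best = sorted(ids, key=lambda i: (-identity[i], -len(seqs[i]), i))[0]
    return consensus, best
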