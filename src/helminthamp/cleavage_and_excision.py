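"""Candidate mature-peptide production from annotated precursors.

Includes two deterministic heuristics — a hydropathy-window signal-peptide
locator and a dibasic-motif propeptide-site scanner — used when external
signal-peptide / propeptide-convertase annotations are not supplied.  They
are plain rule-based stand-ins, documented as such; supplied annotations
always take precedence in the pipeline.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from helminthamp.types import CandidatePeptide, CleavageAnnotation, ModifiedPeptide, PrecursorProtein

logger = logging.getLogger(__name__)

DIBASIC_MOTIFS = frozenset({"KR", "RR", "KK", "RK"})

#: Signal peptides essentially never extend past this position.
SIGNAL_END_CAP = 35
#: Offset from the end of the hydrophobic h-region window to the cleavage
#: site, approximating the polar c-region length.
_C_REGION_OFFSET = 5

DEFAULT_MIN_PEPTIDE_LEN = 10
DEFAULT_MAX_PEPTIDE_LEN = 99


def heuristic_signal_end(
    sequence: str,
    window: int = 8,
    min_kd: float = 1.6,
    search_range: tuple[int, int] = (3, 30),
) -> int | None:
    """Locate a putative signal-peptide end by hydropathy.

    Scans 1-based window start positions within ``search_range`` for the
    first ``window``-residue stretch whose mean Kyte–Doolittle hydropathy is
    at least ``min_kd`` (the h-region), then places the cleavage site a fixed
    ``+5`` residues after the window end, capped at position 35 and at the
    sequence end.  Returns None when no window qualifies.
    """
    lo, hi = search_range
    n = len(sequence)
    for start in range(lo, hi + 1):  # 1-based window start
        end = start + window - 1
        if end > n:
            break
        frag = sequence[start - 1 : end]
        if any(c not in KYTE_DOOLITTLE for c in frag):
            continue
        mean_kd = sum(KYTE_DOOLITTLE[c] for c in frag) / window
        if mean_kd >= min_kd:
            return min(end + _C_REGION_OFFSET, SIGNAL_END_CAP, n)
    return None


def dibasic_sites(sequence: str, motifs: frozenset[str] = DIBASIC_MOTIFS) -> tuple[int, ...]:
    """1-based positions of the second residue of each dibasic motif.

    Cleavage occurs after the dibasic pair; overlapping motifs all report.
    """
    sites = []
    for i in range(1, len(sequence)):
        if sequence[i - 1 : i + 1] in motifs:
            sites.append(i + 1)
    return tuple(sites)


def annotate_heuristically(protein: PrecursorProtein) -> CleavageAnnotation | None:
    """Build a CleavageAnnotation from the two heuristics; None when no
    signal peptide is found."""
    send = heuristic_signal_end(protein.sequence)
    if send is None:
        return None
    sites = tuple(s for s in dibasic_sites(protein.sequence) if s > send)
    return CleavageAnnotation(protein.protein_id, send, sites)


def enumerate_peptides(
    precursor: PrecursorProtein,
    annotation: CleavageAnnotation,
    mode: str = "all_pairs",
) -> list[CandidatePeptide]:
    """Excise candidate peptides between cleavage boundaries.

    The boundary list is ``B = sorted({signal_end} ∪ propeptide_sites ∪
    {len(precursor)})``.  ``all_pairs`` emits one peptide per ordered
    boundary pair (b_i, b_j), i < j, spanning residues b_i+1..b_j — every
    potential peptide when multiple cleavage sites are predicted, m(m−1)/2
    for m boundaries.  ``segments`` emits only consecutive pairs.
    """
    if mode not in ("all_pairs", "segments"):
        raise ValueError(f"unknown excision mode {mode!r}")
    if annotation.signal_end is None:
        logger.info("skipping %s: no signal-peptide annotation", precursor.protein_id)
        return []
    annotation.validate_against(precursor.sequence)
    n = len(precursor)
    labels = {annotation.signal_end: "signal_end", n: "c_terminus"}
    for s in annotation.propeptide_sites:
        labels.setdefault(s, "propeptide_site")
    bounds = sorted(labels)

    pairs: Iterable[tuple[int, int]]
    if mode == "all_pairs":
        pairs = ((bounds[i], bounds[j]) for i in range(len(bounds)) for j in range(i + 1, len(bounds)))
    else:
        pairs = zip(bounds, bounds[1:])

    peptides = []
    for b_lo, b_hi in pairs:
        seq = precursor.sequence[b_lo:b_hi]
        peptides.append(
            CandidatePeptide(
                peptide_id=f"{precursor.protein_id}:{b_lo + 1}-{b_hi}",
                protein_id=precursor.protein_id,
                genome_id=precursor.genome_id,
                start=b_lo + 1,
                end=b_hi,
                sequence=seq,
                source_boundaries=(labels[b_lo], labels[b_hi]),
            )
        )
    return peptides


def length_gate(
    peptides: Sequence[CandidatePeptide],
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    max_len: int = DEFAULT_MAX_PEPTIDE_LEN,
) -> list[CandidatePeptide]:
    """Keep peptides within the usable prediction-tool length range
    (``min_len ≤ length ≤ max_len``; by default <10 and ≥100 are removed)."""
    return [p for p in peptides if min_len <= len(p) <= max_len]


def synthesis_form(peptide: CandidatePeptide) -> ModifiedPeptide:
    """The form a peptide is synthesised in.

    A C-terminal glycine is the biological amide donor: it is removed and
    the peptide amidated.  Anything else is synthesised free.
    """
    seq = peptide.sequence
    if seq.endswith("G") and len(seq) > 1:
        return ModifiedPeptide(seq[:-1], c_term="amide")
    return ModifiedPeptide(seq)
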