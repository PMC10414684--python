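"""Protein-level filter cascade: dedup → unknown-residue removal → length.

Each filter is a pure predicate on single proteins (dedup excepted, which is
keyed per genome), so the final survivor set is order-independent; per-stage
counts follow the documented order.
"""

from __future__ import annotations

import logging
from typing import Sequence

from helminthamp.types import FilterReport, PrecursorProtein

logger = logging.getLogger(__name__)

DEFAULT_MAX_PROTEIN_LEN = 150


def deduplicate(
    proteins: Sequence[PrecursorProtein],
    per_genome: bool = True,
) -> tuple[list[PrecursorProtein], FilterReport]:
    """Remove exact-sequence duplicates, keeping the first occurrence.

    Scope is per genome by default (duplicates of the same sequence in
    different genomes are kept); set ``per_genome=False`` for a cross-genome
    sweep.
    """
    seen: set = set()
    kept: list[PrecursorProtein] = []
    for p in proteins:
        key = (p.genome_id, p.sequence) if per_genome else p.sequence
        if key in seen:
            continue
        seen.add(key)
        kept.append(p)
    report = FilterReport("deduplicate", len(proteins), len(proteins) - len(kept))
    logger.info("deduplicate: removed %d of %d", report.n_removed, report.n_in)
    return kept, report


def remove_invalid(
    proteins: Sequence[PrecursorProtein],
) -> tuple[list[PrecursorProtein], FilterReport]:
    """Drop sequences containing unknown residues (X) or stop codons (*)."""
    kept = [p for p in proteins if "X" not in p.sequence and "*" not in p.sequence]
    report = FilterReport("remove_invalid", len(proteins), len(proteins) - len(kept))
    logger.info("remove_invalid: removed %d of %d", report.n_removed, report.n_in)
    return kept, report


def length_filter(
    proteins: Sequence[PrecursorProtein],
    max_len: int = DEFAULT_MAX_PROTEIN_LEN,
) -> tuple[list[PrecursorProtein], FilterReport]:
    """Remove proteins longer than ``max_len`` residues (> max_len removed;
    a protein of exactly ``max_len`` is retained)."""
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    kept = [p for p in proteins if len(p) <= max_len]
    report = FilterReport("length_filter", len(proteins), len(proteins) - len(kept))
    logger.info("length_filter(max_len=%d): removed %d of %d", max_len, report.n_removed, report.n_in)
    return kept, report


def run_cascade(
    proteins: Sequence[PrecursorProtein],
    max_len: int = DEFAULT_MAX_PROTEIN_LEN,
    per_genome_dedup: bool = True,
) -> tuple[list[PrecursorProtein], list[FilterReport]]:
    """Apply the full cascade and return survivors plus per-stage reports."""
    out, r1 = deduplicate(proteins, per_genome=per_genome_dedup)
    out, r2 = remove_invalid(out)
    out, r3 = length_filter(out, max_len=max_len)
    return out, [r1, r2, r3]
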