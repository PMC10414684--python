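"""Group-level curation: GO blocklist, group length, cysteine class,
expression flag.

All curation stages are pure predicates on groups, so the final prioritised
set does not depend on the order the stages run in; removals are logged with
stage and reason so pre-curated data stays queryable.
"""

from __future__ import annotations

import logging
import re
from typing import Mapping, Sequence

from helminthamp.types import SequelogGroup

logger = logging.getLogger(__name__)

GO_RE = re.compile(r"^GO:\d{7}$")

#: Non-antimicrobial GO terms commonly attached to false-positive candidate
#: groups: signalling, protease-inhibition and hydrolase annotations.
DEFAULT_GO_BLOCKLIST = frozenset({
    "GO:0007165",  # signal transduction
    "GO:0010951",  # negative regulation of endopeptidase activity
    "GO:0007218",  # neuropeptide signalling pathway
    "GO:0006644",  # phospholipid metabolic process
    "GO:0050482",  # arachidonic acid secretion
    "GO:0004867",  # serine-type endopeptidase inhibitor activity
    "GO:0005179",  # hormone activity
    "GO:0004623",  # phospholipase A2 activity
    "GO:0004531",  # deoxyribonuclease II activity
    "GO:0006508",  # proteolysis
    "GO:0008233",  # peptidase activity
})

DEFAULT_GROUP_LEN_CUTOFF = 60
DEFAULT_TPM_CUTOFF = 2.0


def validate_blocklist(blocklist: Sequence[str]) -> frozenset[str]:
    for go in blocklist:
        if not GO_RE.match(go):
            raise ValueError(f"malformed GO accession in blocklist: {go!r}")
    return frozenset(blocklist)


def go_filter(
    groups: Sequence[SequelogGroup],
    annotations: Mapping[str, set[str]],
    blocklist: Sequence[str] = DEFAULT_GO_BLOCKLIST,
    gene_of: Mapping[str, str] | None = None,
    mode: str = "any",
) -> tuple[list[SequelogGroup], list[dict]]:
    """Remove groups carrying blocklisted Biological Process / Molecular
    Function terms.

    ``annotations`` maps gene id → set of GO accessions; ``gene_of`` maps
    member peptide id → gene id (identity when omitted).  In the default
    ``any`` mode a single annotated member suffices to remove the group;
    ``all`` mode requires every *annotated* member to carry a blocklisted
    term.  Groups with no annotations at all are retained.
    """
    if mode not in ("any", "all"):
        raise ValueError(f"unknown GO filter mode {mode!r}")
    block = validate_blocklist(list(blocklist))
    kept, removed = [], []
    for grp in groups:
        hits: dict[str, set[str]] = {}
        n_annotated = 0
        for member in grp.members:
            gene = gene_of[member] if gene_of is not None else member
            terms = annotations.get(gene, set())
            if terms:
                n_annotated += 1
            bad = terms & block
            if bad:
                hits[member] = bad
        if mode == "any":
            kill = bool(hits)
        else:
            kill = n_annotated > 0 and len(hits) == n_annotated
        if kill:
            removed.append({
                "group_id": grp.group_id,
                "stage": "go_filter",
                "reason": ";".join(sorted({t for ts in hits.values() for t in ts})),
            })
        else:
            kept.append(grp)
    if removed:
        logger.info("go_filter: removed %d group(s)", len(removed))
    return kept, removed


def group_length_filter(
    groups: Sequence[SequelogGroup],
    member_lengths: Mapping[str, int],
    cutoff: int = DEFAULT_GROUP_LEN_CUTOFF,
) -> tuple[list[SequelogGroup], list[dict]]:
    """Remove groups where a strict majority of members exceed ``cutoff``
    residues (exactly half long members retains the group)."""
    kept, removed = [], []
    for grp in groups:
        n_long = sum(member_lengths[m] > cutoff for m in grp.members)
        if 2 * n_long > len(grp.members):
            removed.append({
                "group_id": grp.group_id,
                "stage": "group_length_filter",
                "reason": f"{n_long}/{len(grp.members)} members > {cutoff} aa",
            })
        else:
            kept.append(grp)
    if removed:
        logger.info("group_length_filter: removed %d group(s)", len(removed))
    return kept, removed


def cysteine_class(sequence: str) -> str:
    """Structural triage by cysteine count.

    ≤1 Cys → ``linear`` (synthesisable without disulfide concerns), exactly
    2 → ``two_cysteine`` (a single potential disulfide; falls between the
    field's "linear" and "cysteine-rich" definitions), >2 → ``cysteine_rich``.
    """
    n = sequence.count("C")
    if n <= 1:
        return "linear"
    if n == 2:
        return "two_cysteine"
    return "cysteine_rich"


def expression_flag(
    gene_id: str,
    tpm_table: Mapping[str, Sequence[float]],
    cutoff: float = DEFAULT_TPM_CUTOFF,
) -> bool | None:
    """Expressed iff TPM strictly exceeds ``cutoff`` in ≥1 sample/life stage.

    Returns None ("unknown") for genes absent from the table — absence of
    RNA-seq evidence is not evidence of non-expression.
    """
    if gene_id not in tpm_table:
        return None
    values = tpm_table[gene_id]
    if any(v < 0 for v in values):
        raise ValueError(f"negative TPM for gene {gene_id!r}")
    return any(v > cutoff for v in values)
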