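"""Ensemble consensus over per-tool antimicrobial calls.

A peptide is designated an AMP-like peptide (AMP-LP) when strictly more than
half of the contributing prediction tools call it antimicrobial.  With the
full 11-tool ensemble the overall percentage score can only take
values on the lattice {0, 9, 18, 27, 36, 45, 55, 64, 73, 82, 91, 100}, so
the minimum AMP-LP score is 55 % (6/11).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

from helminthamp.characterization import eisenberg_moment, hydrophobic_fraction, net_charge
from helminthamp.io_formats import read_tsv_rows
from helminthamp.types import ModifiedPeptide, PredictionProfile

logger = logging.getLogger(__name__)

DEFAULT_CONSENSUS_FRACTION = 0.5
DEFAULT_CALL_THRESHOLD = 0.5

_TRUE = {"1", "true", "yes", "y", "amp", "positive"}
_FALSE = {"0", "false", "no", "n", "non-amp", "negative"}


class UndefinedProfileError(ValueError):
    """No tool contributed a call for a peptide."""


def _parse_call(value: str, threshold: float) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    return float(v) >= threshold


def load_tool_calls(
    paths: Sequence[str | Path],
    threshold: float = DEFAULT_CALL_THRESHOLD,
    strict: bool = False,
    expected_peptides: Sequence[str] | None = None,
) -> dict[str, dict[str, bool]]:
    """Load per-tool call TSVs (columns peptide_id, tool_name, call).

    Calls may be booleans or probabilities (thresholded at ``threshold``).
    Missing peptide×tool entries are abstentions: the tool simply does not
    contribute to that peptide's denominator.  In ``strict`` mode a peptide
    missing from any tool raises instead (requires ``expected_peptides``).
    """
    calls: dict[str, dict[str, bool]] = {}
    tools: set[str] = set()
    for path in paths:
        for row in read_tsv_rows(path, ["peptide_id", "tool_name", "call"]):
            pid, tool = row["peptide_id"], row["tool_name"]
            tools.add(tool)
            bucket = calls.setdefault(pid, {})
            if tool in bucket:
                raise ValueError(f"duplicate call for peptide {pid!r} × tool {tool!r}")
            bucket[tool] = _parse_call(row["call"], threshold)
    if strict:
        universe = set(expected_peptides) if expected_peptides is not None else set(calls)
        for pid in sorted(universe):
            missing = tools - set(calls.get(pid, {}))
            if missing:
                raise ValueError(f"strict mode: peptide {pid!r} missing call(s) from {sorted(missing)}")
    return calls


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def consensus(
    peptide_id: str,
    calls: Mapping[str, bool],
    min_fraction: float = DEFAULT_CONSENSUS_FRACTION,
) -> PredictionProfile:
    """Fold per-tool calls into a :class:`PredictionProfile`.

    ``is_amp_lp`` is true iff the positive fraction strictly exceeds
    ``min_fraction`` (an exact tie with an even tool count is negative).
    ``overall_pct`` is the nearest-integer percentage (6/11 → 55, 7/11 → 64).
    """
    n_tools = len(calls)
    if n_tools == 0:
        raise UndefinedProfileError(f"peptide {peptide_id!r}: no contributing tools")
    n_pos = sum(bool(v) for v in calls.values())
    return PredictionProfile(
        peptide_id=peptide_id,
        calls=dict(calls),
        n_tools=n_tools,
        n_positive=n_pos,
        overall_pct=_round_half_up(100.0 * n_pos / n_tools),
        is_amp_lp=n_pos / n_tools > min_fraction,
    )


def reference_predictors(sequence: str) -> dict[str, bool]:
    """Three deterministic built-in rules so fixtures run without external
    tools.

    These are physicochemical stand-ins — cationicity, hydrophobic balance
    and helical amphipathy — not reproductions of any published predictor:

    - ``charge``: net charge ≥ +2 (side-chain counting model),
    - ``hydrophobic``: hydrophobic residue fraction in [30 %, 60 %],
    - ``moment``: mean Eisenberg hydrophobic moment ≥ 0.2 over an ideal
      α-helix (100°/residue).
    """
    if len(sequence) < 10:
        raise ValueError("reference predictors require length ≥ 10")
    p = ModifiedPeptide(sequence)
    frac = hydrophobic_fraction(p)
    return {
        "charge": net_charge(p) >= 2.0,
        "hydrophobic": 30 <= frac <= 60,
        "moment": eisenberg_moment(sequence) >= 0.2,
    }


def profile_peptides(
    peptide_ids: Sequence[str],
    calls: Mapping[str, Mapping[str, bool]],
    min_fraction: float = DEFAULT_CONSENSUS_FRACTION,
) -> list[PredictionProfile]:
    """Consensus profiles for a batch; peptides with no calls raise."""
    return [consensus(pid, calls.get(pid, {}), min_fraction) for pid in peptide_ids]
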