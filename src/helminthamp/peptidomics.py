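"""LC-MS/MS validation support: PSM confidence tiers, theoretical b/y
fragment ladders, the consecutive-ion rule, and precursor sequence coverage.

The −10lgP score thresholds follow the standard search-engine mapping:
47.4 (1 % FDR) → high confidence, 20 (P < 0.01) → medium, 13 (P < 0.05) →
low; anything weaker is rejected.  Scores exactly at a boundary fall into
the higher tier.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from pyteomics import mass as _ptmass

from helminthamp.characterization import (
    DELTA_AMIDE_MONO,
    DELTA_OXIDATION,
    DELTA_PYRO_GLU,
    DELTA_SULFATION,
    PROTON,
    WATER_MONO,
)
from helminthamp.types import ModifiedPeptide, PSMRecord

PSM_HIGH = 47.4   # 1 % FDR
PSM_MEDIUM = 20.0  # P < 0.01
PSM_LOW = 13.0     # P < 0.05

_TIER_ORDER = {"high": 3, "medium": 2, "low": 1, "rejected": 0}

_RESIDUE_MOD_DELTA = {"oxidation": DELTA_OXIDATION, "sulfation": DELTA_SULFATION}


@dataclass(frozen=True)
class MatchTolerance:
    """Parent/fragment mass tolerances used during PSM matching."""

    parent_ppm: float = 15.0
    fragment_da: float = 0.1

    def __post_init__(self) -> None:
        if self.parent_ppm <= 0 or self.fragment_da <= 0:
            raise ValueError("tolerances must be positive")


def psm_tier(
    score: float,
    high: float = PSM_HIGH,
    medium: float = PSM_MEDIUM,
    low: float = PSM_LOW,
) -> str:
    """Map a −10lgP score to a confidence tier (boundary goes up)."""
    if not math.isfinite(score):
        raise ValueError("score must be finite")
    if score >= high:
        return "high"
    if score >= medium:
        return "medium"
    if score >= low:
        return "low"
    return "rejected"


def fragment_ladder(p: ModifiedPeptide, charge: int = 1) -> tuple[list[float], list[float]]:
    """Singly/multiply protonated b- and y-ion m/z series.

    b_i covers the first i residues (plus any N-terminal modification),
    y_j the last j (plus any C-terminal modification); residue mods land in
    whichever fragment contains them.  Both series have length n−1.
    """
    n = len(p.sequence)
    if n < 2:
        raise ValueError("fragment ladder requires length ≥ 2")
    if charge < 1:
        raise ValueError("charge must be ≥ 1")
    res = [_ptmass.std_aa_mass[c] for c in p.sequence]
    for pos, mod in p.residue_mods.items():
        res[pos - 1] += _RESIDUE_MOD_DELTA[mod]
    nterm_delta = DELTA_PYRO_GLU if p.n_term == "pyro_glu" else 0.0
    cterm_delta = DELTA_AMIDE_MONO if p.c_term == "amide" else 0.0

    b_series, y_series = [], []
    prefix = nterm_delta
    for i in range(n - 1):
        prefix += res[i]
        b_series.append((prefix + charge * PROTON) / charge)
    suffix = cterm_delta + WATER_MONO
    for j in range(n - 1):
        suffix += res[n - 1 - j]
        y_series.append((suffix + charge * PROTON) / charge)
    return b_series, y_series


_ION_RE = re.compile(r"^([by])(\d+)$")


def consecutive_ion_check(matched_ions: Iterable[str], k: int = 3) -> bool:
    """True iff ≥ k consecutive indices are all matched within the b series
    or all within the y series (the manual-validation rule for accepting a
    PSM)."""
    series: dict[str, set[int]] = {"b": set(), "y": set()}
    for label in matched_ions:
        m = _ION_RE.match(label)
        if not m:
            raise ValueError(f"malformed ion label {label!r}")
        series[m.group(1)].add(int(m.group(2)))
    for idx in series.values():
        for start in idx:
            if all(start + off in idx for off in range(k)):
                return True
    return False


def sequence_coverage(
    precursor_length: int,
    psms: Sequence[PSMRecord],
    min_tier: str = "high",
) -> int:
    """Percent of the prepropeptide covered by PSMs at or above ``min_tier``.

    Overlapping matches are unioned, never double-counted; result is the
    nearest-integer percentage of the full precursor (signal peptide
    included).
    """
    if min_tier not in _TIER_ORDER:
        raise ValueError(f"unknown tier {min_tier!r}")
    floor = _TIER_ORDER[min_tier]
    covered: set[int] = set()
    for psm in psms:
        if not 1 <= psm.start <= psm.end <= precursor_length:
            raise ValueError(
                f"{psm.precursor_id}: PSM span {psm.start}-{psm.end} outside precursor"
            )
        tier = psm.tier or psm_tier(psm.score)
        if _TIER_ORDER[tier] >= floor:
            covered.update(range(psm.start, psm.end + 1))
    return math.floor(100.0 * len(covered) / precursor_length + 0.5)


def assign_tiers(psms: Sequence[PSMRecord]) -> list[PSMRecord]:
    """Fill the ``tier`` field of each PSM from its score."""
    for psm in psms:
        psm.tier = psm_tier(psm.score)
    return list(psms)
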