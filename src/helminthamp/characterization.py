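"""Physicochemical descriptors and unit conversions for peptides.

Masses come from standard residue tables (monoisotopic and average) plus
fixed deltas for the modification set seen in helminth peptidomics:
N-terminal pyroglutamate, methionine oxidation, tyrosine sulfation and
C-terminal amidation.  MIC values in μg/ml convert to μM through the
average mass of the synthesised form.
"""

from __future__ import annotations

import cmath
import math

from pyteomics import mass as _ptmass

from helminthamp.types import MicRecord, ModifiedPeptide

# Modification mass deltas (Da)
WATER_MONO = 18.010565
PROTON = 1.007276
DELTA_PYRO_GLU = -17.026549
DELTA_OXIDATION = 15.994915
DELTA_SULFATION = 79.956815
DELTA_AMIDE_MONO = -0.984016
DELTA_AMIDE_AVG = -0.985

_MOD_DELTA = {"oxidation": DELTA_OXIDATION, "sulfation": DELTA_SULFATION}

#: Residues counted as hydrophobic for the hydrophobic-% descriptor.
HYDROPHOBIC_SET = frozenset("ACFILMVW")

#: Eisenberg consensus hydrophobicity scale (for the helical moment).
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

#: Side-chain / termini pKa values for the Henderson–Hasselbalch charge model.
_PKA = {
    "K": 10.5, "R": 12.5, "H": 6.0,
    "D": 3.65, "E": 4.25, "C": 8.3, "Y": 10.1,
    "n_term": 9.0, "c_term": 2.0,
}


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def monoisotopic_mass(p: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass in Da, reported to 4 decimals."""
    m = _ptmass.calculate_mass(sequence=p.sequence)
    if p.n_term == "pyro_glu":
        m += DELTA_PYRO_GLU
    if p.c_term == "amide":
        m += DELTA_AMIDE_MONO
    for mod in p.residue_mods.values():
        m += _MOD_DELTA[mod]
    return round(m, 4)


def average_mass(p: ModifiedPeptide) -> float:
    """Neutral average (chemical) mass in Da."""
    m = _ptmass.calculate_mass(sequence=p.sequence, average=True)
    if p.n_term == "pyro_glu":
        m += DELTA_PYRO_GLU
    if p.c_term == "amide":
        m += DELTA_AMIDE_AVG
    for mod in p.residue_mods.values():
        m += _MOD_DELTA[mod]
    return m


def mic_to_micromolar(mic_ug_ml: float, p: ModifiedPeptide) -> int:
    """Convert a MIC in μg/ml to the nearest-integer μM.

    μM = 1000 · (μg/ml) / average mass, rounded half-up — the convention of
    the parenthetical values in reported MIC tables.
    """
    if mic_ug_ml <= 0:
        raise ValueError("MIC must be positive")
    return _round_half_up(1000.0 * mic_ug_ml / average_mass(p))


def make_mic_record(peptide_id: str, organism: str, mic_ug_ml: float | None, p: ModifiedPeptide) -> MicRecord:
    um = None if mic_ug_ml is None else mic_to_micromolar(mic_ug_ml, p)
    return MicRecord(peptide_id, organism, mic_ug_ml, um)


def net_charge(p: ModifiedPeptide, model: str = "simple", ph: float = 7.0) -> float:
    """Net charge of a peptide.

    ``simple`` (default): +1 per K/R, −1 per D/E, +0.5 per H, +1 for a free
    N-terminus (0 if pyroglutamate), −1 for a free C-terminus (0 if amide).
    ``hh``: Henderson–Hasselbalch partial charges at the given pH.
    """
    s = p.sequence
    if model == "simple":
        charge = s.count("K") + s.count("R") - s.count("D") - s.count("E") + 0.5 * s.count("H")
        if p.n_term == "free":
            charge += 1.0
        if p.c_term == "free":
            charge -= 1.0
        return charge
    if model == "hh":
        def pos(pka: float) -> float:
            return 1.0 / (1.0 + 10 ** (ph - pka))

        def neg(pka: float) -> float:
            return -1.0 / (1.0 + 10 ** (pka - ph))

        charge = 0.0
        for aa in s:
            if aa in "KRH":
                charge += pos(_PKA[aa])
            elif aa in "DECY":
                charge += neg(_PKA[aa])
        if p.n_term == "free":
            charge += pos(_PKA["n_term"])
        if p.c_term == "free":
            charge += neg(_PKA["c_term"])
        return charge
    raise ValueError(f"unknown charge model {model!r}")


def hydrophobic_fraction(p: ModifiedPeptide) -> int:
    """Percentage of hydrophobic residues (A C F I L M V W), nearest integer."""
    s = p.sequence
    return _round_half_up(100.0 * sum(c in HYDROPHOBIC_SET for c in s) / len(s))


def eisenberg_moment(sequence: str, delta_deg: float = 100.0) -> float:
    """Mean Eisenberg hydrophobic moment per residue over an ideal α-helix."""
    delta = math.radians(delta_deg)
    total = sum(EISENBERG[c] * cmath.exp(1j * delta * i) for i, c in enumerate(sequence))
    return abs(total) / len(sequence)


def cysteine_count(sequence: str) -> int:
    return sequence.count("C")


def describe(p: ModifiedPeptide) -> dict:
    """Descriptor bundle used in characterisation reports."""
    return {
        "sequence": p.sequence,
        "length": len(p),
        "monoisotopic_mass": monoisotopic_mass(p),
        "average_mass": round(average_mass(p), 2),
        "net_charge": net_charge(p),
        "hydrophobic_pct": hydrophobic_fraction(p),
        "n_cysteines": cysteine_count(p.sequence),
        "amidated": p.c_term == "amide",
    }
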