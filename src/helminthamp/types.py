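"""Domain types shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 20 standard amino acids.
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Residues accepted in precursor input (X = unknown, * = stop codon);
#: sequences containing X/* are removed by the precursor filter, not at parse
#: time.
INPUT_AA = STANDARD_AA | {"X", "*"}


@dataclass
class PrecursorProtein:
    """A predicted protein with genome/species provenance."""

    protein_id: str
    genome_id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CleavageAnnotation:
    """Signal-peptide end and propeptide cleavage sites for one precursor.

    Positions are 1-based: ``signal_end`` is the last residue of the signal
    peptide, each propeptide site is the last residue before a cleavage point
    (for a dibasic K/R motif, the second basic residue).
    """

    protein_id: str
    signal_end: int | None = None
    propeptide_sites: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        sites = tuple(sorted(set(self.propeptide_sites)))
        object.__setattr__(self, "propeptide_sites", sites)
        if any(s < 1 for s in sites):
            raise ValueError(f"{self.protein_id}: propeptide site < 1")
        if self.signal_end is not None:
            if self.signal_end < 1:
                raise ValueError(f"{self.protein_id}: signal_end < 1")
            if any(s <= self.signal_end for s in sites):
                raise ValueError(
                    f"{self.protein_id}: propeptide site within signal peptide"
                )

    def validate_against(self, sequence: str) -> None:
        n = len(sequence)
        if self.signal_end is not None and self.signal_end > n:
            raise ValueError(f"{self.protein_id}: signal_end beyond sequence end")
        for s in self.propeptide_sites:
            if s > n:
                raise ValueError(f"{self.protein_id}: propeptide site {s} beyond sequence end")


@dataclass
class CandidatePeptide:
    """A peptide excised from a precursor.

    ``start``/``end`` are 1-based inclusive coordinates on the precursor and
    always satisfy ``sequence == precursor[start-1:end]``.
    """

    peptide_id: str
    protein_id: str
    genome_id: str
    start: int
    end: int
    sequence: str
    amidated: bool = False
    source_boundaries: tuple[str, str] = ("signal_end", "c_terminus")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PredictionProfile:
    """Per-peptide ensemble consensus over AMP prediction tools."""

    peptide_id: str
    calls: dict[str, bool]
    n_tools: int
    n_positive: int
    overall_pct: int
    is_amp_lp: bool


@dataclass
class SequelogGroup:
    """A connected component of AMP-LPs under the bit-score threshold graph."""

    group_id: int
    members: tuple[str, ...]
    genomes: frozenset[str]
    consensus: str = ""
    representative: str = ""


@dataclass
class ModifiedPeptide:
    """Sequence plus post-translational modification state.

    ``residue_mods`` maps 1-based positions to ``"oxidation"`` or
    ``"sulfation"``.  Pyroglutamate is only valid on an N-terminal Q or E.
    """

    sequence: str
    n_term: str = "free"  # free | pyro_glu
    c_term: str = "free"  # free | amide
    residue_mods: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise ValueError(f"non-standard residue(s) {sorted(bad)} in {self.sequence!r}")
        if self.n_term not in ("free", "pyro_glu"):
            raise ValueError(f"unknown n_term {self.n_term!r}")
        if self.c_term not in ("free", "amide"):
            raise ValueError(f"unknown c_term {self.c_term!r}")
        if self.n_term == "pyro_glu" and self.sequence[0] not in "QE":
            raise ValueError("pyro_glu requires an N-terminal Q or E")
        for pos, mod in self.residue_mods.items():
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"modification position {pos} outside sequence")
            if mod not in ("oxidation", "sulfation"):
                raise ValueError(f"unknown residue modification {mod!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MicRecord:
    """One minimum-inhibitory-concentration measurement.

    ``mic_ug_ml`` is None when no activity was seen at the assay ceiling
    (512 μg/ml).  A peptide counts as an AMP when MIC < 100 μg/ml.
    """

    peptide_id: str
    organism: str
    mic_ug_ml: float | None
    mic_um: int | None = None

    @property
    def active(self) -> bool:
        return self.mic_ug_ml is not None and self.mic_ug_ml < 100.0


@dataclass
class PSMRecord:
    """A peptide-spectrum match against a prepropeptide precursor."""

    precursor_id: str
    peptide: ModifiedPeptide
    start: int
    end: int
    score: float  # -10lgP
    tier: str = ""
    matched_ions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.peptide):
            raise ValueError(
                f"{self.precursor_id}: coordinate span {self.start}-{self.end} "
                f"does not match peptide length {len(self.peptide)}"
            )


@dataclass
class FilterReport:
    """Per-stage accounting of a filter cascade."""

    stage: str
    n_in: int
    n_removed: int

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed

    def __post_init__(self) -> None:
        if self.n_removed > self.n_in:
            raise ValueError("n_removed > n_in")
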