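"""Seeded generator of ground-truthed synthetic proteomes.

Emulates the inputs of a helminth AMP-discovery run: pseudo-genomes carrying
planted prepropeptide families (signal peptide + dibasic propeptide cleavage
sites flanking a cationic-amphipathic mature peptide), replicated across
genomes with per-residue substitutions, plus decoy proteins, planted copies
of known AMPs, GO and expression truth tables and per-tool call tables.

Design constraints that keep the truth valid under mutation:

- the signal-peptide h-region, the initial Met, and every K/R residue are
  never substituted, and substitutions never introduce K or R, so cleavage
  motifs are neither created nor destroyed;
- planted mature peptides are 28–44 residues, inside the 10–99 gate by
  construction;
- the hydrophobic h-region is built so the hydropathy heuristic recovers the
  planted signal end exactly.

Everything is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from helminthamp import cleavage_and_excision as cx
from helminthamp import io_formats
from helminthamp.characterization import eisenberg_moment, hydrophobic_fraction, net_charge
from helminthamp.types import CleavageAnnotation, ModifiedPeptide, PrecursorProtein

#: mutation targets: the 20 standard residues minus K and R (so dibasic
#: motifs cannot appear by substitution) and minus C (keeps planted AMPs in
#: the linear cysteine class).
_MUT_ALPHABET = "ADEFGHILMNPQSTVWY"
_H_REGION = "LIVFA"          # strongly hydrophobic (Kyte–Doolittle ≥ 1.8)
_POLAR = "GSTNQDEPH"         # guaranteed below any hydropathy window cutoff
_FACE_HYDRO = "LFWIAV"       # helix hydrophobic face
_FACE_POLAR = "KGSQNT"       # helix polar face (K weighted separately)

_TOOL_NAMES = [f"tool{i:02d}" for i in range(1, 12)]

_BENIGN_GO = ["GO:0042742", "GO:0050830", "GO:0019731"]  # defence-response terms
_BLOCK_GO = ["GO:0010951", "GO:0004867", "GO:0007165"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    seed: int = 17
    n_genomes: int = 4
    n_families: int = 8
    copies_per_family: int = 4
    mutation_rate: float = 0.05
    n_decoys: int = 20
    planted_known_amps: int = 12
    n_blocklisted_families: int = 2
    n_duplicates: int = 0
    n_invalid: int = 0
    n_long: int = 0
    tool_noise: float = 0.08

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0.0 <= self.tool_noise <= 1.0:
            raise ValueError("tool_noise must be in [0, 1]")
        for name in ("n_genomes", "n_families", "copies_per_family", "n_decoys",
                     "planted_known_amps", "n_blocklisted_families",
                     "n_duplicates", "n_invalid", "n_long"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if self.n_families and (self.copies_per_family < 2 or self.n_genomes < 2):
            raise ValueError("families need ≥ 2 copies across ≥ 2 genomes")


@dataclass
class FixtureBundle:
    """In-memory fixture: proteins + every truth table."""

    spec: FixtureSpec
    proteins: list[PrecursorProtein]
    annotations: dict[str, CleavageAnnotation]
    families: list[dict]                       # per-protein truth rows
    go: dict[str, set[str]]
    tpm: dict[str, list[float]]
    tool_calls: dict[str, dict[str, bool]]     # tool → peptide_id → call
    known_amps: list[PrecursorProtein]
    secreted_ids: list[str] = field(default_factory=list)
    ancestors: dict[str, str] = field(default_factory=dict)  # family → mature

    def genomes(self) -> list[str]:
        return sorted({p.genome_id for p in self.proteins})

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for gid in self.genomes():
            recs = [p for p in self.proteins if p.genome_id == gid]
            io_formats.write_fasta(recs, out / f"proteins_{gid}.fasta")
        # cleavage truth in the generic dialect; non-secreted proteins keep an
        # empty signal_end so parsers exercise the skip-and-count path
        with open(out / "cleavage.tsv", "w") as fh:
            fh.write("protein_id\tsignal_end\tpropeptide_sites\n")
            for p in self.proteins:
                ann = self.annotations.get(p.protein_id)
                if ann is None:
                    fh.write(f"{p.protein_id}\t\t\n")
                else:
                    sites = ";".join(map(str, ann.propeptide_sites))
                    fh.write(f"{p.protein_id}\t{ann.signal_end}\t{sites}\n")
        io_formats.write_results(self.families, out / "families.tsv", "tsv")
        with open(out / "go.tsv", "w") as fh:
            fh.write("gene_id\tgo_ids\n")
            for gene in sorted(self.go):
                fh.write(f"{gene}\t{';'.join(sorted(self.go[gene]))}\n")
        with open(out / "tpm.tsv", "w") as fh:
            fh.write("gene_id\tsample\ttpm\n")
            for gene in sorted(self.tpm):
                for k, v in enumerate(self.tpm[gene]):
                    fh.write(f"{gene}\tsample{k}\t{v:.3f}\n")
        calls_dir = out / "tool_calls"
        calls_dir.mkdir(exist_ok=True)
        for tool in sorted(self.tool_calls):
            with open(calls_dir / f"{tool}.tsv", "w") as fh:
                fh.write("peptide_id\ttool_name\tcall\n")
                for pid in sorted(self.tool_calls[tool]):
                    fh.write(f"{pid}\t{tool}\t{int(self.tool_calls[tool][pid])}\n")
        io_formats.write_fasta(self.known_amps, out / "known_amps.fasta")
        with open(out / "ancestors.tsv", "w") as fh:
            fh.write("family_id\tmature_sequence\n")
            for fam in sorted(self.ancestors):
                fh.write(f"{fam}\t{self.ancestors[fam]}\n")


# ---------------------------------------------------------------------------
# Sequence construction
# ---------------------------------------------------------------------------

def _draw(rng: np.random.Generator, alphabet: str, k: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=k))


def _signal_peptide(rng: np.random.Generator) -> str:
    """15-residue signal: Met + spacer + 10-residue h-region + polar c-region.

    The hydropathy heuristic (window 8 from position 3, +5 offset) lands on
    position 15 exactly."""
    return "M" + _draw(rng, "KQN", 1) + _draw(rng, _H_REGION, 10) + _draw(rng, "SAT", 2) + "A"


def _amphipathic_mature(rng: np.random.Generator, min_len: int = 26, max_len: int = 40) -> str:
    """Cationic-amphipathic mature-peptide core (flanking K/R motifs added by
    the caller).  Rejection-sampled until the excised form (core + KR)
    passes all three built-in reference rules with margin."""
    for _ in range(200):
        length = int(rng.integers(min_len, max_len + 1))
        chars: list[str] = []
        for i in range(length):
            angle = math.radians(100.0 * i)
            if math.cos(angle) > 0.25:
                c = _FACE_HYDRO[rng.integers(0, len(_FACE_HYDRO))]
            elif rng.random() < 0.55 and (not chars or chars[-1] not in "KR"):
                c = "K" if rng.random() < 0.8 else "R"
            else:
                c = _FACE_POLAR[1:][rng.integers(0, len(_FACE_POLAR) - 1)]
            chars.append(c)
        if chars[0] in "KR":
            chars[0] = "G"
        if chars[-1] in "KR":
            chars[-1] = "S"
        core = "".join(chars)
        excised = core + "KR"
        p = ModifiedPeptide(excised)
        if (net_charge(p) >= 3.0
                and 32 <= hydrophobic_fraction(p) <= 58
                and eisenberg_moment(excised) >= 0.25):
            return core
    raise RuntimeError("could not sample an amphipathic mature peptide")  # pragma: no cover


def _assemble_precursor(rng: np.random.Generator, core: str) -> tuple[str, int, tuple[int, ...]]:
    """signal + acidic spacer + KR + mature core + KR + polar tail."""
    signal = _signal_peptide(rng)
    spacer = _draw(rng, "EADSQPGT", int(rng.integers(12, 17)))
    tail = _draw(rng, "GSQNT", int(rng.integers(4, 9)))
    seq = signal + spacer + "KR" + core + "KR" + tail
    s1 = len(signal) + len(spacer) + 2          # second residue of first motif
    s2 = s1 + len(core) + 2
    return seq, len(signal), (s1, s2)


def _mutate(rng: np.random.Generator, seq: str, rate: float, protected: set[int]) -> str:
    """i.i.d. substitutions outside protected 0-based positions; never to K/R."""
    chars = list(seq)
    for i in range(len(chars)):
        if i in protected or chars[i] in "KR":
            continue
        if rng.random() < rate:
            new = _MUT_ALPHABET[rng.integers(0, len(_MUT_ALPHABET))]
            while new == chars[i]:
                new = _MUT_ALPHABET[rng.integers(0, len(_MUT_ALPHABET))]
            chars[i] = new
    return "".join(chars)


def _protected_positions(signal_len: int) -> set[int]:
    # Met + h-region (0-based 2..11); K/R residues are protected dynamically.
    return {0} | set(range(2, 12))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate(spec: FixtureSpec) -> FixtureBundle:
    """Build the full fixture bundle for ``spec`` (see module docstring)."""
    rng = np.random.default_rng(spec.seed)
    proteins: list[PrecursorProtein] = []
    annotations: dict[str, CleavageAnnotation] = {}
    families: list[dict] = []
    go: dict[str, set[str]] = {}
    tpm: dict[str, list[float]] = {}
    genome_ids = [f"genome{g:02d}" for g in range(spec.n_genomes)]

    def add(pid: str, gid: str, seq: str, role: str, family: str = "",
            mature: tuple[int, int] | None = None, intended_amp: bool = False,
            ann: CleavageAnnotation | None = None) -> None:
        proteins.append(PrecursorProtein(pid, gid, seq))
        if ann is not None:
            annotations[pid] = ann
        families.append({
            "protein_id": pid, "genome_id": gid, "family_id": family, "role": role,
            "mature_start": mature[0] if mature else "",
            "mature_end": mature[1] if mature else "",
            "intended_amp": intended_amp,
        })

    # --- planted AMP families (+ GO-blocklisted families) ---
    ancestors: dict[str, str] = {}
    n_total_fam = spec.n_families + spec.n_blocklisted_families
    for f in range(n_total_fam):
        blocklisted = f >= spec.n_families
        fam = f"bfam{f - spec.n_families:02d}" if blocklisted else f"fam{f:02d}"
        core = _amphipathic_mature(rng)
        ancestors[fam] = core + "KR"
        ancestor, sig_len, sites = _assemble_precursor(rng, core)
        protected = _protected_positions(sig_len)
        for c in range(spec.copies_per_family):
            gid = genome_ids[c % spec.n_genomes]
            seq = _mutate(rng, ancestor, spec.mutation_rate, protected)
            pid = f"{fam}_{gid}_p{c:02d}"
            ann = CleavageAnnotation(pid, sig_len, sites)
            add(pid, gid, seq, "blocklisted_amp" if blocklisted else "amp",
                fam, (sites[0] + 1, sites[1]), intended_amp=not blocklisted, ann=ann)
            go[pid] = ({_BLOCK_GO[int(rng.integers(0, len(_BLOCK_GO)))]}
                       if blocklisted else set())
            if not blocklisted and rng.random() < 0.3:
                go[pid].add(_BENIGN_GO[int(rng.integers(0, len(_BENIGN_GO)))])
            tpm[pid] = list(np.round(rng.uniform(3.0, 60.0, size=3), 3))

    # --- known-AMP library + planted copies ---
    known_amps = []
    n_lib = 3
    for k in range(n_lib):
        lib_seq = _amphipathic_mature(rng) + "KR"
        known_amps.append(PrecursorProtein(f"known_amp_{k:02d}", "library", lib_seq))
    for k in range(spec.planted_known_amps):
        lib = known_amps[k % n_lib]
        ancestor, sig_len, sites = _assemble_precursor(rng, lib.sequence[:-2])
        gid = genome_ids[int(rng.integers(0, spec.n_genomes))]
        pid = f"known_{k:02d}_{gid}"
        add(pid, gid, ancestor, "known_amp", f"known{k % n_lib}",
            (sites[0] + 1, sites[1]), intended_amp=False,
            ann=CleavageAnnotation(pid, sig_len, sites))
        tpm[pid] = list(np.round(rng.uniform(3.0, 30.0, size=3), 3))

    # --- decoys: secreted-neutral and non-secreted ---
    for d in range(spec.n_decoys):
        gid = genome_ids[int(rng.integers(0, spec.n_genomes))]
        if d % 2 == 0:
            sig = _signal_peptide(rng)
            body = _draw(rng, _POLAR, int(rng.integers(25, 60)))
            pid = f"decoy_sec_{d:02d}_{gid}"
            add(pid, gid, sig + body, "decoy_secreted",
                ann=CleavageAnnotation(pid, len(sig), ()))
        else:
            body = "M" + _draw(rng, _POLAR, int(rng.integers(40, 120)))
            pid = f"decoy_cyt_{d:02d}_{gid}"
            add(pid, gid, body, "decoy_nonsecreted")
        go[pid] = {_BENIGN_GO[int(rng.integers(0, len(_BENIGN_GO)))]} if rng.random() < 0.4 else set()
        tpm[pid] = list(np.round(rng.uniform(0.0, 2.0, size=3), 3))

    # --- pathological proteins for the precursor filters ---
    base_pool = [p for p in proteins]
    for d in range(spec.n_duplicates):
        src = base_pool[int(rng.integers(0, len(base_pool)))]
        add(f"dup_{d:02d}_{src.protein_id}", src.genome_id, src.sequence, "duplicate")
    for d in range(spec.n_invalid):
        gid = genome_ids[int(rng.integers(0, spec.n_genomes))]
        body = list("M" + _draw(rng, _POLAR, int(rng.integers(30, 80))))
        body[int(rng.integers(1, len(body)))] = "X" if d % 2 == 0 else "*"
        add(f"invalid_{d:02d}", gid, "".join(body), "invalid")
    for d in range(spec.n_long):
        gid = genome_ids[int(rng.integers(0, spec.n_genomes))]
        add(f"long_{d:02d}", gid, "M" + _draw(rng, _POLAR, int(rng.integers(160, 220))), "long")

    secreted_ids = sorted(annotations)

    # --- per-tool call tables over the peptides the truth annotation excises ---
    seq_of = {p.protein_id: p for p in proteins}
    tool_calls: dict[str, dict[str, bool]] = {t: {} for t in _TOOL_NAMES}
    from helminthamp.ensemble_prediction import reference_predictors

    for pid in secreted_ids:
        ann = annotations[pid]
        peptides = cx.length_gate(cx.enumerate_peptides(seq_of[pid], ann))
        for pep in peptides:
            rules = reference_predictors(pep.sequence)
            base = sum(rules.values()) >= 2
            for tool in _TOOL_NAMES:
                flip = rng.random() < spec.tool_noise
                tool_calls[tool][pep.peptide_id] = base != flip

    return FixtureBundle(
        spec=spec, proteins=proteins, annotations=annotations, families=families,
        go=go, tpm=tpm, tool_calls=tool_calls, known_amps=known_amps,
        secreted_ids=secreted_ids, ancestors=ancestors,
    )
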