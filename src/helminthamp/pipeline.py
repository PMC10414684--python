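"""End-to-end orchestration: filter → excise → predict → exclude → group →
curate → characterise.

Inputs live in one directory (the layout the fixture generator writes and
the README documents): per-genome ``proteins_<genome>.fasta`` files, an
optional ``cleavage.tsv`` (generic dialect; heuristics are used for proteins
it does not cover), optional ``tool_calls/*.tsv`` (built-in reference rules
otherwise), optional ``go.tsv``, ``tpm.tsv`` and ``known_amps.fasta``.
Per-stage counts are reported in pipeline order so a run log reads like the
discovery funnel.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

from helminthamp import (
    cleavage_and_excision as cx,
    curation,
    ensemble_prediction as ep,
    io_formats,
    precursor_filter as pf,
    sequelog_grouping as sg,
)
from helminthamp.characterization import describe
from helminthamp.config import RunConfig
from helminthamp.types import CandidatePeptide, PrecursorProtein, SequelogGroup

logger = logging.getLogger(__name__)


def load_inputs(input_dir: str | Path) -> dict:
    """Read everything present in a pipeline input directory."""
    d = Path(input_dir)
    proteins: list[PrecursorProtein] = []
    for fp in sorted(d.glob("proteins_*.fasta")):
        proteins.extend(io_formats.read_fasta(fp, genome_id=fp.stem.removeprefix("proteins_")))
    if not proteins:
        raise FileNotFoundError(f"no proteins_*.fasta found in {d}")
    out: dict = {"proteins": proteins}
    if (d / "cleavage.tsv").exists():
        out["annotations"] = io_formats.read_cleavage_tables(generic_tsv=d / "cleavage.tsv")
    calls_dir = d / "tool_calls"
    if calls_dir.is_dir():
        out["call_paths"] = sorted(calls_dir.glob("*.tsv"))
    if (d / "go.tsv").exists():
        out["go"] = io_formats.read_go_tsv(d / "go.tsv")
    if (d / "tpm.tsv").exists():
        out["tpm"] = io_formats.read_tpm_tsv(d / "tpm.tsv")
    if (d / "known_amps.fasta").exists():
        out["known_amps"] = io_formats.read_fasta(d / "known_amps.fasta", genome_id="library")
    return out


def run_pipeline(
    inputs: Mapping,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute the full discovery pipeline; returns a machine-readable report.

    ``inputs`` is the mapping :func:`load_inputs` returns (or an equivalent
    built in memory).  When ``out_dir`` is given, the filtered FASTA, the
    peptide/group tables and the run log are written there.
    """
    cfg = (config or RunConfig()).validate()
    report: dict = {"stages": []}

    def stage(name: str, n_in: int, n_out: int, **extra) -> None:
        entry = {"stage": name, "n_in": n_in, "n_removed": n_in - n_out, "n_out": n_out, **extra}
        report["stages"].append(entry)
        logger.info("%s: %d → %d", name, n_in, n_out)

    # 1. protein-level filters
    proteins: Sequence[PrecursorProtein] = inputs["proteins"]
    survivors, filter_reports = pf.run_cascade(proteins, max_len=cfg.max_protein_len)
    for r in filter_reports:
        stage(r.stage, r.n_in, r.n_out)

    # 2. cleavage annotation + excision + length gate
    annotations = dict(inputs.get("annotations", {}))
    n_heuristic = 0
    for p in survivors:
        if p.protein_id not in annotations:
            ann = cx.annotate_heuristically(p)
            if ann is not None:
                annotations[p.protein_id] = ann
                n_heuristic += 1
    secreted = [p for p in survivors if p.protein_id in annotations]
    stage("signal_peptide", len(survivors), len(secreted), heuristic_annotations=n_heuristic)

    peptides: list[CandidatePeptide] = []
    for p in secreted:
        peptides.extend(cx.enumerate_peptides(p, annotations[p.protein_id], mode=cfg.excision_mode))
    n_pre_gate = len(peptides)
    peptides = cx.length_gate(peptides, cfg.peptide_min_len, cfg.peptide_max_len)
    stage("excision_length_gate", n_pre_gate, len(peptides))

    # 3. ensemble consensus
    if "call_paths" in inputs:
        calls = ep.load_tool_calls(inputs["call_paths"], threshold=cfg.call_threshold)
    else:
        calls = {p.peptide_id: ep.reference_predictors(p.sequence) for p in peptides}
    profiles = {}
    for p in peptides:
        if p.peptide_id in calls and calls[p.peptide_id]:
            profiles[p.peptide_id] = ep.consensus(p.peptide_id, calls[p.peptide_id],
                                                  cfg.consensus_fraction)
    amp_lps = [p for p in peptides if p.peptide_id in profiles and profiles[p.peptide_id].is_amp_lp]
    stage("ensemble_consensus", len(peptides), len(amp_lps))

    # 4. known-AMP exclusion
    if inputs.get("known_amps"):
        amp_lps, excl_log = sg.exclusion_filter(
            amp_lps, inputs["known_amps"], min_bits=cfg.min_bits_exclude)
        stage("known_amp_exclusion", len(amp_lps) + len(excl_log), len(amp_lps))
        report["exclusion_log"] = excl_log

    # 5. sequelog grouping
    precursor_seq = {p.protein_id: p.sequence for p in proteins}
    if cfg.grouping_on == "precursor":
        grouping_seq = {p.peptide_id: precursor_seq[p.protein_id] for p in amp_lps}
    else:
        grouping_seq = {p.peptide_id: p.sequence for p in amp_lps}
    items = [sg.GroupingItem(p.peptide_id, p.genome_id, grouping_seq[p.peptide_id])
             for p in amp_lps]
    groups: list[SequelogGroup] = sg.build_groups(items, min_bits=cfg.min_bits_group) if items else []
    n_grouped = sum(len(g.members) for g in groups)
    stage("sequelog_grouping", len(amp_lps), n_grouped, n_groups=len(groups))

    # 6. curation
    pep_by_id = {p.peptide_id: p for p in amp_lps}
    gene_of = {p.peptide_id: p.protein_id for p in amp_lps}
    removal_log: list[dict] = []
    if "go" in inputs:
        blocklist = cfg.go_blocklist or curation.DEFAULT_GO_BLOCKLIST
        groups, removed = curation.go_filter(groups, inputs["go"], blocklist,
                                             gene_of=gene_of, mode=cfg.go_filter_mode)
        removal_log.extend(removed)
        stage("go_filter", len(groups) + len(removed), len(groups))
    member_lengths = {pid: len(pep_by_id[pid]) for g in groups for pid in g.members}
    groups, removed = curation.group_length_filter(groups, member_lengths, cfg.group_len_cutoff)
    removal_log.extend(removed)
    stage("group_length_filter", len(groups) + len(removed), len(groups))
    report["curation_log"] = removal_log

    # consensus / representative per surviving group (on mature peptides)
    mature_seq = {p.peptide_id: p.sequence for p in amp_lps}
    for g in groups:
        g.consensus, g.representative = sg.consensus_and_representative(g, mature_seq)

    # 7. characterisation of representatives
    rows = []
    for g in groups:
        rep = pep_by_id[g.representative]
        mod = cx.synthesis_form(rep)
        desc = describe(mod)
        desc.update({
            "group_id": g.group_id,
            "n_members": len(g.members),
            "n_genomes": len(g.genomes),
            "representative": g.representative,
            "consensus": g.consensus,
            "cysteine_class": curation.cysteine_class(rep.sequence),
        })
        if "tpm" in inputs:
            flag = curation.expression_flag(rep.protein_id, inputs["tpm"], cfg.tpm_cutoff)
            desc["expressed"] = "unknown" if flag is None else flag
        rows.append(desc)
    report["n_prioritised_groups"] = len(groups)
    report["prioritised"] = rows

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_formats.write_fasta(survivors, out / "filtered_proteins.fasta")
        io_formats.write_results(
            [dataclasses.asdict(p) for p in amp_lps], out / "amp_lp_peptides.tsv", "tsv")
        io_formats.write_results(rows, out / "prioritised_groups.tsv", "tsv")
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)
            fh.write("\n")
    return report
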