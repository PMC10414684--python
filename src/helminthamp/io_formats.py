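"""Readers and writers for every external file the pipeline touches.

Coordinates are 1-based inclusive in all serialised files.  Sequences are
upper-cased on read (lowercase input is accepted with a warning).  Parsers
never silently drop rows: anything skipped is counted and logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from helminthamp.types import CleavageAnnotation, PrecursorProtein

logger = logging.getLogger(__name__)


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line number."""


class FormatError(ValueError):
    """Unrecognised table dialect."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _prevalidate_fasta(path: Path) -> None:
    """Cheap syntax pass so errors can name a line number."""
    n_seq_lines = 0
    saw_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if saw_header and n_seq_lines == 0:
                    raise FastaParseError(f"{path}: empty sequence before line {lineno}")
                if line == ">":
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                saw_header = True
                n_seq_lines = 0
            else:
                if not saw_header:
                    raise FastaParseError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                n_seq_lines += 1
    if not saw_header:
        raise FastaParseError(f"{path}: no FASTA records found")
    if n_seq_lines == 0:
        raise FastaParseError(f"{path}: empty sequence in final record")


def read_fasta(
    path: str | Path,
    genome_id: str | None = None,
    species: str = "",
) -> list[PrecursorProtein]:
    """Read a predicted-proteome FASTA into :class:`PrecursorProtein` records.

    ``genome_id`` is mandatory for provenance; when not given the FASTA
    filename stem is used.  Input order is preserved and duplicates are kept
    (deduplication is a downstream, counted filter stage).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_fasta(path)
    gid = genome_id if genome_id is not None else path.stem

    records: list[PrecursorProtein] = []
    seen: set[str] = set()
    n_lower = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            n_lower += 1
            seq = seq.upper()
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate protein id {rec.id!r} within genome {gid!r}")
        seen.add(rec.id)
        records.append(PrecursorProtein(rec.id, gid, seq, species))
    if n_lower:
        logger.warning("%s: %d record(s) contained lowercase residues (upper-cased)", path, n_lower)
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    """Write records (anything with ``sequence`` and an id) as FASTA."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            rid = getattr(rec, "protein_id", None) or getattr(rec, "peptide_id")
            fh.write(f">{rid}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Cleavage annotation tables
# ---------------------------------------------------------------------------

_SIGNALP_COLS = 12  # name Cmax pos Ymax pos Smax pos Smean D ? Dmaxcut net


def _parse_signalp_short(path: Path) -> dict[str, int]:
    """SignalP 4.1 ``short`` output → protein_id → signal_end.

    Only positive calls (``?`` column == Y) are returned; the reported
    cleavage position is the first residue of the mature protein, so
    signal_end = pos − 1.
    """
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) < _SIGNALP_COLS:
                raise FormatError(f"{path}:{lineno}: not SignalP 4.1 short format")
            name, ypos, call = parts[0], int(parts[4]), parts[9]
            if call == "Y":
                out[name] = ypos - 1
    return out


_PROP_SITE_RE = re.compile(r"^\s*(\d+)\s+([A-Z])\s+([0-9.]+)\s+\*ProP\*")


def _parse_prop(path: Path) -> dict[str, list[int]]:
    """ProP 1.0 text output → protein_id → predicted propeptide sites.

    Blocks open with a ``>name`` (or bare name) line; site lines carry the
    ``*ProP*`` marker with the 1-based position of the residue preceding the
    cleavage point.
    """
    out: dict[str, list[int]] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            m = _PROP_SITE_RE.match(line)
            if m:
                if current is None:
                    raise FormatError(f"{path}: ProP site line before any sequence name")
                out.setdefault(current, []).append(int(m.group(1)))
            elif stripped.startswith(">"):
                current = stripped[1:].split()[0]
                out.setdefault(current, [])
            elif re.match(r"^\S+$", stripped) and not stripped[0].isdigit():
                current = stripped
                out.setdefault(current, [])
    return out


def _parse_generic_tsv(path: Path) -> dict[str, CleavageAnnotation]:
    """Generic dialect: columns protein_id, signal_end, propeptide_sites.

    ``propeptide_sites`` is ``;``-separated (may be empty); an empty
    signal_end means no signal peptide (row skipped with a log entry).
    """
    out: dict[str, CleavageAnnotation] = {}
    n_skipped = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["protein_id", "signal_end", "propeptide_sites"]:
            raise FormatError(f"{path}: not the generic cleavage TSV dialect (header {header!r})")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            pid, sig, sites_s = parts[0], parts[1], parts[2]
            if not sig:
                n_skipped += 1
                continue
            sites = tuple(int(s) for s in sites_s.split(";") if s)
            out[pid] = CleavageAnnotation(pid, int(sig), sites)
    if n_skipped:
        logger.info("%s: skipped %d row(s) without a signal-peptide call", path, n_skipped)
    return out


def read_cleavage_tables(
    signalp_path: str | Path | None = None,
    prop_path: str | Path | None = None,
    generic_tsv: str | Path | None = None,
    sequences: Mapping[str, str] | None = None,
) -> dict[str, CleavageAnnotation]:
    """Assemble per-protein cleavage annotations.

    Either ``generic_tsv`` alone, or ``signalp_path`` (required for the
    signal-peptide call) optionally combined with ``prop_path`` for
    propeptide sites.  Only proteins with a positive signal-peptide call
    appear in the result.  Positions are validated against ``sequences``
    when provided.
    """
    if generic_tsv is not None:
        annots = _parse_generic_tsv(Path(generic_tsv))
    elif signalp_path is not None:
        sig = _parse_signalp_short(Path(signalp_path))
        sites = _parse_prop(Path(prop_path)) if prop_path is not None else {}
        annots = {}
        for pid, send in sig.items():
            psites = tuple(s for s in sites.get(pid, []) if s > send)
            annots[pid] = CleavageAnnotation(pid, send, psites)
    else:
        raise FormatError("need either generic_tsv or signalp_path")

    if sequences is not None:
        for pid, ann in annots.items():
            if pid in sequences:
                ann.validate_against(sequences[pid])
    return annots


def write_cleavage_tsv(annots: Mapping[str, CleavageAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tsignal_end\tpropeptide_sites\n")
        for pid in sorted(annots):
            a = annots[pid]
            sig = "" if a.signal_end is None else str(a.signal_end)
            fh.write(f"{pid}\t{sig}\t{';'.join(map(str, a.propeptide_sites))}\n")


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def _as_dict(rec) -> dict:
    if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
        d = dataclasses.asdict(rec)
        for k, v in list(d.items()):
            if isinstance(v, (set, frozenset)):
                d[k] = sorted(v)
            elif isinstance(v, tuple):
                d[k] = list(v)
        return d
    return dict(rec)


def write_results(
    records: Sequence,
    path: str | Path,
    format: str = "tsv",
    columns: Sequence[str] | None = None,
) -> None:
    """Write records (dataclasses or mappings) as TSV or JSON.

    Column order is deterministic: explicit ``columns`` if given, else the
    field order of the first record.  An empty record set yields a
    header-only TSV (or an empty JSON list).
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"format must be 'tsv' or 'json', got {format!r}")
    dicts = [_as_dict(r) for r in records]
    if columns is None:
        columns = list(dicts[0].keys()) if dicts else []
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(dicts, fh, indent=1, default=str)
            fh.write("\n")
        return
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for d in dicts:
            row = []
            for c in columns:
                v = d.get(c, "")
                if isinstance(v, (list, tuple)):
                    v = ";".join(map(str, v))
                row.append(str(v))
            fh.write("\t".join(row) + "\n")


def read_results_json(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Small keyed tables (tool calls, GO, TPM)
# ---------------------------------------------------------------------------

def read_go_tsv(path: str | Path) -> dict[str, set[str]]:
    """GO annotation table: columns gene_id, go_ids (``;``-separated)."""
    out: dict[str, set[str]] = {}
    for row in read_tsv_rows(path, ["gene_id", "go_ids"]):
        out[row["gene_id"]] = {t for t in row["go_ids"].split(";") if t}
    return out


def read_tpm_tsv(path: str | Path) -> dict[str, list[float]]:
    """Expression table: columns gene_id, sample, tpm (long form)."""
    out: dict[str, list[float]] = {}
    for row in read_tsv_rows(path, ["gene_id", "sample", "tpm"]):
        out.setdefault(row["gene_id"], []).append(float(row["tpm"]))
    return out


def read_tsv_rows(path: str | Path, expected_cols: Sequence[str]) -> list[dict[str, str]]:
    """Read a headered TSV, checking that expected columns are present."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in expected_cols if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        rows = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append(dict(zip(header, parts)))
    return rows
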