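"""Run configuration: every pipeline threshold in one serialisable object."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All tunable thresholds of the discovery pipeline, with their defaults.

    Units/meaning: protein lengths in residues; ``consensus_fraction`` is the
    strict lower bound on the positive-tool fraction; bit scores in bits;
    TPM in transcripts per million; PSM cutoffs in −10lgP; MIC bound in
    μg/ml.
    """

    max_protein_len: int = 150
    peptide_min_len: int = 10
    peptide_max_len: int = 99
    consensus_fraction: float = 0.5
    call_threshold: float = 0.5
    min_bits_group: float = 100.0
    min_bits_exclude: float = 50.0
    group_len_cutoff: int = 60
    tpm_cutoff: float = 2.0
    psm_high: float = 47.4
    psm_medium: float = 20.0
    psm_low: float = 13.0
    mic_active_max_ug_ml: float = 100.0
    excision_mode: str = "all_pairs"
    grouping_on: str = "precursor"  # precursor | peptide
    go_filter_mode: str = "any"
    seed: int = 0
    go_blocklist: list[str] = field(default_factory=list)  # empty → built-in default

    def validate(self) -> "RunConfig":
        pos = ("max_protein_len", "peptide_min_len", "peptide_max_len",
               "min_bits_group", "min_bits_exclude", "group_len_cutoff",
               "psm_high", "psm_medium", "psm_low", "mic_active_max_ug_ml")
        for name in pos:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.consensus_fraction <= 1.0:
            raise ValueError("consensus_fraction must be in (0, 1]")
        if self.peptide_min_len > self.peptide_max_len:
            raise ValueError("peptide_min_len > peptide_max_len")
        if self.tpm_cutoff < 0:
            raise ValueError("tpm_cutoff must be ≥ 0")
        if self.excision_mode not in ("all_pairs", "segments"):
            raise ValueError(f"unknown excision_mode {self.excision_mode!r}")
        if self.grouping_on not in ("precursor", "peptide"):
            raise ValueError(f"unknown grouping_on {self.grouping_on!r}")
        if self.go_filter_mode not in ("any", "all"):
            raise ValueError(f"unknown go_filter_mode {self.go_filter_mode!r}")
        return self

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data).validate()
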