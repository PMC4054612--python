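"""Run configuration.

A single :class:`RunConfig` object carries every tunable the pipeline
exposes.  Defaults reproduce the published analysis settings: the Illumina
small-RNA 3' adapter, cutadapt-style quality/length cutoffs (``-q 20``,
``-m 15``), the bowtie ``-v 2 --best --strata -k 50`` mapping policy, the
DE threshold FDR < 0.1, the enrichment threshold FDR < 0.05, the 4-SD PCA
outlier rule and the 3-of-7 database voting threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

DEFAULT_ADAPTER = "TCGTATGCCGTCTTCTGCTTGAAA"

_VALID_BASES = set("ACGTN")


@dataclass
class RunConfig:
    """All pipeline parameters with their published defaults."""

    adapter: str = DEFAULT_ADAPTER
    quality_cutoff: int = 20
    min_length: int = 15
    max_mismatches: int = 2
    max_loci: int = 50
    de_fdr: float = 0.1
    go_fdr: float = 0.05
    outlier_sd: float = 4.0
    min_db_support: int = 3
    seed: int = 0

    # Secondary knobs (documented open choices, not published values).
    adapter_error_rate: float = 0.1
    adapter_min_overlap: int = 3
    trim_quality_first: bool = False      # sentence order: adapter clip, then quality trim
    loci_cap_post_stratum: bool = False   # bowtie -k semantics: cap on pre-stratum hits
    overlap_fraction: float = 0.5         # same-strand feature must cover >= this of a tag
    nev_mode: str = "rpm"                 # {"rpm", "size_factor"}
    pca_log_transform: bool = True        # PCA on log2(NEV + 1)

    def validate(self) -> None:
        """Raise ``ValueError`` listing every offending field."""
        problems = []
        if not self.adapter or set(self.adapter) - _VALID_BASES:
            problems.append(f"adapter: not a DNA string ({self.adapter!r})")
        if self.quality_cutoff < 0:
            problems.append("quality_cutoff: must be >= 0")
        if self.min_length < 1:
            problems.append("min_length: must be >= 1")
        if self.max_mismatches < 0:
            problems.append("max_mismatches: must be >= 0")
        if self.max_loci < 1:
            problems.append("max_loci: must be >= 1")
        for name in ("de_fdr", "go_fdr", "adapter_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}: must be in [0, 1], got {v}")
        if self.outlier_sd <= 0:
            problems.append("outlier_sd: must be > 0")
        if self.min_db_support < 1:
            problems.append("min_db_support: must be >= 1")
        if self.adapter_min_overlap < 1:
            problems.append("adapter_min_overlap: must be >= 1")
        if not 0.0 < self.overlap_fraction <= 1.0:
            problems.append("overlap_fraction: must be in (0, 1]")
        if self.nev_mode not in ("rpm", "size_factor"):
            problems.append(f"nev_mode: unknown mode {self.nev_mode!r}")
        if problems:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
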