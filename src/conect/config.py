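"""Run configuration: every tunable of the pipeline, in one validated place.

The on-disk format is a flat ``key = value`` text file (``#`` comments
allowed).  Unknown keys are rejected so typos cannot silently fall back to a
default.  The defaults reproduce the pipeline's canonical constants: the
>10 bp terminal-segment rule, the 2% FDR background threshold, the >70%
present-call fraction and the top-2% random-probe subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path


@dataclass
class RunConfig:
    # round-1 masking
    min_terminal_len: int = 10
    min_identity: float = 0.95
    min_hit_len: int = 20
    kmer_size: int = 16
    # round-2 classification
    min_intron_len: int = 40
    max_link_dist: int = 50_000
    splice_set: str = "GT"  # comma-separated donor dinucleotides; acceptor is AG
    # tiling caller
    fdr_q: float = 0.02
    present_frac: float = 0.70
    subtraction_percentile: float = 0.98
    # general
    seed: int = 17
    threads: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.min_terminal_len < 0:
            raise ValueError("min_terminal_len must be >= 0")
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_hit_len < self.kmer_size:
            raise ValueError("min_hit_len must be >= kmer_size")
        if self.kmer_size < 8:
            raise ValueError("kmer_size must be >= 8")
        if self.min_intron_len < 1 or self.max_link_dist < 1:
            raise ValueError("min_intron_len and max_link_dist must be positive")
        if not (0.0 < self.fdr_q < 1.0):
            raise ValueError("fdr_q must be in (0, 1)")
        if not (0.0 <= self.present_frac < 1.0):
            raise ValueError("present_frac must be in [0, 1)")
        if not (0.0 < self.subtraction_percentile < 1.0):
            raise ValueError("subtraction_percentile must be in (0, 1)")
        donors = self.donors
        if not donors or any(len(d) != 2 or set(d) - set("ACGT") for d in donors):
            raise ValueError("splice_set must list dinucleotides, e.g. 'GT' or 'GT,GC'")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")

    @property
    def donors(self) -> tuple[str, ...]:
        return tuple(d.strip().upper() for d in self.splice_set.split(",") if d.strip())


_FIELD_TYPES = {f.name: f.type for f in fields(RunConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat key=value file into a validated RunConfig."""
    values: dict[str, object] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in _FIELD_TYPES:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = _coerce(key, raw)
    return RunConfig(**values)


def _coerce(key: str, raw: str) -> object:
    ftype = _FIELD_TYPES[key]
    if ftype in ("int", int):
        return int(raw)
    if ftype in ("float", float):
        return float(raw)
    return raw


def save_config(config: RunConfig, path: str | Path) -> None:
    lines = [f"{f.name} = {getattr(config, f.name)}" for f in fields(RunConfig)]
    Path(path).write_text("\n".join(lines) + "\n")
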