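"""Shared I/O: FASTQ/FASTA streams, annotated TSV tables, pipeline config.

Tables travel between stages as TSV with '#'-prefixed metadata headers
(tool version, seed, config hash) so every artifact records its provenance
and remains diff-able.
"""
from __future__ import annotations

import gzip
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import __version__
from .errors import ConfigError

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "write_tsv",
    "read_tsv",
    "PipelineConfig",
    "load_config",
    "dump_config",
]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream (id, sequence, quality) records from FASTQ or gzip-FASTQ."""
    with _open_text(path) as fh:
        try:
            for rec in FastqGeneralIterator(fh):
                yield rec
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> Path:
    path = Path(path)
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return path


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    from Bio import SeqIO

    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    with _open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")
    return path


def write_tsv(df: pd.DataFrame, path: str | Path, meta: dict | None = None,
              index: bool | None = None) -> Path:
    """TSV with '#'-prefixed provenance headers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {"tool": f"bcstarprom {__version__}"}
    header.update(meta or {})
    if index is None:
        index = df.index.name is not None
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end pipeline driver."""

    out_dir: str = "bcstarprom_out"
    screen_fastq: str | None = None
    association_reads: str | None = None
    association_mode: str = "junction"
    library_manifest: str | None = None
    association_table: str | None = None
    motifs: str | None = None
    min_reads: int = 50
    max_mismatch: int = 1
    pseudocount: float = 0.0
    top_k: int = 20
    k_groups: int = 4
    n_perm: int = 999
    rel_score_threshold: float = 0.85
    max_cv: float = 0.12
    drug: str = "jasplakinolide"
    control_treatment: str = "DMSO"
    sample_sheet: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    _ranges: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        checks = {
            "min_reads": self.min_reads >= 0,
            "max_mismatch": self.max_mismatch in (0, 1),
            "pseudocount": self.pseudocount >= 0,
            "top_k": self.top_k >= 1,
            "k_groups": self.k_groups >= 1,
            "n_perm": self.n_perm >= 1,
            "rel_score_threshold": 0 < self.rel_score_threshold <= 1,
            "max_cv": self.max_cv >= 0,
            "association_mode": self.association_mode in ("junction", "long"),
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ConfigError(f"config value(s) out of range: {', '.join(bad)}")

    def config_hash(self) -> str:
        # out_dir and log_level do not influence results
        skip = {"out_dir", "log_level"}
        d = {
            k: v for k, v in asdict(self).items()
            if not k.startswith("_") and k not in skip
        }
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]

    def meta(self) -> dict:
        return {"config": self.config_hash(), "seed": self.seed}


_CONFIG_FIELDS = {f for f in PipelineConfig.__dataclass_fields__ if not f.startswith("_")}


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return PipelineConfig(**raw)


def dump_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    d = {k: v for k, v in asdict(cfg).items() if not k.startswith("_")}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
    return path
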