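"""FASTQ input and run-configuration plumbing."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator

import yaml
from Bio import SeqIO

from .libcode import LibraryArchitecture

__all__ = ["open_text", "read_fastq_sequences", "load_architecture"]


def open_text(path):
    """Open plain or gzip-compressed text transparently."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_sequences(path) -> Iterator[str]:
    """Yield read sequences (uppercase strings) from a FASTQ file."""
    with open_text(path) as fh:
        for record in SeqIO.parse(fh, "fastq"):
            yield str(record.seq).upper()


def load_architecture(path) -> LibraryArchitecture:
    """Load a LibraryArchitecture from a YAML/JSON config."""
    with open_text(path) as fh:
        raw = yaml.safe_load(fh)
    if "stop_codons" in raw:
        raw["stop_codons"] = frozenset(raw["stop_codons"])
    return LibraryArchitecture(**raw)
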