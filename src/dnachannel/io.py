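"""File plumbing: FASTA/FASTQ, variant tables, configs, run manifests.

Sequence I/O goes through Biopython; variant tables use a TSV with the
documented edit-string grammar (``reference_id<TAB>edits<TAB>count`` with
edits like ``"1SG;2D"``); channel configs are YAML/JSON mappings mirroring
:class:`~dnachannel.stages.ChannelConfig`.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pool import SequencePool, ValidationError, edits_to_string, string_to_edits, VariantRecord
from .stages import ChannelConfig, ReadSet

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "write_variants_tsv",
    "read_variants_tsv",
    "load_config",
    "save_config",
    "config_hash",
    "RunManifest",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs; an empty file yields an empty list."""
    try:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    except ValueError as err:
        raise ValidationError(f"malformed FASTA {path}: {err}") from err


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def write_fastq(reads: ReadSet, path, quality: int = 40) -> None:
    """Write a read set as FASTQ with constant dummy quality.

    A read with multiplicity m is emitted as m records with suffixed IDs
    (``ref3/2`` = second copy of a read of reference 3).
    """
    def records():
        for i, recs in enumerate(reads.reads):
            copy = 0
            for seq, mult in recs:
                for _ in range(mult):
                    copy += 1
                    rec = SeqRecord(Seq(seq), id=f"ref{i}/{copy}", description="")
                    rec.letter_annotations["phred_quality"] = [quality] * len(seq)
                    yield rec

    SeqIO.write(records(), str(path), "fastq")


def write_variants_tsv(pool: SequencePool, path) -> None:
    with open(path, "w") as fh:
        fh.write("reference_id\tedits\tcount\n")
        for i in range(pool.n_references):
            for rec in pool.variants_of(i):
                fh.write(f"{i}\t{edits_to_string(rec.edits)}\t{rec.count}\n")


def read_variants_tsv(references: Sequence[str], path) -> SequencePool:
    per_ref: list[list[VariantRecord]] = [[] for _ in references]
    with open(path) as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                ref_id, edit_str, count = line.split("\t")
                per_ref[int(ref_id)].append(
                    VariantRecord(string_to_edits(edit_str), int(count))
                )
            except (ValueError, IndexError) as err:
                raise ValidationError(f"{path}:{lineno}: bad variant row: {err}") from err
    return SequencePool.from_records(references, per_ref)


def load_config(path) -> ChannelConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ChannelConfig.from_dict(data)


def save_config(config: ChannelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: ChannelConfig) -> str:
    """Hash of the config, stable under mapping key order."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record of one simulation run."""

    config_hash: str
    seed: int
    stages: list[str]
    outputs: dict[str, str] = field(default_factory=dict)
    wall_time_s: float = 0.0

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "stages": self.stages,
                    "outputs": self.outputs,
                    "wall_time_s": round(self.wall_time_s, 3),
                },
                fh,
                indent=2,
            )

    def verify_outputs(self) -> bool:
        return all(Path(p).exists() for p in self.outputs.values())
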