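"""Shared readers and writers: FASTA proteomes, TSV tables, provenance headers.

All tabular output is tab-delimited UTF-8 with a header row; files written by
the pipeline carry ``#``-prefixed provenance lines (tool version, config hash,
seed) that every reader here skips transparently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

FASTA_WRAP = 80


@dataclass
class Proteome:
    """A genome's predicted protein complement: the unit of relatedness work.

    ``proteins`` maps protein ID to amino-acid sequence (20-letter alphabet;
    ambiguity codes are tolerated on input but never generated).
    """

    genome_id: str
    proteins: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.proteins)

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")


def config_hash(config: Mapping) -> str:
    """Stable short hash of an effective configuration, for provenance lines."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(config: Mapping | None = None, seed: int | None = None) -> list[str]:
    lines = [f"# scfatlas v{__version__}"]
    if config is not None:
        lines.append(f"# config_hash={config_hash(config)}")
    if seed is not None:
        lines.append(f"# seed={seed}")
    return lines


def read_proteome(path: str | Path, genome_id: str | None = None) -> Proteome:
    """Read one amino-acid FASTA file; the filename stem is the genome ID."""
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    proteins: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in proteins:
            raise ValueError(f"duplicate protein ID {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {rec.id!r} in {path}")
        proteins[rec.id] = seq
    return Proteome(genome_id=gid, proteins=proteins)


def read_proteome_dir(directory: str | Path) -> list[Proteome]:
    """Read every ``*.faa`` / ``*.fasta`` / ``*.fa`` file in a directory."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix in {".faa", ".fasta", ".fa"}
    )
    if not paths:
        raise FileNotFoundError(f"no FASTA files found in {directory}")
    proteomes = [read_proteome(p) for p in paths]
    ids = [p.genome_id for p in proteomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome IDs in proteome directory")
    return proteomes


def write_proteome(proteome: Proteome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in proteome.proteins.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(records)


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
    index: bool = False,
) -> None:
    """Write a DataFrame as TSV with provenance comment lines on top."""
    with open(path, "w") as fh:
        for line in provenance_lines(config, seed):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_json(obj, path: str | Path, config: Mapping | None = None, seed: int | None = None) -> None:
    """Pretty-printed JSON with stable key order and an embedded provenance block."""
    payload = dict(obj)
    prov: dict = {"tool": f"scfatlas v{__version__}"}
    if config is not None:
        prov["config_hash"] = config_hash(config)
    if seed is not None:
        prov["seed"] = seed
    payload["_provenance"] = prov
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_matrix_tsv(
    matrix: pd.DataFrame, path: str | Path, config: Mapping | None = None
) -> None:
    """Square symmetric matrix (genomes x genomes) as TSV with an index column."""
    write_tsv(matrix, path, config=config, index=True)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
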