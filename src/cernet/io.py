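"""Plain-text readers and writers shared across the pipeline.

All tables are UTF-8, tab-separated, LF-terminated, with mandatory headers,
so that repeated runs with the same seed produce byte-identical files.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    """Write a DataFrame as a headered, tab-separated, LF-terminated file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format, lineterminator="\n")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w", newline="\n") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 6-column BED file (0-based half-open intervals)."""
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS,
                     dtype={"chrom": str, "start": int, "end": int,
                            "name": str, "score": int, "strand": str})
    bad = df[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"BED intervals with start >= end: {bad['name'].tolist()}")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df[BED_COLUMNS].to_csv(path, sep="\t", index=False, header=False, lineterminator="\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT file: term id -> (description, member gene ids)."""
    terms: dict[str, tuple[str, list[str]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
            if term in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            terms[term] = (desc, members)
    return terms


def write_gmt(terms: Mapping[str, tuple[str, list[str]]], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as handle:
        for term, (desc, members) in terms.items():
            handle.write("\t".join([term, desc, *members]) + "\n")


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_json(path: str | Path):
    with open(path) as handle:
        return json.load(handle)
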