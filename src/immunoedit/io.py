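"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything is tab-delimited UTF-8 with a header row (TSV), FASTA for
protein sequences (via Biopython) and GMT for gene sets. Floats written
by :func:`write_tsv` are rounded to 6 significant digits so outputs are
diff-stable across platforms.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(proteome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in proteome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def round_sig(x: float, digits: int = 6) -> float:
    """Round to ``digits`` significant digits (0, NaN and inf pass through)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: round_sig(v) if pd.notna(v) else v)
    out.to_csv(path, sep="\t", index=index)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: ``term <tab> description <tab> gene...``."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, genes in sets.items():
            fh.write("\t".join([term, "na", *genes]) + "\n")
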