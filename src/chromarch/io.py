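"""Readers and writers for the plain-text genomic formats used by the pipeline.

Coordinates are 0-based half-open everywhere in memory and in BED/bedGraph
output. The GRO table is a five-column TSV with one row per
(gene, strain, replicate) measurement::

    gene_id  strain  replicate  signal  gdna_signal

``signal`` is the background-subtracted hybridization intensity and
``gdna_signal`` the genomic-DNA normalization intensity for that replicate
(a per-filter scalar repeated on every row, or a per-gene value).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GRO_COLUMNS = ["gene_id", "strain", "replicate", "signal", "gdna_signal"]
BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
MARK_COLUMNS = ["gene_id", "mark", "promoter_score", "orf_score"]


def write_fasta(genome: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    if not Path(path).exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(df: pd.DataFrame, path: str | os.PathLike, columns: list[str] | None = None) -> None:
    """Write a BED-like frame (no header). Empty frames yield a valid empty file."""
    if columns is None:
        columns = [c for c in BED6_COLUMNS if c in df.columns]
    try:
        df.to_csv(path, sep="\t", header=False, index=False, columns=columns)
    except OSError as exc:
        raise OSError(f"could not write BED file {path}: {exc}") from exc


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read BED3/4/6 into a frame with as many canonical columns as present."""
    if not Path(path).exists():
        raise FileNotFoundError(f"BED file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED6_COLUMNS[:4]).astype({"start": int, "end": int})
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def write_bedgraph(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"])


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(f"bedGraph file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    df.columns = ["chrom", "start", "end", "value"]
    return df


def track_to_arrays(df: pd.DataFrame, chrom_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Expand a bedGraph frame to per-base arrays; uncovered positions are NaN."""
    arrays = {c: np.full(n, np.nan) for c, n in chrom_lengths.items()}
    for chrom, start, end, value in df[["chrom", "start", "end", "value"]].itertuples(index=False):
        arr = arrays[chrom]
        arr[max(0, int(start)): min(len(arr), int(end))] = value
    return arrays


def arrays_to_bedgraph(arrays: Mapping[str, np.ndarray], decimals: int = 6) -> pd.DataFrame:
    """Run-length encode per-base arrays into a bedGraph frame (NaN runs skipped)."""
    rows = []
    for chrom in arrays:
        vals = np.round(np.asarray(arrays[chrom], dtype=float), decimals)
        n = len(vals)
        if n == 0:
            continue
        change = np.flatnonzero(~np.isclose(vals[1:], vals[:-1], equal_nan=True)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [n]))
        for s, e in zip(starts, ends):
            v = vals[s]
            if not np.isnan(v):
                rows.append((chrom, int(s), int(e), float(v)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_gene_list(ids: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gid in sorted(ids):
            fh.write(f"{gid}\n")


def read_gene_list(path: str | os.PathLike) -> set[str]:
    if not Path(path).exists():
        raise FileNotFoundError(f"gene list not found: {path}")
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gro_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=GRO_COLUMNS)


def read_gro_table(path: str | os.PathLike) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(f"GRO table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = set(GRO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"GRO table {path} lacks columns: {sorted(missing)}")
    return df


def write_marks_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=MARK_COLUMNS)


def read_marks_table(path: str | os.PathLike) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(f"mark score table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = set(MARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mark table {path} lacks columns: {sorted(missing)}")
    return df
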