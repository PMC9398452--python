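"""Thin readers/writers for the plain-text formats the pipeline exchanges.

All genomic coordinates are 0-based, half-open. bedGraph files are 4-column
(chrom, start, end, value); BED6 carries TE/gene intervals with the feature
name in column 4 and strand in column 6; GFF3 is written for genes only.
"""

from __future__ import annotations

import csv
from typing import Iterable

import numpy as np
import pandas as pd

BEDGRAPH_COLS = ["chrom", "start", "end", "value"]
BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BEDGRAPH_COLS, comment="#")
    return df.astype({"start": int, "end": int, "value": float})


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BEDGRAPH_COLS)


def bedgraph_to_bins(df: pd.DataFrame, chrom: str, chrom_length: int, bin_size: int) -> np.ndarray:
    """Expand a bedGraph (possibly run-length compressed) to a per-bin array."""
    n_bins = chrom_length // bin_size
    out = np.zeros(n_bins, dtype=float)
    sub = df[df["chrom"] == chrom]
    for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
        b0, b1 = start // bin_size, min(end // bin_size, n_bins)
        out[b0:b1] = value
    return out


def bins_to_bedgraph(values: np.ndarray, chrom: str, bin_size: int) -> pd.DataFrame:
    """Per-bin array to bedGraph rows, run-length merging equal neighbours."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        return pd.DataFrame(columns=BEDGRAPH_COLS)
    change = np.flatnonzero(np.diff(values) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts * bin_size,
            "end": ends * bin_size,
            "value": values[starts],
        }
    )


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :6]
    df.columns = BED6_COLS
    return df.astype({"start": int, "end": int})


def write_bed6(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in out:
            out[col] = default
    out.to_csv(path, sep="\t", header=False, index=False, columns=BED6_COLS)


def write_gff3_genes(genes: Iterable, path) -> None:
    """Write GeneRecord-like objects (chrom/start/end/strand/gene_id) as GFF3."""
    with open(path, "w", newline="") as fh:
        fh.write("##gff-version 3\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for g in genes:
            writer.writerow(
                [g.chrom, "tespread", "gene", g.start + 1, g.end, ".",
                 g.strand, ".", f"ID={g.gene_id}"]
            )


def read_gff3_genes(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append(
                {
                    "gene_id": attrs.get("ID", "."),
                    "chrom": f[0],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6],
                }
            )
    return pd.DataFrame(rows)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
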