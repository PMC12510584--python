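"""Plain-text readers and writers for the pipeline's file formats.

All tabular data travels as TSV; gene sets as GMT (set name, description,
members); junctions as 6-column BED-like TSV per sample (contig, start,
end, name, count, strand; 0-based half-open, stated in the header).
"""

from __future__ import annotations

import os

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "read_gmt",
    "write_gmt",
    "write_junctions",
]

JUNCTION_HEADER = "# coordinates: 0-based half-open; columns: contig start end name count strand"


def read_matrix(path) -> pd.DataFrame:
    """Feature x sample TSV with feature ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_junctions(tables: dict[str, pd.DataFrame], directory) -> dict[str, str]:
    """One BED-like TSV per sample; returns sample -> path."""
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for sample, table in tables.items():
        path = os.path.join(directory, f"{sample}.junc.tsv")
        with open(path, "w") as fh:
            fh.write(JUNCTION_HEADER + "\n")
            table.to_csv(fh, sep="\t", header=False, index=False)
        paths[sample] = path
    return paths
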