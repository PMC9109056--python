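"""Tab-separated on-disk formats.

Everything is plain TSV with a header row and the literal ``NA`` for
missing values: genotypes (strains x markers, 0/1), marker maps, trait
matrices (samples-or-strains x traits), sample designs, collapse
mappings, truth tables and QTL tables.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .genotype import UniqueMarkerSet
from .simulate import GenotypeData, MarkerMap

NA = "NA"

__all__ = [
    "read_matrix", "write_matrix",
    "read_marker_map", "write_marker_map",
    "read_genotypes", "write_genotypes",
    "read_design", "write_design",
    "write_unique_markers", "write_collapse_mapping",
]


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", na_rep=NA, index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])


def write_marker_map(markers: MarkerMap, path: str | Path) -> None:
    markers.table.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_marker_map(path: str | Path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t", na_values=[NA]))


def write_genotypes(geno: GenotypeData, calls_path: str | Path,
                    map_path: str | Path | None = None) -> None:
    write_matrix(geno.calls, calls_path, index_label="strain")
    if map_path is not None:
        write_marker_map(geno.markers, map_path)


def read_genotypes(calls_path: str | Path, map_path: str | Path) -> GenotypeData:
    calls = read_matrix(calls_path)
    return GenotypeData(calls, read_marker_map(map_path))


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA])


def write_unique_markers(uset: UniqueMarkerSet, calls_path: str | Path,
                         table_path: str | Path) -> None:
    write_matrix(uset.calls, calls_path, index_label="strain")
    uset.table.to_csv(table_path, sep="\t", index=False)


def write_collapse_mapping(uset: UniqueMarkerSet, path: str | Path) -> None:
    """Two-column member marker -> unique marker mapping."""
    uset.member_of.rename_axis("member_marker").to_frame().to_csv(path, sep="\t")


def read_unique_markers(calls_path: str | Path, table_path: str | Path) -> UniqueMarkerSet:
    calls = read_matrix(calls_path)
    table = pd.read_csv(table_path, sep="\t")
    member_rows = {}
    for _, row in table.iterrows():
        for m in str(row["members"]).split(","):
            member_rows[m] = row["unique_marker"]
    return UniqueMarkerSet(calls, table, pd.Series(member_rows, name="unique_marker"))
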