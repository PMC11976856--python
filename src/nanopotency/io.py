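"""Readers and writers for the pipeline's delimited-text interfaces.

Plate measurements and physicochemical tables travel as comma-separated
UTF-8 text with a header row; derived tables (potency, ranks, ANOVA,
correlations, enrichment) as tab-separated text; gene sets as GMT
(tab-separated: name, description, members...).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from nanopotency.enrichment import ClusteredMatrix, GeneSetCollection
from nanopotency.errors import GMTParseError
from nanopotency.potency import PLATE_COLUMNS


def read_plate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: plate table missing columns {missing}")
    df["cell_free"] = df["cell_free"].astype(bool)
    return df


def write_plate_csv(plate: pd.DataFrame, path) -> None:
    plate.to_csv(path, index=False)


def read_physchem_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "particle" not in df.columns:
        raise ValueError(f"{path}: physchem table needs a 'particle' column")
    return df


def read_protein_matrix(path) -> pd.DataFrame:
    """Protein x sample table; first column holds protein ids."""
    df = pd.read_csv(path, sep=None, engine="python")
    return df.set_index(df.columns[0])


def write_protein_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file; malformed lines raise with their line number."""
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"expected >= 3 tab-separated fields, got {len(fields)}", lineno
                )
            name, desc, *members = fields
            members = [m for m in members if m.strip()]
            if not members:
                raise GMTParseError(f"set {name!r} has no members", lineno)
            if name in sets:
                raise GMTParseError(f"duplicate set name {name!r}", lineno)
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(sets):
            desc = sets.descriptions.get(name, "")
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_ranked_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: ranked list needs (id, score) columns")
    return df.iloc[:, :2].set_axis(["protein", "score"], axis=1)


def write_ranked_list(ranked: pd.DataFrame, path) -> None:
    ranked.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a derived table as TSV (UTF-8, header, no index)."""
    df.to_csv(path, sep="\t", index=False)


def write_clustered_matrix(result: ClusteredMatrix, prefix) -> list[Path]:
    """Export a clustered NES grid: reordered matrix, leaf orders, trees."""
    prefix = Path(prefix)
    written = []
    mat_path = prefix.with_suffix(".matrix.tsv")
    result.matrix.to_csv(mat_path, sep="\t")
    written.append(mat_path)
    for label, tree in (("rows", result.row_tree), ("columns", result.col_tree)):
        if tree is None:
            continue
        tree_path = prefix.with_suffix(f".{label}.tree.txt")
        with open(tree_path, "w", encoding="utf-8") as fh:
            fh.write("leaf_order\t" + "\t".join(tree.leaf_order) + "\n")
            fh.write("newick\t" + tree.newick + "\n")
            for a, b, h in tree.merges:
                fh.write(f"merge\t{a}\t{b}\t{h:.10g}\n")
        written.append(tree_path)
    return written


def write_marker_panel(markers: pd.DataFrame, path) -> None:
    markers.to_csv(path, index=False)


def read_marker_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "particle" not in df.columns:
        raise ValueError(f"{path}: marker panel needs a 'particle' column")
    return df
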