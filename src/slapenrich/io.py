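"""Readers and writers for the plain-text interchange formats.

Supported formats:

* mutation pairs — TSV with header ``sample_id<TAB>gene_symbol``, one row per
  observed variant (repeated pairs mean multiple variants in one gene);
* binary matrix — CSV, genes on rows, samples on columns, cells in {0, 1};
* GMT — one gene set per line: ``id<TAB>description<TAB>gene<TAB>gene...``;
* gene lengths — TSV with header ``gene_symbol<TAB>exonic_bp``;
* symbol map — TSV ``old_symbol<TAB>new_symbol`` for nomenclature updating.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import GeneLengthTable, GeneSet, MutationDataset, PathwayCollection

__all__ = [
    "read_mutation_pairs",
    "read_binary_matrix",
    "write_binary_matrix",
    "read_gmt",
    "write_gmt",
    "read_gene_lengths",
    "write_gene_lengths",
    "read_symbol_map",
    "update_gene_symbols",
]


def read_mutation_pairs(
    path: str | Path,
    background: Sequence[str] | None = None,
) -> tuple[MutationDataset, dict]:
    """Read a (sample, gene) pair table into a binary mutation dataset.

    Repeated pairs are collapsed into a single indicator entry but retained
    as per-pair multiplicities, so per-sample variant counts ``n'_j`` reflect
    the raw number of listed variants.

    When ``background`` is given, genes outside it are dropped; the returned
    report counts the dropped pairs rather than failing silently.  By
    default the background is the observed gene universe.

    Returns the dataset and a report dict with keys ``n_pairs``,
    ``n_dropped_pairs`` and ``dropped_genes``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "gene_symbol"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise ValueError(f"{path}: no samples (empty pair table)")
    bad = df.index[df["sample_id"].isna() | df["gene_symbol"].isna()]
    if len(bad):
        # +2: one for the header line, one for 0- vs 1-based numbering
        raise ValueError(f"{path}: malformed row at line {bad[0] + 2}")

    if background is not None:
        bg = list(dict.fromkeys(background))
        if len(bg) != len(background):
            raise ValueError("background gene list contains duplicates")
        in_bg = df["gene_symbol"].isin(set(bg))
        dropped = df.loc[~in_bg, "gene_symbol"]
        report = {
            "n_pairs": int(len(df)),
            "n_dropped_pairs": int((~in_bg).sum()),
            "dropped_genes": sorted(dropped.unique()),
        }
        df = df[in_bg]
        genes = bg
    else:
        report = {"n_pairs": int(len(df)), "n_dropped_pairs": 0, "dropped_genes": []}
        genes = list(dict.fromkeys(df["gene_symbol"]))

    samples = list(dict.fromkeys(df["sample_id"]))
    if not samples:
        raise ValueError(f"{path}: no samples left after background restriction")
    gi = {g: i for i, g in enumerate(genes)}
    sj = {s: j for j, s in enumerate(samples)}
    mult = np.zeros((len(genes), len(samples)), dtype=np.int64)
    for s, g in zip(df["sample_id"], df["gene_symbol"]):
        mult[gi[g], sj[s]] += 1
    dataset = MutationDataset(genes, samples, (mult > 0).astype(np.int8), mult)
    return dataset, report


def read_binary_matrix(path: str | Path) -> MutationDataset:
    """Read a genes x samples CSV of 0/1 cells.

    One variant per mutated gene is assumed (``n'_j = n_j``)."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if df.empty and df.shape[1] == 0:
        raise ValueError(f"{path}: empty matrix")
    values = df.to_numpy()
    mask = ~np.isin(values, (0, 1))
    if mask.any():
        i, j = np.argwhere(mask)[0]
        raise ValueError(
            f"{path}: non-binary cell at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}: {values[i, j]!r}"
        )
    return MutationDataset(
        [str(g) for g in df.index], [str(s) for s in df.columns], values
    )


def write_binary_matrix(dataset: MutationDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path)


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT gene-set collection (id, description, then member genes)."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            set_id, name, *genes = fields
            genes = [g for g in genes if g]
            if len(set(genes)) != len(genes):
                warnings.warn(
                    f"{path}: line {lineno}: duplicate genes in set {set_id!r} "
                    "were deduplicated"
                )
            sets.append(GeneSet(id=set_id, name=name, genes=frozenset(genes)))
    return PathwayCollection(sets)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.id, s.name, *s.sorted_genes()]) + "\n")


def read_gene_lengths(path: str | Path) -> GeneLengthTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_symbol": str})
    for col in ("gene_symbol", "exonic_bp"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["gene_symbol"].duplicated().any():
        dup = df.loc[df["gene_symbol"].duplicated(), "gene_symbol"].iloc[0]
        raise ValueError(f"{path}: duplicated gene {dup!r}")
    return GeneLengthTable(dict(zip(df["gene_symbol"], df["exonic_bp"])))


def write_gene_lengths(table: GeneLengthTable, path: str | Path) -> None:
    table.to_series().rename_axis("gene_symbol").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_symbol_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("old_symbol", "new_symbol"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return dict(zip(df["old_symbol"], df["new_symbol"]))


def update_gene_symbols(obj, mapping: Mapping[str, str]):
    """Rewrite gene symbols via a static old -> new mapping.

    Unmapped symbols pass through unchanged.  When two old symbols map to the
    same new symbol, dataset rows are merged with logical OR (multiplicities
    summed) and gene-set members are deduplicated by the set union.

    Returns ``(rewritten_object, report)`` where the report counts renamed,
    merged and unchanged symbols.
    """
    if isinstance(obj, MutationDataset):
        return _update_dataset_symbols(obj, mapping)
    if isinstance(obj, PathwayCollection):
        return _update_collection_symbols(obj, mapping)
    if isinstance(obj, GeneSet):
        new_genes = {mapping.get(g, g) for g in obj.genes}
        renamed = sum(1 for g in obj.genes if mapping.get(g, g) != g)
        report = {
            "renamed": renamed,
            "merged": obj.size - len(new_genes),
            "unchanged": obj.size - renamed,
        }
        return GeneSet(obj.id, obj.name, frozenset(new_genes), obj.source), report
    raise TypeError(f"cannot update symbols on {type(obj).__name__}")


def _update_dataset_symbols(dataset: MutationDataset, mapping: Mapping[str, str]):
    new_names = [mapping.get(g, g) for g in dataset.gene_ids]
    order = list(dict.fromkeys(new_names))
    pos = {g: i for i, g in enumerate(order)}
    ind = np.zeros((len(order), dataset.n_samples), dtype=np.int8)
    mult = (
        np.zeros((len(order), dataset.n_samples), dtype=np.int64)
        if dataset.multiplicity is not None
        else None
    )
    for old_row, new_name in enumerate(new_names):
        i = pos[new_name]
        ind[i] |= dataset.indicator[old_row]
        if mult is not None:
            mult[i] += dataset.multiplicity[old_row]
    renamed = sum(1 for g, n in zip(dataset.gene_ids, new_names) if g != n)
    report = {
        "renamed": renamed,
        "merged": dataset.n_genes - len(order),
        "unchanged": dataset.n_genes - renamed,
    }
    return MutationDataset(order, dataset.sample_ids, ind, mult), report


def _update_collection_symbols(collection: PathwayCollection, mapping: Mapping[str, str]):
    out: list[GeneSet] = []
    totals = {"renamed": 0, "merged": 0, "unchanged": 0}
    for s in collection:
        new_set, rep = update_gene_symbols(s, mapping)
        out.append(new_set)
        for key in totals:
            totals[key] += rep[key]
    return PathwayCollection(out), totals
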