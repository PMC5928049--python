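"""Core data containers for cohort-level somatic mutation analysis.

The central object is a binary genes x samples alteration matrix
(:class:`MutationDataset`): entry ``(i, j)`` is 1 when gene ``g_i`` carries at
least one somatic point mutation in sample ``s_j``.  Gene exonic lengths live
in a :class:`GeneLengthTable`; pathway gene sets in a
:class:`PathwayCollection` of :class:`GeneSet` objects.

Gene and sample identifiers are treated case-sensitively and kept in
first-appearance order throughout; all public outputs refer to identifiers,
never to positional indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MutationDataset",
    "GeneLengthTable",
    "GeneSet",
    "PathwayCollection",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for x in ids:
            if x in seen:
                raise ValueError(f"duplicate {what} identifier: {x!r}")
            seen.add(x)


class MutationDataset:
    """Binary alteration matrix over a gene background and a sample cohort.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene symbols (the background population ``G``).
    sample_ids
        Ordered, unique sample identifiers (the cohort ``S``).
    indicator
        Array of shape ``(len(gene_ids), len(sample_ids))`` with entries in
        ``{0, 1}``.
    multiplicity
        Optional integer array of the same shape giving the number of
        distinct point mutations per (gene, sample) pair.  When present it
        must be positive exactly where ``indicator`` is 1; per-sample variant
        counts are its column sums.  When absent, one variant per mutated
        gene is assumed.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        indicator: np.ndarray,
        multiplicity: np.ndarray | None = None,
    ) -> None:
        gene_ids = list(gene_ids)
        sample_ids = list(sample_ids)
        _check_unique(gene_ids, "gene")
        _check_unique(sample_ids, "sample")
        indicator = np.asarray(indicator)
        if indicator.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError(
                f"indicator shape {indicator.shape} does not match "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples"
            )
        if indicator.size and not np.isin(indicator, (0, 1)).all():
            bad = np.argwhere(~np.isin(indicator, (0, 1)))[0]
            raise ValueError(
                f"non-binary entry at gene {gene_ids[bad[0]]!r}, "
                f"sample {sample_ids[bad[1]]!r}"
            )
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids
        self.indicator = indicator.astype(np.int8)
        if multiplicity is not None:
            multiplicity = np.asarray(multiplicity, dtype=np.int64)
            if multiplicity.shape != self.indicator.shape:
                raise ValueError("multiplicity shape mismatch")
            if ((multiplicity > 0) != (self.indicator > 0)).any():
                raise ValueError(
                    "multiplicity must be positive exactly where the "
                    "indicator is 1"
                )
        self.multiplicity = multiplicity
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def per_sample_mutation_count(self) -> np.ndarray:
        """``n_j``: number of distinct mutated genes per sample."""
        return self.indicator.sum(axis=0).astype(np.int64)

    @property
    def per_sample_variant_count(self) -> np.ndarray:
        """``n'_j``: total point mutations per sample (>= ``n_j``)."""
        if self.multiplicity is not None:
            return self.multiplicity.sum(axis=0)
        return self.per_sample_mutation_count

    # -- lookups ---------------------------------------------------------
    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices of the given genes, silently dropping unknowns."""
        return np.array(
            [self._gene_index[g] for g in genes if g in self._gene_index],
            dtype=np.int64,
        )

    def genes_present(self, genes: Iterable[str]) -> list[str]:
        return [g for g in genes if g in self._gene_index]

    # -- derived datasets ------------------------------------------------
    def subset_samples(self, sample_ids: Sequence[str]) -> "MutationDataset":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [pos[s] for s in sample_ids]
        mult = self.multiplicity[:, cols] if self.multiplicity is not None else None
        return MutationDataset(
            self.gene_ids, list(sample_ids), self.indicator[:, cols], mult
        )

    def zero_genes(self, genes: Iterable[str]) -> "MutationDataset":
        """Return a copy with all alterations of the given genes removed.

        Variant multiplicities of the zeroed rows are subtracted as well, so
        per-sample variant counts shrink accordingly.
        """
        idx = self.gene_index(genes)
        ind = self.indicator.copy()
        ind[idx, :] = 0
        mult = None
        if self.multiplicity is not None:
            mult = self.multiplicity.copy()
            mult[idx, :] = 0
        return MutationDataset(self.gene_ids, self.sample_ids, ind, mult)

    def copy(self) -> "MutationDataset":
        mult = None if self.multiplicity is None else self.multiplicity.copy()
        return MutationDataset(
            list(self.gene_ids), list(self.sample_ids), self.indicator.copy(), mult
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.indicator, index=self.gene_ids, columns=self.sample_ids
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MutationDataset({self.n_genes} genes x {self.n_samples} samples, "
            f"{int(self.indicator.sum())} alterations)"
        )


class GeneLengthTable:
    """Per-gene total non-overlapping exonic block length, in base pairs."""

    def __init__(self, lengths: Mapping[str, int]) -> None:
        clean: dict[str, int] = {}
        for gene, lam in lengths.items():
            lam = int(lam)
            if lam < 1:
                raise ValueError(f"non-positive exonic length for {gene!r}: {lam}")
            clean[str(gene)] = lam
        self._lengths = clean

    def __contains__(self, gene: str) -> bool:
        return gene in self._lengths

    def __len__(self) -> int:
        return len(self._lengths)

    def __getitem__(self, gene: str) -> int:
        return self._lengths[gene]

    def get(self, gene: str, default: int | None = None) -> int | None:
        return self._lengths.get(gene, default)

    @property
    def genes(self) -> list[str]:
        return list(self._lengths)

    def total(self, genes: Iterable[str] | None = None) -> int:
        """Summed length over a gene subset (``N'`` for a background,
        ``k'`` for a pathway).  Genes absent from the table are skipped."""
        if genes is None:
            return sum(self._lengths.values())
        return sum(self._lengths[g] for g in genes if g in self._lengths)

    def median_length(self) -> int:
        if not self._lengths:
            raise ValueError("empty length table")
        return int(np.median(list(self._lengths.values())))

    def with_imputed(self, genes: Iterable[str]) -> tuple["GeneLengthTable", list[str]]:
        """Return a table covering all requested genes, imputing the median
        length for the missing ones; also returns the imputed gene list."""
        missing = [g for g in genes if g not in self._lengths]
        if not missing:
            return self, []
        med = self.median_length()
        merged = dict(self._lengths)
        for g in missing:
            merged[g] = med
        return GeneLengthTable(merged), missing

    def to_series(self) -> pd.Series:
        return pd.Series(self._lengths, name="exonic_bp")


@dataclass(frozen=True)
class GeneSet:
    """A named pathway gene set ``P`` (size ``k = |P|``)."""

    id: str
    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.id!r} is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    @property
    def size(self) -> int:
        return len(self.genes)

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)


@dataclass
class PathwayCollection:
    """An ordered collection of uniquely identified gene sets."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([s.id for s in self.sets], "gene set")
        self._by_id = {s.id: s for s in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._by_id

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._by_id[set_id]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sets]

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.genes
        return out

    def subset(self, ids: Iterable[str]) -> "PathwayCollection":
        keep = set(ids)
        return PathwayCollection([s for s in self.sets if s.id in keep])
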