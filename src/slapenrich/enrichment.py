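"""The population-level pathway enrichment test.

For each pathway ``P`` the cohort-level statistic is the number of samples
``O(P)`` with at least one mutated pathway gene.  Under the null that each
sample is altered independently with its chance probability ``p_j``, ``O(P)``
follows a Poisson-binomial distribution with parameters ``pi = {p_j}`` and
expectation ``E(P) = sum_j p_j``.  The pathway alteration score is
``Delta(P) = log10(O / E)`` and the p-value is the exact upper tail
``Pr(O(P) >= z)`` at the observed ``z``.

Pathways are pre-filtered (mutated in >= 5% of samples, and >= 2 distinct
mutated genes, by default), p-values are adjusted across the tested pathways
(Bonferroni / Benjamini-Hochberg / Storey), and enrichments are finally
flagged by an exclusive-coverage criterion: ``C(P) = 100 * O'(P) / O(P)``
with ``O'(P)`` the samples carrying exactly one mutated pathway gene.  High
exclusive coverage indicates mutually exclusive mutations across samples,
read as additional evidence of positive selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datamodel import GeneLengthTable, GeneSet, MutationDataset, PathwayCollection
from .poisson_binomial import pb_tail
from .prob_models import ModelSpec, compute_trial_probs

__all__ = [
    "AnalysisConfig",
    "RESULT_COLUMNS",
    "filter_pathways",
    "observed_count",
    "expected_count",
    "alteration_score",
    "pathway_pvalue",
    "adjust_pvalues",
    "exclusive_coverage",
    "slapenrich",
    "mutex_sort",
    "core_components",
    "differential_enrichment",
]

RESULT_COLUMNS = [
    "pathway_id",
    "pathway_name",
    "k",
    "kprime",
    "E",
    "O",
    "Oprime",
    "delta",
    "pvalue",
    "fdr",
    "EC",
    "is_enriched",
    "mutated_genes",
]

FDR_METHODS = ("bonferroni", "bh", "storey")


@dataclass
class AnalysisConfig:
    """Parameters of one enrichment analysis.

    Defaults mirror common practice for somatic-mutation cohorts: Bernoulli
    length model, pathways pre-filtered to those mutated in at least 5% of
    samples with at least two distinct mutated genes, Benjamini-Hochberg
    FDR at 5%, and an exclusive-coverage flag threshold of 50%.
    """

    model: ModelSpec = field(default_factory=ModelSpec)
    min_mutated_sample_fraction: float = 0.05
    min_distinct_mutated_genes: int = 2
    fdr_method: str = "bh"
    fdr_threshold: float = 0.05
    ec_threshold: float = 50.0
    storey_lambda: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_mutated_sample_fraction <= 1.0:
            raise ValueError("min_mutated_sample_fraction must be in [0, 1]")
        if self.min_distinct_mutated_genes < 0:
            raise ValueError("min_distinct_mutated_genes must be >= 0")
        if self.fdr_method not in FDR_METHODS:
            raise ValueError(f"fdr_method must be one of {FDR_METHODS}")
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ValueError("fdr_threshold must be in (0, 1]")
        if not 0.0 <= self.ec_threshold <= 100.0:
            raise ValueError("ec_threshold must be in [0, 100]")
        if not 0.0 < self.storey_lambda < 1.0:
            raise ValueError("storey_lambda must be in (0, 1)")


def filter_pathways(
    dataset: MutationDataset,
    collection: PathwayCollection,
    config: AnalysisConfig | None = None,
) -> tuple[PathwayCollection, list[dict]]:
    """Pre-test pathway selection.

    Retains gene sets with (a) at least ``ceil(frac * M)`` samples carrying a
    mutation in >= 1 pathway gene, and (b) at least the configured number of
    distinct pathway genes mutated anywhere in the cohort.  Returns the
    retained collection and a per-exclusion report.
    """
    config = config or AnalysisConfig()
    min_samples = math.ceil(config.min_mutated_sample_fraction * dataset.n_samples)
    kept: list[GeneSet] = []
    excluded: list[dict] = []
    for gene_set in collection:
        rows = dataset.gene_index(gene_set.genes)
        if rows.size:
            sub = dataset.indicator[rows, :]
            altered_samples = int((sub.sum(axis=0) > 0).sum())
            distinct_genes = int((sub.sum(axis=1) > 0).sum())
        else:
            altered_samples = distinct_genes = 0
        reasons = []
        if altered_samples < min_samples:
            reasons.append(
                f"altered in {altered_samples} samples < required {min_samples}"
            )
        if distinct_genes < config.min_distinct_mutated_genes:
            reasons.append(
                f"{distinct_genes} distinct mutated genes < required "
                f"{config.min_distinct_mutated_genes}"
            )
        if reasons:
            excluded.append({"pathway_id": gene_set.id, "reason": "; ".join(reasons)})
        else:
            kept.append(gene_set)
    return PathwayCollection(kept), excluded


def observed_count(
    dataset: MutationDataset, gene_set: GeneSet
) -> tuple[int, int, np.ndarray]:
    """``O(P)``, ``O'(P)`` and the per-sample mutated-gene counts ``X_j``."""
    rows = dataset.gene_index(gene_set.genes)
    if rows.size == 0:
        return 0, 0, np.zeros(dataset.n_samples, dtype=np.int64)
    x = dataset.indicator[rows, :].sum(axis=0).astype(np.int64)
    return int((x >= 1).sum()), int((x == 1).sum()), x


def expected_count(pi) -> float:
    """``E(P) = sum_j p_j``, the Poisson-binomial mean."""
    return float(np.sum(pi))


def alteration_score(observed: float, expected: float) -> float:
    """``Delta(P) = log10(O / E)``; NaN when ``O = 0`` (reported as NA)."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if observed == 0:
        return float("nan")
    return math.log10(observed / expected)


def pathway_pvalue(pi, observed: int) -> float:
    """Exact Poisson-binomial upper tail Pr(O >= observed)."""
    return pb_tail(pi, observed)


def adjust_pvalues(
    pvalues,
    method: str = "bh",
    storey_lambda: float = 0.5,
    pi0: float | None = None,
) -> np.ndarray:
    """Multiple-testing adjustment across tested pathways.

    ``bonferroni`` and ``bh`` delegate to statsmodels.  ``storey`` computes
    q-values with the fixed-lambda null-proportion estimate
    ``pi0 = #{p > lambda} / ((1 - lambda) m)`` clamped to (0, 1] (a forced
    ``pi0 = 1`` reduces to Benjamini-Hochberg); ``pi0`` may be overridden.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values outside [0, 1]")
    if method == "bonferroni":
        return multipletests(p, method="bonferroni")[1]
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        if pi0 is None:
            pi0 = (p > storey_lambda).sum() / ((1.0 - storey_lambda) * p.size)
            pi0 = min(max(pi0, 1.0 / p.size), 1.0)
        if not 0.0 < pi0 <= 1.0:
            raise ValueError("pi0 must be in (0, 1]")
        return np.minimum(pi0 * multipletests(p, method="fdr_bh")[1], 1.0)
    raise ValueError(f"unknown adjustment method {method!r}")


def exclusive_coverage(observed: int, observed_single: int) -> float:
    """``C(P) = 100 * O'(P) / O(P)``; NaN when ``O = 0``."""
    if observed < 0 or observed_single < 0 or observed_single > observed:
        raise ValueError("need 0 <= O' <= O")
    if observed == 0:
        return float("nan")
    return 100.0 * observed_single / observed


def _mutated_genes_field(dataset: MutationDataset, gene_set: GeneSet) -> str:
    counts = []
    for g in sorted(gene_set.genes):
        i = dataset.gene_index([g])
        if i.size:
            c = int(dataset.indicator[i[0]].sum())
            if c:
                counts.append((g, c))
    counts.sort(key=lambda t: (-t[1], t[0]))
    return ",".join(f"{g}:{c}" for g, c in counts)


def slapenrich(
    dataset: MutationDataset,
    collection: PathwayCollection,
    lengths: GeneLengthTable | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Run the full population-level enrichment analysis.

    Pipeline: pathway pre-filter -> per-sample trial probabilities under the
    configured model -> E, O, Delta, exact Poisson-binomial p-value -> FDR
    across the tested pathways -> exclusive-coverage flag.  Rows are sorted
    by p-value ascending, then Delta descending, then pathway id.

    ``lengths``, when given, overrides the length table referenced by the
    model spec.  The FDR is computed across tested (post-filter) pathways
    only; rows failing the exclusive-coverage threshold are retained with
    ``is_enriched = False`` rather than removed.

    Returns a DataFrame with the stable columns in :data:`RESULT_COLUMNS`;
    the pre-filter exclusion report is attached as ``df.attrs['excluded']``.
    """
    config = config or AnalysisConfig()
    model = config.model
    if lengths is not None:
        model = replace(model, lengths=lengths)

    tested, excluded = filter_pathways(dataset, collection, config)
    if len(tested) == 0:
        warnings.warn("no pathways survive the pre-test filters")
        df = pd.DataFrame(columns=RESULT_COLUMNS)
        df.attrs["excluded"] = excluded
        return df

    trial_probs = compute_trial_probs(dataset, tested, model)
    length_table = model.resolve_lengths(dataset) if model.needs_lengths() else model.lengths

    records = []
    for tp in trial_probs:
        gene_set = tested[tp.pathway_id]
        usable = gene_set.genes.intersection(dataset.gene_ids)
        obs, obs_single, _ = observed_count(dataset, gene_set)
        expected = expected_count(tp.pi)
        records.append(
            {
                "pathway_id": gene_set.id,
                "pathway_name": gene_set.name,
                "k": len(usable),
                "kprime": length_table.total(usable) if length_table else np.nan,
                "E": expected,
                "O": obs,
                "Oprime": obs_single,
                "delta": alteration_score(obs, expected),
                "pvalue": pathway_pvalue(tp.pi, obs),
                "EC": exclusive_coverage(obs, obs_single),
                "mutated_genes": _mutated_genes_field(dataset, gene_set),
            }
        )
    df = pd.DataFrame.from_records(records)
    df["fdr"] = adjust_pvalues(
        df["pvalue"].to_numpy(), config.fdr_method, config.storey_lambda
    )
    df["is_enriched"] = (
        (df["fdr"] < config.fdr_threshold)
        & df["EC"].notna()
        & (df["EC"] > config.ec_threshold)
    )
    df = df.sort_values(
        by=["pvalue", "delta", "pathway_id"],
        ascending=[True, False, True],
        kind="mergesort",
        na_position="last",
    ).reset_index(drop=True)
    df = df[RESULT_COLUMNS]
    df.attrs["excluded"] = excluded
    return df


def mutex_sort(
    dataset: MutationDataset, gene_set: GeneSet
) -> tuple[list[str], list[str]]:
    """Waterfall (oncoprint-style) orderings exposing mutual exclusivity.

    Genes (restricted to the pathway members present in the background) are
    sorted by cohort mutation count descending, ties alphabetically; samples
    are sorted by their binary mutation vector read as a number in that gene
    order, descending.  Both outputs are pure permutations: applying them
    reorders, never alters, the matrix.
    """
    genes = dataset.genes_present(sorted(gene_set.genes))
    counts = {
        g: int(dataset.indicator[dataset.gene_index([g])[0]].sum()) for g in genes
    }
    gene_order = sorted(genes, key=lambda g: (-counts[g], g))
    rows = dataset.gene_index(gene_order)
    sub = dataset.indicator[rows, :] if rows.size else np.zeros((0, dataset.n_samples))
    # sample key: bit vector in gene-sorted order, compared as a number
    keys = [tuple(int(v) for v in sub[:, j]) for j in range(dataset.n_samples)]
    order = sorted(range(dataset.n_samples), key=lambda j: keys[j], reverse=True)
    sample_order = [dataset.sample_ids[j] for j in order]
    return gene_order, sample_order


def core_components(
    enriched_ids: Iterable[str] | pd.DataFrame,
    collection: PathwayCollection,
    j_threshold: float = 0.3,
    core_fraction: float = 0.5,
) -> list[dict]:
    """Group related enriched pathways and extract their shared gene cores.

    Enriched gene sets are linked when their Jaccard similarity reaches
    ``j_threshold``; each connected component contributes one group whose
    core is the genes present in a strict majority (more than
    ``core_fraction``) of its member sets, so for a pair the core is the
    intersection and a singleton keeps all its genes.  Output is
    deterministic (components and members sorted by id).
    """
    if isinstance(enriched_ids, pd.DataFrame):
        enriched_ids = enriched_ids.loc[
            enriched_ids["is_enriched"], "pathway_id"
        ].tolist()
    ids = sorted(set(enriched_ids))
    sets = {i: collection[i].genes for i in ids if i in collection}
    graph = nx.Graph()
    graph.add_nodes_from(sets)
    id_list = sorted(sets)
    for a_pos, a in enumerate(id_list):
        for b in id_list[a_pos + 1 :]:
            inter = len(sets[a] & sets[b])
            union = len(sets[a] | sets[b])
            if union and inter / union >= j_threshold:
                graph.add_edge(a, b)
    groups = []
    for comp in sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]):
        members = sorted(comp)
        need = core_fraction * len(members)
        gene_counts: dict[str, int] = {}
        for m in members:
            for g in sets[m]:
                gene_counts[g] = gene_counts.get(g, 0) + 1
        core = sorted(g for g, c in gene_counts.items() if c > need)
        groups.append({"pathways": members, "core_genes": core})
    return groups


def differential_enrichment(
    dataset: MutationDataset,
    sample_partition: Mapping[str, Sequence[str]],
    collection: PathwayCollection,
    lengths: GeneLengthTable | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Compare enrichment between two labeled subpopulations.

    Runs the full analysis independently on each group and joins the
    per-pathway outcomes; a pathway is flagged differential when enriched in
    exactly one group.  ``Delta`` difference is group A minus group B in the
    partition's key order.
    """
    if len(sample_partition) != 2:
        raise ValueError("sample_partition must contain exactly two groups")
    (label_a, ids_a), (label_b, ids_b) = sample_partition.items()
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError("both groups must be non-empty")
    res_a = slapenrich(dataset.subset_samples(list(ids_a)), collection, lengths, config)
    res_b = slapenrich(dataset.subset_samples(list(ids_b)), collection, lengths, config)
    cols = ["pathway_id", "pathway_name", "delta", "fdr", "is_enriched"]
    merged = res_a[cols].merge(
        res_b[cols],
        on=["pathway_id", "pathway_name"],
        how="outer",
        suffixes=(f"_{label_a}", f"_{label_b}"),
    )
    ea = merged[f"is_enriched_{label_a}"].astype("boolean").fillna(False).astype(bool)
    eb = merged[f"is_enriched_{label_b}"].astype("boolean").fillna(False).astype(bool)
    merged["delta_difference"] = (
        merged[f"delta_{label_a}"] - merged[f"delta_{label_b}"]
    )
    merged["is_differential"] = ea ^ eb
    return merged.sort_values("pathway_id", kind="mergesort").reset_index(drop=True)
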