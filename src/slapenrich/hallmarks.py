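"""Cancer-hallmark layer: keyword mapping, heterogeneity scores, and
driver-excluded re-analysis.

Pathways are routed onto the ten canonical cancer hallmarks by a keyword
engine: hallmark-specific keywords are matched case-insensitively against
pathway names, and key-node keywords as prefixes of member gene symbols.
For a cohort analysis, the cumulative heterogeneity score (CHS) of a
hallmark is the proportion of its mapped (and tested) pathways that are
enriched; the 10-component CHS vector is the cohort's hallmark
heterogeneity signature.

The high-confidence cancer gene (HCG) utilities quantify how much an
enrichment is driven by established drivers (HCG-dominance) and re-run the
analysis with all HCG alterations removed (the *filtered* analysis), to
expose signal carried by the long tail of infrequently mutated genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import GeneLengthTable, GeneSet, MutationDataset, PathwayCollection
from .enrichment import AnalysisConfig, observed_count, slapenrich

__all__ = [
    "HALLMARKS",
    "HallmarkMap",
    "load_keyword_config",
    "default_keyword_config",
    "map_pathways_to_hallmarks",
    "chs",
    "hallmark_signature",
    "hcg_dominance",
    "read_gene_list",
    "filtered_analysis",
    "FilteredComparison",
]

#: The ten canonical cancer hallmarks.
HALLMARKS = (
    "Sustaining proliferative signaling",
    "Evading growth suppressors",
    "Resisting cell death",
    "Enabling replicative immortality",
    "Inducing angiogenesis",
    "Activating invasion and metastasis",
    "Genome instability and mutation",
    "Tumour-promoting inflammation",
    "Deregulating cellular energetics",
    "Avoiding immune destruction",
)


def default_keyword_config() -> dict:
    """The small demonstration keyword map shipped with the package."""
    text = resources.files("slapenrich").joinpath("data/hallmark_keywords.yaml").read_text()
    return yaml.safe_load(text)


def load_keyword_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _validate_keyword_config(config: Mapping) -> dict:
    if not config:
        raise ValueError("keyword config is empty")
    out = {}
    for hallmark, spec in config.items():
        if hallmark not in HALLMARKS:
            raise ValueError(f"unknown hallmark name {hallmark!r}")
        spec = spec or {}
        out[hallmark] = {
            "name_keywords": [str(k) for k in spec.get("name_keywords", []) or []],
            "gene_keywords": [str(k) for k in spec.get("gene_keywords", []) or []],
        }
    return out


@dataclass
class HallmarkMap:
    """Pathway -> hallmark assignment, reproducible from keywords alone."""

    keywords: dict
    assignment: dict[str, frozenset[str]] = field(default_factory=dict)

    def hallmarks_of(self, pathway_id: str) -> frozenset[str]:
        return self.assignment.get(pathway_id, frozenset())

    def pathways_of(self, hallmark: str) -> list[str]:
        return sorted(
            pid for pid, hs in self.assignment.items() if hallmark in hs
        )


def map_pathways_to_hallmarks(
    collection: PathwayCollection, keyword_config: Mapping | None = None
) -> HallmarkMap:
    """Assign each pathway the union of hallmarks triggered by its keywords.

    Name keywords match case-insensitively as substrings of the pathway
    name; gene keywords match as prefixes of member gene symbols.  A pathway
    may map to zero, one or several hallmarks.
    """
    config = _validate_keyword_config(keyword_config or default_keyword_config())
    assignment: dict[str, frozenset[str]] = {}
    for gene_set in collection:
        name_lc = gene_set.name.lower()
        hit: set[str] = set()
        for hallmark, spec in config.items():
            if any(kw.lower() in name_lc for kw in spec["name_keywords"]):
                hit.add(hallmark)
                continue
            if any(
                g.startswith(kw) for kw in spec["gene_keywords"] for g in gene_set.genes
            ):
                hit.add(hallmark)
        assignment[gene_set.id] = frozenset(hit)
    return HallmarkMap(keywords=config, assignment=assignment)


def chs(results: pd.DataFrame, hallmark_map: HallmarkMap, hallmark: str) -> float:
    """Cumulative heterogeneity score of one hallmark.

    The fraction of tested pathways mapped to the hallmark that are flagged
    enriched; 0 (with a warning) when no tested pathway maps to it.
    """
    if hallmark not in HALLMARKS:
        raise ValueError(f"unknown hallmark name {hallmark!r}")
    tested = results["pathway_id"].tolist()
    mapped = [pid for pid in tested if hallmark in hallmark_map.hallmarks_of(pid)]
    if not mapped:
        warnings.warn(f"no tested pathway maps to hallmark {hallmark!r}; CHS = 0")
        return 0.0
    enriched = set(results.loc[results["is_enriched"], "pathway_id"])
    return sum(1 for pid in mapped if pid in enriched) / len(mapped)


def hallmark_signature(
    results: pd.DataFrame, hallmark_map: HallmarkMap
) -> pd.Series:
    """The 10-component CHS vector (hallmark heterogeneity signature)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        values = {h: chs(results, hallmark_map, h) for h in HALLMARKS}
    return pd.Series(values, name="CHS")


def read_gene_list(path: str | Path) -> list[str]:
    """Plain text gene list, one symbol per line; blank lines skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def hcg_dominance(
    dataset: MutationDataset, gene_set: GeneSet, hcg_list: Iterable[str]
) -> float:
    """Fraction of a pathway's altered samples whose alteration involves a
    high-confidence cancer gene: ``|{j: >=1 mutated gene in P & HCG}| / O(P)``."""
    obs, _, _ = observed_count(dataset, gene_set)
    if obs == 0:
        raise ValueError("HCG-dominance undefined for a pathway with O(P) = 0")
    driver_genes = gene_set.genes.intersection(hcg_list)
    if not driver_genes:
        return 0.0
    rows = dataset.gene_index(driver_genes)
    hcg_hit = (dataset.indicator[rows, :].sum(axis=0) > 0).sum()
    return float(hcg_hit) / obs


@dataclass
class FilteredComparison:
    """Driver-excluded re-analysis paired with the unfiltered one."""

    unfiltered: pd.DataFrame
    filtered: pd.DataFrame
    retained: list[str]
    lost: list[str]
    gained: list[str]
    tpr: float
    ppv: float
    signature_unfiltered: pd.Series | None = None
    signature_filtered: pd.Series | None = None
    signature_correlation: float | None = None


def _signature_correlation(a: pd.Series, b: pd.Series) -> float:
    # identical signatures correlate perfectly even when degenerate
    if np.allclose(a.to_numpy(), b.to_numpy()):
        return 1.0
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a.to_numpy(), b.to_numpy())[0, 1])


def filtered_analysis(
    dataset: MutationDataset,
    hcg_list: Sequence[str],
    collection: PathwayCollection,
    lengths: GeneLengthTable | None = None,
    config: AnalysisConfig | None = None,
    hallmark_map: HallmarkMap | None = None,
) -> FilteredComparison:
    """Re-run the enrichment analysis with all HCG alterations removed.

    HCG rows of the alteration matrix are zeroed (with their variant
    multiplicities subtracted from the per-sample counts, when pair-level
    input carried them) and the analysis is repeated on the same background.
    The comparison reports the filtered enriched set against the unfiltered
    one as a retrieval problem — TPR (retained fraction of the unfiltered
    enrichments) and PPV (fraction of filtered enrichments already present
    unfiltered) — plus, when a hallmark map is given, the Pearson
    correlation between the two hallmark signatures.
    """
    hcg_present = set(hcg_list) & set(dataset.gene_ids)
    if hcg_list and not hcg_present:
        warnings.warn("HCG list is disjoint from the dataset; filtered == unfiltered")
    if len(hcg_present) == dataset.n_genes:
        raise ValueError("HCG list covers every background gene; nothing to analyse")

    unfiltered = slapenrich(dataset, collection, lengths, config)
    filtered_ds = dataset.zero_genes(hcg_present) if hcg_present else dataset
    filtered = slapenrich(filtered_ds, collection, lengths, config)

    enr_u = set(unfiltered.loc[unfiltered["is_enriched"], "pathway_id"])
    enr_f = set(filtered.loc[filtered["is_enriched"], "pathway_id"])
    retained = sorted(enr_u & enr_f)
    lost = sorted(enr_u - enr_f)
    gained = sorted(enr_f - enr_u)
    tpr = len(retained) / len(enr_u) if enr_u else 1.0
    ppv = len(retained) / len(enr_f) if enr_f else 1.0

    sig_u = sig_f = corr = None
    if hallmark_map is not None:
        sig_u = hallmark_signature(unfiltered, hallmark_map)
        sig_f = hallmark_signature(filtered, hallmark_map)
        corr = _signature_correlation(sig_u, sig_f)
    return FilteredComparison(
        unfiltered=unfiltered,
        filtered=filtered,
        retained=retained,
        lost=lost,
        gained=gained,
        tpr=tpr,
        ppv=ppv,
        signature_unfiltered=sig_u,
        signature_filtered=sig_f,
        signature_correlation=corr,
    )
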