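"""Per-sample pathway alteration probabilities.

For a pathway ``P`` and a sample ``s_j``, these models give ``p_j``: the
probability that ``s_j`` carries at least one somatic mutation in ``P`` by
chance, given the sample's mutation burden.  Each sample is a Bernoulli
trial with success probability ``p_j``; the trial probabilities feed the
Poisson-binomial test in :mod:`slapenrich.enrichment`.

Three built-in models:

``hypergeom_genes``
    Hypergeometric over genes: draw the sample's ``n_j`` mutated genes
    without replacement from the ``N``-gene background and ask for >= 1 hit
    among the ``k`` pathway genes.

``hypergeom_length``
    Hypergeometric over nucleotides: draw the sample's ``n'_j`` point
    mutations from the total background exonic length ``N'`` and ask for
    >= 1 hit within the pathway's summed exonic length ``k'``.

``bernoulli_length``
    Poisson nucleotide model: ``p_j = 1 - exp(-rho_j * k')`` with ``rho_j``
    the per-nucleotide background mutation rate, either estimated per sample
    as ``n'_j / N'`` or fixed (e.g. 1e-6/nt).  Upon expansion this sums
    per-gene mutation probabilities ``lambda(g) * rho_j``, so gene lengths
    enter gene by gene.

A fourth kind, ``user``, accepts any callable mapping
``(sample_index, gene_set, dataset, lengths) -> probability`` so that
covariate-aware models can be plugged in; the engine only validates range.

Hypergeometric zero-overlap terms are evaluated in log space via the
log-gamma function, and ``Pr(X >= 1)`` is formed as ``-expm1(log H(0))``,
so large backgrounds never overflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammaln

from .datamodel import GeneLengthTable, GeneSet, MutationDataset, PathwayCollection

__all__ = [
    "ModelSpec",
    "PathwayTrialProbs",
    "pj_hypergeom_genes",
    "pj_hypergeom_length",
    "pj_bernoulli",
    "estimate_rho",
    "compute_trial_probs",
    "MODEL_KINDS",
]

MODEL_KINDS = ("hypergeom_genes", "hypergeom_length", "bernoulli_length", "user")

# one near-certain sample must not force a degenerate Poisson-binomial
P_CLAMP_HI = 1.0 - 1e-12


def _log_binom(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def _p_at_least_one(ntotal, nspecial, ndraws):
    """1 - H(0; ntotal, nspecial, ndraws), vectorised, via log-gamma.

    H(0) = C(ntotal - nspecial, ndraws) / C(ntotal, ndraws); when the draws
    exceed the non-special pool the zero-overlap term vanishes and the
    probability is exactly 1.
    """
    ntotal = np.asarray(ntotal, dtype=np.float64)
    nspecial = np.asarray(nspecial, dtype=np.float64)
    ndraws = np.asarray(ndraws, dtype=np.float64)
    rest = ntotal - nspecial
    with np.errstate(invalid="ignore"):
        log_h0 = _log_binom(rest, ndraws) - _log_binom(ntotal, ndraws)
    out = -np.expm1(log_h0)
    out = np.where(ndraws > rest, 1.0, out)
    out = np.where(ndraws == 0, 0.0, out)
    return np.clip(out, 0.0, 1.0)


def pj_hypergeom_genes(k: int, n_background: int, n_j) -> np.ndarray | float:
    """Gene-count hypergeometric model: Pr(>=1 of k pathway genes among the
    n_j mutated genes drawn from an N-gene background)."""
    if k < 0 or k > n_background:
        raise ValueError(f"pathway size k={k} outside [0, N={n_background}]")
    n_arr = np.asarray(n_j)
    if (n_arr < 0).any() or (n_arr > n_background).any():
        raise ValueError("mutated-gene count outside [0, N]")
    out = _p_at_least_one(n_background, k, n_arr)
    return float(out) if np.isscalar(n_j) else out


def pj_hypergeom_length(kprime: int, nprime_total: int, nprime_j) -> np.ndarray | float:
    """Nucleotide hypergeometric model over exonic lengths."""
    if kprime <= 0 or kprime > nprime_total:
        raise ValueError(f"pathway length k'={kprime} outside (0, N'={nprime_total}]")
    n_arr = np.asarray(nprime_j)
    if (n_arr < 0).any() or (n_arr > nprime_total).any():
        raise ValueError("variant count outside [0, N']")
    out = _p_at_least_one(nprime_total, kprime, n_arr)
    return float(out) if np.isscalar(nprime_j) else out


def pj_bernoulli(rho, kprime: float) -> np.ndarray | float:
    """Poisson nucleotide model: p_j = 1 - exp(-rho_j * k')."""
    rho_arr = np.asarray(rho, dtype=np.float64)
    if (rho_arr < 0).any():
        raise ValueError("background mutation rate must be non-negative")
    if kprime <= 0:
        raise ValueError("pathway exonic length must be positive")
    out = -np.expm1(-rho_arr * float(kprime))
    return float(out) if np.isscalar(rho) else out


def estimate_rho(dataset: MutationDataset, lengths: GeneLengthTable) -> np.ndarray:
    """Per-sample background mutation rate rho_j = n'_j / N'.

    ``n'_j`` is the sample's total point-mutation count (falling back to the
    mutated-gene count when multiplicities are unavailable) and ``N'`` the
    summed exonic length of the dataset's gene background.
    """
    nprime_total = lengths.total(dataset.gene_ids)
    if nprime_total == 0:
        raise ValueError("total background exonic length is zero")
    return dataset.per_sample_variant_count / float(nprime_total)


@dataclass
class ModelSpec:
    """Configuration of the per-sample probability model.

    ``rho="auto"`` estimates rho per sample from the data; a float fixes it
    for every sample.  Length-aware kinds require a :class:`GeneLengthTable`.
    """

    kind: str = "bernoulli_length"
    rho: float | str = "auto"
    lengths: GeneLengthTable | None = None
    user_fn: Callable[[int, GeneSet, MutationDataset, GeneLengthTable | None], float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")
        if isinstance(self.rho, str):
            if self.rho != "auto":
                raise ValueError("rho must be 'auto' or a non-negative float")
        elif self.rho < 0:
            raise ValueError("fixed rho must be non-negative")
        if self.kind == "user" and self.user_fn is None:
            raise ValueError("kind='user' requires user_fn")

    def needs_lengths(self) -> bool:
        return self.kind in ("hypergeom_length", "bernoulli_length")

    def resolve_lengths(self, dataset: MutationDataset) -> GeneLengthTable | None:
        """Length table covering the full background, median-imputed where
        genes are missing (a shrunken N' would bias every rate)."""
        if not self.needs_lengths():
            return self.lengths
        if self.lengths is None:
            raise ValueError(f"model {self.kind!r} requires a gene length table")
        table, imputed = self.lengths.with_imputed(dataset.gene_ids)
        if imputed:
            warnings.warn(
                f"{len(imputed)} background genes missing from the length "
                "table; median exonic length imputed"
            )
        return table


@dataclass
class PathwayTrialProbs:
    """Per-sample Bernoulli success probabilities for one pathway."""

    pathway_id: str
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=np.float64)
        if self.pi.size and (self.pi.min() < 0 or self.pi.max() > 1):
            raise ValueError("probabilities outside [0, 1]")


def compute_trial_probs(
    dataset: MutationDataset,
    collection: PathwayCollection | Sequence[GeneSet],
    model: ModelSpec,
) -> list[PathwayTrialProbs]:
    """Trial-probability vectors ``pi`` for every pathway in the collection.

    Pathway genes absent from the dataset background are ignored for ``k``
    and ``k'`` (the background defines the universe); pathways with no
    usable gene are excluded with a warning.  Probabilities are clamped to
    ``[0, 1 - 1e-12]`` before the Poisson-binomial stage.
    """
    lengths = model.resolve_lengths(dataset)
    n_background = dataset.n_genes
    n_j = dataset.per_sample_mutation_count
    nprime_j = dataset.per_sample_variant_count

    if model.kind == "bernoulli_length":
        if model.rho == "auto":
            rho_j = estimate_rho(dataset, lengths)
        else:
            rho_j = np.full(dataset.n_samples, float(model.rho))
    if model.kind == "hypergeom_length":
        nprime_total = lengths.total(dataset.gene_ids)
        capped_nprime_j = np.minimum(nprime_j, nprime_total)

    out: list[PathwayTrialProbs] = []
    for gene_set in collection:
        usable = gene_set.genes.intersection(dataset.gene_ids)
        if not usable:
            warnings.warn(f"pathway {gene_set.id!r} has no genes in the background; excluded")
            continue
        if model.kind == "hypergeom_genes":
            pi = pj_hypergeom_genes(len(usable), n_background, n_j)
        elif model.kind == "hypergeom_length":
            kprime = lengths.total(usable)
            pi = pj_hypergeom_length(kprime, nprime_total, capped_nprime_j)
        elif model.kind == "bernoulli_length":
            kprime = lengths.total(usable)
            pi = pj_bernoulli(rho_j, kprime)
        else:  # user
            pi = np.array(
                [
                    float(model.user_fn(j, gene_set, dataset, lengths))
                    for j in range(dataset.n_samples)
                ]
            )
            if pi.size and (pi.min() < 0 or pi.max() > 1):
                raise ValueError(
                    f"user model returned probability outside [0, 1] for "
                    f"pathway {gene_set.id!r}"
                )
        pi = np.clip(np.asarray(pi, dtype=np.float64), 0.0, P_CLAMP_HI)
        out.append(PathwayTrialProbs(gene_set.id, pi))
    return out
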