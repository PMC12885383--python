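"""Summary statistics of assembled ensembles.

The abundance fluctuation distribution (AFD) is the distribution of a
focal species' final abundance across replicate communities; it is
summarized by Sarle's bimodality coefficient and by its mean.  Alpha
diversity is species richness at completion, beta diversity the pairwise
Jaccard distance on presence/absence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import CommunityState, EnsembleResult

__all__ = [
    "BimodalityUndefinedError",
    "bimodality_coefficient",
    "AFDSummary",
    "afd_summary",
    "richness",
    "mean_pairwise_jaccard",
    "DiversitySummary",
    "diversity_summary",
]

#: number of equal-width histogram bins on [0, 1] (display only)
HIST_BINS = 51

#: BC values above this threshold indicate a bimodal distribution
BC_BIMODAL_THRESHOLD = 5.0 / 9.0


class BimodalityUndefinedError(ValueError):
    """BC is undefined: fewer than 4 values or zero variance."""


def bimodality_coefficient(values: np.ndarray) -> float:
    """Sarle's sample bimodality coefficient.

    ``BC = (g^2 + 1) / (kappa + 3 (M-1)^2 / ((M-2)(M-3)))`` with ``g`` the
    bias-corrected sample skewness and ``kappa`` the bias-corrected sample
    excess kurtosis.  BC lies in (0, 1]; a uniform distribution gives 5/9,
    which serves as the bimodality threshold, and a symmetric two-point
    distribution gives 1.
    """
    values = np.asarray(values, dtype=float)
    M = values.size
    if M < 4:
        raise BimodalityUndefinedError(f"BC undefined: needs at least 4 values, got {M}")
    if np.var(values) == 0.0:
        raise BimodalityUndefinedError("BC undefined: zero variance")
    g = stats.skew(values, bias=False)
    kappa = stats.kurtosis(values, fisher=True, bias=False)
    correction = 3.0 * (M - 1) ** 2 / ((M - 2) * (M - 3))
    return float((g * g + 1.0) / (kappa + correction))


@dataclass
class AFDSummary:
    """Abundance-fluctuation-distribution summary for one focal species."""

    focal_species: int
    abundances: np.ndarray  # M relative abundances in [0, 1]
    bc: float | None  # None when undefined (flagged, not raised)
    bc_defined: bool
    mean_rel_abundance: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray

    @property
    def bimodal(self) -> bool | None:
        if not self.bc_defined:
            return None
        return self.bc > BC_BIMODAL_THRESHOLD


def afd_summary(ensemble: EnsembleResult, focal: int = 0) -> AFDSummary:
    """Summarize the AFD of species ``focal`` over an ensemble.

    Relative abundances are final counts divided by ``K`` (every state
    ends at ``N = K`` exactly).  BC is computed on the raw values; the
    histogram is a fixed 51-bin display binning.  An undefined BC (zero
    variance) is flagged in the summary rather than raised.
    """
    K = ensemble.params.K
    x = ensemble.counts_matrix()[:, focal] / K
    try:
        bc = bimodality_coefficient(x)
        defined = True
    except BimodalityUndefinedError:
        bc, defined = None, False
    counts, edges = np.histogram(x, bins=HIST_BINS, range=(0.0, 1.0))
    return AFDSummary(
        focal_species=focal,
        abundances=x,
        bc=bc,
        bc_defined=defined,
        mean_rel_abundance=float(x.mean()),
        hist_edges=edges,
        hist_counts=counts,
    )


def richness(state: CommunityState) -> int:
    """Number of species present (strictly positive counts, no threshold)."""
    return state.richness


def _presence_matrix(ensemble: EnsembleResult) -> np.ndarray:
    return ensemble.counts_matrix() > 0


def mean_pairwise_jaccard(ensemble: EnsembleResult) -> float:
    """Mean Jaccard distance over all M(M-1)/2 unordered community pairs.

    Per pair, ``beta_J = 1 - |X ∩ Y| / |X ∪ Y|`` on presence/absence at
    completion.  Invariant under relabeling of communities and species.
    """
    if ensemble.M < 2:
        raise ValueError("mean pairwise Jaccard needs at least 2 communities")
    P = _presence_matrix(ensemble).astype(np.float64)
    inter = P @ P.T
    rich = P.sum(axis=1)
    union = rich[:, None] + rich[None, :] - inter
    with np.errstate(invalid="ignore"):
        dist = 1.0 - inter / union
    iu = np.triu_indices(ensemble.M, k=1)
    return float(np.mean(dist[iu]))


@dataclass
class DiversitySummary:
    """Alpha (richness) and beta (Jaccard) diversity of an ensemble."""

    richness_values: np.ndarray
    mean_richness: float
    mean_jaccard: float
    n_pairs: int


def diversity_summary(ensemble: EnsembleResult) -> DiversitySummary:
    rich = np.array([s.richness for s in ensemble.final_states], dtype=np.int64)
    return DiversitySummary(
        richness_values=rich,
        mean_richness=float(rich.mean()),
        mean_jaccard=mean_pairwise_jaccard(ensemble),
        n_pairs=ensemble.M * (ensemble.M - 1) // 2,
    )
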