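"""Pairwise IBD (pi_hat) estimation and unrelated-subset selection.

pi_hat = P(IBD=2) + 0.5 P(IBD=1) is estimated by the method of moments:
observed identity-by-state counts per pair are compared with their
allele-frequency-conditional expectations under IBD = 0, 1, 2 to solve
for the IBD state probabilities, which are then clipped to [0, 1] and
renormalised.  This is the per-site-expectation core of the classical
PLINK estimator, without its genome-wide small-sample bin corrections;
it is validated against pedigree simulations (self ~ 1, parent-offspring
~ 0.5, unrelated ~ 0).

The unrelated subset is a maximum independent set in the relatedness
graph, solved exactly per connected component up to 25 related samples
and by a minimum-degree greedy heuristic above that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import CohortGenotypes, MISSING


@dataclass
class PairwiseIBD:
    """Symmetric pi_hat matrix over the cohort's samples."""

    sample_ids: list[str]
    p_ibd0: np.ndarray
    p_ibd1: np.ndarray
    p_ibd2: np.ndarray
    pi_hat: np.ndarray

    def pair(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.pi_hat[i, j])


def estimate_pihat(cohort: CohortGenotypes, maf_floor: float = 0.02) -> PairwiseIBD:
    """Method-of-moments pi_hat over biallelic SNPs with MAF >= ``maf_floor``.

    Per marker with alt frequency p (q = 1 - p), the IBS-state
    probabilities conditional on IBD state are::

        P(IBS0 | IBD0) = 2 p^2 q^2
        P(IBS1 | IBD0) = 4 p^3 q + 4 p q^3
        P(IBS1 | IBD1) = 2 p^2 q + 2 p q^2
        P(IBS2 | IBDk) = 1 - P(IBS0|k) - P(IBS1|k),  P(IBS2|IBD2) = 1

    Summing expectations over markers and equating to observed counts
    gives P(IBD=0), then P(IBD=1), then P(IBD=2) by subtraction.
    """
    snp = cohort.is_snp_mask()
    af = cohort.cohort_af
    with np.errstate(invalid="ignore"):
        maf = np.minimum(af, 1.0 - af)
    usable = snp & np.isfinite(af) & (maf >= maf_floor)
    m = int(usable.sum())
    if m == 0:
        raise ValueError("no usable markers for relatedness estimation")
    if m < 100:
        warnings.warn(f"only {m} usable markers; pi_hat will be noisy", stacklevel=2)

    gt = cohort.gt[:, usable].astype(np.int16)
    p = af[usable]
    q = 1.0 - p
    valid = (gt != MISSING).astype(np.float64)

    # indicator matrices for genotype codes (missing rows zeroed)
    i0 = (gt == 0) * valid
    i1 = (gt == 1) * valid
    i2 = (gt == 2) * valid

    n_ibs2 = i0 @ i0.T + i1 @ i1.T + i2 @ i2.T
    n_ibs0 = i0 @ i2.T + i2 @ i0.T
    pairs_valid = valid @ valid.T
    n_ibs1 = pairs_valid - n_ibs2 - n_ibs0

    # per-pair expectation sums restricted to markers valid in both samples
    e0_ibd0_site = 2 * p**2 * q**2
    e1_ibd0_site = 4 * p**3 * q + 4 * p * q**3
    e1_ibd1_site = 2 * p**2 * q + 2 * p * q**2
    e0 = valid @ (e0_ibd0_site[:, None] * valid.T)
    e1_0 = valid @ (e1_ibd0_site[:, None] * valid.T)
    e1_1 = valid @ (e1_ibd1_site[:, None] * valid.T)
    e2_0 = pairs_valid - e0 - e1_0
    e2_1 = pairs_valid - e1_1

    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = n_ibs0 / e0
        p1 = (n_ibs1 - p0 * e1_0) / e1_1
        p2 = (n_ibs2 - p0 * e2_0 - p1 * e2_1) / pairs_valid
    probs = np.stack([p0, p1, p2])
    np.nan_to_num(probs, copy=False)
    np.clip(probs, 0.0, 1.0, out=probs)
    total = probs.sum(axis=0)
    total[total == 0] = 1.0
    probs /= total
    pi_hat = probs[2] + 0.5 * probs[1]
    np.fill_diagonal(pi_hat, 1.0)
    np.fill_diagonal(probs[2], 1.0)
    np.fill_diagonal(probs[0], 0.0)
    np.fill_diagonal(probs[1], 0.0)
    return PairwiseIBD(
        sample_ids=list(cohort.sample_ids),
        p_ibd0=probs[0], p_ibd1=probs[1], p_ibd2=probs[2], pi_hat=pi_hat,
    )


EXACT_COMPONENT_LIMIT = 25


def select_unrelated(ibd: PairwiseIBD, threshold: float = 0.0625) -> list[str]:
    """Largest sample set with no internal pair at pi_hat >= ``threshold``.

    Exact (maximum independent set via complement-graph clique) for
    connected components of at most 25 related samples, minimum-degree
    greedy above that.  Ties break deterministically by sample id.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ids = ibd.sample_ids
    n = len(ids)
    adj = (ibd.pi_hat >= threshold)
    np.fill_diagonal(adj, False)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    graph.add_edges_from(zip(*np.nonzero(np.triu(adj))))

    keep: list[int] = []
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        if len(comp) == 1:
            keep.extend(comp)
        elif len(comp) <= EXACT_COMPONENT_LIMIT:
            complement = nx.complement(graph.subgraph(comp))
            clique, _ = nx.max_weight_clique(complement, weight=None)
            keep.extend(sorted(clique))
        else:
            keep.extend(_greedy_independent_set(graph.subgraph(comp)))
    return sorted((ids[i] for i in keep), key=lambda s: ids.index(s))


def _greedy_independent_set(graph: nx.Graph) -> list[int]:
    """Best of a minimum-degree sweep and fixed-seed randomised restarts."""
    g = graph.copy()
    best: list[int] = []
    while g.number_of_nodes():
        node = min(g.nodes, key=lambda v: (g.degree(v), v))
        best.append(node)
        g.remove_nodes_from(list(g.neighbors(node)) + [node])
    for s in range(12):
        cand = nx.maximal_independent_set(graph, seed=s)
        if len(cand) > len(best) or (len(cand) == len(best)
                                     and sorted(cand) < sorted(best)):
            best = list(cand)
    return sorted(best)
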