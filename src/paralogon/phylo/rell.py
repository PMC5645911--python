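"""RELL branch support: bootstrap resampling of per-site log-likelihoods
(no re-optimization within replicates) comparing the ML tree against the two
NNI alternatives of each internal branch.
"""
from __future__ import annotations

import numpy as np

from .alignment import Alignment
from .likelihood import optimize_branch_lengths, site_log_likelihoods
from .models import SubstitutionModel
from .tree import PhyloTree, nni_neighbors


def rell_bootstrap_support(
    site_lnls: np.ndarray,
    n_replicates: int,
    rng: np.random.Generator,
    focal: int = 0,
) -> float:
    """Percent of bootstrap replicates in which the focal tree's resampled
    total log-likelihood is highest.

    ``site_lnls`` is (n_trees, n_sites). Resampling draws site counts from a
    multinomial (equivalent to resampling site indices with replacement).
    Exact ties for the maximum are broken uniformly at random, so trees with
    identical site-lnL vectors share support evenly.
    """
    n_trees, n_sites = site_lnls.shape
    weights = rng.multinomial(n_sites, np.full(n_sites, 1.0 / n_sites),
                              size=n_replicates)
    totals = weights @ site_lnls.T  # (n_replicates, n_trees)
    maxima = totals.max(axis=1, keepdims=True)
    is_max = totals >= maxima  # exact float comparison: ties only when equal
    n_ties = is_max.sum(axis=1)
    wins = 0
    for r in range(n_replicates):
        if not is_max[r, focal]:
            continue
        if n_ties[r] == 1:
            wins += 1
        else:
            tied = np.flatnonzero(is_max[r])
            if tied[rng.integers(n_ties[r])] == focal:
                wins += 1
    return 100.0 * wins / n_replicates


def rell_support(
    ml_tree: PhyloTree,
    aln: Alignment,
    model: SubstitutionModel,
    n_replicates: int = 1000,
    seed: int | None = None,
    ry_model: SubstitutionModel | None = None,
    opt_tol: float = 1e-4,
    max_sweeps: int = 10,
) -> PhyloTree:
    """Annotate each internal branch of the ML tree with RELL support.

    For every internal branch the ML tree is compared against its two NNI
    alternatives (branch lengths of the alternatives re-optimized once, then
    fixed); support is the percent of ``n_replicates`` site resamples in
    which the ML tree's total log-likelihood is highest. Stochastic but
    reproducible from ``seed``. Trees with fewer than four taxa have no
    internal branches and are returned unannotated.
    """
    rng = np.random.default_rng(seed)
    tree = ml_tree.copy()
    ml_sl = site_log_likelihoods(tree, aln, model, ry_model).per_site
    for edge_id in tree.internal_edges():
        vectors = [ml_sl]
        for neighbor in nni_neighbors(tree, edge_id):
            opt, _lnl = optimize_branch_lengths(neighbor, aln, model, ry_model,
                                                tol=opt_tol,
                                                max_sweeps=max_sweeps)
            vectors.append(site_log_likelihoods(opt, aln, model, ry_model).per_site)
        support = rell_bootstrap_support(np.vstack(vectors), n_replicates,
                                         rng, focal=0)
        tree.node(edge_id).support = support
    return tree


def clade_support(supported_tree: PhyloTree, taxon_set: set[str]):
    """Support of the branch subtending ``taxon_set`` if it forms a clade
    (bipartition present in the unrooted tree), else ``"not present"``.
    The full taxon set is trivially a clade with 100% support."""
    taxon_set = set(taxon_set)
    if taxon_set == set(supported_tree.tip_labels()):
        return 100.0
    node = supported_tree.clade_node(taxon_set)
    if node is None:
        return "not present"
    if node.is_leaf():
        return 100.0  # a single tip is trivially a clade
    return node.support
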