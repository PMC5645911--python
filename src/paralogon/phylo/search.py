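"""Maximum-likelihood topology search by repeated local rearrangements:
hill climbing over nearest-neighbor interchanges with branch-length
re-optimization, until no rearrangement improves the total log-likelihood.
"""
from __future__ import annotations

import numpy as np

from .alignment import Alignment
from .likelihood import optimize_branch_lengths
from .models import SubstitutionModel
from .tree import PhyloTree, nni_neighbors, resolve_polytomies


def ml_local_rearrangement_search(
    start_tree: PhyloTree,
    aln: Alignment,
    model: SubstitutionModel,
    ry_model: SubstitutionModel | None = None,
    seed: int | None = None,
    improve_tol: float = 1e-6,
    opt_tol: float = 1e-6,
    max_sweeps: int = 50,
) -> tuple[PhyloTree, float]:
    """Hill-climb over NNI rearrangements from ``start_tree``.

    Polytomies in the start tree are randomly resolved under ``seed``. Each
    candidate is scored after branch-length re-optimization; the best
    strictly improving neighbor is accepted and the search repeats until a
    local optimum. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    tree = resolve_polytomies(start_tree, rng)
    tree, lnl = optimize_branch_lengths(tree, aln, model, ry_model,
                                        tol=opt_tol, max_sweeps=max_sweeps)
    while True:
        best_tree, best_lnl = None, lnl
        for edge_id in tree.internal_edges():
            for neighbor in nni_neighbors(tree, edge_id):
                cand, cand_lnl = optimize_branch_lengths(
                    neighbor, aln, model, ry_model,
                    tol=opt_tol, max_sweeps=max_sweeps)
                if cand_lnl > best_lnl + improve_tol:
                    best_tree, best_lnl = cand, cand_lnl
        if best_tree is None:
            return tree, lnl
        tree, lnl = best_tree, best_lnl


def exhaustive_ml(
    labels_or_trees,
    aln: Alignment,
    model: SubstitutionModel,
    ry_model: SubstitutionModel | None = None,
    opt_tol: float = 1e-6,
    max_sweeps: int = 50,
) -> tuple[PhyloTree, float, list[tuple[PhyloTree, float]]]:
    """Score every unrooted topology (enumerated from tip labels, or as
    given) with optimized branch lengths; returns the best plus all scores.
    Practical only for small taxon sets (15 topologies at 5 taxa)."""
    from .tree import enumerate_topologies

    if isinstance(labels_or_trees[0], str):
        trees = enumerate_topologies(list(labels_or_trees))
    else:
        trees = list(labels_or_trees)
    scored = []
    for t in trees:
        opt, lnl = optimize_branch_lengths(t, aln, model, ry_model,
                                           tol=opt_tol, max_sweeps=max_sweeps)
        scored.append((opt, lnl))
    best = max(scored, key=lambda p: p[1])
    return best[0], best[1], scored
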