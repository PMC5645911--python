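"""Felsenstein pruning likelihood, with discrete-gamma rate mixtures and
per-branch length optimization.

Gap and ambiguity characters are treated as missing data (all-ones partial
likelihood). RY-recoded columns of a mixed alignment are scored under a
separate two-state model sharing the same branch lengths.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import Alignment
from .models import SubstitutionModel, binary_ry
from .tree import PhyloTree

# IUPAC nucleotide ambiguity -> compatible bases
_DNA_AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}
_MISSING = {"-", ".", "?", "N", "X", "*", "O", "J", "U"}


@dataclass
class SiteLikelihoods:
    """Per-site log-likelihoods of a (tree, model, alignment) triple."""

    per_site: np.ndarray

    @property
    def total(self) -> float:
        return float(self.per_site.sum())


class _EncodedPart:
    """Pattern-compressed tip partial likelihoods for one column class."""

    def __init__(self, aln: Alignment, cols: np.ndarray, model: SubstitutionModel):
        self.model = model
        self.cols = cols
        sub = aln.matrix[:, cols]
        if sub.shape[1] == 0:
            self.n_patterns = 0
            self.inverse = np.zeros(0, dtype=int)
            self.weights = np.zeros(0)
            self.tip_partials = {}
            return
        patterns, inverse, counts = np.unique(
            sub, axis=1, return_inverse=True, return_counts=True
        )
        self.n_patterns = patterns.shape[1]
        self.inverse = inverse.ravel()
        self.weights = counts.astype(float)
        states = model.states
        is_protein = len(states) == 20
        lut: dict[str, np.ndarray] = {}
        for ch in np.unique(patterns):
            vec = np.zeros(len(states))
            if ch in states:
                vec[states.index(ch)] = 1.0
            elif not is_protein and len(states) == 4 and ch in _DNA_AMBIG:
                for base in _DNA_AMBIG[ch]:
                    vec[states.index(base)] = 1.0
            elif ch in _MISSING or ch not in states:
                vec[:] = 1.0
            lut[ch] = vec
        self.tip_partials = {
            otu: np.stack([lut[ch] for ch in patterns[i]], axis=1)
            for i, otu in enumerate(aln.otus)
        }


def _encode(aln: Alignment, model: SubstitutionModel,
            ry_model: SubstitutionModel | None) -> list[_EncodedPart]:
    if aln.binary_cols is not None and aln.binary_cols.any():
        if ry_model is None:
            ry_model = binary_ry(gamma_shape=model.gamma_shape,
                                 k=model.n_rate_categories)
        main = np.where(~aln.binary_cols)[0]
        binary = np.where(aln.binary_cols)[0]
        return [_EncodedPart(aln, main, model), _EncodedPart(aln, binary, ry_model)]
    return [_EncodedPart(aln, np.arange(aln.n_cols), model)]


def _part_pattern_lnl(tree: PhyloTree, part: _EncodedPart) -> np.ndarray:
    """Log-likelihood per site pattern for one column class."""
    model = part.model
    rates = model.category_rates()
    post = tree.postorder()
    lik = np.zeros(part.n_patterns)
    for rate in rates:
        partials: dict[int, np.ndarray] = {}
        for node in post:
            if node.is_leaf():
                partials[node.id] = part.tip_partials[node.name]
                continue
            prod = None
            for child in node.children:
                P = model.transition_matrix(child.length, rate)
                contrib = P @ partials[child.id]
                prod = contrib if prod is None else prod * contrib
            partials[node.id] = prod
        lik += model.freqs @ partials[tree.root.id]
    lik /= len(rates)
    with np.errstate(divide="ignore"):
        return np.log(lik)


def _total_lnl(tree: PhyloTree, parts: list[_EncodedPart]) -> float:
    total = 0.0
    for part in parts:
        if part.n_patterns == 0:
            continue
        total += float(part.weights @ _part_pattern_lnl(tree, part))
    return total


def site_log_likelihoods(
    tree: PhyloTree,
    aln: Alignment,
    model: SubstitutionModel,
    ry_model: SubstitutionModel | None = None,
) -> SiteLikelihoods:
    """Per-site log-likelihoods by post-order pruning, averaged over the
    discrete-gamma rate mixture; deterministic given its inputs."""
    missing = set(aln.otus) ^ set(tree.tip_labels())
    if missing:
        raise ValueError(f"tree tips and alignment OTUs differ: {sorted(missing)}")
    parts = _encode(aln, model, ry_model)
    per_site = np.zeros(aln.n_cols)
    for part in parts:
        if part.n_patterns == 0:
            continue
        pattern_lnl = _part_pattern_lnl(tree, part)
        per_site[part.cols] = pattern_lnl[part.inverse]
    return SiteLikelihoods(per_site)


def optimize_branch_lengths(
    tree: PhyloTree,
    aln: Alignment,
    model: SubstitutionModel,
    ry_model: SubstitutionModel | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 50,
    max_length: float = 10.0,
) -> tuple[PhyloTree, float]:
    """Coordinate-wise (Brent) optimization of every branch length.

    Sweeps over branches until the total log-likelihood improves by less
    than ``tol`` in a sweep or ``max_sweeps`` is reached (then a warning is
    issued and the best tree so far returned). The total lnL is
    non-decreasing across sweeps.
    """
    t = tree.copy()
    parts = _encode(aln, model, ry_model)
    current = _total_lnl(t, parts)
    converged = False
    for _sweep in range(max_sweeps):
        before = current
        for node in t.branch_nodes():
            original = node.length

            def neg(x: float) -> float:
                node.length = x
                return -_total_lnl(t, parts)

            res = minimize_scalar(neg, bounds=(1e-9, max_length),
                                  method="bounded",
                                  options={"xatol": 1e-8})
            if -res.fun >= current:
                node.length = float(res.x)
                current = -res.fun
            else:
                node.length = original
        if current - before < tol:
            converged = True
            break
    if not converged:
        warnings.warn("branch-length optimization did not converge; "
                      "returning best tree so far", RuntimeWarning)
    return t, current


def total_log_likelihood(tree: PhyloTree, aln: Alignment,
                         model: SubstitutionModel,
                         ry_model: SubstitutionModel | None = None) -> float:
    parts = _encode(aln, model, ry_model)
    return _total_lnl(tree, parts)
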