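"""Synthetic genomes with the structure the analysis assumes: an ancestral
gene segment evolving on a species tree with one whole-genome duplication
(or independent segmental duplications), irreversible (Dollo) gene-copy
losses, occasional inversions and nucleotide sequence evolution — plus truth
labels for recovery testing.

Also houses the hard-coded 11-gene microsynteny worked example around the
eel rhodopsin paralogons (spotted gar reference order; eel and arowana
carrying synteny copies #1 and #2).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy.linalg import expm

from .model import GeneAnnotation, Region, SequenceStore, SpeciesTree
from .phylo.alignment import Alignment
from .phylo.models import SubstitutionModel, hky
from .phylo.tree import PhyloTree
from .synteny import ABSENT, PRESENT, UNKNOWN, MatrixRow, PresenceOrderMatrix

# branch lengths in neutral substitutions/site; with the default purifying
# selection (omega 0.2) outgroup-ingroup protein identities land in the
# ~75-90% range typical of this gene panel
DEFAULT_TREE = "((eel:0.15,arowana:0.15)teleost:0.08,gar:0.2)root;"

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
SENSE_CODONS = sorted(set(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
) - set(_CODON_TABLE.stop_codons))


@dataclass
class SimulationConfig:
    """Generating conditions for a synthetic paralogon dataset.

    Defaults encode the three-lineage study system: eel and arowana sister
    to each other with gar as outgroup, one whole-genome duplication on
    their stem ('teleost' branch), an 11-gene ancestral segment, and
    moderate per-branch copy-loss and inversion probabilities.
    """

    tree_newick: str = DEFAULT_TREE
    panel_size: int = 11
    wgd_branch: str | None = "teleost"
    independent_dup_branches: list[str] = field(default_factory=list)
    loss_prob: float = 0.2
    inversion_prob: float = 0.1
    kappa: float = 2.0
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    gene_rate_range: tuple = (0.5, 1.5)
    omega: float | None = 0.2  # codon-level dN/dS; None -> plain HKY
    gene_length_codons: int = 100
    intergenic_range: tuple = (500, 5000)
    seed: int = 0

    def __post_init__(self) -> None:
        has_wgd = self.wgd_branch is not None
        has_indep = bool(self.independent_dup_branches)
        if has_wgd == has_indep:
            raise ValueError(
                "exactly one of wgd_branch / independent_dup_branches must be set"
            )
        for p in (self.loss_prob, self.inversion_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.loss_prob == 1.0:
            warnings.warn("loss_prob = 1: every duplicated gene will be lost")

    @property
    def duplication_branches(self) -> list[str]:
        return ([self.wgd_branch] if self.wgd_branch
                else list(self.independent_dup_branches))

    @property
    def scenario_name(self) -> str:
        return "single_wgd" if self.wgd_branch else "independent_duplications"


@dataclass
class SimulationTruth:
    scenario_name: str
    duplication_branches: list[str]
    panel: list[str]
    losses: list[tuple]  # (gene, copy, branch)
    inversions: list[tuple]  # (branch, copy, (first_idx, last_idx))
    template: list[str]
    presence: dict  # (species, copy) -> set of genes
    gene_trees: dict  # gene -> newick (topology only)


@dataclass
class SimulatedDataset:
    regions: dict  # species -> list[Region]
    proteins: SequenceStore
    cds: SequenceStore
    truth: SimulationTruth
    config: SimulationConfig


def _evolve(seq_idx: np.ndarray, P: np.ndarray, rng: np.random.Generator
            ) -> np.ndarray:
    cum = P.cumsum(axis=1)
    u = rng.random(len(seq_idx))
    return (u[:, None] > cum[seq_idx]).sum(axis=1)


class _CodonProcess:
    """Goldman–Yang-style codon process on the 61 sense codons with uniform
    codon frequencies (symmetric rate matrix, so eigh suffices); transition
    matrices are cached per process and scaled by branch length."""

    def __init__(self, kappa: float, omega: float):
        Q = _codon_rate_matrix(kappa, omega)
        self._w, self._U = np.linalg.eigh(Q)

    def transition_matrix(self, t: float) -> np.ndarray:
        if t <= 0:
            return np.eye(len(self._w))
        P = (self._U * np.exp(self._w * t)) @ self._U.T
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def simulate_wgd_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Evolve an ancestral gene segment down the species tree.

    The segment doubles into copy lineages c1/c2 at each duplication branch;
    on every branch at or below a duplication each surviving (gene, copy) is
    lost with ``loss_prob`` (irreversibly); with ``inversion_prob`` per
    branch and copy a random contiguous run of genes is reversed and
    strand-flipped; sequences evolve under an HKY model with per-gene rate
    multipliers. Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    tree = SpeciesTree.from_newick(config.tree_newick)
    panel = [f"g{i + 1:02d}" for i in range(config.panel_size)]
    dup_branches = set(config.duplication_branches)
    if config.omega is None:
        model = hky(config.kappa, config.base_freqs)
        base_idx = {b: i for i, b in enumerate("ACGT")}
        bases = np.array(list("ACGT"))

        def decode(arr: np.ndarray) -> str:
            return "".join(bases[arr])
    else:
        model = _CodonProcess(config.kappa, config.omega)

        def decode(arr: np.ndarray) -> str:
            return "".join(SENSE_CODONS[i] for i in arr)

    gene_rates = {
        g: float(rng.uniform(*config.gene_rate_range)) for g in panel
    }
    n_sites = config.gene_length_codons * 3
    root_seqs = {}
    for g in panel:
        codons = rng.choice(len(SENSE_CODONS), size=config.gene_length_codons)
        if config.omega is None:
            seq = "".join(SENSE_CODONS[i] for i in codons)
            root_seqs[g] = np.array([base_idx[b] for b in seq], dtype=int)
        else:
            root_seqs[g] = codons.astype(int)
    root_strands = {g: ("+" if rng.random() < 0.5 else "-") for g in panel}

    losses: list[tuple] = []
    inversions: list[tuple] = []
    presence: dict = {}
    tip_states: dict = {}

    def branch_label(node) -> str:
        return tree._node_label(node) or f"node{id(node)}"

    def descend(node, copies, entering_duplicated):
        """copies: list of dicts {copy, order: [(gene, strand)], seqs}."""
        lbl = branch_label(node)
        length = node.edge.length or 0.0
        # duplication at the start of this branch
        if lbl in dup_branches:
            assert len(copies) == 1
            src = copies[0]
            copies = [
                {"copy": "c1", "order": list(src["order"]),
                 "seqs": dict(src["seqs"])},
                {"copy": "c2", "order": list(src["order"]),
                 "seqs": {g: s.copy() for g, s in src["seqs"].items()}},
            ]
            entering_duplicated = True
        new_copies = []
        for state in copies:
            order = list(state["order"])
            seqs = dict(state["seqs"])
            if entering_duplicated:
                kept = []
                for gene, strand in order:
                    if rng.random() < config.loss_prob:
                        losses.append((gene, state["copy"], lbl))
                        seqs.pop(gene)
                    else:
                        kept.append((gene, strand))
                order = kept
            if len(order) > 1 and rng.random() < config.inversion_prob:
                i = int(rng.integers(len(order)))
                j = int(rng.integers(len(order)))
                i, j = min(i, j), max(i, j)
                if j > i:
                    flipped = [(g, "-" if s == "+" else "+")
                               for g, s in reversed(order[i:j + 1])]
                    order = order[:i] + flipped + order[j + 1:]
                    inversions.append((lbl, state["copy"], (i, j)))
            for gene in list(seqs):
                t = length * gene_rates[gene]
                P = model.transition_matrix(t)
                seqs[gene] = _evolve(seqs[gene], P, rng)
            new_copies.append({"copy": state["copy"], "order": order,
                               "seqs": seqs})
        if node.is_leaf():
            sp = node.taxon.label
            tip_states[sp] = new_copies
            for state in new_copies:
                presence[(sp, state["copy"])] = {g for g, _s in state["order"]}
        else:
            for child in node.child_nodes():
                descend(child, new_copies, entering_duplicated)

    root = tree.dendropy_tree.seed_node
    initial = [{
        "copy": "c1",
        "order": [(g, root_strands[g]) for g in panel],
        "seqs": dict(root_seqs),
    }]
    for child in root.child_nodes():
        descend(child, initial, False)

    # materialize tip regions and sequence stores
    regions: dict = {}
    prot_seqs: dict[str, str] = {}
    cds_seqs: dict[str, str] = {}
    for sp in sorted(tip_states):
        regions[sp] = []
        for state in tip_states[sp]:
            if not state["order"]:
                continue
            genes = []
            pos = 1 + int(rng.integers(*config.intergenic_range))
            for gene, strand in state["order"]:
                gid = f"{sp}|{gene}|{state['copy']}"
                start, end = pos, pos + n_sites - 1
                genes.append(GeneAnnotation(gid, f"{sp}_{state['copy']}",
                                            start, end, strand, gid))
                cds = decode(state["seqs"][gene])
                cds_seqs[gid] = cds
                prot_seqs[gid] = str(Seq(cds).translate())
                pos = end + 1 + int(rng.integers(*config.intergenic_range))
            region_length = pos + int(rng.integers(*config.intergenic_range))
            regions[sp].append(
                Region(f"{sp}_{state['copy']}", sp, region_length, genes)
            )

    gene_trees = {
        g: _gene_tree_newick(tree, g, dup_branches, presence, branch_label)
        for g in panel
    }
    truth = SimulationTruth(
        scenario_name=config.scenario_name,
        duplication_branches=config.duplication_branches,
        panel=panel,
        losses=losses,
        inversions=inversions,
        template=list(panel),
        presence=presence,
        gene_trees=gene_trees,
    )
    return SimulatedDataset(
        regions=regions,
        proteins=SequenceStore(prot_seqs, alphabet="protein"),
        cds=SequenceStore(cds_seqs, alphabet="dna"),
        truth=truth,
        config=config,
    )


def _gene_tree_newick(tree: SpeciesTree, gene, dup_branches, presence,
                      branch_label) -> str | None:
    """Topology of the gene's copy tree implied by duplications and losses."""

    def join(parts):
        parts = [p for p in parts if p]
        if not parts:
            return None
        if len(parts) == 1:
            return parts[0]
        return "(" + ",".join(parts) + ")"

    def build(node, copy):
        lbl = branch_label(node)
        if lbl in dup_branches and copy == "c1":
            return join([descend_below(node, "c1"), descend_below(node, "c2")])
        return descend_below(node, copy)

    def descend_below(node, copy):
        if node.is_leaf():
            sp = node.taxon.label
            if gene in presence.get((sp, copy), set()):
                return f"{sp}|{gene}|{copy}"
            return None
        return join([build(c, copy) for c in node.child_nodes()])

    root = tree.dendropy_tree.seed_node
    s = join([build(c, "c1") for c in root.child_nodes()])
    return s + ";" if s else None


# --- worked-example microsynteny matrix ---------------------------------

RHO_PANEL = ["lrig1", "slc25a26", "magi1", "rho", "adamts9", "prickle2",
             "pphln1", "slc2a9l1", "psmd6", "atxn7", "thoc7"]


def emit_fixture_matrix() -> PresenceOrderMatrix:
    """The 11-gene microsynteny matrix of the rhodopsin-region worked
    example: spotted gar LG5 carries the full reference panel in order; eel
    and arowana each carry two synteny copies. Copy #1 (eel scaffold 3,
    arowana scaffold 133) retains everything but pphln1; copy #2 (eel
    scaffold 435, arowana scaffold 11) retains magi1, rho (eel only),
    prickle2, pphln1 and atxn7. On eel copy #2 atxn7 sits at the scaffold
    end, so the state of the panel-terminal thoc7 is unknown rather than
    absent.
    """

    def mk_row(row_id, species, copy, present, unknown=(), edge=()):
        states, ranks, orients = {}, {}, {}
        rank = 0
        for g in RHO_PANEL:
            if g in present:
                rank += 1
                states[g] = PRESENT
                ranks[g] = rank
                orients[g] = "+"
            elif g in unknown:
                states[g] = UNKNOWN
            else:
                states[g] = ABSENT
        return MatrixRow(row_id, species, copy, states, ranks, orients,
                         set(edge))

    copy1 = [g for g in RHO_PANEL if g != "pphln1"]
    copy2_eel = ["magi1", "rho", "prickle2", "pphln1", "atxn7"]
    copy2_arowana = ["magi1", "prickle2", "pphln1", "atxn7"]
    rows = [
        mk_row("gar_LG5", "gar", "#1", RHO_PANEL),
        mk_row("eel_scaffold3", "eel", "#1", copy1),
        mk_row("eel_scaffold435", "eel", "#2", copy2_eel,
               unknown=["thoc7"], edge=["atxn7"]),
        mk_row("arowana_scaffold133", "arowana", "#1", copy1),
        mk_row("arowana_scaffold11", "arowana", "#2", copy2_arowana),
    ]
    return PresenceOrderMatrix(list(RHO_PANEL), rows)


# --- sequence simulators for likelihood and selection tests --------------

def simulate_alignment(tree: PhyloTree, model: SubstitutionModel,
                       n_sites: int, rng: np.random.Generator) -> Alignment:
    """Simulate an alignment on a phylogeny under a substitution model
    (single rate category)."""
    states = model.states
    root_seq = rng.choice(len(states), size=n_sites, p=model.freqs)
    seqs: dict[str, np.ndarray] = {}

    def walk(node, seq):
        if node.parent is not None:
            P = model.transition_matrix(node.length)
            seq = _evolve(seq, P, rng)
        if node.is_leaf():
            seqs[node.name] = seq
        for child in node.children:
            walk(child, seq)

    walk(tree.root, root_seq)
    alphabet = "dna" if len(states) <= 4 else "protein"
    letters = np.array(list(states))
    return Alignment.from_sequences(
        {name: "".join(letters[idx]) for name, idx in seqs.items()},
        alphabet=alphabet,
    )


def _codon_rate_matrix(kappa: float, omega: float) -> np.ndarray:
    """Goldman–Yang-style rate matrix on the 61 sense codons (uniform codon
    frequencies), scaled so the neutral (omega = 1) process has unit rate."""
    n = len(SENSE_CODONS)
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    aa = {c: _CODON_TABLE.forward_table[c] for c in SENSE_CODONS}

    def fill(om):
        Q = np.zeros((n, n))
        for i, ci in enumerate(SENSE_CODONS):
            for j, cj in enumerate(SENSE_CODONS):
                if i == j:
                    continue
                diff = [(a, b) for a, b in zip(ci, cj) if a != b]
                if len(diff) != 1:
                    continue
                rate = kappa if (diff[0] in transitions) else 1.0
                if aa[ci] != aa[cj]:
                    rate *= om
                Q[i, j] = rate
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    Q1 = fill(1.0)
    scale = -np.diag(Q1).mean()  # neutral expected rate, uniform frequencies
    return fill(omega) / scale


def simulate_codon_pair(
    n_codons: int,
    divergence: float,
    omega: float | np.ndarray,
    kappa: float = 2.0,
    rng: np.random.Generator | None = None,
) -> tuple[str, str]:
    """Two in-frame coding sequences separated by ``divergence`` expected
    neutral substitutions per site, with per-codon dN/dS ``omega`` (scalar
    or length-``n_codons`` profile)."""
    rng = rng or np.random.default_rng()
    omegas = np.broadcast_to(np.asarray(omega, dtype=float), (n_codons,))
    ancestor = rng.choice(len(SENSE_CODONS), size=n_codons)
    out = []
    for _side in range(2):
        seq = ancestor.copy()
        for om in np.unique(omegas):
            Q = _codon_rate_matrix(kappa, float(om))
            P = expm(Q * divergence / 2.0)
            mask = omegas == om
            seq[mask] = _evolve(seq[mask], P, rng)
        out.append("".join(SENSE_CODONS[i] for i in seq))
    return out[0], out[1]
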