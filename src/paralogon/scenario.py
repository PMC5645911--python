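"""Dollo-parsimony duplication-scenario inference.

Given a presence/order matrix over a gene panel and a rooted species tree,
candidate duplication scenarios (e.g. one whole-genome duplication on the
stem lineage vs. independent segmental duplications in each descendant
lineage) are scored by total event count: the number of duplication
placements plus the Dollo-minimal number of gene-copy losses. A loss is
clade-wide and irreversible: one event removes a gene copy from an entire
descendant subtree, and a copy once lost is never regained.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .model import SpeciesTree
from .synteny import ABSENT, PRESENT, UNKNOWN, PresenceOrderMatrix, duplicated_template


class DolloViolationError(ValueError):
    """A tip state is impossible under the Dollo model for the scenario."""


@dataclass(frozen=True)
class EventCount:
    n_duplications: int
    n_losses: int

    @property
    def total(self) -> int:
        return self.n_duplications + self.n_losses


@dataclass
class DuplicationScenario:
    """A placement of duplication events on the species tree.

    ``duplication_placements`` are branch labels (a branch is named by its
    child node: tip labels for terminal branches, internal node labels
    otherwise). Each placement doubles the ``template`` interval of the panel
    into copy lineages #1/#2 restricted to the clade below the placement.
    ``template`` defaults to the minimal duplicated segment inferred from the
    matrix.
    """

    name: str
    duplication_placements: list[str]
    template: list[str] | None = None

    @classmethod
    def from_yaml(cls, path) -> list["DuplicationScenario"]:
        with open(path) as fh:
            docs = yaml.safe_load(fh)
        if isinstance(docs, dict):
            docs = docs.get("scenarios", [docs])
        return [
            cls(
                name=d["name"],
                duplication_placements=list(d["duplication_placements"]),
                template=list(d["template"]) if d.get("template") else None,
            )
            for d in docs
        ]


@dataclass(frozen=True)
class DolloColumn:
    """Tip states for one (gene, copy lineage) below an origin branch."""

    gene: str
    copy: str
    tip_states: dict  # species -> P/A/U


def minimal_duplicated_segment(matrix: PresenceOrderMatrix) -> list[str]:
    """Smallest contiguous panel interval containing every gene observed on
    any copy-#2 row. Genes inside the interval but absent from all #2 rows
    are implied losses; genes outside incur no events in any scenario."""
    return duplicated_template(matrix)


def dollo_loss_count(
    tree: SpeciesTree, origin_branch: str, column: DolloColumn
) -> int:
    """Dollo-minimal number of clade-wide loss events explaining the tip
    states of one gene copy, given the copy present at the origin branch.

    Computed by post-order dynamic programming: a maximal subtree containing
    no 'present' tip but at least one 'absent' tip is eliminated by a single
    loss on its subtending branch. 'unknown' tips are unconstrained.
    """
    origin = tree.find_node(origin_branch)
    below = set(tree.tips_below(origin_branch))
    for sp, state in column.tip_states.items():
        if state == PRESENT and sp not in below:
            raise DolloViolationError(
                f"gene {column.gene} copy {column.copy}: present in {sp}, "
                f"outside the clade below {origin_branch}"
            )

    def walk(node) -> tuple[bool, bool, int]:
        """(has_present, has_absent, losses-if-alive-entering-node)."""
        if node.is_leaf():
            state = column.tip_states.get(node.taxon.label, UNKNOWN)
            return state == PRESENT, state == ABSENT, 0
        has_p = has_a = False
        losses = 0
        child_info = [walk(c) for c in node.child_nodes()]
        has_p = any(ci[0] for ci in child_info)
        has_a = any(ci[1] for ci in child_info)
        for cp, ca, cl in child_info:
            if cp:
                losses += cl
            elif ca:
                losses += 1  # kill the whole child subtree with one event
        return has_p, has_a, losses

    has_p, has_a, losses = walk(origin)
    if not has_p:
        # copy present at origin but absent everywhere observed below:
        # one loss on the origin branch itself suffices (if anything absent)
        return 1 if has_a else 0
    return losses


def _column_states(
    matrix: PresenceOrderMatrix,
    gene: str,
    copy_label: str,
    species_below: set[str],
) -> dict:
    """Tip states of one template gene copy for the species below a
    placement. A species present in the matrix but lacking a row for this
    copy counts as absent; species not sampled in the matrix are unknown."""
    states = {}
    sampled = set(matrix.species())
    for sp in species_below:
        if sp not in sampled:
            states[sp] = UNKNOWN
            continue
        try:
            row = matrix.row(sp, copy_label)
        except KeyError:
            states[sp] = ABSENT
            continue
        states[sp] = row.states.get(gene, ABSENT)
    return states


def scenario_total_events(
    scenario: DuplicationScenario,
    matrix: PresenceOrderMatrix,
    tree: SpeciesTree,
) -> EventCount:
    """Total parsimony cost of a scenario: duplication placements plus the
    Dollo-minimal losses over every (copy lineage x template gene).

    Unknown states resolve in whichever direction minimizes events (they are
    unconstrained in the Dollo recursion). The count is invariant to matrix
    row order and to panel-order permutations within the template.
    """
    template = scenario.template or minimal_duplicated_segment(matrix)
    n_losses = 0
    for branch in scenario.duplication_placements:
        below = set(tree.tips_below(branch))
        for copy_label in ("#1", "#2"):
            for gene in template:
                states = _column_states(matrix, gene, copy_label, below)
                col = DolloColumn(gene, copy_label, states)
                n_losses += dollo_loss_count(tree, branch, col)
    return EventCount(len(scenario.duplication_placements), n_losses)


@dataclass
class ScenarioRanking:
    ranked: list[tuple[DuplicationScenario, EventCount]]
    best_is_strict: bool

    @property
    def best(self) -> DuplicationScenario:
        return self.ranked[0][0]


def rank_scenarios(
    candidates: list[DuplicationScenario],
    matrix: PresenceOrderMatrix,
    tree: SpeciesTree,
) -> ScenarioRanking:
    """Rank candidate scenarios by ascending total events; ties break by
    fewer duplications, then input order. Flags whether the best scenario is
    strictly better than the runner-up."""
    if not candidates:
        raise ValueError("at least one candidate scenario required")
    scored = [
        (scenario, scenario_total_events(scenario, matrix, tree))
        for scenario in candidates
    ]
    order = sorted(
        range(len(scored)),
        key=lambda i: (scored[i][1].total, scored[i][1].n_duplications, i),
    )
    ranked = [scored[i] for i in order]
    strict = len(ranked) == 1 or ranked[0][1].total < ranked[1][1].total
    return ScenarioRanking(ranked, strict)


def dollo_violations(
    matrix: PresenceOrderMatrix,
    tree: SpeciesTree,
    scenario: DuplicationScenario,
) -> list[tuple[str, str]]:
    """Genes whose observed states would force a regain under the scenario.

    Under Dollo counting any presence/absence pattern *within* a placement's
    clade is explainable by losses alone, so the only impossible pattern is a
    copy observed present in a species that does not descend from the
    placement that created it. An empty list means the matrix is consistent
    with the scenario.
    """
    template = scenario.template or minimal_duplicated_segment(matrix)
    covered: set[str] = set()
    for branch in scenario.duplication_placements:
        covered |= set(tree.tips_below(branch))
    violations = []
    for row in matrix.rows:
        if row.copy_label != "#2":
            continue
        if row.species_id in covered:
            continue
        for gene in template:
            if row.states.get(gene) == PRESENT:
                violations.append(
                    (gene,
                     f"copy #2 of {gene} present in {row.species_id}, which is "
                     f"outside every duplication placement of scenario "
                     f"{scenario.name!r}; a regain would be required")
                )
    return violations


def ranking_report(ranking: ScenarioRanking) -> dict:
    """JSON-ready report of a scenario ranking."""
    return {
        "ranked": [
            {
                "name": s.name,
                "n_duplications": ec.n_duplications,
                "n_losses": ec.n_losses,
                "total_events": ec.total,
            }
            for s, ec in ranking.ranked
        ],
        "best": ranking.best.name,
        "best_is_strict": ranking.best_is_strict,
    }
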