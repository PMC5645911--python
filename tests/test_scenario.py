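"""Dollo-parsimony loss counting against an exhaustive subset oracle, and
duplication-scenario event totals and ranking on the worked-example matrix."""
from itertools import combinations

import pytest

from conftest import random_rooted_newick
from paralogon.model import SpeciesTree
from paralogon.scenario import (
    DolloColumn,
    DolloViolationError,
    DuplicationScenario,
    dollo_loss_count,
    dollo_violations,
    minimal_duplicated_segment,
    rank_scenarios,
    scenario_total_events,
)
from paralogon.synteny import MatrixRow, PresenceOrderMatrix


def exhaustive_dollo_minimum(tree: SpeciesTree, origin: str, states: dict) -> int:
    """Minimum number of clade-kill events over all branch subsets below the
    origin: every absent tip must be covered, no present tip may be."""
    node = tree.find_node(origin)
    branches = []  # (branch_key, killed tip set)

    def collect(n):
        tips = {lf.taxon.label for lf in n.leaf_iter()}
        branches.append(tips)
        for c in n.child_nodes():
            collect(c)

    collect(node)
    tips_below = {lf.taxon.label for lf in node.leaf_iter()}
    absent = {t for t in tips_below if states.get(t) == "A"}
    present = {t for t in tips_below if states.get(t) == "P"}
    for k in range(0, len(branches) + 1):
        for comb in combinations(range(len(branches)), k):
            killed = set().union(*(branches[i] for i in comb)) if comb else set()
            if absent <= killed and not (present & killed):
                return k
    raise AssertionError("unreachable")


def test_all_present_zero_losses(three_lineage_tree):
    col = DolloColumn("g", "#1", {"eel": "P", "arowana": "P"})
    assert dollo_loss_count(three_lineage_tree, "teleost", col) == 0


def test_single_absent_tip_single_loss(three_lineage_tree):
    col = DolloColumn("g", "#1", {"eel": "P", "arowana": "A"})
    assert dollo_loss_count(three_lineage_tree, "teleost", col) == 1


def test_shared_absence_counts_once(three_lineage_tree):
    col = DolloColumn("g", "#1", {"eel": "A", "arowana": "A"})
    assert dollo_loss_count(three_lineage_tree, "teleost", col) == 1


def test_present_outside_origin_clade_is_violation(three_lineage_tree):
    col = DolloColumn("g", "#2", {"eel": "P", "gar": "P"})
    with pytest.raises(DolloViolationError):
        dollo_loss_count(three_lineage_tree, "teleost", col)


def test_dollo_dp_equals_exhaustive_minimum(rng):
    """DP loss count equals the exhaustive minimum over loss-branch subsets
    on random trees (<= 6 tips) and random state columns."""
    for _ in range(60):
        n_tips = int(rng.integers(2, 7))
        tree = SpeciesTree.from_newick(random_rooted_newick(rng, n_tips))
        origin = "root"
        tips = tree.tip_labels()
        states = {t: str(rng.choice(["P", "A", "U"])) for t in tips}
        col = DolloColumn("g", "#1", states)
        got = dollo_loss_count(tree, origin, col)
        want = exhaustive_dollo_minimum(tree, origin, states)
        assert got == want, (tree.to_newick(), states)


def test_adding_absent_tip_never_decreases_losses(rng):
    for _ in range(20):
        tree = SpeciesTree.from_newick(random_rooted_newick(rng, 6))
        tips = tree.tip_labels()
        states = {t: str(rng.choice(["P", "A", "U"])) for t in tips}
        unknowns = [t for t in tips if states[t] == "U"]
        if not unknowns:
            continue
        before = dollo_loss_count(tree, "root", DolloColumn("g", "#1", states))
        states2 = dict(states)
        states2[unknowns[0]] = "A"
        after = dollo_loss_count(tree, "root", DolloColumn("g", "#1", states2))
        assert after >= before


PANEL = ["lrig1", "slc25a26", "magi1", "rho", "adamts9", "prickle2",
         "pphln1", "slc2a9l1", "psmd6", "atxn7", "thoc7"]


def test_minimal_segment_on_worked_example(fixture_matrix):
    seg = minimal_duplicated_segment(fixture_matrix)
    assert seg == ["magi1", "rho", "adamts9", "prickle2", "pphln1",
                   "slc2a9l1", "psmd6", "atxn7"]
    assert len(seg) == 8


def test_minimal_segment_single_gene():
    rows = [
        MatrixRow("a1", "sp", "#1",
                  {g: "P" for g in PANEL},
                  {g: i + 1 for i, g in enumerate(PANEL)}, {}),
        MatrixRow("a2", "sp", "#2",
                  {g: ("P" if g == "rho" else "A") for g in PANEL},
                  {"rho": 1}, {}),
    ]
    m = PresenceOrderMatrix(list(PANEL), rows)
    assert minimal_duplicated_segment(m) == ["rho"]


def test_minimal_segment_requires_duplication_evidence():
    rows = [MatrixRow("a1", "sp", "#1", {g: "P" for g in PANEL},
                      {g: i + 1 for i, g in enumerate(PANEL)}, {})]
    m = PresenceOrderMatrix(list(PANEL), rows)
    with pytest.raises(ValueError, match="no duplication evidence"):
        minimal_duplicated_segment(m)


def test_minimal_segment_matches_window_scan(rng):
    for _ in range(20):
        k = int(rng.integers(1, 8))
        present = set(rng.choice(PANEL, size=k, replace=False))
        rows = [MatrixRow("r2", "sp", "#2",
                          {g: ("P" if g in present else "A") for g in PANEL},
                          {g: i + 1 for i, g in
                           enumerate(sorted(present, key=PANEL.index))}, {})]
        m = PresenceOrderMatrix(list(PANEL), rows)
        seg = minimal_duplicated_segment(m)
        # brute force: smallest window of the panel covering all present genes
        best = None
        for i in range(len(PANEL)):
            for j in range(i, len(PANEL)):
                window = PANEL[i:j + 1]
                if present <= set(window):
                    if best is None or len(window) < len(best):
                        best = window
        assert seg == best


def _scenarios():
    return (DuplicationScenario("single_wgd", ["teleost"]),
            DuplicationScenario("independent_duplications", ["eel", "arowana"]))


def exhaustive_scenario_cost(scenario, matrix, tree):
    """Independent total-event count: duplications plus exhaustive-minimum
    losses per (placement, copy, template gene)."""
    template = minimal_duplicated_segment(matrix)
    losses = 0
    for branch in scenario.duplication_placements:
        below = set(tree.tips_below(branch))
        for copy in ("#1", "#2"):
            for gene in template:
                states = {}
                for sp in below:
                    try:
                        states[sp] = matrix.row(sp, copy).states.get(gene, "A")
                    except KeyError:
                        states[sp] = "A"
                losses += exhaustive_dollo_minimum(tree, branch, states)
    return len(scenario.duplication_placements) + losses


def test_scenario_totals_on_worked_example(fixture_matrix, three_lineage_tree):
    s1, s2 = _scenarios()
    ec1 = scenario_total_events(s1, fixture_matrix, three_lineage_tree)
    ec2 = scenario_total_events(s2, fixture_matrix, three_lineage_tree)
    # confirmed against the exhaustive loss-placement oracle
    assert ec1.total == exhaustive_scenario_cost(s1, fixture_matrix,
                                                 three_lineage_tree)
    assert ec2.total == exhaustive_scenario_cost(s2, fixture_matrix,
                                                 three_lineage_tree)
    assert (ec1.n_duplications, ec1.n_losses, ec1.total) == (1, 5, 6)
    assert (ec2.n_duplications, ec2.n_losses, ec2.total) == (2, 9, 11)


def test_full_retention_costs_only_the_duplication(three_lineage_tree):
    rows = []
    for sp in ("eel", "arowana"):
        for copy in ("#1", "#2"):
            rows.append(MatrixRow(f"{sp}{copy}", sp, copy,
                                  {g: "P" for g in PANEL},
                                  {g: i + 1 for i, g in enumerate(PANEL)}, {}))
    m = PresenceOrderMatrix(list(PANEL), rows)
    s1 = DuplicationScenario("single_wgd", ["teleost"])
    ec = scenario_total_events(s1, m, three_lineage_tree)
    assert (ec.n_duplications, ec.n_losses, ec.total) == (1, 0, 1)


def test_ranking_prefers_single_wgd(fixture_matrix, three_lineage_tree):
    s1, s2 = _scenarios()
    ranking = rank_scenarios([s2, s1], fixture_matrix, three_lineage_tree)
    assert ranking.best.name == "single_wgd"
    assert ranking.best_is_strict


def test_single_candidate_trivially_best(fixture_matrix, three_lineage_tree):
    (s1, _s2) = _scenarios()
    ranking = rank_scenarios([s1], fixture_matrix, three_lineage_tree)
    assert ranking.best is s1 and ranking.best_is_strict


def test_ranking_matches_bruteforce_on_random_matrices(rng, three_lineage_tree):
    s1, s2 = _scenarios()
    for _ in range(10):
        rows = []
        for sp in ("eel", "arowana"):
            for copy in ("#1", "#2"):
                k = int(rng.integers(1, len(PANEL) + 1))
                present = set(rng.choice(PANEL, size=k, replace=False))
                rows.append(MatrixRow(
                    f"{sp}{copy}", sp, copy,
                    {g: ("P" if g in present else "A") for g in PANEL},
                    {g: i + 1 for i, g in
                     enumerate(sorted(present, key=PANEL.index))}, {}))
        m = PresenceOrderMatrix(list(PANEL), rows)
        ranking = rank_scenarios([s1, s2], m, three_lineage_tree)
        costs = {s.name: exhaustive_scenario_cost(s, m, three_lineage_tree)
                 for s in (s1, s2)}
        assert [ec.total for _s, ec in ranking.ranked] == \
               sorted(costs[s.name] for s, _e in ranking.ranked)
        assert ranking.ranked[0][1].total == min(costs.values())


def test_row_order_invariance(fixture_matrix, three_lineage_tree):
    s1, _ = _scenarios()
    reversed_matrix = PresenceOrderMatrix(list(fixture_matrix.panel),
                                          list(reversed(fixture_matrix.rows)))
    a = scenario_total_events(s1, fixture_matrix, three_lineage_tree)
    b = scenario_total_events(s1, reversed_matrix, three_lineage_tree)
    assert (a.n_duplications, a.n_losses) == (b.n_duplications, b.n_losses)


def test_no_violations_on_worked_example(fixture_matrix, three_lineage_tree):
    s1, s2 = _scenarios()
    assert dollo_violations(fixture_matrix, three_lineage_tree, s1) == []


def test_violation_when_copy_present_outside_placement(three_lineage_tree):
    # duplication placed on the eel branch only, yet arowana carries copy #2
    rows = []
    for sp in ("eel", "arowana"):
        for copy in ("#1", "#2"):
            rows.append(MatrixRow(f"{sp}{copy}", sp, copy,
                                  {g: "P" for g in PANEL},
                                  {g: i + 1 for i, g in enumerate(PANEL)}, {}))
    m = PresenceOrderMatrix(list(PANEL), rows)
    s = DuplicationScenario("eel_only", ["eel"])
    violations = dollo_violations(m, three_lineage_tree, s)
    assert violations and all(v[1].count("arowana") for v in violations)


def test_scenario_yaml_round_trip(tmp_path):
    p = tmp_path / "s.yaml"
    p.write_text(
        "scenarios:\n"
        "  - name: single_wgd\n"
        "    duplication_placements: [teleost]\n"
        "  - name: independent\n"
        "    duplication_placements: [eel, arowana]\n"
        "    template: [magi1, rho]\n"
    )
    s1, s2 = DuplicationScenario.from_yaml(p)
    assert s1.duplication_placements == ["teleost"] and s1.template is None
    assert s2.template == ["magi1", "rho"]
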