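"""Dot-plot statistics, microsynteny extraction, order conservation (LCS)
and shared-loss patterns, checked against brute-force oracles and the
worked-example matrix."""
from itertools import combinations

import pytest

from paralogon.anchoring import Anchor
from paralogon.model import GeneAnnotation, Region
from paralogon.synteny import (
    MatrixRow,
    PresenceOrderMatrix,
    build_dotplot,
    duplicated_template,
    extract_microsynteny,
    macrosynteny_stats,
    order_conservation,
    shared_loss_pattern,
)


def _region(rid, sp, genes, length=100_000):
    return Region(rid, sp, length,
                  [GeneAnnotation(g, rid, s, e, st) for g, s, e, st in genes])


def test_dotplot_midpoints_and_orientation():
    ref = _region("ref", "gar", [("gA", 100, 200, "+")])
    query = _region("q", "eel", [("gB", 1000, 1100, "-")])
    (rec,) = build_dotplot(ref, query, [Anchor("gA", "gB", 88.0, 50.0)])
    assert (rec.x_mid, rec.y_mid) == (150, 1050)
    assert rec.orientation == "opposite"


def test_dotplot_unknown_gene_errors():
    ref = _region("ref", "gar", [("gA", 100, 200, "+")])
    query = _region("q", "eel", [("gB", 1000, 1100, "+")])
    with pytest.raises(KeyError):
        build_dotplot(ref, query, [Anchor("gX", "gB", 88.0, 50.0)])


def test_macrosynteny_stats_partition(rng):
    ref_genes = [(f"r{i}", 1 + 1000 * i, 500 + 1000 * i,
                  "+" if i % 3 else "-") for i in range(7)]
    q_genes = [(f"q{i}", 1 + 1000 * i, 500 + 1000 * i,
                "+" if i % 2 else "-") for i in range(7)]
    ref = _region("ref", "gar", ref_genes)
    query = _region("q", "eel", q_genes)
    anchors = [Anchor(f"r{i}", f"q{i}", 90.0, 100.0) for i in range(7)]
    records = build_dotplot(ref, query, anchors)
    stats = macrosynteny_stats(records)
    expected_same = sum(1 for i in range(7) if (i % 3 != 0) == (i % 2 != 0))
    assert stats["n_anchored"] == 7
    assert stats["n_same_orientation"] == expected_same
    assert stats["n_same_orientation"] + stats["n_opposite"] == 7
    assert macrosynteny_stats([]) == {"n_anchored": 0, "n_same_orientation": 0,
                                      "n_opposite": 0}


PANEL = [f"p{i}" for i in range(6)]


def _row(present_in_order, copy="#1", species="sp", states_extra=None):
    states = {g: ("P" if g in present_in_order else "A") for g in PANEL}
    if states_extra:
        states.update(states_extra)
    ranks = {g: i + 1 for i, g in enumerate(present_in_order)}
    return MatrixRow(f"{species}_{copy}", species, copy, states, ranks, {})


def test_extract_microsynteny_rows(rng):
    ref = _region("ref", "gar", [(g, 1 + 2000 * i, 1000 + 2000 * i, "+")
                                 for i, g in enumerate(PANEL)])
    genes_q = [("x0", 1000, 1500, "+"), ("x1", 3000, 3500, "-")]
    query = _region("q1", "eel", genes_q)
    anchors = {"ref": [Anchor(g, g, 100.0, 1.0, True) for g in PANEL],
               "q1": [Anchor("x0", "p1", 90.0, 10.0, True),
                      Anchor("x1", "p4", 85.0, 9.0, False)]}
    m = extract_microsynteny(PANEL, [ref, query], anchors)
    row = m.row("eel", "#1")
    assert row.states == {"p0": "A", "p1": "P", "p2": "A", "p3": "A",
                          "p4": "P", "p5": "A"}
    assert row.ranks == {"p1": 1, "p4": 2}
    assert row.orientations == {"p1": "+", "p4": "-"}


def test_extract_duplicate_panel_anchor_errors():
    query = _region("q1", "eel", [("x0", 100, 200, "+"), ("x1", 300, 400, "+")])
    anchors = {"q1": [Anchor("x0", "p1", 90.0, 1.0), Anchor("x1", "p1", 80.0, 1.0)]}
    with pytest.raises(ValueError, match="tandem"):
        extract_microsynteny(PANEL, [query], anchors)


def test_region_without_anchors_is_all_absent():
    query = _region("q1", "eel", [("x0", 100, 200, "+")])
    m = extract_microsynteny(PANEL, [query], {"q1": []})
    assert set(m.rows[0].states.values()) == {"A"}


def test_order_conservation_against_lcs_oracle(rng):
    def lcs_bruteforce(seq, panel):
        best = 0
        for r in range(len(seq), 0, -1):
            for comb in combinations(range(len(seq)), r):
                sub = [seq[i] for i in comb]
                it = iter(panel)
                if all(g in it for g in sub):
                    return r
        return best

    for _ in range(20):
        k = int(rng.integers(1, 7))
        present = list(rng.choice(PANEL, size=k, replace=False))
        row = _row(present)
        assert order_conservation(row, PANEL) == lcs_bruteforce(present, PANEL)


def test_order_conservation_identity_and_swap():
    assert order_conservation(_row(PANEL), PANEL) == len(PANEL)
    swapped = PANEL[:2] + [PANEL[3], PANEL[2]] + PANEL[4:]
    assert order_conservation(_row(swapped), PANEL) == len(PANEL) - 1


def test_order_conservation_bounded_by_present_count(rng):
    for _ in range(10):
        k = int(rng.integers(1, 7))
        present = list(rng.choice(PANEL, size=k, replace=False))
        row = _row(present)
        oc = order_conservation(row, PANEL)
        assert oc <= k
        in_panel_order = sorted(present, key=PANEL.index) == present
        assert (oc == k) == in_panel_order


def test_shared_loss_matches_bruteforce(rng):
    for _ in range(20):
        rows = []
        for sp in ("s1", "s2"):
            for copy in ("#1", "#2"):
                k = int(rng.integers(1, 7))
                present = sorted(rng.choice(PANEL, size=k, replace=False),
                                 key=PANEL.index)
                rows.append(_row(present, copy, sp))
        try:
            matrix = PresenceOrderMatrix(list(PANEL), rows)
            template = duplicated_template(matrix)
        except ValueError:
            continue
        got = shared_loss_pattern(matrix, ("s1", "s2"))
        expected = set()
        for g in template:
            p1 = (matrix.row("s1", "#1").states[g], matrix.row("s1", "#2").states[g])
            p2 = (matrix.row("s2", "#1").states[g], matrix.row("s2", "#2").states[g])
            if p1 == p2 and sorted(p1) == ["A", "P"]:
                expected.add(g)
        assert got == expected


def test_shared_loss_full_retention_empty():
    rows = [_row(PANEL, c, s) for s in ("s1", "s2") for c in ("#1", "#2")]
    matrix = PresenceOrderMatrix(list(PANEL), rows)
    assert shared_loss_pattern(matrix, ("s1", "s2")) == set()


def test_shared_loss_missing_row_errors(fixture_matrix):
    with pytest.raises(KeyError):
        shared_loss_pattern(fixture_matrix, ("eel", "zebrafish"))


def test_matrix_tsv_round_trip(tmp_path, fixture_matrix):
    p = tmp_path / "m.tsv"
    fixture_matrix.to_tsv(p)
    back = PresenceOrderMatrix.from_tsv(p)
    assert back.panel == fixture_matrix.panel
    for r1, r2 in zip(fixture_matrix.rows, back.rows):
        assert (r1.row_id, r1.species_id, r1.copy_label) == \
               (r2.row_id, r2.species_id, r2.copy_label)
        assert r1.states == r2.states and r1.ranks == r2.ranks
        assert r1.edge_genes == r2.edge_genes
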