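"""Nei–Gojobori counting against an independent pathway-enumeration oracle,
and the sliding-window scan with masking."""
import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from paralogon.phylo.alignment import Alignment
from paralogon.selection import (
    mask_windows,
    ng86_pair_counts,
    sliding_dnds,
)
from paralogon.simulate import SENSE_CODONS, simulate_codon_pair

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


def oracle_counts(cds_a: str, cds_b: str):
    """Independent NG86 re-implementation built on Biopython translation:
    per-position site fractions and explicit pathway enumeration."""

    def translate(codon):
        return str(Seq(codon).translate())

    def sites(codon):
        syn = 0.0
        for pos, alts in ((p, [b for b in BASES if b != codon[p]])
                          for p in range(3)):
            for alt in alts:
                mut = codon[:pos] + alt + codon[pos + 1:]
                if mut not in STOPS and translate(mut) == translate(codon):
                    syn += 1
        return syn / 3.0, 3 - syn / 3.0

    N = S = Nd = Sd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        if any(c not in BASES for c in ca + cb):
            continue
        for c in (ca, cb):
            s, n = sites(c)
            S += s / 2
            N += n / 2
        diff = [p for p in range(3) if ca[p] != cb[p]]
        if not diff:
            continue
        ok_paths, bad_paths = [], []
        for order in itertools.permutations(diff):
            cur, sd, nd, hit_stop = ca, 0.0, 0.0, False
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1:]
                if nxt in STOPS:
                    hit_stop = True
                if (cur not in STOPS and nxt not in STOPS
                        and translate(cur) == translate(nxt)):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            (bad_paths if hit_stop else ok_paths).append((sd, nd))
        paths = ok_paths or bad_paths
        Sd += sum(p[0] for p in paths) / len(paths)
        Nd += sum(p[1] for p in paths) / len(paths)
    return N, S, Nd, Sd


def test_identical_sequences_zero_substitutions():
    c = ng86_pair_counts("ATGAAACCC", "ATGAAACCC")
    assert c["Nd"] == 0 and c["Sd"] == 0
    assert c["dN"] == 0 and c["dS"] == 0


def test_synonymous_single_change():
    c = ng86_pair_counts("GGG", "GGA")
    assert c["Sd"] == 1.0 and c["Nd"] == 0.0


def test_frame_and_length_validation():
    with pytest.raises(ValueError):
        ng86_pair_counts("ATGA", "ATGA")
    with pytest.raises(ValueError):
        ng86_pair_counts("ATG", "ATGATG")
    with pytest.raises(ValueError, match="stop"):
        ng86_pair_counts("TAAATG", "ATGATG")


def test_counts_match_pathway_oracle(rng):
    """Random 30-codon pairs agree with the independent enumeration oracle."""
    for rep in range(25):
        a, b = simulate_codon_pair(30, 0.5, 1.0, rng=rng)
        got = ng86_pair_counts(a, b)
        N, S, Nd, Sd = oracle_counts(a, b)
        assert got["N"] == pytest.approx(N)
        assert got["S"] == pytest.approx(S)
        assert got["Nd"] == pytest.approx(Nd)
        assert got["Sd"] == pytest.approx(Sd)


def test_site_counts_partition_and_symmetry(rng):
    for _ in range(10):
        a, b = simulate_codon_pair(20, 0.4, 0.5, rng=rng)
        ab = ng86_pair_counts(a, b)
        ba = ng86_pair_counts(b, a)
        assert ab["N"] + ab["S"] == pytest.approx(3 * 20)
        assert ab["Nd"] == pytest.approx(ba["Nd"])
        assert ab["Sd"] == pytest.approx(ba["Sd"])


def test_gapped_codons_skipped():
    c = ng86_pair_counts("ATG---AAA", "ATGAAAAAG")
    assert c["N"] + c["S"] == pytest.approx(6.0)  # two scored codons


def _pair_alignment(a, b):
    return Alignment.from_sequences({"x": a, "y": b}, "dna", from_cds=True)


def test_window_positions_25_by_5():
    a, b = simulate_codon_pair(100, 0.2, 1.0, rng=np.random.default_rng(0))
    scan = sliding_dnds(_pair_alignment(a, b))
    full = [w for w in scan.windows if not w.truncated]
    assert [w.start_codon for w in full] == list(range(1, 77, 5))
    assert all(w.end_codon - w.start_codon + 1 == 25 for w in full)
    # trailing partial windows kept only at >= half window
    trunc = [w for w in scan.windows if w.truncated]
    assert all(w.end_codon == 100 for w in trunc)
    assert all(w.end_codon - w.start_codon + 1 >= 12.5 for w in trunc)


def test_sliding_dnds_requires_pair_argument_default():
    a, b = simulate_codon_pair(30, 0.2, 1.0, rng=np.random.default_rng(1))
    scan = sliding_dnds(_pair_alignment(a, b), ("x", "y"))
    assert scan.pair == ("x", "y")


def test_identical_sequences_all_windows_undefined():
    a = "".join(np.random.default_rng(2).choice(SENSE_CODONS, size=60))
    scan = sliding_dnds(_pair_alignment(a, a))
    assert all(w.Nd == 0 and w.Sd == 0 and w.ratio is None
               for w in scan.windows)


def test_short_alignment_single_truncated_window():
    a, b = simulate_codon_pair(10, 0.2, 1.0, rng=np.random.default_rng(3))
    scan = sliding_dnds(_pair_alignment(a, b))
    assert len(scan.windows) == 1 and scan.windows[0].truncated


def test_elevated_window_detected(rng):
    hits = 0
    for _ in range(7):
        om = np.full(100, 0.1)
        om[40:60] = 4.0
        a, b = simulate_codon_pair(100, 0.6, om, rng=rng)
        scan = sliding_dnds(_pair_alignment(a, b))
        w = scan.max_dn_window()
        if w.start_codon <= 60 and w.end_codon >= 41:
            hits += 1
    assert hits >= 5  # majority of seeds localize the elevated run


def test_masking_removes_union_of_flagged_windows(rng):
    om = np.full(100, 0.05)
    om[40:60] = 5.0
    a, b = simulate_codon_pair(100, 0.6, om, rng=rng)
    aln = _pair_alignment(a, b)
    scan = sliding_dnds(aln)
    masked = mask_windows(aln, scan, ratio_threshold=1.0)
    flagged = set()
    for w in scan.windows:
        if w.ratio is not None and w.ratio > 1.0:
            flagged.update(range(w.start_codon - 1, w.end_codon))
    assert masked.n_cols == aln.n_cols - 3 * len(flagged)
    assert masked.codon_positions is not None


def test_masking_identity_when_nothing_flagged(rng):
    a, b = simulate_codon_pair(50, 0.2, 0.05, rng=rng)
    aln = _pair_alignment(a, b)
    scan = sliding_dnds(aln)
    masked = mask_windows(aln, scan, ratio_threshold=50.0)
    assert masked.n_cols == aln.n_cols


def test_masking_all_flagged_warns(rng):
    from paralogon.selection import ScanWindow, SelectionScanResult

    a, b = simulate_codon_pair(30, 0.2, 1.0, rng=rng)
    aln = _pair_alignment(a, b)
    scan = SelectionScanResult(
        [ScanWindow(1, 30, 60.0, 30.0, 5.0, 1.0, 0.1, 0.01, 10.0)],
        window_aa=30, step_aa=30, pair=("x", "y"))
    with pytest.warns(UserWarning, match="all windows"):
        masked = mask_windows(aln, scan, ratio_threshold=1.0)
    assert masked.n_cols == 0


def test_threshold_must_be_positive(rng):
    a, b = simulate_codon_pair(30, 0.2, 1.0, rng=rng)
    aln = _pair_alignment(a, b)
    scan = sliding_dnds(aln)
    with pytest.raises(ValueError):
        mask_windows(aln, scan, ratio_threshold=0.0)
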