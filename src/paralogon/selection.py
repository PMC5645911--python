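"""Sliding-window dN/dS scan by Nei–Gojobori (1986) counting.

Synonymous and nonsynonymous sites are counted per codon as the fraction of
the three possible changes at each position that preserve the encoded amino
acid; substitutions between codons differing at several positions are
averaged over all shortest mutational pathways. Proportions are corrected
for multiple hits with the Jukes–Cantor formula d = -3/4 ln(1 - 4p/3).

Conventions: changes creating a stop codon count as nonsynonymous in site
counting (so N + S = 3 x codon count exactly); pathways passing through a
stop codon are excluded from substitution averaging unless every pathway is
blocked. Codons containing a gap or ambiguity in either sequence are skipped.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

from .phylo.alignment import Alignment

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)
BASES = "ACGT"


def _translate(codon: str) -> str | None:
    return _AA.get(codon)  # None for stops


def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon."""
    if codon in _STOPS or any(b not in BASES for b in codon):
        raise ValueError(f"not a sense codon: {codon}")
    aa = _AA[codon]
    syn = 0.0
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant not in _STOPS and _AA[mutant] == aa:
                syn += 1.0
    syn /= 3.0
    return syn, 3.0 - syn


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over all shortest
    mutational pathways; stop-crossing pathways excluded when avoidable."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    valid, blocked = [], []
    for order in permutations(diff):
        cur = codon_a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                through_stop = True
            if (cur not in _STOPS and nxt not in _STOPS
                    and _AA[cur] == _AA[nxt]):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (blocked if through_stop else valid).append((sd, nd))
    paths = valid if valid else blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jc_correct(p: float) -> float | None:
    """Jukes–Cantor distance; None (undefined) when p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pair_counts(cds_a: str, cds_b: str) -> dict:
    """Nei–Gojobori counts and distances for an in-frame codon pair.

    Returns N, S (site counts averaged over both sequences), Nd, Sd
    (substitution counts averaged over shortest pathways), and dN, dS
    (Jukes–Cantor corrected proportions; None when undefined).
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3:
        raise ValueError("length not a multiple of 3")
    n_sites = s_sites = nd = sd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if any(ch not in BASES for ch in ca + cb):
            continue  # gap or ambiguity: skip codon
        if ca in _STOPS or cb in _STOPS:
            raise ValueError(f"internal stop codon at codon {i // 3 + 1}")
        sa, na = codon_site_counts(ca)
        sb, nb = codon_site_counts(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        psd, pnd = _pathway_counts(ca, cb)
        sd += psd
        nd += pnd
    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    return {
        "N": n_sites, "S": s_sites, "Nd": nd, "Sd": sd,
        "pN": pn, "pS": ps,
        "dN": _jc_correct(pn) if n_sites > 0 else None,
        "dS": _jc_correct(ps) if s_sites > 0 else None,
    }


@dataclass(frozen=True)
class ScanWindow:
    start_codon: int  # 1-based inclusive
    end_codon: int  # 1-based inclusive
    N: float
    S: float
    Nd: float
    Sd: float
    dN: float | None
    dS: float | None
    ratio: float | None  # dN/dS; None when dS is 0 or either is undefined
    truncated: bool = False


@dataclass
class SelectionScanResult:
    windows: list[ScanWindow]
    window_aa: int
    step_aa: int
    pair: tuple[str, str]

    def max_dn_window(self) -> ScanWindow:
        return max(self.windows, key=lambda w: (w.dN if w.dN is not None else -1.0))

    def to_tsv(self, path) -> None:
        def fmt(x):
            return "NA" if x is None else f"{x:.6g}"

        with open(path, "w") as fh:
            fh.write("window_start\twindow_end\tN\tS\tNd\tSd\tdN\tdS\tratio\n")
            for w in self.windows:
                fh.write(f"{w.start_codon}\t{w.end_codon}\t{w.N:.3f}\t{w.S:.3f}"
                         f"\t{w.Nd:.3f}\t{w.Sd:.3f}\t{fmt(w.dN)}\t{fmt(w.dS)}"
                         f"\t{fmt(w.ratio)}\n")


def _codon_rows(aln: Alignment, pair: tuple[str, str]) -> tuple[str, str, int]:
    if aln.codon_positions is None:
        raise ValueError("alignment lacks codon annotation")
    seq_a, seq_b = aln.row(pair[0]), aln.row(pair[1])
    if len(seq_a) % 3:
        raise ValueError("alignment length not a multiple of 3")
    return seq_a, seq_b, len(seq_a) // 3


def sliding_dnds(
    aln: Alignment,
    pair: tuple[str, str] | None = None,
    window_aa: int = 25,
    step_aa: int = 5,
    min_final_fraction: float = 0.5,
) -> SelectionScanResult:
    """Nei–Gojobori scan of a focal sequence pair in sliding windows of
    ``window_aa`` codons advanced by ``step_aa``.

    The trailing partial window is kept when it covers at least
    ``min_final_fraction`` of a full window. An alignment shorter than one
    window yields a single truncated window. ``pair`` defaults to the first
    two OTUs of the alignment.
    """
    if pair is None:
        pair = (aln.otus[0], aln.otus[1])
    seq_a, seq_b, n_codons = _codon_rows(aln, pair)
    windows = []
    if n_codons < window_aa:
        windows.append(_window_record(seq_a, seq_b, 0, n_codons, truncated=True))
    else:
        start = 0
        while start + window_aa <= n_codons:
            windows.append(_window_record(seq_a, seq_b, start, start + window_aa))
            start += step_aa
        while start < n_codons:
            if (n_codons - start) >= window_aa * min_final_fraction:
                windows.append(_window_record(seq_a, seq_b, start, n_codons,
                                              truncated=True))
            start += step_aa
    return SelectionScanResult(windows, window_aa, step_aa, pair)


def _window_record(seq_a: str, seq_b: str, start: int, end: int,
                   truncated: bool = False) -> ScanWindow:
    counts = ng86_pair_counts(seq_a[start * 3:end * 3], seq_b[start * 3:end * 3])
    dn, ds = counts["dN"], counts["dS"]
    ratio = None
    if dn is not None and ds is not None and ds > 0:
        ratio = dn / ds
    return ScanWindow(start + 1, end, counts["N"], counts["S"], counts["Nd"],
                      counts["Sd"], dn, ds, ratio, truncated)


def mask_windows(
    aln: Alignment,
    scan: SelectionScanResult,
    ratio_threshold: float,
    dn_quantile: float | None = None,
) -> Alignment:
    """Remove all codon columns covered by any window whose dN/dS exceeds
    ``ratio_threshold`` (or, when the ratio is undefined because dS = 0,
    whose dN exceeds the ``dn_quantile`` quantile of window dN values).
    Codon annotation is retained; masking the whole alignment warns."""
    import warnings

    if ratio_threshold <= 0:
        raise ValueError("ratio threshold must be positive")
    flagged: set[int] = set()
    dn_cut = None
    if dn_quantile is not None:
        dns = [w.dN for w in scan.windows if w.dN is not None]
        if dns:
            dn_cut = float(np.quantile(dns, dn_quantile))
    for w in scan.windows:
        hit = (w.ratio is not None and w.ratio > ratio_threshold)
        if not hit and w.ratio is None and dn_cut is not None:
            hit = w.dN is not None and w.dN > dn_cut
        if hit:
            flagged.update(range(w.start_codon - 1, w.end_codon))
    if not flagged:
        return aln.select_columns(np.arange(aln.n_cols))
    keep_cols = [
        c for c in range(aln.n_cols) if (c // 3) not in flagged
    ]
    if not keep_cols:
        warnings.warn("all windows flagged: masked alignment is empty")
    return aln.select_columns(np.array(keep_cols, dtype=int))
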