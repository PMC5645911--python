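"""Ortholog anchoring between genomic regions.

Anchors are reciprocal best hits (RBH) under local protein alignment. At the
scale of a gene panel on two regions, where each gene has at most one
counterpart, RBH recovers the same pairs a graph-clustering orthology method
would, while remaining fully self-contained and deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .model import SequenceStore


@dataclass(frozen=True)
class Anchor:
    """A reciprocal-best-hit ortholog pair between two regions."""

    gene_a: str
    gene_b: str
    identity: float  # percent amino-acid identity over aligned columns
    score: float  # local alignment score
    same_strand: bool = True


def _make_aligner(open_gap: float = -11.0, extend_gap: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    open_gap: float = -11.0,
    extend_gap: float = -1.0,
) -> tuple[float, float]:
    """Percent identity and score of the best local (Smith–Waterman)
    alignment under BLOSUM62.

    Identity is matches over aligned columns (gap columns included) x 100.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = _make_aligner(open_gap, extend_gap)
    alignments = aligner.align(seq_a.upper(), seq_b.upper())
    best = alignments[0]
    counts = best.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    return identity, float(best.score)


def reciprocal_best_hits(
    set_a: SequenceStore,
    set_b: SequenceStore,
    min_identity: float = 40.0,
    strands_a: dict[str, str] | None = None,
    strands_b: dict[str, str] | None = None,
) -> list[Anchor]:
    """Anchor gene pairs where each is the other's highest-scoring hit and
    percent identity exceeds ``min_identity``.

    Ties are broken by score, then identity, then lexicographic partner id,
    so the anchor set is deterministic and symmetric in its two arguments.
    When per-gene strands are supplied, each anchor records whether the two
    genes lie on the same strand.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("both sequence stores must be non-empty")
    ids_a, ids_b = sorted(set_a.ids()), sorted(set_b.ids())
    table: dict[tuple[str, str], tuple[float, float]] = {}
    for a in ids_a:
        for b in ids_b:
            identity, score = pairwise_identity(set_a[a], set_b[b])
            table[(a, b)] = (identity, score)

    def best_partner(focal: str, partners: list[str], lookup) -> str:
        # highest score, then highest identity, then lexicographically first id
        return min(partners,
                   key=lambda p: (-lookup(focal, p)[1], -lookup(focal, p)[0], p))

    anchors = []
    for a in ids_a:
        b = best_partner(a, ids_b, lambda x, y: table[(x, y)])
        a_back = best_partner(b, ids_a, lambda x, y: table[(y, x)])
        if a_back != a:
            continue
        identity, score = table[(a, b)]
        if identity <= min_identity:
            continue
        same = True
        if strands_a is not None and strands_b is not None:
            same = strands_a[a] == strands_b[b]
        anchors.append(Anchor(a, b, identity, score, same))
    return anchors


def anchors_to_tsv(anchors: list[Anchor], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tidentity\tscore\tsame_strand\n")
        for an in anchors:
            fh.write(
                f"{an.gene_a}\t{an.gene_b}\t{an.identity:.2f}\t{an.score:.1f}"
                f"\t{int(an.same_strand)}\n"
            )


def anchors_from_tsv(path) -> list[Anchor]:
    anchors = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            ga, gb, ident, score, same = line.rstrip("\n").split("\t")
            anchors.append(Anchor(ga, gb, float(ident), float(score), bool(int(same))))
    return anchors
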