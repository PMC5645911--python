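"""Core domain types: annotated genomic regions, sequence stores, marker hits,
and a rooted species tree.

Coordinates are 1-based inclusive throughout (GFF3 convention); BED input is
converted on read. Strands are restricted to ``+``/``-`` because orientation
agreement between paralogous regions is a primary statistic downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZJUOX*-.")
DNA_ALPHABET = set("ACGTUNRYSWKMBDHV-.")


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A stranded gene model on a genomic region (1-based inclusive)."""

    gene_id: str
    region_id: str
    start: int
    end: int
    strand: str
    protein_id: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def midpoint(self) -> int:
        """Integer midpoint, floor of the mean of start and end."""
        return (self.start + self.end) // 2


@dataclass
class Region:
    """An annotated genomic interval (scaffold or chromosome arm) carrying
    ordered gene models."""

    region_id: str
    species_id: str
    length: int
    genes: list[GeneAnnotation] = field(default_factory=list)
    linkage_group: str | None = None

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.gene_id))
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(
                    f"region {self.region_id}: duplicate gene id {g.gene_id}"
                )
            seen.add(g.gene_id)
            if g.end > self.length:
                raise ValidationError(
                    f"region {self.region_id}: gene {g.gene_id} end {g.end} "
                    f"exceeds region length {self.length}"
                )

    def gene(self, gene_id: str) -> GeneAnnotation:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class SequenceStore:
    """A mapping from sequence id to residue string, with a declared alphabet.

    Residues are upper-cased on construction; alphabet membership is checked
    against the declared alphabet plus gap/ambiguity symbols.
    """

    sequences: dict[str, str]
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if self.alphabet not in ("protein", "dna"):
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        normalized = {}
        for sid, seq in self.sequences.items():
            seq = seq.upper()
            bad = set(seq) - allowed
            if bad:
                raise ValidationError(
                    f"sequence {sid}: residues {sorted(bad)} outside {self.alphabet} alphabet"
                )
            normalized[sid] = seq
        self.sequences = normalized

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, sid: str) -> str:
        return self.sequences[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self.sequences

    def ids(self) -> list[str]:
        return list(self.sequences)


@dataclass(frozen=True)
class MarkerHit:
    """A linkage-marker BLASTN hit on a scaffold."""

    marker_id: str
    scaffold_id: str
    identity: float
    linkage_group: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValidationError(
                f"marker {self.marker_id}: identity {self.identity} outside [0, 100]"
            )


class SpeciesTree:
    """A rooted species tree with uniquely labelled tips.

    Thin wrapper over a :class:`dendropy.Tree` adding the lookups the
    duplication-scenario machinery needs: a branch is named by the label of
    its child node (tip labels name terminal branches, internal node labels
    name internal branches).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        self._tree.is_rooted = True

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=False
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValidationError(f"newick parse error: {exc}") from exc
        return cls(tree)

    @classmethod
    def read(cls, path) -> "SpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def _node_label(self, node) -> str | None:
        if node.taxon is not None:
            return node.taxon.label
        return node.label

    def find_node(self, label: str):
        """Node whose subtending branch carries ``label``."""
        for node in self._tree.preorder_node_iter():
            if self._node_label(node) == label:
                return node
        raise KeyError(f"no branch labelled {label!r}")

    def tips_below(self, label: str) -> list[str]:
        """Tip labels of the clade subtended by the branch named ``label``."""
        node = self.find_node(label)
        return [lf.taxon.label for lf in node.leaf_iter()]

    def topology_signature(self) -> frozenset[frozenset[str]]:
        """Set of tip-label clades; equal signatures mean equal rooted topology."""
        out = set()
        for node in self._tree.preorder_node_iter():
            tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if len(tips) > 1:
                out.add(tips)
        return frozenset(out)
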