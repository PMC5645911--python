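"""Multiple-sequence-alignment container and supermatrix operations:
gap-site pruning, third-codon-position treatments (include / RY-recode /
exclude) and partition-aware concatenation.

Alignment construction itself (e.g. MAFFT) is an input to the pipeline, not
an operation: alignments arrive pre-aligned in FASTA or relaxed PHYLIP.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..model import SequenceStore

GAP_CHARS = {"-", ".", "?"}
RY_MAP = {"A": "R", "G": "R", "C": "Y", "T": "Y"}


@dataclass
class Alignment:
    """Aligned residue matrix with optional codon-position and partition
    annotations.

    ``binary_cols`` flags columns that have been RY-recoded to the two-state
    purine/pyrimidine alphabet; such columns are scored under a binary model
    while the rest keep the nucleotide model.
    """

    otus: list[str]
    matrix: np.ndarray  # (n_otus, n_cols), dtype '<U1', upper-case
    alphabet: str  # "dna" | "protein"
    codon_positions: np.ndarray | None = None  # per-column 1/2/3
    partition_map: np.ndarray | None = None  # per-column source-gene label
    binary_cols: np.ndarray | None = None  # per-column bool

    def __post_init__(self) -> None:
        self.matrix = np.char.upper(np.asarray(self.matrix, dtype="<U1"))
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.otus):
            raise ValueError("matrix must be (n_otus, n_cols)")
        for name, ann in (("codon_positions", self.codon_positions),
                          ("partition_map", self.partition_map),
                          ("binary_cols", self.binary_cols)):
            if ann is not None and len(ann) != self.n_cols:
                raise ValueError(f"{name} length != number of columns")

    @property
    def n_otus(self) -> int:
        return len(self.otus)

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def row(self, otu: str) -> str:
        return "".join(self.matrix[self.otus.index(otu)])

    @classmethod
    def from_sequences(
        cls,
        sequences: dict[str, str] | list[tuple[str, str]],
        alphabet: str = "dna",
        codon_positions: np.ndarray | list | None = None,
        partition_map: np.ndarray | list | None = None,
        from_cds: bool = False,
    ) -> "Alignment":
        items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
        lengths = {len(s) for _n, s in items}
        if len(lengths) != 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")
        otus = [n for n, _s in items]
        matrix = np.array([list(s.upper()) for _n, s in items], dtype="<U1")
        if from_cds and codon_positions is None:
            (length,) = lengths
            if length % 3:
                raise ValueError("CDS alignment length not a multiple of 3")
            codon_positions = np.tile([1, 2, 3], length // 3)
        cp = None if codon_positions is None else np.asarray(codon_positions, dtype=int)
        pm = None if partition_map is None else np.asarray(partition_map, dtype=object)
        return cls(otus, matrix, alphabet, cp, pm)

    @classmethod
    def from_store(cls, store: SequenceStore, alphabet: str | None = None,
                   from_cds: bool = False) -> "Alignment":
        return cls.from_sequences(store.sequences,
                                  alphabet=alphabet or store.alphabet,
                                  from_cds=from_cds)

    def select_columns(self, index) -> "Alignment":
        index = np.asarray(index)
        return Alignment(
            otus=list(self.otus),
            matrix=self.matrix[:, index],
            alphabet=self.alphabet,
            codon_positions=None if self.codon_positions is None
            else self.codon_positions[index],
            partition_map=None if self.partition_map is None
            else self.partition_map[index],
            binary_cols=None if self.binary_cols is None
            else self.binary_cols[index],
        )

    def reorder(self, otus: list[str]) -> "Alignment":
        idx = [self.otus.index(o) for o in otus]
        return Alignment(list(otus), self.matrix[idx], self.alphabet,
                         self.codon_positions, self.partition_map, self.binary_cols)

    # --- IO -------------------------------------------------------------

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, otu in enumerate(self.otus):
                fh.write(f">{otu}\n{''.join(self.matrix[i])}\n")

    @classmethod
    def read_fasta(cls, path, alphabet: str = "dna", from_cds: bool = False
                   ) -> "Alignment":
        from Bio import SeqIO

        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        return cls.from_sequences(records, alphabet=alphabet, from_cds=from_cds)

    def to_phylip(self, path) -> None:
        """Relaxed (whitespace-delimited names) sequential PHYLIP."""
        with open(path, "w") as fh:
            fh.write(f"{self.n_otus} {self.n_cols}\n")
            width = max(len(o) for o in self.otus) + 2
            for i, otu in enumerate(self.otus):
                fh.write(otu.ljust(width) + "".join(self.matrix[i]) + "\n")

    @classmethod
    def read_phylip(cls, path, alphabet: str = "dna") -> "Alignment":
        with open(path) as fh:
            n, length = map(int, fh.readline().split())
            items = []
            for line in fh:
                if not line.strip():
                    continue
                name, seq = line.split(None, 1)
                items.append((name, seq.replace(" ", "").strip()))
        if len(items) != n or any(len(s) != length for _n, s in items):
            raise ValueError("PHYLIP dimensions disagree with data")
        return cls.from_sequences(items, alphabet=alphabet)

    def write_raxml_partitions(self, path) -> None:
        if self.partition_map is None:
            raise ValueError("alignment has no partition map")
        with open(path, "w") as fh:
            kind = "DNA" if self.alphabet == "dna" else "WAG"
            for name, start, end in partition_intervals(self.partition_map):
                fh.write(f"{kind}, {name} = {start}-{end}\n")


def partition_intervals(partition_map) -> list[tuple[str, int, int]]:
    """Contiguous (name, 1-based start, end) runs of a per-column partition map."""
    out = []
    pm = list(partition_map)
    i = 0
    while i < len(pm):
        j = i
        while j + 1 < len(pm) and pm[j + 1] == pm[i]:
            j += 1
        out.append((str(pm[i]), i + 1, j + 1))
        i = j + 1
    return out


def prune_gap_sites(aln: Alignment) -> Alignment:
    """Drop columns whose gap count exceeds half the OTUs (strictly more
    than n/2 gaps); annotations are sliced consistently."""
    is_gap = np.isin(aln.matrix, sorted(GAP_CHARS))
    keep = is_gap.sum(axis=0) <= aln.n_otus / 2
    return aln.select_columns(np.where(keep)[0])


def third_position_treatment(aln: Alignment, mode: str) -> Alignment:
    """Handle fast-evolving third codon positions.

    ``include``: identity. ``ry``: recode A,G -> R and C,T -> Y at
    position-3 columns, flagging them as binary (transition differences at
    those positions then carry no signal). ``exclude``: drop position-3
    columns.
    """
    if aln.codon_positions is None:
        raise ValueError("alignment lacks codon-position annotation")
    if mode not in ("include", "ry", "exclude"):
        raise ValueError(f"unknown mode {mode!r}")
    third = aln.codon_positions == 3
    if mode == "include":
        return aln.select_columns(np.arange(aln.n_cols))
    if mode == "exclude":
        return aln.select_columns(np.where(~third)[0])
    matrix = aln.matrix.copy()
    sub = matrix[:, third]
    for src, dst in RY_MAP.items():
        sub[sub == src] = dst
    matrix[:, third] = sub
    binary = np.zeros(aln.n_cols, dtype=bool) if aln.binary_cols is None \
        else aln.binary_cols.copy()
    binary |= third
    return Alignment(list(aln.otus), matrix, aln.alphabet,
                     aln.codon_positions.copy(),
                     None if aln.partition_map is None else aln.partition_map.copy(),
                     binary)


def concatenate(alns: list[Alignment], partition_names: list[str] | None = None
                ) -> Alignment:
    """Concatenate gene alignments into a supermatrix, matching OTUs by
    label. OTU sets must be identical (order may differ); the partition map
    records the source gene of every column."""
    if not alns:
        raise ValueError("nothing to concatenate")
    ref_otus = sorted(alns[0].otus)
    for i, a in enumerate(alns):
        missing = set(ref_otus) ^ set(a.otus)
        if missing:
            raise ValueError(
                f"OTU set mismatch in alignment {i}: {sorted(missing)}"
            )
    alphabets = {a.alphabet for a in alns}
    if len(alphabets) != 1:
        raise ValueError(f"mixed alphabets: {sorted(alphabets)}")
    if partition_names is None:
        partition_names = [f"part{i + 1}" for i in range(len(alns))]
    mats, cps, pms, bins = [], [], [], []
    any_cp = any(a.codon_positions is not None for a in alns)
    for a, name in zip(alns, partition_names):
        a = a.reorder(ref_otus)
        mats.append(a.matrix)
        if any_cp:
            cps.append(a.codon_positions if a.codon_positions is not None
                       else np.zeros(a.n_cols, dtype=int))
        if a.partition_map is not None:
            pms.append(a.partition_map)
        else:
            pms.append(np.array([name] * a.n_cols, dtype=object))
        bins.append(a.binary_cols if a.binary_cols is not None
                    else np.zeros(a.n_cols, dtype=bool))
    binary = np.concatenate(bins)
    return Alignment(
        otus=ref_otus,
        matrix=np.concatenate(mats, axis=1),
        alphabet=alns[0].alphabet,
        codon_positions=np.concatenate(cps) if any_cp else None,
        partition_map=np.concatenate(pms),
        binary_cols=binary if binary.any() else None,
    )
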