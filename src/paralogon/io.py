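"""Readers and writers for the standard formats the pipeline consumes:
GFF3/BED gene annotations, FASTA sequence stores, newick trees and TSV
marker-hit tables.

GFF3 coordinates are kept 1-based inclusive; BED is converted from 0-based
half-open on read and back on write, so both round-trip exactly.
"""
from __future__ import annotations

import csv
from collections import Counter
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    GeneAnnotation,
    MarkerHit,
    Region,
    SequenceStore,
    SpeciesTree,
    ValidationError,
)


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotations(path, dialect: str = "gff3", species_id: str | None = None,
                     region_lengths: dict[str, int] | None = None) -> list[Region]:
    """Read gene annotations into :class:`Region` objects.

    Parameters
    ----------
    path:
        Annotation file.
    dialect:
        ``"gff3"`` (1-based inclusive; ``gene`` features only, others ignored)
        or ``"bed"`` (BED6, 0-based half-open, converted on read).
    species_id:
        Species label attached to every region; defaults to the file stem.
    region_lengths:
        Optional region lengths in bp. GFF3 ``##sequence-region`` pragmas are
        honoured; otherwise the maximum gene end is used.
    """
    path = Path(path)
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    species = species_id if species_id is not None else path.stem
    lengths: dict[str, int] = dict(region_lengths or {})
    genes_by_region: dict[str, list[GeneAnnotation]] = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if dialect == "gff3":
                if line.startswith("##sequence-region"):
                    parts = line.split()
                    if len(parts) >= 4:
                        lengths.setdefault(parts[1], int(parts[3]))
                    continue
                if line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise ParseError(
                        f"{path.name}:{lineno}: expected 9 tab-separated GFF3 "
                        f"fields, got {len(fields)}"
                    )
                seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
                if ftype != "gene":
                    continue
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError as exc:
                    raise ParseError(f"{path.name}:{lineno}: non-integer coordinate") from exc
                attr = _parse_gff3_attributes(attrs)
                gene_id = attr.get("ID") or attr.get("Name")
                if gene_id is None:
                    raise ParseError(f"{path.name}:{lineno}: gene feature lacks ID attribute")
                protein_id = attr.get("protein_id")
            else:  # bed
                if line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 6:
                    raise ParseError(
                        f"{path.name}:{lineno}: expected >=6 BED fields, got {len(fields)}"
                    )
                seqid, start_s, end_s, gene_id, _score, strand = fields[:6]
                try:
                    # BED: 0-based half-open -> 1-based inclusive
                    start, end = int(start_s) + 1, int(end_s)
                except ValueError as exc:
                    raise ParseError(f"{path.name}:{lineno}: non-integer coordinate") from exc
                protein_id = None
            if end < start:
                raise ValidationError(
                    f"{path.name}:{lineno}: end {end} < start {start} for gene {gene_id}"
                )
            try:
                gene = GeneAnnotation(gene_id, seqid, start, end, strand, protein_id)
            except ValidationError as exc:
                raise ValidationError(f"{path.name}:{lineno}: {exc}") from exc
            genes_by_region.setdefault(seqid, []).append(gene)

    regions = []
    for region_id, genes in genes_by_region.items():
        length = lengths.get(region_id, max(g.end for g in genes))
        regions.append(Region(region_id, species, length, genes))
    return regions


def write_annotations(regions: list[Region], path, dialect: str = "gff3") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for region in regions:
                fh.write(f"##sequence-region {region.region_id} 1 {region.length}\n")
            for region in regions:
                for g in region.genes:
                    attrs = f"ID={g.gene_id}"
                    if g.protein_id:
                        attrs += f";protein_id={g.protein_id}"
                    fh.write(
                        f"{region.region_id}\tparalogon\tgene\t{g.start}\t{g.end}"
                        f"\t.\t{g.strand}\t.\t{attrs}\n"
                    )
        elif dialect == "bed":
            for region in regions:
                for g in region.genes:
                    fh.write(
                        f"{region.region_id}\t{g.start - 1}\t{g.end}\t{g.gene_id}"
                        f"\t0\t{g.strand}\n"
                    )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_fasta(path, alphabet: str = "protein") -> SequenceStore:
    """Read FASTA into a :class:`SequenceStore`; duplicate ids are an error."""
    records = list(SeqIO.parse(str(path), "fasta"))
    counts = Counter(r.id for r in records)
    dupes = sorted(k for k, n in counts.items() if n > 1)
    if dupes:
        raise ParseError(f"duplicate FASTA ids: {dupes}")
    return SequenceStore({r.id: str(r.seq) for r in records}, alphabet=alphabet)


def write_fasta(store: SequenceStore, path) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="")
               for sid, seq in store.sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_newick(path) -> SpeciesTree:
    return SpeciesTree.read(path)


def read_marker_hits(path) -> list[MarkerHit]:
    """TSV with header: marker_id, scaffold_id, identity, linkage_group."""
    hits = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            hits.append(
                MarkerHit(
                    marker_id=row["marker_id"],
                    scaffold_id=row["scaffold_id"],
                    identity=float(row["identity"]),
                    linkage_group=row["linkage_group"],
                )
            )
    return hits
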