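"""Macrosynteny dot plots and microsynteny presence/order matrices.

The presence/order matrix records, for each (species, synteny copy) row, which
genes of a reference panel are present, their rank order along the region and
their orientation relative to the reference — the object the duplication
scenario inference consumes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .anchoring import Anchor
from .model import Region

PRESENT, ABSENT, UNKNOWN = "P", "A", "U"


@dataclass(frozen=True)
class DotPlotRecord:
    """One anchored gene pair positioned by bp midpoints in both regions."""

    gene_ref: str
    gene_query: str
    x_mid: int
    y_mid: int
    identity: float
    orientation: str  # "same" | "opposite"


def build_dotplot(
    region_ref: Region, region_query: Region, anchors: list[Anchor]
) -> list[DotPlotRecord]:
    """One record per anchor; midpoints are the floor of the mean of the gene
    start and end, orientation is strand agreement."""
    ref_genes = {g.gene_id: g for g in region_ref.genes}
    query_genes = {g.gene_id: g for g in region_query.genes}
    records = []
    for anchor in anchors:
        # anchors may be given as (query, ref) or (ref, query); resolve by id
        if anchor.gene_a in ref_genes and anchor.gene_b in query_genes:
            gr, gq = ref_genes[anchor.gene_a], query_genes[anchor.gene_b]
        elif anchor.gene_b in ref_genes and anchor.gene_a in query_genes:
            gr, gq = ref_genes[anchor.gene_b], query_genes[anchor.gene_a]
        else:
            raise KeyError(
                f"anchor ({anchor.gene_a}, {anchor.gene_b}) names genes absent "
                f"from regions {region_ref.region_id}/{region_query.region_id}"
            )
        orientation = "same" if gr.strand == gq.strand else "opposite"
        records.append(
            DotPlotRecord(gr.gene_id, gq.gene_id, gr.midpoint, gq.midpoint,
                          anchor.identity, orientation)
        )
    return records


def macrosynteny_stats(records: list[DotPlotRecord]) -> dict[str, int]:
    n_same = sum(1 for r in records if r.orientation == "same")
    return {
        "n_anchored": len(records),
        "n_same_orientation": n_same,
        "n_opposite": len(records) - n_same,
    }


@dataclass
class MatrixRow:
    """One (species, synteny copy) row of a presence/order matrix."""

    row_id: str
    species_id: str
    copy_label: str  # "#1" / "#2" ("ref" allowed for an unduplicated outgroup)
    states: dict[str, str]  # panel gene -> P/A/U
    ranks: dict[str, int] = field(default_factory=dict)  # present genes only
    orientations: dict[str, str] = field(default_factory=dict)  # "+"/"-"
    edge_genes: set[str] = field(default_factory=set)  # predicted at region end

    def present_in_order(self) -> list[str]:
        present = [g for g, s in self.states.items() if s == PRESENT]
        return sorted(present, key=lambda g: self.ranks.get(g, 0))


@dataclass
class PresenceOrderMatrix:
    """Per-region presence, order and orientation of a reference gene panel."""

    panel: list[str]
    rows: list[MatrixRow]

    def __post_init__(self) -> None:
        for row in self.rows:
            ranks = [row.ranks[g] for g in row.states if row.states[g] == PRESENT
                     and g in row.ranks]
            if len(ranks) != len(set(ranks)):
                raise ValueError(f"row {row.row_id}: duplicate ranks")

    def row(self, species_id: str, copy_label: str) -> MatrixRow:
        for r in self.rows:
            if r.species_id == species_id and r.copy_label == copy_label:
                return r
        raise KeyError((species_id, copy_label))

    def species(self) -> list[str]:
        seen: list[str] = []
        for r in self.rows:
            if r.species_id not in seen:
                seen.append(r.species_id)
        return seen

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("row_id\tspecies\tcopy\t" + "\t".join(self.panel) + "\n")
            for row in self.rows:
                cells = []
                for g in self.panel:
                    state = row.states.get(g, ABSENT)
                    if state == PRESENT:
                        cell = f"P:{row.ranks.get(g, 0)}:{row.orientations.get(g, '+')}"
                        if g in row.edge_genes:
                            cell += ":edge"
                    else:
                        cell = state
                    cells.append(cell)
                fh.write(f"{row.row_id}\t{row.species_id}\t{row.copy_label}\t"
                         + "\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "PresenceOrderMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            panel = header[3:]
            rows = []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                row_id, species, copy = fields[:3]
                states, ranks, orients, edges = {}, {}, {}, set()
                for g, cell in zip(panel, fields[3:]):
                    if cell.startswith("P"):
                        parts = cell.split(":")
                        states[g] = PRESENT
                        ranks[g] = int(parts[1])
                        orients[g] = parts[2]
                        if "edge" in parts[3:]:
                            edges.add(g)
                    else:
                        states[g] = cell
                rows.append(MatrixRow(row_id, species, copy, states, ranks,
                                      orients, edges))
        return cls(panel, rows)


def _assign_copy_labels(regions_by_species: dict[str, list[tuple[Region, int]]]
                        ) -> dict[str, str]:
    """Label each species' regions #1/#2 by descending panel-gene content."""
    labels = {}
    for _species, items in regions_by_species.items():
        ordered = sorted(items, key=lambda t: (-t[1], t[0].region_id))
        for i, (region, _n) in enumerate(ordered):
            labels[region.region_id] = f"#{i + 1}"
    return labels


def extract_microsynteny(
    panel: list[str],
    regions: list[Region],
    anchors_by_region: dict[str, list[Anchor]],
    copy_labels: dict[str, str] | None = None,
    boundary_unknown: bool = False,
) -> PresenceOrderMatrix:
    """Build a presence/order matrix over ``panel`` from per-region anchor
    sets against the reference.

    Each anchor links a region gene (``gene_a``) to a reference panel gene
    (``gene_b``). A panel gene anchored twice within one region is an error
    (candidate tandem duplication, outside the model). With
    ``boundary_unknown`` enabled, a missing panel gene distal to all present
    genes is marked unknown instead of absent when its extrapolated position
    falls beyond the region boundary.

    Copy labels default to #1 for the fullest region per species, #2 next.
    """
    rows = []
    per_species: dict[str, list[tuple[Region, int]]] = {}
    mapped: dict[str, dict[str, object]] = {}
    for region in regions:
        anchors = anchors_by_region.get(region.region_id, [])
        gene_map: dict[str, object] = {}
        for anchor in anchors:
            if anchor.gene_b not in panel:
                continue
            if anchor.gene_b in gene_map:
                raise ValueError(
                    f"panel gene {anchor.gene_b} anchored twice in region "
                    f"{region.region_id} (candidate tandem duplication)"
                )
            gene_map[anchor.gene_b] = (region.gene(anchor.gene_a), anchor)
        mapped[region.region_id] = gene_map
        per_species.setdefault(region.species_id, []).append((region, len(gene_map)))

    if copy_labels is None:
        copy_labels = _assign_copy_labels(per_species)

    for region in regions:
        gene_map = mapped[region.region_id]
        states = {g: (PRESENT if g in gene_map else ABSENT) for g in panel}
        present = sorted(gene_map, key=lambda g: gene_map[g][0].start)
        ranks = {g: i + 1 for i, g in enumerate(present)}
        orients = {g: ("+" if gene_map[g][1].same_strand else "-") for g in gene_map}
        edge_genes = set()
        if present:
            first, last = gene_map[present[0]][0], gene_map[present[-1]][0]
            margin = _median_gap(gene_map, present)
            if first.start <= margin:
                edge_genes.add(present[0])
            if region.length - last.end <= margin:
                edge_genes.add(present[-1])
            if boundary_unknown:
                _flag_boundary_unknowns(panel, states, present, gene_map,
                                        region, margin)
        rows.append(
            MatrixRow(
                row_id=region.region_id,
                species_id=region.species_id,
                copy_label=copy_labels[region.region_id],
                states=states,
                ranks=ranks,
                orientations=orients,
                edge_genes=edge_genes,
            )
        )
    return PresenceOrderMatrix(list(panel), rows)


def _median_gap(gene_map, present: list[str]) -> int:
    gaps = [
        gene_map[present[i + 1]][0].start - gene_map[present[i]][0].end
        for i in range(len(present) - 1)
    ]
    gaps = sorted(g for g in gaps if g > 0)
    if not gaps:
        return 10_000
    return gaps[len(gaps) // 2]


def _flag_boundary_unknowns(panel, states, present, gene_map, region, gap) -> None:
    """Mark panel genes beyond the outermost present gene as unknown when
    their extrapolated position falls off the region end."""
    if not present:
        return
    idx = {g: i for i, g in enumerate(panel)}
    present_idx = sorted(idx[g] for g in present)
    lo, hi = present_idx[0], present_idx[-1]
    first_gene = min(present, key=lambda g: gene_map[g][0].start)
    last_gene = max(present, key=lambda g: gene_map[g][0].end)
    for g in panel:
        if states[g] != ABSENT:
            continue
        i = idx[g]
        if i > hi:
            steps = i - hi
            expected = gene_map[last_gene][0].end + steps * gap
            if expected > region.length:
                states[g] = UNKNOWN
        elif i < lo:
            steps = lo - i
            expected = gene_map[first_gene][0].start - steps * gap
            if expected < 1:
                states[g] = UNKNOWN


def order_conservation(row: MatrixRow, panel: list[str]) -> int:
    """Number of order-conserved genes: the longest common subsequence
    between the row's present-gene order and the panel order (orientation
    ignored). Equals the present-gene count iff the observed order is a
    subsequence of the panel order."""
    observed = row.present_in_order()
    return _lcs_length(observed, panel)


def _lcs_length(a: list[str], b: list[str]) -> int:
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0] * (len(b) + 1)
        for j, y in enumerate(b, start=1):
            cur[j] = prev[j - 1] + 1 if x == y else max(prev[j], cur[j - 1])
        prev = cur
    return prev[-1]


def duplicated_template(matrix: PresenceOrderMatrix) -> list[str]:
    """Smallest contiguous panel interval containing every gene observed on
    any copy-#2 row — the minimal segment the duplication must have copied."""
    on_two = {
        g
        for row in matrix.rows
        if row.copy_label == "#2"
        for g, s in row.states.items()
        if s == PRESENT
    }
    if not on_two:
        raise ValueError("no duplication evidence: no gene present on any #2 row")
    idx = [matrix.panel.index(g) for g in on_two]
    return matrix.panel[min(idx): max(idx) + 1]


def shared_loss_pattern(
    matrix: PresenceOrderMatrix,
    species_pair: tuple[str, str],
    template: list[str] | None = None,
) -> set[str]:
    """Genes of the duplicated template lost in the same single-copy pattern
    in both species.

    A gene qualifies when its (copy-#1 state, copy-#2 state) pattern is
    identical in the two species and contains exactly one absence. Genes with
    an unknown state in any row are excluded, as are genes outside the
    duplicated template (never doubled, so a copy-#2 absence there is not a
    loss).
    """
    sp1, sp2 = species_pair
    rows = {}
    for sp in (sp1, sp2):
        for copy in ("#1", "#2"):
            rows[(sp, copy)] = matrix.row(sp, copy)  # KeyError if missing
    if template is None:
        template = duplicated_template(matrix)
    out = set()
    for g in template:
        pats = {}
        for sp in (sp1, sp2):
            pats[sp] = (rows[(sp, "#1")].states.get(g, ABSENT),
                        rows[(sp, "#2")].states.get(g, ABSENT))
        if any(UNKNOWN in p for p in pats.values()):
            continue
        if pats[sp1] == pats[sp2] and pats[sp1].count(ABSENT) == 1:
            out.add(g)
    return out


def dotplot_to_tsv(records: list[DotPlotRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_ref\tgene_query\tx_mid\ty_mid\tidentity\torientation\n")
        for r in records:
            fh.write(f"{r.gene_ref}\t{r.gene_query}\t{r.x_mid}\t{r.y_mid}"
                     f"\t{r.identity:.2f}\t{r.orientation}\n")
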