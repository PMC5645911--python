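"""Annotation-support filters: marker-based linkage-group assignment and
gene-model length validation against reference proteins.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .model import MarkerHit, Region, SequenceStore


@dataclass
class LinkageAssignmentReport:
    """Outcome of marker-based linkage-group assignment.

    ``assignments`` maps scaffold id -> linkage group for cleanly assigned
    scaffolds; ``split_required`` maps scaffold id -> {linkage group -> marker
    ids} for scaffolds whose surviving markers name two or more groups and
    must be split; ``excluded_markers`` lists markers dropped for hitting
    multiple scaffolds; ``low_identity_hits`` counts hits below threshold.
    """

    assignments: dict[str, str] = field(default_factory=dict)
    split_required: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    excluded_markers: list[str] = field(default_factory=list)
    low_identity_hits: int = 0


def assign_linkage_groups(
    hits: list[MarkerHit],
    regions: list[Region] | None = None,
    min_identity: float = 90.0,
) -> LinkageAssignmentReport:
    """Assign scaffolds to linkage groups from single-hit markers.

    Hits below ``min_identity`` are dropped first; markers that then still hit
    two or more scaffolds are excluded entirely; each scaffold inherits the
    linkage group of its surviving markers, and scaffolds whose markers name
    two or more groups are flagged for splitting rather than assigned.
    The result is independent of input hit order.
    """
    known = {r.region_id for r in regions} if regions is not None else None
    kept = []
    low = 0
    for h in sorted(hits, key=lambda h: (h.marker_id, h.scaffold_id)):
        if known is not None and h.scaffold_id not in known:
            raise KeyError(f"marker {h.marker_id} hits unknown scaffold {h.scaffold_id}")
        if h.identity >= min_identity:
            kept.append(h)
        else:
            low += 1

    by_marker: dict[str, set[str]] = {}
    for h in kept:
        by_marker.setdefault(h.marker_id, set()).add(h.scaffold_id)
    multi = {m for m, scafs in by_marker.items() if len(scafs) > 1}

    report = LinkageAssignmentReport(
        excluded_markers=sorted(multi), low_identity_hits=low
    )
    by_scaffold: dict[str, dict[str, list[str]]] = {}
    for h in kept:
        if h.marker_id in multi:
            continue
        by_scaffold.setdefault(h.scaffold_id, {}).setdefault(
            h.linkage_group, []
        ).append(h.marker_id)
    for scaffold, lg_map in sorted(by_scaffold.items()):
        if len(lg_map) == 1:
            report.assignments[scaffold] = next(iter(lg_map))
        else:
            report.split_required[scaffold] = {
                lg: sorted(markers) for lg, markers in sorted(lg_map.items())
            }
    return report


def filter_by_length_agreement(
    predicted: SequenceStore,
    reference: SequenceStore,
    pairs: list[tuple[str, str]],
    max_rel_diff: float = 0.05,
) -> list[tuple[str, str]]:
    """Keep (predicted, reference) pairs whose length difference relative to
    the reference is strictly below ``max_rel_diff``.

    A pair at exactly the threshold is rejected (strict ``<``); the reference
    length is the denominator. Zero-length references are an error.
    """
    kept = []
    for pred_id, ref_id in pairs:
        lp = len(predicted[pred_id])
        lr = len(reference[ref_id])
        if lr == 0:
            raise ValueError(f"reference {ref_id} has zero length")
        if abs(lp - lr) / lr < max_rel_diff:
            kept.append((pred_id, ref_id))
    return kept
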