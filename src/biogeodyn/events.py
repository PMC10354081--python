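"""Classification of species-level biogeographic events.

Given a dated tree whose nodes carry MAP geographic ranges (tips from the
coding table, internal nodes from a DEC reconstruction), two event classes
are extracted for the focal area (the biome under assembly):

* ``dispersal_in`` — an edge whose child range contains the focal area while
  the parent range does not: the lineage colonised the biome somewhere along
  that branch.
* ``in_situ`` — an internal node whose range and both children's ranges all
  contain the focal area: a speciation event inside the biome.

Timing intervals use node-age HPDs where available: a dispersal event could
have happened anywhere on its branch, so its window runs from the parent
node's older HPD bound to the child node's younger bound; an in-situ event
is pinned to its node's HPD. Dispersal events are optionally annotated with
a source region from a finer (e.g. 13-region) reconstruction of the same
tree; widespread/mixed parent ranges leave the source ambiguous and such
events are excluded from per-source tallies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .dec import AncestralRangeTable, AreaScheme
from .treeio import CodingTable, DatedTree, EventRecord, EventTable, TreeValidationError

__all__ = [
    "classify_events",
    "attach_timing",
    "assign_source",
    "assign_sources",
    "tally",
    "EventTally",
]


def _node_ranges(tree: DatedTree, anc: AncestralRangeTable,
                 tips: CodingTable) -> dict[int, frozenset[str]]:
    """MAP range (as an area set) for every node of the tree."""
    code_sets = tips.as_sets()
    out: dict[int, frozenset[str]] = {}
    maps = anc.map_ranges()
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            lab = tree.labels[v]
            if lab not in code_sets:
                raise TreeValidationError(f"tip {lab!r} has no range coding")
            out[v] = code_sets[lab]
        else:
            if v not in maps:
                raise TreeValidationError(f"internal node {v} has no MAP range")
            out[v] = frozenset(maps[v])
    return out


def attach_timing(tree: DatedTree, event_type: str, node_id: int
                  ) -> tuple[float, tuple[float, float]]:
    """Point age and credibility window for an event.

    dispersal_in: point age = child-node age; window = (parent older HPD
    bound or parent age, child younger HPD bound or child age) — the full
    span of the branch on which the gain occurred, widened by dating
    uncertainty. in_situ: node age and node HPD (degenerate if absent).
    """
    age = float(tree.ages[node_id])
    if event_type == "in_situ":
        older, younger = tree.hpd.get(node_id, (age, age))
        return age, (float(older), float(younger))
    if event_type == "dispersal_in":
        p = int(tree.parent[node_id])
        if p < 0:
            raise TreeValidationError("dispersal event on the root has no stem edge")
        parent_age = float(tree.ages[p])
        if parent_age < age - 1e-9:
            raise TreeValidationError(
                f"parent {p} younger than child {node_id}")
        older = float(tree.hpd.get(p, (parent_age, parent_age))[0])
        younger = float(tree.hpd.get(node_id, (age, age))[1])
        return age, (older, max(younger, 0.0))
    raise ValueError(f"unknown event type {event_type!r}")


def classify_events(tree: DatedTree, anc: AncestralRangeTable,
                    tips: CodingTable, scheme: AreaScheme) -> EventTable:
    """Extract dispersal-into-focal-area and in-situ diversification events
    from MAP node ranges, sorted old to young."""
    focal = scheme.focal_area
    ranges = _node_ranges(tree, anc, tips)
    records: list[EventRecord] = []
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p >= 0 and focal in ranges[v] and focal not in ranges[p]:
            age, (older, younger) = attach_timing(tree, "dispersal_in", v)
            records.append(EventRecord(tree.clade_id, "dispersal_in", v,
                                       age, older, younger))
        if not tree.is_tip(v) and focal in ranges[v]:
            c1, c2 = tree.children[v][0], tree.children[v][-1]
            if len(tree.children[v]) == 2 and focal in ranges[c1] and focal in ranges[c2]:
                age, (older, younger) = attach_timing(tree, "in_situ", v)
                records.append(EventRecord(tree.clade_id, "in_situ", v,
                                           age, older, younger))
    records.sort(key=lambda e: (-e.point_age, e.event_type, e.node_id))
    return EventTable(records, provenance={"clade_id": tree.clade_id,
                                           "focal_area": focal})


def assign_source(event: EventRecord, tree: DatedTree,
                  anc_regions: AncestralRangeTable, tips_regions: CodingTable,
                  scheme_regions: AreaScheme) -> str:
    """Source region of a dispersal event from a finer regional scheme.

    The source is the parent's range with the focal area removed, reported
    only when it names a single region; widespread or mixed parents yield
    the empty string (ambiguous).
    """
    if scheme_regions.focal_area not in scheme_regions.areas:
        raise ValueError("regional scheme lacks the focal area")
    if event.event_type != "dispersal_in":
        raise ValueError("sources apply to dispersal events only")
    ranges = _node_ranges(tree, anc_regions, tips_regions)
    p = int(tree.parent[event.node_id])
    non_focal = ranges[p] - {scheme_regions.focal_area}
    if len(non_focal) == 1:
        return next(iter(non_focal))
    return ""


def assign_sources(events: EventTable, tree: DatedTree,
                   anc_regions: AncestralRangeTable, tips_regions: CodingTable,
                   scheme_regions: AreaScheme) -> EventTable:
    """Annotate every dispersal event of one clade with its source region."""
    out = []
    for e in events:
        if e.event_type == "dispersal_in" and e.clade_id == tree.clade_id:
            src = assign_source(e, tree, anc_regions, tips_regions, scheme_regions)
            out.append(EventRecord(e.clade_id, e.event_type, e.node_id,
                                   e.point_age, e.older_bound, e.younger_bound, src))
        else:
            out.append(e)
    return EventTable(out, provenance=dict(events.provenance))


@dataclass
class EventTally:
    """Event counts by type and by source region."""

    n_dispersal: int
    n_insitu: int
    n_total: int
    ratio: float  # dispersal / in-situ; inf when no in-situ events
    by_source: dict[str, int]
    pct_by_source: dict[str, float]

    @property
    def ratio_defined(self) -> bool:
        return math.isfinite(self.ratio)

    @classmethod
    def from_counts(cls, n_dispersal: int, n_insitu: int,
                    by_source: dict[str, int] | None = None) -> "EventTally":
        by_source = dict(by_source or {})
        n_assigned = sum(by_source.values())
        pct = ({r: 100.0 * n / n_assigned for r, n in by_source.items()}
               if n_assigned else {})
        ratio = (n_dispersal / n_insitu if n_insitu
                 else (math.inf if n_dispersal else math.nan))
        return cls(n_dispersal=n_dispersal, n_insitu=n_insitu,
                   n_total=n_dispersal + n_insitu, ratio=ratio,
                   by_source=by_source, pct_by_source=pct)

    def summary(self) -> str:
        ratio = f"{self.ratio:.2f}" if self.ratio_defined else "undefined (no in-situ events)"
        lines = [
            "Biogeographic event tally",
            "=" * 40,
            f"dispersal into focal area: {self.n_dispersal}",
            f"in situ diversification:   {self.n_insitu}",
            f"total events:              {self.n_total}",
            f"dispersal : in-situ ratio: {ratio}",
        ]
        if self.by_source:
            lines.append("source regions (assigned dispersals):")
            for region, n in sorted(self.by_source.items(),
                                    key=lambda kv: (-kv[1], kv[0])):
                lines.append(f"  {region}: {n} ({self.pct_by_source[region]:.1f}%)")
        return "\n".join(lines)


def tally(events: EventTable) -> EventTally:
    """Counts, dispersal:in-situ ratio and per-source-region percentages
    (over source-assigned dispersal events only)."""
    n_disp = sum(1 for e in events if e.event_type == "dispersal_in")
    n_ins = sum(1 for e in events if e.event_type == "in_situ")
    by_source: dict[str, int] = {}
    for e in events:
        if e.event_type == "dispersal_in" and e.source_region:
            by_source[e.source_region] = by_source.get(e.source_region, 0) + 1
    n_assigned = sum(by_source.values())
    pct = {r: 100.0 * n / n_assigned for r, n in by_source.items()} if n_assigned else {}
    ratio = n_disp / n_ins if n_ins else (math.inf if n_disp else math.nan)
    return EventTally(n_dispersal=n_disp, n_insitu=n_ins, n_total=n_disp + n_ins,
                      ratio=ratio, by_source=by_source, pct_by_source=pct)
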