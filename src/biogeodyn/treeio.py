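"""Dated-tree, coding-table and event-table I/O.

All ages are in Ma before present (larger = older). Trees are read with
dendropy (newick, or NEXUS with BEAST-style bracketed node comments carrying
``height_95%_HPD`` annotations) and normalised into :class:`DatedTree`, a
flat array-indexed structure that the likelihood and simulation code
traverses directly.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DatedTree",
    "CodingTable",
    "EventRecord",
    "EventTable",
    "TreeFormatError",
    "TreeValidationError",
    "read_tree",
    "write_tree",
    "read_coding",
    "write_coding",
    "read_event_table",
    "write_event_table",
]

AGE_TOL = 1e-9

EVENT_COLUMNS = [
    "clade_id",
    "event_type",
    "node_id",
    "point_age",
    "older_bound",
    "younger_bound",
    "source_region",
]


class TreeFormatError(ValueError):
    """Raised when an input file cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when parsed data violates a structural invariant."""


@dataclass
class DatedTree:
    """Rooted dated tree with node ages and optional 95% HPD intervals.

    Nodes are indexed 0..n-1. ``parent[i]`` is the parent index (-1 for the
    root), ``children[i]`` the child indices in input order, ``labels[i]``
    the tip label (None for internal nodes) and ``ages[i]`` the node age in
    Ma before present. ``hpd`` maps node index -> (older, younger) bounds.
    """

    parent: np.ndarray
    children: list[list[int]]
    labels: list[str | None]
    ages: np.ndarray
    hpd: dict[int, tuple[float, float]] = field(default_factory=dict)
    clade_id: str = ""
    hpd_flags: list[str] = field(default_factory=list)

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeValidationError(f"expected exactly one root, found {len(roots)}")
        return int(roots[0])

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def tips(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def branch_length(self, i: int) -> float:
        p = self.parent[i]
        return 0.0 if p < 0 else float(self.ages[p] - self.ages[i])

    def tip_label_map(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for i in self.tips():
            lab = self.labels[i]
            if lab is None:
                raise TreeValidationError(f"tip node {i} has no label")
            if lab in out:
                raise TreeValidationError(f"duplicate tip label {lab!r}")
            out[lab] = i
        return out

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        _ = self.root
        for i in range(self.n_nodes):
            if not self.is_tip(i) and len(self.children[i]) < 2:
                raise TreeValidationError(f"internal node {i} has a single child")
            p = self.parent[i]
            if p >= 0 and self.ages[p] < self.ages[i] - AGE_TOL:
                raise TreeValidationError(
                    f"node {i} (age {self.ages[i]:.6g}) is older than its "
                    f"parent {p} (age {self.ages[p]:.6g})"
                )
            if self.ages[i] < -AGE_TOL:
                raise TreeValidationError(f"node {i} has negative age {self.ages[i]}")
        for i, (older, younger) in self.hpd.items():
            if older < younger:
                raise TreeValidationError(
                    f"node {i} HPD has older bound {older} < younger bound {younger}"
                )

    # -- conversion --------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, clade_id: str = "") -> "DatedTree":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        children: list[list[int]] = [[] for _ in range(n)]
        labels: list[str | None] = [None] * n
        depth = np.zeros(n)
        hpd: dict[int, tuple[float, float]] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                bl = nd.edge.length if nd.edge.length is not None else 0.0
                if bl < 0:
                    raise TreeValidationError(f"negative branch length {bl}")
                depth[i] = depth[p] + bl
            if nd.is_leaf():
                labels[i] = nd.taxon.label if nd.taxon is not None else nd.label
            for ann in nd.annotations:
                if ann.name == "height_95%_HPD":
                    lo, hi = (float(v) for v in ann.value)
                    hpd[i] = (max(lo, hi), min(lo, hi))
        max_depth = depth.max() if n else 0.0
        ages = max_depth - depth
        ages[np.abs(ages) < AGE_TOL] = 0.0
        out = cls(parent=parent, children=children, labels=labels, ages=ages,
                  hpd=hpd, clade_id=clade_id)
        out._flag_pathological_hpds()
        out.validate()
        return out

    def _flag_pathological_hpds(self) -> None:
        # HPDs excluding the point age are flagged, not rejected
        self.hpd_flags = [
            f"node {i}: HPD ({o:.6g}, {y:.6g}) excludes point age {self.ages[i]:.6g}"
            for i, (o, y) in sorted(self.hpd.items())
            if not (o + AGE_TOL >= self.ages[i] >= y - AGE_TOL)
        ]

    def to_newick(self, include_hpd: bool = False) -> str:
        def render(i: int) -> str:
            if self.is_tip(i):
                s = _quote_label(self.labels[i] or f"t{i}")
            else:
                s = "(" + ",".join(render(c) for c in self.children[i]) + ")"
            if include_hpd and i in self.hpd:
                o, y = self.hpd[i]
                s += f"[&height_95%_HPD={{{y:.12g},{o:.12g}}}]"
            if self.parent[i] >= 0:
                s += f":{self.branch_length(i):.12g}"
            return s

        return render(self.root) + ";"


def _quote_label(label: str) -> str:
    if re.search(r"[\s(),:;\[\]']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_tree(path: str, format: str = "newick", clade_id: str | None = None) -> DatedTree:
    """Read a dated tree from a newick or NEXUS file.

    Branch lengths are interpreted as Ma; node ages are recovered from
    root-to-tip path lengths with the deepest tip at 0 Ma. BEAST-style
    ``height_95%_HPD`` node comments (NEXUS dialect) become HPD intervals;
    all other comments are ignored.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    try:
        tree = dendropy.Tree.get(
            path=path,
            schema=format,
            extract_comment_metadata=True,
            suppress_internal_node_taxa=True,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise TreeFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    if clade_id is None:
        clade_id = re.sub(r"\.(nwk|newick|tre|trees|nex|nexus|txt)$", "",
                          path.rsplit("/", 1)[-1])
    return DatedTree.from_dendropy(tree, clade_id=clade_id)


def write_tree(tree: DatedTree, path: str, format: str = "newick",
               node_labels: dict[int, str] | None = None) -> None:
    """Write a tree as newick or as a minimal NEXUS trees block.

    NEXUS output carries ``height_95%_HPD`` node comments so HPDs round-trip;
    plain newick keeps topology and ages only. ``node_labels`` (e.g. MAP
    ranges) are appended to internal nodes as label comments.
    """
    include_hpd = format == "nexus"
    nwk = tree.to_newick(include_hpd=include_hpd)
    if node_labels:
        # annotate by rebuilding: simplest is a labelled render
        nwk = _newick_with_labels(tree, node_labels, include_hpd)
    with open(path, "w") as fh:
        if format == "nexus":
            fh.write("#NEXUS\nBegin trees;\n")
            fh.write(f"tree {tree.clade_id or 'TREE1'} = [&R] {nwk}\n")
            fh.write("End;\n")
        elif format == "newick":
            fh.write(nwk + "\n")
        else:
            raise ValueError(f"unknown tree format {format!r}")


def _newick_with_labels(tree: DatedTree, node_labels: dict[int, str],
                        include_hpd: bool) -> str:
    def render(i: int) -> str:
        if tree.is_tip(i):
            s = _quote_label(tree.labels[i] or f"t{i}")
        else:
            s = "(" + ",".join(render(c) for c in tree.children[i]) + ")"
            if i in node_labels:
                s += _quote_label(node_labels[i])
        if include_hpd and i in tree.hpd:
            o, y = tree.hpd[i]
            s += f"[&height_95%_HPD={{{y:.12g},{o:.12g}}}]"
        if tree.parent[i] >= 0:
            s += f":{tree.branch_length(i):.12g}"
        return s

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# coding tables


@dataclass
class CodingTable:
    """Species -> range/state code over a declared ordered alphabet."""

    codes: dict[str, str]
    alphabet: tuple[str, ...]
    scheme_id: str = ""

    def __post_init__(self) -> None:
        alpha = set(self.alphabet)
        bad = {sp: code for sp, code in self.codes.items()
               if not code or any(sym not in alpha for sym in code)}
        if bad:
            rows = ", ".join(f"{sp}={code!r}" for sp, code in sorted(bad.items()))
            raise TreeValidationError(
                f"codes outside alphabet {''.join(self.alphabet)!r}: {rows}")

    def as_sets(self) -> dict[str, frozenset[str]]:
        return {sp: frozenset(code) for sp, code in self.codes.items()}

    def max_observed_range_size(self) -> int:
        return max(len(set(code)) for code in self.codes.values())

    def __len__(self) -> int:
        return len(self.codes)


def _read_delimited(path: str) -> pd.DataFrame:
    with open(path) as fh:
        head = fh.read(4096)
    sep = "\t" if "\t" in head.splitlines()[0] else ("," if "," in head.splitlines()[0] else r"\s+")
    return pd.read_csv(path, sep=sep, comment="#", dtype=str, engine="python")


def read_coding(path: str, alphabet: tuple[str, ...] | str,
                scheme_id: str = "") -> CodingTable:
    """Read a two-column (species, code) delimited table."""
    df = _read_delimited(path)
    if df.shape[1] < 2:
        raise TreeFormatError(f"{path}: expected two columns (species, code)")
    species = df.iloc[:, 0].astype(str)
    codes = df.iloc[:, 1].astype(str)
    dups = species[species.duplicated()].tolist()
    if dups:
        raise TreeValidationError(f"duplicate species in {path}: {dups}")
    return CodingTable(codes=dict(zip(species, codes)),
                       alphabet=tuple(alphabet), scheme_id=scheme_id)


def write_coding(table: CodingTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("species\tcode\n")
        for sp, code in table.codes.items():
            fh.write(f"{sp}\t{code}\n")


# ---------------------------------------------------------------------------
# event tables


@dataclass(frozen=True)
class EventRecord:
    """A classified biogeographic event with timing interval.

    ``event_type`` is "dispersal_in" (range gain of the focal area on a
    branch; node_id is the child node) or "in_situ" (speciation within the
    focal area; node_id is the parent node). The interval is the closed age
    window [older, younger] in which the event could have occurred.
    """

    clade_id: str
    event_type: str
    node_id: int
    point_age: float
    older_bound: float
    younger_bound: float
    source_region: str = ""

    def __post_init__(self) -> None:
        if self.event_type not in ("dispersal_in", "in_situ"):
            raise TreeValidationError(f"unknown event type {self.event_type!r}")
        if self.older_bound < self.younger_bound:
            raise TreeValidationError(
                f"event at node {self.node_id}: older bound {self.older_bound} "
                f"< younger bound {self.younger_bound}")
        if self.younger_bound < 0:
            raise TreeValidationError("negative younger bound")
        if self.event_type == "in_situ" and self.source_region:
            raise TreeValidationError("source_region only applies to dispersal_in")

    @property
    def interval(self) -> tuple[float, float]:
        return (self.older_bound, self.younger_bound)


@dataclass
class EventTable:
    """A list of classified events plus provenance metadata."""

    events: list[EventRecord] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(e.clade_id, e.node_id, e.event_type) for e in self.events]
        if len(set(keys)) != len(keys):
            seen: set = set()
            dups = []
            for k in keys:
                if k in seen:
                    dups.append(k)
                seen.add(k)
            raise TreeValidationError(f"duplicate events: {dups}")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def of_type(self, event_type: str) -> "EventTable":
        return EventTable([e for e in self.events if e.event_type == event_type],
                          provenance=dict(self.provenance))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[e.clade_id, e.event_type, e.node_id, e.point_age,
              e.older_bound, e.younger_bound, e.source_region]
             for e in self.events],
            columns=EVENT_COLUMNS,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   provenance: dict[str, str] | None = None) -> "EventTable":
        events = [
            EventRecord(
                clade_id=str(r.clade_id),
                event_type=str(r.event_type),
                node_id=int(r.node_id),
                point_age=float(r.point_age),
                older_bound=float(r.older_bound),
                younger_bound=float(r.younger_bound),
                source_region="" if pd.isna(r.source_region) else str(r.source_region),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(events, provenance=provenance or {})


def write_event_table(table: EventTable, path: str) -> None:
    """Write a tab-delimited event table with a provenance header."""
    with open(path, "w") as fh:
        for key, val in table.provenance.items():
            fh.write(f"# {key}: {val}\n")
        table.to_frame().to_csv(fh, sep="\t", index=False)


def read_event_table(path: str) -> EventTable:
    provenance: dict[str, str] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition(":")
                if val:
                    provenance[key.strip()] = val.strip()
            else:
                body.write(line)
    body.seek(0)
    df = pd.read_csv(body, sep="\t", dtype={"source_region": str},
                     keep_default_na=False)
    if df.empty:
        return EventTable([], provenance=provenance)
    return EventTable.from_frame(df, provenance=provenance)
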