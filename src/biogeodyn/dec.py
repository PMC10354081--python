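"""Dispersal-extinction-cladogenesis (DEC) range evolution model.

The model tracks a lineage's geographic range (a non-empty subset of a fixed
area set, capped at ``max_range_size`` areas) as a continuous-time Markov
chain along branches — range expansion at rate ``d`` per (occupied, free)
area pair, scaled by per-time-slice dispersal multipliers, and per-area
extirpation at rate ``e`` — combined with cladogenetic range inheritance at
nodes: a singleton range is copied to both daughters; a widespread range is
split either by subset sympatry (one daughter keeps the full range, the
other a single constituent area) or by vicariance into a singleton plus the
remainder, all unordered splitting scenarios being equally likely. The empty
(null) range is an absorbing anagenetic state representing lineage-wide
extirpation; it is excluded from observations and from cladogenesis.

The public surface follows the Model/Results idiom: build a
:class:`DECModel` from a dated tree, a range coding table and an
:class:`AreaScheme`; ``fit()`` maximises the likelihood over (d, e) and
returns a :class:`DECResults` from which marginal ancestral ranges are
obtained. Thin functional wrappers (:func:`dec_loglik`, :func:`fit_dec`,
:func:`ancestral_ranges`) cover one-shot use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .treeio import CodingTable, DatedTree, TreeValidationError

__all__ = [
    "AreaScheme",
    "DECParams",
    "StateSpace",
    "AncestralRangeTable",
    "DECModel",
    "DECResults",
    "build_state_space",
    "anagenetic_rate_matrix",
    "cladogenesis_distribution",
    "dec_loglik",
    "fit_dec",
    "ancestral_ranges",
]


@dataclass(frozen=True)
class DECParams:
    """Free rates of the DEC model: expansion ``d`` and extirpation ``e``
    (events per Ma)."""

    d: float
    e: float

    def __post_init__(self) -> None:
        if self.d < 0 or self.e < 0:
            raise ValueError(f"DEC rates must be non-negative, got d={self.d}, e={self.e}")


@dataclass
class AreaScheme:
    """Ordered area set with focal area, range-size cap and time-stratified
    dispersal multipliers.

    ``slice_boundaries`` are ages (Ma) strictly decreasing toward the
    present; ``multipliers`` holds one square matrix per time slice, ordered
    oldest slice first (length = number of boundaries + 1). ``None``
    multipliers mean no scaling (all ones).
    """

    areas: tuple[str, ...]
    focal_area: str
    max_range_size: int | None = None
    slice_boundaries: tuple[float, ...] = ()
    multipliers: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.areas = tuple(self.areas)
        if len(set(self.areas)) != len(self.areas):
            raise ValueError("duplicate area symbols")
        if self.focal_area not in self.areas:
            raise ValueError(f"focal area {self.focal_area!r} not in areas")
        if self.max_range_size is not None:
            if not (1 <= self.max_range_size <= len(self.areas)):
                raise ValueError(
                    f"max_range_size {self.max_range_size} outside "
                    f"[1, {len(self.areas)}]")
        b = self.slice_boundaries
        if any(b[i] <= b[i + 1] for i in range(len(b) - 1)) or any(x <= 0 for x in b):
            raise ValueError("slice boundaries must be positive and strictly decreasing")
        if self.multipliers is not None:
            k = len(self.areas)
            self.multipliers = [np.asarray(m, dtype=float) for m in self.multipliers]
            if len(self.multipliers) != len(b) + 1:
                raise ValueError("need one multiplier matrix per time slice")
            for m in self.multipliers:
                if m.shape != (k, k):
                    raise ValueError(f"multiplier matrix must be {k}x{k}")
                if (m < 0).any() or (m > 1).any():
                    raise ValueError("multipliers must lie in [0, 1]")

    @property
    def n_slices(self) -> int:
        return len(self.slice_boundaries) + 1

    def multiplier(self, slice_index: int) -> np.ndarray:
        if self.multipliers is None:
            return np.ones((len(self.areas), len(self.areas)))
        return self.multipliers[slice_index]

    def slice_of(self, age: float) -> int:
        # slice k spans (b_k, b_{k-1}]; ages above the first boundary are slice 0
        return int(sum(age <= b for b in self.slice_boundaries))

    def resolved(self, coding: CodingTable | None = None) -> "AreaScheme":
        """Return a copy with ``max_range_size`` filled in from the coding
        (maximum number of areas observed among extant taxa)."""
        if self.max_range_size is not None:
            return self
        if coding is None:
            raise ValueError("max_range_size unset and no coding given")
        return AreaScheme(self.areas, self.focal_area,
                          coding.max_observed_range_size(),
                          self.slice_boundaries, self.multipliers)


class StateSpace:
    """Ordered DEC state space over bitmask-encoded ranges.

    State 0 is the null (empty) range; observable states follow, ordered by
    range size then lexicographically by area order.
    """

    def __init__(self, scheme: AreaScheme):
        scheme = scheme.resolved()
        self.scheme = scheme
        self.areas = scheme.areas
        k = len(self.areas)
        masks = [m for m in range(1, 1 << k)
                 if bin(m).count("1") <= scheme.max_range_size]
        masks.sort(key=lambda m: (bin(m).count("1"),
                                  tuple(i for i in range(k) if m >> i & 1)))
        self.masks: list[int] = [0] + masks
        self.index: dict[int, int] = {m: i for i, m in enumerate(self.masks)}
        self.n_states = len(self.masks)
        self.focal_bit = 1 << self.areas.index(scheme.focal_area)
        self._clado: dict[int, list[tuple[int, int, float]]] = {}

    # -- labels ------------------------------------------------------------

    def label(self, state: int) -> str:
        mask = self.masks[state]
        return "".join(a for i, a in enumerate(self.areas) if mask >> i & 1)

    def labels(self, observable_only: bool = True) -> list[str]:
        start = 1 if observable_only else 0
        return [self.label(i) for i in range(start, self.n_states)]

    def state_of(self, code: str | frozenset) -> int:
        mask = 0
        for sym in code:
            try:
                mask |= 1 << self.areas.index(sym)
            except ValueError:
                raise TreeValidationError(f"unknown area symbol {sym!r}") from None
        if mask not in self.index:
            raise TreeValidationError(
                f"range {''.join(sorted(code))!r} exceeds max_range_size "
                f"{self.scheme.max_range_size}")
        return self.index[mask]

    # -- anagenesis --------------------------------------------------------

    def rate_matrix(self, params: DECParams, slice_index: int = 0) -> np.ndarray:
        """Anagenetic generator: expansion d*sum of multipliers from occupied
        areas, extirpation e per occupied area (singletons decay to null)."""
        m = self.scheme.multiplier(slice_index)
        k = len(self.areas)
        Q = np.zeros((self.n_states, self.n_states))
        for si, G in enumerate(self.masks):
            if G == 0:
                continue  # null range is absorbing
            occ = [i for i in range(k) if G >> i & 1]
            if len(occ) < self.scheme.max_range_size:
                for j in range(k):
                    if G >> j & 1:
                        continue
                    target = G | (1 << j)
                    if target in self.index:
                        Q[si, self.index[target]] = params.d * sum(m[i, j] for i in occ)
            for i in occ:
                Q[si, self.index[G & ~(1 << i)]] += params.e
        np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
        return Q

    # -- cladogenesis ------------------------------------------------------

    def cladogenesis(self, state: int) -> list[tuple[int, int, float]]:
        """Unordered splitting scenarios (x, y, weight) for an observable
        parent state, weights summing to 1. x <= y in state order; the two
        daughters are exchangeable."""
        if state == 0:
            raise ValueError("null range cannot speciate")
        if state not in self._clado:
            G = self.masks[state]
            pairs: set[tuple[int, int]] = set()
            bits = [1 << i for i in range(len(self.areas)) if G >> i & 1]
            if len(bits) == 1:
                pairs.add((state, state))
            else:
                for b in bits:
                    s = self.index[b]
                    pairs.add(tuple(sorted((s, state))))          # subset sympatry
                    rest = self.index[G & ~b]
                    pairs.add(tuple(sorted((s, rest))))           # vicariance
            w = 1.0 / len(pairs)
            self._clado[state] = [(x, y, w) for x, y in sorted(pairs)]
        return self._clado[state]

    def cladogenesis_ordered(self, state: int) -> list[tuple[int, int, float]]:
        """Ordered daughter scenarios with equal probabilities summing to 1
        (both orderings of each asymmetric unordered scenario)."""
        unordered = self.cladogenesis(state)
        ordered = []
        for x, y, _ in unordered:
            ordered.append((x, y))
            if x != y:
                ordered.append((y, x))
        p = 1.0 / len(ordered)
        return [(x, y, p) for x, y in ordered]


def build_state_space(scheme: AreaScheme) -> list[str]:
    """Observable range labels, ordered by size then area order."""
    return StateSpace(scheme).labels()


def anagenetic_rate_matrix(scheme: AreaScheme, params: DECParams,
                           slice_index: int = 0) -> pd.DataFrame:
    space = StateSpace(scheme)
    Q = space.rate_matrix(params, slice_index)
    labels = ["" if i == 0 else space.label(i) for i in range(space.n_states)]
    return pd.DataFrame(Q, index=labels, columns=labels)


def cladogenesis_distribution(parent_range: str, scheme: AreaScheme
                              ) -> dict[tuple[str, str], float]:
    """Ordered daughter-range scenarios and their probabilities."""
    space = StateSpace(scheme)
    s = space.state_of(parent_range)
    return {(space.label(x), space.label(y)): p
            for x, y, p in space.cladogenesis_ordered(s)}


# ---------------------------------------------------------------------------
# likelihood machinery


def _branch_segments(child_age: float, parent_age: float,
                     scheme: AreaScheme) -> list[tuple[float, int]]:
    """Split a branch at slice boundaries; return (duration, slice_index)
    ordered oldest segment first."""
    cuts = [b for b in scheme.slice_boundaries if child_age < b < parent_age]
    edges = [parent_age] + cuts + [child_age]
    segs = []
    for hi, lo in zip(edges[:-1], edges[1:]):
        segs.append((hi - lo, scheme.slice_of((hi + lo) / 2)))
    return segs


class DECModel:
    """DEC likelihood over a dated tree with coded tip ranges.

    Parameters
    ----------
    tree : DatedTree
        Binary rooted ultrametric (or tip-dated) tree, ages in Ma.
    ranges : CodingTable
        Tip range codes over the scheme's area alphabet.
    scheme : AreaScheme
        Areas, focal area, range cap and dispersal multipliers. An unset
        ``max_range_size`` is resolved to the largest observed tip range.
    """

    def __init__(self, tree: DatedTree, ranges: CodingTable, scheme: AreaScheme):
        tree.validate()
        for i in range(tree.n_nodes):
            if not tree.is_tip(i) and len(tree.children[i]) != 2:
                raise TreeValidationError(
                    "DEC cladogenesis requires a binary tree "
                    f"(node {i} has {len(tree.children[i])} children)")
        self.tree = tree
        self.scheme = scheme.resolved(ranges)
        self.space = StateSpace(self.scheme)
        self.tip_state: dict[int, int] = {}
        code_sets = ranges.as_sets()
        missing = []
        for i in tree.tips():
            lab = tree.labels[i]
            if lab not in code_sets:
                missing.append(lab)
            else:
                self.tip_state[i] = self.space.state_of(code_sets[lab])
        if missing:
            raise TreeValidationError(f"tips without range coding: {missing}")

    # -- internals ---------------------------------------------------------

    def _branch_matrices(self, params: DECParams) -> dict[int, np.ndarray]:
        Qs = [self.space.rate_matrix(params, k) for k in range(self.scheme.n_slices)]
        out: dict[int, np.ndarray] = {}
        cache: dict[tuple[int, float], np.ndarray] = {}
        for i in range(self.tree.n_nodes):
            if self.tree.parent[i] < 0:
                continue
            P = None
            for dt, sl in _branch_segments(self.tree.ages[i],
                                           self.tree.ages[self.tree.parent[i]],
                                           self.scheme):
                key = (sl, round(dt, 12))
                if key not in cache:
                    cache[key] = expm(Qs[sl] * dt)
                P = cache[key] if P is None else P @ cache[key]
            out[i] = np.eye(self.space.n_states) if P is None else P
        return out

    def _combine(self, state: int, L1: np.ndarray, L2: np.ndarray) -> float:
        tot = 0.0
        for x, y, w in self.space.cladogenesis(state):
            if x == y:
                tot += w * L1[x] * L2[x]
            else:
                tot += w * (L1[x] * L2[y] + L1[y] * L2[x])
        return tot

    def _down_pass(self, params: DECParams):
        """Post-order conditional likelihoods with rescaling.

        Returns (D at nodes, D at branch bottoms, branch matrices,
        log scaling total).
        """
        P = self._branch_matrices(params)
        S = self.space.n_states
        D = np.zeros((self.tree.n_nodes, S))
        Dbot = np.zeros((self.tree.n_nodes, S))
        logscale = 0.0
        for v in self.tree.postorder():
            if self.tree.is_tip(v):
                D[v, self.tip_state[v]] = 1.0
            else:
                c1, c2 = self.tree.children[v]
                for s in range(1, S):
                    D[v, s] = self._combine(s, Dbot[c1], Dbot[c2])
            m = D[v].max()
            if m <= 0:
                raise FloatingPointError(
                    f"zero conditional likelihood at node {v}; data and model "
                    "are incompatible")
            D[v] /= m
            logscale += np.log(m)
            if self.tree.parent[v] >= 0:
                Dbot[v] = P[v] @ D[v]
        return D, Dbot, P, logscale

    # -- public ------------------------------------------------------------

    def loglik(self, params: DECParams) -> tuple[float, pd.Series]:
        """Log-likelihood under a flat root prior over observable ranges,
        plus the per-root-state conditional likelihoods (relative scale)."""
        D, _, _, logscale = self._down_pass(params)
        root = D[self.tree.root].copy()
        root[0] = 0.0
        mean = root[1:].mean()
        ll = np.log(mean) + logscale
        cond = pd.Series(root[1:] * np.exp(logscale) if logscale > -700 else root[1:],
                         index=self.space.labels())
        return float(ll), cond

    def fit(self, start: tuple[float, float] = (0.1, 0.01),
            bounds: tuple = ((1e-8, 10.0), (1e-8, 10.0))) -> "DECResults":
        """Maximum-likelihood estimate of (d, e) by bounded L-BFGS-B from a
        fixed pair of starting points (deterministic)."""

        def nll(x):
            try:
                ll, _ = self.loglik(DECParams(*x))
            except FloatingPointError:
                return 1e12
            return -ll

        starts = [start, (0.5, 0.1)]
        best = None
        for x0 in starts:
            res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        if not np.isfinite(best.fun) or best.fun >= 1e12:
            raise FloatingPointError(
                "non-finite DEC likelihood at optimum; consider rescaling ages")
        params = DECParams(*best.x)
        return DECResults(model=self, params=params, llf=-float(best.fun),
                          converged=bool(best.success), nit=int(best.nit))

    def ancestral_ranges(self, params: DECParams) -> "AncestralRangeTable":
        """Marginal ancestral range probabilities for every internal node
        (down-pass/up-pass algorithm) with MAP ranges."""
        D, Dbot, P, _ = self._down_pass(params)
        S = self.space.n_states
        U = np.zeros((self.tree.n_nodes, S))
        root = self.tree.root
        U[root, 1:] = 1.0 / (S - 1)
        for v in self.tree.preorder():
            if self.tree.is_tip(v):
                continue
            c1, c2 = self.tree.children[v]
            for child, sib in ((c1, c2), (c2, c1)):
                Utop = np.zeros(S)
                for s in range(1, S):
                    if U[v, s] == 0:
                        continue
                    for x, y, w in self.space.cladogenesis(s):
                        if x == y:
                            Utop[x] += U[v, s] * w * Dbot[sib][x]
                        else:
                            Utop[x] += U[v, s] * w * Dbot[sib][y]
                            Utop[y] += U[v, s] * w * Dbot[sib][x]
                U[child] = P[child].T @ Utop
                m = U[child].max()
                if m > 0:
                    U[child] /= m
        internal = [v for v in range(self.tree.n_nodes) if not self.tree.is_tip(v)]
        probs = np.zeros((len(internal), S - 1))
        for r, v in enumerate(internal):
            post = D[v] * U[v]
            post[0] = 0.0
            tot = post.sum()
            if tot <= 0:
                raise FloatingPointError(f"zero marginal at node {v}")
            probs[r] = post[1:] / tot
        return AncestralRangeTable(node_ids=internal,
                                   range_labels=self.space.labels(),
                                   probs=probs)


@dataclass
class AncestralRangeTable:
    """Per-internal-node marginal probabilities over observable ranges."""

    node_ids: list[int]
    range_labels: list[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("node probabilities must sum to 1")

    def map_range(self, node_id: int) -> str:
        # deterministic tie-break: first state in state order
        row = self.probs[self.node_ids.index(node_id)]
        return self.range_labels[int(np.argmax(row))]

    def map_ranges(self) -> dict[int, str]:
        return {v: self.range_labels[int(np.argmax(self.probs[r]))]
                for r, v in enumerate(self.node_ids)}

    def probability(self, node_id: int, range_label: str) -> float:
        return float(self.probs[self.node_ids.index(node_id),
                                self.range_labels.index(range_label)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=self.range_labels)
        df.insert(0, "node_id", self.node_ids)
        df["map_range"] = [self.range_labels[int(np.argmax(p))] for p in self.probs]
        return df


@dataclass
class DECResults:
    """Fitted DEC model: rate estimates, log-likelihood and reconstructions."""

    model: DECModel
    params: DECParams
    llf: float
    converged: bool
    nit: int
    _anc: AncestralRangeTable | None = field(default=None, repr=False)

    def ancestral_ranges(self) -> AncestralRangeTable:
        if self._anc is None:
            self._anc = self.model.ancestral_ranges(self.params)
        return self._anc

    def summary(self) -> str:
        sch = self.model.scheme
        lines = [
            "DEC model fit",
            "=" * 40,
            f"clade:             {self.model.tree.clade_id or '<unnamed>'}",
            f"tips:              {len(self.model.tree.tips())}",
            f"areas:             {''.join(sch.areas)} (focal {sch.focal_area})",
            f"max range size:    {sch.max_range_size}",
            f"time slices:       {sch.n_slices}",
            f"d (expansion/Ma):  {self.params.d:.6g}",
            f"e (extirpation/Ma):{self.params.e:.6g}",
            f"log-likelihood:    {self.llf:.6f}",
            f"converged:         {self.converged} ({self.nit} iterations)",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers


def dec_loglik(tree: DatedTree, ranges: CodingTable, scheme: AreaScheme,
               params: DECParams) -> tuple[float, pd.Series]:
    return DECModel(tree, ranges, scheme).loglik(params)


def fit_dec(tree: DatedTree, ranges: CodingTable, scheme: AreaScheme) -> DECResults:
    return DECModel(tree, ranges, scheme).fit()


def ancestral_ranges(tree: DatedTree, ranges: CodingTable, scheme: AreaScheme,
                     params: DECParams) -> AncestralRangeTable:
    return DECModel(tree, ranges, scheme).ancestral_ranges(params)
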