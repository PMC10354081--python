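"""Ancestral habitat-state reconstruction (open vs closed vegetation).

Species are scored as living in open habitat (no canopy: tundra, grassland,
alpine), closed habitat (forest understory) or both. Ancestral states are
reconstructed under a two-state continuous-time Markov (Mk) model — equal
rates or all-rates-different — with "both" treated as an ambiguous
observation (partial likelihood 1 for either state). Rates are estimated by
maximum likelihood and node marginals come from the standard two-pass
pruning algorithm under a flat root prior.

Combined with a classified event table, :func:`preadaptation_report` asks
whether lineages dispersing into the focal biome descended from open-habitat
ancestors (the pre-adaptation hypothesis): for each dispersal event it
reports the MAP habitat of the parent node, calling it only when the
marginal probability clears a threshold (default 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar, minimize

from .treeio import DatedTree, EventTable, TreeValidationError

__all__ = ["HabitatCoding", "MkModel", "MkResults", "ancestral_habitat",
           "preadaptation_report", "PreadaptationReport", "read_habitat_coding"]

STATES = ("open", "closed")
AMBIGUOUS = "both"


@dataclass
class HabitatCoding:
    """Species -> habitat state in {open, closed, both}."""

    states: dict[str, str]

    def __post_init__(self) -> None:
        bad = {sp: st for sp, st in self.states.items()
               if st not in STATES + (AMBIGUOUS,)}
        if bad:
            raise TreeValidationError(f"unknown habitat states: {bad}")

    def partial(self, species: str) -> np.ndarray:
        st = self.states[species]
        if st == AMBIGUOUS:
            return np.ones(2)
        return np.eye(2)[STATES.index(st)]

    def __len__(self) -> int:
        return len(self.states)


def read_habitat_coding(path: str) -> HabitatCoding:
    df = pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise TreeValidationError(f"{path}: expected two columns (species, state)")
    sp = df.iloc[:, 0].astype(str)
    if sp.duplicated().any():
        raise TreeValidationError(f"duplicate species in {path}")
    return HabitatCoding(dict(zip(sp, df.iloc[:, 1].str.strip().str.lower())))


def _pmat(q01: float, q10: float, t: float) -> np.ndarray:
    """Transition matrix of the 2-state chain, closed form."""
    s = q01 + q10
    if s <= 0:
        return np.eye(2)
    pi0, pi1 = q10 / s, q01 / s
    e = np.exp(-s * t)
    return np.array([[pi0 + pi1 * e, pi1 - pi1 * e],
                     [pi0 - pi0 * e, pi1 + pi0 * e]])


class MkModel:
    """Two-state Mk likelihood for habitat evolution on a dated tree.

    model "equal-rates" fits a single transition rate; "all-rates-different"
    fits open->closed and closed->open separately. Every tip must be coded.
    """

    def __init__(self, tree: DatedTree, coding: HabitatCoding,
                 model: str = "equal-rates"):
        if model not in ("equal-rates", "all-rates-different"):
            raise ValueError(f"unknown Mk model {model!r}")
        tree.validate()
        if len(tree.tips()) < 2:
            raise TreeValidationError("need at least 2 tips")
        self.tree = tree
        self.coding = coding
        self.kind = model
        missing = [tree.labels[i] for i in tree.tips()
                   if tree.labels[i] not in coding.states]
        if missing:
            raise TreeValidationError(f"tips without habitat coding: {missing}")

    def _passes(self, q01: float, q10: float):
        tree = self.tree
        P = {i: _pmat(q01, q10, tree.branch_length(i))
             for i in range(tree.n_nodes) if tree.parent[i] >= 0}
        D = np.zeros((tree.n_nodes, 2))
        Dbot = np.zeros((tree.n_nodes, 2))
        logscale = 0.0
        for v in tree.postorder():
            if tree.is_tip(v):
                D[v] = self.coding.partial(tree.labels[v])
            else:
                D[v] = np.prod([Dbot[c] for c in tree.children[v]], axis=0)
            m = D[v].max()
            if m <= 0:
                raise FloatingPointError(f"zero partial likelihood at node {v}")
            D[v] /= m
            logscale += np.log(m)
            if tree.parent[v] >= 0:
                Dbot[v] = P[v] @ D[v]
        return D, Dbot, P, logscale

    def loglik(self, q01: float, q10: float) -> float:
        D, _, _, logscale = self._passes(q01, q10)
        return float(np.log(D[self.tree.root].mean()) + logscale)

    def fit(self) -> "MkResults":
        """ML rate estimate(s), deterministic.

        Rates are optimised on the log scale after a coarse log-spaced grid
        scan: the likelihood saturates for fast rates, so a naive bounded
        search over a wide linear interval can stall on the flat shoulder.
        """
        span = max(float(self.tree.ages.max()), 1e-6)
        lo, hi = np.log10(1e-6 / span), np.log10(100.0 / span)
        grid = np.linspace(lo, hi, 25)
        if self.kind == "equal-rates":
            vals = [-self.loglik(10.0 ** u, 10.0 ** u) for u in grid]
            i = int(np.argmin(vals))
            a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
            res = minimize_scalar(lambda u: -self.loglik(10.0 ** u, 10.0 ** u),
                                  bounds=(a, b), method="bounded")
            if res.fun > vals[i]:
                q01 = q10 = float(10.0 ** grid[i])
                llf = -float(vals[i])
            else:
                q01 = q10 = float(10.0 ** res.x)
                llf = -float(res.fun)
            ok = True
        else:
            gvals = [[-self.loglik(10.0 ** u, 10.0 ** v) for v in grid]
                     for u in grid]
            gi, gj = np.unravel_index(int(np.argmin(gvals)), (len(grid), len(grid)))
            starts = [(grid[gi], grid[gj]), (np.log10(0.1 / span),) * 2]
            best = None
            for x0 in starts:
                r = minimize(lambda x: -self.loglik(10.0 ** x[0], 10.0 ** x[1]),
                             x0, method="L-BFGS-B", bounds=[(lo, hi)] * 2)
                if best is None or r.fun < best.fun:
                    best = r
            q01, q10 = (float(10.0 ** v) for v in best.x)
            llf, ok = -float(best.fun), bool(best.success)
        return MkResults(model=self, q01=q01, q10=q10, llf=llf, converged=ok)

    def ancestral_states(self, q01: float, q10: float) -> pd.DataFrame:
        """Marginal open/closed probabilities and MAP state per internal node."""
        tree = self.tree
        D, Dbot, P, _ = self._passes(q01, q10)
        U = np.zeros((tree.n_nodes, 2))
        U[tree.root] = 0.5
        for v in tree.preorder():
            if tree.is_tip(v):
                continue
            for c in tree.children[v]:
                sib_prod = np.prod([Dbot[s] for s in tree.children[v] if s != c],
                                   axis=0)
                U[c] = P[c].T @ (U[v] * sib_prod)
                m = U[c].max()
                if m > 0:
                    U[c] /= m
        rows = []
        for v in range(tree.n_nodes):
            if tree.is_tip(v):
                continue
            post = D[v] * U[v]
            post = post / post.sum()
            rows.append({"node_id": v, "p_open": post[0], "p_closed": post[1],
                         "map_state": STATES[int(np.argmax(post))]})
        return pd.DataFrame(rows)


@dataclass
class MkResults:
    """Fitted Mk habitat model."""

    model: MkModel
    q01: float  # open -> closed rate (per Ma)
    q10: float  # closed -> open rate (per Ma)
    llf: float
    converged: bool
    _anc: pd.DataFrame | None = field(default=None, repr=False)

    def ancestral_states(self) -> pd.DataFrame:
        if self._anc is None:
            self._anc = self.model.ancestral_states(self.q01, self.q10)
        return self._anc

    def summary(self) -> str:
        return "\n".join([
            "Mk habitat model fit",
            "=" * 40,
            f"model:              {self.model.kind}",
            f"tips:               {len(self.model.tree.tips())}",
            f"open->closed rate:  {self.q01:.6g} /Ma",
            f"closed->open rate:  {self.q10:.6g} /Ma",
            f"log-likelihood:     {self.llf:.6f}",
            f"converged:          {self.converged}",
        ])


def ancestral_habitat(tree: DatedTree, coding: HabitatCoding,
                      model: str = "equal-rates") -> tuple[MkResults, pd.DataFrame]:
    """Fit the Mk model and return (results, per-node state table)."""
    res = MkModel(tree, coding, model=model).fit()
    return res, res.ancestral_states()


@dataclass
class PreadaptationReport:
    """Per-dispersal-event ancestral habitat calls."""

    table: pd.DataFrame
    threshold: float

    @property
    def n_events(self) -> int:
        return len(self.table)

    @property
    def fraction_open(self) -> float:
        if not self.n_events:
            return float("nan")
        return float((self.table["call"] == "open").mean())

    def summary(self) -> str:
        counts = self.table["call"].value_counts().to_dict()
        return (f"{self.n_events} dispersal events; ancestral habitat calls "
                f"(threshold {self.threshold}): "
                + ", ".join(f"{k}={v}" for k, v in sorted(counts.items()))
                + f"; fraction open = {self.fraction_open:.2f}")


def preadaptation_report(tree: DatedTree, anc_habitat: pd.DataFrame,
                         events: EventTable, threshold: float = 0.8
                         ) -> PreadaptationReport:
    """Ancestral habitat of the parent node of every dispersal event.

    The call is the MAP state when its marginal probability reaches
    ``threshold``, else "ambiguous".
    """
    anc = anc_habitat.set_index("node_id")
    rows = []
    for e in events:
        if e.event_type != "dispersal_in" or e.clade_id != tree.clade_id:
            continue
        p = int(tree.parent[e.node_id])
        if p not in anc.index:
            raise TreeValidationError(
                f"event node {e.node_id}: parent {p} missing from habitat "
                "reconstruction (mismatched trees?)")
        p_open = float(anc.loc[p, "p_open"])
        map_state = str(anc.loc[p, "map_state"])
        p_map = max(p_open, 1 - p_open)
        call = map_state if p_map >= threshold else "ambiguous"
        rows.append({"clade_id": e.clade_id, "node_id": e.node_id,
                     "parent_node": p, "point_age": e.point_age,
                     "p_open": p_open, "map_state": map_state, "call": call})
    cols = ["clade_id", "node_id", "parent_node", "point_age",
            "p_open", "map_state", "call"]
    return PreadaptationReport(table=pd.DataFrame(rows, columns=cols),
                               threshold=threshold)
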