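import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from biogeodyn import AreaScheme, CodingTable, read_tree
from biogeodyn.dec import StateSpace, _branch_segments


@pytest.fixture
def two_area_scheme():
    return AreaScheme(areas=("A", "B"), focal_area="A", max_range_size=2)


@pytest.fixture
def three_area_scheme():
    return AreaScheme(areas=("A", "B", "C"), focal_area="A", max_range_size=3)


@pytest.fixture
def cherry(tmp_path):
    p = tmp_path / "cherry.nwk"
    p.write_text("(a:1.0,b:1.0);\n")
    return read_tree(str(p))


def write_newick(tmp_path, newick, name="t.nwk"):
    p = tmp_path / name
    p.write_text(newick + "\n")
    return str(p)


def coding(mapping, alphabet):
    return CodingTable(dict(mapping), alphabet=tuple(alphabet))


def brute_dec(tree, tip_coding, scheme, params):
    """Independent DEC oracle: explicit enumeration over all internal-node
    state assignments, with per-branch matrix exponentials. Returns
    (log-likelihood, marginal probabilities over observable states per
    internal node)."""
    scheme = scheme.resolved(tip_coding)
    space = StateSpace(scheme)
    S = space.n_states
    P = {}
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        M = np.eye(S)
        for dt, sl in _branch_segments(float(tree.ages[v]),
                                       float(tree.ages[p]), scheme):
            M = M @ expm(space.rate_matrix(params, sl) * dt)
        P[v] = M
    code = tip_coding.as_sets()
    tip_state = {v: space.state_of(code[tree.labels[v]]) for v in tree.tips()}
    internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    total = 0.0
    marg = {v: np.zeros(S) for v in internal}
    for assign in itertools.product(range(1, S), repeat=len(internal)):
        st = dict(zip(internal, assign))
        st.update(tip_state)
        w = 1.0 / (S - 1)  # flat root prior over observable states
        for v in internal:
            c1, c2 = tree.children[v]
            term = 0.0
            for x, y, wu in space.cladogenesis(st[v]):
                if x == y:
                    term += wu * P[c1][x, st[c1]] * P[c2][x, st[c2]]
                else:
                    term += wu * (P[c1][x, st[c1]] * P[c2][y, st[c2]]
                                  + P[c1][y, st[c1]] * P[c2][x, st[c2]])
            w *= term
        total += w
        for v in internal:
            marg[v][st[v]] += w
    return np.log(total), {v: marg[v][1:] / total for v in internal}
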