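import itertools

import numpy as np
import pytest

from iscutrace import seeds as seedlib
from iscutrace.profiles import (
    AMINO_ACIDS,
    SeedAlignment,
    _gap_run_cost,
    build_profile,
)


@pytest.fixture(scope="session")
def iscu_seed():
    return seedlib.iscu_seed()


@pytest.fixture(scope="session")
def iscu_profile(iscu_seed):
    return build_profile(iscu_seed)


@pytest.fixture(scope="session")
def cyay_profile():
    return build_profile(seedlib.cyay_seed())


def random_seed_alignment(rng: np.random.Generator, n_rows: int, width: int) -> SeedAlignment:
    rows = [
        (f"r{i}", "".join(AMINO_ACIDS[j] for j in rng.integers(20, size=width)))
        for i in range(n_rows)
    ]
    return SeedAlignment(rows=rows, reference_row="r0")


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[j] for j in rng.integers(20, size=length))


def brute_force_glocal_score(S: np.ndarray, gap_open: float, gap_extend: float) -> float:
    """Exhaustive enumeration of all glocal alignment paths (tiny instances).

    A path is a strictly increasing set of (query, column) pairs; leading
    and trailing profile deletions are charged as gap runs, query flanks
    are free, and internal insertion/deletion runs are charged separately.
    """
    n, m = S.shape
    best = -_gap_run_cost(m, gap_open, gap_extend)  # empty path: delete everything
    for k in range(1, min(n, m) + 1):
        for qs in itertools.combinations(range(n), k):
            for cs in itertools.combinations(range(m), k):
                sc = sum(S[q, c] for q, c in zip(qs, cs))
                sc -= _gap_run_cost(cs[0], gap_open, gap_extend)
                sc -= _gap_run_cost(m - 1 - cs[-1], gap_open, gap_extend)
                for t in range(k - 1):
                    sc -= _gap_run_cost(qs[t + 1] - qs[t] - 1, gap_open, gap_extend)
                    sc -= _gap_run_cost(cs[t + 1] - cs[t] - 1, gap_open, gap_extend)
                if sc > best:
                    best = sc
    return best


def random_rooted_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary rooted tree by sequential joins, deterministic given rng."""
    import dendropy

    ns = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_leaves):
        nd = dendropy.Node()
        nd.taxon = ns.new_taxon(f"L{i}")
        nd.edge.length = float(rng.uniform(0.1, 1.0))
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.1, 1.0))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nd for t, nd in enumerate(nodes) if t not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree


def brute_force_parsimony(tree, leaf_states: dict[str, bool], dollo: bool) -> int:
    """Minimum change count over all internal labelings (<= 8 leaves).

    In Dollo mode only labelings with exactly one gain are admitted
    (root considered absent above the tree), and the cost is losses + 1.
    """
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    best = None
    for bits in itertools.product([False, True], repeat=len(internals)):
        assign = {id(nd): b for nd, b in zip(internals, bits)}
        for leaf in tree.leaf_node_iter():
            assign[id(leaf)] = leaf_states[leaf.taxon.label]
        gains = losses = 0
        root_state = assign[id(tree.seed_node)]
        if root_state:
            gains += 1  # virtual branch from an absent origin
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            p, c = assign[id(nd.parent_node)], assign[id(nd)]
            if not p and c:
                gains += 1
            elif p and not c:
                losses += 1
        if dollo:
            if gains != 1:
                continue
            cost = losses + 1
        else:
            cost = gains + losses - (1 if root_state else 0)
        if best is None or cost < best:
            best = cost
    return best
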