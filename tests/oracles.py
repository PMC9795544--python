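"""Independent brute-force oracles used by the test suite.

These implementations deliberately share no code with the package: the MCS
oracle enumerates connected common subgraphs explicitly, and the conformal
p-value oracle counts ranks by hand.
"""

from itertools import combinations

import networkx as nx
from networkx.algorithms import isomorphism

_NODE_MATCH = isomorphism.categorical_node_match(["el", "ring"], [None, None])
_EDGE_MATCH = isomorphism.categorical_edge_match(["order", "ring"], [None, None])


def mol_graph(mol) -> nx.Graph:
    g = nx.Graph()
    for a in mol.GetAtoms():
        g.add_node(a.GetIdx(), el=a.GetSymbol(), ring=a.IsInRing())
    for b in mol.GetBonds():
        g.add_edge(
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            order=b.GetBondType(),
            ring=b.IsInRing(),
        )
    return g


def max_common_subgraph_atoms(mol_a, mol_b) -> int:
    """Atom count of the largest connected common subgraph (exhaustive).

    A set of atoms of the smaller molecule is a common subgraph iff some
    spanning tree of its induced subgraph embeds into the other molecule as
    a (non-induced) monomorphism under element, ring-membership and exact
    bond-order matching.  Enumerates atom subsets largest-first.
    """
    ga, gb = mol_graph(mol_a), mol_graph(mol_b)
    if ga.number_of_nodes() > gb.number_of_nodes():
        ga, gb = gb, ga
    nodes = list(ga.nodes)
    for k in range(len(nodes), 0, -1):
        for sub in combinations(nodes, k):
            sg = ga.subgraph(sub)
            if not nx.is_connected(sg):
                continue
            for tree in nx.SpanningTreeIterator(sg):
                gm = isomorphism.GraphMatcher(
                    gb, tree, node_match=_NODE_MATCH, edge_match=_EDGE_MATCH
                )
                if gm.subgraph_is_monomorphic():
                    return k
    return 0


def mcs_distance_oracle(mol_a, mol_b) -> float:
    k = max_common_subgraph_atoms(mol_a, mol_b)
    return 1.0 - k / max(mol_a.GetNumHeavyAtoms(), mol_b.GetNumHeavyAtoms())


def pvalue_oracle(new_score: float, calib: list[float], smoothing: bool = True) -> float:
    """Rank-counting conformal p-value, written independently of the package."""
    if smoothing:
        n_le = sum(1 for s in calib if s <= new_score)
        return (n_le + 1) / (len(calib) + 1)
    n_lt = sum(1 for s in calib if s < new_score)
    return n_lt / len(calib)
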