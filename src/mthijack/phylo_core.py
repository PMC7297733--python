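"""Distances, neighbour joining, newick I/O, parsimony, haplogroup assignment.

Trees are dendropy ``Tree`` objects throughout; tip labels are sample ids
and must be unique.  Neighbour joining is implemented in-package so that
tie-breaking is deterministic (lexicographically smallest pair on equal
Q-criterion).  Ancestral-state parsimony uses a unit-cost Sankoff dynamic
programme (up and down passes), which yields the Fitch minimum-change count
and exact most-parsimonious-reconstruction (MPR) state sets on binary and
multifurcating trees alike, and supports missing tip states.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .variant_store import Variant


@dataclass(frozen=True)
class HaplotypeProfile:
    """A named haplogroup defined by a variant set relative to reference."""

    name: str
    variants: frozenset[Variant]


def profiles_from_mapping(
        profiles: Mapping[str, Iterable[Variant]]) -> list[HaplotypeProfile]:
    return [HaplotypeProfile(n, frozenset(v)) for n, v in profiles.items()]


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def p_distance(profile_a, profile_b, n_sites: int | None = None) -> float:
    """Proportion of differing sites between two samples.

    Accepts either two equal-length sequences (strings) or two variant sets;
    for variant sets the number of differing sites is the size of the
    symmetric difference and ``n_sites`` is required.
    """
    if isinstance(profile_a, str) and isinstance(profile_b, str):
        if len(profile_a) != len(profile_b):
            raise ValueError("sequences must have equal length")
        if n_sites is None:
            n_sites = len(profile_a)
        diffs = sum(a != b for a, b in zip(profile_a, profile_b))
    else:
        if n_sites is None:
            raise ValueError("n_sites is required for variant-set profiles")
        diffs = len(set(profile_a) ^ set(profile_b))
    if n_sites <= 0:
        raise ValueError("n_sites must be > 0")
    return diffs / n_sites


def distance_matrix_from_profiles(
        variant_sets: Mapping[str, Iterable[Variant]]) -> pd.DataFrame:
    """Symmetric-difference distance matrix over samples (counts)."""
    names = sorted(variant_sets)
    sets = {n: set(variant_sets[n]) for n in names}
    mat = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            d = len(sets[a] ^ sets[names[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)


def _validate_distance_matrix(dm: pd.DataFrame) -> None:
    if list(dm.index) != list(dm.columns):
        raise ValueError("distance matrix index/columns must match")
    vals = dm.to_numpy(float)
    if not np.allclose(vals, vals.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if (vals < -1e-12).any() or not np.allclose(np.diag(vals), 0, atol=1e-9):
        raise ValueError("distances must be non-negative with zero diagonal")


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

def nj_tree(dm: pd.DataFrame) -> dendropy.Tree:
    """Neighbour-joining tree (Saitou & Nei) with deterministic tie-break.

    When two pairs minimise the Q-criterion equally, the pair whose sorted
    (minimum-tip-label, ...) key is lexicographically smallest is joined.
    Returns an unrooted tree represented with a trifurcating seed node.
    """
    _validate_distance_matrix(dm)
    labels = list(dm.index)
    if len(labels) < 3:
        raise ValueError("neighbour joining requires >= 3 taxa")

    taxa = dendropy.TaxonNamespace(labels)
    nodes: list[dendropy.Node] = []
    keys: list[str] = []  # min tip label per cluster, for tie-breaking
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
        keys.append(lab)
    d = dm.to_numpy(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        totals = d.sum(axis=1)
        q = (m - 2) * d - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] <= qmin + 1e-12:
                    key = tuple(sorted((keys[i], keys[j])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        dij = d[i, j]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep],
                       dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        new_key = min(keys[i], keys[j])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]

    root = dendropy.Node()
    if len(nodes) == 3:
        d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
        lens = [(d01 + d02 - d12) / 2, (d01 + d12 - d02) / 2,
                (d02 + d12 - d01) / 2]
        for node, length in zip(nodes, lens):
            node.edge.length = length
            root.add_child(node)
    else:  # exactly 2 clusters left (cannot happen for >= 3 taxa input)
        for node in nodes:
            node.edge.length = d[0, 1] / 2
            root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _check_unique_tips(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()
              if leaf.taxon is not None]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")


def read_newick(path: str | Path) -> dendropy.Tree:
    from dendropy.dataio.newickreader import NewickReader

    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels: {exc}") from exc
    _check_unique_tips(tree)
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> Path:
    path = Path(path)
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)
    return path


# ---------------------------------------------------------------------------
# Haplogroup assignment
# ---------------------------------------------------------------------------

def assign_haplotype(sample_variants: Iterable[Variant],
                     profiles: Mapping[str, Iterable[Variant]]
                     ) -> tuple[str, int, bool]:
    """Assign the profile minimising symmetric-difference distance.

    Returns ``(haplotype name, distance, ambiguous)``; ties at the minimum
    set ``ambiguous`` and resolve to the lexicographically smallest name.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    sample = set(sample_variants)
    dists = {name: len(sample ^ set(vs)) for name, vs in profiles.items()}
    best = min(dists.values())
    winners = sorted(n for n, d in dists.items() if d == best)
    return winners[0], best, len(winners) > 1


# ---------------------------------------------------------------------------
# Parsimony (unit-cost Sankoff)
# ---------------------------------------------------------------------------

def _fold(cost: np.ndarray) -> np.ndarray:
    """min_t(cost[t] + [t != s]) for every s, under unit substitution cost."""
    return np.minimum(cost, cost.min() + 1.0)


def sankoff_mpr(tree: dendropy.Tree,
                tip_states: Mapping[str, Hashable | None],
                states: Sequence[Hashable] | None = None):
    """Unit-cost Sankoff DP over a rooted tree with optional missing tips.

    ``tip_states`` maps tip label -> state, or ``None`` for missing data
    (all states allowed at zero cost).  Returns ``(mpr_sets, min_changes)``
    where ``mpr_sets`` maps each node to the frozenset of states it takes
    in at least one most parsimonious reconstruction.
    """
    if states is None:
        states = sorted({s for s in tip_states.values() if s is not None},
                        key=str)
    states = list(states)
    if not states:
        raise ValueError("no observed states")
    idx = {s: i for i, s in enumerate(states)}
    k = len(states)
    big = float(len(tip_states) + len(states) + 10)

    up: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            if label not in tip_states:
                raise ValueError(f"tip {label!r} has no state")
            state = tip_states[label]
            cost = np.zeros(k) if state is None else np.full(k, big)
            if state is not None:
                if state not in idx:
                    raise ValueError(f"state {state!r} not in state list")
                cost[idx[state]] = 0.0
            up[node] = cost
        else:
            up[node] = sum(_fold(up[c]) for c in node.child_nodes())

    root = tree.seed_node
    down: dict[dendropy.Node, np.ndarray] = {root: np.zeros(k)}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        folded = {c: _fold(up[c]) for c in node.child_nodes()}
        total_folded = sum(folded.values())
        for child in node.child_nodes():
            above = down[node] + total_folded - folded[child]
            down[child] = _fold(above)

    min_changes = float(up[root].min())
    mpr: dict[dendropy.Node, frozenset] = {}
    for node in tree.preorder_node_iter():
        total = up[node] + down[node]
        best = total.min()
        mpr[node] = frozenset(states[i] for i in range(k)
                              if total[i] <= best + 1e-9)
    return mpr, int(round(min_changes))


def mpr_reconstruction(tree: dendropy.Tree,
                       tip_states: Mapping[str, Hashable | None],
                       states: Sequence[Hashable] | None = None
                       ) -> dict[dendropy.Node, Hashable]:
    """One canonical most-parsimonious labelling of every node.

    Deterministic tie-breaks: the root takes the lexicographically smallest
    minimal-cost state; children prefer their parent's state on cost ties,
    then the lexicographically smallest state.
    """
    if states is None:
        states = sorted({s for s in tip_states.values() if s is not None},
                        key=str)
    states = list(states)
    idx = {s: i for i, s in enumerate(states)}
    k = len(states)
    big = float(len(tip_states) + k + 10)

    up: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            state = tip_states.get(label)
            cost = np.zeros(k) if state is None else np.full(k, big)
            if state is not None:
                cost[idx[state]] = 0.0
            up[node] = cost
        else:
            up[node] = sum(_fold(up[c]) for c in node.child_nodes())

    chosen: dict[dendropy.Node, Hashable] = {}
    root = tree.seed_node
    best = up[root].min()
    chosen[root] = next(states[i] for i in range(k)
                        if up[root][i] <= best + 1e-9)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = chosen[node.parent_node]
        cost = up[node] + (np.arange(k) != idx[parent_state])
        best = cost.min()
        if cost[idx[parent_state]] <= best + 1e-9:
            chosen[node] = parent_state
        else:
            chosen[node] = next(states[i] for i in range(k)
                                if cost[i] <= best + 1e-9)
    return chosen


def fitch_parsimony(tree: dendropy.Tree,
                    tip_labels: Mapping[str, Hashable]
                    ) -> tuple[dict, int]:
    """Ancestral MPR label sets and the parsimony minimum change count."""
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else None
        if label not in tip_labels or tip_labels[label] is None:
            raise ValueError(f"unlabelled tip {label!r}")
    return sankoff_mpr(tree, dict(tip_labels))
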