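"""Independent brute-force oracles used to validate the fast algorithms.

Everything here is deliberately naive: likelihoods by full enumeration
over ancestral state assignments, Dollo by exhaustive minimisation over
single-gain placements, Fisher by hypergeometric enumeration, KS by an
explicit ECDF scan.  None of it shares code with the implementation it
checks.
"""

from __future__ import annotations

from itertools import product
from math import comb

import numpy as np

from paralintron.trees import AnnotatedTree, TreeNode


# ---------------------------------------------------------------------------
# two-state likelihood / posteriors by enumeration
# ---------------------------------------------------------------------------

def _branch_prob(rates, name, parent_state, child_state):
    g = rates.gain[name]
    l = rates.loss[name]
    table = [[1.0 - g, g], [l, 1.0 - l]]
    return table[parent_state][child_state]


def enumerate_joint(pattern, tree: AnnotatedTree, rates):
    """Yield (assignment, probability) over all ancestral assignments.

    ``assignment`` maps every node name to a state in {0, 1}; leaf
    states are constrained by the pattern ('?' leaves range over both).
    """
    nodes = list(tree.preorder())
    choices = []
    for node in nodes:
        if node.is_leaf and pattern.get(node.name, "?") in ("0", "1"):
            choices.append([int(pattern[node.name])])
        else:
            choices.append([0, 1])
    for states in product(*choices):
        assignment = {n.name: s for n, s in zip(nodes, states)}
        prob = (
            rates.root_prior
            if assignment[tree.root.name] == 1
            else 1.0 - rates.root_prior
        )
        for node in nodes:
            if node.parent is None:
                continue
            prob *= _branch_prob(
                rates, node.name, assignment[node.parent.name], assignment[node.name]
            )
        yield assignment, prob


def brute_likelihood(pattern, tree, rates) -> float:
    return sum(p for _, p in enumerate_joint(pattern, tree, rates))


def brute_posteriors(pattern, tree, rates):
    """(node marginal presence, branch joint (parent, child) posteriors)."""
    total = 0.0
    node_marginal = {n.name: 0.0 for n in tree.preorder()}
    joint = {
        n.name: np.zeros((2, 2)) for n in tree.preorder() if n.parent is not None
    }
    for assignment, prob in enumerate_joint(pattern, tree, rates):
        total += prob
        for name, state in assignment.items():
            if state == 1:
                node_marginal[name] += prob
        for node in tree.preorder():
            if node.parent is not None:
                joint[node.name][
                    assignment[node.parent.name], assignment[node.name]
                ] += prob
    if total <= 0:
        raise ValueError("zero-probability pattern")
    return (
        {k: v / total for k, v in node_marginal.items()},
        {k: v / total for k, v in joint.items()},
    )


# ---------------------------------------------------------------------------
# Dollo minimum-loss oracle
# ---------------------------------------------------------------------------

def dollo_min_losses(tree: AnnotatedTree, carriers: set[str]) -> int:
    """Minimum loss count over all single-gain placements.

    For a gain at node v the intron can be present on any connected
    subtree of v's clade covering the carriers; the loss-minimising
    choice is the union of the paths from v to each carrier, so the
    oracle scans every admissible v and counts the edges leaving that
    union.
    """
    if not carriers:
        raise ValueError("no carriers")
    parent_of = {}
    for node in tree.preorder():
        for child in node.children:
            parent_of[child.name] = node.name

    clade = {
        node.name: {leaf.name for leaf in node.leaves()}
        for node in tree.preorder()
    }
    best = None
    for v in tree.preorder():
        if not carriers <= clade[v.name]:
            continue
        region = {v.name}
        for carrier in carriers:
            name = carrier
            while name != v.name:
                region.add(name)
                name = parent_of[name]
        losses = 0
        for name in region:
            for child in tree.node(name).children:
                if child.name not in region:
                    losses += 1
        if best is None or losses < best:
            best = losses
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Fisher / KS oracles
# ---------------------------------------------------------------------------

def fisher_two_sided(table) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def pmf(k):
        return comb(row1, k) * comb(row2, col1 - k) / comb(n, col1)

    support = range(max(0, col1 - row2), min(row1, col1) + 1)
    observed = pmf(a)
    return sum(pmf(k) for k in support if pmf(k) <= observed * (1 + 1e-9))


def ks_statistic(x, y) -> float:
    """sup |ECDF_x − ECDF_y| by explicit scan over pooled points."""
    x = sorted(x)
    y = sorted(y)
    points = sorted(set(x) | set(y))
    d = 0.0
    for t in points:
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        d = max(d, abs(fx - fy))
    return d


# ---------------------------------------------------------------------------
# random instances
# ---------------------------------------------------------------------------

def random_tree(rng: np.random.Generator, n_leaves: int) -> AnnotatedTree:
    """Random rooted bifurcating topology with leaves L1..Ln."""
    nodes = [TreeNode(name=f"L{i + 1}", node_type="leaf") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(node_type="speciation")
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    return AnnotatedTree(nodes[0])


def random_rates(rng: np.random.Generator, tree: AnnotatedTree):
    from paralintron.ancestral import BranchRates

    names = [n.name for n in tree.branches()]
    return BranchRates(
        gain={n: float(rng.uniform(0.0, 0.6)) for n in names},
        loss={n: float(rng.uniform(0.0, 0.9)) for n in names},
        root_prior=float(rng.uniform(0.05, 0.95)),
    )


def random_pattern(rng: np.random.Generator, tree, missing_prob=0.2):
    states = "01?"
    pattern = {}
    for leaf in tree.leaf_names:
        if rng.uniform() < missing_prob:
            pattern[leaf] = "?"
        else:
            pattern[leaf] = str(int(rng.uniform() < 0.5))
    return pattern
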