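"""Maximum-likelihood ancestral reconstruction of intron presence.

Each intron position evolves on the rooted species tree as a two-state
(absent/present) Markov chain.  Every branch ``b`` has its own gain
probability ``g_b = P(absent → present)`` and loss probability
``l_b = P(present → absent)``; the root carries a prior presence
probability ``π``.  Likelihoods are computed by Felsenstein pruning over
the two states; node and branch posteriors by the standard up–down
(outside) recursion; ``?`` observations contribute a partial likelihood
of one for both states.

Because an intron table can, by construction, never contain a position
absent in every species, the likelihood used for rate estimation is
conditioned on observability: each pattern's likelihood is divided by
``1 − P(all-absent)``.  Without this correction gain rates would be
biased downward.

A single rate category is used across positions (no rates-across-sites
variation); posterior LECA calls at the 0.5 threshold are robust to
this simplification in simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .trees import AnnotatedTree

#: leaf partial likelihoods indexed by observation code (0, 1, ?)
_LEAF_PARTIALS = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
_CODE = {"0": 0, "1": 1, "?": 2}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BranchRates:
    """Per-branch gain/loss probabilities plus the root presence prior.

    Branches are named by their child node (every non-root node of the
    tree names the branch leading into it).
    """

    gain: dict[str, float]
    loss: dict[str, float]
    root_prior: float

    def __post_init__(self) -> None:
        for name, g in self.gain.items():
            if not 0.0 <= g < 1.0:
                raise ValueError(f"gain probability out of range on {name!r}")
        for name, l in self.loss.items():
            if not 0.0 <= l <= 1.0:
                raise ValueError(f"loss probability out of range on {name!r}")
        if not 0.0 <= self.root_prior <= 1.0:
            raise ValueError("root prior out of range")

    @classmethod
    def uniform(
        cls, tree: AnnotatedTree, gain: float, loss: float, root_prior: float
    ) -> "BranchRates":
        names = [n.name for n in tree.branches()]
        return cls(
            gain={n: gain for n in names},
            loss={n: loss for n in names},
            root_prior=root_prior,
        )


@dataclass
class PosteriorPresence:
    """Posterior presence per node and event probabilities per branch."""

    node_prob: dict[str, float]
    branch_gain_prob: dict[str, float]
    branch_loss_prob: dict[str, float]
    log_likelihood: float
    position: object = None


@dataclass
class LECACall:
    position: object
    leca_probability: float
    threshold: float = 0.5

    @property
    def is_leca(self) -> bool:
        return self.leca_probability >= self.threshold


# ---------------------------------------------------------------------------
# tree indexing and vectorised pruning
# ---------------------------------------------------------------------------

class _TreeIndex:
    """Postorder-indexed view of a tree for array-based recursions."""

    def __init__(self, tree: AnnotatedTree, leaf_order: Sequence[str]):
        self.nodes = list(tree.postorder())  # root last
        idx = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [[idx[id(c)] for c in n.children] for n in self.nodes]
        self.names = [n.name for n in self.nodes]
        self.is_leaf = [n.is_leaf for n in self.nodes]
        self.root = len(self.nodes) - 1
        # branch parameter index for every non-root node
        self.branch_nodes = [i for i, n in enumerate(self.nodes) if n.parent is not None]
        self.branch_param = {i: k for k, i in enumerate(self.branch_nodes)}
        self.branch_names = [self.names[i] for i in self.branch_nodes]
        leaf_col = {name: j for j, name in enumerate(leaf_order)}
        self.leaf_col = [
            leaf_col[n.name] if n.is_leaf else -1 for n in self.nodes
        ]
        missing = [n.name for n in self.nodes if n.is_leaf and n.name not in leaf_col]
        if missing:
            raise ValueError(f"leaves absent from pattern order: {missing}")

    def matrices(self, gains: np.ndarray, losses: np.ndarray) -> np.ndarray:
        m = np.empty((len(self.branch_nodes), 2, 2))
        m[:, 0, 0] = 1.0 - gains
        m[:, 0, 1] = gains
        m[:, 1, 0] = losses
        m[:, 1, 1] = 1.0 - losses
        return m


def _encode_patterns(
    patterns: Sequence[Mapping[str, str]], leaf_order: Sequence[str]
) -> np.ndarray:
    codes = np.full((len(patterns), len(leaf_order)), 2, dtype=np.int8)
    for i, pattern in enumerate(patterns):
        for j, leaf in enumerate(leaf_order):
            state = pattern.get(leaf, "?")
            codes[i, j] = _CODE[state]
    return codes


def _down_pass(ti: _TreeIndex, codes: np.ndarray, mats: np.ndarray):
    """Scaled conditional likelihoods of the data below each node."""
    n_patterns = codes.shape[0]
    down: list[Optional[np.ndarray]] = [None] * len(ti.nodes)
    logscale = np.zeros(n_patterns)
    for i in range(len(ti.nodes)):
        if ti.is_leaf[i]:
            partial = _LEAF_PARTIALS[codes[:, ti.leaf_col[i]]]
        else:
            partial = np.ones((n_patterns, 2))
            for c in ti.children[i]:
                partial = partial * (down[c] @ mats[ti.branch_param[c]].T)
            peak = partial.max(axis=1)
            safe = np.where(peak > 0.0, peak, 1.0)
            partial = partial / safe[:, None]
            with np.errstate(divide="ignore"):
                logscale += np.where(peak > 0.0, np.log(safe), -np.inf)
        down[i] = partial
    return down, logscale


def _log_likelihoods(
    ti: _TreeIndex, codes: np.ndarray, mats: np.ndarray, prior: np.ndarray
) -> np.ndarray:
    down, logscale = _down_pass(ti, codes, mats)
    root_l = down[ti.root] @ prior
    with np.errstate(divide="ignore"):
        return logscale + np.log(root_l)


def _rates_arrays(ti: _TreeIndex, rates: BranchRates):
    try:
        gains = np.array([rates.gain[name] for name in ti.branch_names])
        losses = np.array([rates.loss[name] for name in ti.branch_names])
    except KeyError as exc:
        raise ValueError(f"rates missing for branch {exc.args[0]!r}") from exc
    return gains, losses


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def pattern_likelihood(
    pattern: Mapping[str, str], tree: AnnotatedTree, rates: BranchRates
) -> float:
    """Likelihood of one presence/absence/missing pattern."""
    leaves = tree.leaf_names
    unknown = set(pattern) - set(leaves)
    if unknown:
        raise ValueError(f"pattern species not on tree: {sorted(unknown)}")
    ti = _TreeIndex(tree, leaves)
    codes = _encode_patterns([pattern], leaves)
    gains, losses = _rates_arrays(ti, rates)
    prior = np.array([1.0 - rates.root_prior, rates.root_prior])
    ll = _log_likelihoods(ti, codes, ti.matrices(gains, losses), prior)
    return float(np.exp(ll[0]))


def all_absent_probability(tree: AnnotatedTree, rates: BranchRates) -> float:
    """Probability that a position is absent in every leaf (unobservable)."""
    return pattern_likelihood({n: "0" for n in tree.leaf_names}, tree, rates)


def _up_down(ti: _TreeIndex, codes: np.ndarray, mats: np.ndarray, prior: np.ndarray):
    """Vectorised up–down recursion over all patterns at once.

    Returns ``(loglik (P,), node_post (N, P), joint (B, P, 2, 2))``:
    posterior presence per node and, per branch, the posterior joint
    distribution of (parent state, child state).
    """
    n_patterns = codes.shape[0]
    down, logscale = _down_pass(ti, codes, mats)
    root_l = down[ti.root] @ prior
    bad = (root_l <= 0.0) | ~np.isfinite(logscale)
    if bad.any():
        raise ValueError("pattern has zero likelihood under these rates")
    loglik = logscale + np.log(root_l)

    up: list[Optional[np.ndarray]] = [None] * len(ti.nodes)
    up[ti.root] = np.broadcast_to(prior, (n_patterns, 2)).copy()
    node_post = np.empty((len(ti.nodes), n_patterns))
    joint = np.empty((len(ti.branch_nodes), n_patterns, 2, 2))

    for i in reversed(range(len(ti.nodes))):  # parents before children
        weights = up[i] * down[i]
        total = weights.sum(axis=1)
        if (total <= 0.0).any():
            raise ValueError("pattern has zero likelihood under these rates")
        node_post[i] = weights[:, 1] / total
        if ti.is_leaf[i]:
            continue
        msgs = {c: down[c] @ mats[ti.branch_param[c]].T for c in ti.children[i]}
        for c in ti.children[i]:
            partial = up[i].copy()
            for c2 in ti.children[i]:
                if c2 != c:
                    partial = partial * msgs[c2]
            mat = mats[ti.branch_param[c]]
            b = ti.branch_param[c]
            j = partial[:, :, None] * mat[None, :, :] * down[c][:, None, :]
            j_total = j.sum(axis=(1, 2), keepdims=True)
            if (j_total <= 0.0).any():
                raise ValueError("pattern has zero likelihood under these rates")
            joint[b] = j / j_total
            up_c = partial @ mat
            peak = up_c.max(axis=1)
            peak = np.where(peak > 0.0, peak, 1.0)
            up[c] = up_c / peak[:, None]
    return loglik, node_post, joint


def posterior_presence_many(
    patterns: Sequence[Mapping[str, str]],
    tree: AnnotatedTree,
    rates: BranchRates,
    positions: Optional[Sequence] = None,
) -> list[PosteriorPresence]:
    """Node and branch posteriors for many patterns in one pass."""
    leaves = tree.leaf_names
    for pattern in patterns:
        unknown = set(pattern) - set(leaves)
        if unknown:
            raise ValueError(f"pattern species not on tree: {sorted(unknown)}")
    ti = _TreeIndex(tree, leaves)
    codes = _encode_patterns(patterns, leaves)
    gains, losses = _rates_arrays(ti, rates)
    mats = ti.matrices(gains, losses)
    prior = np.array([1.0 - rates.root_prior, rates.root_prior])
    loglik, node_post, joint = _up_down(ti, codes, mats, prior)
    out = []
    for p in range(len(patterns)):
        out.append(
            PosteriorPresence(
                node_prob={
                    ti.names[i]: float(node_post[i, p])
                    for i in range(len(ti.nodes))
                },
                branch_gain_prob={
                    ti.branch_names[b]: float(joint[b, p, 0, 1])
                    for b in range(len(ti.branch_nodes))
                },
                branch_loss_prob={
                    ti.branch_names[b]: float(joint[b, p, 1, 0])
                    for b in range(len(ti.branch_nodes))
                },
                log_likelihood=float(loglik[p]),
                position=None if positions is None else positions[p],
            )
        )
    return out


def posterior_presence(
    pattern: Mapping[str, str],
    tree: AnnotatedTree,
    rates: BranchRates,
    position=None,
) -> PosteriorPresence:
    """Node presence posteriors and branch gain/loss event posteriors.

    ``branch_gain_prob[b] = P(parent(b) = absent, child(b) = present |
    data)`` and symmetrically for losses.
    """
    return posterior_presence_many([pattern], tree, rates, [position])[0]


def call_leca(
    post: PosteriorPresence, leca_node: str, threshold: float = 0.5
) -> LECACall:
    """Call an intron position ancestral when its posterior presence at
    the LECA node is at least the threshold (default 0.5, inclusive)."""
    if leca_node not in post.node_prob:
        raise ValueError(f"node {leca_node!r} not in posterior")
    return LECACall(
        position=post.position,
        leca_probability=post.node_prob[leca_node],
        threshold=threshold,
    )


def node_intron_count(
    posteriors: Iterable[PosteriorPresence],
    node: str,
    tree: Optional[AnnotatedTree] = None,
    rates: Optional[BranchRates] = None,
) -> float:
    """Expected intron count at a node, corrected for unobservable sites.

    Positions absent from every extant species never enter an intron
    table, so the plain sum of posterior presence probabilities
    undercounts ancestral introns.  Given the tree and rates, the
    expected number of unobservable positions — ``N·p0/(1 − p0)`` with
    ``p0 = P(all-absent)`` — is added back, each weighted by the
    posterior presence at the node *conditional on the all-absent
    pattern*.  (Scaling the observed sum by ``1/(1 − p0)`` instead would
    credit never-present positions with the observed positions' high
    posteriors and overestimates badly whenever unobservable positions
    are dominated by ones that never existed.)  Without tree and rates
    the uncorrected sum is returned.
    """
    posteriors = list(posteriors)
    total = sum(p.node_prob[node] for p in posteriors)
    if tree is None or rates is None:
        return total
    all_absent = {leaf: "0" for leaf in tree.leaf_names}
    p0 = pattern_likelihood(all_absent, tree, rates)
    if p0 <= 0.0:
        return total
    if p0 >= 1.0:
        raise ValueError("every position is unobservable under these rates")
    hidden_posterior = posterior_presence(all_absent, tree, rates).node_prob[node]
    n_unobservable = len(posteriors) * p0 / (1.0 - p0)
    return total + n_unobservable * hidden_posterior


# ---------------------------------------------------------------------------
# rate estimation
# ---------------------------------------------------------------------------

@dataclass
class RateEstimate:
    rates: BranchRates
    log_likelihood: float
    converged: bool
    n_patterns: int
    messages: list[str] = field(default_factory=list)


def _unique_patterns(tables, leaf_order):
    patterns = []
    for table in tables:
        for j in range(len(table.positions)):
            patterns.append(table.pattern(j))
    if not patterns:
        raise ValueError("no observed positions in the supplied tables")
    codes = _encode_patterns(patterns, leaf_order)
    unique, counts = np.unique(codes, axis=0, return_counts=True)
    return unique, counts.astype(float)


def estimate_rates(
    tables,
    tree: AnnotatedTree,
    mode: str = "loss",
    root_prior: Optional[float] = None,
    condition_on_observed: bool = True,
    n_starts: int = 5,
    maxiter: int = 2000,
    tol: float = 1e-8,
) -> RateEstimate:
    """Maximum-likelihood branch gain/loss probabilities and root prior.

    Maximises ``Σ log[L(pattern) / (1 − P(all-absent))]`` by
    expectation–maximisation: the E-step computes posterior branch
    (parent, child) joint distributions with the up–down recursion, the
    M-step sets each branch's gain and loss probability to the expected
    transition fractions.  Conditioning on observability is handled by
    augmenting the data each iteration with a phantom all-absent
    pattern of weight ``N·p0/(1 − p0)`` — the expected number of
    unobservable positions — which makes the EM fixed point the
    conditional MLE.  Multi-start (seeds ``1..n_starts``, uniform random
    initial probabilities); the best final likelihood wins, ties broken
    by the first seed.

    ``mode`` selects the parameterisation: ``"loss"`` (default) fits a
    loss probability per branch and one gain probability shared by all
    branches; ``"tied"`` shares both; ``"full"`` frees both per branch.
    With ``"full"`` the root prior is confounded with the root-edge
    gain probabilities (lowering π while raising root-edge gains leaves
    the leaf distribution unchanged), so root-state inferences under
    that mode are not identifiable; the default mode keeps them so.
    ``root_prior`` may be fixed; by default it is estimated jointly.
    """
    if mode not in ("tied", "loss", "full"):
        raise ValueError(f"unknown estimation mode {mode!r}")
    leaf_order = tree.leaf_names
    ti = _TreeIndex(tree, leaf_order)
    unique, counts = _unique_patterns(tables, leaf_order)
    n_total = counts.sum()
    n_branches = len(ti.branch_nodes)
    estimate_prior = root_prior is None

    # last row: the phantom all-absent pattern (weight updated per iteration)
    codes = np.vstack([unique, np.zeros((1, len(leaf_order)), dtype=np.int8)])

    eps = 1e-9

    def conditional_loglik(gains, losses, pi) -> float:
        mats = ti.matrices(gains, losses)
        prior = np.array([1.0 - pi, pi])
        ll = _log_likelihoods(ti, codes, mats, prior)
        p0 = np.exp(ll[-1])
        if p0 >= 1.0 or not np.all(np.isfinite(ll[:-1])):
            return -np.inf
        return float(counts @ ll[:-1]) - n_total * float(np.log1p(-p0))

    def run_em(gains, losses, pi):
        previous = -np.inf
        converged = False
        for _ in range(maxiter):
            mats = ti.matrices(gains, losses)
            prior = np.array([1.0 - pi, pi])
            ll, node_post, joint = _up_down(ti, codes, mats, prior)
            p0 = np.exp(ll[-1])
            if p0 >= 1.0:
                break
            current = float(counts @ ll[:-1]) - n_total * float(np.log1p(-p0))
            if condition_on_observed:
                phantom = n_total * p0 / (1.0 - p0)
                weights = np.concatenate([counts, [phantom]])
            else:
                current = float(counts @ ll[:-1])
                weights = np.concatenate([counts, [0.0]])
            if abs(current - previous) < tol * max(1.0, abs(current)):
                converged = True
                break
            previous = current
            # M-step: expected transition fractions per branch
            w = weights[None, :, None, None]
            j_sum = (joint * w).sum(axis=1)  # (B, 2, 2)
            from_absent = j_sum[:, 0, 0] + j_sum[:, 0, 1]
            from_present = j_sum[:, 1, 0] + j_sum[:, 1, 1]
            with np.errstate(invalid="ignore", divide="ignore"):
                new_g = np.where(from_absent > 0, j_sum[:, 0, 1] / from_absent, 0.0)
                new_l = np.where(from_present > 0, j_sum[:, 1, 0] / from_present, 0.0)
            if mode in ("tied", "loss"):
                g_pool = j_sum[:, 0, 1].sum() / max(from_absent.sum(), eps)
                new_g = np.full(n_branches, g_pool)
            if mode == "tied":
                l_pool = j_sum[:, 1, 0].sum() / max(from_present.sum(), eps)
                new_l = np.full(n_branches, l_pool)
            gains = np.clip(new_g, 0.0, 1.0 - eps)
            losses = np.clip(new_l, 0.0, 1.0)
            if estimate_prior:
                root_post = node_post[ti.root]
                pi = float(
                    np.clip((root_post * weights).sum() / weights.sum(), eps, 1 - eps)
                )
        final = conditional_loglik(gains, losses, pi)
        return gains, losses, pi, final, converged

    best = None
    messages = []
    for seed in range(1, n_starts + 1):
        rng = np.random.default_rng(seed)
        start = rng.uniform(0.02, 0.5, size=2 * n_branches + 1)
        gains0, losses0 = start[:n_branches], start[n_branches:-1]
        if mode in ("tied", "loss"):
            gains0 = np.full(n_branches, gains0.mean())
        if mode == "tied":
            losses0 = np.full(n_branches, losses0.mean())
        pi0 = start[-1] if estimate_prior else float(root_prior)
        fit = run_em(gains0.copy(), losses0.copy(), pi0)
        messages.append(f"seed {seed}: loglik={fit[3]:.6f} converged={fit[4]}")
        if best is None or fit[3] > best[3] + 1e-9:
            best = fit
    assert best is not None
    gains, losses, pi, loglik, converged = best

    rates = BranchRates(
        gain={name: float(g) for name, g in zip(ti.branch_names, gains)},
        loss={name: float(l) for name, l in zip(ti.branch_names, losses)},
        root_prior=pi,
    )
    return RateEstimate(
        rates=rates,
        log_likelihood=loglik,
        converged=converged,
        n_patterns=int(n_total),
        messages=messages,
    )


# ---------------------------------------------------------------------------
# per-table convenience
# ---------------------------------------------------------------------------

def reconstruct_table(
    table,
    tree: AnnotatedTree,
    rates: BranchRates,
    leca_node: Optional[str] = None,
    threshold: float = 0.5,
) -> list[tuple[PosteriorPresence, LECACall]]:
    """Posterior reconstruction and LECA call for every table position.

    The LECA node defaults to the tree root (the LECA under the
    Opimoda–Diphoda rooting; under the unresolved-root topology the root
    of the multifurcation plays the same role).
    """
    if leca_node is None:
        leca_node = tree.root.name
    patterns = [table.pattern(j) for j in range(len(table.positions))]
    posts = posterior_presence_many(patterns, tree, rates, table.positions)
    return [(post, call_leca(post, leca_node, threshold)) for post in posts]
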