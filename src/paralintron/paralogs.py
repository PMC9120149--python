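"""Shared introns between ancient paralogs and pre-duplication inference.

A family groups orthogroups (OGs) that descend from pre-LECA gene
duplications.  After the per-OG ancestral (LECA) introns have been
transferred into the family's merged-alignment coordinates, an intron
position found in two or more *paralogous* OGs is *shared*: it was most
likely present before the duplication separating them.  Homologous OGs
that entered the proto-eukaryotic lineage as separate genes (separate
acquisitions, or pseudoparalogs) can only share positions through
parallel gains, so sharing between separate acquisitions serves as the
parallel-gain null control and never makes an intron "shared".

Pre-duplication intron content on a gene tree is reconstructed by Dollo
parsimony: each intron is gained exactly once — on the branch into the
root of the minimal subtree spanning its carrier OGs — and lost on every
branch leaving that subtree toward a carrier-free clade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional

from .stats import TestResult, bh_fdr, chi2_contingency, fisher_exact
from .trees import AnnotatedTree, TreeNode

Key = tuple[int, int]  # (merged alignment column, phase)


# ---------------------------------------------------------------------------
# paralogy from acquisition-annotated gene trees
# ---------------------------------------------------------------------------

@dataclass
class ParalogyMap:
    """Which OG pairs are paralogous, separate acquisitions, or excluded.

    ``acquisition_of`` maps each OG (gene-tree leaf) to the name of its
    nearest ancestral acquisition node (the root acts as an implicit
    acquisition when none is annotated).  ``ambiguous`` lists
    acquisitions whose sister group contains another acquisition; their
    OGs are excluded from both the paralog and the control sets.
    """

    acquisition_of: dict[str, str]
    ambiguous: set[str] = field(default_factory=set)

    def relation(self, og_a: str, og_b: str) -> str:
        acq_a = self.acquisition_of[og_a]
        acq_b = self.acquisition_of[og_b]
        if acq_a == acq_b:
            return "excluded" if acq_a in self.ambiguous else "paralogous"
        if acq_a in self.ambiguous or acq_b in self.ambiguous:
            return "excluded"
        return "separate"

    @property
    def ogs(self) -> list[str]:
        return sorted(self.acquisition_of)


def paralogy_from_tree(gene_tree: AnnotatedTree) -> ParalogyMap:
    """Derive the paralogy map from an acquisition-annotated gene tree.

    Separate acquisitions are only a clean parallel-gain control when
    nothing in the tree suggests they descend from an already-duplicated
    ancestor.  An acquisition is therefore flagged ambiguous — and its
    OGs excluded from both the paralog and the control sets — when a
    duplication or another acquisition lies among its ancestors.
    """
    acquisitions: list[TreeNode] = [
        n for n in gene_tree.preorder() if n.node_type == "acquisition"
    ]

    def nearest_acquisition(leaf: TreeNode) -> str:
        node = leaf
        while node is not None:
            if node.node_type == "acquisition":
                return node.name
            node = node.parent
        return gene_tree.root.name

    acquisition_of = {
        leaf.name: nearest_acquisition(leaf) for leaf in gene_tree.root.leaves()
    }

    ambiguous = set()
    for acq in acquisitions:
        ancestor = acq.parent
        while ancestor is not None:
            if ancestor.node_type in ("duplication", "acquisition"):
                ambiguous.add(acq.name)
                break
            ancestor = ancestor.parent
    return ParalogyMap(acquisition_of=acquisition_of, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# shared / unique classification
# ---------------------------------------------------------------------------

@dataclass
class SharedClassification:
    """Per-intron category and the carrier map behind it.

    Categories: ``shared`` (an equivalent LECA intron exists in at least
    one paralogous OG), ``unique`` (no equivalent in any paralog),
    ``parallel_only`` (shared exclusively with separate acquisitions —
    excluded from both the numerator and the denominator of the shared
    fraction), ``excluded`` (the OG sits under an ambiguous acquisition
    or has no paralogous partner at all).
    """

    category: dict[tuple[str, Key], str]
    carriers: dict[Key, set[str]]

    def count(self, category: str) -> int:
        return sum(1 for c in self.category.values() if c == category)

    @property
    def n_considered(self) -> int:
        return self.count("shared") + self.count("unique")

    @property
    def fraction_shared(self) -> float:
        n = self.n_considered
        if n == 0:
            raise ValueError("no introns in the shared/unique denominator")
        return self.count("shared") / n


def classify_shared(
    leca_sets: Mapping[str, Iterable[Key]],
    pmap: ParalogyMap,
) -> SharedClassification:
    """Classify each OG's LECA introns as shared, unique, or excluded.

    ``leca_sets`` maps each OG to its LECA intron positions in merged
    coordinates.  Only sharing between paralogous OGs makes an intron
    shared; OGs without any paralogous partner (separately acquired from
    every other OG, or ambiguous) contribute no introns to the shared
    fraction.
    """
    unknown = set(leca_sets) - set(pmap.acquisition_of)
    if unknown:
        raise ValueError(f"OGs missing from the paralogy map: {sorted(unknown)}")
    carriers: dict[Key, set[str]] = {}
    for og, keys in leca_sets.items():
        for key in keys:
            carriers.setdefault(tuple(key), set()).add(og)

    ogs = sorted(leca_sets)
    has_paralog = {
        og: any(
            pmap.relation(og, other) == "paralogous" for other in ogs if other != og
        )
        for og in ogs
    }

    category: dict[tuple[str, Key], str] = {}
    for og in ogs:
        for key in sorted(map(tuple, leca_sets[og])):
            others = carriers[key] - {og}
            relations = {pmap.relation(og, other) for other in others}
            if not has_paralog[og]:
                category[(og, key)] = "excluded"
            elif "paralogous" in relations:
                category[(og, key)] = "shared"
            elif "separate" in relations:
                category[(og, key)] = "parallel_only"
            else:
                category[(og, key)] = "unique"
    return SharedClassification(category=category, carriers=carriers)


@dataclass
class ControlResult:
    """Parallel-gain control: sharing between separate acquisitions."""

    fraction_paralogs: float
    fraction_separate: float
    table: list[list[int]]  # [[shared, unshared] paralogs; ... separate]
    fisher: TestResult


def _control_counts(
    leca_sets: Mapping[str, Iterable[Key]], pmap: ParalogyMap
) -> tuple[int, int, int, int]:
    classification = classify_shared(leca_sets, pmap)
    n_shared = classification.count("shared")
    n_unique = classification.count("unique")

    ogs = sorted(leca_sets)
    carriers = classification.carriers
    sep_shared = 0
    sep_unshared = 0
    for og in ogs:
        partners = [
            other
            for other in ogs
            if other != og and pmap.relation(og, other) == "separate"
        ]
        if not partners:
            continue
        for key in sorted(map(tuple, leca_sets[og])):
            if any(p in carriers[key] for p in partners):
                sep_shared += 1
            else:
                sep_unshared += 1
    return n_shared, n_unique, sep_shared, sep_unshared


def parallel_gain_control(
    families: Iterable[tuple[Mapping[str, Iterable[Key]], ParalogyMap]],
) -> Optional[ControlResult]:
    """Compare paralog sharing against the separate-acquisition null.

    ``families`` pairs each family's merged-coordinate LECA intron sets
    with its paralogy map; counts are summed over families (sharing is
    only ever evaluated within a family, since OGs of different families
    are not homologous).  The pooled 2×2 table [shared, unshared] ×
    [paralogs, separate acquisitions] is tested with a two-sided Fisher
    exact test.  The separate arm counts, over every OG with at least
    one clean separate partner, the introns whose position recurs in a
    separately acquired OG.  Returns ``None`` when either arm is empty.
    """
    n_shared = n_unique = sep_shared = sep_unshared = 0
    for leca_sets, pmap in families:
        s, u, ss, su = _control_counts(leca_sets, pmap)
        n_shared += s
        n_unique += u
        sep_shared += ss
        sep_unshared += su
    if sep_shared + sep_unshared == 0:
        warnings.warn("no separate-acquisition introns: control unavailable")
        return None
    if n_shared + n_unique == 0:
        warnings.warn("no paralogous introns: control unavailable")
        return None
    table = [[n_shared, n_unique], [sep_shared, sep_unshared]]
    return ControlResult(
        fraction_paralogs=n_shared / (n_shared + n_unique),
        fraction_separate=sep_shared / (sep_shared + sep_unshared),
        table=table,
        fisher=fisher_exact(table),
    )


# ---------------------------------------------------------------------------
# Dollo parsimony on gene trees
# ---------------------------------------------------------------------------

@dataclass
class GeneTreeState:
    """Dollo reconstruction of intron history on one gene tree.

    ``present[node]`` is the intron set present at a node (membership in
    the minimal spanning subtree); ``gain_branch[key]`` names the node
    whose incoming branch carries the single gain; ``loss_branches``
    names the nodes whose incoming branches carry losses.
    """

    gene_tree: AnnotatedTree
    present: dict[str, set[Key]]
    gain_branch: dict[Key, str]
    loss_branches: dict[Key, set[str]]

    def duplications_with_introns(self) -> dict[str, bool]:
        return {
            n.name: bool(self.present[n.name])
            for n in self.gene_tree.preorder()
            if n.node_type == "duplication"
        }

    def ancestral_duplication_had_introns(self) -> dict[str, bool]:
        """Per duplication node: a strict-ancestor duplication was intron-bearing."""
        out = {}
        for node in self.gene_tree.preorder():
            if node.node_type != "duplication":
                continue
            ancestor = node.parent
            flag = False
            while ancestor is not None:
                if ancestor.node_type == "duplication" and self.present[ancestor.name]:
                    flag = True
                    break
                ancestor = ancestor.parent
            out[node.name] = flag
        return out


def dollo_preduplication(
    gene_tree: AnnotatedTree,
    leca_intron_sets: Mapping[str, Iterable[Key]],
) -> GeneTreeState:
    """Dollo-parsimony reconstruction of pre-duplication introns.

    Each intron is present on exactly the minimal subtree spanning its
    carrier leaves, gained on the branch entering that subtree's root
    and lost once on each branch leaving it toward a carrier-free clade.
    Multifurcations are handled as-is.
    """
    leaf_names = set(gene_tree.leaf_names)
    unknown = set(leca_intron_sets) - leaf_names
    if unknown:
        raise ValueError(f"carrier leaves absent from gene tree: {sorted(unknown)}")

    keys = sorted(
        {tuple(k) for keys in leca_intron_sets.values() for k in keys}
    )
    carriers_of = {
        key: {
            og
            for og, og_keys in leca_intron_sets.items()
            if key in set(map(tuple, og_keys))
        }
        for key in keys
    }

    nodes = list(gene_tree.postorder())
    has_carrier: dict[Key, dict[str, bool]] = {key: {} for key in keys}
    for node in nodes:
        for key in keys:
            if node.is_leaf:
                has_carrier[key][node.name] = node.name in carriers_of[key]
            else:
                has_carrier[key][node.name] = any(
                    has_carrier[key][c.name] for c in node.children
                )

    present: dict[str, set[Key]] = {n.name: set() for n in nodes}
    gain_branch: dict[Key, str] = {}
    loss_branches: dict[Key, set[str]] = {key: set() for key in keys}

    for key in keys:
        # MRCA of carriers: deepest node whose subtree holds all carriers
        n_carriers = len(carriers_of[key])
        counts: dict[str, int] = {}
        for node in nodes:
            if node.is_leaf:
                counts[node.name] = int(node.name in carriers_of[key])
            else:
                counts[node.name] = sum(counts[c.name] for c in node.children)
        mrca = None
        for node in nodes:  # postorder: first hit is the deepest
            if counts[node.name] == n_carriers:
                mrca = node
                break
        assert mrca is not None
        gain_branch[key] = mrca.name
        # spanning subtree: descendants of the MRCA whose clade has a carrier
        stack = [mrca]
        while stack:
            node = stack.pop()
            present[node.name].add(key)
            for child in node.children:
                if has_carrier[key][child.name]:
                    stack.append(child)
                else:
                    loss_branches[key].add(child.name)

    return GeneTreeState(
        gene_tree=gene_tree,
        present=present,
        gain_branch=gain_branch,
        loss_branches=loss_branches,
    )


def count_preduplication_events(
    states: Iterable[GeneTreeState],
) -> tuple[int, int, int, int]:
    """Event totals: (gains before duplications, losses before
    duplications, gains on LECA-family branches, losses on LECA-family
    branches), summed over families.

    A branch "before a duplication" enters an internal node; a "LECA
    branch" enters a leaf (a LECA orthogroup).
    """
    gains_dup = losses_dup = gains_leca = losses_leca = 0
    for state in states:
        tree = state.gene_tree
        for key, node_name in state.gain_branch.items():
            if tree.node(node_name).is_leaf:
                gains_leca += 1
            else:
                gains_dup += 1
        for key, node_names in state.loss_branches.items():
            for node_name in node_names:
                if tree.node(node_name).is_leaf:
                    losses_leca += 1
                else:
                    losses_dup += 1
    return gains_dup, losses_dup, gains_leca, losses_leca


# ---------------------------------------------------------------------------
# U12 annotation
# ---------------------------------------------------------------------------

def annotate_u12(
    predictions: Iterable[tuple],
    positions: Iterable,
    min_species: int = 3,
) -> dict:
    """U12-type calls: U12 when at least ``min_species`` distinct species
    predict U12 at a position, U2 otherwise (including no prediction).

    ``predictions`` rows are ``(species_id, og_id, alignment_column,
    phase, predicted_type)``; ``positions`` are
    :class:`~paralintron.intron_mapping.IntronPosition` objects.
    """
    u12_species: dict[tuple[str, int, int], set[str]] = {}
    for species_id, og_id, column, phase, ptype in predictions:
        if ptype == "U12":
            u12_species.setdefault((og_id, int(column), int(phase)), set()).add(
                species_id
            )
    out = {}
    for pos in positions:
        supporters = u12_species.get(
            (pos.og_id, pos.alignment_column, pos.phase), set()
        )
        out[pos] = "U12" if len(supporters) >= min_species else "U2"
    return out


# ---------------------------------------------------------------------------
# group fractions
# ---------------------------------------------------------------------------

@dataclass
class GroupTable:
    """Per-group success/failure counts with the attached tests.

    ``counts[group] = (with, without)``; ``chi2`` tests heterogeneity
    across all reported groups; ``pairwise`` holds every 2×2 Fisher
    comparison with BH-adjusted p values; ``main_group_chi2`` tests the
    three main functional groups after excluding units whose categories
    span more than one of them.
    """

    counts: dict[str, tuple[int, int]]
    chi2: Optional[TestResult]
    pairwise: list[tuple[str, str, TestResult]]
    main_group_chi2: Optional[TestResult] = None
    main_group_counts: Optional[dict[str, tuple[int, int]]] = None


def group_fractions(
    outcomes: Mapping[str, bool],
    categories: Mapping[str, Iterable[str]],
    min_units: int = 10,
    main_group_of: Optional[Mapping[str, str]] = None,
) -> GroupTable:
    """Success fractions per category with χ² and pairwise Fisher tests.

    ``outcomes`` maps a unit (a LECA intron or a duplication node) to a
    binary outcome (shared / has pre-duplication introns); a unit may
    belong to several categories and contributes to each.  Categories
    with fewer than ``min_units`` units are dropped from reporting and
    testing.  When ``main_group_of`` maps categories to main groups, a
    main-group test is added in which units whose categories span more
    than one main group are excluded.
    """
    counts: dict[str, list[int]] = {}
    for unit, outcome in outcomes.items():
        for category in categories.get(unit, ()):  # uncategorised units drop out
            entry = counts.setdefault(category, [0, 0])
            entry[0 if outcome else 1] += 1

    reported = {
        cat: (with_, without)
        for cat, (with_, without) in sorted(counts.items())
        if with_ + without >= min_units
    }

    chi2 = None
    if len(reported) >= 2:
        chi2 = chi2_contingency([list(v) for v in reported.values()])

    pairwise = []
    pairs = list(combinations(sorted(reported), 2))
    raw = [fisher_exact([list(reported[a]), list(reported[b])]) for a, b in pairs]
    for p_adj, (a, b), result in zip(bh_fdr([r.p for r in raw]), pairs, raw):
        result.p_adj = p_adj
        pairwise.append((a, b, result))

    main_chi2 = None
    main_counts = None
    if main_group_of is not None:
        main_counts = {}
        for unit, outcome in outcomes.items():
            mains = {
                main_group_of[cat]
                for cat in categories.get(unit, ())
                if cat in main_group_of
            }
            if len(mains) != 1:
                continue  # spans several main groups (or none): excluded
            entry = main_counts.setdefault(next(iter(mains)), [0, 0])
            entry[0 if outcome else 1] += 1
        main_counts = {k: (v[0], v[1]) for k, v in sorted(main_counts.items())}
        if len(main_counts) >= 2:
            main_chi2 = chi2_contingency([list(v) for v in main_counts.values()])

    return GroupTable(
        counts=reported,
        chi2=chi2,
        pairwise=pairwise,
        main_group_chi2=main_chi2,
        main_group_counts=main_counts,
    )
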