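"""Forward simulator of intron evolution through eukaryogenesis.

The simulator emulates the history the pipeline is built to recover:

* a *stem* phase (eukaryogenesis): each gene family enters the
  proto-eukaryotic lineage as a single gene (an acquisition), undergoes
  gene duplications at configured times, gains introns as a Poisson
  process with a phase bias (most gains in phase 0, fewest in phase 2)
  and loses introns with a 3'-positional bias — losses pick a present
  intron with probability proportional to ``exp(bias · relative
  position)``, the simplest monotone form of the reverse-transcription
  loss mechanism.  Lineages surviving to the end of the stem are the
  LECA orthogroups (OGs) of the family.
* a *post-LECA* phase: every LECA intron of every OG evolves down the
  species tree as a two-state chain with per-branch gain and loss
  probabilities; novel (post-LECA) introns arise on branches at a
  configurable rate.  Positions absent from every extant species are
  dropped from the emitted tables, mirroring the observability of real
  intron tables.
* emission: per-species genome FASTA + GFF3 with real GT…AG introns
  inserted at the exact coding offsets, protein FASTA, per-OG and merged
  (true) alignments, annotated Newick trees, and a ground-truth log.

Every random draw flows from the single config seed through named
streams (per family / per stage), so any subset of the simulation is
reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np

from .trees import AnnotatedTree, TreeNode, parse_newick

Key = tuple[int, int]  # (anchor residue == merged column in gap-free mode, phase)

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"],
    "D": ["GAT", "GAC"],
    "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"],
    "E": ["GAA", "GAG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "K": ["AAA", "AAG"],
    "M": ["ATG"],
    "F": ["TTT", "TTC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
}
_AMINO_ACIDS = sorted(_CODONS)


def stream(seed: int, *keys) -> np.random.Generator:
    """Named, reproducible random stream derived from the master seed."""
    entropy = [seed & 0x7FFFFFFF]
    for key in keys:
        entropy.append(zlib.crc32(str(key).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def default_species_tree(n_species: int = 8) -> AnnotatedTree:
    """A balanced rooted species tree with leaves ``sp01..spNN``.

    The root is the LECA node of the post-LECA simulation.
    """
    import warnings as _warnings

    names = [f"sp{i + 1:02d}" for i in range(n_species)]

    def build(block: list[str]) -> str:
        if len(block) == 1:
            return block[0]
        half = (len(block) + 1) // 2
        return f"({build(block[:half])},{build(block[half:])})"

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        return parse_newick(build(names) + "LECA;")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for the synthetic intron histories.

    Stem rates are per unit of stem time (the stem spans time 0→1 from
    acquisition to LECA); ``gain_rate_stem`` is per lineage,
    ``loss_rate_stem`` per present intron.  ``phase_weights`` follow the
    genome-wide phase bias (phase 0 most common, phase 2 rarest).
    ``parallel_gain_rate`` is the probability that a stem gain re-uses
    an intron position already seen in the family, creating the parallel
    gains the separate-acquisition control is calibrated against.
    """

    seed: int
    n_families: int = 20
    n_species: int = 8
    n_acquisitions: int = 1  # separately acquired homologous genes per family
    n_duplications: int = 2  # per acquisition
    duplication_times: Optional[tuple[float, ...]] = None  # pin instead of drawing
    gain_rate_stem: float = 12.0
    loss_rate_stem: float = 1.0
    phase_weights: tuple[float, float, float] = (0.48, 0.30, 0.22)
    loss_3prime_bias: float = 2.0
    parallel_gain_rate: float = 0.0
    protein_length: int = 400
    branch_gain_prob: float = 0.01
    branch_loss_prob: float = 0.2
    post_leca_gain_rate: float = 0.3  # expected novel gains per branch per OG
    substitution_rate: float = 0.05  # per residue, per species sequence
    indel_mode: bool = False
    n_gap_columns: int = 10
    species_tree: Optional[AnnotatedTree] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if any(w < 0 for w in self.phase_weights):
            raise ValueError("phase weights must be nonnegative")
        total = sum(self.phase_weights)
        if total <= 0:
            raise ValueError("phase weights must not all be zero")
        self.phase_weights = tuple(w / total for w in self.phase_weights)
        for name in ("gain_rate_stem", "loss_rate_stem", "loss_3prime_bias",
                     "parallel_gain_rate", "branch_gain_prob",
                     "branch_loss_prob", "post_leca_gain_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def tree(self) -> AnnotatedTree:
        if self.species_tree is not None:
            return self.species_tree
        return default_species_tree(self.n_species)


# ---------------------------------------------------------------------------
# stem simulation
# ---------------------------------------------------------------------------

@dataclass
class FamilySim:
    """Ground truth for one family's stem history."""

    family_id: str
    gene_tree: AnnotatedTree
    leca_sets: dict[str, set[Key]]  # OG -> intron keys at LECA
    node_present: dict[str, set[Key]]  # gene-tree node -> state at the node
    gain_node: dict[Key, str]  # first gain: branch named by its child node
    gain_phase: dict[Key, int]
    n_parallel_gains: int
    loss_events: list[tuple[str, Key]]  # (branch child node, key)
    #: chronological per-branch event log: (branch child, "gain"/"loss", key)
    events: list[tuple[str, str, Key]]

    def true_preduplication(self, dup_name: str) -> set[Key]:
        return self.node_present[dup_name]


def _draw_new_key(rng, length: int, phase_weights, used: set[Key]) -> Key:
    while True:
        phase = int(rng.choice(3, p=phase_weights))
        # keep the coding offset >= 3 and the intron inside the CDS
        residue = int(rng.integers(2, length))
        key = (residue, phase)
        if key not in used:
            return key


def _pick_loss(rng, present: set[Key], bias: float, length: int) -> Key:
    keys = sorted(present)
    weights = np.exp([bias * key[0] / length for key in keys])
    weights = weights / weights.sum()
    return keys[int(rng.choice(len(keys), p=weights))]


def simulate_stem(config: SimulationConfig, family_id: str) -> FamilySim:
    """Simulate one family's eukaryogenesis stem.

    A family comprises ``n_acquisitions`` separately acquired homologous
    genes; each acquisition lineage undergoes its own duplications
    (times drawn uniformly on the stem unless pinned by
    ``duplication_times``), with each duplication splitting a uniformly
    chosen live lineage of that acquisition.  Between events the intron
    complement of each lineage evolves by a Gillespie walk of gains and
    (3'-biased) losses.  Intron positions are never re-used by fresh
    gains, so with ``parallel_gain_rate = 0`` every history is
    Dollo-consistent; parallel gains deliberately re-insert at positions
    already used elsewhere in the family (including other acquisitions).
    """
    rng = stream(config.seed, "stem", family_id)

    used: set[Key] = set()
    gain_node: dict[Key, str] = {}
    gain_phase: dict[Key, int] = {}
    node_present: dict[str, set[Key]] = {}
    loss_events: list[tuple[str, Key]] = []
    events: list[tuple[str, str, Key]] = []
    n_parallel = 0

    def evolve(state: set[Key], t0: float, t1: float, branch_child: str) -> set[Key]:
        nonlocal n_parallel
        state = set(state)
        t = t0
        while True:
            gain_rate = config.gain_rate_stem
            loss_rate = config.loss_rate_stem * len(state)
            total = gain_rate + loss_rate
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= t1:
                break
            if rng.uniform() < gain_rate / total:
                reusable = sorted(used - state)
                if (
                    config.parallel_gain_rate > 0
                    and reusable
                    and rng.uniform() < config.parallel_gain_rate
                ):
                    key = reusable[int(rng.integers(len(reusable)))]
                    n_parallel += 1
                else:
                    key = _draw_new_key(
                        rng, config.protein_length, config.phase_weights, used
                    )
                    gain_node[key] = branch_child
                    gain_phase[key] = key[1]
                used.add(key)
                state.add(key)
                events.append((branch_child, "gain", key))
            else:
                key = _pick_loss(
                    rng, state, config.loss_3prime_bias, config.protein_length
                )
                state.discard(key)
                loss_events.append((branch_child, key))
                events.append((branch_child, "loss", key))
        return state

    if config.n_acquisitions == 1:
        root = TreeNode(name=f"{family_id}_acq1", node_type="acquisition")
        acquisition_nodes = [root]
    else:
        root = TreeNode(name=f"{family_id}_root", node_type="speciation")
        acquisition_nodes = [
            root.add_child(
                TreeNode(
                    name=f"{family_id}_acq{a + 1}",
                    node_type="acquisition",
                    length=0.0,
                )
            )
            for a in range(config.n_acquisitions)
        ]
    node_present[root.name] = set()

    leca_sets: dict[str, set[Key]] = {}
    og_counter = 0
    for a, acq in enumerate(acquisition_nodes, start=1):
        node_present[acq.name] = set()
        if config.duplication_times is not None:
            dup_times = np.sort(np.asarray(config.duplication_times, dtype=float))
        else:
            dup_times = np.sort(rng.uniform(0.05, 0.95, size=config.n_duplications))
        # live lineages: (node to attach to, current state, branch start time)
        live: list[tuple[TreeNode, set[Key], float]] = [(acq, set(), 0.0)]
        for d, dup_time in enumerate(dup_times, start=1):
            idx = int(rng.integers(len(live)))
            parent_node, state, t0 = live.pop(idx)
            dup_name = f"{family_id}_A{a}_D{d}"
            child = parent_node.add_child(
                TreeNode(name=dup_name, node_type="duplication", length=dup_time - t0)
            )
            state = evolve(state, t0, dup_time, branch_child=dup_name)
            node_present[dup_name] = set(state)
            live.append((child, set(state), dup_time))
            live.append((child, set(state), dup_time))

        for parent_node, state, t0 in live:
            og_counter += 1
            og = f"{family_id}_OG{og_counter}"
            parent_node.add_child(TreeNode(name=og, node_type="leaf", length=1.0 - t0))
            final = evolve(state, t0, 1.0, branch_child=og)
            node_present[og] = set(final)
            leca_sets[og] = set(final)

    return FamilySim(
        family_id=family_id,
        gene_tree=AnnotatedTree(root),
        leca_sets=leca_sets,
        node_present=node_present,
        gain_node=gain_node,
        gain_phase=gain_phase,
        n_parallel_gains=n_parallel,
        loss_events=loss_events,
        events=events,
    )


def replay_events(family: FamilySim) -> dict[str, set[Key]]:
    """Recompute every node's intron state from the event log alone.

    Used to assert the ground truth's internal consistency: the replayed
    states must equal ``node_present`` bit-exactly.
    """
    events_by_branch: dict[str, list[tuple[str, Key]]] = {}
    for branch_child, kind, key in family.events:
        events_by_branch.setdefault(branch_child, []).append((kind, key))
    states: dict[str, set[Key]] = {}

    def walk(node, inherited: set[Key]) -> None:
        state = set(inherited)
        for kind, key in events_by_branch.get(node.name, []):
            if kind == "gain":
                state.add(key)
            else:
                state.discard(key)
        states[node.name] = state
        for child in node.children:
            walk(child, state)

    walk(family.gene_tree.root, set())
    return states


# ---------------------------------------------------------------------------
# post-LECA simulation
# ---------------------------------------------------------------------------

@dataclass
class PostLecaResult:
    """Leaf presence per OG plus the post-LECA novel introns."""

    presence: dict[str, dict[str, set[Key]]]  # og -> species -> keys present
    novel_keys: dict[str, set[Key]]  # og -> keys gained after LECA
    dropped_keys: dict[str, set[Key]]  # og -> LECA keys lost everywhere


def _branch_prob(spec_value, branch_name: str) -> float:
    if isinstance(spec_value, Mapping):
        return float(spec_value[branch_name])
    return float(spec_value)


def simulate_post_leca(
    leca_sets: Mapping[str, Iterable[Key]],
    species_tree: AnnotatedTree,
    branch_gain_prob,
    branch_loss_prob,
    seed: int,
    post_leca_gain_rate: float = 0.0,
    protein_length: int = 400,
    phase_weights=(0.48, 0.30, 0.22),
    og_tag: str = "",
) -> PostLecaResult:
    """Evolve each OG's introns down the species tree.

    LECA introns start present at the root; each (OG, position) evolves
    as an independent two-state chain with the given gain and loss
    probabilities (scalars applied to every branch, or mappings keyed by
    branch child-node name).  Novel positions arise as Poisson gains on
    branches and evolve below their gain branch.  Positions present in
    no extant species are reported in ``dropped_keys`` and omitted from
    ``presence`` values (unobservable).
    """
    phase_weights = np.asarray(phase_weights, dtype=float)
    phase_weights = phase_weights / phase_weights.sum()
    presence: dict[str, dict[str, set[Key]]] = {}
    novel: dict[str, set[Key]] = {}
    dropped: dict[str, set[Key]] = {}

    for og in sorted(leca_sets):
        rng = stream(seed, "post_leca", og_tag, og)
        keys = sorted(map(tuple, leca_sets[og]))
        used = set(keys)
        og_leaf_state: dict[str, set[Key]] = {
            leaf: set() for leaf in species_tree.leaf_names
        }
        novel[og] = set()

        def evolve_key(key: Key, start_node: TreeNode, present_at_start: bool):
            stack = [(start_node, present_at_start)]
            while stack:
                node, present = stack.pop()
                if node.is_leaf and present:
                    og_leaf_state[node.name].add(key)
                for child in node.children:
                    if present:
                        nxt = rng.uniform() >= _branch_prob(
                            branch_loss_prob, child.name
                        )
                    else:
                        nxt = rng.uniform() < _branch_prob(
                            branch_gain_prob, child.name
                        )
                    stack.append((child, nxt))

        for key in keys:
            evolve_key(key, species_tree.root, True)

        if post_leca_gain_rate > 0:
            for branch in species_tree.branches():
                for _ in range(int(rng.poisson(post_leca_gain_rate))):
                    key = _draw_new_key(rng, protein_length, phase_weights, used)
                    used.add(key)
                    novel[og].add(key)
                    evolve_key(key, branch, True)

        observable = {k for state in og_leaf_state.values() for k in state}
        dropped[og] = set(keys) - observable
        novel[og] &= observable
        presence[og] = {
            leaf: state & observable for leaf, state in og_leaf_state.items()
        }
    return PostLecaResult(presence=presence, novel_keys=novel, dropped_keys=dropped)


def simulate_patterns(
    tree: AnnotatedTree,
    gain_prob: float,
    loss_prob: float,
    root_prior: float,
    n_positions: int,
    seed: int,
):
    """Independent presence patterns for rate-recovery experiments.

    Each position draws its root state from ``root_prior`` and evolves
    down the tree with uniform per-branch probabilities.  Returns
    ``(patterns, root_states, node_states)`` where patterns are
    ``{leaf: '0'/'1'}`` dictionaries over all simulated positions
    (including unobservable ones; filter on observability as needed).
    """
    rng = stream(seed, "patterns")
    patterns = []
    root_states = []
    node_states = []
    for _ in range(n_positions):
        states: dict[str, int] = {}
        root_state = int(rng.uniform() < root_prior)
        states[tree.root.name] = root_state
        for node in tree.preorder():
            if node.parent is None:
                continue
            parent_state = states[node.parent.name]
            if parent_state == 1:
                states[node.name] = int(rng.uniform() >= loss_prob)
            else:
                states[node.name] = int(rng.uniform() < gain_prob)
        patterns.append({leaf: str(states[leaf]) for leaf in tree.leaf_names})
        root_states.append(root_state)
        node_states.append(states)
    return patterns, root_states, node_states


# ---------------------------------------------------------------------------
# sequence emission
# ---------------------------------------------------------------------------

def _random_protein(rng, length: int) -> str:
    return "".join(rng.choice(_AMINO_ACIDS) for _ in range(length))


def _mutate_protein(rng, protein: str, rate: float) -> str:
    residues = list(protein)
    for i in range(len(residues)):
        if rng.uniform() < rate:
            residues[i] = _AMINO_ACIDS[int(rng.integers(len(_AMINO_ACIDS)))]
    return "".join(residues)


def _back_translate(rng, protein: str) -> str:
    return "".join(
        _CODONS[aa][int(rng.integers(len(_CODONS[aa])))] for aa in protein
    )


def _random_intron(rng) -> str:
    length = int(rng.integers(60, 121))
    body = "".join("ACGT"[int(rng.integers(4))] for _ in range(length - 4))
    return "GT" + body + "AG"


@dataclass
class GeneModel:
    """One emitted gene: its protein, introns and genomic realisation."""

    species: str
    og_id: str
    protein: str
    intron_keys: list[Key]
    strand: str
    contig: str
    contig_seq: str
    cds_segments_1based: list[tuple[int, int]]  # GFF3 convention


def emit_gene(
    rng, species: str, og_id: str, protein: str, intron_keys: Iterable[Key]
) -> GeneModel:
    """Realise a gene genomically: back-translate, insert introns, pick a
    strand.  Intron key (residue, phase) sits after coding offset
    ``3·(residue−1)+phase`` nucleotides."""
    cds = _back_translate(rng, protein) + "TAA"
    offsets = sorted(
        (3 * (residue - 1) + phase) for residue, phase in set(intron_keys)
    )
    if any(o < 3 or o >= len(cds) - 3 for o in offsets):
        raise ValueError("intron offset outside the coding sequence")

    pieces = []
    segments_sense: list[tuple[int, int]] = []  # 0-based half-open, sense coords
    genome_pos = 0
    prev = 0
    boundaries = offsets + [len(cds)]
    for i, offset in enumerate(boundaries):
        exon = cds[prev:offset]
        pieces.append(exon)
        segments_sense.append((genome_pos, genome_pos + len(exon)))
        genome_pos += len(exon)
        if i < len(offsets):
            intron = _random_intron(rng)
            pieces.append(intron)
            genome_pos += len(intron)
        prev = offset
    sense = "".join(pieces)

    # flanking sequence so genes do not start at the contig edge
    flank5 = "".join("ACGT"[int(rng.integers(4))] for _ in range(20))
    flank3 = "".join("ACGT"[int(rng.integers(4))] for _ in range(20))
    sense_contig = flank5 + sense + flank3
    segments_sense = [
        (start + len(flank5), end + len(flank5)) for start, end in segments_sense
    ]

    strand = "+" if rng.uniform() < 0.5 else "-"
    if strand == "+":
        contig_seq = sense_contig
        segments = segments_sense
    else:
        complement = str.maketrans("ACGT", "TGCA")
        contig_seq = sense_contig.translate(complement)[::-1]
        n = len(sense_contig)
        segments = sorted((n - end, n - start) for start, end in segments_sense)

    return GeneModel(
        species=species,
        og_id=og_id,
        protein=protein,
        intron_keys=sorted(set(intron_keys)),
        strand=strand,
        contig=f"{og_id}_{species}_ctg",
        contig_seq=contig_seq,
        cds_segments_1based=[(s + 1, e) for s, e in segments],
    )


def write_species_files(genes: list[GeneModel], outdir, species: str) -> None:
    """Write one species' genome FASTA, GFF3 and protein FASTA."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"{species}.genome.fa", "w") as fa, open(
        outdir / f"{species}.gff3", "w"
    ) as gff, open(outdir / f"{species}.proteins.fa", "w") as prot:
        gff.write("##gff-version 3\n")
        for gene in genes:
            fa.write(f">{gene.contig}\n{gene.contig_seq}\n")
            prot.write(f">{gene.og_id}\n{gene.protein}\n")
            first = min(s for s, _ in gene.cds_segments_1based)
            last = max(e for _, e in gene.cds_segments_1based)
            mrna = f"{gene.og_id}.t"
            gff.write(
                f"{gene.contig}\tsim\tgene\t{first}\t{last}\t.\t{gene.strand}\t."
                f"\tID={gene.og_id}.g\n"
            )
            gff.write(
                f"{gene.contig}\tsim\tmRNA\t{first}\t{last}\t.\t{gene.strand}\t."
                f"\tID={mrna};Parent={gene.og_id}.g;protein_id={gene.og_id}\n"
            )
            for start, end in gene.cds_segments_1based:
                gff.write(
                    f"{gene.contig}\tsim\tCDS\t{start}\t{end}\t.\t{gene.strand}"
                    f"\t.\tParent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def _insert_gap_columns(rows: dict[str, str], columns: list[int]) -> dict[str, str]:
    """Insert all-row gap columns before the given residue indices."""
    out = {}
    for sid, row in rows.items():
        chars = list(row)
        for col in sorted(columns, reverse=True):
            chars.insert(col, "-")
        out[sid] = "".join(chars)
    return out


@dataclass
class FamilyAlignments:
    family_id: str
    og_rows: dict[str, dict[str, str]]  # og -> sequence_id -> row
    merged_rows: dict[str, str]  # sequence_id -> row
    og_column_of_residue: dict[str, dict[int, int]]  # og -> residue -> column
    merged_column_of_residue: dict[int, int]


def emit_alignments(
    family_id: str,
    proteins: Mapping[str, Mapping[str, str]],  # og -> species -> protein
    seed: int,
    indel_mode: bool = False,
    n_gap_columns: int = 10,
) -> FamilyAlignments:
    """True per-OG and merged alignments (no aligner is invoked).

    In the default substitution-only mode all rows are gap-free and the
    merged column of a residue is its index.  In indel mode, all-row gap
    columns are inserted at random (different ones per OG and for the
    merged alignment), exercising the column-transfer bookkeeping while
    keeping the true coordinates known.
    """
    rng = stream(seed, "alignments", family_id)
    length = len(next(iter(next(iter(proteins.values())).values())))
    og_rows = {}
    og_colmap = {}
    for og in sorted(proteins):
        rows = {
            f"{species}|{og}": protein
            for species, protein in sorted(proteins[og].items())
        }
        colmap = {r: r for r in range(1, length + 1)}
        if indel_mode:
            gap_cols = sorted(rng.choice(length + 1, size=n_gap_columns, replace=False))
            rows = _insert_gap_columns(rows, list(gap_cols))
            colmap = {}
            for residue in range(1, length + 1):
                shift = sum(1 for g in gap_cols if g < residue)
                colmap[residue] = residue + shift
        og_rows[og] = rows
        og_colmap[og] = colmap

    merged_colmap = {r: r for r in range(1, length + 1)}
    merged_rows = {
        sid: row for og in sorted(proteins) for sid, row in (
            (f"{species}|{og}", protein)
            for species, protein in sorted(proteins[og].items())
        )
    }
    if indel_mode:
        gap_cols = sorted(rng.choice(length + 1, size=n_gap_columns, replace=False))
        merged_rows = _insert_gap_columns(merged_rows, list(gap_cols))
        merged_colmap = {}
        for residue in range(1, length + 1):
            shift = sum(1 for g in gap_cols if g < residue)
            merged_colmap[residue] = residue + shift

    return FamilyAlignments(
        family_id=family_id,
        og_rows=og_rows,
        merged_rows=merged_rows,
        og_column_of_residue=og_colmap,
        merged_column_of_residue=merged_colmap,
    )


# ---------------------------------------------------------------------------
# whole-dataset driver
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything one simulation run produces, with its ground truth."""

    config: SimulationConfig
    species_tree: AnnotatedTree
    families: list[FamilySim]
    post_leca: dict[str, PostLecaResult]  # family -> result
    proteins: dict[str, dict[str, dict[str, str]]]  # family -> og -> species -> seq
    alignments: dict[str, FamilyAlignments]

    def leaf_presence(self, family_id: str) -> dict[str, dict[str, set[Key]]]:
        return self.post_leca[family_id].presence


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the full stem + post-LECA + emission simulation."""
    tree = config.tree()
    families = [
        simulate_stem(config, f"fam{i + 1:03d}") for i in range(config.n_families)
    ]
    post = {}
    proteins: dict[str, dict[str, dict[str, str]]] = {}
    alignments = {}
    for family in families:
        post[family.family_id] = simulate_post_leca(
            family.leca_sets,
            tree,
            config.branch_gain_prob,
            config.branch_loss_prob,
            seed=config.seed,
            post_leca_gain_rate=config.post_leca_gain_rate,
            protein_length=config.protein_length,
            phase_weights=config.phase_weights,
            og_tag=family.family_id,
        )
        rng = stream(config.seed, "proteins", family.family_id)
        ancestral = _random_protein(rng, config.protein_length)
        proteins[family.family_id] = {
            og: {
                species: _mutate_protein(rng, ancestral, config.substitution_rate)
                for species in tree.leaf_names
            }
            for og in sorted(family.leca_sets)
        }
        alignments[family.family_id] = emit_alignments(
            family.family_id,
            proteins[family.family_id],
            seed=config.seed,
            indel_mode=config.indel_mode,
            n_gap_columns=config.n_gap_columns,
        )
    return SyntheticDataset(
        config=config,
        species_tree=tree,
        families=families,
        post_leca=post,
        proteins=proteins,
        alignments=alignments,
    )


def emit_genomes(dataset: SyntheticDataset) -> dict[str, list[GeneModel]]:
    """Realise every (species, OG) gene genomically."""
    genes: dict[str, list[GeneModel]] = {
        sp: [] for sp in dataset.species_tree.leaf_names
    }
    for family in dataset.families:
        presence = dataset.post_leca[family.family_id].presence
        for og in sorted(family.leca_sets):
            for species in dataset.species_tree.leaf_names:
                rng = stream(dataset.config.seed, "genome", og, species)
                genes[species].append(
                    emit_gene(
                        rng,
                        species,
                        og,
                        dataset.proteins[family.family_id][og][species],
                        sorted(presence[og][species]),
                    )
                )
    return genes


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write the dataset as FASTA/GFF3/alignment/Newick/TSV files."""
    from pathlib import Path

    from .data_io import write_fasta
    from .trees import write_annotated_tree

    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    (outdir / "alignments").mkdir(exist_ok=True)
    (outdir / "trees").mkdir(exist_ok=True)

    write_annotated_tree(dataset.species_tree, outdir / "trees" / "species.nwk")
    for family in dataset.families:
        write_annotated_tree(
            family.gene_tree, outdir / "trees" / f"{family.family_id}.nwk"
        )

    genes = emit_genomes(dataset)
    for species, species_genes in genes.items():
        write_species_files(species_genes, outdir / "genomes", species)

    for family_id, fam_aln in dataset.alignments.items():
        for og, rows in fam_aln.og_rows.items():
            write_fasta(rows, outdir / "alignments" / f"{og}.aln.fa")
        write_fasta(
            fam_aln.merged_rows, outdir / "alignments" / f"{family_id}.merged.fa"
        )

    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("family\tog\tresidue\tphase\tleca\tgain_node\n")
        for family in dataset.families:
            for og in sorted(family.leca_sets):
                for key in sorted(family.leca_sets[og]):
                    gain = family.gain_node.get(key, "parallel")
                    fh.write(
                        f"{family.family_id}\t{og}\t{key[0]}\t{key[1]}\t1\t{gain}\n"
                    )
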