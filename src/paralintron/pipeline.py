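"""End-to-end orchestration: map → reconstruct → shared → dollo → stats.

The pipeline consumes a directory in the layout the simulator emits
(and which mirrors how a real dataset would be organised):

    genomes/<species>.genome.fa, <species>.gff3, <species>.proteins.fa
    alignments/<og>.aln.fa            per-orthogroup alignments
    alignments/<family>.merged.fa     merged per-family alignments
    trees/species.nwk                 rooted species tree
    trees/<family>.nwk                annotated gene trees

Orthogroup ids follow ``<family>_OG<k>``; sequence ids in alignments
follow ``<species>|<og>``.  Every output TSV starts with a provenance
comment (package version, config hash, seed); a rerun with an identical
config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from . import ancestral, data_io, intron_mapping, paralogs, stats
from .trees import AnnotatedTree, collapse_branch

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration of a pipeline run."""

    data_dir: str
    out_dir: str
    seed: int = 1
    rooting: str = "opimoda-diphoda"  # or "unresolved"
    leca_threshold: float = 0.5
    gap_mask_threshold: float = 0.9
    u12_min_species: int = 3
    rates_mode: str = "tied"  # tied rates: the sane default at desk scale
    u12_predictions: Optional[str] = None
    metadata: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.leca_threshold <= 1.0:
            raise ValueError("LECA threshold must lie in (0, 1]")
        if not 0.0 < self.gap_mask_threshold <= 1.0:
            raise ValueError("gap-mask threshold must lie in (0, 1]")
        if self.u12_min_species < 1:
            raise ValueError("U12 species minimum must be at least 1")
        if self.rooting not in ("opimoda-diphoda", "unresolved"):
            raise ValueError(f"unknown rooting mode {self.rooting!r}")
        if self.rates_mode not in ("tied", "loss", "full"):
            raise ValueError(f"unknown rates mode {self.rates_mode!r}")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded: they locate
        the data but do not influence the computation)."""
        fields = asdict(self)
        fields.pop("data_dir")
        fields.pop("out_dir")
        payload = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    tables: dict[str, intron_mapping.IntronTable]
    rates: ancestral.BranchRates
    leca_sets_merged: dict[str, dict[str, set]]  # family -> og -> merged keys
    classifications: dict[str, paralogs.SharedClassification]
    control: Optional[paralogs.ControlResult]
    dollo_states: dict[str, paralogs.GeneTreeState]
    event_counts: tuple[int, int, int, int]
    leca_density: float
    relative_positions: dict[str, list[float]]
    phase_counts: dict[str, tuple[int, int, int]]
    u12_types: dict = field(default_factory=dict)
    group_table: Optional[paralogs.GroupTable] = None


def _provenance(config: PipelineConfig) -> str:
    return (
        f"# paralintron v{__version__} config={config.config_hash()} "
        f"seed={config.seed}\n"
    )


def _family_of_og(og_id: str) -> str:
    return og_id.rsplit("_OG", 1)[0]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in dependency order and write the outputs."""
    data_dir = Path(config.data_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # ---------------- stage 1: map introns onto alignments -------------
    species_tree = data_io.read_annotated_tree(data_dir / "trees" / "species.nwk")
    species_list = sorted(species_tree.leaf_names)
    genomes = {}
    for gff in sorted((data_dir / "genomes").glob("*.gff3")):
        species = gff.stem
        genomes[species] = data_io.read_gff3(
            gff, data_dir / "genomes" / f"{species}.genome.fa", species_id=species
        )
    if not genomes:
        raise RuntimeError(f"stage map: no GFF3 files under {data_dir / 'genomes'}")

    tables: dict[str, intron_mapping.IntronTable] = {}
    ogs: dict[str, data_io.OrthogroupAlignment] = {}
    tables_dir = out_dir / "tables"
    tables_dir.mkdir(exist_ok=True)
    for aln_path in sorted((data_dir / "alignments").glob("*.aln.fa")):
        og_id = aln_path.name[: -len(".aln.fa")]
        og = data_io.read_alignment(aln_path, og_id=og_id)
        ogs[og_id] = og
        mapped: dict[str, list] = {}
        for species, genome in genomes.items():
            mapped.update(intron_mapping.map_genome_introns(genome, og))
        tables[og_id] = intron_mapping.build_intron_table(og, mapped, species_list)
        data_io.write_intron_table(tables[og_id], tables_dir / f"{og_id}.tsv")
    logger.info("stage map: %d orthogroups, %d species", len(tables), len(genomes))

    # ---------------- stage 2: ancestral reconstruction ----------------
    if config.rooting == "unresolved" and not species_tree.root_is_multifurcating:
        # collapse the basal bifurcation into a root multifurcation
        internal_children = [
            c for c in species_tree.root.children if not c.is_leaf
        ]
        if internal_children:
            species_tree = collapse_branch(
                species_tree, internal_children[0].name
            )
    estimate = ancestral.estimate_rates(
        list(tables.values()), species_tree, mode=config.rates_mode
    )
    rates = estimate.rates
    with open(out_dir / "rates.tsv", "w") as fh:
        fh.write(_provenance(config))
        fh.write(f"# root_prior={rates.root_prior:.6f}\n")
        fh.write("branch\tgain\tloss\n")
        for name in sorted(rates.gain):
            fh.write(f"{name}\t{rates.gain[name]:.6f}\t{rates.loss[name]:.6f}\n")

    leca_node = species_tree.root.name
    posteriors_by_og = {}
    leca_calls_by_og: dict[str, list] = {}
    for og_id, table in tables.items():
        recon = ancestral.reconstruct_table(
            table, species_tree, rates, leca_node, config.leca_threshold
        )
        posteriors_by_og[og_id] = [post for post, _ in recon]
        leca_calls_by_og[og_id] = [call for _, call in recon]

    n_ogs = len(tables)
    root_count = sum(
        ancestral.node_intron_count(
            posteriors_by_og[og], leca_node, species_tree, rates
        )
        for og in tables
    )
    leca_density = root_count / n_ogs if n_ogs else 0.0

    with open(out_dir / "leca_calls.tsv", "w") as fh:
        fh.write(_provenance(config))
        fh.write("og\tcolumn\tphase\tleca_probability\tis_leca\n")
        for og_id in sorted(leca_calls_by_og):
            for call in leca_calls_by_og[og_id]:
                pos = call.position
                fh.write(
                    f"{og_id}\t{pos.alignment_column}\t{pos.phase}"
                    f"\t{call.leca_probability:.6f}\t{int(call.is_leca)}\n"
                )

    # ---------------- stage 3: shared introns between paralogs ---------
    merged_rows_by_family: dict[str, dict[str, str]] = {}
    for merged_path in sorted((data_dir / "alignments").glob("*.merged.fa")):
        family = merged_path.name[: -len(".merged.fa")]
        merged_rows_by_family[family] = data_io.read_fasta(merged_path)

    leca_sets_merged: dict[str, dict[str, set]] = {}
    merged_position_of: dict[str, dict] = {}
    for og_id, calls in leca_calls_by_og.items():
        family = _family_of_og(og_id)
        merged_rows = merged_rows_by_family.get(family, {})
        leca_positions = [c.position for c in calls if c.is_leca]
        transfer = intron_mapping.transfer_positions(
            leca_positions, ogs[og_id], merged_rows
        )
        merged_position_of[og_id] = transfer
        keys = {
            (m.alignment_column, m.phase)
            for m in transfer.values()
            if m is not None
        }
        leca_sets_merged.setdefault(family, {})[og_id] = keys

    # optional U12-type annotation of LECA calls (OG coordinates)
    u12_types: dict[str, dict] = {}
    if config.u12_predictions:
        predictions = data_io.read_u12_predictions(config.u12_predictions)
        for og_id, calls in leca_calls_by_og.items():
            positions = [c.position for c in calls if c.is_leca]
            u12_types[og_id] = paralogs.annotate_u12(
                predictions, positions, min_species=config.u12_min_species
            )

    classifications = {}
    control_tables = []
    with open(out_dir / "classification.tsv", "w") as fh:
        fh.write(_provenance(config))
        fh.write("family\tog\tmerged_column\tphase\tcategory\tintron_type\n")
        for family in sorted(leca_sets_merged):
            gene_tree = data_io.read_annotated_tree(
                data_dir / "trees" / f"{family}.nwk"
            )
            pmap = paralogs.paralogy_from_tree(gene_tree)
            classification = paralogs.classify_shared(
                leca_sets_merged[family], pmap
            )
            classifications[family] = classification
            control_tables.append((leca_sets_merged[family], pmap))
            merged_to_og = {
                og: {
                    (m.alignment_column, m.phase): pos
                    for pos, m in merged_position_of[og].items()
                    if m is not None
                }
                for og in leca_sets_merged[family]
            }
            for (og, key), category in sorted(classification.category.items()):
                og_pos = merged_to_og[og].get(key)
                intron_type = u12_types.get(og, {}).get(og_pos, "U2")
                fh.write(
                    f"{family}\t{og}\t{key[0]}\t{key[1]}\t{category}"
                    f"\t{intron_type}\n"
                )

    control = None
    if control_tables:
        control = paralogs.parallel_gain_control(control_tables)
    with open(out_dir / "control.tsv", "w") as fh:
        fh.write(_provenance(config))
        fh.write("fraction_paralogs\tfraction_separate\tfisher_p\n")
        if control is None:
            fh.write("NA\tNA\tNA\n")
        else:
            fh.write(
                f"{control.fraction_paralogs:.6f}\t"
                f"{control.fraction_separate:.6f}\t{control.fisher.p:.6g}\n"
            )

    # ---------------- stage 4: Dollo pre-duplication inference ---------
    dollo_states = {}
    for family in sorted(leca_sets_merged):
        gene_tree = data_io.read_annotated_tree(data_dir / "trees" / f"{family}.nwk")
        dollo_states[family] = paralogs.dollo_preduplication(
            gene_tree, leca_sets_merged[family]
        )
    event_counts = paralogs.count_preduplication_events(dollo_states.values())
    with open(out_dir / "dollo_events.tsv", "w") as fh:
        fh.write(_provenance(config))
        fh.write(
            "gains_before_duplications\tlosses_before_duplications"
            "\tgains_to_leca\tlosses_to_leca\n"
        )
        fh.write("\t".join(str(c) for c in event_counts) + "\n")
    with open(out_dir / "duplications.tsv", "w") as fh:
        fh.write(_provenance(config))
        fh.write("family\tduplication\thas_introns\tancestral_had_introns\n")
        for family in sorted(dollo_states):
            state = dollo_states[family]
            flags = state.duplications_with_introns()
            ancestral_flags = state.ancestral_duplication_had_introns()
            for dup in sorted(flags):
                fh.write(
                    f"{family}\t{dup}\t{int(flags[dup])}"
                    f"\t{int(ancestral_flags[dup])}\n"
                )

    # ---------------- stage 5: group fractions (optional metadata) -----
    group_table = None
    if config.metadata:
        import pandas as pd

        meta = pd.read_csv(config.metadata, sep="\t", comment="#", dtype=str)
        og_categories = {
            row.og_id: set(str(row.function).split(";"))
            for row in meta.itertuples()
        }
        outcomes = {}
        categories = {}
        for family, classification in classifications.items():
            for (og, key), category in classification.category.items():
                if category not in ("shared", "unique"):
                    continue
                unit = f"{og}:{key[0]}.{key[1]}"
                outcomes[unit] = category == "shared"
                categories[unit] = og_categories.get(og, set())
        group_table = paralogs.group_fractions(outcomes, categories)
        with open(out_dir / "groups.tsv", "w") as fh:
            fh.write(_provenance(config))
            fh.write("group\tshared\tunique\n")
            for group, (with_, without) in group_table.counts.items():
                fh.write(f"{group}\t{with_}\t{without}\n")
            if group_table.chi2 is not None:
                fh.write(
                    f"# chi2={group_table.chi2.statistic:.4f} "
                    f"df={group_table.chi2.df} p={group_table.chi2.p:.4g}\n"
                )
            for a, b, result in group_table.pairwise:
                fh.write(
                    f"# pair {a} vs {b}: p={result.p:.4g} "
                    f"p_adj={result.p_adj:.4g}\n"
                )

    # ---------------- stage 6: positional and phase statistics ---------
    category_of_key: dict[tuple[str, tuple], str] = {}
    for family, classification in classifications.items():
        for (og, key), category in classification.category.items():
            category_of_key[(og, key)] = category

    relative_positions: dict[str, list[float]] = {
        "shared": [], "unique": [], "post-LECA": []
    }
    phases: dict[str, list[int]] = {"shared": [], "unique": [], "post-LECA": []}
    for og_id, table in tables.items():
        mask = intron_mapping.mask_alignment(
            ogs[og_id], gap_threshold=config.gap_mask_threshold
        )
        calls = {c.position: c for c in leca_calls_by_og[og_id]}
        for pos in table.positions:
            call = calls[pos]
            if call.is_leca:
                merged = merged_position_of[og_id].get(pos)
                if merged is None:
                    continue
                key = (merged.alignment_column, merged.phase)
                category = category_of_key.get((og_id, key))
                if category not in ("shared", "unique"):
                    continue
            else:
                category = "post-LECA"
            relative_positions[category].append(
                intron_mapping.relative_position(pos, mask)
            )
            phases[category].append(pos.phase)

    phase_counts, phase_tests = stats.phase_distribution(
        {k: v for k, v in phases.items() if v}
    )
    ks_results = []
    nonempty = [k for k, v in relative_positions.items() if v]
    from itertools import combinations

    raw = []
    pairs = list(combinations(nonempty, 2))
    for a, b in pairs:
        raw.append(stats.ks_two_sample(relative_positions[a], relative_positions[b]))
    for (a, b), result, p_adj in zip(pairs, raw, stats.bh_fdr([r.p for r in raw])):
        result.p_adj = p_adj
        ks_results.append((a, b, result))

    with open(out_dir / "stats.tsv", "w") as fh:
        fh.write(_provenance(config))
        fh.write("test\tgroup_a\tgroup_b\tstatistic\tdf\tp\tp_adj\n")
        for a, b, result in ks_results:
            fh.write(
                f"ks_relative_position\t{a}\t{b}\t{result.statistic:.6f}\t."
                f"\t{result.p:.6g}\t{result.p_adj:.6g}\n"
            )
        for a, b, result in phase_tests:
            fh.write(
                f"chi2_phase\t{a}\t{b}\t{result.statistic:.6f}\t{result.df}"
                f"\t{result.p:.6g}\t{result.p_adj:.6g}\n"
            )

    with open(out_dir / "summary.tsv", "w") as fh:
        fh.write(_provenance(config))
        fh.write("quantity\tvalue\n")
        fh.write(f"n_orthogroups\t{len(tables)}\n")
        fh.write(f"leca_density_per_og\t{leca_density:.4f}\n")
        total_considered = sum(
            c.n_considered for c in classifications.values()
        )
        total_shared = sum(c.count("shared") for c in classifications.values())
        fraction = total_shared / total_considered if total_considered else float("nan")
        fh.write(f"n_leca_introns_considered\t{total_considered}\n")
        fh.write(f"fraction_shared\t{fraction:.6f}\n")

    return PipelineResult(
        config=config,
        tables=tables,
        rates=rates,
        leca_sets_merged=leca_sets_merged,
        classifications=classifications,
        control=control,
        dollo_states=dollo_states,
        event_counts=event_counts,
        leca_density=leca_density,
        relative_positions=relative_positions,
        phase_counts=phase_counts,
        u12_types=u12_types,
        group_table=group_table,
    )
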