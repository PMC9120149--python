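"""Genomic→protein intron coordinates and alignment projection."""

import numpy as np
import pytest

from paralintron.data_io import OrthogroupAlignment, Transcript
from paralintron.intron_mapping import (
    IntronPosition,
    build_intron_table,
    introns_from_transcript,
    map_genome_introns,
    mask_alignment,
    project_to_alignment,
    relative_position,
    transfer_to_merged,
)
from paralintron.simulate import (
    SimulationConfig,
    emit_gene,
    simulate_dataset,
    stream,
)


def t(strand, segments):
    # segments given 1-based inclusive for readability, as in GFF3
    return Transcript(
        transcript_id="t1",
        protein_id="p1",
        strand=strand,
        cds_segments=[(s - 1, e) for s, e in segments],
        contig="ctg",
    )


class TestIntronsFromTranscript:
    @pytest.mark.parametrize(
        "strand,segments,offset,phase,anchor",
        [
            ("+", [(1, 9), (16, 24)], 9, 0, 4),
            ("+", [(1, 7), (16, 24)], 7, 1, 3),
            # '-' strand: mRNA order is (120,128) then (101,109)
            ("-", [(101, 109), (120, 128)], 9, 0, 4),
        ],
    )
    def test_single_intron_coordinates(self, strand, segments, offset, phase, anchor):
        (intron,) = introns_from_transcript(t(strand, segments))
        assert intron.coding_offset == offset
        assert intron.phase == phase
        assert intron.anchor_residue == anchor

    def test_short_intron_flagged_but_reported(self):
        with pytest.warns(UserWarning, match="short intron"):
            introns = introns_from_transcript(t("+", [(1, 9), (12, 20)]))
        assert len(introns) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_phase_is_coding_offset_mod_three(self, seed):
        rng = np.random.default_rng(seed)
        n_seg = int(rng.integers(2, 6))
        pos = 1
        segments = []
        for _ in range(n_seg):
            length = int(rng.integers(1, 30))
            segments.append((pos, pos + length - 1))
            pos += length + int(rng.integers(4, 50))
        strand = "+" if rng.uniform() < 0.5 else "-"
        for intron in introns_from_transcript(t(strand, segments)):
            assert intron.phase == intron.coding_offset % 3

    @pytest.mark.parametrize("seed", range(10))
    def test_strand_symmetry(self, seed):
        """Mirroring a gene onto the other strand preserves all introns."""
        rng = np.random.default_rng(seed)
        pos = 1
        segments = []
        for _ in range(int(rng.integers(2, 5))):
            length = int(rng.integers(3, 30))
            segments.append((pos, pos + length - 1))
            pos += length + int(rng.integers(10, 60))
        span = segments[-1][1] + 10
        mirrored = sorted((span - e + 1, span - s + 1) for s, e in segments)
        forward = introns_from_transcript(t("+", segments))
        reverse = introns_from_transcript(t("-", mirrored))
        assert [(i.coding_offset, i.phase) for i in forward] == [
            (i.coding_offset, i.phase) for i in reverse
        ]


class TestProjection:
    def test_anchor_counts_non_gap_characters(self):
        pi_like = introns_from_transcript(t("+", [(1, 7), (16, 24)]))[0]
        assert pi_like.anchor_residue == 3
        pos = project_to_alignment(pi_like, "A-CD-EF", og_id="og")
        assert pos.alignment_column == 4
        assert pos.phase == 1

    def test_leading_gaps_shift_first_residue(self):
        pi = introns_from_transcript(t("+", [(1, 1), (10, 18)]))[0]
        assert pi.anchor_residue == 1
        assert project_to_alignment(pi, "---MAAA").alignment_column == 4

    def test_anchor_beyond_sequence_is_unsuccessful(self):
        pi = introns_from_transcript(t("+", [(1, 30), (40, 45)]))[0]
        assert pi.anchor_residue == 11
        assert project_to_alignment(pi, "AC-DE") is None


class TestIntronTableConstruction:
    def og(self):
        return OrthogroupAlignment(
            og_id="og",
            rows={"spA|s1": "AAAA", "spA|s2": "AAAA", "spB|s3": "AAAA"},
            species_of={"spA|s1": "spA", "spA|s2": "spA", "spB|s3": "spB"},
        )

    def test_any_sequence_of_a_species_sets_presence(self):
        table = build_intron_table(
            self.og(),
            {"spA|s1": [IntronPosition("og", 2, 0)], "spA|s2": [], "spB|s3": []},
            ["spA", "spB"],
        )
        assert table.states["spA"] == "1"
        assert table.states["spB"] == "0"

    def test_species_absent_from_og_gets_question_marks(self):
        table = build_intron_table(
            self.og(),
            {"spA|s1": [IntronPosition("og", 2, 0)], "spA|s2": [], "spB|s3": []},
            ["spA", "spB", "spC"],
        )
        assert table.states["spC"] == "?"

    def test_unmappable_species_gets_question_marks(self):
        # spB present in the OG but none of its sequences mapped
        table = build_intron_table(
            self.og(),
            {"spA|s1": [IntronPosition("og", 2, 0)], "spA|s2": []},
            ["spA", "spB"],
        )
        assert table.states["spB"] == "?"

    def test_disjoint_positions_sorted_by_column_then_phase(self):
        table = build_intron_table(
            self.og(),
            {
                "spA|s1": [IntronPosition("og", 3, 1)],
                "spA|s2": [],
                "spB|s3": [IntronPosition("og", 2, 0)],
            },
            ["spA", "spB"],
        )
        assert [p.key for p in table.positions] == [(2, 0), (3, 1)]
        assert table.states["spA"] == "01"
        assert table.states["spB"] == "10"


class TestMergedTransfer:
    def test_column_recomputed_by_residue_rank(self):
        pos = IntronPosition("og", 4, 1)  # residue D in "A-CD-EF" is rank 3
        merged = transfer_to_merged(pos, "A-CD-EF", "A--C-D--EF")
        assert merged.alignment_column == 6
        assert merged.phase == 1

    def test_identity_when_rows_match(self):
        pos = IntronPosition("og", 4, 2)
        assert transfer_to_merged(pos, "A-CD-EF", "A-CD-EF").alignment_column == 4

    def test_mismatched_sequences_rejected(self):
        with pytest.raises(ValueError, match="seq9"):
            transfer_to_merged(
                IntronPosition("og", 1, 0), "AC", "AG", sequence_id="seq9"
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_invariant_to_gap_only_edits(self, seed):
        rng = np.random.default_rng(seed)
        residues = "".join(rng.choice(list("ACDEFGHIK"), size=12))

        def regap(seq):
            out = []
            for ch in seq:
                while rng.uniform() < 0.3:
                    out.append("-")
                out.append(ch)
            return "".join(out)

        row_a, row_b = regap(residues), regap(residues)
        rank = int(rng.integers(1, 13))
        col_a = [i for i, ch in enumerate(row_a, 1) if ch != "-"][rank - 1]
        pos = IntronPosition("og", col_a, 0)
        merged = transfer_to_merged(pos, row_a, row_b)
        col_b = [i for i, ch in enumerate(row_b, 1) if ch != "-"][rank - 1]
        assert merged.alignment_column == col_b


class TestMaskAndRelativePosition:
    def test_gap_fraction_at_threshold_is_masked(self):
        og = OrthogroupAlignment(
            og_id="og",
            rows={
                "a": "A-A",
                "b": "A-A",
                "c": "A-A",
                "d": "A-A",
                "e": "A-A",
                "f": "A-A",
                "g": "A-A",
                "h": "A-A",
                "i": "A-A",
                "j": "AAA",
            },
            species_of={k: k for k in "abcdefghij"},
        )
        mask = mask_alignment(og)  # column 2 has exactly 90% gaps
        assert mask.kept_columns == [1, 3]

    def test_x_and_ambiguity_codes_are_residues(self):
        og = OrthogroupAlignment(
            og_id="og",
            rows={"a": "X-", "b": "X-"},
            species_of={"a": "a", "b": "b"},
        )
        assert mask_alignment(og).kept_columns == [1]

    def test_rank_over_kept_columns(self):
        from paralintron.intron_mapping import MaskedAlignment

        mask = MaskedAlignment(og_id="og", kept_columns=list(range(1, 81)))
        assert relative_position(IntronPosition("og", 25, 0), mask) == 25 / 80

    def test_first_kept_column_boundary(self):
        from paralintron.intron_mapping import MaskedAlignment

        mask = MaskedAlignment(og_id="og", kept_columns=[5, 9, 14])
        assert relative_position(IntronPosition("og", 5, 0), mask) == pytest.approx(1 / 3)

    def test_masked_column_takes_nearest_kept_five_prime(self):
        from paralintron.intron_mapping import MaskedAlignment

        mask = MaskedAlignment(og_id="og", kept_columns=[5, 9, 14])
        assert relative_position(IntronPosition("og", 11, 0), mask) == pytest.approx(2 / 3)
        assert relative_position(IntronPosition("og", 2, 0), mask) == 0.0

    def test_empty_mask_is_an_error(self):
        from paralintron.intron_mapping import MaskedAlignment

        with pytest.raises(ValueError):
            relative_position(
                IntronPosition("og", 1, 0), MaskedAlignment("og", [])
            )


class TestSimulatedRoundTrip:
    def test_planted_introns_recovered_exactly(self, tmp_path):
        """Mapping recovers every planted (residue, phase) on both strands."""
        from paralintron import data_io
        from paralintron.simulate import write_species_files, emit_genomes

        config = SimulationConfig(seed=11, n_families=3, n_species=4)
        dataset = simulate_dataset(config)
        genes = emit_genomes(dataset)
        recovered_total = planted_total = 0
        for species in dataset.species_tree.leaf_names:
            write_species_files(genes[species], tmp_path, species)
            genome = data_io.read_gff3(
                tmp_path / f"{species}.gff3",
                tmp_path / f"{species}.genome.fa",
                species_id=species,
            )
            for family in dataset.families:
                fam_aln = dataset.alignments[family.family_id]
                for og, rows in fam_aln.og_rows.items():
                    og_obj = OrthogroupAlignment(
                        og_id=og,
                        rows=rows,
                        species_of={sid: sid.split("|")[0] for sid in rows},
                    )
                    mapped = map_genome_introns(genome, og_obj)
                    sid = f"{species}|{og}"
                    truth = dataset.post_leca[family.family_id].presence[og][species]
                    planted_total += len(truth)
                    got = {(p.alignment_column, p.phase) for p in mapped.get(sid, [])}
                    expected = {
                        (fam_aln.og_column_of_residue[og][res], ph)
                        for res, ph in truth
                    }
                    assert got == expected
                    recovered_total += len(got & expected)
        assert planted_total > 100
        assert recovered_total == planted_total
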