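"""Mapping introns from genomic coordinates onto protein alignments.

An intron interrupts the coding sequence after ``coding_offset``
nucleotides; its *phase* is ``coding_offset mod 3`` (0: between codons;
1/2: after the first/second nucleotide of a codon).  Anchor convention:
an intron is attached to the residue whose codon contains the first
coding nucleotide 3' of the intron — the residue following the intron
for phase 0, the interrupted residue for phases 1 and 2.  Any consistent
convention preserves whether two introns occupy the same position, which
is the property the downstream analyses rely on; this one is used
throughout the package.

Intron positions are compared as exact (alignment column, phase) pairs;
positions one column apart are never merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .data_io import AnnotatedGenome, OrthogroupAlignment, Transcript

GAP = "-"

#: introns shorter than this many nucleotides are annotation artefacts
MIN_PLAUSIBLE_INTRON_NT = 4


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinIntron:
    """An intron located in protein coordinates.

    ``coding_offset`` is the number of coding nucleotides 5' of the
    intron; ``anchor_residue`` (1-based) is the residue carrying the
    intron under the anchor convention above.
    """

    protein_id: str
    coding_offset: int

    @property
    def phase(self) -> int:
        return self.coding_offset % 3

    @property
    def anchor_residue(self) -> int:
        return self.coding_offset // 3 + 1


@dataclass(frozen=True, order=True)
class IntronPosition:
    """An intron position in an orthogroup alignment: (column, phase)."""

    og_id: str = field(compare=False)
    alignment_column: int  # 1-based
    phase: int

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValueError(f"invalid phase {self.phase}")
        if self.alignment_column < 1:
            raise ValueError("alignment_column is 1-based")

    @property
    def key(self) -> tuple[int, int]:
        return (self.alignment_column, self.phase)


@dataclass
class IntronTable:
    """Species × intron-position presence matrix.

    ``states[species]`` is a string over ``{1, 0, ?}`` aligned with
    ``positions``: ``1`` if at least one sequence of the species carries
    an intron at that (column, phase), ``0`` if the species has mappable
    sequences but none carries it, ``?`` if the ortholog is missing or
    no sequence of the species could be mapped.
    """

    og_id: str
    positions: list[IntronPosition]
    states: dict[str, str]

    def __post_init__(self) -> None:
        keys = [p.key for p in self.positions]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (column, phase) positions")
        for species, state in self.states.items():
            if len(state) != len(self.positions):
                raise ValueError(f"state length mismatch for {species!r}")

    @property
    def species(self) -> list[str]:
        return sorted(self.states)

    def pattern(self, position_index: int) -> dict[str, str]:
        return {sp: self.states[sp][position_index] for sp in self.states}

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntronTable):
            return NotImplemented
        return (
            self.og_id == other.og_id
            and [p.key for p in self.positions] == [p.key for p in other.positions]
            and self.states == other.states
        )


@dataclass
class MaskedAlignment:
    """Columns of an orthogroup alignment that survive gap masking."""

    og_id: str
    kept_columns: list[int]  # 1-based original indices, ascending


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def introns_from_transcript(t: "Transcript") -> list[ProteinIntron]:
    """Introns of a transcript as protein-coordinate records, 5'→3'.

    One intron per gap between consecutive CDS segments, walked in mRNA
    order (reverse genomic order on the '-' strand).  The coding offset
    of each intron is the cumulative coding length of the segments 5' of
    it.
    """
    segments = t.segments_in_mrna_order()
    introns = []
    cumulative = 0
    for prev, curr in zip(segments, segments[1:]):
        cumulative += prev[1] - prev[0]
        if t.strand == "+":
            intron_nt = curr[0] - prev[1]
        else:
            intron_nt = prev[0] - curr[1]
        if intron_nt < MIN_PLAUSIBLE_INTRON_NT:
            warnings.warn(
                f"suspiciously short intron ({intron_nt} nt) in "
                f"{t.transcript_id}; reported anyway"
            )
        introns.append(ProteinIntron(protein_id=t.protein_id, coding_offset=cumulative))
    return introns


def project_to_alignment(
    pi: ProteinIntron, row: str, og_id: str = ""
) -> Optional[IntronPosition]:
    """Column of the anchor residue in a gapped alignment row.

    Returns ``None`` when the anchor lies beyond the (ungapped) row, in
    which case the mapping is unsuccessful and the sequence contributes
    a ``?`` downstream.
    """
    residue_rank = 0
    for column, char in enumerate(row, start=1):
        if char != GAP:
            residue_rank += 1
            if residue_rank == pi.anchor_residue:
                return IntronPosition(
                    og_id=og_id, alignment_column=column, phase=pi.phase
                )
    return None


def build_intron_table(
    og: "OrthogroupAlignment",
    introns: Mapping[str, Iterable[IntronPosition]],
    expected_species: Iterable[str],
) -> IntronTable:
    """Assemble the per-species presence/absence/missing table of an OG.

    ``introns`` maps each successfully mapped sequence id to its intron
    positions; sequences absent from the mapping are treated as
    unmappable.  A species is scored ``1`` at a position if at least one
    of its mapped sequences carries an intron there.
    """
    for sid in introns:
        if sid not in og.rows:
            raise ValueError(f"sequence {sid!r} not in alignment {og.og_id}")
    positions = sorted(
        {pos.key for seq_positions in introns.values() for pos in seq_positions}
    )
    position_objs = [
        IntronPosition(og_id=og.og_id, alignment_column=col, phase=phase)
        for col, phase in positions
    ]

    by_species: dict[str, list[str]] = {}
    for sid, species in og.species_of.items():
        by_species.setdefault(species, []).append(sid)

    states = {}
    for species in expected_species:
        seqs = by_species.get(species, [])
        mapped = [sid for sid in seqs if sid in introns]
        if not mapped:
            states[species] = "?" * len(position_objs)
            continue
        carried = {pos.key for sid in mapped for pos in introns[sid]}
        states[species] = "".join(
            "1" if key in carried else "0" for key in positions
        )
    return IntronTable(og_id=og.og_id, positions=position_objs, states=states)


def _ungapped(row: str) -> str:
    return row.replace(GAP, "")


def transfer_to_merged(
    pos: IntronPosition,
    og_row: str,
    merged_row: str,
    sequence_id: str = "",
) -> IntronPosition:
    """Re-express an OG-alignment position in merged-alignment columns.

    Both rows must contain the same ungapped sequence; the intron keeps
    its ungapped residue index (and phase) and only its column changes.
    """
    if _ungapped(og_row) != _ungapped(merged_row):
        raise ValueError(
            f"ungapped sequences differ between OG and merged rows"
            + (f" for {sequence_id!r}" if sequence_id else "")
        )
    if pos.alignment_column > len(og_row):
        raise ValueError("position outside the OG alignment row")
    if og_row[pos.alignment_column - 1] == GAP:
        raise ValueError("anchor column is a gap in the provided OG row")
    residue_rank = sum(
        1 for c in og_row[: pos.alignment_column] if c != GAP
    )
    seen = 0
    for column, char in enumerate(merged_row, start=1):
        if char != GAP:
            seen += 1
            if seen == residue_rank:
                return IntronPosition(
                    og_id=pos.og_id, alignment_column=column, phase=pos.phase
                )
    raise AssertionError("unreachable: ungapped rows were equal")


def transfer_positions(
    positions: Iterable[IntronPosition],
    og: "OrthogroupAlignment",
    merged_rows: Mapping[str, str],
) -> dict[IntronPosition, Optional[IntronPosition]]:
    """Transfer OG positions to merged coordinates via any carrier row.

    For each position the first OG row (sorted by sequence id) with a
    residue in the anchor column is used as the bridge.  Positions with
    no residue in any row map to ``None`` (and are excluded upstream
    with a warning).
    """
    result: dict[IntronPosition, Optional[IntronPosition]] = {}
    ordered_ids = sorted(og.rows)
    for pos in positions:
        merged: Optional[IntronPosition] = None
        for sid in ordered_ids:
            row = og.rows[sid]
            if (
                sid in merged_rows
                and pos.alignment_column <= len(row)
                and row[pos.alignment_column - 1] != GAP
            ):
                merged = transfer_to_merged(pos, row, merged_rows[sid], sid)
                break
        if merged is None:
            warnings.warn(
                f"position {pos.key} of {og.og_id} not transferable to the "
                "merged alignment; excluded"
            )
        result[pos] = merged
    return result


def mask_alignment(og: "OrthogroupAlignment", gap_threshold: float = 0.9) -> MaskedAlignment:
    """Columns with a gap fraction below the threshold (default 0.9).

    A column whose gap fraction is greater than or equal to the
    threshold is masked.  Only ``-`` counts as a gap; ``X`` and other
    ambiguity codes are residues.
    """
    n_rows = len(og.rows)
    if n_rows == 0:
        raise ValueError("empty alignment")
    kept = []
    rows = list(og.rows.values())
    for column in range(og.length):
        gaps = sum(1 for row in rows if row[column] == GAP)
        if gaps / n_rows < gap_threshold:
            kept.append(column + 1)
    return MaskedAlignment(og_id=og.og_id, kept_columns=kept)


def relative_position(pos: IntronPosition, mask: MaskedAlignment) -> float:
    """Relative 5'→3' position of an intron among unmasked columns.

    ``r = rank / n_kept`` where rank is the 1-based index of the
    intron's column among the kept columns.  An intron in a masked
    column takes the rank of the nearest kept column 5' of it (0 if
    there is none, giving ``r = 0``).
    """
    if not mask.kept_columns:
        raise ValueError("empty mask: every column is masked")
    import bisect

    rank = bisect.bisect_right(mask.kept_columns, pos.alignment_column)
    return rank / len(mask.kept_columns)


# ---------------------------------------------------------------------------
# genome → table convenience
# ---------------------------------------------------------------------------

def map_genome_introns(
    genome: "AnnotatedGenome",
    og: "OrthogroupAlignment",
) -> dict[str, list[IntronPosition]]:
    """Map one species' introns onto an OG alignment.

    Returns positions for every sequence of the species that is present
    in the alignment and whose transcript translates cleanly to the
    aligned (ungapped) protein; sequences failing either check are
    omitted, so they contribute ``?`` in :func:`build_intron_table`.
    """
    by_protein: dict[str, list] = {}
    for t in genome.transcripts:
        by_protein.setdefault(t.protein_id, []).append(t)

    mapped: dict[str, list[IntronPosition]] = {}
    for sid, row in og.rows.items():
        if og.species_of[sid] != genome.species_id:
            continue
        protein_id = sid.split("|", 1)[1] if "|" in sid else sid
        candidates = by_protein.get(protein_id, [])
        for t in candidates:
            protein = genome.protein_sequence(t)
            if protein is None or protein != _ungapped(row):
                continue
            positions = []
            ok = True
            for pi in introns_from_transcript(t):
                pos = project_to_alignment(pi, row, og_id=og.og_id)
                if pos is None:
                    ok = False
                    break
                positions.append(pos)
            if ok:
                mapped[sid] = positions
                break
    return mapped
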