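"""Readers and writers for the pipeline's external formats.

Formats handled here:

* genome annotation (GFF3) together with the genome FASTA, yielding
  transcript models with strand-consistent CDS segments;
* protein FASTA / aligned FASTA (orthogroup and merged alignments);
* the intron-table TSV (species × intron-position presence matrix with
  ``1`` / ``0`` / ``?`` states);
* per-species U12-type intron predictions (TSV);
* annotated Newick trees (re-exported from :mod:`paralintron.trees`).

All genomic coordinates are converted exactly once, at parse time, from
GFF3's 1-based inclusive convention to 0-based half-open; every
downstream type uses 0-based half-open coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .trees import (  # noqa: F401  (re-exported)
    AnnotatedTree,
    parse_newick,
    read_annotated_tree,
    write_annotated_tree,
)

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    """A protein-coding transcript: an ordered set of CDS segments.

    ``cds_segments`` are 0-based half-open genomic intervals stored in
    genomic order (ascending start) regardless of strand.
    """

    transcript_id: str
    protein_id: str
    strand: str  # '+' or '-'
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    contig: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        for start, end in self.cds_segments:
            if start >= end:
                raise ValueError(f"empty CDS segment ({start}, {end})")
        self.cds_segments.sort()

    @property
    def coding_length(self) -> int:
        return sum(end - start for start, end in self.cds_segments)

    def segments_in_mrna_order(self) -> list[tuple[int, int]]:
        """CDS segments ordered 5'→3' along the mRNA."""
        if self.strand == "+":
            return list(self.cds_segments)
        return list(reversed(self.cds_segments))


@dataclass
class AnnotatedGenome:
    """One species' genome sequences plus its transcript models."""

    species_id: str
    sequences: dict[str, str]
    transcripts: list[Transcript] = field(default_factory=list)

    def coding_sequence(self, t: Transcript) -> str:
        """Spliced coding sequence of a transcript, 5'→3'."""
        contig = self.sequences[t.contig]
        parts = [contig[s:e] for s, e in t.cds_segments]
        cds = "".join(parts)
        if t.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds.upper()

    def protein_sequence(self, t: Transcript) -> Optional[str]:
        """Translate a transcript; ``None`` if the CDS is not clean.

        A trailing stop codon is trimmed.  A coding length that is not a
        multiple of three marks the transcript as unmappable (it will
        contribute ``?`` downstream).
        """
        cds = self.coding_sequence(t)
        if len(cds) % 3 != 0:
            return None
        if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        if not cds:
            return None
        protein = str(Seq(cds).translate())
        if "*" in protein:
            return None  # internal stop: annotation problem
        return protein


@dataclass
class OrthogroupAlignment:
    """A per-orthogroup protein multiple alignment."""

    og_id: str
    rows: dict[str, str]  # sequence_id -> aligned residues with '-'
    species_of: dict[str, str]  # sequence_id -> species_id

    def __post_init__(self) -> None:
        lengths = {len(row) for row in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment for {self.og_id}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def species(self) -> set[str]:
        return set(self.species_of.values())


# ---------------------------------------------------------------------------
# GFF3 + genome FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3(path, genome_fasta_path, species_id: str = "") -> AnnotatedGenome:
    """Parse a GFF3 annotation plus genome FASTA into transcript models.

    CDS features are grouped by their ``Parent`` attribute.  A CDS whose
    Parent cannot be resolved is skipped with a warning; a contig named
    in the GFF3 but absent from the FASTA raises an error naming it.
    """
    sequences = read_fasta(genome_fasta_path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    known_parents = {f.id for f in db.all_features() if f.featuretype != "CDS"}

    grouped: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents:
            warnings.warn(f"CDS without Parent at {cds.seqid}:{cds.start}; skipped")
            continue
        parent = parents[0]
        if parent not in known_parents:
            warnings.warn(f"CDS Parent {parent!r} unresolvable; record skipped")
            continue
        if cds.seqid not in sequences:
            raise ValueError(
                f"contig {cds.seqid!r} named in GFF3 but absent from FASTA"
            )
        info = grouped.setdefault(
            parent, {"strand": cds.strand, "contig": cds.seqid, "segments": []}
        )
        if info["strand"] != cds.strand or info["contig"] != cds.seqid:
            warnings.warn(f"inconsistent strand/contig for {parent!r}; skipped")
            grouped.pop(parent)
            known_parents.discard(parent)
            continue
        # GFF3 is 1-based inclusive; convert here, once.
        info["segments"].append((cds.start - 1, cds.end))

    transcripts = []
    for parent, info in grouped.items():
        parent_feature = db[parent]
        protein_ids = parent_feature.attributes.get("protein_id", [parent])
        transcripts.append(
            Transcript(
                transcript_id=parent,
                protein_id=protein_ids[0],
                strand=info["strand"],
                cds_segments=sorted(info["segments"]),
                contig=info["contig"],
            )
        )

    genome = AnnotatedGenome(
        species_id=species_id, sequences=sequences, transcripts=transcripts
    )
    logger.info("parsed %d transcripts from %s", len(transcripts), path)
    return genome


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def default_species_of(sequence_id: str) -> str:
    """Species id of a sequence id following the ``species|seq`` convention."""
    return sequence_id.split("|", 1)[0]


def read_alignment(
    path,
    og_id: str = "",
    species_from_id: Callable[[str], str] = default_species_of,
) -> OrthogroupAlignment:
    """Read an aligned FASTA file into an :class:`OrthogroupAlignment`."""
    rows = read_fasta(path)
    return OrthogroupAlignment(
        og_id=og_id,
        rows=rows,
        species_of={sid: species_from_id(sid) for sid in rows},
    )


def write_alignment(alignment: OrthogroupAlignment, path) -> None:
    write_fasta(alignment.rows, path)


# ---------------------------------------------------------------------------
# intron-table TSV
# ---------------------------------------------------------------------------

def write_intron_table(table, path) -> None:
    """Serialise an :class:`~paralintron.intron_mapping.IntronTable`.

    Dialect: an optional leading ``# og=<id>`` comment; a header row
    ``species`` followed by one column per intron position named
    ``<alignmentColumn>.<phase>`` (column 1-based); then one row per
    species with one ``1``/``0``/``?`` field per position.
    """
    for species, state in table.states.items():
        if len(state) != len(table.positions):
            raise ValueError(
                f"state string for {species!r} has {len(state)} characters "
                f"for {len(table.positions)} positions"
            )
    with open(path, "w") as fh:
        if table.og_id:
            fh.write(f"# og={table.og_id}\n")
        header = ["species"] + [f"{p.alignment_column}.{p.phase}" for p in table.positions]
        fh.write("\t".join(header) + "\n")
        for species in sorted(table.states):
            fh.write("\t".join([species] + list(table.states[species])) + "\n")


def read_intron_table(path):
    """Read an intron-table TSV written by :func:`write_intron_table`."""
    from .intron_mapping import IntronPosition, IntronTable

    og_id = ""
    with open(path) as fh:
        lines = [line.rstrip("\n") for line in fh]
    body = []
    for line in lines:
        if line.startswith("#"):
            if "og=" in line:
                og_id = line.split("og=", 1)[1].strip()
        elif line:
            body.append(line)
    if not body:
        raise ValueError(f"empty intron table {path}")
    header = body[0].split("\t")
    if header[0] != "species":
        raise ValueError(f"bad intron-table header in {path}")
    positions = []
    for token in header[1:]:
        column_text, _, phase_text = token.partition(".")
        positions.append(
            IntronPosition(
                og_id=og_id,
                alignment_column=int(column_text),
                phase=int(phase_text),
            )
        )
    states = {}
    for line in body[1:]:
        fields = line.split("\t")
        species, chars = fields[0], fields[1:]
        if len(chars) != len(positions):
            raise ValueError(
                f"row for {species!r} has {len(chars)} states, "
                f"expected {len(positions)}"
            )
        if not all(c in "10?" for c in chars):
            raise ValueError(f"invalid state characters in row for {species!r}")
        states[species] = "".join(chars)
    return IntronTable(og_id=og_id, positions=positions, states=states)


# ---------------------------------------------------------------------------
# U12 predictions
# ---------------------------------------------------------------------------

def read_u12_predictions(path):
    """Read per-species U2/U12 intron-type predictions.

    Returns a list of ``(species_id, og_id, alignment_column, phase,
    predicted_type)`` tuples.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species_id", "og_id", "alignment_column", "phase", "predicted_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"U12 prediction TSV missing columns: {sorted(missing)}")
    bad = set(df["predicted_type"]) - {"U2", "U12"}
    if bad:
        raise ValueError(f"invalid predicted_type values: {sorted(bad)}")
    return [
        (
            row.species_id,
            row.og_id,
            int(row.alignment_column),
            int(row.phase),
            row.predicted_type,
        )
        for row in df.itertuples()
    ]


def write_u12_predictions(rows, path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\tog_id\talignment_column\tphase\tpredicted_type\n")
        for species_id, og_id, column, phase, ptype in rows:
            fh.write(f"{species_id}\t{og_id}\t{column}\t{phase}\t{ptype}\n")
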