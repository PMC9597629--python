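"""Six-frame stop-to-stop ORF database construction and coordinate mapping.

A proteogenomic search database is built by translating the genome in all
six reading frames and splitting each frame's translation at stop codons.
Every inter-stop segment (including the leading segment before the first
stop and the trailing segment after the last one) of at least ``min_len``
residues becomes one database entry.  Translation is start-codon agnostic:
start assignment happens downstream during reannotation.

Coordinates are 1-based, inclusive, reported on the forward strand with
``start < end`` for both strands, matching identifiers of the form
``orf|<frame>|<strand>|<start>-<end>``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import IUPAC_NT, reverse_complement, translate_codon


class GenomeFormatError(ValueError):
    """Raised for empty or non-nucleotide FASTA input."""


@dataclass(frozen=True)
class Genome:
    """A single DNA sequence with linear or circular topology."""

    id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeFormatError("genome sequence is empty")
        bad = set(self.sequence) - IUPAC_NT
        if bad:
            raise GenomeFormatError(
                f"non-nucleotide characters in genome: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfEntry:
    """One stop-to-stop translated segment.

    ``frame`` is the offset (0-2) of the first codon in the strand's read
    direction; ``start``/``end`` are forward-strand 1-based inclusive and
    satisfy ``end - start + 1 == 3 * len(aa_sequence)``.
    """

    orf_id: str
    strand: str
    frame: int
    start: int
    end: int
    aa_sequence: str

    def __len__(self) -> int:
        return len(self.aa_sequence)


@dataclass
class SixFrameDb:
    """Ordered collection of stop-to-stop ORF entries for one genome."""

    genome_id: str
    min_len: int = 7
    entries: list[OrfEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[OrfEntry]:
        return iter(self.entries)

    def by_id(self) -> dict[str, OrfEntry]:
        return {e.orf_id: e for e in self.entries}


def make_orf_id(frame: int, strand: str, start: int, end: int) -> str:
    return f"orf|{frame}|{strand}|{start}-{end}"


_ORF_ID_RE = re.compile(r"^orf\|(-?\d+)\|([+-])\|(\d+)-(\d+)$")


def parse_orf_id(orf_id: str) -> tuple[int, str, int, int]:
    """Parse ``orf|frame|strand|start-end`` into its components."""
    m = _ORF_ID_RE.match(orf_id)
    if not m:
        raise ValueError(f"malformed orf id: {orf_id!r}")
    frame, strand, start, end = m.groups()
    return int(frame), strand, int(start), int(end)


def read_genome_fasta(path: str | Path) -> Genome:
    """Read the first FASTA record as the genome, upper-casing the sequence."""
    records = SeqIO.parse(str(path), "fasta")
    try:
        rec = next(records)
    except StopIteration:
        raise GenomeFormatError(f"no FASTA records in {path}") from None
    return Genome(id=rec.id, sequence=str(rec.seq).upper())


def write_genome_fasta(genome: Genome, path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(genome.sequence), id=genome.id, description="")],
        str(path),
        "fasta",
    )


def translate_frame(seq: str) -> str:
    """Codon-by-codon translation; trailing partial codon dropped.

    Stops become '*'; codons containing ambiguity codes become 'X' (an 'X'
    never splits an ORF).
    """
    n = len(seq) - len(seq) % 3
    return "".join(translate_codon(seq[i : i + 3]) for i in range(0, n, 3))


def _segment_coords(
    strand: str, frame: int, aa_lo: int, aa_hi: int, genome_len: int
) -> tuple[int, int]:
    """Forward-strand 1-based interval of aa indices [aa_lo, aa_hi) in a frame."""
    if strand == "+":
        return frame + 3 * aa_lo + 1, frame + 3 * aa_hi
    return genome_len - (frame + 3 * aa_hi) + 1, genome_len - (frame + 3 * aa_lo)


def six_frame_orfs(genome: Genome, min_len: int = 7) -> SixFrameDb:
    """Build the stop-to-stop six-frame database.

    For each of the six frames (3 offsets x 2 strands) the frame translation
    is split at stop codons and every inter-stop segment of length >=
    ``min_len`` is emitted, stops excluded.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    db = SixFrameDb(genome_id=genome.id, min_len=min_len)
    L = len(genome)
    for strand in "+-":
        strand_seq = genome.sequence if strand == "+" else reverse_complement(
            genome.sequence
        )
        for frame in range(3):
            protein = translate_frame(strand_seq[frame:])
            pos = 0
            for segment in protein.split("*"):
                if len(segment) >= min_len:
                    start, end = _segment_coords(
                        strand, frame, pos, pos + len(segment), L
                    )
                    db.entries.append(
                        OrfEntry(
                            orf_id=make_orf_id(frame, strand, start, end),
                            strand=strand,
                            frame=frame,
                            start=start,
                            end=end,
                            aa_sequence=segment,
                        )
                    )
                pos += len(segment) + 1  # skip the stop
    return db


def map_protein_to_genome(
    orf: OrfEntry, aa_start: int, aa_end: int
) -> tuple[int, int, str]:
    """Forward-strand nucleotide interval covering residues aa_start..aa_end.

    Positions are 1-based inclusive within ``orf.aa_sequence``; for minus
    strand entries the interval is counted downward from ``orf.end``.
    """
    n = len(orf.aa_sequence)
    if not (1 <= aa_start <= aa_end <= n):
        raise IndexError(
            f"aa positions {aa_start}..{aa_end} out of range for {n}-residue ORF"
        )
    if orf.strand == "+":
        return orf.start + 3 * (aa_start - 1), orf.start + 3 * aa_end - 1, "+"
    return orf.end - 3 * aa_end + 1, orf.end - 3 * (aa_start - 1), "-"


def orf_nucleotide_sequence(orf: OrfEntry, genome: Genome) -> str:
    """Coding-strand nucleotide sequence of an ORF entry."""
    seq = genome.sequence[orf.start - 1 : orf.end]
    return seq if orf.strand == "+" else reverse_complement(seq)


def codon_at(orf: OrfEntry, aa_pos: int, genome: Genome) -> str:
    """The codon encoding ORF residue ``aa_pos`` (coding-strand orientation)."""
    s, e, strand = map_protein_to_genome(orf, aa_pos, aa_pos)
    codon = genome.sequence[s - 1 : e]
    return codon if strand == "+" else reverse_complement(codon)


def write_fasta_db(db: SixFrameDb, path: str | Path) -> None:
    """Write the protein database as FASTA, one record per ORF entry."""
    records = [
        SeqRecord(Seq(e.aa_sequence), id=e.orf_id, description="")
        for e in db.entries
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_db(path: str | Path, min_len: int = 1, genome_id: str = "") -> SixFrameDb:
    """Read a protein FASTA whose headers are ``orf|frame|strand|start-end``."""
    db = SixFrameDb(genome_id=genome_id, min_len=min_len)
    for rec in SeqIO.parse(str(path), "fasta"):
        frame, strand, start, end = parse_orf_id(rec.id)
        db.entries.append(
            OrfEntry(
                orf_id=rec.id,
                strand=strand,
                frame=frame,
                start=start,
                end=end,
                aa_sequence=str(rec.seq),
            )
        )
    return db


def write_bed(db: SixFrameDb, path: str | Path) -> None:
    """BED6 of ORF coordinates (0-based half-open, per BED convention)."""
    with open(path, "w") as fh:
        for e in db.entries:
            fh.write(
                f"{db.genome_id}\t{e.start - 1}\t{e.end}\t"
                f"{e.orf_id}\t0\t{e.strand}\n"
            )
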