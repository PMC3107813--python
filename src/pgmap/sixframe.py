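"""Six-frame translation and exact peptide-to-genome mapping.

Frame labels follow the usual convention: ``+k`` translates the forward
strand starting at 0-based offset ``k-1``; ``-k`` translates the reverse
complement starting at offset ``k-1`` of the reverse complement.  All
emitted coordinates are 1-based inclusive on the forward strand (the GFF3
convention); internal arithmetic is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .automaton import Keyword, build_automaton, find_matches
from .codes import GeneticCode, translate_codon

__all__ = [
    "NucleotideRecord",
    "FrameTranslation",
    "PeptideMatch",
    "FRAME_ORDER",
    "VALID_AMINO_ACIDS",
    "reverse_complement",
    "translate_frames",
    "protein_to_genome_span",
    "validate_peptides",
    "map_peptides",
]

logger = logging.getLogger(__name__)

#: Deterministic frame iteration order used throughout the pipeline.
FRAME_ORDER: tuple[int, ...] = (1, 2, 3, -1, -2, -3)

#: The 20 standard amino acids accepted in peptide patterns.
VALID_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"
)
_IUPAC_NT = frozenset("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class NucleotideRecord:
    """A FASTA nucleotide record with a normalized uppercase DNA sequence."""

    id: str
    description: str
    seq: str


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six translated frames of a record.

    ``offset`` is the 0-based offset into the forward sequence for ``+``
    frames and into the reverse complement for ``-`` frames; 1-2 trailing
    nucleotides that do not fill a codon are dropped.
    """

    record_id: str
    frame: int
    protein: str
    source_length: int

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    @property
    def offset(self) -> int:
        return abs(self.frame) - 1

    @property
    def label(self) -> str:
        return f"{self.frame:+d}"


@dataclass(frozen=True)
class PeptideMatch:
    """An exact peptide hit with strand, frame and genomic coordinates.

    ``nt_start``/``nt_end`` are 1-based inclusive forward-strand bounds of
    the reverse-translated peptide; ``coding_nt`` is the codon-level
    nucleotide substring read on the coding strand, so translating it
    under the run's genetic code reproduces ``peptide_seq`` exactly.
    """

    peptide_id: str
    peptide_seq: str
    record_id: str
    strand: str
    frame: int
    nt_start: int
    nt_end: int
    coding_nt: str

    @property
    def frame_label(self) -> str:
        return f"{self.frame:+d}"


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC ambiguity letters complemented."""
    for i, ch in enumerate(seq):
        if ch not in _IUPAC_NT:
            raise ValueError(
                f"unknown nucleotide {ch!r} at position {i + 1}"
            )
    return seq.translate(_COMPLEMENT)[::-1]


def _translate(seq: str, code: GeneticCode) -> str:
    n = len(seq) - len(seq) % 3
    return "".join(translate_codon(code, seq[i : i + 3]) for i in range(0, n, 3))


def translate_frames(
    record: NucleotideRecord, code: GeneticCode
) -> list[FrameTranslation]:
    """Translate a record in all six frames (order +1,+2,+3,-1,-2,-3)."""
    if len(record.seq) < 3:
        logger.info(
            "record %s is shorter than one codon; all frames empty", record.id
        )
    rc = reverse_complement(record.seq)
    frames = []
    for frame in FRAME_ORDER:
        source = record.seq if frame > 0 else rc
        off = abs(frame) - 1
        frames.append(
            FrameTranslation(
                record_id=record.id,
                frame=frame,
                protein=_translate(source[off:], code),
                source_length=len(record.seq),
            )
        )
    return frames


def protein_to_genome_span(
    frame: FrameTranslation, prot_start: int, prot_len: int
) -> tuple[int, int, str]:
    """Map a protein-coordinate slice of a frame to forward-strand bounds.

    Returns 1-based inclusive ``(nt_start, nt_end, strand)``.  For ``-``
    frames the span is computed on the reverse complement and mirrored
    through ``[s, e] -> [L - e + 1, L - s + 1]``.
    """
    if prot_start < 0 or prot_len < 0 or prot_start + prot_len > len(frame.protein):
        raise ValueError(
            f"protein span [{prot_start}, {prot_start + prot_len}) outside "
            f"frame of length {len(frame.protein)}"
        )
    s = frame.offset + 3 * prot_start + 1
    e = s + 3 * prot_len - 1
    if frame.strand == "+":
        return s, e, "+"
    L = frame.source_length
    return L - e + 1, L - s + 1, "-"


def validate_peptides(keywords: list[Keyword]) -> tuple[list[Keyword], list[Keyword]]:
    """Split peptides into (valid, skipped) by the 20-letter alphabet.

    Sequences are uppercased; anything containing a character outside the
    standard amino-acid alphabet is skipped with a logged warning rather
    than aborting the run.
    """
    valid, skipped = [], []
    for kw in keywords:
        pattern = kw.pattern.upper()
        if pattern and VALID_AMINO_ACIDS.issuperset(pattern):
            valid.append(Keyword(kw.id, pattern))
        else:
            bad = sorted(set(pattern) - VALID_AMINO_ACIDS) or ["<empty>"]
            logger.warning(
                "skipping peptide %s: invalid amino-acid letter(s) %s",
                kw.id,
                ",".join(map(str, bad)),
            )
            skipped.append(kw)
    return valid, skipped


def map_peptides(
    peptides: list[Keyword],
    records: list[NucleotideRecord],
    code: GeneticCode,
) -> list[PeptideMatch]:
    """Find every exact occurrence of every peptide in every frame.

    The automaton is built once and reused across all records and frames.
    Output order is deterministic: record order, then frame order
    +1,+2,+3,-1,-2,-3, then position, then peptide id.
    """
    valid, _ = validate_peptides(peptides)
    if not valid:
        return []
    auto = build_automaton(valid)
    matches: list[PeptideMatch] = []
    for record in records:
        rc = None
        for frame in translate_frames(record, code):
            hits = find_matches(auto, frame.protein)
            if hits and frame.strand == "-" and rc is None:
                rc = reverse_complement(record.seq)
            for hit in hits:
                prot_len = hit.end - hit.start
                nt_start, nt_end, strand = protein_to_genome_span(
                    frame, hit.start, prot_len
                )
                if strand == "+":
                    coding = record.seq[nt_start - 1 : nt_end]
                else:
                    L = len(record.seq)
                    coding = rc[L - nt_end : L - nt_start + 1]
                matches.append(
                    PeptideMatch(
                        peptide_id=hit.keyword_id,
                        peptide_seq=frame.protein[hit.start : hit.end],
                        record_id=record.id,
                        strand=strand,
                        frame=frame.frame,
                        nt_start=nt_start,
                        nt_end=nt_end,
                        coding_nt=coding,
                    )
                )
    return matches
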