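"""Synthetic genome/peptide fixture generation with a known ground truth.

The generator emulates the situation the mapper is built for: a genome in
which a handful of MS-identified peptides are encoded at known positions
inside ORF-like cassettes.  Each cassette carries, on a random strand and
in a random frame, an in-frame 5' stop codon, a start codon, the reverse
translated peptide, and an in-frame 3' stop; in eukaryotic mode a GT
donor downstream of the peptide and an AG acceptor upstream of it bound
the tag instead.  Filler codons inside a cassette are drawn from the
A/C-only codon alphabet, which contains no start, stop or splice-signal
letters, so the planted boundaries are provably the nearest ones.
Background sequence is rejection-sampled until no peptide occurs anywhere
outside its planted site in any of the six frames (checked with a naive
substring scan, independent of the mapper).

What this deliberately does not emulate: base-composition bias, repeats,
sequencing errors, I/L ambiguity in peptide identifications, or real
splice-site context beyond the GT/AG dinucleotides.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .automaton import Keyword
from .codes import GeneticCode, translate_codon
from .sixframe import NucleotideRecord, reverse_complement

__all__ = ["TruthRow", "Fixture", "generate_fixture"]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
# A/C-only codons: never start/stop codons in the standard code, and free of
# G and T so no GT/AG signal can form inside or across filler.
_FILLER_CODONS = ("AAA", "AAC", "ACA", "ACC", "CAA", "CAC", "CCA", "CCC")


@dataclass(frozen=True)
class TruthRow:
    """Expected mapping and extension result for one planted peptide."""

    peptide_id: str
    peptide_seq: str
    record_id: str
    strand: str
    frame: int
    nt_start: int
    nt_end: int
    epst_start: int
    epst_end: int
    boundary_5: str
    boundary_3: str


@dataclass
class Fixture:
    """A generated genome, its planted peptides and the expected results."""

    record: NucleotideRecord
    peptides: list[Keyword]
    truth: list[TruthRow]

    def write(self, outdir: str | Path, prefix: str = "fixture") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / f"{prefix}.genome.fasta",
            "peptides": outdir / f"{prefix}.peptides.fasta",
            "truth": outdir / f"{prefix}.truth.tsv",
        }
        with open(paths["genome"], "w") as fh:
            fh.write(f">{self.record.id} synthetic fixture genome\n")
            for i in range(0, len(self.record.seq), 60):
                fh.write(self.record.seq[i : i + 60] + "\n")
        with open(paths["peptides"], "w") as fh:
            for kw in self.peptides:
                fh.write(f">{kw.id}\n{kw.pattern}\n")
        cols = (
            "peptide_id peptide_seq record_id strand frame nt_start nt_end "
            "epst_start epst_end boundary_5 boundary_3"
        ).split()
        with open(paths["truth"], "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in self.truth:
                fh.write("\t".join(str(getattr(row, c)) for c in cols) + "\n")
        return paths


def _codons_by_aa(code: GeneticCode) -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    for codon, aa in sorted(code.aa_table.items()):
        table.setdefault(aa, []).append(codon)
    return table


def _reverse_translate(rng: random.Random, peptide: str, by_aa) -> str:
    return "".join(rng.choice(by_aa[aa]) for aa in peptide)


def _cassette(
    rng: random.Random, peptide_nt: str, code: GeneticCode, mode: str
) -> tuple[str, dict[str, int]]:
    """Build one cassette in coding-strand space; returns (seq, layout).

    Layout positions are 1-based within the cassette.  Prokaryotic layout:
    ``[stop][filler][ATG][filler][peptide][filler][stop]``; eukaryotic
    layout replaces the outer stop codons with an AG acceptor upstream and
    a GT donor downstream (planted as CAG / GTA codons).
    """
    stop = rng.choice(sorted(code.stop_codons))
    stop2 = rng.choice(sorted(code.stop_codons))
    fill = lambda n: "".join(rng.choice(_FILLER_CODONS) for _ in range(n))
    k1, k2, k3 = rng.randint(1, 4), rng.randint(1, 4), rng.randint(1, 4)
    if mode == "prokaryote":
        parts = [stop, fill(k1), "ATG", fill(k2), peptide_nt, fill(k3), stop2]
        layout = {}
        pos = 1 + 3 * (1 + k1)  # after 5' stop + filler
        layout["epst_start"] = pos  # the planted ATG
        layout["boundary_5"] = "start_codon"
        pep_start = pos + 3 * (1 + k2)
        layout["pep_start"] = pep_start
        layout["pep_end"] = pep_start + len(peptide_nt) - 1
        layout["epst_end"] = layout["pep_end"] + 3 * k3 + 3  # includes 3' stop
        layout["boundary_3"] = "stop_codon"
    elif mode == "eukaryote_signal":
        # CAG plants an AG acceptor (last base at codon position 3); GTA
        # plants a GT donor (first base at codon position 1).
        parts = [fill(1), "CAG", fill(k1), peptide_nt, fill(k2), "GTA", fill(1)]
        layout = {}
        acc_codon = 1 + 3  # CAG starts at cassette position 4
        pep_start = acc_codon + 3 + 3 * k1
        layout["pep_start"] = pep_start
        layout["pep_end"] = pep_start + len(peptide_nt) - 1
        # upstream scan crosses the acceptor at the CAG codon -> starts after it
        layout["epst_start"] = acc_codon + 3
        layout["boundary_5"] = "splice_acceptor"
        donor_pos = layout["pep_end"] + 3 * k2 + 1  # first base of GTA
        layout["epst_end"] = donor_pos - 1
        layout["boundary_3"] = "splice_donor"
    else:
        raise ValueError(f"unknown fixture mode {mode!r}")
    return "".join(parts), layout


def _naive_sixframe_occurrences(seq: str, peptide: str, code: GeneticCode) -> int:
    """Count peptide occurrences over all six frames by naive scanning."""
    count = 0
    rc = reverse_complement(seq)
    for source in (seq, rc):
        for off in range(3):
            n = (len(source) - off) // 3
            prot = "".join(
                translate_codon(code, source[off + 3 * i : off + 3 * i + 3])
                for i in range(n)
            )
            idx = prot.find(peptide)
            while idx != -1:
                count += 1
                idx = prot.find(peptide, idx + 1)
    return count


def generate_fixture(
    n_peptides: int,
    genome_length: int,
    mode: str,
    seed: int,
    code: GeneticCode,
    peptide_length: tuple[int, int] = (8, 15),
    record_id: str = "synth1",
    max_attempts: int = 50,
) -> Fixture:
    """Generate a deterministic single-record fixture with planted peptides.

    Cassettes are placed in evenly spaced, non-overlapping slots; each is
    inserted forward or reverse-complemented with equal probability, so
    strand and frame of the planted matches vary with the seed.  Raises if
    the genome cannot hold the cassettes or if, after ``max_attempts``
    background resamplings, some peptide still occurs away from its
    planted site.
    """
    rng = random.Random(seed)
    by_aa = _codons_by_aa(code)
    aa_pool = [aa for aa in _AA20 if aa in by_aa]

    planted = []
    for i in range(n_peptides):
        pep = "".join(
            rng.choice(aa_pool) for _ in range(rng.randint(*peptide_length))
        )
        pep_nt = _reverse_translate(rng, pep, by_aa)
        cassette, layout = _cassette(rng, pep_nt, code, mode)
        strand = rng.choice("+-")
        planted.append((f"pep{i + 1}", pep, cassette, layout, strand))

    total_cassette = sum(len(c) for _, _, c, _, _ in planted)
    gap = (genome_length - total_cassette) // (n_peptides + 1)
    if gap < 3:
        raise ValueError(
            f"genome_length {genome_length} too small for {n_peptides} "
            f"cassettes totalling {total_cassette} nt"
        )

    for _ in range(max_attempts):
        pieces, truth = [], []
        pos = 0  # 0-based length assembled so far
        for pid, pep, cassette, layout, strand in planted:
            lead = rng.randint(3, gap)
            pieces.append(
                "".join(rng.choice("ACGT") for _ in range(lead))
            )
            pos += lead
            g0 = pos  # cassette occupies forward positions g0+1 .. g0+len
            Lc = len(cassette)
            if strand == "+":
                pieces.append(cassette)
                nt_start, nt_end = g0 + layout["pep_start"], g0 + layout["pep_end"]
                e_start, e_end = g0 + layout["epst_start"], g0 + layout["epst_end"]
                frame = (nt_start - 1) % 3 + 1
            else:
                pieces.append(reverse_complement(cassette))
                nt_start = g0 + Lc - layout["pep_end"] + 1
                nt_end = g0 + Lc - layout["pep_start"] + 1
                e_start = g0 + Lc - layout["epst_end"] + 1
                e_end = g0 + Lc - layout["epst_start"] + 1
                frame = None  # fixed after total length is known
            truth.append(
                [pid, pep, strand, frame, nt_start, nt_end, e_start, e_end,
                 layout["boundary_5"], layout["boundary_3"]]
            )
            pos += Lc
        tail = genome_length - pos
        if tail > 0:
            pieces.append("".join(rng.choice("ACGT") for _ in range(tail)))
        seq = "".join(pieces)
        L = len(seq)
        for row in truth:
            if row[2] == "-":
                # frame from the 0-based offset of the match start in rc space
                row[3] = -((L - row[5]) % 3 + 1)

        ok = all(
            _naive_sixframe_occurrences(seq, pep, code) == 1
            for _, pep, _, _, _ in planted
        )
        if ok:
            record = NucleotideRecord(record_id, record_id, seq)
            rows = [
                TruthRow(pid, pep, record_id, strand, frame, s, e, es, ee, b5, b3)
                for pid, pep, strand, frame, s, e, es, ee, b5, b3 in truth
            ]
            return Fixture(
                record=record,
                peptides=[Keyword(pid, pep) for pid, pep, *_ in planted],
                truth=rows,
            )
    raise RuntimeError(
        f"could not place peptides without spurious six-frame occurrences "
        f"after {max_attempts} attempts"
    )
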