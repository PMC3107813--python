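# Methods

## Model and procedure

`pgmap` treats proteogenomic mapping as exact multi-pattern string
matching over translated nucleotide space. Given peptides
`P = {p_1..p_k}` and nucleotide records, every record is translated in
all six reading frames under the selected NCBI genetic code; the
peptides are compiled once into an Aho–Corasick automaton (keyword trie
plus breadth-first failure links, outputs merged along the links) and
each frame's protein string is scanned in a single pass. Construction is
`O(Σ|p_i|)` states and the scan is `O(text)` with each character
advancing the cursor exactly once, which is the property that lets the
peptide set scale independently of the genome size. Matching is exact on
residues after case normalisation: no I/L folding, no mismatches, and
any codon containing a non-ACGT character translates to `X`, which can
never equal a peptide letter — ambiguity therefore suppresses matches
rather than inventing them.

A hit in frame space is converted to genomic coordinates as
`nt_start = offset + 3·prot_start + 1` on the coding strand; reverse
frames map through `[s, e] → [L − e + 1, L − s + 1]`. All downstream
arithmetic (ePST extension) runs in coding-strand space — a reverse
match is mirrored onto the reverse complement, extended identically, and
mirrored back — which makes strand invariance structural rather than a
special case.

### ePST extension

*Prokaryotic*: 3' codon-by-codon to the first in-frame stop codon, which
is **included** in the tag (the tag is then a complete ORF-like unit;
the containment checks are insensitive to this choice). 5': find the
first in-frame stop strictly upstream, then take the first in-frame
start codon between it and the peptide start (inclusive of the
peptide's own first codon); with no intervening start the peptide start
begins the tag. A sequence end truncates at the last complete codon and
is flagged `sequence_end` instead of erroring, since contigs
legitimately end mid-ORF.

*Eukaryotic signal-bounded*: both scans are codon-by-codon and
nearest-wins among the admissible terminators — 3': in-frame stop
(included) or the last complete codon before the next donor (GT)
position; 5': in-frame start (included), in-frame stop (excluded) or
the first codon after the nearest upstream acceptor (AG) position. When
an acceptor falls inside a codon that is itself a start or stop, the
acceptor wins: scanning upstream, the signal at the higher coordinate
is encountered first. Canonical signals are every GT/AG dinucleotide on
the coding strand, scanned without frame restriction; GeneSplicer
predictions (five whitespace-delimited columns: end5, end3, score,
confidence, site type; donor rows contribute min(end5,end3), acceptor
rows max(end5,end3)) may replace them, mirrored into
reverse-complement space for minus-strand matches. The GeneSplicer
dialect accepted is the tool's standard tabular prediction output.

*Fixed-length*: a symmetric flank of `n` nucleotides clamped at the
sequence ends, with no codon-boundary guarantee; the protein column is
translated from the first complete codon of the peptide's frame inside
the span. A codon count is `3n` sugar at the CLI.

The stop-to-stop context column always spans from the upstream in-frame
stop codon to the downstream one (both included, truncated at sequence
ends), independent of the extension mode.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `--code-id` | 1 | NCBI translation table (bundled file carries 16 common tables; any gc.prt-style file can be substituted) |
| `--mode` | `prokaryote` | extension rule: `prokaryote`, `eukaryote_signal`, `fixed` |
| `--splice` | `canonical` | splice source in `eukaryote_signal` mode: `canonical`, `genesplicer`, `none` |
| `--extend-nt` | 0 | flank in nucleotides for `fixed` mode |

Start/stop codon sets come from the table file (`sncbieaa` `M` flags and
`*` translations), never from hard-coded assumptions, so non-standard
codes behave correctly throughout.

## Numerical and representational choices

- Coordinates: 0-based half-open internally, 1-based inclusive forward
  strand everywhere visible (GFF3 convention). Frame `±k` = offset
  `k−1` on the forward / reverse-complement sequence.
- Hit order: end offset, then keyword id; pipeline output order: record,
  frame (+1,+2,+3,−1,−2,−3), position. All outputs are byte-deterministic
  for fixed inputs.
- Duplicate FASTA ids are uniquified (`id.2`, logged); duplicate peptide
  sequences under distinct ids each report their own matches.
- Peptides outside the 20-letter alphabet (stops, digits, B/Z/X) are
  skipped with a warning and listed in `<prefix>.skipped.txt`, never
  fatal. Zero matches is a valid result with valid empty outputs.
- GFF3 features are SOFA `protein_match`, phase `0` when the tag length
  is a codon multiple and `.` otherwise; attribute values are
  percent-encoded.

## Synthetic fixture generator

`pgmap fixture` emulates the tool's target situation: a genome carrying
peptides at known positions inside ORF-like cassettes
(`stop – filler – ATG – filler – peptide – filler – stop`, or acceptor/
donor-bounded in eukaryote mode), inserted on a random strand at random
offsets so all six frames arise across seeds. Filler codons are drawn
from the A/C-only codon alphabet, which contains no start codon, no stop
codon and no GT/AG signal even across codon junctions, so the planted
boundaries are provably the nearest terminators — the truth table is
exact by construction. Background sequence is uniform ACGT,
rejection-sampled until a naive (automaton-independent) six-frame scan
finds each peptide exactly once. The generator does **not** emulate
base-composition bias, repeats, sequencing error, I/L-ambiguous
identifications or realistic splice-site context, so passing recovery
tests demonstrates correctness of the mapping and extension logic, not
robustness to messy real data. Default fixture sizes in the test suite
(4–10 peptides of 8–15 residues in 5–9 kb genomes; 200 randomized
matcher instances with texts up to 10 kb) keep the whole suite in the
seconds range while exercising every rule path.

## Regression data

The bundled channel catfish virus set (17 peptides and the 17 ePST
nucleotide sequences they anchor) is used as a self-contained
containment regression: every peptide must map exactly into the
six-frame translation of its ePST. Containment rather than sequence
identity is asserted because the published ePST strings include context
beyond a strict start-to-stop span for several entries (e.g.
Proteinase-1's sequence begins upstream of its in-frame start codon),
so their exact extent is not reproducible from the stated rules alone.
The full-genome check against reference NC_001493.1 runs only when that
genome is available (local copy or download); the frame convention
above places Proteinase-1's peptide NLDLLDNSTG in frame +1 there.

## Known limitations

- No spliced (gapped) matches across exon boundaries: a peptide must lie
  within one frame of one record.
- No approximate matching, I/L equivalence or wildcard residues.
- GeneSplicer is consumed, not run; splice-graph assembly, boundary
  scoring and intron-length constraints are out of scope.
- Single-threaded; the whole-genome scan is one pass per frame.
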