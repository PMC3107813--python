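# pgmap

Exact proteogenomic mapping: place MS-identified peptides back onto their
source genome and turn each placement into an evidence track for
structural genome annotation.

## The problem

Tandem-MS proteomics yields peptides whose spectra match a six-frame
translation of the genome but not the predicted proteome. Each such
peptide is direct evidence of translation from an unannotated region, but
only once it is located *exactly* on the genome. `pgmap` does that
location step and the follow-up:

1. **Six-frame translation** of a nucleotide FASTA (genome, contigs or
   selected features) under a user-selected NCBI genetic code table, so
   the tool works unchanged for bacteria, viruses, organelles or nuclear
   genomes.
2. **Exact multi-pattern search** of all peptides at once with an
   Aho–Corasick automaton built from scratch: construction is linear in
   the summed peptide lengths and the scan is linear in the text length,
   so large eukaryotic genomes are a single pass rather than a per-peptide
   rescan.
3. **ePST extension**: each match (the reverse-translated peptide) is
   grown into an expressed Protein Sequence Tag. Prokaryotic rule: 3' to
   the first in-frame stop codon (included); 5' to the first in-frame
   start codon downstream of the nearest upstream in-frame stop, falling
   back to the peptide start. Eukaryotic rule: codon-by-codon to the
   nearest in-frame stop, in-frame start (5' only) or splice signal —
   canonical GT/AG dinucleotides or GeneSplicer predictions. A
   fixed-length flank is the third option.
4. **Outputs**: an ePST FASTA, a 14-column TSV with full mapping detail
   (coordinates, strand, reading frame, stop-to-stop context, translated
   ePST), and a GFF3 `protein_match` track ready for genome browsers.

Coordinates are 1-based inclusive on the forward strand; frame `+k`
means forward offset `k−1`, `−k` the same on the reverse complement.

## Worked example

The package bundles the channel catfish virus (CCV) dataset: 17 peptides
that map to novel open reading frames, and the 17 published ePST
nucleotide sequences they anchor. Mapping the peptides against the ePST
sequences themselves is a self-contained round trip:

```sh
pgmap map \
  --peptides src/pgmap/data/ccv_peptides.fasta \
  --genome   src/pgmap/data/ccv_epsts.fasta \
  --out-prefix ccv_out
```

prints

```
peptides: 17 (skipped 0); records: 17; matches: 17; peptides with >=1 match: 17; ePSTs: 17
```

— every one of the 17 peptides finds at least one exact six-frame match,
and each match is extended into an ePST under the prokaryotic rule
(appropriate for a virus). The first TSV row reads, in part:

```
Proteinase-1  NLDLLDNSTG  Proteinase-1_ePST ...  30  59  +  +3  AATCTTGACCTTCTCGACAATTCCACTGGT  ...
```

i.e. the peptide NLDLLDNSTG sits at nucleotides 30–59 of its ePST record
on the forward strand, reading frame +3 of that record, and
`AATCTTGACCTTCTCGACAATTCCACTGGT` is its reverse-translated (genomic)
sequence. `ccv_out.fasta` holds the extended tags and `ccv_out.gff3` the
browser track.

Synthetic genomes with a known ground truth (planted ORFs, splice
signals, strand/frame randomised by seed) come from the companion
subcommand:

```sh
pgmap fixture --n-peptides 10 --genome-length 20000 --seed 42 --out-dir fx/
```

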