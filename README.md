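# pamscreen

Analysis pipeline for discovering the protospacer-adjacent motif (PAM) of a
Cas9 nuclease from a randomized-PAM GFP-activation reporter screen, and for
quantifying genome-editing efficiency from targeted amplicon sequencing.
It is aimed at genome-editing labs that profile Cas9 orthologs or engineered
chimeras: the same read-level machinery that turns sorted-cell deep
sequencing into PAM logos, PAM wheels and consensus calls also measures
indel frequencies at endogenous targets.

## The assay and the model

The reporter construct inserts a 24-nt protospacer followed by an 8-bp
randomized PAM window between an ATG start codon and the GFP coding
sequence, flanked by fixed 20-bp anchors:

```
[AAGCCTTGTTTGCCACCATG] [GAGAGTAGAGGCGGCCACGACCTG] [N8] [GTGAGCAAGGGCGAGGAGCT]
      left anchor             protospacer           PAM    right anchor (GFP 5')
```

The insert length (24 + 8 = 32 ≡ 2 mod 3) puts GFP out of frame. If the
nuclease recognizes a read's PAM it cuts ~3 bp 5' of the PAM and error-prone
repair leaves an indel of net length Δ; GFP fluoresces exactly when
(2 + Δ) mod 3 = 0 with Δ ≠ 0. Sequencing the sorted GFP-positive cells
therefore samples PAMs in proportion to nuclease activity. Per read the
pipeline:

1. locates both anchors by Hamming match (≤ k mismatches, default 1),
   requires the protospacer suffix `CTG` immediately 5' of the PAM window,
   and extracts the target region and the PAM;
2. globally aligns the target region to the protospacer (affine gaps:
   match +2, mismatch −3, gap open −5, extend −1) and classifies it as
   unedited / substitution-only / in-frame / frameshift from the net
   length change Δ;
3. tabulates the PAMs of in-frame reads into a position × base frequency
   matrix `f[j][b]`, with per-position information content
   `IC_j = 2 − H_j − e(n)` bits (`H_j` the column entropy,
   `e(n) = 3/(2·ln2·n)` the small-sample correction) and logo letter
   heights `f[j][b]·IC_j`;
4. calls a degenerate IUPAC consensus — `N` where `IC_j < 0.3` bits,
   otherwise the symbol covering all bases with `f ≥ 0.15` — and builds
   the PAM wheel (a prefix-count tree, the data behind a sunburst chart)
   plus unique-PAM/median-coverage statistics.

For endogenous targets, `indel_efficiency` counts reads whose alignment to
the amplicon has a gap event overlapping the cut-site window (± 5 nt) and
reports the edited fraction with a per-allele table.

A synthetic-data module simulates both assays with known ground truth
(PAM-dependent editing probability, single indel near the cut, GFP sorting,
per-base sequencing error), so every stage is testable without any
sequencing download. A packaged table carries the metadata of the 29
type II-C Cas9 orthologs under study (UniProt accession, host, length,
identity to Nme1Cas9).

## Worked example

Simulate a 50,000-cell screen for a nuclease with an N4CC-type PAM, sort,
and analyze (the `analysis/` scripts run exactly this):

```sh
$ python analysis/01_simulate_screens.py
dinucleotide_n4cc: 1284 GFP-sorted reads (2.568% of 50000 cells) -> scratch/sim/dinucleotide_n4cc.fastq
...
$ python analysis/02_pam_discovery.py
dinucleotide_n4cc:
  reads=1284 ok-parsed=460
  in-frame PAMs=460 unique=444 median coverage=1.0
  consensus=NNNNCC (expected NNNNCC: recovered); f[5][C]=0.889
```

Of 1,284 sorted reads, 460 parse cleanly with an in-frame edit (most
drop-outs are deletions that consumed the 3-nt PAM anchor); their PAM
profile shows C enriched to ~0.89 at positions 5–6 against ~0.25
background, and the consensus call `NNNNCC` recovers the planted PAM. The
single-base library recovers `NNNNC` the same way, and
`analysis/03_indel_quantification.py` recovers true editing rates of
0.05–0.70 with a maximum absolute error of 0.0003 at 4,000 reads per
amplicon.

The same workflows are available as a CLI (`pamscreen simulate`,
`pamscreen screen`, `pamscreen indel`) over YAML configs; see
`pamscreen --help`.

## Layout

- `src/pamscreen/` — the library: `design`, `simulate`, `parsing`,
  `editing`, `pam`, `orthologs`, `pipeline`, `cli`.
- `analysis/` — numbered drivers reproducing the analyses, writing to
  `results/` (and bulky intermediates to `scratch/`).
- `docs/methods.md` — model assumptions, parameter choices, limitations.
- `tests/` — unit, property and end-to-end acceptance tests.
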