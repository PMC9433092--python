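# Methods

## The reporter model

The screen analyzed here is a GFP-activation assay: a 24-nt protospacer
plus an 8-bp randomized PAM window sit between the ATG start codon and the
GFP coding sequence, so the unedited insert (32 nt ≡ 2 mod 3) forces a
frameshift. Editing at the protospacer leaves an indel of net length Δ;
GFP is restored exactly when the total insert length returns to a multiple
of 3, i.e. (frame_offset + Δ) mod 3 = 0 with Δ ≠ 0, where
frame_offset = (|protospacer| + pam_len) mod 3. Sorting GFP-positive cells
and sequencing the insert therefore enriches PAMs the nuclease recognizes.
`AmpliconDesign` carries this geometry; everything downstream
(simulation, parsing, classification) derives from it, and frame_offset is
always recomputed, never trusted from a config file.

Extended ("shifted") libraries that read out up to 11 PAM positions are
modelled with `pam_fixed_prefix`: the PAM-proximal positions of the wider
window are construct-fixed bases (default `CTG` for the 11-bp design, the
trinucleotide left adjacent to the random 8-mer after a 3-nt 5' shift of
the target). The exact fixed/random split of such designs is configurable
because it is a property of the cloned construct, not of the analysis.

The cut site defaults to the blunt position 3 bp 5' of the PAM
(`cut_offset = 3`), the standard Cas9 geometry; it is configurable since
cut chemistry varies across orthologs.

## Synthetic data: what it emulates, what it does not

`simulate_screen` draws each read's randomized PAM positions uniformly and
independently, edits the read with probability p(PAM) (either a
consensus-match model with `p_match`/`p_mismatch`, or a positional product
model), applies a single indel whose start is jittered uniformly within
±2 nt of the cut site, sorts (keeping frame-restoring reads plus an
optional impurity fraction), and finally applies per-base substitution
error. Defaults, chosen once as realistic study conditions:

- `p_match = 0.8`, `p_mismatch = 0.01` — an active nuclease with ~1%
  background/leaky editing on non-cognate PAMs;
- indels 30% insertions / 70% deletions, insertion lengths geometric with
  p = 0.7 (mostly +1, the canonical NHEJ insertion), deletion lengths
  geometric with p = 0.3 (mean ~3 nt), both capped at 12 nt;
- substitution error 10⁻³ per base (Illumina-like), constant quality
  symbol `I` (Q40) — quality decay adds nothing to the logic under test;
- deletions are clipped at the randomized PAM start so the planted PAM is
  never destroyed and the flanking anchors stay intact
  (`allow_anchor_damage` exposes the alternative).

Deliberately out of model: multi-indel alleles (only net Δ matters for the
frame logic), substitution-only "edits" as GFP restorers (a substitution
cannot change insert length), PCR duplicates and chimeras, paired-end
structure, and library composition skew (real randomized libraries are not
perfectly uniform; `compare_profiles` offers a background correction when
an unsorted library profile is available). Passing recovery tests on this
generator demonstrates the pipeline's correctness under these assumptions,
not robustness to artifacts it does not simulate.

A useful closed form for interpreting recovery runs: with a dinucleotide
ground truth (match probability 1/16 per read) the expected C frequency at
a constrained position among edited — hence among sorted — reads is

  (p_match/16 + p_mismatch·(3/16)) / (p_match/16 + p_mismatch·(15/16)) ≈ 0.874

at the defaults, not 1.0: mismatched PAMs still edit at `p_mismatch` and
dilute the signal. Frame restoration is PAM-independent, so sorting does
not sharpen this further. The consensus caller is designed to saturate
well below that value. For a single-base ground truth the same expression
with match probability 1/4 gives ≈ 0.96.

## Read parsing

Anchors are located by exhaustive Hamming scan (leftmost window with ≤ k
mismatches; k = 1 per 20-bp anchor by default). Anchors are never aligned
with gaps: they are short and fixed, and gapped anchor matching would
conflate parsing with edit calling. The 3-nt PAM anchor `CTG` is matched
exactly (k = 0 — one tolerated mismatch in 3 nt would accept random
sequence far too often). The PAM window is located from the right anchor
(its `pam_len` preceding bases), so PAM extraction survives indels in the
target region. Failures are statuses — `no_left_anchor`,
`no_right_anchor`, `no_pam_anchor`, `region_out_of_bounds`, assigned in
that order — and always partition the input; reads whose deletion consumed
the PAM anchor or ran into the window are excluded from PAM analysis
rather than mis-extracted. If the forward orientation fails, the reverse
complement is tried and the orientation recorded.

A consequence worth knowing: deletions near the cut site (3 bp from the
PAM) frequently destroy the `CTG` anchor, so a substantial fraction of
genuinely edited, frame-restored reads parse as `no_pam_anchor` and drop
out. The drop-out is independent of the PAM sequence, so profiles and
consensus calls are unbiased; only the effective n shrinks.

## Edit calling

Target regions are aligned to the protospacer globally with affine gaps
(match +2, mismatch −3, gap open −5, extend −1; a gap of length L costs
open + (L−1)·extend). These defaults keep a single substitution cheaper
than an insertion/deletion pair, so sequencing errors do not masquerade as
indels. Classification uses the net length change only — GFP translation
depends on total insert length, not on how individual events compose — and
substitution-only reads are excluded from the edited set (indistinguishable
from sequencing error; the nuclease's repair products are indels). Among
co-optimal alignments the first reported by the aligner is used; score, Δ
and hence the classification are invariant across co-optimal choices, and
CIGARs are deterministic for fixed inputs.

Indel efficiency at an endogenous amplicon counts a read as edited when
its alignment has a gap event overlapping the window ±5 nt around the cut
site; gaps entirely outside the window are ignored as likely PCR or
sequencing artifacts. Reads are oriented by score and must reach 75%
alignment identity to count as aligned; zero aligned reads yields an
*undefined* efficiency, reported distinctly from a measured 0.0.

## PAM summarization

Information content per position follows the sequence-logo convention for
DNA (2 − entropy − small-sample correction 3/(2·ln2·n), clamped to
[0, 2]); the correction can be disabled. The consensus caller makes the
by-eye logo reading explicit and reproducible: a position is `N` below
0.3 bits; otherwise the IUPAC symbol covering all bases with frequency
≥ 0.15, falling back to the single most frequent base. Both thresholds are
exposed (`ConsensusParams`); the defaults were fixed a priori so that at
the generator's ≈ 0.87 constrained-position frequency the constrained base
is called alone while genuinely mixed positions (e.g. 0.5/0.45) receive a
two-base symbol. Full-length calls keep trailing `N`s; the pipeline report
additionally prints the conventional trimmed form (NNNNCCNN → NNNNCC).
A `min_count` floor (default 1, i.e. off) can drop low-coverage PAM
variants before profiling. The PAM wheel is a prefix-count tree in a
configurable position order (protospacer-proximal first by default);
node.count/root.count is the angular fraction a sunburst renderer would
draw. Rendering itself is out of scope; exports are TSV/JSON.

## Numerical and interface choices

- All internal coordinates are 0-based half-open; user-facing PAM
  positions are 1-based from the protospacer-proximal side.
- All simulation randomness flows from one integer seed through a single
  generator; outputs are byte-identical across runs with equal seeds.
- Empty inputs are contracts, not errors: an empty FASTQ yields a report
  with zero counts and no consensus; an empty PAM list yields an n = 0
  profile whose downstream statistics (IC, consensus, logo) raise.
- Problem sizes used by the shipped analyses and checks: 50,000 simulated
  cells per screen (≈ 460–1,750 informative PAMs after sorting and
  parsing), 10,000 reads per indel-efficiency run, 160-nt synthetic
  amplicons. These sizes give 3-σ sampling noise comfortably inside every
  asserted tolerance.

## Known limitations

- Consensus calling reduces a full activity landscape to one degenerate
  string; orthologs with graded, inter-dependent position preferences are
  better read from the exported logo matrix and wheel than from the call.
- The efficiency estimator attributes any near-cut gap to editing; it does
  not model indel-shaped PCR artifacts and has no unedited-control
  subtraction built in.
- Percent-identity metadata in the ortholog table is carried as published,
  not recomputed.
- The anchor-based parser requires both 20-bp flanks within the read; it
  is not a general-purpose amplicon demultiplexer.
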