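# Methods

## Model of the data

An amplicon sequencing sample from pooled edited embryos is modelled as a
multinomial mixture of discrete alleles: the wild-type amplicon (WT), the
programmed substitution allele (MUT), and a site-characteristic set of
insertion/deletion alleles produced by NHEJ around the Cas9 cut (or the
PE2 nick). Each sequenced read is one draw from that mixture, corrupted by
independent per-base substitution errors from PCR and sequencing. Under
this model the observed read shares are unbiased estimates of allele
frequencies, with binomial standard error `sqrt(p(1-p)/n)`; equal
amplification efficiency across alleles is assumed (no correction for
amplicon-length bias, which is negligible for the small indels modelled
here).

Two consequences shape the classifier:

* substitutions are **evidence of error**, never of editing, unless they
  form the complete programmed alt allele at the edit positions;
* indels are **evidence of editing** anywhere in the amplicon, because the
  error model is substitution-only.

PE2 reverse-transcriptase errors are indistinguishable from PCR/sequencing
substitutions at the read level and are not modelled separately. Large
rearrangements and donor multimer insertions fall outside what amplicon
sequencing can see and are out of scope.

## Alignment

Reads are aligned to the wild-type amplicon globally (Needleman–Wunsch
with Gotoh's three-state affine-gap recursion), both orientations, best
score kept (forward preferred on ties). Default scoring: match +2,
mismatch −4, gap open −12, gap extend −1; a gap of length *L* costs
`gap_open + L·gap_extend`. The scheme deliberately makes one contiguous
indel cheaper than several scattered mismatches only when the indel is
real (a 1-nt gap costs 13, vs. 6 per avoided mismatch), matching how
editing outcomes are read: error-only reads stay gapless, cut-site indels
align as single events. `N` bases score 0 against anything.

Traceback is deterministic with tie-break order diagonal > up (deletion) >
left (insertion). Two exact shortcuts keep 200k-read samples fast without
changing any result: (i) a same-length read whose Hamming distance *h* to
the reference satisfies `match·L − (match−mismatch)·h >
match·(L−1) + 2(gap_open+gap_extend)` (h ≤ 4 under the defaults) is
provably optimally aligned gaplessly, since any gapped alternative pairs
at most L−1 columns and pays two gap openings; (ii) duplicate read
sequences are aligned once. The DP kernel is JIT-compiled (numba).

After alignment every indel is shifted to its leftmost score-equivalent
placement (the flanking reference/read character rule, as in VCF
normalisation), so identical outcomes aggregate under one canonical key:
`-<len>@<pos>` for deletions, `+<seq>@<pos>` for insertions, positions
cut-site-relative, composite events joined with `&`. Left-alignment is
idempotent and score-preserving.

## Classification

Label precedence is INDEL > MUT > WT. A read is MUT only if the *entire*
alt allele is present (a read carrying 2 of 3 programmed bases is WT with
`edit_site_genotype = "other"`, preserved for inspection rather than
guessed at). Reads carrying both an indel and the programmed edit are
INDEL: they are not the desired clean genotype. Reads whose terminal
deletions cover the edit positions are uninformative and excluded from
the allele table but counted. An optional cut-site window (off by
default) can restrict which indels count toward the INDEL label for noisy
real data; by default any indel in the amplicon counts.

## Quantification

Allele frequencies are counts over informative reads (reported linear and
log10; zero-count variants are absent rather than −inf). The fidelity
ratio is MUT/INDEL counts, rendered `X:1` with one decimal below 10 and
as an integer above; MUT with zero INDEL renders "MUT-only", neither
class "no-editing". Optional Clopper–Pearson intervals are available for
any share. Development rate is `(blastocyst + morula)/injected`, reported
as a percentage to one decimal.

## Design audits

Conventions: blunt cut 3 bp 5′ of the PAM (between protospacer positions
17/18); the PE2 nick at the same inter-base position on the
protospacer/PAM strand; PAM-relative offsets counted on the protospacer
strand with −1 adjacent to the PAM and 0..2 inside it; the degenerate N
of NGG matches any base.

Re-cleavage risk of the edited allele is tiered: an exact 20-nt
protospacer match next to an NGG within ±6 frames of the original PAM is
`recleavable`; an NGG frame whose protospacer mismatches include the seed
(offsets −1..−12) is `low_risk_seed_mismatch`; no supporting NGG is
`abolished_pam`. Frames with mismatches only outside the seed are treated
as recleavable (PAM-distal mismatches are commonly tolerated); the tiered
output avoids over-claiming that a seed mismatch guarantees protection.

PE2 feasibility is purely geometric: every edited base must lie 3′ of the
nick on the nicked strand and within the RT-template span. HR donors are
built from the *edited* allele, centered on the edit: 200-nt ssDNA
(optionally 5′-biotinylated for Cas9·mSA), blunt dsDNA, or two 200-nt
strands offset by 50 nt so both protruding ends are 5′ (or both 3′) with
a 150-bp paired core.

## Synthetic data

The simulator emulates the study-like data-generating process: multinomial
allele draws at depth 200,000 (the sequencing regime's floor), full-length
single-end reads, constant quality, independent per-base substitution
errors (default 0.002 — a configuration choice in the realistic Illumina
range, not an estimate from data), exact-match 5′ barcodes. A sidecar
truth table enables exact end-to-end checks. Identical seed and
configuration give byte-identical FASTQ.

What it does *not* emulate — and what passing tests therefore do not
demonstrate about real data: sequencing indel errors (an error-only read
can never be called INDEL here by construction; optional stress-testing
requires adding indel variants to the spectrum), quality-score structure,
position-dependent error rates, chimeric reads, amplification bias
between alleles, and paired-end structure. The recovery guarantees are
statements about the pipeline's correctness under its own model, not
about sequencing chemistry.

## Numerical and design choices

* Toy loci: flanks are drawn once from fixed seeds; the ±10 nt
  neighbourhoods of each PAM are hand-engineered so the five printed
  geometries hold exactly (offsets −3/−3/−1/PAM-internal/−4..−6, the
  shifted-PAM case at POS3, the all-frames-abolished case at POS4). The
  printed GRCm39 coordinates anchor the genomic coordinate arithmetic.
* Problem sizes: the test suite runs the full-depth recovery at 200,000
  reads (≈20 s) and the aligner/oracle cross-check at 1,000 random pairs
  of length ≤30; the acceptance script simulates three full-depth samples
  (≈1–2 min total). These sizes are the study's own regime, chosen so the
  binomial 3-SE bounds are meaningfully tight.
* All randomness flows from explicit integer seeds (numpy Generator);
  the pipeline itself is deterministic.
* Degenerate inputs are errors, not silent defaults: empty sequences,
  empty sample sheets, duplicate barcodes, spectra not summing to 1,
  deletions running off the amplicon, zero informative reads.

## Known limitations

* The alignment scheme is a fixed choice; the original analyses' aligner
  and parameters are unstated, so allele tallies on real reads may differ
  marginally near ambiguous complex indels.
* Barcode matching is exact; one sequencing error in a barcode discards
  the read to `undetermined`.
* Multi-amplicon reads, large rearrangements, and donor concatemers are
  undetectable by design.
* The fidelity ratio is a point estimate; at very low INDEL counts its
  sampling variance is large (use the provided binomial CIs on the
  underlying shares).
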