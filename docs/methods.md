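# Methods

## Problem

The CFTR gene carries a polymorphic (TG)mTn sequence — m TG dinucleotide
repeats followed by an n-thymine homopolymer — in the splice-acceptor
region of intron 9.  T7 and T9 alleles are benign; T5 alleles are
clinically significant when combined with long TG repeats ((TG)12T5,
(TG)13T5), so laboratories must determine the TG repeat size whenever T5
is present.  Sanger sequencing of the region is cheap, but compound
heterozygotes with alleles of different total length put the two
haplotypes out of register downstream of the tract, superposing peaks and
making manual chromatogram reading slow and error-prone.  `polytg`
automates the genotype call from one forward and one reverse .ab1
chromatogram.

## Pipeline

1. **ABIF parsing** (`polytg.abif`).  Only the analyzed trace channels,
   called bases, per-base peak locations, channel order and sample name
   are read.  Channel order always comes from the file's `FWO_` record.
   Where editable (tag 1) and basecaller-original (tag 2) records both
   exist, the editable one wins.  All indices are 0-based internally.
2. **Relative intensities** (`polytg.trace`).  At each called base's peak
   location the four channel values are divided by their total.  Positions
   whose total falls below `min_total_signal` (default 50 analyzed-trace
   units; exposed on the CLI because the right value depends on a
   laboratory's instruments) are masked uninformative: they contribute
   nothing to any comparison but still count as detected tract positions.
   A base is "present" at a position when its relative intensity is at
   least `presence_fraction` (default 0.10, inclusive).  The relative
   threshold is scanner-gain invariant; 0.10 keeps a half-amplitude
   heterozygous peak (0.5) solidly present while typical bleed-through
   (<10%) stays absent.  Reverse profiles are flipped into
   genomic-forward orientation (positions reversed, channels
   complemented), so every downstream step sees the tract as T/G.
3. **Tract detection** (`polytg.detect`).  The tract is anchored on fixed
   15 bp flanking sequences: the forward read on the upstream flank, the
   reverse (oriented) read on the downstream flank.  Anchor matching is a
   unique-best Hamming match over dominant bases, tolerating 2 mismatches
   (uninformative positions match anything).  Forward scan: a position
   stays in the tract while thymine is present there or at the next
   position; the first two consecutive thymine-free positions terminate
   it.  The two-consecutive rule is a deliberate reconstruction of
   "thymine no longer detected": clean guanine positions inside the TG
   repeat lack thymine, while the downstream flank begins with two non-T
   bases, so the rule terminates exactly at the flank.  Reverse scan:
   leftward from the downstream anchor while adenine is absent; the first
   adenine peak ends the tract.  That terminating adenine must reach
   relative intensity 0.25 (`TERMINATION_FRACTION`), not the generic 0.10:
   a genuine terminator A is never diluted below 0.5 by heterozygous
   superposition, whereas baseline noise at realistic levels crosses 0.10
   often enough to truncate windows.  Scans are capped at 60 positions
   (longest searched allele, 43, plus margin); hitting the cap or the read
   end marks the window partially detected, which is reported as a warning
   rather than an error.
4. **Expected patterns** (`polytg.model`).  For every genotype in the
   search space (default T3–T11 × (TG)8–(TG)16: 81 alleles, 3321 unordered
   pairs) the two allele sequences are aligned left (5') for the forward
   comparison and right (3') for the reverse one — both alleles share the
   primer-proximal sequence, so their tracts coincide at the end nearest
   each sequencing primer.  Each position's expected base set is the union
   of the aligned allele bases: {T}, {G} or {T,G}, with expected relative
   intensities 1/0 or 0.5/0.5.  Positions beyond the shorter allele carry
   only the longer allele's base; the shorter allele's flank contamination
   there is treated as signal dilution, not as an expectation.
5. **Elimination and scoring** (`polytg.scoring`).  A genotype is
   eliminated when any single-base expected position lacks that base's
   signal.  The check covers the whole expected pattern: positions beyond
   the detected window are read from the profile by extending the window's
   frame (forward: rightward; reverse: leftward past the window start).
   This is essential, not cosmetic — without it a pattern one thymine
   longer than a homozygous truth is never contradicted and would outrank
   the truth via the length-bonus term.  {T,G} positions never eliminate;
   observed-but-unexpected signal never eliminates.  Survivors get the
   normalized difference score over the nF + nR observed positions

       D = Σ [(OGi − EGi)² + (OTi − ETi)²] / (2 (nF + nR))
           + (100 − mF − mR) / 1e5

   with E = 0 at observed positions beyond the expected length and
   uninformative positions contributing 0 while staying in nF/nR.
   Reverse windows are compared right-aligned (indexed by distance from
   the downstream anchor).  Survivors are ranked ascending by D, ties
   broken by canonical genotype order.  Ranking runs through a vectorized
   engine over precomputed pattern matrices; the scalar functions
   `is_compatible`/`difference_score` define the reference semantics and
   the tests hold the two paths to 1e-12 agreement, plus an independent
   string-and-loop brute force as a third opinion.

## Reference region and flank anchors

The packaged reference (`polytg/data/synthetic_reference_amplicon.fasta`)
is a **synthetic stand-in**, not genomic sequence: a 427 bp
primer-to-primer amplicon with the published PCR primers at its ends, a
(TG)11T7 reference tract, fixed 15 bp flanks, and generated intronic-style
padding.  Construction constraints (all asserted by tests): the upstream
flank ends in an A/C-only tail terminating in A — the A immediately 5' of
the tract terminates the reverse scan exactly, and the A/C tail contradicts
over-long candidate patterns crisply; the downstream flank and the 12
bases after it are thymine-free, so the forward scan terminates exactly
for every allele-length offset up to the search-space maximum; neither
flank recurs anywhere in the amplicon (or its reverse complement) within
Hamming distance 4, keeping anchor matches unique; no TG or poly-T runs
exist outside the tract and the primers.  Consequence of the terminal-A
choice: for noiseless heterozygotes the forward window spans the longer
allele and the reverse window the shorter one (the shorter allele's flank
A stops the leftward scan); homozygous windows are exact in both
directions.  The reverse truncation loses nothing: the dropped positions
are exactly the flank-contaminated ones, and noiseless recovery over the
search grid is exact.

## Simulator

`polytg.synthetic` renders each haplotype's full template (5' context +
tract + 3' context, defaults from the packaged amplicon) as Gaussian peaks
(spacing 12 trace points, sigma 3, total amplitude 1000 split half per
allele) summed positionwise anchored at the read's 5' end, which
reproduces the in-register-then-overlapping-peak phenomenology of
heterozygous Sanger traces.  Optional channel bleed-through (fraction of
each peak leaked into its paired channel, T↔G and A↔C; 0.08 mimics
G-under-T shoulders) and additive Gaussian baseline noise (clipped at
zero, then rounded to integers) complete the model.  Peak kernels are
truncated one point short of the neighboring peak center so that a
noiseless read yields mathematically exact relative intensities (0, 0.5,
1); this is what lets closed-form score tests assert to 1e-12.  An
optional tandem-duplication mode superposes a shifted copy of one
haplotype to emulate heterozygous-indel interference.  Everything is
seeded and byte-reproducible.

What the simulator does **not** emulate: mobility shifts, peak-width and
quality decay along the read, polymerase slippage/stutter, dye blobs,
baseline drift, or inter-run gain variation.  Passing tests therefore
demonstrate correctness of the inference machinery under idealized
analyzed traces, not robustness to every real-world chromatogram
pathology; the signal thresholds exist precisely because real data need
them tuned.

## Known limitations

- **Sibling-genotype near-degeneracy.**  For a heterozygous truth
  (m1,n1)/(m2,n2) with m1<m2 and n1<n2, the poly-T-swapped sibling
  (m1,n2)/(m2,n1) has a smaller maximum length, fits inside the observed
  windows, and differs in score only through the (100−mF−mR)/1e5 term
  (4e-5 per 2 bp): at positions past the shorter allele the observed
  relative thymine is 0.5, exactly equidistant from the two candidates'
  expected 1 and 0.  Any realistic noise therefore flips such pairs; in
  the noisy recovery benchmark they account for essentially all top-1
  misses (recovery ≈ 90% at 5% amplitude noise over a uniform subgrid,
  versus 100% noiseless).  Clinically important genotypes — T5 alleles
  carrying the longer TG repeat — sit in the opposite, safe configuration
  where the sibling exceeds the observation and is eliminated by the
  signal-free flank.  Reports should still be reviewed when the top ranks
  are separated only by the length-bonus term.
- Heterozygous indels elsewhere in the amplicon are flagged (more than 3
  of 15 anchor positions carrying a second base), never deconvolved.
- Partially detected windows are scored with a warning; such results
  should be discarded on review.
- Only the canonical (TG)mTn structure is modeled: no interrupted repeats,
  no phasing against variants outside the tract.
- The bundled reference is synthetic; deployments against real data
  should verify the flank constants against the genomic region their
  assay amplifies.

## Benchmark sizes

Test-suite benchmarks use the 210-genotype subgrid (T5–T9 × (TG)10–(TG)13)
for exhaustive noiseless recovery and subgrid × 5 seeds for noisy
recovery, 50 seeded samples for brute-force oracle equivalence, and all 81
homozygotes for the closed-form score check; these sizes keep the whole
suite comfortably under a few minutes while covering the full default
space through the corner-case tests.
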