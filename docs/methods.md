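# Methods

## Coordinate system and structure model

All hairpin positions are addressed as signed offsets from the putative
DROSHA 5′ cleavage site, defined as the 5′-most nucleotide of the annotated
5p mature arm (offset 0). Negative offsets run 5′-ward into the basal stem
and flank; 3′-arm positions are addressed through their pairing partners.
Inputs are annotated pri-miRNAs: a sequence of at most 200 nt (the length
practical for subcloning) with 1-based closed intervals for the 18–25 nt
mature arms. Cleavage sites are *not* predicted: the package requires
annotated arms and anchors everything to them.

Secondary structure comes from an injected folding service returning the
minimum-free-energy (MFE) dot-bracket structure; the default implementation
wraps the ViennaRNA bindings and memoizes results, so folding is
deterministic and byte-stable across calls. No thermodynamic parameters are
implemented in this package and no suboptimal ensembles are used — every
structural claim is a claim about the single MFE structure.

## The engineered scaffold layout

The design engine builds scaffolds constructively:

```
flank5 (10 nt) | basal stem 5′ (b nt) | guide arm | loop | passenger arm | basal stem 3′ | flank3 (10 nt)
```

with the 3′ basal strand the exact Watson–Crick mirror of the 5′ strand.
The determinants are imposed on this layout:

* **Basal GU** — `G` at offset −14, `U` at −13 (the published orientation;
  the basal-motif literature also writes UG, so the dinucleotide is a
  configurable field).
* **35-bp stem** — the stem is counted as the base pairs *enclosing the
  designated loop interval* in the refolded structure. The basal length
  `b` starts at the debulge-window width and is corrected by feedback
  (`b += target − observed`) against the refold until the count is exactly
  `stem_len_target` (default 35). This absorbs whatever pairing the natural
  duplex adopts, including its mismatches. With a canonical 22-nt duplex
  the converged layout corresponds to ~13 basal pairs + the duplex, i.e.
  the mature duplex abuts the loop; any upper-stem remnant of the parent
  between the DICER sites is collapsed into the loop region, because a
  35-pair stem equal to basal + duplex is not otherwise attainable.
* **Unstructured stem base** — operationalized as
  `flank_unstructured_len` = 10 nt unpaired on each end of the refold.
  Attempt 0 reuses the parent's own flank sequence (which makes
  reconstruction of an already-valid scaffold byte-identical and every
  `apply_*` idempotent); later attempts resample flanks from a seeded
  generator restricted to A/C (two A/C-only strands cannot pair with each
  other) with homopolymer runs < 4.
* **CHC bulge** — the bulged H nucleotide (default `A`, any IUPAC H
  allowed) sits on the 3′ (passenger-side) basal strand between two
  paired C's opposite offsets −5/−6; the 5′ strand carries G/G there. The
  debulged window (offsets −13…0) must be entirely Watson–Crick or GU
  paired after refolding; the passenger position pairing offset 0 is
  repaired to the guide's complement when needed. Only the 3′-strand bulge
  geometry is implemented (the strand field exists as a config switch and
  rejects "5p" explicitly).
* **Loop** — the designated loop interval must carry the configured loop
  sequence verbatim. The default is the 19-nt loop region of the
  hsa-mir-30a precursor between its annotated arms; it ships as an
  editable fixture, not asserted ground truth, because published loop
  boundaries vary.

**Why the loop check is sequence-level.** At unconstrained MFE the
authentic miR-30a loop region partially pairs with itself — it does so even
in the natural hsa-mir-30a precursor — so "loop entirely unpaired" would
reject the authentic loop. The validator therefore checks (i) the
designated interval carries the configured sequence, and (ii) the
structure's terminal loop falls within/overlapping that interval (the
hairpin apex is in the loop region, single-hairpin topology). Stem pairs
are counted as pairs *enclosing the designated interval*, so loop-internal
zipping is never mistaken for stem.

`apply_chc_insertion` and `apply_loop_swap` applied alone operate
surgically on the natural parent (rewriting only the window's 3′ partner
segment, or only the terminal loop) and leave the rest untouched.
`apply_all` uses the constructive path and must pass all seven checks:
basal_GU, chc_bulge, debulged_window, stem_length, loop_identity,
flanks_unstructured, single_hairpin.

**Duplex grafting.** `embed_duplex` rebuilds the scaffold with its recorded
modification set rather than splicing bytes: the basal complements must
track the passenger tail or every downstream check would fail, so sequence
"outside the duplex" is preserved only where it already satisfies the
checks. A derived passenger is the full reverse complement of the guide
(blunt duplex); an explicitly supplied passenger is assumed to follow the
natural miRNA geometry in which its last two nucleotides pair offsets
−1/−2 (the DROSHA 2-nt overhang). Because a fully complementary duplex
helix dominates the MFE, even strongly self-pairing guides are rescued by
their derived passengers; post-graft validation fails in practice when an
explicit passenger cannot pair the guide.

**Candidate screening.** `screen_candidates` keeps backbones whose CNNC
motif (C, any, any, C) starts 16–21 nt downstream of the 3p DROSHA site
(canonical placement; window configurable), ranks by abundance, and breaks
ties lexicographically by id for reproducibility.

## Quantification model

Reference windows are built per scaffold — mature strand plus 10 flanking
scaffold bases on each side (42 bases for a 22-nt strand) — so two
scaffolds can never cross-map by construction. Read acceptance mirrors a
strict isomiR filter: a single `M` (or `=`) CIGAR run of 18–24 nt, mapped,
primary, non-supplementary, forward strand. `M` tolerates substitutions
because only indels are disqualifying; a strict mode demands `=` runs or
an NM:i:0 tag. Soft/hard clips are rejected. Reads shorter than the core
are accepted if ≥ 18 nt (isomiR trimming).

Strand counts are normalized as reads-per-million classified small-RNA
reads; RPM is the minimal assumption for "normalized quantification" and
the library-size factor is a parameter. The guide:passenger ratio is the
raw count ratio, reported as an infinity-flagged sentinel when the
passenger count is zero and an error when both are zero. Precision
profiles put each accepted read's start and (inclusive) end position into
per-position percentage vectors over the window; both vectors sum to 100
whenever at least one read is assigned, and zero assigned reads is an
error, never a NaN vector. The 5′ fidelity is the start percentage at the
expected mature start (window position 10, 0-based). Reports print 1-based
positions with the mature strand uppercase and flanks lowercase.

## Simulator: what it emulates and what it does not

The simulator draws reads as exact substrings of the reference windows:
strand role ~ Bernoulli(guide_fraction), 5′ and 3′ shifts from
user-supplied jitter distributions over small offsets, lengths clamped to
18–24 nt by resampling (hard cap, then error). Defaults represent a
well-processed scaffold: guide fraction 0.998 (~500:1, the middle of the
observed 10²–10³-fold range) and point-mass-at-zero jitter; the precision
experiments use 1% start jitter split ±1, matching the >98% 5′-fidelity
regime. Base qualities are constant; there is no sequencing-error,
adapter, or ligation-bias model, and no endogenous miRNA background. A
passing round trip therefore demonstrates that the quantifier recovers
known processing statistics from ideal reads — not that it is robust to
sequencing artifacts, which are assumed to be handled by upstream QC
(FastQC/fastp/Kraken2 are deliberately out of scope). SAM output is
emitted alongside FASTQ so no external aligner is needed; a naive
exact-substring aligner is bundled for exercising the FASTQ path in tests.

## Assay calculators

Residual reporter expression is mCherry X-median(GFP+) / X-median(GFP−)
within the same sample (knockdown% = 100·(1 − ratio)); it is
scale-invariant, and a non-positive denominator is an error. ddPCR genome
integrity is the percent of droplets positive for both cassette-end probes;
the default denominator is all probe-positive droplets (double + single
positives), with negatives-included mode available since the published
phrasing is ambiguous. No Poisson copies-per-droplet correction is applied.

## Numerical choices and problem sizes

Stochastic design steps (flank/basal resampling) and the simulator draw
from seeded generators; identical seeds give byte-identical scaffolds,
FASTQ and SAM. Design uses at most 50 attempts × 25 basal-feedback
iterations before failing loudly. The bundled study sizes — 10,000 reads
for fidelity, 20,000 for the 500:1 ratio — put the binomial 99% CI
comfortably inside the claimed bounds (≥98% fidelity, ≥100-fold ratio)
while keeping the full test suite in seconds on one CPU.

## Fixtures and limitations

The bundled parents are the miRBase stem-loops of hsa-let-7a-1 and
hsa-mir-26b padded with 25 nt of synthetic low-structure (A/C) sequence on
each side; the true genomic pri flanks are not reproduced, and the bundled
22-nt screening guide is synthetic. Results on engineered scaffolds are
statements about MFE structures of ~100–120 nt constructs; in-cell folding,
RNA-binding-protein effects, and tissue-specific processing are outside the
model. The adversarial-graft failure mode ("self-complementary guide breaks
the hairpin") is largely neutralized by the constructive rebuild with a
complementary passenger; failures require a genuinely unpairable duplex.
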