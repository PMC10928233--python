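# Methods

## Scope and model

`mmrdkit` quantifies mismatch repair deficiency (MMRD) from four orthogonal
read-outs. The biological model is simple: loss of MMR leaves DNA-polymerase
slippage at short tandem repeats uncorrected, so (i) mononucleotide
microsatellites accumulate 1-bp deletions genome-wide, (ii) the classic
clinical panel loci shift allele length, (iii) somatic point mutations
accumulate (hypermutation), and (iv) the mutation spectrum shifts toward the
MMRD-hallmark signatures (Signature 6 / SBS6 and relatives). Each read-out is
implemented as a pure function from explicit inputs to an explicit result
object with full provenance, so a report can be re-derived bit-identically
from its recorded seed and thresholds.

## Genome-wide MSI (MMRDness) score

**Locus catalog.** A microsatellite locus is a *maximal* homopolymer run in
the reference (flanking bases differ from the run base, or the run abuts a
contig end). Coordinates are 0-based half-open (BED-compatible). Only
mononucleotide runs are catalogued — the panel loci are mononucleotide and
the score counts single-base deletions, so di-/tri-nucleotide repeats add
nothing here. Runs containing N are excluded. The score uses runs of 10–15 bp
inclusive. An optional mask hook exists for users who want to restrict loci
by mappability; no mask is applied by default.

**Deletion tabulation.** The SAM/BAM is streamed once and reads are matched
to loci by per-contig binary search, so neither a coordinate sort nor an
index is required. A read *spans* a locus when its aligned reference interval
covers the run plus ≥1 flanking base on each side. A spanning read counts as
a deletion observation iff the only indel its alignment places inside the run
is a single 1-bp deletion (CIGAR `D` of length 1 with both endpoints inside
the run). Insertions and ≥2-bp deletions inside the run count toward neither
the numerator nor the deleted state: the statistic is defined on 1-bp
deletions, and conflating event types would change its operating point.

**Locus call and denominator.** At ~1× coverage most loci carry a single
read, so a locus is *deleted* when ≥`min_support` (default 1) spanning reads
show a 1-bp deletion, and only loci with ≥1 spanning read enter the
denominator — unobserved loci are uninformative at low pass. (Using the full
reference catalog as denominator would deflate the score by the fraction of
loci that happened to draw zero reads.)

**Score.** With per-length fractions f(L) = (n_del(L)+ψ)/(n(L)+ψ):

    score = log_b( mean_L f(L) ) + offset,   offset = 1.1, b = 10, ψ = 0

Bins with zero observed loci are excluded from the mean and listed in the
result provenance. score > 0 → "MMRD"; score ≤ 0 → "MMR-proficient"; the
boundary is assigned to proficient because positive scores indicate
deficiency. The log base is configurable but defaults to 10: with the +1.1
offset, base 10 places the decision threshold at a mean deleted-locus
fraction of 10^−1.1 ≈ 7.9%, a plausible operating point between proficient
(~1–2% observed at 1× with per-read slippage 0.01) and deficient (~30%
observed at per-read slippage 0.2); natural log would imply an implausible
33%. The pseudocount ψ defaults to 0; a small ψ avoids the −∞ sentinel on
ultra-clean samples (with ψ=0 and zero deletions everywhere the score is −∞
and the call is proficient, flagged in provenance).

## Panel MSI

Per locus the *representative allele* is the highest peak whose immediate
neighbours in allele-length order both have strictly lower height — the
stutter-flanked main peak. Boundary peaks cannot satisfy the flanking rule;
when no interior peak does (single-peak or monotone profiles) the global
maximum is used, so the function is total on degenerate electropherograms.
Height ties break toward the shorter allele (slippage deletions shorten
alleles); this is configurable. The locus shift is |test − normal| in bp —
shifts count in either direction — and a locus is unstable at shift ≥ 3 bp
(≤2 bp is stable). Sample call: ≥2 unstable loci → MSI-High, exactly 1 →
MSI-Low, 0 → MS-Stable. Loci missing from either profile reduce the assayed
denominator and are flagged; profiles with two genuine alleles
(heterozygous-like) are not specially handled — a single representative
allele is still chosen and the profile can be inspected via the flags.

## Consensus TMB

Caller VCFs are read with multi-allelic records split and alleles normalized
by shared suffix-then-prefix trimming (reference-free left-normalization);
identity across callers is (contig, position, ref, alt). Whether the original
pipelines deduplicated by position or full allele is generally unstated in
the literature; full-allele identity is the stricter, documented choice.
Non-PASS records are excluded by default. The consensus keeps variants
reported by ≥2 callers (configurable), partitioned into SNVs and indels, each
record retaining its supporting-caller set. TMB = distinct consensus SNVs /
callable Mb; the callable span defaults to a scalar 50 Mb (typical callable
exome footprint) and can instead be computed from a BED. Indels are reported
separately and never enter the TMB numerator or the hypermutator call, which
is strict: hypermutant iff TMB > 10 mut/Mb, so exactly 10.0 is not
hypermutant.

## Signature refitting

SNVs are binned into the 96 pyrimidine-normalized trinucleotide channels in
COSMIC order (substitution class, then 5′, then 3′ context); purine-reference
variants are reverse-complemented, context included, before assignment. The
channel order is written into every catalog/matrix output header to prevent
silent misalignment. Refitting solves the non-negative least squares problem
e* = argmin_{e≥0} ‖c − S·e‖₂ with scipy's active-set NNLS — the same
plain-refit behavior as the standard R refitting tools; strict-refit/forward
selection variants are out of scope. Results report exposures (mutation
counts), percentage contributions, the reconstruction, cosine similarity and
residual norm; rank-deficient matrices are solved but flagged unstable in
provenance. The MMRD read-out sums contributions over a configurable id set —
{Signature.6} for COSMIC-v2-style matrices, {SBS6, SBS15, SBS21, SBS26,
SBS44} for v3-style. Signature matrices are user-supplied TSVs in the COSMIC
download layout; a deterministic synthetic 96×4 matrix
(`sim.synthetic_signature_matrix`, sparse Dirichlet columns, seed-fixed) is
used by the tests so nothing is downloaded. It is a synthetic stand-in, not
the real COSMIC profiles.

## Synthetic data: what it emulates, and what it does not

The simulator produces every pipeline input with machine-readable ground
truth; outputs are pure functions of (config, seed) using
`numpy.random.default_rng`.

- **Reference**: one contig with a configured number of loci per length
  (default 100 per length 10–15, ~100 kb). Spacers are random sequence
  constrained to runs ≤3 bp, and run-adjacent spacer bases differ from the
  run base, so embedded runs are maximal and are the only runs ≥10 bp.
- **Reads**: Poisson(coverage) reads per locus (default coverage 1.0,
  emulating low-pass sequencing), spanning with 6–15 bp flanks; each read
  independently carries a 1-bp deletion of the run with probability
  `slippage_del_rate`, encoded as a CIGAR 1-bp `D` at a uniform position in
  the run. Proficient vs deficient conditions use per-read rates ~0.01 vs
  ~0.2–0.4. Reads are emitted directly as aligned records: no sequencing
  error, base quality, PCR-artifact or alignment modelling, and no diploid
  genotypes — this isolates the scoring logic under test, and means passing
  tests certify the statistic, not robustness to alignment artifacts.
- **Caller sets**: n true variants (SNVs, plus 1-bp indels at
  `indel_fraction`=0.15) at distinct positions; each of `caller_count`
  (default 4) callers reports each truth independently with probability
  `caller_overlap`, plus Poisson caller-private false positives
  (`fp_rate` default 0 — caller noise is uncharacterized, so it is off
  unless configured).
- **Catalogs**: multinomial draws from the mixture-weighted channel
  distribution; `simulate_context_snvs` additionally realizes a catalog as
  concrete VCF-writable SNVs placed at context-matching reference positions.
- **Panel profiles**: main peak per locus at a fixed per-locus baseline
  length, stutter side-peaks at ±1/±2 bp with 50%/25% of the main height
  (arbitrary but documented; chosen so the flanked-peak rule is exercised),
  test-profile main peak displaced by the configured signed shift.

## Numerical and testing choices

- Statistical oracles: binomial quantities are tested at 3 standard errors;
  whole-catalog calibration uses a chi-square goodness-of-fit (channels with
  expected count <5 lumped) rather than 96 per-channel 3-SE bounds, which
  would be miscalibrated under multiplicity.
- Frozen arithmetic oracles (e.g. the mixed-table score
  log₁₀(mean(.03,.05,.08,.12,.15,.20))+1.1 = 0.12118929906993825) were
  computed independently and asserted to 1e-12.
- End-to-end checks run at 100 loci per length (600 loci, ~30 kb genomes) and
  n = 10⁴ mutations for signature recovery — sizes at which the binomial/
  multinomial noise is far smaller than the effect separations being tested.
- Determinism: every simulator seeds a fresh generator from (seed, stage
  salt), so stages are independent and reports are byte-identical across
  reruns of the same config.

## Known limitations

- The MS-indel caller operates on alignments as given; there is no
  realignment or quality filtering, and real low-pass data would add
  alignment noise the simulator does not model.
- The genome-wide score is unpaired (no tumor-vs-normal subtraction).
- Panel classification starts from peak tables; raw capillary trace
  processing (.fsa parsing, size-standard calibration) is out of scope.
- TMB's callable span is a scalar unless a BED is supplied; no
  coverage-based callability computation.
- Signature refitting is plain NNLS refit against a supplied matrix; de novo
  extraction (NMF) and indel/doublet signatures are out of scope.
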