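# Methods

## SILAC measurement model and quantification

Each purified exon RNP complex mixture yields peptide-level light and
heavy intensities. The quantification path is:

1. **Peptide ratio** r = I_light / I_heavy, defined only when both
   channels are present and strictly positive. Peptides failing this are
   excluded and logged with a reason code (`missing-channel`,
   `zero-channel`); a missing channel is recorded as absent, never as
   zero, so the exclusion policy is explicit rather than an artifact of
   arithmetic.
2. **Protein aggregation**: the exponentiated median of log₂ peptide
   ratios (configurable to the mean). The median was chosen because a
   single mis-quantified peptide otherwise drags a protein's ratio;
   aggregation in log space respects the multiplicative error structure.
   `n_peptides` is always reported; no minimum-peptide filter is applied
   by default (a configurable filter exists).
3. **Anchor normalization**: every protein ratio is divided by the
   average ratio of the cap-binding proteins CBP20 and CBP80, which bind
   each capped substrate RNA once and are therefore equimolar across
   complexes. "Average" is the geometric mean by default (ratios are
   multiplicative; the arithmetic mean is available as an option). After
   normalization the anchor geometric mean is exactly 1; a missing
   anchor pair is a hard error, a single anchor a warning.
4. **Fold changes**: for a direct light-A/heavy-B mixture the normalized
   ratio is itself the A/B fold change (orientation metadata records the
   numerator state). For two mixtures sharing a reference state, the
   **ratio of ratios** R̂(A/C)/R̂(B/C) cancels C and estimates A/B — this
   is how EDC/active fold changes are derived from EDC/repressed and
   active/repressed mixtures without a direct EDC-vs-active experiment.
   Proteins present in only one input table are omitted from the derived
   comparison and reported separately.
5. **Spiked-reference abundances**: when three light complexes are each
   spiked with one common heavy reference, abundance(p, s) =
   [L(p,s)/H(p,s)] normalized to the geometric mean of the anchors'
   ratios in the same state. Per-state loading inflation cancels because
   the anchors carry it too. State-vs-state fold changes are ratios of
   these abundances. The direct-mixture and spiked-reference routes are
   kept as distinct operations; on noise-free synthetic data they agree
   exactly (asserted in the test suite), and on real data their
   agreement is an internal consistency check, not an identity.
6. **Enrichment classes**: enriched if fold change > 2, depleted if
   < 0.5, else unchanged — strictly ("greater than two-fold"), with the
   threshold configurable. Proteins lacking two-channel evidence are
   `insufficient-evidence`, never ±∞. No multiple-testing correction is
   applied: the quantities are ratio estimates, not hypothesis tests.
7. **Cross-experiment consistency**: proteins quantified in only one of
   two independent experiments are discarded; retained proteins report
   both fold changes and whether they fall on the same side of 1.

NSAF spectral abundance is NSAF_i = (SpC_i/L_i) / Σ_j (SpC_j/L_j);
zero-count proteins are kept at 0 so tables from different complexes
stay aligned. Whether counts are unique or total spectra is the
caller's semantics — the arithmetic is identical.

## Cluster zone classification

All coordinates are 0-based half-open; BED input is native, GFF3
conversion goes through a single utility. Minus-strand loci are mirrored
onto the transcribed axis, so every rule is written once; strand
symmetry (mirror the locus, flip the strand, labels unchanged) is
property-tested.

The decision operand is the cluster **midpoint** (for even lengths, the
central position nearer the 3' splice site — a single deterministic
point; an any-overlap variant was considered and rejected because it
requires an arbitrary zone precedence). The decision sequence:

1. midpoint inside the exon → `c`;
2. midpoint past the 5' splice site → `d`;
3. midpoint more than 100 nt upstream of the first base of the
   intron-terminal AG (exclusive distance, strict `>`; a `>=` option
   exists) → `a`;
4. otherwise the branch point decides: more than 25 nt upstream of the
   branch adenosine → `a`, else `b`.

The branch point is predicted once per exon (per-intron, not
per-cluster) by scanning a 5-column position-weight matrix over the
final 100 nt of the upstream intron, excluding the last 3 nt (the AG
and its preceding base). Candidates are adenosines at the matrix's
branch position; scores are summed log₂ odds against a uniform
background; ties break toward the 3' splice site. The default matrix
encodes the mammalian consensus (pyrimidine-U-n-A-g; canonical instance
cucAg) and is data, not code — any matrix can be supplied, including
from JSON. If no adenosine is scoreable where the branch point is
needed, the cluster is labelled `b` with a degraded-evidence flag — the
conservative choice, since calling it `a` would overcount distal-only
architectures.

Cohort processing filters to exons with ΔPSI ≥ 15 percentage points
upon regulator depletion (inclusive, per "≥15%") that carry at least
one associated cluster; exclusions are logged per exon. Architectures
collapse the per-exon label multiset: `distal-only` (non-empty, ⊆{a,d}),
`contains-b`, `contains-c`, `mixed` (both b and c), `unbound`. Fractions
use the full retained cohort as denominator, including exons whose
evidence is degraded — nothing is silently dropped.

## Synthetic data: what it emulates and what it does not

**SILAC generator.** Per peptide, a base intensity is drawn log-uniform
over ±1.5 decades around `base_intensity` (10⁶ arbitrary units); the
heavy channel is base × 2^ε_h and the light channel base × fold-change ×
mixing-error × 2^ε_l. `log2_noise_sd` (default 0.2) is the standard
deviation of the peptide log₂-ratio noise and is realized as
sd/√2 per channel independently, so single channels fluctuate while the
ratio carries exactly the stated scatter. Single-run comparative
experiments of this design provide no replicate-based noise estimate,
so 0.2 — a typical peptide-level SILAC ratio spread for well-behaved
complexes — was fixed once as the default and is a config field, not a
constant. Anchors are
hard-wired to fold change 1 (a config that plants anything else is
rejected); the mixing error (default 1) multiplies every light
intensity, so anchors carry it and normalization must remove it.
Missing peptides lose one randomly chosen channel (recorded absent, not
zero) with probability `missing_rate`.

What this does not emulate: peptide-level interference and chimeric
spectra, intensity-dependent variance, shared peptides between
paralogs, digestion variability, or any identification-level error.
Passing tests therefore demonstrate the correctness of the ratio
algebra and its estimators under a clean error model, not robustness to
search-engine artifacts.

**Exon cohort generator.** Each exon sits on its own synthetic gene
laid out [upstream intron | exon | downstream intron] (introns 250–450
nt, exons 60–150 nt), plus strand by construction; minus-strand
fixtures are exact mirror images. The last 100 nt of the upstream
intron is an adenosine-free pyrimidine-skewed background carrying one
planted CTCAG with the branch A at a recorded offset 20–40 nt upstream
of the intron end, and the intron terminates in AG — so branch-point
prediction has exactly one candidate and recovery is checkable exactly.
Cluster midpoints are placed at least `boundary_margin` (default 5) nt
inside their intended zone, so label recovery tests the rules, not
tie-breaking; setting the margin to 0 generates boundary-straddling
clusters for edge tests. Architecture counts are apportioned exactly
(largest remainder when probabilities are given), not sampled, so a
planted composition is deterministic. The default cohort plants 95
exons: 40 bound distally on both sides, 8 + 8 on one side (56
distal-only), 19 with a branch-point/3'ss cluster, 10 with an exonic
cluster, 10 with both — non-distal architectures always include a
distal cluster, matching the observation that repressed exons are never
bound only in the exon or its 3' splice site. ΔPSI values are drawn
uniform on [15, 80] percentage points (all exons pass the derepression
filter — the cohort represents the already-selected exon set).

Real iCLIP data differ in ways the generator does not model: cluster
boundaries are read-depth artifacts, multiple clusters can tile one
zone, branch points can be degenerate or multiple, and ΔPSI estimates
carry error. Exact label recovery on synthetic cohorts validates the
rule implementation; on real data the 100-nt/25-nt thresholds and the
PWM are the scientific degrees of freedom.

## Numerical choices and degenerate inputs

- All ratio averaging is done in log₂ space; anchor geometric means are
  exact to 1e-12 after normalization (tested).
- `ratio_of_ratios(x, x) = 1` and reversal reciprocity (f → 1/f,
  enriched ↔ depleted) hold to 1e-9 over randomized inputs (tested on
  1,000 cases).
- Zero or missing channels never enter a ratio; all-zero spectral
  counts and empty cohorts are errors, not NaN propagation.
- Even-length cluster midpoints round toward the 3' splice site;
  distance comparisons are strict by default with an inclusive option.
- Seeds: every generator takes an explicit seed; identical
  (config, seed) gives byte-identical outputs, including through the
  CLI.

## Problem sizes

The reproduction script (`scripts/acceptance.py`) uses 40 proteins ×
5–10 peptides for the remodeling fold-change run, 20 proteins × 5
peptides for the noise-free oracle, 100 proteins × 5 peptides × 20
seeds for the recovery benchmark, and the 95-exon default cohort —
sizes at which the estimators' sampling error is comfortably inside
the reported precision while a full run completes in seconds.

## Known limitations

- Protein inference is taken as given: one accession per peptide row,
  no shared-peptide apportioning (and no dNSAF).
- The branch-point PWM is a consensus stand-in with a documented
  default; it is not a trained model, and its scores are comparable
  only within one matrix.
- The classifier assumes one cassette exon per locus; overlapping exon
  models would need explicit cluster-to-exon assignments via the
  cluster name field.
- Fold-change uncertainty is not propagated (no confidence intervals);
  `n_peptides` is the only evidence weight reported.
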