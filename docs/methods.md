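# Methods

## The barcode and its registry

A sample's barcode is the ordered vector of categorical genotype calls —
HOM1 (homozygous allele 1), HET, HOM2, NOAMP (no amplification), UNDET
(undetermined) — over a fixed panel of biallelic SNP assays, 32 by default
with three Y-linked assays. The registry stores one reference barcode per
patient; when no patient sample exists the earliest available xenograft
passage stands in, recorded in a `provenance` field but treated identically
in matching. Same-patient duplicates (diagnosis/relapse pairs, independent
xenografts of one patient) are legitimate and therefore only warned about,
never rejected. Panel size is configurable so small autosomal-only panels
can be used in toy settings; the three Y assays occupy the last panel
positions for exactly this reason.

Three of the default panel's assay IDs (the Y-linked trio) and five assays
with known chromosomal locations are real vendor identifiers of a
commercial human-identification barcode panel; the remaining 24 IDs and the
Y-assay coordinates are synthetic placeholders, since the full assay list
is not public. Nothing downstream depends on the placeholder coordinates
except karyotype-region overlap, which uses the five real locations.

## Amplification model

The package models each biallelic assay as two logistic fluorescence
channels over `cycles` qPCR cycles (default 40). With allele template
amounts `a = (a1, a2)` in copies per diploid genome-equivalent:

* threshold crossing at `Ct_i = ct0 − log2(a_i/2)` — the canonical
  one-cycle-per-doubling Ct law, anchored exactly at the instrument
  detection threshold (`anchor_threshold`, default 10 fluorescence units);
* plateau at `plateau · a_i/2` (default full-template plateau 1000 units);
* logistic growth rate `ln 2` per cycle (doubling in the exponential phase).

Making the plateau proportional to template amount — rather than common to
both channels — is a deliberate choice: the two allele probes compete for
one amplicon pool, and it is what gives the endpoint of the allelic
discrimination trajectory its information content, `angle = atan2(a2, a1)`.
The model then reproduces both experimental signatures at once: endpoint
angle shifts under copy-number imbalance (dosage `(1,2)` sits at 63.4°,
between the heterozygous and homozygous clusters) and late minor-channel
rises under small admixture (`ΔCt ≈ log2(1/f)`; at f = 1/32 the endpoint
is still inside the homozygous calling band while the minor channel rises
five cycles late). A hemizygous male Y locus, dosage `(1,0)`, plateaus at
half the autosomal level — which is also why a 50:50 male/female chimera's
Y signal (quarter level) lands in the undetermined magnitude band and sex
inference reports INCONSISTENT.

Noise has three interpretable components (`NoiseModel`): multiplicative
plateau scatter (CV 0.05), additive per-cycle baseline noise (SD 2 units),
and Gaussian Ct jitter (SD 0.1 cycles). Defaults were chosen once as
plausible instrument behavior: ~5% endpoint scatter, a baseline floor two
orders of magnitude below plateau, and sub-cycle Ct reproducibility.

## Summaries, calls, thresholds

Rise cycles are measured as fractional cycle numbers: the first
threshold crossing of a 3-cycle moving average, linearly interpolated.
Smoothing suppresses baseline spikes (the rise threshold of 10 units is
~9 baseline SDs after smoothing, so a channel with zero template
essentially never crosses); interpolation preserves the sub-cycle Ct
differences that carry template ratios (a factor of 2 per cycle).

Calling thresholds (`CallThresholds`): NOAMP below magnitude 50; UNDET
between 50 and 300 (weak) regardless of angle; otherwise angle bands
HOM1 < 15°, HET 35–55°, HOM2 > 75°, UNDET between bands. The bands are wide
enough that pure genotypes at default noise are recovered in ≥ 99% of
draws, and narrow enough that dosage `(1,2)` (63.4°) and an equal-parts
cross-sex Y locus fall outside them. Call quality decreases linearly with
angular distance from the band center and with low magnitude; it is
reported for ranking/inspection and makes no decisions.

Allele-fraction estimation inverts the Ct law,
`frac2 = 1/(1 + 2^(Ct2−Ct1))`, falling back to the endpoint ratio when no
crossing is measurable and returning exactly 0 or 1 for single-channel
amplification. Rise-cycle differences are preferred over endpoint ratios
because Ct jitter (0.1 cycles) is a much smaller relative error than
plateau scatter (5%).

## Validation and contamination triage

Pairwise barcode comparison tallies informative loci (both calls
determined), strong mismatches (opposite homozygotes), weak mismatches
(homozygote vs heterozygote) and undetermined loci. Concordant Y dropout
(two female samples) is excluded entirely, as are Y differences between
same-sex samples — hemizygous calls are treated as less reliable than
autosomal ones.

A sample is VALIDATED when the expected reference is the unique
concordance maximum with zero strong mismatches and at most 2 weak ones
(copy-number changes can produce a weak mismatch or two, and the closest
known inter-patient pair differs at 12 SNPs, so these thresholds leave a
wide margin). MISMATCHED names the reference that does fit when the
expected one does not — the mis-labeling scenario. Four or more
undetermined loci trigger the triage (contaminated serial-passage groups
and high-white-square solid-tumor profiles both show ≥ 4): with traces the
sample is resolved by the detector below, without traces it is
INCONCLUSIVE. Ties for best reference are reported as ambiguous, never
silently broken. When traces are available the detector's verdict takes
precedence even over a clean-looking barcode, because small mixtures shift
curves long before they flip categorical calls.

The contamination detector integrates evidence across the whole panel.
A locus with adequate magnitude (≥ 300) counts as mixture evidence when
(a) the reference expects a homozygote and the opposite channel rises
within the cycle budget, (b) the reference expects Y dropout and anything
rises, or (c) the endpoint angle is shifted more than 10° from the
expected genotype's canonical angle. Dispositions: CONTAMINATED at ≥ 3
corroborating loci (single-probe artifacts never condemn a sample);
INEFFICIENT_AMPLIFICATION when weak/undetermined loci exist but every
measurable angle stays canonical — attenuation scales both channels and
so preserves angles, which is exactly how it is distinguished from
admixture; CLEAN otherwise. Assays inside a karyotype region annotated
for the expected reference are exempt from angle-shift evidence, since
copy-number imbalance shifts angles reproducibly without contamination.

The implied second contributor is the registry entry whose genotype
carries the implied minor allele at the largest share of flagged loci,
reported only with ≥ 2 flagged loci, a score ≥ 0.5 and a ≥ 0.1 lead over
the runner-up — identification of the contaminant is genuinely harder than
detection, and the field stays empty rather than guessing. The estimated
fraction is the median over flagged homozygous-expected loci of the
minor-allele fraction mapped through the contributor's allele dosage
(or dosage 2 when the contributor is unknown). Between two named
references, `estimate_mixture_fraction` uses only opposite-homozygote
loci, where the entire minor-allele signal belongs to the contaminant.

Serial-passage drift scores each locus 0 / 0.5 / 1 for HOM1 / HET-or-UNDET
/ HOM2 and flags loci whose score moves monotonically by ≥ 0.5 across
passages; ≥ 3 such loci flag a takeover, and the registry entry most
consistent with the final calls at those loci is reported as the apparent
target.

## Clustering and panel statistics

The barcode distance is `(strong + 0.5·weak) / informative` (1 when
nothing is informative). Undetermined loci carry no distance, so a
heavily-mixed sample separates from its cohort mainly through the weak
mismatches mixtures create at opposite-homozygote loci. Agglomeration
(average or complete linkage) is implemented directly with lowest-index
tie-breaking so the merge order is fully deterministic; scipy's linkage is
used in the test suite as an independent cross-check on tie-free inputs.
The reproduction target for cohort clustering is structural — identical
profiles merge at height zero, discrepant groups separate from the
validated group — not any particular leaf order. Heatmaps use the
conventional color map (HOM1 red, HOM2 blue, HET green, white for
NOAMP/UNDET) and are always accompanied by a round-trippable TSV of the
ordered call matrix.

Random-match probability multiplies per-locus genotype-pair coincidence
probabilities, `p = Π_i Σ_j g_ij²`; the biobank collision risk is the
birthday bound `1 − (1−p)^C(N,2)` evaluated in `log1p` form. Because the
panel's true allele frequencies are unpublished, all discriminatory-power
outputs state their frequency assumptions inline (MAF 0.5 / genotype
frequencies (0.25, 0.5, 0.25) unless overridden). The detection-limit
simulation contaminates one HWE reference with another at each requested
fraction (200 replicates each, plus pure controls) and reports the power
curve, the false-positive rate and the smallest fraction reaching the
power target.

## What the simulator does and does not emulate

It emulates: HWE genotypes at configurable per-locus frequencies,
sex-dependent Y dropout, purified-DNA mixtures of up to three contributors
(template fractions, not cells), arbitrary allele copy dosages for
karyotype abnormalities, and locus-wise amplification inefficiency.
It does not model probe cross-hybridization, passive-reference
normalization, instrument optics, mouse-DNA carry-over, differential
extraction efficiency, or engraftment dynamics. Passing tests therefore
demonstrate the *decision layer's* correctness under a faithful signal
model, not robustness to every instrument artifact; with real exports the
calling thresholds may need site-specific tuning, which is why every
threshold is a plain dataclass field.

Problem sizes used in the shipped tests and the acceptance script —
200 replicates per mixture fraction, 10,000-profile collision checks,
a 75-sample serial-passage rehearsal — were chosen to make binomial noise
small relative to the margins being checked while keeping any single run
in the seconds-to-a-minute range.

## Degenerate inputs and numerical choices

All-zero traces summarize to magnitude 0 with no rise cycles (not an
error). Channels whose plateau cannot reach the rise threshold are
modeled as genuinely sub-threshold. Allele frequencies of exactly 1 are
allowed (degenerate all-HOM1 loci); frequency 0 is expressed as frequency
1 of the other allele. Registry reads/writes are bit-stable on call
categories; trace CSVs round-trip to 6 significant digits. Detection
refuses to run with more than 25% of loci missing traces rather than
deciding on partial evidence. Every stochastic entry point takes an
explicit seed or `numpy.random.Generator`; identical config and seed give
bit-identical output.

## Known limitations

* The contaminant-identification step is best-effort and confidence-gated;
  closely related registry entries can suppress it (by design).
* Three-source chimeras are detected as mixtures, but no full contributor
  deconvolution is attempted beyond the single implied second contributor.
* Match probabilities assume locus independence and no population
  substructure (no θ correction, no kinship).
* The categorical distance ignores undetermined loci, so cohorts dominated
  by UNDET calls cluster less informatively than their traces would allow.
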