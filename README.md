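# pdxauth

SNP-barcode authentication of patient-derived xenografts (PDXs).

PDX models are serially passaged through mice for years and shared between
laboratories, so mis-labeling and cross-contamination accumulate silently
unless every sample is checked. `pdxauth` implements a complete
authentication platform around a 32-assay biallelic SNP barcode of the kind
produced by TaqMan allelic-discrimination genotyping: a reference registry
of one barcode per patient (or earliest xenograft passage), validation of
every new sample against that registry, trace-level detection of
two- and three-source DNA mixtures down to a few percent, triage of
undetermined genotypes into *contamination* versus *inefficient
amplification*, handling of copy-number-driven allelic imbalance and
sex-linked Y-assay dropout, hierarchical clustering and heatmaps of barcode
cohorts, and the panel's discriminatory-power statistics. A synthetic-data
generator reproduces every one of these scenarios, so the whole pipeline is
testable without an instrument.

It is aimed at groups running PDX or cell-line biobanks who want a
scriptable, auditable quality-control layer over their genotyping exports.

## The model in brief

Each assay interrogates one biallelic SNP with two allele-specific
fluorescence channels. Writing `a = (a1, a2)` for the allele template
amounts in copies per diploid genome (heterozygote `(1,1)`, hemizygous male
Y locus `(1,0)`, a mixture the fraction-weighted sum of its contributors'
dosages), each channel follows a logistic amplification curve that crosses
the detection threshold at

```
Ct_i = ct0 − log2(a_i / 2)          (one cycle per template doubling)
```

and plateaus at a level proportional to its template amount, so the
endpoint of the allelic-discrimination trajectory sits at angle
`atan2(a2, a1)`: homozygotes on the axes, heterozygotes on the diagonal,
copy-number imbalance in between. Genotypes are called from angle bands
(HOM1 < 15°, HET 35–55°, HOM2 > 75°) plus magnitude floors; anything else
is undetermined (UNDET) or no-amplification (NOAMP).

A contaminant at fraction *f* of the sample contributes a minor allele
whose channel rises `≈ log2(1/f)` cycles after the major channel — at 1/32
the endpoint still looks homozygous, but the late minor-channel rise is
unmistakable. Contamination is never declared from one probe: the detector
requires corroborating evidence (late minor rise, unexpected amplification,
or an angle shifted > 10° from the expected genotype) at ≥ 3 adequately
amplified loci, and weak-but-canonical curves are dispositioned as
inefficient amplification instead.

Panel-level discriminatory power: with per-locus genotype frequencies
`g = (g_HOM1, g_HET, g_HOM2)`, two unrelated samples match with probability
`p = Π_i Σ_j g_ij²` (0.375³² ≈ 2.3×10⁻¹⁴ at MAF 0.5), and the chance of
*any* identical pair among N biobank samples is the birthday bound
`1 − (1−p)^C(N,2)`.

## Worked example

Contaminate one simulated PDX with 1/32 (3.1%) of another and run the
integrated detector:

```python
import numpy as np
import pdxauth as px

cfg = px.SimulationConfig(seed=42)
rng = np.random.default_rng(42)
host, donor = px.simulate_profiles(cfg, 2, rng=rng)
host.sample_id, donor.sample_id = "ALL-19", "ALL-10"
registry = px.assign_references([host, donor])

spec = px.MixtureSpec((("ALL-19", 31/32), ("ALL-10", 1/32)))
traces = px.simulate_mixture([host, donor], spec, cfg, rng)
report = px.detect_contamination(traces, host, registry, reference_id="ALL-19")
print("disposition:", report.disposition.value)
print("flagged loci:", report.n_flagged)
print("implied contributor:", report.implied_second_contributor)
print(f"estimated fraction: {report.estimated_fraction:.4f}")

g = px.hwe_genotype_freqs(0.5, 32)
p = px.random_match_probability(g)
print(f"random-match probability: {p:.3e}")
print(f"collision risk, 10,000-sample biobank: {100 * px.collision_probability(p, 10_000):.5f}%")
```

prints

```
disposition: CONTAMINATED
flagged loci: 12
implied contributor: ALL-10
estimated fraction: 0.0251
random-match probability: 2.339e-14
collision risk, 10,000-sample biobank: 0.00012%
```

Twelve of the 32 loci are informative for this pair (host homozygous,
contaminant carrying the opposite allele) and every one shows the late
minor rise; the mixture fraction recovered from the rise-cycle offsets
(0.025) is close to the true 0.031; and at the stated frequency assumptions
a 10,000-sample biobank has a ~0.0001% chance of containing two identical
barcodes.

The same operations are available from the shell:

```
pdxauth simulate   --out demo --seed 1 --n-samples 20
pdxauth assign-refs --calls demo/calls.csv --out demo/refs.csv
pdxauth validate   --refs demo/refs.csv --calls batch.csv \
                   --expected expected.csv --out reports/
pdxauth detect     --refs demo/refs.csv --traces traces.csv --expected-ref PDX-01
pdxauth cluster    --calls demo/calls.csv --out heatmap.png
pdxauth stats      --maf 0.5 --n-loci 32
pdxauth fixtures   --out fixtures --seed 7
```

`validate` exits 1 when any sample is flagged and writes the three report
files (`summary.txt`, `contaminated.txt`, `validated.txt`) plus a
machine-readable `verdicts.csv`. File dialects (calls CSV, traces CSV,
reference registry CSV) are documented in `src/pdxauth/io.py` and
`src/pdxauth/panel.py`; spreadsheet users can export to CSV directly.

## Layout

```
src/pdxauth/panel.py        barcode/registry types, sex inference, CSV persistence
src/pdxauth/signal.py       trace summaries, genotype calling, per-locus evidence
src/pdxauth/simulate.py     HWE cohorts, mixtures, CNV, inefficiency, traces
src/pdxauth/authenticate.py verdicts, contamination triage, fraction & drift
src/pdxauth/cluster.py      clustering, heatmaps, match/collision/power statistics
src/pdxauth/io.py, cli.py   file dialects, reports, command-line surface
docs/methods.md             model, parameters, defaults, and their rationale
```
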