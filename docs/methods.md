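# Methods

## Mass arithmetic and ion conventions

Atomic monoisotopic masses are hard-coded CODATA/NIST values at 7 decimals
(H 1.0078250, C 12.0, N 14.0030740, O 15.9949146, S 31.9720707,
Na 22.9897693) for bit-stable tests. Two label constants coexist by design:
the physical ¹³C−¹²C difference 1.0033548 Da is used whenever a formula with
explicitly labeled carbons is converted to a mass, while the per-carbon
spacing 1.003355 Da is used for isotopologue tracing steps and for the
".13Cn" ruleset variants, matching the convention of the reference workflow.
They differ by 2 × 10⁻⁷ Da — far below every matching tolerance used here.

Negative-mode ion m/z values are plain atomic-mass sums with **no
electron-mass correction**. This convention was adopted because it exactly
reproduces the reference Δppm values for deprotonated ion formulas (e.g.
−0.4 ppm for the chicoric acid ion C₂₂H₁₇O₁₂⁻ observed at 473.0718);
adding the electron mass would shift every ion by ~1.2 ppm at m/z 450.
Supported forms: [M−H]⁻ (−1.007825), [M+Ac−H]⁻ (+59.013305), [2M−H]⁻
(2M − 1.007825), all singly charged.

## The conversion ruleset

The packaged table (`silcspp/data/conversions.tsv`) holds 25 base
biotransformations plus 12 labeled variants and the hexose+acetate-adduct
row — 38 rows. Compositions were assigned from the conversion names
(hexose = +C₆H₁₀O₅, coumarate = +C₉H₆O₂, …); matching always uses the
full-precision composition-derived delta, never the printed 4-decimal value,
which is retained only as a test fixture. Four printed values are treated as
printing artifacts (tartarate 132.0060 vs computed 132.0059, shikimate
156.0420 vs 156.0423, quinate 174.0530 vs 174.0528, and the labeled benzoic
acid row printed identical to the unlabeled one); all other rows agree with
their compositions to ≤ 0.0005 Da.

The elution-order flag encodes the reversed-phase polarity convention:
1 = product elutes earlier (polar additions: glycosylations, hydroxylation,
acidic moieties), 2 = product elutes later (methylations, acylations with
hydrophobic moieties).

## Multiplet detection

Within each co-elution group (single-linkage RT chaining, default tolerance
0.1 min — chosen to mimic FWHM-window grouping; the reference parameters are
not published), candidate light features are scanned in ascending m/z. The
lowest-m/z member of a spacing chain anchors the multiplet; heavies are the
nearest unclaimed features at k × 3 × 1.003355 ± 0.005 Da for k = 1..5, ties
broken by smaller absolute error then id, discarded candidates logged. No
heavy/light intensity-ratio constraint is applied by default because label
enrichment is time-varying, unlike natural isotope abundance; optional
bounds exist for noisy data, and a 1-carbon step traces natural-abundance
+1.003355 isotopes of side-chain-shortened benzenoids.

## CSPP matching and the network

Mass differences are computed as m/z(later-eluting) − m/z(earlier-eluting)
and matched at ±0.002 Da against the signed rule deltas, so the elution
order decides the substrate. RT ties are skipped (direction undefined) and
logged. Multiple rules matching one pair emit one edge per rule. The network
is restricted to multiplet members; pairs inside one multiplet (pure label
shifts) are excluded. Edge weights are Pearson correlations across all 36
samples; a constant intensity vector yields a missing weight, with the edge
kept. Adduct artifacts are detected by interpreting each co-eluting feature
under every known adduct form and checking whether another feature matches a
sibling form of the same neutral mass; homodimer ions are marked
`adduct_suspect` and their incident edges flagged but never removed — the
known failure mode being a glucoside homodimer whose m/z difference to an
unrelated molecular ion fortuitously matches a tartarate conjugation.

## Time-course clustering

Profiles are per-time-point means over replicates (missing = 0), z-normalized
with the n−1 denominator. The shape-based distance is
1 − max over all integer lags of the zero-padded cross-correlation normalized
by √(CC₀(x,x)·CC₀(y,y)), bounded in [0, 2] and invariant to positive scaling
and shifts. Linkage is average by default (robust for a non-Euclidean
dissimilarity; the reference work does not state its linkage), selectable by
flag. Exact-tie merge order follows scipy's deterministic internal ordering.

Heavy/light ratio profiles divide mean-heavy by mean-light per time point; a
floor (default half the smallest nonzero intensity in the table) masks time
points where the light feature sits near the detection limit. Ratio
clustering uses the feeding window (default ≤ 24 h); abundance clustering
uses all time points. The native-reference cut places the threshold at the
highest merge height strictly below the first merge that joins a known
fully-native compound with a labeled profile — the largest cut at which no
cluster mixes the two, the root height if they never mix.

## Calibration and inverse prediction

Ordinary least squares of response on concentration, retaining the residual
SD s, Sxx, and x̄. Inverse prediction uses the approximate (Massart-style)
interval: SE(x̂₀) = (s/|b₁|)·√(1/m + 1/n + (x̂₀ − x̄)²/Sxx) with a
t(n−2) quantile — the default of the standard chemometric calibration
tooling. Monte-Carlo simulation (1000 replicate 10-level calibrations) shows
94–96% empirical coverage for the 95% interval. Predictions outside the
calibrated range carry an `extrapolated` flag. Regression is on raw areas
(not log-transformed); weighted regression is unsupported. Content
normalization converts µM → µg/seedling via extract volume and average molar
mass (computed from the neutral formula, e.g. 474.37 g/mol for C₂₂H₁₈O₁₂),
then to µg/g via measured dry weight. The positive-mode quantification EIC
(m/z 497.06905 [M+Na]⁺, 5 ppm) is recorded as configuration metadata only;
peak integration happens upstream.

## The synthetic feeding experiment

The generator emulates: 12 sampling times (0, 0.5, 1, 1.5, 2, 3, 4, 6, 8,
12, 24, 36 h after feeding) × 3 replicates; negative-mode [M−H]⁻/[M+Ac−H]⁻/
[2M−H]⁻ ions; native, ¹³C₃ and ¹³C₆ isotopologues; successive transient
accumulation waves along a 22-compound pathway (a hydroxycinnamic-ester
branch ending in dicaffeoyl tartaric acid and a coniferin-derived lignan
branch); lognormal intensity noise and a detection limit.

*Kinetics.* Labeled moiety-equivalents follow a linear first-order
compartment cascade — medium → precursor → pathway edges → sink — solved
exactly with a matrix exponential. Linearity is a deliberate choice: the
reference study asserts no rate law, and first-order compartments admit
closed-form Bateman solutions that serve as independent oracles. The label
dose sits in the medium at t = 0, so the t = 0 sample is unlabeled and the
precursor's heavy/light ratio peaks at the first post-feeding time point.
Native pools are quasi-steady with a 5% linear drift. Doubly labeled
species of q·m moiety sites are assembled binomially from the per-site
labeled fraction p = x/(x + m·native), which reproduces the delayed
appearance of ¹³C₆ conjugates. Mass balance (pools + medium + sink = dose)
holds to machine precision. Rate constants (0.04–0.25 h⁻¹, uptake 8 h⁻¹)
were chosen once to produce the qualitative wave ordering of the reference
time course — early glucosides and lignans, intermediate tartarate esters,
late accumulation of chicoric acid — and absolute pool sizes
(8 × 10³–2 × 10⁵ intensity units against a detection limit of 50) are
arbitrary but realistic for Orbitrap intensities.

*Noise model.* Multiplicative lognormal on intensities (default CV 20%),
Gaussian on m/z (σ 0.0003 Da), uniform RT jitter (±0.02 min), zeroing below
the detection limit. Ground truth (planted multiplet links and the
SIL-restricted all-pairs CSPP edge set) is derived from the noise-free
table, so recall under noise is a meaningful robustness measure. What the
generator does **not** emulate: chromatographic peak shapes, co-eluting
isobaric interferences beyond the planted adducts, retention-time drift
between samples, heteroscedastic detector saturation, and background
features unrelated to the pathway. Passing tests therefore demonstrate the
pipeline's correctness and noise robustness on well-behaved feature tables,
not peak-picking performance on raw data.

*Wave design.* For clustering validation a separate five-wave design plants
gamma-shaped pulses peaking at 4, 6, 8, 12 and 36 h (six features per wave,
three replicates, CV 20%); SBD clustering cut at k = 5 recovers the planted
membership with mean adjusted Rand ≥ 0.99 over 20 seeds.

## Determinism and problem sizes

Every random quantity derives from a single integer seed through
`numpy.random.default_rng`; pipeline outputs contain no timestamps, and a
rerun with the same seed is byte-identical (verified by SHA-256 in the
manifest). Test and acceptance problem sizes — 57-feature tables, 20 seeds
for recall and clustering, 1000 calibration replicates, 100 random series
for the SBD oracle, brute-force oracles up to 200 features — keep the whole
suite under half a minute while exercising every code path at realistic
scale.

## Known limitations

- The binomial ¹³C₆ model ignores intramolecular correlation of moiety
  sources (a dimer formed from one labeled and one unlabeled monomer pool is
  treated as independent draws).
- The anchor-greedy multiplet assignment resolves overlapping chains
  first-come by ascending m/z; pathological dense groups could be assigned
  differently by a global optimizer.
- `native_reference_cut` assumes the native references were clustered
  together with the labeled profiles and only moves the cut, never reorders
  merges.
- Charge states other than 1 and positive-mode adducts (beyond recorded
  metadata) are unsupported.
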