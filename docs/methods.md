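# Methods

This note records the models, parameter choices and numerical decisions
behind `nucleokit`, and what the synthetic-data tests do and do not show
about real data.

## The DAmFRET measurement model

A DAmFRET experiment expresses a protein fused to a photoconvertible
fluorophore from a construct with strong cell-to-cell copy-number
variation, photoconverts a fraction *p* of molecules to the acceptor form,
and reads three channels per cell: donor, acceptor and FRET.  AmFRET =
FRET/acceptor is a per-cell proximity proxy; acceptor intensity is the
expression proxy.  The synthetic generator
(`synthetic_cytometry.simulate_population`) emulates:

* **Expression**: log-uniform over `[c_min, c_max]`, default 1–10⁴ a.u.
  (four decades, mimicking copy-number variation).
* **Photoconversion**: fixed fraction *p* = 0.1 of molecules in the
  acceptor form.  (Real photoconversion varies slightly cell-to-cell; this
  is not modelled.)
* **Assembly state**: Bernoulli per cell with probability given by the
  archetype — never (`monomer`), a constant fraction A
  (`constitutive_oligomer`), a step at a solubility threshold c*
  (`threshold_polymer`), or the Weibull law
  `F(c) = A·(1 − 2^−(c/EC50)^δ)` (`nucleated_polymer`).
* **AmFRET**: drawn from a low (mean 0, sd 0.03) or high (mean 0.55,
  sd 0.05) component according to the assembly state.  The gap (0.55 ≫
  4×sd) produces the bimodal distribution with almost no intermediate
  cells that signals rapid completion of polymerization after a single
  nucleation event.
* **Channels**: acceptor ∝ p·c, donor ∝ (1−p)·c reduced by donor quench
  proportional to AmFRET, FRET = AmFRET·acceptor plus additive noise.
  Each channel carries 5% lognormal detection noise (typical of a
  high-end analyser) and an additive noise floor of 1 a.u.  These defaults
  give the monomer control an AmFRET sd of ≈0.05 at mid-expression.
* **Seeding in trans**: a condensed template removes the nucleation
  barrier but not the thermodynamic requirement, so seeded cells assemble
  whenever c exceeds a saturation onset, default EC50/10.

The default Weibull shape is δ = 3.  At the per-sample scale of 5×10⁵
events this places the supersaturation signature — assembled and
unassembled cells coexisting over ≥ 1 decade of expression — comfortably
inside the generated data (≈1.8 decades; ≈2.5 at δ = 2).  The overlap
window narrows as δ grows (≈1 decade at δ = 5, ≈0.8 at δ = 6), which is why
the overlap property is asserted at δ ≤ 3 while parameter-recovery checks
run at δ = 6.

## Weibull fitting

The form `F(c) = A·(1 − 2^−(c/EC50)^δ)` is chosen so that `F(EC50) = A/2`:
EC50 is then literally the median concentration at which nucleation has
occurred.  The fit is weighted least squares on the 64-bin
(fraction vs. geometric bin center) profile with weights equal to bin
occupancy, multi-started over a 6×4 grid of log-EC50 × log-δ starts and
solved by Levenberg–Marquardt in (log EC50, log δ, logit A); A is fixed to
1 unless `fit_plateau=True`.  An event-wise binomial maximum-likelihood fit
on the same bins is available behind `method="binomial"`.  Bootstrap CIs
resample events with bins held fixed (equivalently, a multinomial over the
2×64 (bin, outcome) categories), 200 replicates by default, seeded.

Three optional forward-model corrections remove known small biases; all
default off in `fit_weibull` and on in the pipeline's analyze stage:

* **Bin averaging** (`bin_average`): the model value for a bin is the
  Simpson average of F over the bin in log-concentration rather than F at
  the center, removing discretization bias on steep profiles.
* **Measurement kernel** (`log_smear_sd`): binning is by *measured*
  acceptor intensity, so the observed per-bin fraction is F convolved with
  the detection-noise kernel; the model convolves F with a lognormal
  kernel (7-node Gauss–Hermite) of the instrument's log-sd.  Without it a
  δ = 6 profile reads ≈7% shallow at 5% channel CV.
* **Gate floor** (`false_positive_rate`): a quantile-q negative gate
  passes unassembled cells at rate α = 1−q, so the observed fraction is
  α + (1−α)·F.  Without this the low-expression tail reads ≈1% high and
  δ slightly shallow.

Censoring: a profile whose *excess* assembled fraction over the gate floor
is below 1% (with no bin above α+5%) is reported as class `monomer` with
EC50 and δ undefined — never extrapolated.

Robustness choices: bin edges span the 0.1–99.9 percentile acceptor range
so a handful of noise-floor events cannot stretch the geometric binning;
events with acceptor ≤ 0 are flagged and excluded, not zeroed.

## Negative gate

Per-expression-bin AmFRET quantile (default 0.99) from the monomer
control, with bins under 50 control events inheriting the global quantile
(recorded in the gate's provenance).  Calibration is checked by scoring a
held-out monomer sample: exceedance should equal 1−q within binomial
error.

## Profile classification

`discontinuous` requires (a) a bimodal AmFRET histogram in the expression
decade around EC50 — relative dip at the midpoint between the two mode
peaks above 0.5 — and (b) assembled and unassembled cells coexisting over
≥ 1 decade of expression.  Both tests are corrected for the gate floor:
the monomer rule uses the excess fraction, and a bin counts as containing
assembled cells only when its above-gate count exceeds the binomial
background at three sigma (and at least 3 events of each class are
present).  Samples with fewer than 200 events in the diagnostic window are
`indeterminate`.  All thresholds are keyword arguments.

## Nucleation kinetics

The hazard `λ(c, dose) = (k_spont + k_stim·dose)·max(0,(c−c_sat)/c_sat)^γ`
is the minimal form satisfying the phenomenology of a supersaturation
switch: exactly zero at or below the solubility limit at any dose or
horizon, monotone in both concentration and dose, and memoryless
(exponential waiting times), which makes homogeneous populations follow
the closed-form survival `1 − e^{−λt}` used as the test oracle.
Recalcitrance is a zero-hazard subpopulation (default 0 in unit tests,
0.25 in the dose-response driver to mirror the observed ceiling).  The
hazard prefactors are not calibrated to any published percentages — the
spontaneous-onset simulation is checked only for the qualitative
time-monotone trend.  Reporter ON levels are lognormal and independent of
dose, concentration and stimulus duration; only the probability of being
ON varies.

## Imaging

Cells are disks with inner-disk nuclei on a jittered grid (masks disjoint
by construction).  Punctate cells put 80% of their intensity into 3
Gaussian spots (σ = 1.5 px) — a two-level partition with ~1% of area
holding 80% of signal, giving CV ≈ 8 ≫ the 0.8 call threshold — while
diffuse cells sit at CV ≈ 0.1 (shot + read noise), so the CV > 0.8 rule
separates the classes with wide margin.  Filaments (70% of intensity in a
3-px-wide line) also score CV > 0.8, consistent with scoring elongating
polymers as positive.  The 0.8 threshold is a named, overridable constant.
CV uses raw in-mask pixels over the whole cell (background subtraction and
cytoplasm-only variants were considered; whole-cell raw pixels is the
default because the call margin makes the refinement immaterial here).

Segmentation is global Otsu on the log-compressed channel with ≥32-px
component filtering and hole filling — log compression keeps bright
puncta from dominating the threshold, and the cleanup makes noise-free
disks recover exactly (IoU 1.0; ≥0.99 at default noise).  It exists to
exercise the downstream metrics: real micrographs need a real segmenter
(e.g. Cellpose), whose label images can be passed directly to
`field_metrics` / `image-quant`.

CV time courses report the per-frame CV, the peak frame, and the first
post-peak frame at or below baseline + 2×baseline sd (baseline = first
frame(s); sd 0 when a single baseline frame is used).  A trace with no
excursion above baseline (peak ≤ 1.05×baseline + 2 sd) reports no peak.

## Structure comparison

Cα atoms are taken first-altloc, model 0 by default (NMR ensembles: choose
the model explicitly); residues are paired by global alignment (match +1,
mismatch −1, gap −2).  Kabsch superposition is the SVD solution with
reflection correction; RMSD is over all aligned pairs with no trimming by
default.  Because published RMSDs sometimes derive from trimming aligners,
a trim mode re-fits after rejecting pairs deviating beyond
max(2 Å, mean + 2 sd) for up to 5 cycles; drivers report both.  The
polymer protomer is the first chain covering ≥80% of the monomer sequence
unless specified.  Tests cross-check the SVD route against a
rotation-grid + Nelder–Mead brute force and `scipy`'s rotation alignment.

## Pipeline and determinism

Every stage derives its seed deterministically from the global seed via
`numpy.random.SeedSequence`, and identical configs produce byte-identical
outputs; the manifest records stage seeds, parameters and the package
version.  CSV is the canonical event interchange; the FCS 3.0 support is
deliberately minimal (list mode, float32, one TEXT segment) and
round-trips its own files.

## Problem sizes

Default test and acceptance problem sizes are chosen as the smallest that
make the statistical assertions sharp: 5×10⁵ events per sample for
parameter recovery (matching the per-sample event scale of the assay),
2×10⁵-event fixtures for classification, 10⁵ for gate calibration, 10⁴
cells per dose for kinetics, and 24-cell fields for imaging.

## Known limitations

* The generator omits scatter channels, autofluorescence structure,
  spectral spillover and cell-cycle effects; gating on synthetic data is
  therefore expression-window + positivity only.  Passing tests show the
  estimators are correct under the stated noise model, not that gating
  choices on a real cytometer are optimal.
* The measurement-kernel correction takes the channel CV as known (from
  the generator or config); on real data it would need calibration from
  controls.
* EC50 is reported in acceptor a.u.; mapping to molar concentration
  requires instrument calibration outside this package's scope.
* The hazard model treats stimulus dose as scaling a rate prefactor;
  stimulus duration and intensity are not modelled separately.
* Synthetic image fields are far easier to segment than real micrographs;
  the segmentation module is a stand-in that exists to exercise the
  metrics, which accept external label images for real use.
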