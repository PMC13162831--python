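# Methods

This note documents the models, constants and numerical choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the known limitations.

## Fuel properties from a FAME composition

All six mixture properties are linear (or affine) functionals of the
composition. Mass percentages are normalized to sum to exactly 100 before
any computation (the packaged GC-MS table sums to 100.007; the
pre-normalization sum is recorded), and equations stated on a
fraction-of-one basis divide by 100 internally.

**Equations.** With A_i/W_i the mass percent/fraction of ester i, MW_i its
formula weight, D_i its double-bond count and (rho_i, nu_i, CN_i) its
pure-ester constants:

- rho = sum(W_i rho_i), nu = sum(W_i nu_i) (linear mixing)
- SN = sum(K A_i / MW_i), IV = 254 sum(D_i A_i / MW_i)
- HHV = 49.43 - 0.041 SN - 0.015 IV
- CN = 1.068 sum(CN_i W_i) - 6.747

**The SN constant.** The classical saponification summation uses
K = 3 x 56.1 ~ 560 on the mg KOH/g scale; with K = 254 the sum is not on
that scale and comes out a factor ~2.2 low. The default is therefore 560,
with 254 selectable for strict formula fidelity; the constant used is
always echoed in the `constants_record`.

**Reference constants.** `data/fame_reference.csv` carries, per straight-
chain ester, the formula weight, density at 15 degC, kinematic viscosity
at 40 degC and cetane number, each row tagged with provenance:
`measured` (published experimental determinations of pure esters),
`interpolated` (between measured homologs on the chain-length trend), or
`correlation` (filled from published MW/unsaturation regressions — needed
for the short-chain unsaturated esters C7:1, C9:1 and C10:1, for which no
experimental fuel data exist). The file has a schema-version header so the
table can evolve without breaking readers.

**Inclusion policy.** Hydroxy-, branched- and otherwise substituted
esters have no published pure-ester constants. Three policies are
offered: `homolog` (default) maps such a component onto the straight-chain
homolog with the same double-bond count and nearest chain length, keeping
its mass in the mixture and recording the mapping; `exclude` drops it and
renormalizes; `strict` raises. The homolog default reflects that the
substituted esters still contribute mass and roughly homolog-like physics,
and that dropping 7% of the mixture distorts the weighted sums more than
approximating it does.

**Molecular weights** are computed from atomic composition
(C(n+1)H(2n+2-2d)O2 for the methyl ester of a C_n:d acid) when not
supplied, so SN and IV do not depend on the reference table.

**Rounding** is presentation-only (1-2 d.p. in the markdown report); all
internal arithmetic is full double precision.

**Standards.** EN 14214 limits density (860-900 kg/m^3), viscosity
(3.5-5.0 mm^2/s), CN (>= 51) and IV (<= 120); ASTM D6751 limits viscosity
(1.9-6.0 mm^2/s) and CN (here taken as >= 47, the stricter end of the
commonly quoted 45-47 band) and has no density limit. Margins are signed
distances to the nearest limit; the overall verdict is the conjunction
over limited properties.

## Fermentation summaries

Lipid content, lipid yield and consumed sugar are the exact ratios /
difference defined in the README. Optimum detection is a pure argmax over
the tested substrate grid — the screening designs sampled discrete
loadings and no kinetic model is implied — with ties resolved to the
lowest loading and flagged. Ranking is a stable descending sort on the
response mean, so equal means keep input order. Replicate standard
deviations propagate through ratios by the first-order relative-variance
rule and through differences in quadrature; they are reported only, never
used to gate a verdict. Published tables mix rounded cells with unrounded
narrative values; where both exist the unrounded value is the one the
derived ratios reproduce.

## Pigment spectroscopy

**Peak detection** finds local maxima above a prominence threshold
(default 2% of the spectrum's absorbance range) via `scipy.signal.
find_peaks`, then refines each position and height with a 3-point
parabola. Points at or above a user-given instrument ceiling are excluded
from candidates: a clipped plateau (e.g. the 204-210 nm region of a
strongly absorbing extract) has no recoverable apex. With 3-point
refinement the position error is noise-limited: on a grid of step h with
band width sigma ~ 3h, sub-half-step recovery is reliable at
signal-to-noise ratios of order 100 and above; at lower SNR the vertex
estimate's standard deviation (~0.1 h at SNR 100, scaling inversely with
SNR) makes occasional half-step misses expected.

**Stability** is summarized as percent retention 100 I(t)/I(0), which is
scale-invariant by construction, and classified stable/degrading by the
retention at the final common time point (150 min in the study design)
against a threshold (default 90%).

**Antioxidant activity** is 100 (A_sample - A_blank)/(A_control -
A_blank): the ratio-of-differences reading, the only bracketing of the
assay formula that yields bounded percentages with standard-matched
controls. It is invariant under a common shift of all three absorbances
but not under gain changes.

**EC50** interpolates linearly on the untransformed concentration axis
between the first adjacent pair bracketing 50% activity (log-axis
interpolation is available but never default). An exact 50% measurement
returns that concentration; no crossing raises; multiple crossings use
the first and record a warning. Linear bracket interpolation on a coarse
grid carries a discretization bias that shrinks with grid spacing (the
convergence test halves the spacing from 20 to 2.5 ug/mL); on the study's
five printed points it gives 23.24 ug/mL against the reported 23.6, a
discrepancy attributable to the authors' unstated rounding or point pair.

## Chitosan characterization

**Degree of deacetylation** uses the two-point baseline method: within
each band window (defaults centered at 1655 and 3450 cm^-1, half-width
40 cm^-1) a straight baseline joins the window endpoints and the apex of
the baseline-corrected absorbance is read, parabola-refined so band
centers off the sampling grid are not underread. Then
DD = 100 - (A1655/A3450) x 100/1.33, where 1.33 is the published
amide-I/hydroxyl ratio of fully acetylated chitin (a named, overridable
constant). A linear background is removed exactly by the chord; curvature
in the background within a window biases the height reading — windows are
configurable for spectra whose bands sit elsewhere (the study's own bands
at 1630/3451 cm^-1 fall inside the defaults). The 0.2-percentage-point
round-trip contract is an SNR statement: it holds at absorbance noise
~5e-4 AU on a unit hydroxyl band (a typical mid-IR noise floor); at ~2e-3
the max-over-window statistic of the noise biases DD near the ratio-0 end
by several tenths of a point.

**Band matching** is greedy nearest-neighbor within a window (default
60 cm^-1): candidate pairs are consumed in order of increasing |shift|
(ties to the lower wavenumber), each band used once; leftovers are
reported as appearing/disappearing. Greedy-by-smallest-shift makes the
matching antisymmetric under swapping the two spectra.

**EE and LC** are the exact ratios defined in the README; the identity
EE + 100 free/total = 100 is tested, and all three mass ratios are
scale-invariant so mg and g inputs agree.

## Synthetic generators

Each generator draws from a single `numpy.random.default_rng(seed)`
stream, so an identical spec reproduces identical data bit for bit (the
CLI `simulate` command writes fixtures plus a ground-truth JSON sidecar
and is byte-deterministic). Noise is additive Gaussian, clipped at zero
where the physical quantity cannot be negative; t = 0 of decay series is
left noise-free so retention has an exact reference.

Defaults mirror the study conditions: the FAME allocation concentrates
Dirichlet weight on C16-C18 species (the dominant esters of the fungal
oil); spectra span 200-800 nm (UV-Vis) or 500-4000 cm^-1 (FTIR); decay
series sample 0-150 min in 30 min steps; dose-response curves are
logistic with midpoint 23.6 ug/mL on the 10-100 ug/mL assay grid;
fermentation grids use the 25-200 g/L loadings with a bell-shaped
(quadratic-in-log) response peaking at 100 g/L and mass-balance-consistent
sugar columns. The fermentation noise model deliberately never promotes a
non-optimal grid point above the optimum, so generated tables keep their
nominal optimum — recovery tests exercise the argmax plumbing, not
noise-induced optimum migration.

What the generators do **not** emulate: instrument drift or multiplicative
noise, peak asymmetry and band overlap pathologies, matrix effects on
absorptivity, biological replicate structure, or any mechanistic
fermentation kinetics. Passing recovery tests therefore demonstrate
correctness of the estimators under clean additive-noise conditions, not
robustness to every artifact of real instruments.

## Problem sizes and determinism

The test suite runs randomized property suites at 200 cases each
(mixture-equation oracle equivalence at 1e-12 relative, permutation
invariance, normalization idempotence, EC50/peak/decay recovery, EE/LC/
yield identities), all seeded or derandomized, completing in a few
seconds. The study-scale computations are tiny (15 esters, 6-14-row
tables, <= 1751-point spectra), so everything is exact-arithmetic-fast.

## Known limitations

- The study's own pure-ester constants and inclusion choices are
  unpublished, so the reproduced fuel vector is tolerance-bounded, not
  exact: the largest residual is SN (~+6% vs the assay value), consistent
  with straightforward summation over the printed composition.
- The EC50 reproduces the interpolation definition, not the published
  23.6 exactly (see above).
- DD is validated by synthetic round trip only; the study's FTIR
  absorbance values behind its 67.6% are not published.
- Glucosamine content, mineral/proximate composition and the composite
  antioxidant values are stored as assay data (`datasets`) and summarized,
  never modelled.
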