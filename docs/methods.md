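# Methods

This note documents the models, estimators, numerical choices and known
limitations of `gddqc`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Chemical model

A single complex species is assumed throughout:

```
m Cu + n L  ⇌  Cu_mL_n,    K = [Cu_mL_n] / ([Cu]^m [L]^n)
```

with `K` in (mol/L)^(1−m−n). No stepwise intermediates, pH-dependent
speciation, or competing ligands are modelled: this is precisely the model
that the mole-ratio, equilibrium-shift and Van't Hoff analyses presuppose,
and the package's purpose is to implement and stress those analyses, not to
refine the chemistry. The studied GDD markers map onto it as 2:1
ligand:Cu (quercetin, curcumin; `m=1, n=2`), 1:1 (kaempferide), and 1:2
(rhein, chrysophanol, emodin; `m=2, n=1`).

**Equilibrium solve.** With totals fixed, the complex concentration `c` is
the unique root of `K(L_tot−nc)^n (Cu_tot−mc)^m = c` on
`[0, min(L_tot/n, Cu_tot/m)]`. The residual is strictly decreasing on that
bracket, so bracketed Brent iteration converges unconditionally; we run it at
machine tolerance (`rtol ≈ 9e-16`) and verify the mass-action residual
afterwards (`≤ 1e-6` relative, with a 1e-30 mol/L concentration floor in
ratios). Mass balances hold to 1e-10 relative — this is a test invariant.

**Absorbance.** Beer–Lambert with independent extinction coefficients per
species at a single working wavelength; spectra are treated as independent
single-wavelength evaluations. The study reports no extinction
coefficients, so they are free scenario parameters: mole-ratio simulations
use an absorbing ligand whose complex absorbs less (`ε_L=200`,
`ε_c=80 L·mol⁻¹·cm⁻¹` at 5 mM ligand — a falling curve with a kink, as
observed for these compounds), while shift simulations put the signal on the
complex (`ε_L=0`): a nonzero free-ligand extinction would make the A∞
plateau of the linearization nonexistent, since the ligand term grows
without bound as its concentration is raised.

## Estimators

**Mole-ratio breakpoint.** The abscissa is the titrant:fixed mole ratio
(Cu:L, Cu titrated into fixed ligand). Every admissible split of the curve
into two disjoint segments (≥ 2 points each) is fitted by OLS; the best
two-segment model is tested against the single-line null with an F-test
(2 extra parameters, α = 0.01). Noiseless piecewise-linear data (residual
sum of squares at rounding level) are accepted directly; flat or perfectly
linear curves raise a "no breakpoint" error, which is the correct verdict
for K = 0 or a range that never crosses saturation. The breakpoint is the
intersection of the two fitted lines and must fall inside the titrated
range. The ligand:Cu ratio `1/x*` is snapped to the catalogue
{1:2, 1:1, 3:2, 2:1, 5:2, 3:1} when within 15% relative distance — the
small-integer ratios a single-complex model plausibly produces.

**Equilibrium-shift fit.** OLS of `ln[(A₀−Aₑ)/(Aₑ−A∞)]` on `ln C`. Points
whose Aₑ falls outside the open interval between the asymptotes (possible
under measurement scatter) are dropped and counted, never clamped: the log
of a non-positive ratio is undefined, and dropping preserves the
unbiasedness of the linear fit. Orientation (absorbance rising or falling
with ligand) is immaterial because numerator and denominator flip sign
together. The method is exact only for `m = 1`; for two-copper complexes
the recovered K is a conditional constant (the ratio then equals
`2K·Cⁿ·[Cu]_free`, not `K·Cⁿ`), and the pipeline flags this in its report.

**Van't Hoff / Gibbs.** OLS of `ln K` on `1/T`; `ΔH = −slope·R/1000`
(kJ/mol), `ΔS = intercept·R` (J·mol⁻¹·K⁻¹), with R = 8.314 J·mol⁻¹·K⁻¹
fixed. `ΔG = ΔH − T·ΔS/1000` at a configurable reference temperature
(default 298.15 K; the published thermodynamic table is arithmetically
consistent with 298 K, although titrations were incubated at 37 °C, so
298 K is used where those printed values are compared). The published
equilibrium constants are mutually inconsistent with the published ΔG
through `ΔG = −RT ln K` (e.g. −RT·ln(1.616×10⁷) ≈ −41 kJ/mol vs the printed
−6.894); the pipeline computes **both** ΔG routes and reports their
difference as a warning rather than guessing which the authors intended as
primary. Driving-force classification follows the Ross–Subramanian sign
convention (ΔH<0, ΔS<0 → hydrogen bonding / van der Waals; ΔH<0, ΔS>0 →
electrostatic; ΔH>0, ΔS>0 → hydrophobic).

## Fingerprint QC

**Peak matching.** Batches are expressed as relative retention times (RRT)
against the designated anchor (peak 13, identified by id within a table).
Sample-to-reference assignment is a nearest-RRT alignment constrained to
preserve elution order (dynamic program maximizing the number of matches
within the RRT tolerance, then minimizing total RRT discrepancy). A pure
greedy nearest-neighbour assignment was evaluated first and rejected: at
realistic retention jitter it occasionally swaps adjacent late-eluting
peaks — physically impossible, since peaks keep their elution order between
runs — and a swap involving the dominant peak collapses the similarity of an
otherwise consistent batch. The default RRT tolerance is 2% relative, an
order of magnitude above the published per-peak RRT RSDs (0.04–0.57%).

**Common pattern.** Per-peak mean retention time and mean area across
batches (mean, not median, matching how the published averages are
defined); a peak is "common" when present in ≥ 90% of batches —
all-batch presence is implied by the study but brittle to synthetic
dropout. Cross-batch peak correspondence is by id: tables are pre-numbered
by the upstream matching step, as in the pharmacopoeia workflow.

**Similarity.** Cosine (congruence) coefficient on matched common-peak
area vectors, with unmatched reference peaks contributing zero. The matrix
is symmetric with unit diagonal and carries a final row/column "R" against
the common pattern. Whether the pharmacopoeia software uses peak vectors or
full traces is not public; peak vectors are the core measure here, and
trace rendering plus trapezoidal re-integration are provided to close the
loop from simulated chromatograms.

## Quantitation

OLS calibration (`r` = Pearson correlation; linear range = span of the
calibrated concentrations), inverse prediction with an extrapolation flag
rather than rejection, and content mapping through the 0.035 g/ml stock
preparation (µg/ml ÷ 35 = mg/g, configurable). LOD/LOQ use the ICH 3.3σ/S
and 10σ/S conventions; the published LOD:LOQ pairs do not sit at the
3.3:10 ratio (e.g. 0.48 → 1.67), so the study's own noise-estimation
procedure is unknowable and its printed limits are carried as metadata,
not recomputed. RSDs use the n−1 sample standard deviation (validation
panels are n = 6).

## Synthetic data

Generators are deterministic under their seed and keep ground truth for
recovery tests.

* **Titrations** come from the exact solver; noise is additive Gaussian on
  absorbance (default 0 in analyses; 0.002 AU is a realistic instrument
  level when wanted). A₀ and A∞ are treated as separately averaged
  measurements and left noiseless. A∞ is realized at 1000× the
  half-saturation ligand scale rather than true infinity; for 1:1
  complexes this leaves the plateau ~0.1% short of its asymptote, which
  biases shift fits that titrate deep into saturation by up to ~1% — hence
  shift designs keep their grids in the rising region (≈ 1/20× to 3× the
  half-saturation scale) and the excess multiple is a scenario parameter.
  An idealized generator (`generate_ideal_shift_series`) places Aₑ exactly
  on the saturation law the estimator assumes, serving as the
  exact-recovery oracle.
* **K(T) series** are generated exactly from (ΔH, ΔS); refitting them is an
  identity of the linear model, and `ΔG(T) = −RT·ln K(T)/1000` holds to
  rounding for any such series (a test invariant).
* **Fingerprint batches** jitter the 30 published peak means with
  independent mean-one lognormal multipliers on retention time and area.
  Dispersion may be a flat percentage (default 0.3% / 10%) or the published
  per-peak RSD columns (`table_calibrated_scenario`), which reproduce the
  study's observed batch variability peak by peak. Optional traces are sums
  of Gaussians (default width 0.12 min) plus baseline noise.

What the generators deliberately do **not** emulate: full 200–400 nm UV
continua, within-run drift, gradient-elution physics, peak overlap/tailing,
and batch-to-batch correlation structure (real batch areas co-vary through
extraction yield; synthetic areas are independent). Passing tests therefore
demonstrate estimator correctness under the stated model, not robustness to
every real-data pathology. The published batch-content table and the animal
endpoints are not reproducible from summary statistics at all and are
covered only by property-based surrogates.

## Problem sizes and defaults

Mole-ratio grids use 60 points (Cu:L 0.05–3.0, step 0.05; the study's own
design used 8 ratios from 1:10 to 3:1 — the denser grid is used for
breakpoint localization); shift fits use 15 log-spaced ligand totals;
Van't Hoff series use T ∈ {288, 298, 308, 318} K (the study does not list
its temperatures; a symmetric bracket around ambient is conventional);
fingerprint sets use 10 batches × 30 peaks, and the similarity-floor check
runs 100 seeded replicates.
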