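# gddqc

Copper-complexation thermodynamics and HPLC fingerprint quality control for
**Gandou Decoction (GDD)**, the six-herb traditional Chinese medicine formula
used against hepatolenticular degeneration (Wilson's disease). GDD's proposed
decoppering mechanism is chelation: its marker compounds (quercetin,
kaempferide, curcumin, rhein, chrysophanol, emodin) coordinate Cu(II) in
solution. This package implements the computational side of that story for
analytical chemists and herbal-medicine QC labs:

* **Mass-action forward model.** A single complex
  `m Cu + n L ⇌ Cu_mL_n` with constant
  `K = [Cu_mL_n]/([Cu]^m [L]^n)` is solved exactly (bracketed root-finding on
  the unique physical root) and converted to absorbance by Beer–Lambert,
  `A = b·(ε_L[L] + ε_Cu[Cu] + ε_c[Cu_mL_n])`. This is the oracle the
  classical estimators below are tested against.
* **Mole-ratio method.** The turning point of the absorbance vs Cu:ligand
  mole-ratio curve gives the coordination ratio; located by exhaustive
  two-segment linear least squares with an F-test against a single-line null.
* **Equilibrium-shift method.** Under excess ligand,
  `ln[(A₀−Aₑ)/(Aₑ−A∞)] = n·ln C + ln K`; ordinary least squares of the log
  ratio on ln C returns the coordination number *n* (slope) and equilibrium
  constant *K* (exp intercept).
* **Van't Hoff / Gibbs thermodynamics.**
  `ln K = −Δ_rH_m/(RT) + Δ_rS_m/R` fitted over temperature yields ΔH and ΔS;
  `Δ_rG_m = Δ_rH_m − T·Δ_rS_m` and the Ross–Subramanian sign convention
  classify the driving force (all six GDD complexes: exothermic,
  entropy-reducing, spontaneous — hydrogen bonding / van der Waals).
* **Fingerprint QC.** Order-preserving RRT peak matching, common-pattern
  construction over 10 production batches, cosine (congruence) similarity on
  matched peak-area vectors with a 0.98 batch-consistency floor, and RRT/RPA
  tables against reference peak 13.
* **Quantitation.** Linear calibration with inverse prediction, ICH 3.3σ/S
  and 10σ/S detection/quantitation limits, spike recovery and RSD panels for
  the eight quantified markers.
* **Synthetic data.** The raw instrument data behind the study were never
  deposited, so seeded generators emulate them from the published summary
  tables (30 fingerprint peak means and RSDs, complexation parameters,
  calibration equations). Ground truth is retained for recovery testing.

## Worked example

Run the whole simulated pipeline (all three analysis arms) with one seed:

```bash
$ gddqc all --seed 1 --out demo
...
quercetin: ratio 2:1 (L:Cu), K = 1.608e+07, dH = -11.683 kJ/mol, dG(298.15 K) = -6.891 kJ/mol -> demo/complexation_quercetin.json
rhein: ratio 1:2 (L:Cu), K = 113.7, dH = -14.453 kJ/mol, dG(298.15 K) = -11.164 kJ/mol -> demo/complexation_rhein.json
10 batches, 30 common peaks, min pairwise similarity 0.9886 -> demo/fingerprint_report.json
fitted 8 calibration curves (0 failures) -> demo/quantitation_report.json
```

Reading the quercetin line: the mole-ratio breakpoint detector found the kink
at Cu:L ≈ 0.5 and snapped it to a **2:1 ligand:Cu** complex; the
equilibrium-shift fit on the simulated excess-ligand titration recovered
**K ≈ 1.61×10⁷** (generated with 1.616×10⁷ — the ~0.5% shortfall is the
finite realization of the A∞ plateau); Van't Hoff regression on the K(T)
series returned **ΔH = −11.683 kJ/mol**, and the Gibbs relation gives
**ΔG ≈ −6.89 kJ/mol** at 298.15 K: spontaneous, exothermic binding. For
rhein (a 1:2 ligand:Cu complex, two coppers per ligand) the reported K is a
*conditional* constant — the shift linearization assumes one Cu per complex —
and the report carries a warning saying so. The fingerprint arm generated 10
batches at the published dispersion and found every pairwise cosine
similarity ≥ 0.9886, clearing the 0.98 QC floor; `similarity_matrix.csv`
mirrors the usual S1…S10 + R (reference pattern) layout.

Each stage is also available alone (`gddqc complexation --simulate
--compound quercetin`, `gddqc fingerprint --tables S1.csv --tables S2.csv …`,
`gddqc quantitation --calibration-csv cal.csv --samples-csv samples.csv`) or
from Python:

```python
from gddqc import generate_ideal_shift_series, equilibrium_shift_fit
import numpy as np

series = generate_ideal_shift_series(K=1.616e7, n=2, concs=np.geomspace(1e-5, 1e-3, 15))
fit = equilibrium_shift_fit(series)
print(fit.n, fit.K)   # 2.0 16160000.0
```

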