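# groovestate

Analysis toolkit for the **locked / unlocked states of the MHC class I
peptide-binding groove** (HLA-A*02:01 and its disulfide-stabilized,
peptide-free-capable variant dsA2), covering the three measurement layers
such a study rests on:

1. **Crystal-structure geometry and state classification.**  The A pocket
   is gated by the Phe9–His70–Tyr99 triad: in the peptide-bound *locked*
   state the His70 imidazole hydrogen-bonds the Tyr99 hydroxyl
   (d(N···O) ≤ 3.5 Å) and Phe9 sits in its peptide-bound rotamer; in the
   peptide-receptive *unlocked* state the bond is released (> 3.5 Å) and
   the Phe9 ring flips.  The F pocket is gated by Arg97–His114–Tyr116
   (with His74/Asp77 as locking partners on the α1 helix): *unlocked* =
   Tyr116 χ1 in gauche− with an H-bond to His114; *partially unlocked* =
   Tyr116–Arg97 bonded without the His114 bond; *locked* = Tyr116 χ1 trans
   bonded to His74 or Asp77.  The package reads PDB/mmCIF files (gemmi),
   measures distances, χ1 dihedrals, rotamer regimes and B-factor means,
   classifies each asymmetric-unit molecule, and tallies pinned structure
   lists into cohort fractions and distance histograms.

2. **Umbrella-sampling free-energy profiles (WHAM).**  Biased dihedral
   time series — windows at centers ξᵢ with quadratic penalty
   U(ξ) = k·Δ(ξ, ξᵢ)², k in kcal mol⁻¹ deg⁻² (no ½ factor; a switch for
   the other convention exists) — are combined by the self-consistent
   weighted-histogram estimator on a periodic grid into the potential of
   mean force W(ξ) = −k_BT ln p(ξ), with integrated autocorrelation times,
   10-block standard errors and cumulative-PMF convergence checks.
   The reference protocol for the Tyr116 χ1 coordinate is 17 windows from
   −210° to −50° in 10° steps with k = 0.015 kcal mol⁻¹ deg⁻² at 300 K.

3. **nanoDSF melting-temperature extraction.**  F350/F330 ratio curves are
   smoothed with a Savitzky–Golay local polynomial; unfolding transitions
   are prominent maxima of dR/dT, and Tm is the (sub-grid refined) peak
   position — two-event curves (heavy chain, then β2m near 62 °C) and
   dipeptide-concentration series are first-class.

A seeded synthetic layer generates all three input types — toy groove
structures with prescribed geometry, Metropolis samples from an
analytically known periodic double-well potential, and noisy logistic
melting curves — so every stage is testable without downloads.

## Worked example

Reconstruct the free-energy profile of the benchmark double-well landscape
(minima near the gauche− and trans rotamers, barrier ≈ 2.9 kcal/mol)
from the 17-window protocol:

```python
from groovestate import UmbrellaSampling, make_windows
from groovestate.synthetic import default_double_well, sample_protocol

potential = default_double_well()
windows = sample_protocol(potential, make_windows(-210, -50, 10),
                          k=0.015, n_steps=50_000, seed=1, burn_in=1000)
result = UmbrellaSampling(windows).fit()
print(result.summary())
```

```
Umbrella-sampling PMF (WHAM)
==================================
windows:           17
temperature:       300 K
bin width:         2 deg
iterations:        2002
final residual:    9.99e-09 kcal/mol
sampled bins:      96/180
barrier height:    3.401 kcal/mol
autocorr time:     max 5.8 sampling intervals
local minimum:        -61.0 deg  0.000 kcal/mol
local minimum:       -177.0 deg  0.723 kcal/mol
cumulative-PMF max deviation from full sampling:
   40% of samples: 0.1484 kcal/mol
   60% of samples: 0.1077 kcal/mol
   80% of samples: 0.0205 kcal/mol
  100% of samples: 0.0000 kcal/mol
```

The two local minima are the unlocked (gauche−, global minimum) and
locked (trans, ~0.7 kcal/mol higher) states of the reaction coordinate;
`barrier height` is the max-minus-min over all sampled bins, and the
shrinking cumulative deviations show the profile has converged in
sampling time.  `result.profile` carries the per-bin free energies,
block standard errors and counts (`result.to_dataframe()`,
`result.plot()`).

Classify a structure and extract melting temperatures the same way:

```python
from groovestate import read_structure, measure_groove
report = measure_groove(read_structure("entry.cif"))
print(report.states)           # {'1': {'A': locked, 'F': partially_unlocked}, ...}

from groovestate import MeltCurveModel
from groovestate.synthetic import make_melt_curve
curve = make_melt_curve([45.0, 62.0], noise_sigma=0.002, seed=1,
                        label="1 mM GM")
print(MeltCurveModel(curve).fit(max_transitions=2).summary())
```

```
nanoDSF melting-curve analysis
==================================
curve label:    1 mM GM
points:         281 (25.0-95.0 °C)
smoothing:      Savitzky-Golay window 11, order 3
transitions:    2
  Tm 1 (heavy chain):  45.19 °C  (prominence 2.46e-02)
  Tm 2 (beta2m):  62.00 °C  (prominence 2.32e-02)
```

A `groovestate` console script wraps the same functionality
(`inspect`, `measure`, `classify`, `survey`, `wham`, `melt`,
`synth fixture|windows|melt`); see `groovestate --help`.

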