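# Methods

This note documents the models, conventions and numerical choices behind
`groovestate`, and what the synthetic generators do and do not emulate.

## Structure model and residue addressing

Coordinate files (PDB, mmCIF; gemmi parser) are flattened to an explicit
atom table with author residue numbering.  Only the first model of a file
is read — crystal structures have one.  Hetero groups (dipeptides,
cryo-solvent such as EDO/GOL, waters) are retained and addressable by
residue name, since groove-occupancy analysis refers to them.

**Alternate locations.**  Default policy is highest occupancy per atom
name; occupancy ties break by altloc letter (blank first).  A `specific`
policy selects one labelled conformer.  The policy is deterministic so
that repeated runs are bit-identical.  Occupancies are clamped to [0, 1]
and negative B-factors to 0 on ingestion (rare deposition artifacts).

**Heavy-chain identification.**  The MHC class I heavy chain is, in auto
mode, any protein chain with ≥ 250 residues (the mature ectodomain has
~275; β2-microglobulin ~99, so the margin is wide).  Each qualifying
chain is one asymmetric-unit molecule, labelled "1", "2", … in file
order — the literature does not fix a labelling for the two P2₁ copies,
so file order is used and both are always reported.  An explicit config
(`heavy_chains = …`, per-residue numbers) always overrides the heuristic;
groove residues default to HLA-A2 mature-chain numbering (Phe9, His70,
His74, Asp77, Arg97, Tyr99, His114, Tyr116) and mapped residue types are
validated against the expected amino acids.

## Geometry and state classification

* **Distances** are heavy-atom minimum distances over named atom sets:
  Tyr OH; His {ND1, NE2}; Arg {NE, NH1, NH2}; Asp {OD1, OD2} — the
  "closest nitrogen/oxygen partner" rule.
* **Hydrogen bonds** are distance-only calls, cutoff 3.5 Å *inclusive*,
  no angular term: crystal structures carry no hydrogens, and the
  survey's statements are phrased as distance thresholds.  The raw
  distance is always reported next to the boolean so a tally under a
  different threshold can be reproduced.
* **χ1** is the N–CA–CB–γ torsion (γ = CG, or CG1/OG/OG1/SG per residue
  type), IUPAC sign convention, range (−180°, 180°].
* **Rotamer regimes** are fixed ±60° windows about 180° (trans), −60°
  (gauche−) and +60° (gauche+), half-open toward increasing angle, so
  they partition the circle exactly; −125° is trans, −120° is gauche−.
* **Phe9 flip.**  The unlocked, "perpendicular" Phe9 conformation is
  operationalized as |Δχ1| > 60° from a stored locked-reference χ1
  (default −60°, the common Phe rotamer of peptide-bound A2 structures).
  The reference is an explicit, overridable parameter because the flip is
  described qualitatively in the literature, not numerically.
* **B-factor means** are plain arithmetic means over the selection after
  altloc resolution, reported at full precision; comparisons to printed
  integers round at the end.

**State rules.**  A pocket: locked ⇔ His70–Tyr99 ≤ 3.5 Å and Phe9 not
flipped; unlocked ⇔ distance > 3.5 Å and Phe9 flipped; anything mixed is
*indeterminate* — surveys should not force calls on intermediate
structures.  F pocket: unlocked ⇔ Tyr116 gauche− with the His114 bond;
partially unlocked ⇔ Arg97 bond without the His114 bond; locked ⇔ Tyr116
trans with a bond to His74 **or** Asp77 (both appear as locking partners
on the α1 helix; the disjunction covers both readings).  When several
patterns fire the precedence is unlocked > partially unlocked > locked.
Classification is a pure function of the measurement record, hence
invariant under rigid-body motion of the input.

**Surveys** take a pinned list of files (reproducible against a moving
database; an optional helper downloads mmCIF into a cache).  One row per
asymmetric-unit molecule; entry-level calls are per-molecule majorities
with ties indeterminate.  Unreadable or unmappable entries are skipped
with a recorded reason.  The His70–Tyr99 histogram uses left-closed
0.25 Å bins anchored at 0, which resolves the 3.5 Å threshold exactly.

## Umbrella sampling and WHAM

The reaction coordinate is periodic; everything is computed on
(−180°, 180°] with minimum-image differences.  Window centers are labels
and may lie outside the interval (the Tyr116 protocol spans −210° to
−50°, 17 windows, crossing the wrap point).

* **Bias convention.**  U(ξ) = k·Δ², *without* the ½ factor, k in
  kcal mol⁻¹ deg⁻² (protocol value 0.015).  The ½ ambiguity is classic;
  `bias_convention="half"` switches it.
* **Constants.**  k_B = 0.0019872041 kcal mol⁻¹ K⁻¹, default T = 300 K,
  default bin width 2° (180 bins; fine enough for ~4.5° window widths).
* **Solver.**  Standard self-consistent WHAM on binned counts: window
  free-energy constants start at 0 and iterate until the maximum change
  per sweep < 10⁻⁸ kcal/mol (cap 10⁵ iterations; non-convergence raises,
  carrying the last residual).  Far-window Boltzmann factors underflow
  harmlessly to zero.  Bins with zero counts carry NaN free energy and
  are flagged, never interpolated; the profile minimum over sampled bins
  is normalized to 0.  Adjacent windows sharing no occupied bins trigger
  a warning (their relative offset is unconstrained).
* **Autocorrelation.**  τ = 1 + 2Σρ_k, FFT-based, truncated at the first
  negative ρ_k, reported in the series' sampling-interval units.  This
  truncation is adequate for the benchmark's short correlation times;
  for strongly bimodal windows it can underestimate slow modes — the
  block errors below are the robust uncertainty statement.
* **Block errors.**  Each window's series is split into 10 contiguous
  equal blocks (intervals in sampling order, mirroring time intervals);
  a full WHAM solve per block, each block profile min-normalized, then
  per-bin stderr = std/√10.  **Caveat:** min-normalization anchors each
  block at its own minimum, so with (near-)degenerate wells the anchor
  can flip between wells block-to-block and inject a sample-size
  independent common offset into the stderr.  The benchmark potential is
  therefore deliberately non-degenerate (below), and error/convergence
  statements are made over *well-sampled bins* — bins occupied by at
  least two windows (`well_sampled_mask`); single-window edge bins have
  poorly constrained offsets.
* **Convergence.**  Cumulative profiles on growing sample prefixes
  (default 40/60/80/100%); the max deviation from the full-data profile
  over well-sampled bins should shrink toward 0.
* **Conditional distributions.**  Secondary-dihedral histograms
  conditioned on the primary coordinate's rotamer regime (e.g. a
  neighboring side chain given Tyr116 trans vs gauche−); empty regimes
  are flagged, not errors.

## Melting curves

Transitions are maxima of the smoothed first derivative of the F350/F330
ratio.  Smoothing is Savitzky–Golay (default window 11 points, order 3 —
the standard for derivative melting analysis; the instrument vendor's
exact filter is proprietary, so only midpoint recovery, not curve shape,
is a meaningful target).  The temperature grid is assumed uniform; edges
are truncated by half a window.  Default peak threshold is 5× the median
absolute derivative of the first 10 points (a baseline-noise proxy that
makes calls invariant under rescaling the ratio); peak positions are
refined by a least-squares parabola over ±5 points.  For curves whose
event count is known (the two-event heavy-chain/β2m layout),
`max_transitions=2` keeps the two most prominent peaks — with
noise-tracking thresholds, pure-noise wiggles can otherwise exceed the
default prominence.  Transitions are reported ascending in temperature:
index 0 is the heavy chain, index 1 the β2m event.

## Synthetic generators

All generators are deterministic under a fixed seed and record the seed
in their output metadata.

**Fixture structures** build the eight groove residues from ideal
internal coordinates (standard bond lengths/angles, NeRF chain
extension); only χ torsions and rigid placement vary, which is exactly
what classification depends on.  Named contacts (His70→Tyr99 OH, the
four Tyr116 partners) are placed along distinct directions at prescribed
distances (2.9 Å bonded / 6.0 Å unbonded by default), exact to 10⁻³ Å
before optional Gaussian coordinate noise.  Specs that request states
inconsistent with their geometry are rejected at construction.  Optional
extras: Gly padding to a target chain length (for the heavy-chain
heuristic), a Gly light chain, Tyr116 altloc pairs, and dipeptide-like
hetero ligands with prescribed mean B placed near either pocket.  These
fixtures are *synthetic stand-ins*: they reproduce prescribed groove
geometry and nothing else about any deposited structure — no packing,
no full fold, no real ligand chemistry.  Tests passing on them validate
the measurement/classification logic, not the crystallography.

**Benchmark potential.**  V(ξ) = Σ A_j(1 − cos(j(ξ − φ_j))) with terms
(j=3, A=1.45, φ=180°) and (j=1, A=0.8, φ=−90°): minima near −60°
(gauche−, global) and 180° (trans, ~0.7 kcal/mol higher), barrier
~2.9 kcal/mol through −120° — the same qualitative landscape as the
Tyr116 χ1 coordinate in the empty groove (gauche− slightly more stable,
barrier in the 2.5–3 kcal/mol range), chosen as an echo, not a
reproduction.  The wells are deliberately non-degenerate; an earlier
exactly-degenerate variant made block-error anchoring unstable (see the
WHAM caveat above).  The 1-D analytic reference PMF is V − min V with
the minimum refined to machine precision, so reference values are
grid-independent.

**Umbrella sampler.**  Metropolis on V + bias at 300 K, uniform ±10°
proposals, started at the window center, burn-in discarded, every
post-move state recorded, acceptance rate reported.  It emulates the
well-understood statistics of a biased 1-D coordinate — not molecular
dynamics: no inertia, no coupling to other degrees of freedom, no
force-field realism.  Benchmark sampling uses 50,000 recorded steps per
window (17 windows), which runs in seconds and determines the PMF to
well under 0.1 kcal/mol over well-sampled bins.

**Melting curves.**  Sum of logistic sigmoids (default amplitude 0.1 —
a realistic F350/F330 step per transition — width 1.2 °C) on a linear
baseline, homoscedastic Gaussian noise (default σ = 0.002), grid
25–95 °C in 0.25 °C steps.  The concentration-series helper raises the
heavy-chain midpoint logarithmically with dipeptide concentration
(default +2.5 °C per decade from 46 °C) with β2m fixed at 62 °C,
emulating groove stabilization by bound dipeptide.  Real nanoDSF data
additionally show drifting baselines, heteroscedastic noise and
scan-rate effects that these curves do not model.

## Known limitations

* Cohort-scale statements (e.g. bonded fractions across hundreds of
  deposited structures) depend on a user-supplied pinned entry list; the
  package does not curate database cohorts.
* H-bond calls are geometric only; no donor/acceptor chemistry or
  angular screening.
* WHAM is one-dimensional; multidimensional reaction coordinates and
  MBAR-style binless estimators are out of scope.
* Thermodynamic two-state fits of melting curves (ΔH, ΔG) are not
  attempted; only Tm extraction.
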