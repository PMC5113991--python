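# Methods

## Electrophysiological model

The pipeline treats the epithelium as a two-ion constant-field barrier. Only
Na⁺ and Cl⁻ enter the potential and conductance equations: the other bath
ions (K⁺, Mg²⁺, Ca²⁺, the HEPES anion) are identical on both sides in every
protocol, contribute no diffusion potential, and their conductance
contribution is absorbed into the measured G. Molar concentrations are used
directly (no activity coefficients); ion totals are derived from the full
solution composition, counting Na⁺ from NaCl and the NaOH titrating HEPES,
and Cl⁻ from NaCl, KCl and twice the divalent chlorides. For the standard
buffer this gives 150 mM Na⁺ / 149 mM Cl⁻, an electrically symmetric
background, so β = 1 still nulls the potential under any NaCl gradient.

**Forward potential.** V = (RT/F)·ln[(β·Na_b + Cl_a)/(β·Na_a + Cl_b)],
apical minus basal; with the apical side diluted, a cation-selective barrier
(β > 1) gives a positive potential. The measured convention of a given rig is
unknowable from the data, so `analyze --flip-sign` negates potentials on
ingest; β is invariant to a consistently applied convention.

**Inversion.** With x = exp(VF/RT), β = (Cl_a − x·Cl_b)/(x·Na_a − Na_b),
exact to floating point. V must lie strictly inside the open interval bounded
by the Cl⁻-only and Na⁺-only Nernst potentials; values at or outside it raise
`NernstRangeError` naming the interval. Forward/inverse round trips hold to
1e−9 relative over β ∈ [0.05, 100] and all 70/140/210 mM NaCl pairings
(tested, including against an independent zero-current root-finding oracle of
the GHK current equations).

**Conductance split.** G = 1/TER is decomposed as
G = (F²/RT)(P_Na·C̄_Na + P_Cl·C̄_Cl) with P_Cl = P_Na/β. Under a standing
gradient the per-ion concentration term C̄ is ambiguous; the default is the
logarithmic mean of the apical and basal concentrations, the form consistent
with constant-field flux, with arithmetic-mean and basal-only variants
selectable (`kk_variant`). For a two-fold gradient the choice moves P by a
few percent at most, which is why it is explicit rather than hidden.
Temperature defaults to 310.15 K; raw ohm readings can be area-normalized
with the 1.12 cm² growth area of a 12-mm insert.

**Blank correction.** The cell-free filter's resistance and potential (the
latter standing in for electrode/liquid-junction offsets, optionally
drifting) are subtracted at each time point, pairing sample to blank times
within ±0.5 min; unpairable times are an error listing the orphans, and
corrected records with TER ≤ 0 are flagged and carried through as missing
values rather than dropped.

## Protocols and summaries

Nine bath presets cover the condition matrix (apical/basal NaCl halved or
increased by half, with or without 130 mM sucrose or mannitol back-fill) plus
the reversibility protocol, which removes the osmotic gradient at 120 min by
adding sucrose apically without changing NaCl — so the inversion's bath
bookkeeping is continuous across the switch. Nominal osmolarities use ideal
dissociation counts (NaCl → 2, MgCl₂ → 3, sugars → 1, …); 130 mM sucrose
back-fills 140 mM osmotic units of NaCl, leaving the "isosmotic" conditions
10 mOsm/L short of exact, and a ±50 mOsm/L band classifies presets as
isosmotic versus gradient-bearing. Time-course summaries: the 115-min delta
(value at 5 min minus value at 120 min, anchors matched within ±2.5 min — the
measurement grid of such experiments is instrument-dependent, so the
tolerance is a parameter), the recovery triple β(5)/β(switch)/β(switch+5),
and a single-exponential relaxation fit used only to recover the simulator's
latent endpoints.

## Synthetic monolayers

The simulator is deliberately phenomenological: β(t) and G(t) relax
exponentially toward a condition-dependent target within each bath epoch —
toward the low-selectivity plateau with time constant τ (default 30 min,
putting the relaxation ~98% complete at 120 min) under a relative apical
hyposmotic gradient, and toward their resting targets with τ_rec (default
1 min, so recovery is complete within the 5-min read) otherwise. No dynamic
model is being fit to data; the exponential is the minimal monotone shape
consistent with a gradual decline and a prompt recovery, and the preset
parameters are illustrative. The `wt_reversibility` preset is anchored so
the noise-free pipeline reproduces the characteristic selectivity triple
22.41/3.40/16.55 and P_Na triple 46.20/33.46/27.13 ×10⁻⁶ cm/s at
5/120/125 min; `wt_hypo` relaxes β from 9 to 3; `ko` is a tight,
gradient-insensitive monolayer (β ≈ 1.1, conductance an order of magnitude
below wild type). Conductances put TER near 50 Ω·cm², the leaky-epithelium
range.

Noise is Gaussian on each reading (defaults σ_V = 0.2 mV, σ_R = 1 Ω·cm²,
chosen so simulated replicate SEMs sit at the scale typical of volt-ohm-meter
series, e.g. ~0.1 on β ≈ 3 with n = 4); the blank filter carries a series
resistance and a potential offset with optional linear drift. All randomness
flows through one explicitly passed `numpy` generator; a fixed seed
reproduces runs bit for bit. True instrument noise magnitudes are not
published for this class of experiment — the defaults are calibration
choices, and recovery tests state their noise level explicitly.

What the simulator does *not* emulate: electrode polarization transients,
temperature drift, paracellular/transcellular pathway separation, or any
mechanism linking osmotic water flux to the selectivity change. Passing
recovery tests therefore demonstrate that the inversion pipeline is correct
and unbiased at realistic noise, not that the biological model is right.

## Morphometry

The zigzag index is the ratio of sums Σ arc length / Σ chord length over
contact sides — not the mean of per-edge ratios; long sides weigh more, and
the pooled value always lies between the per-edge extremes and is invariant
under rigid motions and uniform scaling. Sampling follows the five-window
protocol: 815 µm² axis-aligned squares placed uniformly at random (seeded); a
side belongs to a window iff both its junction vertices fall inside (whole
sides, no clipping — one defensible reading of "contained in an area"), all
windows pool into one per-sample index, and fewer than 80 pooled sides emits
a protocol warning rather than an error.

Synthetic meshes are seeded Voronoi tessellations whose straight edges are
replaced by symmetric sawtooth polylines. The half-period count is rounded
per edge and the amplitude co-scaled so every segment has lateral slope
exactly 2a/p, making the network index identically √(1 + (2a/p)²) — an exact
ground truth rather than an asymptotic one.

Label masks are traced on the inter-pixel crack lattice: corners where ≥3
labels meet (or boundary dead ends) become junction vertices and crack chains
between them become edges, excluding background contacts. Raw crack paths
measure oblique boundaries in the city-block metric and would inflate arc
lengths by up to √2, so chains are Douglas–Peucker simplified at a 1-pixel
tolerance by default (`simplify_px`, 0 disables); at pixel sizes well below
the jag amplitude this recovers analytic sawtooth indices to well under 5%.
No sub-pixel spline or Gaussian smoothing is applied.

## Statistics

Replicates summarize as mean ± SEM (sample SD, n−1). Group comparisons use
the two-sided pooled-variance Student's t-test at α = 0.05 (Welch via flag;
comparisons are treated as unpaired since conditions are separate filters).
The degenerate zero-variance/equal-means case returns p = 1 by convention.
No multiple-testing correction is applied.

## Verification problem sizes

The test suite and acceptance script size their simulations to keep the full
run in tens of seconds while leaving comfortable statistical margins: the
selectivity/permeability round trips are exact single-reading computations;
forward–inverse grids use 41 β values × 6 bath pairings; parameter-recovery
Monte Carlo uses a 5–120 min grid at 5-min spacing, σ_V = 0.2 mV, 4
replicates × 20 repeats (mean endpoint estimates land within ~1% of truth,
against a 5% bound); the SEM-scaling check uses 40 repeats per group size
n ∈ {2, 4, 8, 16}; the type-I-error check runs 1000 two-group comparisons;
zigzag checks use ~600-cell meshes yielding well over 80 pooled sides.
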