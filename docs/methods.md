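# Methods

## Model and assumptions

`sxm` models the aerobic oxidative degradation of individual organic
compounds identified only by elemental composition (CHNOPS + net charge).
The core assumptions:

* **Complete oxidation with O₂ as the sole terminal acceptor.** The donor
  half reaction oxidizes all carbon to HCO₃⁻ and releases heteroatoms as
  NH₄⁺, HPO₄²⁻ and HS⁻; the acceptor couple is O₂ + 4H⁺ + 4e⁻ → 2H₂O.
  Alternative acceptors (NO₃⁻, SO₄²⁻, Fe(III)), fermentation and
  disproportionation are out of scope.
* **Fixed species basis.** All reactions are vectors over an ordered
  10-species basis (OC, H₂O, HCO₃⁻, NH₄⁺, HPO₄²⁻, HS⁻, H⁺, e⁻, O₂,
  biomass); every constructor guarantees element and charge balance to
  < 1e−9 (in practice machine precision, since coefficients are closed
  forms in integer element counts).
* **Average biomass CH₁.₈N₀.₂O₀.₅** (stored as exact rationals, 4.2
  electron equivalents per C-mol, formation energy −67 kJ/C-mol).
* **Thermodynamics at 25 °C, 1 bar**, with two standard states: pH 0
  (unit activities) and the biological standard pH 7
  (a<sub>H⁺</sub> = 10⁻⁷, correction R·T·y<sub>H⁺</sub>·ln 10⁻⁷ ≈ −39.96
  kJ per mol of protons produced). No enthalpy-based temperature
  correction, no activity-coefficient model; arbitrary activities can be
  supplied explicitly through the reaction quotient (the electron is never
  part of the quotient).
* **Formation energy by inversion.** A compound's ΔG⁰_f is back-calculated
  so the donor half reaction's standard energy reproduces
  a·(60.3 − 28.5·NOSC). Group-contribution estimation is impossible
  without structures; this inversion is exact by construction, which is
  verified as a round-trip property.

### Energy coupling (λ)

λ follows the thermodynamic electron equivalents model: the catabolic
energy, discounted by a transfer efficiency η = 0.43 (applied with
exponent m = +1 when the carbon-source→building-block step releases
energy, −1 when it costs energy), must cover the building-block energy
ΔG_block (identified with ΔG_ana, since building block and biomass share
one composition) plus a fixed synthesis cost ΔG_syn = 200 kJ/C-mol.
Dissipation energy then closes the balance: ΔG_dis = λ·(−ΔG_cat) − ΔG_ana.
Both identities are enforced simultaneously as invariants. At
ΔG_block = 0 we take m = +1; the term vanishes either way, so this only
removes an undefined branch.

By default λ (and hence the metabolic vector and all kinetics) uses the
pH 7 energies; `ThermoConfig(lambda_ph=0)` switches the whole chain to
pH 0. Both energy sets are always reported.

### Anabolic electron closure

Balancing the electrons between the carbon source (n_e/a per C-mol) and
biomass (4.2 per C-mol) admits two conventions. The default scales the
carbon-source donor half reaction (consuming x = 4.2/(n_e/a) C-mol of
substrate carbon per C-mol biomass, releasing x − 1 as HCO₃⁻ — negative,
i.e. CO₂-fixing, for very reduced substrates), which keeps anabolism free
of O₂ and reduces to the classic heterotrophic construction. The
alternative (`closure="acceptor"`) feeds exactly 1 C-mol of substrate
carbon and closes electrons with the O₂ couple. The choice is isolated in
`anabolic_reaction`; everything downstream is agnostic to it.

### Degenerate inputs

Compounds are flagged, never fatal, so a batch of thousands of rows
always completes: `not_oxidizable` (n_e ≤ 0), `nosc_out_of_range`
(outside [−4, 4]; warning only), `endergonic_catabolism` (ΔG_cat ≥ 0 at
the selected pH; λ = NaN), `nonpositive_lambda` (retained, not clamped,
to avoid biasing distributions). Kinetics, simulation and aggregation
refuse or exclude flagged compounds; exclusion counts are reported.

## Kinetics

The growth law μ = μ^max·exp(−|y_OC|/(V_h[OC]))·exp(−|y_O₂|/(V_h[O₂]))
carries the metabolic coefficient **divided by** the harvest product
V_h·[S]: a smaller product (stronger limitation) must slow growth, which
is the only reading consistent with treating V_h[S] = 1 as moderate and
0.2 as severe limitation. This interpretation is deliberately confined to
one function (`growth_rate`). Scenario analysis parameterizes the
dimensionless products directly; only the product matters, so no unit
convention for [S] is imposed. μ^max defaults to 1 for comparative
analyses, where it cancels from every correlation and ratio.

Chemical rates are coefficient × μ; r_C multiplies the compound rate by
its carbon count. The simplified cybernetic weights
u_i = μ_i^kin/Σ_j μ_j^kin regulate competing pathways; an all-zero rate
vector yields all-zero weights (no activity to allocate). The full enzyme
synthesis/degradation balance is intentionally not integrated — the
weights are recomputed algebraically from the instantaneous state.

## Batch dynamics

`simulate_batch` integrates the mass balances with SciPy's LSODA
(rtol 1e−8, atol 1e−12) on a fixed output grid for reproducible reports.
Three modes share one right-hand side: `sxm` (one biomass pool, all
pathways unregulated; per-compound growth contributions sum into the
pool), `sxm_exm` (cybernetic weights applied at every evaluation),
`sxm_mxm` (guilds differing only in μ^max_j, one biomass pool each,
shared V_h and stoichiometry — so one guild reproduces `sxm` exactly).
Exponential kinetics vanish smoothly as a substrate approaches zero, so
no event handling is needed; rate factors are cut to exactly zero below
1e−300 to avoid overflow in the division. Total carbon
(Σ aᵢ[OCᵢ] + [HCO₃⁻] + Σ[Bⱼ]) is conserved identically by the
stoichiometry and drifts only at solver precision (< 1e−6 relative is
asserted; observed ~1e−15).

The compound-count scaling experiment evaluates aggregate specific
respiration at a fixed state (default V_h[OC] = V_h[O₂] = 1) for seeded
subsets of a pool — no ODE integration — because the contrast of interest
(linear growth without regulation vs near-constancy with it) is a
property of the rate structure, not of a particular trajectory.

## Cohort analyses

Samples are treated as presence/absence compound sets: FTICR intensities
carry no concentration information, so aggregation defaults to the
unweighted mean (median available) over detected, unflagged compounds; an
intensity-weighted mean sits behind an optional argument for data with
trustworthy abundances.
Donor and catabolic energies can be aggregated per mol or per C-mol
(divided by each compound's own carbon count); λ is defined per C-mol of
biomass and needs no rescaling. Pearson correlation with a per-sample
respiration proxy is reported with sample counts and no p-value
gatekeeping; zero-variance inputs produce a missing value with a warning.
Two-sample ("zone") comparison reports distribution summaries and
high/low activity rate ratios per limitation scenario and level; the
empirical ordering of those ratios is data-dependent and therefore
reported, not asserted.

## Synthetic data

The generator emulates the *structure* of assigned-formula reports —
CHNOPS compositions on C5–C40 backbones with H/C ∈ [0.3, 2.2],
O/C ∈ [0, 1.2], rare heteroatoms (N ≤ 3, S ≤ 2, P ≤ 1 with the common
≥ 4-oxygen assignment rule for P) — and nothing about instrument physics:
no intensities, noise, isotopologues or calibration drift. Passing tests
therefore demonstrate correctness of the computational chain on realistic
composition space, not robustness to instrument artifacts.

NOSC targeting draws each compound's desired NOSC from a normal
distribution around the target (recentred so the draws average to the
target exactly) and solves for the oxygen count given a feasible hydrogen
count, achieving the requested location to well within ±0.15.

Synthetic cohorts give each of 30 samples its own NOSC target (uniform on
[−0.8, 0.6]), producing mean-λ variation of sd ≈ 0.0045 across samples;
the respiration proxy is α − link_strength·mean(λ) + N(0, noise_sd) with
defaults link_strength = 1 and noise_sd = 0.004, i.e. noise comparable to
the signal ("moderate"), yielding recovered correlations around −0.7.
True generating parameters are returned in a provenance record. Note the
λ–carbon-count coupling: λ scales roughly inversely with a compound's
carbon number (catabolic energy is per mol, synthesis cost per C-mol), so
within-sample λ spread is dominated by size, and the NOSC shift moves the
mean λ by less than it moves per-C-mol energies.

## Problem sizes

The test suite and examples use 1,000-compound pools for balance and
consistency sweeps, 500-compound pools with subset sizes 10–100 for the
scaling experiment, and 20 seeded cohorts of 30 samples × 120 compounds
for sign recovery — sizes chosen so the complete suite runs in well under
a minute of compute while keeping Monte-Carlo margins wide.

## Known limitations

* Only aerobic respiration; no alternative electron acceptors or
  fermentative pathways.
* The NOSC–energy relation is an empirical linear correlation; errors in
  it propagate directly into every downstream energy.
* No ionic strength, temperature or pressure corrections.
* FTICR intensities are not quantitative, so aggregation defaults to
  presence/absence; the optional intensity-weighted mean should be used
  only with externally calibrated abundances.
* Charged compounds are handled by a consistent net-charge convention in
  the electron count, but assigned-formula reports typically contain
  neutral formulae only; the convention is a generalization.
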