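# Methods

## Model structure and assumptions

The model is a deterministic, well-mixed two-compartment ODE system: a
plasma compartment where drugs are administered and cleared, and a tumor
compartment holding cancer cells, tumor-associated macrophages (TAMs), and
CD8+ T cells. Nineteen state variables track nanoparticle (NP) mass in
plasma and tumor interstitium plus a cumulative sink ledger, intracellular
anti-miR-155 in cancer cells and TAMs (mg/mL), miR-155, PD-L1 and PD-1
(pM), cisplatin and two antibodies in plasma and tumor, tumor volume (cm³),
and the two immune-cell pools. Units throughout: days, mg, mL (≡ cm³ for
tumor), pM.

Key constitutive choices:

* **Tumor growth** is logistic, dV/dt = γ_eff·V·(1 − V/K), with
  γ_eff = γ·(1 + (A_M,L − 1)·M/(k_M + M)). The saturating Michaelis form
  lets miR-155 stimulate proliferation without unbounded rates and produces
  a stable pre-treatment equilibrium of the molecular subsystem.
* **miR-155 balance.** Cancer cells produce miR-155 at g⁰_M,c and receive
  exosomal transfer from TAMs at k_exo·M_TAM (transfer is one-way,
  TAM→cancer). Anti-miR-155 multiplies the degradation rate δ_M by
  1 + (A_AM,M − 1)·AM/(EC50_AM + AM) — catalytic enhancement, not
  stoichiometric sequestration. With the default production/turnover rates
  both pools equilibrate at exactly 1.5 pM untreated and fall to
  ~0.01–0.07 pM under saturating drug.
* **Chemoresistance** acts on potency, not efficacy: the cisplatin kill term
  is δ_chemo·C/(EC50_cis·(1 + A_MR·M/(k_M + M)) + C)·V, so depleting miR-155
  lowers the effective EC50 ~3.7-fold without changing the maximal kill
  rate.
* **Checkpoint inhibition.** PD-1:PD-L1 occupancy is computed at binding
  quasi-equilibrium: f_PD = L_eff/(L_eff + Kd_PDL1) with
  L_eff = L/((1 + C_ate/Kd_ate)(1 + C_pem/Kd_pem)). This avoids stiff
  binding kinetics while giving the correct competitive limits (each
  antibody alone can fully de-repress killing at saturating concentration).
  Immune kill is δ_immun·(ρ₈/(ρ₈ + K_ρ8))·(1 − f_PD)·V where ρ₈ is the
  CD8+ density; the density form keeps δ_immun in 1/day and produces immune
  escape in large tumors through saturating T-cell recruitment.
* **NP transport** is permeation-limited and bidirectional:
  J = P_NP·S(V)·V·(C_pl − C_int) with S(V) = S₀(V/V_ref)^(−1/3).
  Interstitial NPs reach cells through a diffusion step over the
  intercapillary length (rate D_NP/Len²) in series with uptake k_up. NP
  size enters through a Stokes–Einstein-like factor (100 nm/Φ_NP) on both
  P_NP and D_NP; by default Φ_NP = 100 nm so the factor is 1 and Φ_NP
  matters only in sensitivity analyses. A consequence of the bidirectional
  flux worth knowing: the interstitium near-equilibrates with plasma, so
  per-cycle intracellular drug peaks are nearly flat while interstitial
  *concentration* peaks (exposure per unit tumor) decline as the tumor
  grows.
* **Dosing** is bolus-only: dose·BW mg added instantaneously to the drug's
  plasma state, with the stiff integrator restarted at each dose time.

## Parameters

Two complete baselines ship with the package (`mouse_defaults()`,
`human_defaults()`); every symbol carries units and an allometric class
(rate −0.25, clearance 0.75, volume 1, dose −0.25, or none) and the pair is
round-trippable through a YAML table. The defaults are themselves a
calibration product, fixed once by 1-D root solves and then frozen:

* **Mouse** values are set so that a xenograft grows ~10× in four weeks from
  100 mm³, pre-treatment miR-155 sits at 1.5 pM and PD-1 at 1 pM, tumor
  interstitial NP delivery peaks near 3% of injected dose, and the five
  treatment arms of the synthetic preclinical design land near 62%
  (anti-miR-155, 0.2 mg/kg twice weekly), 49% (cisplatin 8 mg/kg weekly),
  16% (atezolizumab 10 mg/kg), 22% (pembrolizumab 5 mg/kg) and 96%
  (anti-miR + cisplatin) tumor growth inhibition. The combination arm is
  deliberately left where near-additive kill rates put it: with both
  monotherapies pinned on a shared four-week control, any
  reference-form parameterization makes the combination TGI ≥ ~95%.
* **Human** values start from the allometric conversion of the rate-class
  symbols and then recalibrate the pharmacodynamic couplings (γ, A_M,L,
  δ_immun, δ_chemo, Kd_ate) and EC50_AM against clinical
  time-to-progression anchors for an average 70 kg patient with a 1.5 cm
  tumor: control TTP ≈ 1.4 months, anti-miR-155 2.5 mg/kg Q3W ≈ 6.5 months,
  pembrolizumab ≈ 7.4, atezolizumab ≈ 6.9, cisplatin ≈ 2.8 months, and a
  dose–response EC50 of 0.033 mg/kg on the Q3W schedule. Mechanical
  scaling alone cannot hit clinical endpoints — this post-scaling
  adjustment step is standard translational-modeling practice and is why
  A_M,L differs between the species baselines (2.28 vs 23.8): in the human
  parameterization it absorbs the much stronger dependence of net growth on
  miR-155 required for the monotherapy ceiling to sit near seven months.

The allometric dose exponent deserves a note: the conventional
body-surface-area value is −0.33, but the package default is −0.25, which
maps the 0.2 mg/kg mouse dose to the 0.026 mg/kg human-equivalent dose used
throughout the clinical analyses (−0.33 would give 0.0135 mg/kg). Both are
selectable per call.

## Synthetic data

`synthetic.generate_preclinical` emulates the *structure* of pooled NSCLC
xenograft studies: seven arms (two controls and five treatments), nine
twice-weekly caliper measurements over 28 days, eight animals per arm, and
multiplicative lognormal measurement noise (default CV 15%, mean-one
factors) on volumes. The generating parameters are stored with the data so
calibration can be scored against the truth. What it does **not** emulate:
inter-animal growth-rate heterogeneity (noise is observation-level only),
animal dropout or ulceration censoring, inter-study baseline differences
(both controls share one truth), or caliper-specific biases. Passing
recovery tests therefore demonstrate identifiability under honest
measurement noise, not robustness to biological heterogeneity.

Toy survival tables (exponential event times with known hazard ratios) and
exact Hill-curve dose-effect tables serve as oracles for the survival and
dose-response fitters.

## Numerical choices

* Integration: LSODA with per-state absolute tolerances reflecting typical
  magnitudes; relative tolerance 1e-8 for model-level work (halving it moves
  end-of-course volume by < 1e-4 relative), relaxed to 1e-6 inside cohort
  sweeps where thousands of simulations are needed. Bolus events restart
  the integrator; duplicate time samples at dose instants keep the
  post-bolus state. Tiny solver undershoots below zero are clipped after a
  tolerance check; NP mass balance (injected = plasma + interstitium +
  cumulative sinks) holds to < 1e-6 relative.
* RECIST evaluation uses the dense ODE grid by default; progression is the
  first time diameter ≥ max(1.2·nadir, nadir + 0.5 cm) with the nadir
  including baseline, linearly interpolated between stored points
  (months = days/30.44). With an explicit visit schedule, progression is
  instead recorded at the detecting visit — back-interpolating between
  widely spaced visits can spuriously antedate progression on convex growth
  curves. Patients without progression are censored at the 36-month
  horizon.
* Virtual patients: Latin-hypercube sample of the ten most
  response-sensitive parameters within ±10% of baseline plus a log-uniform
  initial volume in [0.5, 10] cm³; a patient is plausible if the untreated
  net growth rate is positive on a geometric volume grid up to its target
  (the untreated molecular subsystem is at equilibrium for any V, so
  reachability reduces to rate positivity). Rejected draws are resampled
  from a fresh deterministic stream; with the default ranges nothing is
  rejected and marginal LHS stratification is exact.
* Calibration pools log-volume residuals across arms (equalizing arm
  weighting across magnitudes), with bounds of ±2 orders of magnitude
  around the initial values and seeded multi-start (default 10) log-uniform
  within the bounds.
* Sensitivity analysis defines TGI against the control arm re-simulated
  under the same perturbed parameters; signs of the suppression-pathway
  indices are regime-dependent and are read out at a partial-engagement
  dose. Tukey grouping joins parameters into connected components of
  "not significantly different" pairs in rank order at α = 0.05.
* Chou–Talalay: the affected fraction is cohort- or average-patient TGI/100
  clipped to [0.01, 0.99]; combination studies use non-constant-ratio CI
  with each combination's own observed fa, monotherapy median-effect lines
  fitted on log-spaced Q3W dose grids. Classification thresholds: strong
  synergy < 0.3, synergy < 0.9, additive ≤ 1.1, antagonism above.

## Problem sizes

The shipped analysis scripts favor turnaround: the acceptance pipeline uses
a 200-patient cohort per trial arm, 20-dose × 3-schedule response grids,
50 LHS dose vectors per combination with the average-patient affected
fraction, and single-start calibration from a perturbed initial guess.
The library accepts the full-scale settings (1,000 patients, 50×500 GSA
replicates, cohort-mean fa) through the same interfaces; the CLI exposes
both via `--scale`.

## Known limitations

No spatial heterogeneity or NP distribution gradients; no toxicity or
adverse-event modeling; no resistant subclones or PD-L1 expression
heterogeneity between patients; immune populations are recruited
algebraically rather than mechanistically; antibody tumor exposure uses an
effect-compartment approximation without target-mediated disposition; and
the two-compartment reduction ignores peripheral drug distribution. The
TGI and percent-diameter-change summaries are mutually constrained through
the shared trajectories — a high-TGI regimen here necessarily also shows a
small diameter change, so the two dose-response characterizations cannot be
tuned independently.
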