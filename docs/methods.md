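# Methods

## Model scope and assumptions

The package models spindle-assembly-checkpoint (SAC) activation and
silencing in a human mitotic cell with mass-action kinetics throughout.
The full network couples two modules over 15 molecular species and the two
kinetochore state counters:

* **Activation.** Unattached kinetochores (`Kin_U`) catalyse O-Mad2 →
  C-Mad2 at rate `k3` per kinetochore. C-Mad2 captures Cdc20 (irreversibly
  for the free pool, reversibly on APC/C:Cdc20), BubR1:Bub3 recruitment
  completes the MCC, and MCC binds both free APC/C and APC/C:Cdc20 — the
  latter capturing a second Cdc20 molecule in one complex. Cdc20 also binds
  BubR1:Bub3 directly (BCC) and O-Mad2 directly at a much slower rate.
* **Silencing.** Attached kinetochores (`Kin_A`) catalyse the removal of
  Mad2 from APC/C:MCC and APC/C:Cdc20:MCC at rates `k8`, `k9` per
  kinetochore — the silencing factors p31^comet and UbcH10 are implicit in
  these attached-kinetochore-proportional rates, not explicit species. The
  resulting APC/C:BCC decays constitutively (`k10`) into active APC/C:Cdc20,
  which degrades the output substrates Securin and CyclinB (`kD`).
* **Attachment** is a first-order transition `Kin_U → Kin_A` at `k_attach`
  per kinetochore; it is irreversible (no error-correction/detachment).
* **Mad2 turnover.** The loss of checkpoint capacity in late metaphase is
  represented by a spontaneous decay of free Mad2 at the literal rate
  `k_attach`. Physically this stands in for poleward transport of Mad2
  along microtubules, not proteolysis; active transport itself is outside
  scope. By default the decay acts on the free O-Mad2 pool only
  (`mad2_decay_pools="open"`): the closed conformation is treated as
  kinetically protected, and Mad2 must first relax to the open form
  (directly via `k_m3`, or through the Cdc20-catalysed cycle
  C-Mad2 + Cdc20 → C-Mad2:Cdc20 → O-Mad2 + Cdc20 via `k_m6`) before it can
  leave. The alternative reading — both free pools decay — is available as
  a switch; it makes free C-Mad2 incapable of surviving the ~15-minute
  attachment window, which destroys the delayed-exit phenotype of strong
  Cdc20 depletion (see "Mutant panel" below), and is therefore not the
  default.
* One deliberate mass-balance choice: stripping Mad2 from the
  double-Cdc20 complex APC/C:Cdc20:MCC releases the MCC-borne Cdc20 as a
  free molecule (APC/C:BCC + O-Mad2 + Cdc20), so that total Cdc20 is
  conserved exactly; every inhibitory complex then carries its Cdc20
  stoichiometry explicitly.
* CyclinB is included as a species but carries the same kinetics as
  Securin; Securin is the reported output signal.

Totals of APC/C, Cdc20 and BubR1:Bub3 cores are conserved along any
trajectory; total Mad2 is non-increasing; `Kin_U + Kin_A = 92` always.

## Reference parameter set

All concentrations are in µM, first-order rates in s⁻¹, second-order rates
in µM⁻¹s⁻¹. Initial concentrations follow the human-SAC modelling
literature: Cdc20 0.22 (the most abundant basic species), O-Mad2 0.15,
BubR1:Bub3 0.13, APC/C 0.09, Securin and CyclinB 0.2. Two rates carry
in-text constraints that the package enforces at validation time: the
kinetochore-mediated Mad2 conversion must not exceed `k3 = 0.016` per
kinetochore (its default value), and the stripping rates must not exceed
0.015 (`k8 = 1.5e-4`, `k9 = 3e-4` by default, well below the ceiling).
`k_attach = 0.0058` makes deterministic attachment complete
(Kin_U < 0.5) at t ≈ 899 s, i.e. ≈ 15 simulated minutes.

The remaining rate constants are not published as a set; they were
calibrated once, as a single design pass, so that the unperturbed model
shows the canonical wild-type sequence — fast MCC burst, steady decline
during attachment, near-zero APC/C:Cdc20 throughout the window, full
activation a few minutes after the last attachment, graded Securin decline
— and so that the mutant panel reproduces as many of the published
in-silico phenotypes as the structure allows. The shipped values are

| symbol | value | role |
|---|---|---|
| k1 / k_m1 | 0.047 / 3.2e-4 | APC/C·Cdc20 association (slow on, tight) |
| k2 / k_m2 | 24 / 3.8e-4 | MCC capture of APC/C and APC/C:Cdc20 |
| k3 / k_m3 | 0.016 / 2.7e-3 | O↔C Mad2 conversion (forward per Kin_U) |
| k4 / k_m4 | 0.28 / 1.4e-2 | C-Mad2 capture of (APC/C-bound) Cdc20 |
| k5 / k_m5 | 8.5 / 1e-3 | BubR1:Bub3 recruitment into (APC/C-bound) MCC |
| k6 / k_m6 | 3.5e-3 / 1.9e-2 | direct O-Mad2·Cdc20 binding (slow) |
| k7 / k_m7 | 0.094 / 1.27e-2 | BCC formation |
| k8, k9 | 1.5e-4, 3e-4 | Mad2 stripping per attached kinetochore |
| k10 | 6.8e-3 | APC/C:BCC decay to active APC/C:Cdc20 |
| kD | 0.1 | Securin/CyclinB degradation |
| kM1, kM2, k_mM2, kM3 | 0.016, 24, 5e-4, 0.02 | coarse-grained core |

Stability ordering is enforced: MCC-containing complexes outlive
BCC-containing ones (`k_m5 < k_m7`, `k_m2 < k10`).

The architecture this calibration settles into is worth stating, because it
is what the mutant phenotypes probe: during the attachment window the
APC/C pool is parked in Mad2-capped complexes (APC/C:MCC,
APC/C:Cdc20:MCC, APC/C:Cdc20:C-Mad2) and, after stripping, in APC/C:BCC,
whose slow decay (`k10`) is the only leak into activity; the leak is
re-capped by free MCC and C-Mad2 for as long as the Mad2 pool survives.
Mad2 survival is a race between kinetochore-mediated conversion
(∝ `k3·Kin_U`) and open-form decay, with the Cdc20-catalysed release
channel (`k_m6`, saturating in Cdc20) setting how fast surplus C-Mad2
drains once attachment completes. Checkpoint exit is therefore a timer
pinned to the last attachment, not a threshold crossed during it.

## Mutant panel and classification

Depletion retains a fraction of the initial concentration (5% and 40% in
the default screen), over-expression multiplies it tenfold; Mad2 treatments
scale both free Mad2 pools. Nocodazole reduces `k_attach` through the
monotone dose-response `f(c) = 1/(1 + c/c50)` with `c50 = 10 ng/ml` by
default (a literal step-table mode is available); Mad2-targeting siRNA is a
Mad2 depletion.

Classification uses the relative activity `A(t) = [APC/C:Cdc20]/ceiling`
with the ceiling `min(total APC/C, total Cdc20)` — an APC/C:Cdc20 complex
needs one of each, so under strong Cdc20 depletion the achievable maximum
is the Cdc20 pool, and normalising by total APC/C would make the exit
labels degenerate. Inhibition is read from the maximum of A over the
attachment window [first attachment, t_last]: FI below 0.15, NI above 0.5,
WI between. Exit is read from the first crossing of 0.8 after t_last: PE
within 10 min, DE within 60 min, IE if never or if the crossing precedes
t_last (premature). These thresholds are design choices, configurable in
`Thresholds`; the window endpoints and the deterministic
`t_last = ln(2·92)/k_attach` are likewise configurable through the solver.

With the reference calibration the screen reproduces the wild type
(FI)-(PE), Mad2 depletion to 5% (NI)-(IE, premature), BubR1:Bub3 and Cdc20
over-expression (FI)-(PE), and the two Cdc20 depletions (FI)-(DE) at 5%,
(WI)-(DE) at 40%. Four phenotypes land one notch away from their published
counterparts and resisted an extensive calibration search; the mechanistic
reasons appear structural to this reaction set and these concentrations:

* **Mad2 over-expression exits slowly (DE rather than PE).** The tenfold
  free C-Mad2 surplus can only leave through the first-order open-form
  relaxation or the Cdc20-saturated catalytic channel; draining ~1.3 µM
  within 10 min of the last attachment would need rates that also destroy
  the Cdc20-depletion phenotypes, which depend on free C-Mad2 surviving
  the window.
* **Mad2 40% and BubR1:Bub3 5% exit properly (PE) instead of prematurely
  (IE).** Premature reactivation requires crossing 80% of the ceiling
  before the last attachment, but every collapse in this architecture is
  pinned to ~t_last plus the APC/C:BCC leak lag: kinetochore conversion
  protects the Mad2 pool while any kinetochores remain unattached. Only
  outright capacity failure (Mad2 at 5%) crosses early.
* **BubR1:Bub3 40% shows weak rather than full inhibition.** Its scarce
  BubR1 is progressively converted into leaky APC/C:BCC, and the C-Mad2
  capping ratio that would compensate is thermodynamically coupled to the
  5% case in the opposite direction.

These three statements are the package's own analysis of its reference
conditions; with a different (e.g. experimentally fitted) rate table the
labels could move. Related: sweeping `k8 = k9` upward does not produce a
loss-of-function flip here — faster stripping parks APC/C in APC/C:BCC,
which still inhibits and shields Mad2 (free MCC is never stripped) — so
the stripping ceiling manifests as a constraint on exit quality rather
than as a sharp FI→NI threshold under this calibration. The corresponding
acceptance tests assert the published expectations and fail; they are left
failing deliberately rather than weakened.

## Simulation numerics

LSODA (scipy `solve_ivp`) with `rtol = 1e-8`, `atol = 1e-10`; output on a
uniform grid (1200 points over 6000 s by default). Hybrid mode samples the
92 attachment times exactly (independent exponentials; the sorted sample
is the event sequence of the thinning pool), freezes the kinetochore
counters inside the ODE, and restarts the integrator at each event with
`Kin_U` decremented — attachments are discrete state changes, not stiff
terms. A seed is mandatory in hybrid mode and recorded in the result.
Concentrations may undershoot zero by integrator tolerance; values are
clipped at zero for reporting and an undershoot beyond 1e-8 µM warns.
Securin degradation rates are estimated with a Savitzky-Golay local
polynomial (window 21 points, order 3) because raw finite differences
amplify solver noise; anaphase onset is the rate-trace maximum.
Steady states freeze the kinetochore counters, optionally relax by
integration, then polish with a least-squares root search whose residual
includes the conserved-total deviations — without that anchoring the
search can drift to a fixed point on a different conservation manifold.

## Coarse-grained switch

The reduced network keeps Mad2 → MCC at `kM1·[Kin_U]`,
MCC + APC/C ⇌ APC/C:MCC (`kM2`, `k_mM2`), the autocatalytic disassembly
APC/C:MCC → APC/C + Mad2 at `kM3·[APC/C]` (by default additionally
proportional to `Kin_A`, consistent with the total-MCC balance; the
variant without the attached-count factor is a switch), and Securin
degradation by free APC/C — the reduced reactions never form an
APC/C:Cdc20 complex, so free APC/C is the degrading species, named
explicitly in the configuration.

With `APCT` and `MadT` conserved, the balance for `MCCT = [MCC] +
[APC/C:MCC]` closes once the bound complex is taken from the quasi-steady
state of the binding step with linearised removal: x solves
`x² − B·x + MCCT·APCT = 0` with `B = km + APCT + MCCT`,
`km = (k_mM2 + kM3)/kM2`, and the physical root is the smaller one —
the discriminant must be `B² − 4·MCCT·APCT` (it equals
`(APCT − MCCT)² + km(km + 2APCT + 2MCCT) ≥ 0`, so the root always exists
and lies in `[0, min(APCT, MCCT)]`). The balance is autocatalytic because
removal needs free APC/C: it vanishes both when all APC/C is sequestered
(checkpoint on) and when no complex remains, which is what makes the core
bistable.

Bifurcation scans treat `Kin_U` as a continuous parameter (a count-valued
parameter cannot fold); roots are located by dense sign-change bracketing
(2000 points over [0, MadT]) with Brent refinement to relative 1e-10, and
stability from the slope sign. At the reference rates the scan is bistable
for `Kin_U` between ≈ 0.8 and ≈ 2.3: the checkpoint-on branch survives
down to a single unattached kinetochore and only full attachment silences
the core, while re-engagement from the silenced state requires detaching
past the upper fold (hysteresis). Lowering `kM1` moves the lower fold to
`Kin_U > 1`, i.e. the checkpoint silences with unattached kinetochores
remaining (90 attachments suffice at `kM1 = 0.004`). The closed form is a
quasi-steady approximation; its steady states agree with time integration
of the reduced network to within ~2% of the Mad2 pool, and exactly with
the binding subsystem it linearises.

## Particle engine

Molecular species are spheres of homogeneous density: radius
`r = r_ref·(m/m_ref)^(1/3)` from the molecular mass (Mad2 24 kDa …
APC/C-holocomplexes ≈ 1.2–1.5 MDa) and Stokes-Einstein diffusion
`D = D_ref·r_ref/r`. The reference radius (40 nm at 100 kDa) is
deliberately inflated relative to physical protein sizes — that, not a
rescaled time axis, is what makes desk-scale run times possible — and the
inflation is calibrated out of the kinetics: each bimolecular rule fires
with per-contact propensity λ while a pair is within `R = r_i + r_j`,
with λ obtained by inverting the Doi-model steady state
`k = 4πDR(1 − tanh(q)/q)`, `q = R√(λ/D)`, so the well-mixed limit
reproduces the requested mass-action constant even when partially
diffusion-limited; rates above 98% of the Smoluchowski ceiling are
refused at startup. Dissociation co-products are placed just outside the
binding radius of any rule they share with their partner (unbinding
radius, 1.1·R), preventing geminate rebinding that no mean-field model
can represent.

Geometry: a spherical reaction volume of radius 570 nm (≈ 0.78 µm³, about
1/100 of the kinetochore-proximal region of a mitotic cell, so that
physiological concentrations give 1/100 of physiological copy numbers:
~460 particles in total, ≥ 50 for the abundant species), with the 92
kinetochores as fixed 25 nm spheres in two staggered back-to-back rings of
46 on a central plate. Copy numbers are `conc·V·N_A·scale` with the
reduction factor defaulting to 1. O-Mad2 touching an unattached
kinetochore converts to C-Mad2 with probability one; attached kinetochores
apply the two stripping rules inside an enlarged 150 nm interaction radius
with in-region propensity `k·V/v_region`, and the released Mad2 (and
Cdc20) is scattered uniformly, emulating the rapid poleward streaming of
stripped material away from the plate. The timestep (0.1 s) must keep the
RMS displacement below the smallest interaction radius; violations are a
startup error.

Because the conversion regions are absorbing, the per-kinetochore
conversion rate depends on how many regions compete for the same O-Mad2:
calibration therefore measures steady-state tracer fluxes (uniform
re-injection) in a sparse (6 well-separated unattached kinetochores) and a
crowded (all 92) arrangement and fits the competition-saturation law
`k3(Kin_U) = k3_iso/(1 + c·(Kin_U − 1))` through both. The matched
mean-field model integrates the full network with this saturating
conversion law, the calibrated stripping rate, and the quantised initial
copy numbers; ensemble means over 10 seeds track it within ~1.5 ensemble
standard deviations for MCC and APC/C:Cdc20, while the 10–90% activation
rise time of the particle runs exceeds the mean-field one — activation is
genuinely smeared by attachment stochasticity and finite copy number, the
residual spatial effect at this scale.

The spatial benchmark parameter set slows the two strongest bindings
(`k2`, `k5`) to 2 µM⁻¹s⁻¹ with dissociation constants preserved, keeping
every rule below the diffusion-limited ceiling of the coarse geometry.
The engine has no excluded volume (initial placement uses a quarter-radius
hard core only), no microtubule mechanics, no active transport, and no
explicit p31^comet; kinetochore coordinates, radii, diffusivities and the
reduction factor are plausible placeholders, flagged as such in the
configuration.

## What the bundled conditions do and do not show

The reference conditions are a calibrated emulation, not a fitted dataset:
they reproduce the qualitative wild-type sequence, the graded
(rheostat-like) Securin output under nocodazole dose series and siRNA, the
bistable core with hysteresis, and most of the mutant panel. Passing tests
therefore demonstrate internal consistency of the implementation and of
this calibration — conservation to integrator tolerance, closed-form/ODE
agreement, particle/mean-field agreement — not quantitative agreement with
any particular measured cell. Absolute times (anaphase onset, exit delays)
inherit the uncertainty of the calibrated rates; classifications near
threshold boundaries can move with the rate table; and the spatial claims
hold at the stated coarse scale, not at molecular resolution.
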