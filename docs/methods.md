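# Methods

## The model

The model abstracts EGFR-driven EMT signaling in a lung epithelial cell into
eight ordinary differential equations: a three-tier kinase cascade (SOS, Ras,
ERK), a transcription factor (MYC), two microRNAs with opposite regulation
(miR-9 activated by MYC, let-7 repressed by MYC), and two EMT markers
(E-Cadherin and MMP mRNA). Assumptions:

- The EGF-EGFR complex is at binding equilibrium and held constant; receptor
  dynamics are not modeled.
- SOS, Ras and ERK each cycle between an active and an inactive form with a
  conserved total. Only the active pools are state variables; the inactive
  pools are recovered from the totals at every evaluation, keeping the system
  at dimension eight.
- Activation/deactivation fluxes follow Michaelis–Menten kinetics with the
  upstream active species (or the constant complex) as catalyst. The
  Raf/MEK steps are folded into a single Ras→ERK conversion; active MEK is
  proxied by active Ras with a copy-number rescaling. The PI3K/Akt branch is
  out of scope.
- ERK catalyzes SOS deactivation — the cascade's negative feedback. The
  feedback strength is the deactivation constant `deg_sos`, exposed to the
  scenario runner under the alias `erk_sos_feedback` because "weakened
  feedback" is one of the three mutation axes.
- let-7 represses Ras activation through the multiplicative factor
  1/(1 + x₆/h₁); MYC represses let-7 production through the same functional
  form. MYC drives miR-9 through a fourth-order Hill function (transcription
  with several cooperative/enzymatic steps).
- E-Cadherin is produced in proportion to let-7, repressed by miR-9 (the
  miR-9→HMGA2/Snail→E-Cadherin chain collapsed into one inhibition factor),
  and degrades linearly. Although the parameter table labels the relevant
  constant "control of MYC on E-Cadherin", the production term involves the
  two microRNAs, not MYC directly; the code therefore names it
  `k_mir9_on_ecad`.
- MMP mRNA is produced at a constant rate and removed at rate
  d₈·x₈·(x₇/h₅): removal is proportional to E-Cadherin, and with h₅ set to
  the healthy E-Cadherin level the healthy MMP turnover equals its measured
  mRNA half-life rate. Alternative forms (bilinear without the scaling
  constant, or saturating in x₇) have the same sign structure; this one keeps
  the half-life interpretation of d₈ exact at the healthy state.
- All other degradation is linear mass action.

Units are nM and minutes throughout. nM keeps every species within
~1e-3–1e3, and the calibration chain (counts → molarity) lands there
naturally.

## Calibration

`derive_parameter_set` rebuilds every constant from primitives
(`CalibrationPrimitives`, bundled as `data/primitives.json`):

1. **Geometry.** The cell is a sphere with the HeLa total volume of Fujioka
   et al. (2006) (2.6 pL; cytoplasm 1.9 pL, nucleus 0.7 pL). Surface species
   (the EGF-EGFR complex) are converted to concentration through a 10-nm
   membrane shell (area × thickness); the shell thickness cancels exactly
   against the matching factor in the SOS activation constant, so it fixes
   units without influencing dynamics.
2. **Binding equilibrium.** Complex count C = R_T·EGF/(EGF + koff/kon) from
   the steady-state balance of binding and unbinding, with EGF in excess.
3. **Counts → concentrations.** Cytoplasmic totals (SOS 1e5, Ras 1e5,
   ERK 6e5 molecules — the Brown et al. (2004) cascade initial pools) use the
   cytoplasm volume; nuclear MYC (6e4, Rudolph et al. 1999) the nucleus
   volume; let-7 uses the HeLa copy number of Lim et al. (2003) (1e4); the
   normal-lung miR-9 copy number is taken as 1 molecule/cell — an explicit
   small positive primitive rather than zero, so fold changes stay defined.
   The MMP mRNA steady state converts a per-tissue-mass copy number through
   the lung tissue density (≈1.05 g/cm³).
4. **Half-lives → rates.** ln 2/t½ with MYC 30 min, miR-9 60 min (brain
   tissue), let-7 240 min, E-Cadherin 300 min, MMP-9 mRNA 720 min. These
   produce the model's slow tiers; the printed sources span ranges, and the
   defaults are chosen inside them so the canonical fast-cascade → microRNA →
   MMP hierarchy is explicit.
5. **Cascade kinetics.** Per-molecule catalytic constants and molecule-unit
   Michaelis constants (Brown et al. 2004 style) are rescaled by N_A·V;
   constant phosphatase pools (Ras-Gap, PP2A) fold into the Ras/ERK
   deactivation rates, and active P90Rsk is proxied by active ERK for the SOS
   feedback.
6. **Steady-state closure.** The SOS/Ras/ERK fixed point is solved (long
   LSODA integration from the inactive state, then a damped root polish;
   relative residual < 1e-9 enforced), and the five downstream production
   rates are solved algebraically from the steady-state identities. The
   healthy state is therefore a fixed point by construction — exactly for
   equations 4–8, to solver tolerance for 1–3 — for *any* valid primitives,
   not only the bundled ones (tested).

Estimated control/saturation constants are expressed as multiples of the
corresponding healthy steady state:

- `k_myc_on_mir9` = 10× healthy MYC. Large relative to MYC keeps the Hill
  drive in its quartic regime, so a fold-f rise in MYC yields ≈f⁴ in miR-9 —
  the amplification consistent with the tens-fold miR-9 overexpression seen
  in tumor tissue at a few-fold MYC change.
- `k_myc_on_let7` = 1× healthy MYC (let-7 production halved at baseline,
  responsive in both directions).
- `k_mir9_on_ecad` = 10× healthy miR-9: negligible repression in the healthy
  cell, strong repression at the mutant's elevated miR-9.
- `k_ecad_on_mmp` = 1× healthy E-Cadherin (see above).
- `k_let7_on_ras` = 20× healthy let-7. The repression must be present (it is
  one of the model's two negative-feedback damping paths) but weak: at 1× the
  healthy level, most of the Ras/ERK mutant response would ride on the slow
  let-7 timescale and the cascade would no longer settle in minutes,
  contradicting the intended fast/slow hierarchy.

No intermediate is rounded; only display output rounds.

## Simulation engines

- **Deterministic:** `scipy.integrate.solve_ivp`, LSODA (stiff-capable;
  BDF selectable), rtol 1e-8. The absolute tolerance default is 1e-14 nM —
  far below the smallest species level (healthy miR-9 ≈ 1e-3 nM) — because a
  1e-10 floor would let the integrator park small species at errors that are
  large *relative* to their level. Cross-checked against an independent
  fixed-step RK4 at 0.01-min steps (max relative deviation < 1e-5).
- **Stochastic:** fixed-step Euler–Maruyama; the additive term σ·√dt·Z enters
  only the targeted microRNA equation ("background" regulation, not shot
  noise — hence additive, not state-dependent). States are clipped at zero
  after each step; clip events are counted and reported (for small σ around a
  positive state the clip rate is zero to well under 0.1% of steps). A step
  that deterministically moves any species by more than 50% of its value is a
  stability violation: logged, escalated to an error in strict mode. Default
  dt 0.05 min against cascade relaxation times of ≈0.7–3 min. Realization i
  draws from a Philox stream keyed by (master seed, i), so ensembles are
  reproducible, order-independent, and each member is bitwise identical to
  the single path with the same derived seed.
- **Settling times** are reported as the first time a species traverses the
  given fraction (default 95%) of its net change, which is monotone in the
  fraction; species with no net change settle at 0, and a species that never
  reaches the threshold is flagged rather than raising.

## Sensitivity analysis

Latin hypercube sampling (scipy's stratified `qmc.LatinHypercube`) over the
14 estimated parameters — the four estimated steady-state concentrations
(entering as initial values), five control/saturation constants, five
production rates — each on [0.5×, 2×] of its calibrated value. Each sample is
simulated from its healthy initial state to t = 2880 min and summarized by
the miR-9/let-7 ratio. Parameters and output are rank-transformed (average
ranks on ties) and the PRCC of parameter j is the correlation of the
residuals of its ranks and the output ranks after regressing each on all
other parameters' ranks — implemented as explicit residual regressions (not
correlation-matrix inversion) and pinned to a normal-equations oracle at
1e-10. Significance: t = r·√((n−2−(k−1))/(1−r²)) with n−2−(k−1) degrees of
freedom, two-sided, α = 0.01, no multiple-testing correction. Samples whose
simulation fails are dropped with a warning; more than 5% drops aborts.

t = 2880 min (two days) evaluates the ratio after the microRNA tier has
settled (≈400–1100 min) without requiring the much slower MMP equilibration,
which does not enter the ratio.

## What the defaults emulate, and what they do not

The bundled primitives define one reference parameterization: an "average"
(HeLa-geometry) lung epithelial cell with literature-scale copy numbers and
half-lives, mutations represented as 10× (receptor/Ras) or 0.01–1×
(feedback) multipliers, noise amplitudes in nM/√min around the mutant
operating point. Passing tests demonstrate the *structural* claims — fixed-
point closure for any valid primitives, monotone dose–response on all three
mutation axes, the fast-cascade/slow-MMP hierarchy, greater MMP fragility to
miR-9 than to let-7 input, and the PRCC sign pattern (MYC and miR-9
production up; let-7 production and both MYC control constants down). They do
not validate the specific fold-change magnitudes against measurements: those
scale with the estimated control constants, and real tissue data (cell-line
qPCR, tumor cohorts) are outside the package's scope.

## Known limitations

- The EGF-EGFR complex is constant; receptor internalization/recycling and
  ligand depletion are ignored.
- One well-mixed compartment per species; no nuclear/cytoplasmic transport
  delays, despite using different volumes for unit conversion.
- The miR-9→E-Cadherin and let-7→HMGA2 chains are single inhibition factors;
  intermediate species would add delay and could change transient shapes.
- Additive Gaussian noise cannot represent low-copy-number discreteness —
  at 1 miR-9 molecule/cell a birth–death treatment would differ; the additive
  input models unknown regulatory drive, not molecular noise.
- PRCC measures monotone association; strongly non-monotone parameter
  effects (none observed on the sampled ranges) would need variance-based
  indices, which are out of scope.
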