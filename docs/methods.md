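# Methods

`crsim` simulates the vital-sign response of an adult human to respiratory
perturbations — airway obstruction, inspired-gas changes, prescribed
arterial-gas challenges, hemorrhage and positive-pressure ventilation — with
a closed loop of three components: chemoreflex respiratory control,
lumped-parameter two-lung airway mechanics, and a reduced gas-exchange /
cardiovascular core.  This note records the model, its assumptions, the
numerical choices, and what the tests do and do not establish.

## Respiratory control

Central chemoreceptors sense the deviation of arterial CO2 pressure from its
nominal value `PaCO2_n`; peripheral chemoreceptors are summarized by their
firing activity `f_ac(PaO2, PaCO2)` relative to its nominal `f_acn`.  Each
pathway drives first-order deviations of the respiratory rate `RR` and of
the minimum respiratory muscle pressure `P_mus,min`:

    dx/dt + tau * x = G * u        (default, "printed" convention)
    tau * dx/dt + x = G * u        ("standard" convention)

where `u` is the sensed deviation.  The two conventions differ only in
whether the steady gain is `G/tau` or `G`; both are implemented behind a
switch because either parameterization appears in the lumped-control
literature, and the calibration procedure absorbs the difference into the
fitted gains.  Totals are `RR = RR_o + dRR_c + dRR_p` and
`P_mus,min = P_mus,min_o + dPmusmin_c + dPmusmin_p`, with RR clamped to a
floor of 2 breaths/min (guards `T = 1/RR`) and `P_mus,min` clamped to <= 0.

At the start of each breath cycle the current `(RR, P_mus,min)` pair is
frozen into a muscle-pressure waveform over the cycle `T = 1/RR` with
inspiration time `T_i = 0.375 T`: a parabolic descent from 0 to `P_mus,min`
on `[0, T_i)` and the exponential recovery
`P_mus,min * (e^(3-8*RR*t) - e^-5) / (1 - e^-5)` on `[T_i, T]`, which equals
`P_mus,min` at `T_i` and exactly 0 at `T`.  In the default mode the parabola
has its vertex at `T_i` (continuous hand-off with zero slope, matching the
narrative "decreases from 0 to P_mus,min during inspiration"); an alternate
"literal" mode keeps the polynomial `4*P*RR*t - 4*P*RR^2*t^2`, whose vertex
sits at `T/2` so its value at `T_i` is `0.9375 * P_mus,min` — a 6.25% jump
that the default mode removes.  Reflex states integrate continuously
underneath the per-cycle sample-and-hold.

## Respiratory mechanics

Air flows from the airway opening through three serial resistances
(mouth–larynx `R_ml`, larynx–trachea `R_lt`, trachea–bronchi `R_tb`) to a
bronchial node, then through two parallel branch resistances into left and
right lung compliances, inside the chest-wall compliance driven by
`P_mus`.  Segment compliances of the larynx/trachea/bronchi are omitted
(negligible contribution).  The bronchial pressure is algebraic — the flow
balance is linear in `P_b` and is eliminated exactly every step, so total
serial inflow equals the sum of branch flows to rounding.

Obstruction at one of the three serial segments multiplies its resistance by
`1/(1 - F_ao)^2` (Poiseuille scaling of a narrowed lumen).  Complete
obstruction (`F_ao = 1`) is represented as a zero-flow serial path rather
than a huge finite resistance, which would otherwise make the explicit
integrator unstable; the bronchial node then only redistributes volume
between the lungs, so total lung volume is exactly conserved while blocked.
Because the serial segments enter only through their sum, equal resistance
increments at the three locations produce identical ventilation — a model
property, not a physiological claim.

The two lungs carry 45% (left) and 55% (right) of total lung volume and
compliance; branch resistances are inversely proportional to those shares
(222% and 181% of the single-compartment value), so their parallel
combination recovers the single-compartment resistance.  Tidal volume is
`max - min` of total lung volume over the completed cycle, and
`MV = TV * RR`.

Baseline magnitudes (airway resistances, lung and chest-wall compliances,
resting lung volume) follow the lumped-parameter respiratory-mechanics
literature, converted to mmHg·min/L and L/mmHg.

## Reduced gas-exchange / cardiovascular core

The loop is closed by a deliberately small core with the same input/output
signature as a full-scale cardio-respiratory model, so the control and
mechanics components, the calibration, the validation metrics and the
sensitivity machinery are exercised end-to-end.  It is a reduced closure,
not a reimplementation of a full circulation; `CardioRespModel` isolates its
interface so a richer core can be swapped in.

**Gas stores.** Alveolar ventilation is `VA = MV * (1 - k_ds)` with dead
space fraction `k_ds = 0.30`.  PaCO2 relaxes (time constant 1.5 min) toward
the metabolic hyperbola `PiCO2 + 863 * M_dCO2 / VA`; PaO2 relaxes (0.2 min)
toward the alveolar-air target `PiO2 - PaCO2/RQ` with `RQ = 0.8`.  The time
constants shape transients only, never steady states.  As `VA` falls below
0.5 L/min both derivatives blend linearly into constant asphyxia ramps
(+5 mmHg/min for PaCO2, -30 mmHg/min for PaO2), the exact rates at `MV = 0`;
the ramp values are literature-order apnea figures.  `SpO2` is the Hill
sigmoid `100 * PaO2^gamma / (PaO2^gamma + P_50^gamma)`; `ETCO2` tracks PaCO2
minus a configurable alveolar–end-tidal gradient (0 by default).

**Peripheral chemoreceptor activity.** A decreasing sigmoid in PaO2
(half-activation 45 mmHg, slope 10 mmHg), normalized to its value at the
nominal operating point, times a linear CO2 factor `1 + 0.03*(PaCO2 - 40)`,
scaled by `f_acn = 1`.  Strictly decreasing in PaO2, strictly increasing in
PaCO2 while positive, and exactly `f_acn` at nominal gases.

**Circulation.** Stressed venous volume `V_s = V_V - V_Vu,eff` sets cardiac
output `CO = CO_0 * (V_s / V_sn) * (1 + k_ino * u)`; hemorrhage drains the
venous volume while venoconstriction recruits a fraction `k_veno = 0.7` of
the loss from the unstressed pool.  `MAP = CO * TPR` with
`TPR = TPR_0 * (1 + k_tpr * u)`.  The sympathetic drive `u` is first-order
(0.5 min) toward a target rising with fractional MAP deficit and with
chemoreceptor excess, saturating at `u_max = 2` (and at -0.9 from below so
TPR stays positive).  Heart rate combines four terms:

    HR = HR_0 + HR_1 * u + HR_2 * (f_ac - f_acn) + HR_v * (V_s - V_sn)

The volume term is an atrial-stretch (Bainbridge-type) contribution; its
gain and the sympathetic gain are set so that both a venous-volume increase
and a hemorrhage raise heart rate — with a pure baroreflex HR the two
responses cannot both have the observed direction.  Pulse pressure is
proportional to stroke volume (`PP_0 = 45` mmHg at `SV_0 = CO_0/HR_0`), and
`SBP = MAP + 2PP/3`, `DBP = MAP - PP/3`, preserving `DBP <= MAP <= SBP`.

**Anchored defaults.** Three defaults are solved once at parameter-set
construction so that the closed loop has its fixed point exactly on the
textbook resting baselines (MV 6.6 L/min, RR 12 breaths/min, SpO2 98%,
ETCO2 40 mmHg, MAP 90 mmHg, SBP 120 mmHg, HR 70 beats/min):
`M_dCO2 = 40 * VA_n / 863` (≈ 0.214 L/min, a normal CO2 production),
`gamma = ln(49) / ln(PaO2_n / P_50)` (≈ 2.94 with `P_50 = 26.6` mmHg), and
`P_mus,min_o` by bisection so the mechanics deliver TV = 0.55 L at RR = 12
(≈ -3.75 mmHg ≈ -5.1 cmH2O, a normal resting effort).  Because ventilation,
gas stores and chemoreflex are mutually consistent at that point, the
deviations vanish there and the fixed point is unique by monotonicity, so
initialization converges onto the anchors from any physiological start.
One caveat: blood volume has no restoring force (no fluid shifts or renal
handling — resuscitation physiology is out of scope), so a perturbed
*volume* start settles at a correspondingly shifted pressure, by design.

## Numerics

Explicit Euler at a fixed step of 4.17e-4 min (25 ms) integrates all states;
the breath cycle is event-driven on that grid (rollover at the first step
past `T`).  The stiffest mode — inter-lung pressure redistribution, time
constant ≈ 2.7e-4 min — satisfies `dt/tau < 2`, so the scheme is stable;
step-halving changes the slow output channels by well under 0.1% (asserted
on MV, RR, gases and pressures at scenario end; instantaneous within-breath
channels shift by sub-step breath phase and are not meaningfully comparable
pointwise for a first-order method).

Two implementation details matter for long runs.  First, the kernel stores
airway/lung pressures *relative to* `P_mus` and injects the muscle pressure
analytically each step: Euler-integrating `dP_mus/dt` alongside the flow
terms accumulates a secular pleural-pressure drift (~0.01 mmHg per cycle)
that eventually collapses a lung in multi-hour runs.  The module-level
`step_mechanics` retains the absolute differential-algebraic form with an
explicit `P_mus_rate` argument.  Second, a converged steady state is one
step past its last cycle rollover; reusing it (scenario start,
re-initialization) rebases the cycle clock to `-dt` so the continuation is
exact — re-initializing from a converged state then terminates in the
minimum number of cycles the convergence test requires.

Steady-state initialization runs the closed loop at nominal inputs
(FiO2 21%, FiCO2 0%, `P_ao = 0`, `F_ao = 0`, no hemorrhage) until the
relative cycle-to-cycle change of every tracked output falls below 1e-6
(denominator floored at 1e-3 so near-zero channels such as the resting
sympathetic drive compare absolutely), with a cap of 10,000 cycles;
convergence takes ~80 cycles (≈ 6.5 min of model time, ~2 s of wall time).

**Ventilation windows.** A positive airway-opening pressure in a schedule is
applied during the inspiratory fraction of each cycle and drops to
atmospheric during expiration (a constant mouth pressure cannot ventilate an
RC network), and the cycle runs at the ventilator's rate — the baseline
`RR_o` — while patient effort continues.  Without the fixed rate,
reflex-suppressed RR makes MV non-monotone in `P_ao` and the
pressure-matching bisection (`match_pao_to_target_mv`, tolerance
0.05 L/min) would be ill-posed.  Actuation is one-sided: targets below the
spontaneous MV report a bracket failure.

## Calibration

The eight chemoreflex parameters (four time constants, four gains) are
searched over `[0.5, 2] x` their nominal values with a Latin Hypercube
design (default 10,000 samples; every dimension stratified into n
equal-probability bins with exactly one sample each; seeded and
reproducible).  Each candidate simulates every subject's prescribed
arterial-gas trace open-loop — the reflex states start at their closed-form
steady values for the initial gases, so no spin-up transient contaminates
the fit — and predicted MV is normalized by the ratio of experimental to
simulated baseline before the RMSE against the observed series is summed
over subjects.  The argmin (first occurrence on ties) is the nominal
parameter set.  Failed simulations score +inf and are logged, not fatal.

Parameter recovery is validated by self-consistency: synthetic observations
are generated from a truth that is a member of the seeded candidate design
(with multi-subject inputs emulating a progressive-hypoxia protocol and
Gaussian observation noise, sigma = 0.3 L/min), and the fit must return
exactly that member, with mean per-subject RMSE at the noise floor.  With a
finite design this is the sharpest recovery statement available — a truth
off the design can only be recovered to the design's resolution in the few
directions the MV objective constrains.

## Validation metrics and sensitivity analysis

Predictions are compared with observation tables (time, channel, mean, SEM,
n) by per-channel RMSE and by the percentage of predictions within two
standard errors of the observed mean (closed interval).  Raw vital-sign
series can be denoised with an l1 trend filter
(`argmin 0.5*||y-x||^2 + lam*||D2 x||_1`, default `lam = 50`): ADMM with a
banded Cholesky x-update, residual-balancing adaptive rho (capped at 1e8),
and termination by a certified duality gap below 1e-6 evaluated through a
projected dual-feasible multiplier.  For total-obstruction phases, where
signals move too fast for pointwise comparison, the value with the largest
deviation from baseline inside a window from 2 min before to 1 min after
the release time is extracted (ties to the earliest time).

Local sensitivity of output `i` to parameter `j` at time `t` is the
normalized central difference `S_ij(t) = (y+ - y-) / (0.2 * y0)` under
one-at-a-time ±10% perturbations.  The registry is frozen at 163 named
slots: 64 live parameters and 99 documented inert `reserved_*` placeholders
standing in for the parameters of a full-scale core, so the sweep costs
exactly 2*163 + 1 = 327 simulations (each perturbed run re-initializes its
own steady state before executing the slow graded-obstruction protocol and
is evaluated at the ends of the 0/25/50/75/100% phases).  Inert slots and
parameters with no causal path return S = 0; cells with `y0 = 0` are flagged
undefined and excluded from rankings.  For the reduced core only sensitivity
*signs* at baseline are meaningful (CO2 production and dead-space fraction
raise ETCO2; a steeper dissociation sigmoid raises SpO2; venous volume
raises SBP and HR while unstressed venous volume lowers them); magnitudes
depend on the full-scale core and are out of scope.

## Synthetic studies

`crsim.synthetic` emulates the study-style data the validation pipeline
consumes: per subject, the chemoreflex parameters are jittered
multiplicatively inside the calibration box, the scenario is simulated,
channels are sampled on an observation grid, i.i.d. Gaussian noise with
per-channel SD is added, and mean/SEM/n are aggregated across subjects;
ground-truth parameters are recorded.  Ten protocol files covering the
eight study archetypes ship with the package (hypoxia, hypercapnia,
hypocapnic hypoxia, inspired-gas changes, slow and rapid airway obstruction,
hemorrhage with spontaneous or positive-pressure ventilation).  What these
fixtures establish is pipeline correctness — recovery, metric arithmetic,
schema round-trips — not fidelity to any real animal or human dataset: the
generator inherits every simplification of the model (no breath-to-breath
variability, no measurement drift, Gaussian noise, no inter-subject
variation outside the chemoreflex box).

## Known limitations

- The gas-exchange and cardiovascular core is a reduced closure; quantities
  that depend on full-core detail (sensitivity magnitudes, absolute
  transient shapes under combined insults) are indicative only.
- Linear compliances: lung volumes are unbounded above, so extreme
  ventilator pressures produce unphysiologically large tidal volumes.
- No respiratory-rhythm variability, airway-tone modulation, dynamic airway
  compliance (edema/hematoma), temperature/humidity effects, or
  fluid-resuscitation and analgesia pharmacology.
- Blood volume has no homeostatic return; hemorrhage effects persist.
- The asphyxia ramps are fixed rates, not an alveolar-store mass balance;
  they bound the speed of desaturation during complete obstruction.
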