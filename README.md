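# crsim

Closed-loop simulation of human cardio-respiratory responses to airway
obstruction and related respiratory insults, for generating and analyzing
synthetic vital-sign data.

Airway obstruction from head and neck trauma impairs ventilation, driving
hypoxia and hypercapnia that feed back onto breathing effort and the
circulation.  Decision-support and training tools for this injury need large
amounts of vital-sign data that do not exist clinically; a validated
physiological simulator is the practical substitute.  `crsim` implements
such a simulator as three coupled components:

- **Respiratory control** — central (CO2-sensing) and peripheral
  (O2/CO2-sensing) chemoreflex pathways, each a first-order ODE
  `ẋ + τx = G·(u − u_n)`, driving deviations of respiratory rate RR and of
  the minimum respiratory muscle pressure P_mus,min.  Each breath cycle
  (T = 1/RR, inspiration time T_i = 0.375·T) freezes the current pair into
  a muscle-pressure waveform: parabolic descent to P_mus,min, then the
  exponential recovery (e^(3−8·RR·t) − e^(−5))/(1 − e^(−5))·P_mus,min.
- **Respiratory mechanics** — an RC airway network: three serial segment
  resistances (mouth–larynx, larynx–trachea, trachea–bronchi), a bronchial
  node, and two parallel lung branches (45%/55% volume split; branch
  resistances 222%/181% of the single-compartment value) inside the
  chest-wall compliance.  Obstruction scales one segment by
  R = R₀/(1 − F_ao)²; F_ao = 1 is an exact zero-flow path.  Tidal volume is
  max − min lung volume per cycle and MV = TV·RR.
- **Reduced gas/cardio core** — alveolar gas stores (metabolic hyperbola
  PaCO2 → PiCO2 + 863·M_dCO2/VA, alveolar air equation for PaO2, Hill
  O2–Hb saturation with γ and P_50), peripheral chemoreceptor activity
  f_ac, and a stressed-volume circulation (CO, MAP = CO·TPR, SBP/DBP, HR)
  with a sympathetic drive and hemorrhage handling.

On top of the simulator: Latin-hypercube calibration of the eight
chemoreflex parameters against minute-ventilation data, validation metrics
(RMSE, 2-SEM coverage, ℓ₁ trend filtering, obstruction-release window
extraction), a ±10% one-at-a-time sensitivity sweep over a fixed 163-slot
parameter registry (327 simulations), and a synthetic multi-subject study
generator.  See `docs/methods.md` for the full model description.

## Worked example

```python
from crsim import CardioRespModel
from crsim.io import load_protocol

model = CardioRespModel()
steady = model.initialize()          # closed-loop steady state, ~2 s
print({k: round(steady.outputs[k], 2)
       for k in ("MV", "RR", "SpO2", "ETCO2", "MAP", "SBP", "HR")})

res = model.simulate(load_protocol("study7_slow"))
ts = res.timeseries
for t, fao in zip((2, 10, 18, 26, 29), (0, 0.25, 0.5, 0.75, 1.0)):
    print(f"{fao:4.0%}  SpO2 {ts.at(t,'SpO2'):6.2f}  "
          f"ETCO2 {ts.at(t,'ETCO2'):6.2f}  SBP {ts.at(t,'SBP'):6.1f}  "
          f"HR {ts.at(t,'HR'):6.1f}  MV {ts.at(t,'MV'):5.2f}")
```

prints

```
{'MV': 6.6, 'RR': 12.0, 'SpO2': 98.0, 'ETCO2': 40.0, 'MAP': 90.0,
 'SBP': 120.0, 'HR': 70.0}
  0%  SpO2  98.00  ETCO2  40.00  SBP  120.0  HR   70.0  MV  6.60
 25%  SpO2  97.99  ETCO2  40.11  SBP  120.0  HR   70.0  MV  6.58
 50%  SpO2  97.95  ETCO2  40.70  SBP  120.1  HR   70.1  MV  6.49
 75%  SpO2  97.31  ETCO2  47.79  SBP  120.9  HR   70.8  MV  5.52
100%  SpO2   0.03  ETCO2  62.50  SBP  186.1  HR  121.7  MV  0.00
```

The first line is the resting operating point the initialization converges
to.  The table follows the slow graded-obstruction protocol (25/50/75% for
8 min each at the mouth–larynx segment, then 3 min of complete
obstruction): mild obstruction is almost fully compensated by reflex-driven
effort, 75% obstruction produces measurable hypercapnia and desaturation,
and complete obstruction collapses ventilation — profound desaturation with
asphyxial hypertension and tachycardia before release.

Command-line equivalents: `crsim init-check`,
`crsim simulate --scenario study7_slow --out out/`,
`crsim sensitivity`, `crsim match-pao --target-mv 9.0`,
`crsim make-fixtures`, `crsim calibrate`, `crsim validate`.

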