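"""Flat index layout shared by the parameter registry and the jitted kernel.

The full model exposes a fixed 163-slot parameter vector.  Slots 0-63 are the
live parameters of the respiratory control, respiratory mechanics and reduced
cardio/gas core; slots 64-162 are inert placeholders that stand in for the
parameters of the full-scale cardio-respiratory core this package does not
re-implement (they have no causal path to any output and exist so that
whole-registry bookkeeping, e.g. one-at-a-time sensitivity sweeps, operates on
a registry of fixed, documented size).
"""

N_PARAMS = 163
N_LIVE = 64

# --- respiratory control -------------------------------------------------
TAU_CR = 0      # central RR reflex time constant (min)
TAU_CP = 1      # central P_mus,min reflex time constant (min)
TAU_PR = 2      # peripheral RR reflex time constant (min)
TAU_PP = 3      # peripheral P_mus,min reflex time constant (min)
G_CR = 4        # central RR gain
G_CP = 5        # central P_mus,min gain
G_PR = 6        # peripheral RR gain
G_PP = 7        # peripheral P_mus,min gain
RR_O = 8        # baseline respiratory rate (breaths/min)
PMM_O = 9       # baseline minimum respiratory muscle pressure (mmHg, <= 0)
PACO2_N = 10    # nominal arterial CO2 pressure (mmHg)
F_ACN = 11      # nominal peripheral chemoreceptor activity (dimensionless)
RR_FLOOR = 12   # numerical floor on RR (breaths/min)

# --- respiratory mechanics ----------------------------------------------
R_ML0 = 13      # mouth->larynx nominal resistance (mmHg.min/L)
R_LT0 = 14      # larynx->trachea nominal resistance (mmHg.min/L)
R_TB0 = 15      # trachea->bronchi nominal resistance (mmHg.min/L)
R_BLL = 16      # bronchi->left-lung resistance (mmHg.min/L)
R_BRL = 17      # bronchi->right-lung resistance (mmHg.min/L)
C_CW = 18       # chest-wall compliance (L/mmHg)
C_LL = 19       # left-lung compliance (L/mmHg)
C_RL = 20       # right-lung compliance (L/mmHg)
V_LLU = 21      # left-lung unstressed volume (L)
V_RLU = 22      # right-lung unstressed volume (L)

# --- gas exchange / blood gases -----------------------------------------
GAMMA = 23      # Hill coefficient of the O2-Hb dissociation sigmoid
P_50 = 24       # PaO2 at 50% Hb saturation (mmHg)
M_DCO2 = 25     # CO2 production rate in body tissue (L/min STPD)
K_DS = 26       # dead-space fraction of ventilation
RQ = 27         # respiratory quotient
TAU_O2 = 28     # O2 store time constant (min)
TAU_CO2 = 29    # CO2 store time constant (min)
R_CO2_AP = 30   # apneic PaCO2 rise rate (mmHg/min)
R_O2_AP = 31    # apneic PaO2 fall rate (mmHg/min)
VA_FLOOR = 32   # alveolar-ventilation floor in the hyperbola (L/min)
VA_APNEA = 33   # alveolar ventilation below which apneic ramps blend in (L/min)
ETCO2_GRAD = 34  # alveolar - end-tidal CO2 gradient (mmHg)
P_ATM = 35      # barometric pressure (mmHg)
P_H2O = 36      # water vapor pressure at body temperature (mmHg)

# --- peripheral chemoreceptor activity ----------------------------------
FAC_FMIN = 37   # hypoxic sigmoid floor (raw activity units)
FAC_FMAX = 38   # hypoxic sigmoid ceiling (raw activity units)
FAC_PHALF = 39  # PaO2 at half activation (mmHg)
FAC_KO2 = 40    # sigmoid slope constant (mmHg)
FAC_KCO2 = 41   # linear CO2 modulation (1/mmHg)
PAO2_N = 42     # nominal arterial O2 pressure (mmHg)

# --- cardiovascular core -------------------------------------------------
V_V0 = 43       # initial venous blood volume (L)
V_VU0 = 44      # initial unstressed venous volume (L)
V_SN = 45       # nominal stressed venous volume (L)
V_BLOOD0 = 46   # total blood volume (L)
CO_0 = 47       # nominal cardiac output (L/min)
MAP_0 = 48      # nominal mean arterial pressure (mmHg)
TPR_0 = 49      # nominal total peripheral resistance (mmHg.min/L)
HR_0 = 50       # intercept of the HR equation (beats/min)
HR_1 = 51       # HR gain on sympathetic drive (beats/min per unit)
HR_2 = 52       # HR gain on chemoreceptor drive (beats/min per f_ac unit)
HR_V = 53       # HR gain on stressed-volume excess (beats/min per L)
G_BARO = 54     # sympathetic gain on fractional MAP deficit
G_CHEMO = 55    # sympathetic gain on chemoreceptor drive
K_TPR = 56      # fractional TPR increase per unit sympathetic drive
TAU_SYMP = 57   # sympathetic drive time constant (min)
PP_0 = 58       # nominal pulse pressure (mmHg)
SV_0 = 59       # nominal stroke volume (L)
K_INO = 60      # fractional CO increase per unit sympathetic drive
K_VENO = 61     # fraction of lost volume recruited from the unstressed pool
HR_MIN = 62     # physiological floor on HR (beats/min)
U_MAX = 63      # saturation of the sympathetic drive target

FIRST_RESERVED = 64

# --- continuous state layout --------------------------------------------
S_DRRC = 0      # central RR deviation (breaths/min)
S_DRRP = 1      # peripheral RR deviation (breaths/min)
S_DPMC = 2      # central P_mus,min deviation (mmHg)
S_DPMP = 3      # peripheral P_mus,min deviation (mmHg)
S_PPL = 4       # pleural pressure (mmHg)
S_PLL = 5       # left-lung pressure (mmHg)
S_PRL = 6       # right-lung pressure (mmHg)
S_PAO2 = 7      # arterial O2 pressure (mmHg)
S_PACO2 = 8     # arterial CO2 pressure (mmHg)
S_U = 9         # sympathetic drive (dimensionless, 0 at rest)
S_VV = 10       # venous blood volume (L)
S_VBLOOD = 11   # total blood volume (L)
N_STATE = 12

# --- per-cycle (breath) state layout ------------------------------------
C_TSTART = 0    # cycle start time (min)
C_T = 1         # cycle duration (min)
C_TI = 2        # inspiration duration (min)
C_RR = 3        # RR held for this cycle (breaths/min)
C_PMIN = 4      # P_mus,min held for this cycle (mmHg)
C_VMIN = 5      # running min of V_l over the cycle (L)
C_VMAX = 6      # running max of V_l over the cycle (L)
C_MV = 7        # minute ventilation from the last completed cycle (L/min)
C_TV = 8        # tidal volume from the last completed cycle (L)
N_CYCLE = 9

# record channel layout (engine output decimation)
REC_CHANNELS = (
    "time_min", "P_mus", "V_l", "TV", "MV", "RR", "PaO2", "PaCO2",
    "SpO2", "ETCO2", "f_ac", "MAP", "SBP", "DBP", "HR", "CO",
    "V_V", "V_blood", "u_symp", "Q_in",
)
N_REC = len(REC_CHANNELS)

REC_UNITS = (
    "min", "mmHg", "L", "L", "L/min", "breaths/min", "mmHg", "mmHg",
    "%", "mmHg", "dimensionless", "mmHg", "mmHg", "mmHg", "beats/min",
    "L/min", "L", "L", "dimensionless", "L/min",
)

# obstruction location codes
LOC_ML = 0
LOC_LT = 1
LOC_TB = 2
LOC_CODES = {"ml": LOC_ML, "lt": LOC_LT, "tb": LOC_TB}

# simulation status codes
STATUS_OK = 0
STATUS_EXSANGUINATION = 1
STATUS_NONFINITE = 2
STATUS_NEGATIVE_VOLUME = 3
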