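{
 "meta": {
  "description": "Default Purkinje-cell channel inventory: 12 channel types with per-compartment-type conductance densities. Rate coefficients transcribed from the classic 1,600-compartment Purkinje model's published kinetics (alpha-beta forms for NaF, NaP, CaP, CaT, KA; direct x_inf/tau forms for the rest). KC/K2 calcium dependence enters as a multiplicative Hill term ca/(ca+ca_half) on the activation steady state; Ca-carrying currents use a fixed Nernst-style E_Ca rather than GHK (a documented fidelity knob). Units: mV, ms, mS/cm^2, uM.",
  "rates_unit": "1/ms",
  "voltage_unit": "mV"
 },
 "calcium": {"ca_rest": 0.04, "shell_depth": 0.2, "tau_ca": 20.0},
 "channels": {
  "Leak": {
   "e_rev": -80.0,
   "g_max": {"soma": 0.1, "main": 0.1, "smooth": 0.1, "spiny": 0.53},
   "gates": []
  },
  "NaF": {
   "e_rev": 45.0,
   "g_max": {"soma": 7500.0},
   "gates": [
    {"name": "m", "exponent": 3, "kinetics": "alpha_beta",
     "alpha": {"form": "exp", "params": [35.0, -5.0, 10.0]},
     "beta":  {"form": "exp", "params": [7.0, -65.0, -20.0]}},
    {"name": "h", "exponent": 1, "kinetics": "alpha_beta",
     "alpha": {"form": "sigmoid", "params": [0.225, -80.0, 10.0]},
     "beta":  {"form": "exp", "params": [7.5, 3.0, 18.0]}}
   ]
  },
  "NaP": {
   "e_rev": 45.0,
   "g_max": {"soma": 1.0},
   "gates": [
    {"name": "m", "exponent": 3, "kinetics": "alpha_beta",
     "alpha": {"form": "sigmoid", "params": [0.2, 18.0, -16.0]},
     "beta":  {"form": "sigmoid", "params": [0.025, -58.0, 8.0]}}
   ]
  },
  "CaP": {
   "e_rev": 135.0,
   "g_max": {"main": 4.5, "smooth": 4.5, "spiny": 4.5},
   "carries_ca": true,
   "gates": [
    {"name": "m", "exponent": 1, "kinetics": "alpha_beta",
     "alpha": {"form": "sigmoid", "params": [8.5, 8.0, -12.5]},
     "beta":  {"form": "sigmoid", "params": [35.0, -74.0, 14.5]}},
    {"name": "h", "exponent": 1, "kinetics": "alpha_beta",
     "alpha": {"form": "sigmoid", "params": [0.0015, -29.0, 8.0]},
     "beta":  {"form": "sigmoid", "params": [0.0055, -23.0, -8.0]}}
   ]
  },
  "CaT": {
   "e_rev": 135.0,
   "g_max": {"soma": 0.5, "main": 0.5, "smooth": 0.5, "spiny": 0.5},
   "carries_ca": true,
   "gates": [
    {"name": "m", "exponent": 1, "kinetics": "alpha_beta",
     "alpha": {"form": "sigmoid", "params": [2.6, -21.0, -8.0]},
     "beta":  {"form": "sigmoid", "params": [0.18, -40.0, 4.0]}},
    {"name": "h", "exponent": 1, "kinetics": "alpha_beta",
     "alpha": {"form": "sigmoid", "params": [0.0025, -40.0, 8.0]},
     "beta":  {"form": "sigmoid", "params": [0.19, -50.0, -10.0]}}
   ]
  },
  "Kh1": {
   "e_rev": -30.0,
   "g_max": {"soma": 0.3},
   "gates": [
    {"name": "m", "exponent": 1, "kinetics": "direct",
     "xinf": {"form": "sigmoid", "params": [1.0, -82.0, 7.0]},
     "tau":  {"form": "constant", "params": [38.0]}}
   ]
  },
  "Kh2": {
   "e_rev": -30.0,
   "g_max": {"soma": 0.15},
   "gates": [
    {"name": "m", "exponent": 1, "kinetics": "direct",
     "xinf": {"form": "sigmoid", "params": [1.0, -82.0, 7.0]},
     "tau":  {"form": "constant", "params": [319.0]}}
   ]
  },
  "Kdr": {
   "e_rev": -85.0,
   "g_max": {"soma": 600.0, "main": 60.0},
   "gates": [
    {"name": "m", "exponent": 4, "kinetics": "direct",
     "xinf": {"form": "sigmoid", "params": [1.0, -25.0, -9.1]},
     "tau":  {"form": "gauss", "params": [0.5, 4.0, -30.0, 30.0]}},
    {"name": "h", "exponent": 1, "kinetics": "direct",
     "xinf": {"form": "sigmoid", "params": [1.0, -25.0, 4.0]},
     "tau":  {"form": "constant", "params": [400.0]}}
   ]
  },
  "KM": {
   "e_rev": -85.0,
   "g_max": {"soma": 0.04, "main": 0.01, "smooth": 0.013, "spiny": 0.013},
   "gates": [
    {"name": "m", "exponent": 1, "kinetics": "direct",
     "xinf": {"form": "sigmoid", "params": [1.0, -35.0, -10.0]},
     "tau":  {"form": "dualexp", "params": [60.6, -35.0, 40.0, 20.0]}}
   ]
  },
  "KA": {
   "e_rev": -85.0,
   "g_max": {"soma": 15.0, "main": 2.0},
   "gates": [
    {"name": "m", "exponent": 4, "kinetics": "alpha_beta",
     "alpha": {"form": "sigmoid", "params": [1.4, -27.0, -12.0]},
     "beta":  {"form": "sigmoid", "params": [0.49, -30.0, 4.0]}},
    {"name": "h", "exponent": 1, "kinetics": "alpha_beta",
     "alpha": {"form": "sigmoid", "params": [0.0175, -50.0, 8.0]},
     "beta":  {"form": "sigmoid", "params": [1.3, -13.0, -10.0]}}
   ]
  },
  "KC": {
   "e_rev": -85.0,
   "g_max": {"main": 80.0, "smooth": 80.0, "spiny": 80.0},
   "gates": [
    {"name": "m", "exponent": 1, "kinetics": "direct", "ca_half": 3.0,
     "xinf": {"form": "sigmoid", "params": [1.0, -10.0, -10.0]},
     "tau":  {"form": "constant", "params": [2.0]}}
   ]
  },
  "K2": {
   "e_rev": -85.0,
   "g_max": {"main": 0.39, "smooth": 0.39, "spiny": 0.39},
   "gates": [
    {"name": "m", "exponent": 1, "kinetics": "direct", "ca_half": 0.2,
     "xinf": {"form": "constant", "params": [1.0]},
     "tau":  {"form": "constant", "params": [20.0]}}
   ]
  }
 }
}
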