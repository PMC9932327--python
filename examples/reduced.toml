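# Reduced-scale experiment on the packaged synthetic morphology:
# a 39-compartment tree (1 soma, 2 main, 6 smooth, 30 spiny) stimulated
# along a 5-compartment spiny path at the distal tip.

[morphology]
n_main = 2
n_smooth = 6
n_spiny = 30
branching = 1

[solver]
dt = 0.005          # ms, explicit exponential-Euler
settle_time = 500.0 # ms of pre-stimulus equilibration

[stimulus]
start_id = 39       # distal spiny tip; path walks toward the soma
n_pulses = [5]
intervals = [10.0, 20.0, 30.0]   # ms
weights = [1.4, 1.6]             # nA (single pulses are subthreshold here)
mode = "ideal"

[detector]
threshold = 0.0       # mV
min_separation = 2.0  # ms
grace = 500.0         # ms after the last pulse still counted as a response

[plasticity]
a1 = 2.0              # aggressive LTD for the one-trial reversal demo
a2 = 0.0
a3 = 0.0005
tau_pre = 100.0
tau_post = 400.0
presentations = 2     # two presentations per 5,000 ms trial
cf_delay = 2.0

[output]
dir = "pcseq_out"
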