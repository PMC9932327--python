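"""Packaged reduced-scale study conditions.

The full-scale experiments (1,600-compartment morphology, 19x20x20 sweep
cubes, thousands of multi-second trials) are far beyond a desktop run.  The
presets here define the package's reduced analogue once, so every consumer
(tests, scripts, CLI examples) runs the same conditions:

* the default ~39-compartment reduced tree (1 soma, 2 main, 6 smooth,
  30 spiny in a chain) with a 5-compartment stimulation path anchored at
  the distal spiny tip;
* a weight x interval scan bracketing the spiking threshold (single pulses
  around 1.4-1.7 nA are subthreshold there, so sequence order decides);
* the tau-scan factors f in {0.1, 1, 3} over the same boundary cells;
* an LTD smoke protocol with deliberately aggressive depression (A1 = 2.0,
  tau_post = 400 ms, two presentations per trial) so that one learning
  trial visibly moves response classes at this scale.
"""

from __future__ import annotations

from .channels import load_channel_set
from .discrimination import SpikeDetectorConfig
from .morphology import Morphology, generate_reduced
from .plasticity import LearningProtocol, PlasticityParams
from .solver import SolverConfig
from .stimulation import SweepGrid

#: weight/interval scan at the spiking boundary of the reduced tree
REDUCED_N_PULSES = (5,)
REDUCED_INTERVALS = (10.0, 20.0, 30.0, 40.0, 60.0)
REDUCED_WEIGHTS = (1.4, 1.5, 1.6, 1.7)
TAU_SCAN_F = (0.1, 1.0, 3.0)


def reduced_morphology() -> Morphology:
    return generate_reduced()


def reduced_solver_config() -> SolverConfig:
    return SolverConfig(dt=0.005, settle_time=500.0)


def reduced_detector() -> SpikeDetectorConfig:
    return SpikeDetectorConfig()


def reduced_grid(m: Morphology,
                 intervals=REDUCED_INTERVALS,
                 weights=REDUCED_WEIGHTS) -> SweepGrid:
    tip = max(c.id for c in m.compartments)
    return SweepGrid(start_id=tip, n_pulses_values=REDUCED_N_PULSES,
                     interval_values=tuple(intervals),
                     weight_values=tuple(weights))


def aggressive_ltd_params() -> PlasticityParams:
    """LTD constants for the one-trial reversal smoke experiment."""
    return PlasticityParams(a1=2.0, tau_post=400.0, a3=0.0005)


def smoke_learning_protocol(sequence) -> LearningProtocol:
    return LearningProtocol(sequence=sequence, presentations=2)
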