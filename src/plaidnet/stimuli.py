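"""Grating and plaid stimulus sets, and their per-neuron input currents.

A grating of orientation theta_g injects current into each excitatory
neuron in proportion to the neuron's von Mises input tuning curve
V(theta_g, theta_i, kappa_i) = exp(kappa_i cos(theta_g - theta_i)), with
the whole input vector renormalised so the summed injected current equals
the stimulus amplitude A.  A plaid injects the linear average of its two
component gratings' tuned currents.  Inhibitory neurons receive no tuned
input.  Orientations use the doubled-angle convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .builder import PopulationLayout

__all__ = [
    "Stimulus",
    "StimulusSet",
    "DEFAULT_AMPLITUDE",
    "grating_input",
    "plaid_input",
    "stimulus_input",
    "build_stimulus_protocol",
]

#: Default total injected current (pA summed over the population), 20 pA
#: per neuron at the default 8000-neuron scale.  Chosen so that peak
#: steady-state firing rates in the nominal large-scale model fall in a
#: physiological band; response correlations are invariant to this choice
#: because the threshold-linear dynamics with beta = 0 are positively
#: homogeneous in the input.
AMPLITUDE_PER_NEURON = 20.0
DEFAULT_AMPLITUDE = AMPLITUDE_PER_NEURON * 8000

#: Default stimulus duration, ms.
DEFAULT_DURATION = 500.0


def _double(theta_true_deg: float) -> float:
    """True orientation in degrees -> doubled angle in radians."""
    return np.angle(np.exp(2j * np.deg2rad(theta_true_deg)))


@dataclass(frozen=True)
class Stimulus:
    """One visual stimulus: a grating, plaid, blank, or stimulus mixture.

    ``components`` holds 1 (grating) or 2 (plaid) orientations as doubled
    angles in radians.
    """

    kind: str                       # grating | plaid | blank | mixture
    components: tuple[float, ...] = ()
    amplitude: float = DEFAULT_AMPLITUDE
    duration: float = DEFAULT_DURATION

    def __post_init__(self) -> None:
        if self.kind == "plaid":
            if len(self.components) != 2:
                raise ValueError("a plaid needs exactly two components")
            if np.isclose(*self.components):
                raise ValueError("plaid components must be distinct")
        if self.kind == "grating" and len(self.components) != 1:
            raise ValueError("a grating needs exactly one component")
        if self.kind == "blank" and self.amplitude != 0.0:
            raise ValueError("a blank stimulus has zero amplitude")


@dataclass
class StimulusSet:
    stimuli: list[Stimulus]
    protocol: str = "custom"

    def __post_init__(self) -> None:
        if not self.stimuli:
            raise ValueError("stimulus set must be non-empty")

    def __len__(self) -> int:
        return len(self.stimuli)

    def __iter__(self):
        return iter(self.stimuli)

    @property
    def grating_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.stimuli)
                         if s.kind == "grating"], dtype=int)

    @property
    def plaid_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.stimuli)
                         if s.kind == "plaid"], dtype=int)


def _tuning(layout: PopulationLayout, theta_g: float,
            kappa=None) -> np.ndarray:
    kappa = layout.kappa if kappa is None else np.broadcast_to(
        np.asarray(kappa, dtype=float), (layout.n_neurons,))
    v = np.zeros(layout.n_neurons)
    exc = layout.excitatory
    v[exc] = np.exp(kappa[exc] * np.cos(theta_g - layout.theta[exc]))
    return v


def _normalise_to_amplitude(v: np.ndarray, A: float) -> np.ndarray:
    total = v.sum()
    if total <= 0:
        if A == 0:
            return np.zeros_like(v)
        raise ValueError("tuned input sums to zero; cannot normalise")
    return v * (A / total)


def grating_input(layout: PopulationLayout, theta_g: float, A: float,
                  kappa=None) -> np.ndarray:
    """Per-neuron injected current (pA) for a full-field grating."""
    if A < 0:
        raise ValueError("amplitude must be non-negative")
    return _normalise_to_amplitude(_tuning(layout, theta_g, kappa), A)


def plaid_input(layout: PopulationLayout, theta_g1: float, theta_g2: float,
                A: float, kappa=None) -> np.ndarray:
    """Per-neuron current for a plaid: average of the component tunings."""
    if A < 0:
        raise ValueError("amplitude must be non-negative")
    v = 0.5 * (_tuning(layout, theta_g1, kappa) +
               _tuning(layout, theta_g2, kappa))
    return _normalise_to_amplitude(v, A)


def stimulus_input(layout: PopulationLayout,
                   stimulus: Stimulus) -> np.ndarray:
    """Dispatch a :class:`Stimulus` to its input-current vector."""
    if stimulus.kind == "blank":
        return np.zeros(layout.n_neurons)
    if stimulus.kind == "grating":
        return grating_input(layout, stimulus.components[0],
                             stimulus.amplitude)
    if stimulus.kind == "plaid":
        return plaid_input(layout, *stimulus.components, stimulus.amplitude)
    raise ValueError(f"cannot build input for stimulus kind "
                     f"{stimulus.kind!r}")


def build_stimulus_protocol(name: str,
                            base_orientation: float = 0.0,
                            amplitude: float = DEFAULT_AMPLITUDE,
                            duration: float = DEFAULT_DURATION,
                            orientations=None,
                            plaid_pairs=None) -> StimulusSet:
    """Assemble a named stimulus battery.

    - ``drifting16_plaids``: 16 drift directions (22.5 deg steps) plus the
      three full plaid sets at 45/90/135 deg relative component
      orientation;
    - ``oscillating5_plaids``: 5 orientations spanning +-40 deg about the
      base orientation plus all 10 pairwise plaids;
    - ``custom``: explicit ``orientations`` (true degrees) and optional
      ``plaid_pairs`` of index tuples into that list.
    """
    stimuli: list[Stimulus] = []
    if name == "drifting16_plaids":
        directions = base_orientation + 22.5 * np.arange(16)
        for d in directions:
            stimuli.append(Stimulus("grating", (_double(d),),
                                    amplitude, duration))
        for rel in (45.0, 90.0, 135.0):
            for d in directions:
                c1, c2 = _double(d), _double(d + rel)
                stimuli.append(Stimulus("plaid", (c1, c2),
                                        amplitude, duration))
    elif name == "orientation8_plaids":
        # the orientation-space content of the 16-direction battery: in
        # an orientation-only model (doubled angles) directions d and
        # d+180 are identical stimuli and a 135-deg plaid is a 45-deg
        # plaid of another base, so the unique stimuli are 8 gratings,
        # eight 45-deg plaids and four 90-deg plaids
        oris = base_orientation + 22.5 * np.arange(8)
        for o in oris:
            stimuli.append(Stimulus("grating", (_double(o),),
                                    amplitude, duration))
        for o in oris:
            stimuli.append(Stimulus("plaid", (_double(o), _double(o + 45)),
                                    amplitude, duration))
        for o in oris[:4]:
            stimuli.append(Stimulus("plaid", (_double(o), _double(o + 90)),
                                    amplitude, duration))
    elif name == "oscillating5_plaids":
        oris = base_orientation + np.array([-40.0, -20.0, 0.0, 20.0, 40.0])
        for o in oris:
            stimuli.append(Stimulus("grating", (_double(o),),
                                    amplitude, duration))
        for o1, o2 in combinations(oris, 2):
            stimuli.append(Stimulus("plaid", (_double(o1), _double(o2)),
                                    amplitude, duration))
    elif name == "custom":
        if orientations is None:
            raise ValueError("custom protocol needs explicit orientations")
        oris = np.asarray(orientations, dtype=float)
        for o in oris:
            stimuli.append(Stimulus("grating", (_double(o),),
                                    amplitude, duration))
        for i, j in (plaid_pairs or []):
            stimuli.append(Stimulus("plaid",
                                    (_double(oris[i]), _double(oris[j])),
                                    amplitude, duration))
    else:
        raise ValueError(f"unknown protocol {name!r}")
    return StimulusSet(stimuli=stimuli, protocol=name)
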