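"""Synthetic trial-structured datasets with known ground truth.

Generates calcium-imaging-like response tables for three population
archetypes so that every analysis stage can be exercised without any
recording:

- ``component``: every neuron combines grating components identically —
  its mean plaid response is the average of its responses to the two
  component gratings.  Any pair with similar grating tuning then has
  similar plaid tuning, the regime in which the grating/plaid R-squared
  is high.
- ``feature_binding``: neurons belong to subnetworks that pair two
  protocol orientations.  The plaid matching a neuron's subnetwork is
  amplified (facilitation gain > 1, applied to the neuron's best grating
  response); all other plaids are attenuated (competition).  Pairs with
  identical grating tuning but different subnetwork membership therefore
  decorrelate on plaids.
- ``random``: plaid means are drawn independently of grating means.

Trial noise follows the variability model (Gaussian with std
sigma * rbar_max); neuropil samples are zero-mean Gaussian at the
population noise scale, which is all the responsivity filter consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import ResponseTable
from .stimuli import StimulusSet, build_stimulus_protocol
from .variability import generate_trials

__all__ = [
    "SyntheticConfig",
    "SyntheticPopulation",
    "SyntheticDataset",
    "make_population",
    "make_dataset",
    "make_synthetic_dataset",
]


@dataclass
class SyntheticConfig:
    """Ground-truth generation parameters.

    ``amplitude_sigma`` is the log-std of the lognormal peak-response
    distribution; ``facilitation_gain``/``attenuation`` only apply to the
    feature-binding rule.  Defaults give modulation indices spanning
    roughly [-0.5, 0.4].
    """

    n_neurons: int = 300
    rule: str = "component"        # component | feature_binding | random
    protocol: str = "oscillating5_plaids"
    kappa: float = 4.0
    amplitude_sigma: float = 0.35
    facilitation_gain: float = 1.5
    attenuation: float = 0.6
    loser_fraction: float = 0.35
    sigma: float = 0.3
    trials: int = 12
    neuropil_units: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ValueError("need at least two neurons")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.rule not in ("component", "feature_binding", "random"):
            raise ValueError(f"unknown rule {self.rule!r}")


@dataclass
class SyntheticPopulation:
    means: np.ndarray              # (n, n_stimuli) ground-truth responses
    stimulus_set: StimulusSet
    theta: np.ndarray              # (n,) doubled-angle preferred orientation
    subnetwork: np.ndarray         # (n,) matched-plaid index; -1 if none
    config: SyntheticConfig


@dataclass
class SyntheticDataset:
    table: ResponseTable
    population: SyntheticPopulation
    neuropil: np.ndarray           # (units, n_stimuli, trials)


def _von_mises_tuning(theta_stim: np.ndarray, theta_pref: np.ndarray,
                      kappa: float) -> np.ndarray:
    """Peak-normalised tuning: 1 at the preferred orientation."""
    return np.exp(kappa * (np.cos(theta_stim[None, :] -
                                  theta_pref[:, None]) - 1.0))


def make_population(config: SyntheticConfig) -> SyntheticPopulation:
    """Ground-truth mean responses (+ subnetwork labels) for one rule."""
    rng = np.random.default_rng(config.seed)
    stim = build_stimulus_protocol(config.protocol)
    g_idx = stim.grating_indices
    p_idx = stim.plaid_indices
    grating_oris = np.array([stim.stimuli[i].components[0] for i in g_idx])
    n = config.n_neurons
    amplitude = rng.lognormal(mean=0.0, sigma=config.amplitude_sigma,
                              size=n)

    def _nearest_grating(ori: float) -> int:
        return int(np.argmin(np.abs(np.angle(np.exp(1j * (grating_oris
                                                          - ori))))))

    # map each plaid to the indices of its component gratings
    plaid_comp = [tuple(_nearest_grating(c)
                        for c in stim.stimuli[i].components)
                  for i in p_idx]

    subnetwork = np.full(n, -1, dtype=int)
    if config.rule == "feature_binding":
        # one subnetwork per plaid combination; theta is one of the pair
        subnetwork = rng.integers(len(p_idx), size=n)
        pick = rng.integers(2, size=n)
        theta = np.array([grating_oris[plaid_comp[k][p]]
                          for k, p in zip(subnetwork, pick)])
    else:
        theta = rng.uniform(-np.pi, np.pi, size=n)

    G = amplitude[:, None] * _von_mises_tuning(grating_oris, theta,
                                               config.kappa)
    P = np.empty((n, len(p_idx)))
    for p, (i, j) in enumerate(plaid_comp):
        P[:, p] = 0.5 * (G[:, i] + G[:, j])
    if config.rule == "feature_binding":
        # winners are amplified on their subnetwork's plaid; a fraction of
        # neurons lose the inter-subnetwork competition at their site and
        # are suppressed on every plaid (negative MI)
        best_grating = G.max(axis=1)
        P *= config.attenuation
        winners = rng.random(n) >= config.loser_fraction
        rows = np.arange(n)[winners]
        P[rows, subnetwork[winners]] = (config.facilitation_gain
                                        * best_grating[winners])
    elif config.rule == "random":
        # independent plaid tuning: shuffle identities and redraw widths
        theta_p = rng.uniform(-np.pi, np.pi, size=n)
        pref = rng.integers(len(p_idx), size=n)
        shape = np.exp(config.kappa * (np.cos(
            2 * np.pi * (np.arange(len(p_idx))[None, :] - pref[:, None])
            / len(p_idx)) - 1.0))
        P = amplitude[:, None] * shape
        del theta_p

    means = np.zeros((n, len(stim)))
    means[:, g_idx] = G
    means[:, p_idx] = P
    return SyntheticPopulation(means=means, stimulus_set=stim, theta=theta,
                               subnetwork=subnetwork, config=config)


def make_dataset(population: SyntheticPopulation,
                 sigma: float | None = None,
                 T: int | None = None,
                 neuropil_units: int | None = None,
                 seed: int | None = None) -> SyntheticDataset:
    """Noisy trials plus neuropil samples for a ground-truth population.

    Arguments default to the population's config; ``seed`` defaults to a
    stream derived from the config seed so that repeated calls with
    identical arguments reproduce the dataset exactly.
    """
    cfg = population.config
    sigma = cfg.sigma if sigma is None else sigma
    T = cfg.trials if T is None else T
    units = cfg.neuropil_units if neuropil_units is None else neuropil_units
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if seed is None:
        seed = None if cfg.seed is None else cfg.seed + 1
    rng = np.random.default_rng(seed)
    stim = population.stimulus_set
    table = generate_trials(
        population.means, sigma, T=T,
        seed=int(rng.integers(2 ** 31)),
        stimulus_kinds=np.array([s.kind for s in stim]),
        stimulus_components=[s.components for s in stim])
    rmax = population.means.max(axis=1)
    scale = sigma * (np.median(rmax[rmax > 0]) if np.any(rmax > 0) else 1.0)
    neuropil = scale * rng.standard_normal((units, len(stim), T))
    return SyntheticDataset(table=table, population=population,
                            neuropil=neuropil)


def make_synthetic_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Convenience: population + dataset in one seeded call."""
    return make_dataset(make_population(config))
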