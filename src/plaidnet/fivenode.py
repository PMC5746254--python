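"""Five-node analytical model (4 excitatory + 1 inhibitory neurons).

The four excitatory neurons form two 2-neuron subnetworks; a proportion
``s`` of each excitatory neuron's output synapses is reserved for its own
subnetwork.  The inhibitory node connects non-specifically.  With total
excitatory output weight ``w_E``, total inhibitory output weight ``w_I``
and inhibitory fraction ``f_I``, the weight matrix is

    W = [[ a, a, b, b, -w_ie],
         [ a, a, b, b, -w_ie],
         [ b, b, a, a, -w_ie],
         [ b, b, a, a, -w_ie],
         [ w_ei, w_ei, w_ei, w_ei, -w_I f_I]]

with w_S = w_E (1-f_I) s, w_N = w_E (1-f_I)(1-s), a = w_S/2 + w_N/4,
b = w_N/4, w_ie = w_I (1-f_I)/4 and w_ei = w_E f_I.  All entries are
unitless gains (the I-F gain alpha is folded in), so the dynamics engine
is run with alpha = 1 and rates are reported in arbitrary units.

Stability is classified from the Jacobian J = (W - Id)/T linearised around
the all-active fixed point; the inhibition-stabilised (ISN) test removes
all inhibitory output (w_I = 0) and asks whether the purely excitatory
subsystem is unstable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ratenet import NetworkModel, NeuronParams, fixed_point

__all__ = [
    "NOMINAL_W_E",
    "NOMINAL_W_I",
    "FiveNodeConfig",
    "StabilityReport",
    "PhaseDiagram",
    "MixtureResult",
    "build_five_node_weights",
    "classify_stability",
    "competition_current",
    "phase_diagram",
    "mixture_experiment",
]

# Nominal total output weights derived from anatomical estimates for mouse
# V1 L2/3: 8142 output synapses per excitatory neuron at 0.01 pA/Hz,
# 8566 per inhibitory neuron at 0.1 pA/Hz, I-F gain 0.066 Hz/pA.
NOMINAL_W_E = 8142 * 0.01 * 0.066   # ~5.37
NOMINAL_W_I = 8566 * 0.10 * 0.066   # ~56.5

#: Winner margins below this rate difference are reported as a tie.
TIE_TOLERANCE = 1e-6


@dataclass
class FiveNodeConfig:
    """Parameters of the five-node model.

    s is the proportion of subnetwork-specific excitatory synapses in
    [0, 1]; iota the stimulus input current in pA.
    """

    w_E: float = NOMINAL_W_E
    w_I: float = NOMINAL_W_I
    f_I: float = 0.2
    s: float = 0.0
    tau: float = 10.0
    iota: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s must lie in [0, 1], got {self.s}")
        if not 0.0 < self.f_I < 1.0:
            raise ValueError(f"f_I must lie in (0, 1), got {self.f_I}")
        if self.w_E < 0 or self.w_I < 0:
            raise ValueError("w_E and w_I must be non-negative")


@dataclass
class StabilityReport:
    eigenvalues: np.ndarray        # eig(J), complex
    trace: float                   # Tr(J)
    eigenvalues_exc: np.ndarray    # eig(J^E), inhibition removed
    regime: str                    # one of "AS", "ISN", "Exp", "IO"
    stable: bool


@dataclass
class PhaseDiagram:
    axis_names: tuple[str, str]
    axis_values: tuple[np.ndarray, np.ndarray]
    regimes: np.ndarray            # (len(ax1), len(ax2)) object array of str
    competition: np.ndarray        # pA; NaN where unstable / not probed


@dataclass
class MixtureResult:
    mixture_levels: np.ndarray     # percentages, sorted
    rates: np.ndarray              # (n_levels, 5) steady-state rates
    winners: np.ndarray            # 1, 2 or 0 (tie); -1 if not converged
    converged: np.ndarray          # bool per level
    reference_response: float      # SN1 mean rate for a single component
    reference_rates: np.ndarray = field(default=None)


def build_five_node_weights(config: FiveNodeConfig) -> np.ndarray:
    """Assemble the 5x5 weight matrix from the subnetwork decomposition."""
    c = config
    w_S = c.w_E * (1 - c.f_I) * c.s
    w_N = c.w_E * (1 - c.f_I) * (1 - c.s)
    a = w_S / 2 + w_N / 4
    b = w_N / 4
    w_ie = c.w_I * (1 - c.f_I) / 4
    w_ei = c.w_E * c.f_I
    W = np.empty((5, 5))
    W[:4, :4] = b
    W[:2, :2] = a
    W[2:4, 2:4] = a
    W[:4, 4] = -w_ie
    W[4, :4] = w_ei
    W[4, 4] = -c.w_I * c.f_I
    return W


def _remove_inhibition(W: np.ndarray, inhibitory: np.ndarray) -> np.ndarray:
    WE = W.copy()
    WE[:, inhibitory] = 0.0
    return WE


def classify_stability(W: np.ndarray, tau: float | np.ndarray = 10.0,
                       inhibitory: np.ndarray | None = None,
                       tol: float = 1e-9) -> StabilityReport:
    """Eigenvalue classification of the all-active linearisation.

    Stable iff all Re(eig(J)) <= 0 and Tr(J) <= 0 with J = (W - Id)/T,
    T the post-synaptic time-constant of each row.  Regimes:

    - ``AS``: stable, and still stable with inhibition removed;
    - ``ISN``: stable, but the excitatory-only system is unstable
      (inhibition-stabilised);
    - ``Exp``: unstable with a real dominant eigenvalue (runaway);
    - ``IO``: unstable with a complex dominant pair (inhibition-driven
      oscillation).

    ``inhibitory`` marks the inhibitory columns; by default any column
    containing a negative entry is treated as inhibitory output.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"W must be square, got {W.shape}")
    n = W.shape[0]
    tau_v = np.broadcast_to(np.asarray(tau, dtype=float), (n,))
    J = (W - np.eye(n)) / tau_v[:, None]
    eig = np.linalg.eigvals(J)
    trace = float(np.trace(J))
    stable = bool(np.all(eig.real <= tol) and trace <= tol)

    if inhibitory is None:
        inhibitory = (W < 0).any(axis=0)
    JE = (_remove_inhibition(W, inhibitory) - np.eye(n)) / tau_v[:, None]
    eig_e = np.linalg.eigvals(JE)
    exc_unstable = bool(eig_e.real.max() > tol or np.trace(JE) > tol)

    if stable:
        regime = "ISN" if exc_unstable else "AS"
    else:
        dominant = eig[np.argmax(eig.real)]
        regime = "Exp" if abs(dominant.imag) <= tol else "IO"
    return StabilityReport(eigenvalues=eig, trace=trace,
                           eigenvalues_exc=eig_e, regime=regime,
                           stable=stable)


def _model(config: FiveNodeConfig) -> NetworkModel:
    W = build_five_node_weights(config)
    return NetworkModel(W, NeuronParams(tau=config.tau, alpha=1.0, beta=0.0))


def _solve(config: FiveNodeConfig, I: np.ndarray, damping: float = 0.05):
    return fixed_point(_model(config), I, tolerance=1e-12,
                       max_iterations=200_000, damping=damping)


def competition_current(config: FiveNodeConfig,
                        damping: float = 0.05) -> float:
    """Net recurrent current (pA) into an opposite-subnetwork E neuron.

    Injects ``iota`` into excitatory neuron 0 (subnetwork 1), solves the
    steady state, and returns the total recurrent synaptic current
    (excitatory plus inhibitory, excluding leak and stimulus) received by
    excitatory neuron 2 (subnetwork 2).  Negative values indicate
    competition between subnetworks.
    """
    I = np.array([config.iota, 0.0, 0.0, 0.0, 0.0])
    ss = _solve(config, I, damping=damping)
    if not ss.converged:
        regime = classify_stability(build_five_node_weights(config),
                                    config.tau).regime
        raise RuntimeError(
            f"fixed point did not converge (regime {regime}); "
            "competition is undefined at an unstable operating point")
    W = build_five_node_weights(config)
    return float(W[2] @ ss.rates)


def phase_diagram(template: FiveNodeConfig,
                  axis1: tuple[str, np.ndarray],
                  axis2: tuple[str, np.ndarray],
                  measure_competition: bool = True) -> PhaseDiagram:
    """Regime label (and competition strength where stable) on a 2-D grid.

    Axis names are FiveNodeConfig field names, typically ``w_I``/``w_E``
    (total inhibitory/excitatory output weight, i.e. g.n scaled by the I-F
    gain) or ``s``.
    """
    (name1, vals1), (name2, vals2) = axis1, axis2
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    if vals1.size == 0 or vals2.size == 0:
        raise ValueError("phase diagram grid must be non-empty")
    regimes = np.empty((vals1.size, vals2.size), dtype=object)
    comp = np.full((vals1.size, vals2.size), np.nan)
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            cfg = replace(template, **{name1: v1, name2: v2})
            rep = classify_stability(build_five_node_weights(cfg), cfg.tau)
            regimes[i, j] = rep.regime
            if measure_competition and rep.stable:
                try:
                    comp[i, j] = competition_current(cfg)
                except RuntimeError:
                    pass
    return PhaseDiagram(axis_names=(name1, name2),
                        axis_values=(vals1, vals2),
                        regimes=regimes, competition=comp)


def mixture_experiment(config: FiveNodeConfig,
                       mixture_levels=None,
                       damping: float = 0.05) -> MixtureResult:
    """Graduated stimulus mixture between the two subnetworks' ideal inputs.

    At mixture level m%, subnetwork-1 neurons receive (1 - m/100) * iota
    and subnetwork-2 neurons m/100 * iota.  The single-component reference
    is the SN1 response when only SN1 receives half input (one grating
    component of a plaid).
    """
    if mixture_levels is None:
        mixture_levels = np.linspace(0.0, 100.0, 21)
    levels = np.sort(np.asarray(mixture_levels, dtype=float))
    rates = np.zeros((levels.size, 5))
    winners = np.zeros(levels.size, dtype=int)
    conv = np.zeros(levels.size, dtype=bool)
    for idx, m in enumerate(levels):
        f = m / 100.0
        I = config.iota * np.array([1 - f, 1 - f, f, f, 0.0])
        ss = _solve(config, I, damping=damping)
        conv[idx] = ss.converged
        if not ss.converged:
            winners[idx] = -1
            rates[idx] = np.nan
            continue
        rates[idx] = ss.rates
        r1 = ss.rates[:2].mean()
        r2 = ss.rates[2:4].mean()
        if abs(r1 - r2) < TIE_TOLERANCE:
            winners[idx] = 0
        else:
            winners[idx] = 1 if r1 > r2 else 2
    I_ref = config.iota * np.array([0.5, 0.5, 0.0, 0.0, 0.0])
    ss_ref = _solve(config, I_ref, damping=damping)
    ref = float(ss_ref.rates[:2].mean()) if ss_ref.converged else np.nan
    return MixtureResult(mixture_levels=levels, rates=rates, winners=winners,
                         converged=conv, reference_response=ref,
                         reference_rates=ss_ref.rates)
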