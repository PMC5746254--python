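"""Threshold-linear rate-network dynamics.

Implements the standard rate equation for recurrently coupled
linear-threshold ("ReLU") units,

    tau_i dx_i/dt = -x_i + sum_j w_ij * alpha_j [x_j - beta_j]_+ * (g_j n_ij)
                  + I_i(t) + sigma_i zeta_i(t),

where ``x_i`` is the activation current of neuron *i* (pA), the firing rate
is ``r_i = alpha_i [x_i - beta_i]_+`` (Hz), and ``w_ij = g_j n_ij alpha_j``
is the assembled unitless gain from neuron *j* onto neuron *i*.  The noise
term is a Wiener process whose standard deviation after 1 s equals
``sigma_i``.

Two solvers are provided: a fixed-step Euler--Maruyama integrator
(:func:`simulate`) and a damped fixed-point iteration on the noise-free
nullcline ``x = W r(x) + I`` (:func:`fixed_point`).  The damped map is
contractive only when the damping constant is small relative to the most
negative eigenvalue of ``W`` (strong recurrent inhibition), hence the
conservative default damping of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "NeuronParams",
    "NetworkModel",
    "RateTrajectory",
    "SteadyState",
    "firing_rate",
    "simulate",
    "fixed_point",
]

#: Activation magnitude (pA) beyond which a trajectory is flagged divergent.
DIVERGENCE_CAP = 1.0e6


@dataclass
class NeuronParams:
    """Per-neuron cellular parameters (scalars broadcast to the population).

    Parameters
    ----------
    tau:
        Lumped time constant in ms (membrane + synaptic + firing dynamics).
    alpha:
        I-F gain in Hz/pA of the linear-threshold transfer function.
    beta:
        Activation threshold in pA; below it the neuron is silent.
    g_out:
        Current injected per output synapse, pA/Hz.  Inhibitory neurons
        carry a positive ``g_out`` here; their sign enters the assembled
        weight matrix.
    sigma_noise:
        Standard deviation (pA) of the Wiener noise current after 1 s.
    """

    tau: float | np.ndarray = 10.0
    alpha: float | np.ndarray = 0.066
    beta: float | np.ndarray = 0.0
    g_out: float | np.ndarray = 0.01
    sigma_noise: float | np.ndarray = 0.0

    def broadcast(self, n: int) -> "NeuronParams":
        """Return a copy with every field as a length-``n`` float array."""
        def _b(v):
            a = np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()
            return a

        return NeuronParams(*(_b(getattr(self, f)) for f in
                              ("tau", "alpha", "beta", "g_out", "sigma_noise")))

    def validate(self) -> None:
        if np.any(np.asarray(self.tau) <= 0):
            raise ValueError("tau must be positive")
        if np.any(np.asarray(self.alpha) < 0):
            raise ValueError("alpha must be non-negative")


@dataclass
class NetworkModel:
    """A weighted threshold-linear network.

    ``weights`` holds the unitless gains ``w_ij`` (dense ndarray or scipy
    sparse matrix); row = postsynaptic target, column = presynaptic source.
    """

    weights: np.ndarray | sparse.spmatrix
    params: NeuronParams = field(default_factory=NeuronParams)

    def __post_init__(self) -> None:
        w = self.weights
        if w.shape[0] != w.shape[1]:
            raise ValueError(f"weight matrix must be square, got {w.shape}")
        if sparse.issparse(w):
            if not np.all(np.isfinite(w.data)):
                raise ValueError("weights contain non-finite entries")
        elif not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite entries")
        self.params = self.params.broadcast(self.n_neurons)
        self.params.validate()

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Firing rates (Hz) for activations ``x`` (pA)."""
        return firing_rate(x, self.params.alpha, self.params.beta)


@dataclass
class RateTrajectory:
    times: np.ndarray          # ms
    activations: np.ndarray    # (n_steps+1, n) pA
    rates: np.ndarray          # (n_steps+1, n) Hz
    diverged: bool


@dataclass
class SteadyState:
    activations: np.ndarray    # pA
    rates: np.ndarray          # Hz
    converged: bool
    residual: float            # max |dx/dt| proxy: max |W r + I - x|
    diverged: bool = False


def firing_rate(activation, alpha, beta):
    """Linear-threshold I-F relation ``alpha * max(0, x - beta)``.

    Accepts scalars or arrays; raises on non-finite activations.
    """
    x = np.asarray(activation, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite activation current")
    return np.asarray(alpha) * np.maximum(0.0, x - np.asarray(beta))


def _input_at(input_currents, step: int, n: int) -> np.ndarray:
    """Resolve constant / time-indexed / callable input to a step vector."""
    if callable(input_currents):
        out = np.asarray(input_currents(step), dtype=float)
    else:
        arr = np.asarray(input_currents, dtype=float)
        out = arr[step] if arr.ndim == 2 else arr
    if out.shape != (n,):
        raise ValueError(f"input current shape {out.shape} does not match "
                         f"network size {n}")
    return out


def simulate(model: NetworkModel, input_currents, duration: float,
             dt: float = 1.0, seed: int | None = None,
             x0: np.ndarray | None = None,
             cap: float = DIVERGENCE_CAP) -> RateTrajectory:
    """Euler--Maruyama integration of the rate dynamics.

    Parameters
    ----------
    input_currents:
        Constant per-neuron vector (n,), a time-indexed array
        (n_steps+1, n), or a callable ``f(step) -> (n,)`` in pA.
    duration, dt:
        Simulation horizon and step, in ms.  ``dt`` must not exceed
        ``min(tau)/5`` for reasonable accuracy of the explicit scheme.
    seed:
        Seeds the per-step Wiener increments; runs are bit-reproducible.

    The per-step noise increment has standard deviation
    ``sigma_noise * sqrt(dt / 1000)`` so that the accumulated noise reaches
    ``sigma_noise`` pA after one second, matching the Wiener specification.
    """
    n = model.n_neurons
    p = model.params
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > np.min(p.tau) / 5.0:
        raise ValueError(f"dt={dt} too large: must be <= min(tau)/5 "
                         f"= {np.min(p.tau) / 5.0}")
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    x = np.zeros(n) if x0 is None else np.array(x0, dtype=float)
    xs = np.empty((n_steps + 1, n))
    xs[0] = x
    rng = np.random.default_rng(seed)
    noisy = np.any(p.sigma_noise > 0)
    noise_std = p.sigma_noise * np.sqrt(dt / 1000.0)
    W = model.weights
    diverged = False
    for k in range(n_steps):
        I = _input_at(input_currents, k, n)
        r = firing_rate(x, p.alpha, p.beta)
        drive = W @ r
        x = x + (dt / p.tau) * (-x + drive + I)
        if noisy:
            x = x + noise_std * rng.standard_normal(n)
        if np.max(np.abs(x)) > cap:
            diverged = True
            xs[k + 1:] = x
            break
        xs[k + 1] = x
    rates = np.maximum(0.0, xs - p.beta) * p.alpha
    return RateTrajectory(times=times, activations=xs, rates=rates,
                          diverged=diverged)


def fixed_point(model: NetworkModel, constant_input, tolerance: float = 1e-9,
                max_iterations: int = 100_000, damping: float = 0.05,
                x0: np.ndarray | None = None,
                polish: bool = True,
                cap: float = DIVERGENCE_CAP) -> SteadyState:
    """Noise-free steady state of the nullcline ``x = W r(x) + I``.

    Damped iteration ``x <- (1-d) x + d (W r(x) + I)``; equivalent to Euler
    integration with step ``d * tau``.  After convergence of the active set,
    an optional exact linear solve on that set polishes the solution to
    machine precision (skipped if it disagrees with the iterate, which can
    happen on marginally stable partitions).

    Returns ``converged=False`` (with ``diverged=True`` when the activation
    cap was exceeded) if the residual criterion is not met; this signals an
    unstable or oscillatory regime rather than raising.
    """
    n = model.n_neurons
    p = model.params
    I = np.asarray(constant_input, dtype=float)
    if I.shape != (n,):
        raise ValueError(f"input shape {I.shape} does not match network {n}")
    if not np.all(np.isfinite(I)):
        raise ValueError("constant input must be finite")
    W = model.weights
    x = np.zeros(n) if x0 is None else np.array(x0, dtype=float)
    converged = False
    diverged = False
    residual = np.inf
    for _ in range(max_iterations):
        target = W @ firing_rate(x, p.alpha, p.beta) + I
        residual = float(np.max(np.abs(target - x)))
        if residual <= tolerance:
            converged = True
            x = target
            break
        x = (1.0 - damping) * x + damping * target
        if np.max(np.abs(x)) > cap:
            diverged = True
            break
    if converged and polish:
        polished = _polish_active_set(W, p, I, x, cap)
        if polished is not None:
            x = polished
    r = firing_rate(x if np.all(np.isfinite(x)) else np.zeros(n),
                    p.alpha, p.beta)
    return SteadyState(activations=x, rates=r, converged=converged,
                       residual=residual, diverged=diverged)


def _polish_active_set(W, p, I, x, cap):
    """Exact solve of (I - W A diag(alpha)) x = I_ext - W A' on the active set.

    With beta = 0 this reduces to (Id - W diag(alpha * active)) x = I_ext.
    Returns None if the solve fails or changes the active partition.
    """
    active = (x - p.beta) > 0
    scale = p.alpha * active
    n = len(x)
    rhs = I - W @ (scale * p.beta)
    try:
        if sparse.issparse(W):
            A = sparse.eye(n, format="csc") - (W.tocsc() @
                                               sparse.diags(scale)).tocsc()
            sol = sparse.linalg.spsolve(A, rhs)
        else:
            A = np.eye(n) - W * scale[None, :]
            sol = np.linalg.solve(A, rhs)
    except Exception:
        return None
    if not np.all(np.isfinite(sol)) or np.max(np.abs(sol)) > cap:
        return None
    if np.array_equal((sol - p.beta) > 0, active):
        return sol
    return None
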