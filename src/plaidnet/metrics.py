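"""Response statistics for trial-structured grating/plaid data.

The central container is :class:`ResponseTable`: scalar responses (model
rates or dF/F-like amplitudes) indexed by neuron x stimulus x trial,
together with the stimulus metadata needed to split gratings from plaids.
On top of it this module computes the selectivity indices

    OSI = (max R_g - min R_g) / sum(R_g)
    PSI = 1 - (-1 + sum_j R_p,j / max R_p) / (#R_p - 1)
    MI  = (max R_p - max R_g) / (max R_p + max R_g)

pairwise grating/plaid signal correlations (rho_g, rho_p), the squared
correlation between them across pairs (the headline decorrelation
statistic), facilitation/suppression classification with an exact 2 x k
Fisher test, a neuropil-based responsivity filter, receptive-field centre
estimation from a response-weighted Gaussian mixture, and masked
movie-trace signal correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .stimuli import StimulusSet

__all__ = [
    "ResponseTable",
    "PairCorrelations",
    "ModulationSummary",
    "osi",
    "psi",
    "modulation_index",
    "pairwise_correlations",
    "grating_plaid_r2",
    "classify_modulation",
    "fisher_compare",
    "responsivity_filter",
    "estimate_rf_centre",
    "movie_signal_correlation",
]


@dataclass
class ResponseTable:
    """Neuron x stimulus x trial scalar responses plus stimulus metadata.

    ``stimulus_kinds`` marks each stimulus as ``grating``/``plaid``/...;
    trial means and the per-neuron maximum trial-averaged response are
    derived properties.
    """

    responses: np.ndarray               # (n_neurons, n_stimuli, n_trials)
    stimulus_kinds: np.ndarray          # (n_stimuli,) str
    stimulus_components: list = field(default_factory=list)

    def __post_init__(self) -> None:
        r = np.asarray(self.responses, dtype=float)
        if r.ndim != 3:
            raise ValueError("responses must be 3-D "
                             "(neuron, stimulus, trial)")
        self.responses = r
        self.stimulus_kinds = np.asarray(self.stimulus_kinds)
        if self.stimulus_kinds.shape[0] != r.shape[1]:
            raise ValueError("one stimulus kind per stimulus required")

    @classmethod
    def from_means(cls, means: np.ndarray,
                   stimulus_set: StimulusSet) -> "ResponseTable":
        """Single-'trial' table holding noiseless mean responses."""
        means = np.asarray(means, dtype=float)
        return cls(means[:, :, None],
                   np.array([s.kind for s in stimulus_set]),
                   [s.components for s in stimulus_set])

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.responses.shape[1]

    @property
    def n_trials(self) -> int:
        return self.responses.shape[2]

    @property
    def trial_means(self) -> np.ndarray:
        return self.responses.mean(axis=2)

    @property
    def r_max(self) -> np.ndarray:
        """Maximum trial-averaged response per neuron."""
        return self.trial_means.max(axis=1)

    @property
    def grating_mask(self) -> np.ndarray:
        return self.stimulus_kinds == "grating"

    @property
    def plaid_mask(self) -> np.ndarray:
        return self.stimulus_kinds == "plaid"

    def grating_means(self) -> np.ndarray:
        return self.trial_means[:, self.grating_mask]

    def plaid_means(self) -> np.ndarray:
        return self.trial_means[:, self.plaid_mask]

    def to_frame(self) -> pd.DataFrame:
        """Tidy view: neuron_id, stimulus_id, trial, response."""
        n, s, t = self.responses.shape
        idx = np.indices((n, s, t)).reshape(3, -1)
        return pd.DataFrame({
            "neuron_id": idx[0], "stimulus_id": idx[1], "trial": idx[2],
            "response": self.responses.ravel(),
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   stimulus_kinds) -> "ResponseTable":
        pivot = frame.pivot_table(index="neuron_id", columns=["stimulus_id",
                                                              "trial"],
                                  values="response", sort=True)
        n = pivot.shape[0]
        s = frame["stimulus_id"].nunique()
        t = frame["trial"].nunique()
        return cls(pivot.to_numpy().reshape(n, s, t),
                   np.asarray(stimulus_kinds))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PairCorrelations:
    pairs: np.ndarray        # (n_pairs, 2) neuron indices, i < j
    rho_g: np.ndarray        # (n_pairs,)
    rho_p: np.ndarray        # (n_pairs,)
    neuron_osi: np.ndarray   # (n_neurons,) OSI per neuron (NaN if undefined)
    excluded: np.ndarray     # neurons dropped for zero-variance tuning


@dataclass
class ModulationSummary:
    n_facilitating: int
    n_suppressing: int
    n_nonmodulated: int
    threshold: float = 0.05

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.n_facilitating, self.n_suppressing,
                         self.n_nonmodulated])

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


def osi(grating_responses) -> float:
    """Orientation selectivity index (max-min)/sum on trial means."""
    r = np.asarray(grating_responses, dtype=float)
    if r.size < 2:
        raise ValueError("OSI needs at least two grating responses")
    if np.any(r < 0):
        raise ValueError("OSI is defined for non-negative responses")
    total = r.sum()
    if total == 0:
        return np.nan
    return float((r.max() - r.min()) / total)


def psi(plaid_responses) -> float:
    """Plaid selectivity index; 1 = single-plaid responder, 0 = uniform."""
    r = np.asarray(plaid_responses, dtype=float)
    if r.size < 2:
        raise ValueError("PSI needs at least two plaid responses")
    if np.any(r < 0):
        raise ValueError("PSI is defined for non-negative responses")
    m = r.max()
    if m == 0:
        return np.nan
    return float(1.0 - (-1.0 + r.sum() / m) / (r.size - 1))


def modulation_index(grating_responses, plaid_responses) -> float:
    """Facilitation (+) or suppression (-) of peak plaid vs peak grating."""
    rg = np.asarray(grating_responses, dtype=float)
    rp = np.asarray(plaid_responses, dtype=float)
    mg, mp = rg.max(), rp.max()
    if mg + mp == 0:
        return np.nan
    return float((mp - mg) / (mp + mg))


def _correlation_matrix(vectors: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; rows with zero variance give NaN."""
    v = vectors - vectors.mean(axis=1, keepdims=True)
    sd = np.sqrt((v ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        u = v / sd[:, None]
        c = u @ u.T
    c[sd == 0, :] = np.nan
    c[:, sd == 0] = np.nan
    return np.clip(c, -1.0, 1.0)


def pairwise_correlations(table: ResponseTable,
                          scope: np.ndarray | None = None
                          ) -> PairCorrelations:
    """rho_g and rho_p for every unordered neuron pair within ``scope``.

    Correlations are computed on trial-averaged tuning vectors.  Neurons
    whose grating or plaid vector has zero variance are excluded (their
    Pearson correlation is undefined).
    """
    if table.grating_mask.sum() < 2 or table.plaid_mask.sum() < 2:
        raise ValueError("need at least two grating and two plaid stimuli")
    idx = (np.arange(table.n_neurons) if scope is None
           else np.asarray(scope, dtype=int))
    G = table.grating_means()[idx]
    P = table.plaid_means()[idx]
    cg = _correlation_matrix(G)
    cp = _correlation_matrix(P)
    valid = ~(np.isnan(np.diagonal(cg)) | np.isnan(np.diagonal(cp)))
    keep = np.where(valid)[0]
    iu = np.triu_indices(len(keep), k=1)
    pairs = np.column_stack([idx[keep[iu[0]]], idx[keep[iu[1]]]])
    osi_all = np.full(table.n_neurons, np.nan)
    for local, neuron in zip(keep, idx[keep]):
        # dF/F-like trial means may dip below zero; the selectivity index
        # is taken on the rectified tuning curve
        osi_all[neuron] = osi(np.maximum(G[local], 0.0))
    return PairCorrelations(
        pairs=pairs,
        rho_g=cg[np.ix_(keep, keep)][iu],
        rho_p=cp[np.ix_(keep, keep)][iu],
        neuron_osi=osi_all,
        excluded=idx[~valid],
    )


def grating_plaid_r2(pairs: PairCorrelations,
                     osi_threshold: float = 0.3) -> float:
    """Squared Pearson correlation between rho_g and rho_p across pairs.

    Restricted to pairs in which both neurons exceed ``osi_threshold``.
    For simple regression with intercept this equals the R-squared of the
    fitted line through the (rho_g, rho_p) cloud.
    """
    o = pairs.neuron_osi
    keep = ((o[pairs.pairs[:, 0]] > osi_threshold) &
            (o[pairs.pairs[:, 1]] > osi_threshold) &
            np.isfinite(pairs.rho_g) & np.isfinite(pairs.rho_p))
    if keep.sum() < 3:
        raise ValueError(f"only {int(keep.sum())} pairs survive the OSI "
                         "filter; need at least 3")
    r = np.corrcoef(pairs.rho_g[keep], pairs.rho_p[keep])[0, 1]
    return float(r ** 2)


def classify_modulation(mis, threshold: float = 0.05) -> ModulationSummary:
    """Count facilitating (MI > t), suppressing (MI < -t), non-modulated."""
    mi = np.asarray(mis, dtype=float)
    mi = mi[np.isfinite(mi)]
    if mi.size == 0:
        raise ValueError("no finite modulation indices to classify")
    return ModulationSummary(
        n_facilitating=int((mi > threshold).sum()),
        n_suppressing=int((mi < -threshold).sum()),
        n_nonmodulated=int(((mi >= -threshold) & (mi <= threshold)).sum()),
        threshold=threshold,
    )


def _log_table_prob(cells: np.ndarray, row_sums, col_sums, n) -> float:
    return (gammaln(np.asarray(row_sums) + 1).sum()
            + gammaln(np.asarray(col_sums) + 1).sum()
            - gammaln(n + 1)
            - gammaln(cells + 1).sum())


def fisher_compare(summary_a: ModulationSummary,
                   summary_b: ModulationSummary) -> float:
    """Two-tailed exact test on the 2 x 3 modulation contingency table.

    Conditional on the margins, the probability of a table is the
    generalised hypergeometric mass; the two-tailed p-value sums the mass
    of every table no more probable than the observed one
    (Fisher-Freeman-Halton).  Exact enumeration is feasible because only
    two cells are free in a 2 x 3 table.
    """
    obs = np.array([summary_a.counts, summary_b.counts])
    return _exact_fisher_2xk(obs)


def _exact_fisher_2xk(obs: np.ndarray) -> float:
    obs = np.asarray(obs, dtype=int)
    if obs.shape[0] != 2:
        raise ValueError("contingency table must have two rows")
    if (obs.sum(axis=1) == 0).any() or obs.sum() == 0:
        raise ValueError("empty group: p-value undefined")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    k = obs.shape[1]
    log_obs = _log_table_prob(obs, row, col, n)
    # enumerate first row (second row fixed by column margins)
    total = 0.0
    stack = [(np.zeros(k, dtype=int), 0, 0)]
    while stack:
        partial, j, used = stack.pop()
        if j == k - 1:
            last = row[0] - used
            if 0 <= last <= col[-1]:
                cells = partial.copy()
                cells[-1] = last
                table = np.array([cells, col - cells])
                if (table >= 0).all():
                    lp = _log_table_prob(table, row, col, n)
                    if lp <= log_obs + 1e-9:
                        total += np.exp(lp)
            continue
        for v in range(min(col[j], row[0] - used) + 1):
            nxt = partial.copy()
            nxt[j] = v
            stack.append((nxt, j + 1, used + v))
    return float(min(total, 1.0))


def responsivity_filter(table: ResponseTable, neuropil_samples,
                        alpha: float = 0.01) -> np.ndarray:
    """Inclusion mask: responds above neuropil, reliably, at best stimulus.

    ``z_trial`` is the (1-alpha) quantile of neuropil single-presentation
    responses; ``z_max`` the analogous quantile of per-unit maximum
    trial-averaged neuropil responses (when 3-D neuropil samples are
    given; for a flat sample both thresholds use the same distribution).
    A neuron is included iff its maximum trial-averaged response exceeds
    ``z_max`` and more than half of its trials at that stimulus exceed
    ``z_trial``.
    """
    if table.n_trials < 2:
        raise ValueError("responsivity filtering needs >= 2 trials")
    np_samples = np.asarray(neuropil_samples, dtype=float)
    if np_samples.size == 0:
        raise ValueError("neuropil sample set is empty")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    q = 1.0 - alpha
    z_trial = np.quantile(np_samples.ravel(), q)
    if np_samples.ndim == 3:
        unit_max = np_samples.mean(axis=2).max(axis=1)
        z_max = np.quantile(unit_max, q)
    else:
        z_max = z_trial
    means = table.trial_means
    best = means.argmax(axis=1)
    rows = np.arange(table.n_neurons)
    reliable = ((table.responses[rows, best] > z_trial).sum(axis=1)
                > table.n_trials / 2)
    return (means[rows, best] > z_max) & reliable


def estimate_rf_centre(grid_responses, grid_x, grid_y,
                       sigma: float = 7.5,
                       resolution: float = 0.1) -> tuple[float, float]:
    """Receptive-field centre from a response-weighted Gaussian mixture.

    A circular Gaussian (dispersion ``sigma``, visual degrees) is placed
    at each stimulus grid location, weighted by the response there; the
    centre is the argmax of the mixture on a dense evaluation grid with
    the requested resolution (grid midpoints are always included).
    """
    w = np.asarray(grid_responses, dtype=float).ravel()
    gx = np.asarray(grid_x, dtype=float).ravel()
    gy = np.asarray(grid_y, dtype=float).ravel()
    if w.size != gx.size or w.size != gy.size:
        raise ValueError("responses and grid coordinates differ in length")
    if np.all(w <= 0):
        raise ValueError("all responses non-positive: centre undefined")
    def _axis(vals):
        lo, hi = vals.min(), vals.max()
        n = max(2, int(round((hi - lo) / resolution)) + 1)
        if n % 2 == 0:        # force odd count so the midpoint is on-grid
            n += 1
        return np.linspace(lo, hi, n)
    xs = _axis(gx)
    ys = _axis(gy)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    d2 = ((pts[:, None, :] -
           np.stack([gx, gy], axis=1)[None, :, :]) ** 2).sum(axis=2)
    mix = (w[None, :] * np.exp(-d2 / (2 * sigma ** 2))).sum(axis=1)
    best = int(np.argmax(mix))
    return float(pts[best, 0]), float(pts[best, 1])


def movie_signal_correlation(trace_a, trace_b, segment_onsets,
                             exclusion: float = 1.0,
                             dt: float = 1.0) -> float:
    """Pearson correlation of trial-averaged traces, onset windows removed.

    ``segment_onsets`` are sample times (same unit as ``exclusion``;
    seconds by default, with ``dt`` the sample spacing) whose following
    ``exclusion`` window is dropped before correlating.
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("traces differ in length")
    t = np.arange(a.size) * dt
    keep = np.ones(a.size, dtype=bool)
    for onset in np.atleast_1d(segment_onsets):
        keep &= ~((t >= onset) & (t < onset + exclusion))
    if keep.sum() < 2:
        raise ValueError("fewer than two samples retained")
    return float(np.corrcoef(a[keep], b[keep])[0, 1])
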