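# Methods

## Model

All neurons are rate-coded linear-threshold units. The activation current
`x_i` (pA) of neuron *i* obeys

    tau_i dx_i/dt = -x_i + sum_j g_j n_ij alpha_j [x_j - beta_j]_+
                    + I_i(t) + sigma_i zeta_i(t)

with firing rate `r_i = alpha_i [x_i - beta_i]_+` (Hz). `g_j` is the
current injected per output synapse (pA/Hz), `n_ij` the synapse count from
*j* to *i*, and `alpha_j` the I–F gain, so `w_ij = g_j n_ij alpha_j` is a
unitless gain. The noise term is a Wiener process whose standard deviation
reaches `sigma_i` after 1 s; the Euler–Maruyama integrator adds per-step
increments of std `sigma_i sqrt(dt/1000 ms)`.

Nominal cellular parameters: `tau = 10 ms`, `alpha = 0.066 Hz/pA`,
`beta = 0`, `g = 0.01 pA/Hz` per excitatory synapse and 10x that per
inhibitory synapse. The nominal noise parameter is listed in the source
material as 5 mA, which is seven orders of magnitude above the pA scale of
every other current in the model and is treated as a units typo; noise
amplitude is therefore a free configuration parameter with default 0
(stimulus-response statistics are computed from noise-free steady states,
with response variability added by the explicit trial-noise model below).

Because `beta = 0`, the network map `I -> x*` is positively homogeneous:
scaling the stimulus scales all steady-state rates, and every correlation
statistic below is invariant to the overall input amplitude. The default
amplitude (20 pA per neuron of total injected current) merely places peak
rates in a plausible range.

## Five-node analytical model

Four excitatory neurons form two subnetworks of two, plus one inhibitory
neuron; a proportion `s` of excitatory output is reserved for the own
subnetwork (weight matrix in `fivenode.build_five_node_weights`). Total
output weights default to the anatomical derivation
`w_E = 8142 x 0.01 x 0.066 ~ 5.37` and `w_I = 8566 x 0.1 x 0.066 ~ 56.5`
(these are not printed anywhere as totals; the derivation is the package's
own and both values are overridable).

Stability is classified from the Jacobian `J = (W - Id)/T` of the
all-active linearisation: stable iff all eigenvalue real parts and the
trace are non-positive. The inhibition-stabilised (ISN) test removes all
inhibitory output and requires the remaining excitatory system to be
unstable. Unstable systems are labelled `Exp` (real dominant eigenvalue)
or `IO` (complex dominant pair).

A caveat discovered during implementation: with equal time constants the
Eq-2 weight family *cannot* produce an `IO` label — the complexity
condition for the uniform E/I mode reduces to `(4 w_E - w_I)^2 < 0`. The
oscillatory regime appears as soon as inhibition is slower than
excitation (e.g. `tau_I = 50 ms` at nominal weights), which is why
`classify_stability` accepts per-neuron time constants. Phase diagrams
computed with equal time constants therefore show AS/ISN/Exp only.

Competition is measured by injecting `iota = 1 pA` into one excitatory
neuron, solving the fixed point, and reading the net recurrent synaptic
current (excitatory plus inhibitory, excluding leak and stimulus) into an
excitatory neuron of the opposite subnetwork; negative means competition.
At nominal weights the net current is +0.13 pA at `s = 0`, turns negative
between `s = 0.05` and `s = 0.1`, reaches −0.32 pA at `s = 0.2`, and the
all-active point destabilises near `s = 0.25` (winner-take-all).

## Fixed-point solver

Steady states solve `x = W r(x) + I` by damped iteration
`x <- (1-d) x + d (W r(x) + I)`. The damped map is contractive only when
`d < 2 Re(1-mu)/|1-mu|^2` for every eigenvalue `mu` of `W` on the active
set; strong recurrent inhibition puts an eigenvalue near −11 in the
five-node model, so the default damping is 0.05 (a damping of 0.5
diverges). For large sparse networks the damping is derived from the
extreme eigenvalues at run time, and the iteration is accelerated by an
exact GMRES solve on the active set whenever the rectification pattern has
nearly settled — winner-take-all transitions otherwise converge slowly
(active-set eigenvalues close to 1). A plain active-set policy iteration
was rejected because it cycles in the winner-take-all regime.

## Large-scale model

80,000 neurons (18% inhibitory) on a 2.2 x 2.2 mm torus is the reference
scale; the package's standard experiment uses 8,000 neurons on a
proportionally shrunken torus (~0.70 mm side) that preserves areal
density, with the same `density_factor = 0.1` synapse scaling as the
reference model (output budgets 814 excitatory / 857 inhibitory synapses,
per-synapse strength x10 so each neuron's total output conductance is
preserved). Axonal/dendritic fields are periodised (heat-kernel) Gaussians
on the torus (`rho_d = 75 um`; `rho_a = 290 um` excitatory, `100 um`
inhibitory); the axo-dendritic overlap integral then has an exact
separable closed form, a Gaussian of inter-soma offset with variance
`rho_d^2 + rho_a^2` summed over periodic images.

Connectivity rules (per excitatory source; inhibitory sources always wire
by pure Peters' rule):

- random: `p = [[overlap]]` (normalised over targets, no self-connections);
- like-to-like: `p = (1-s1) [[overlap]] + s1 [[overlap * exp(kappa1
  cos(theta_i - theta_j))]]`;
- feature-binding: `p = (1-s2) p_like + s2 [[overlap * b_same]]`, where
  `b_same = 1` iff source and target belong to the same subnetwork.

`[[.]]` denotes normalisation to a probability distribution over targets.
The specificity parameters are interpreted as mixture weights over
normalised distributions — i.e. `s1`/`s2` are the expected *proportions of
synapses* drawn from the specific distributions. (Multiplying the Peters
term by a normalised von Mises term *inside* a single distribution, as a
literal reading of the printed formula suggests, makes the orientation
term O(1/N) relative to the non-specific term and the rule
indistinguishable from Peters' rule at any `s1`.) Orientations are stored
as doubled angles so that orthogonal preferred orientations give
`cos = -1`. The specific factors are undefined for inhibitory targets
(no preferred orientation); they receive the Peters-weighted population
average factor, which keeps E->I untuned and the expected E->E/E->I
output split identical across the three rules.

Subnetwork compositions follow the filtered-noise construction: for each
of `N_S = 6` subnetworks and `theta = 2` components, unit-magnitude
complex numbers with uniform angles are placed at every neuron position,
smoothed by Gaussian-weighted summation (`rho = 75 um`) over the torus,
and read out as component orientations at each neuron position. Neurons
join the subnetwork whose local components best match their preferred
orientation (von Mises similarity, `kappa2 = 4`, max over the two
components).

Parameter presets: random `s1 = s2 = 0`; like-to-like `s1 = 0.8,
kappa1 = 0.5`; feature-binding `s1 = 0.1, s2 = 0.25, kappa1 = 0.5,
kappa2 = 4` (default), with the alternative parameterisation fitted to
paired-recording data (`s1 = 0.45, s2 = 0.225`) available as
`feature_binding_methods`. In measurements at the 8,000-neuron scale only
the default preset produces strong grating/plaid decorrelation; the
fitted preset's strong like-to-like component keeps grating and plaid
responses aligned (R^2 ~ 0.8).

## Stimuli

A grating injects current into each excitatory neuron proportional to its
von Mises input tuning `exp(kappa cos(theta_g - theta_i))` (`kappa = 4`,
doubled angles), renormalised so the population total equals the stimulus
amplitude; a plaid injects the average of its two components' currents.
Inhibitory neurons receive no tuned input. Two named batteries:
`drifting16_plaids` (16 directions plus full plaid sets at 45/90/135 deg
relative orientation, 64 stimuli) and `oscillating5_plaids` (5
orientations spanning +-40 deg plus all 10 pairwise plaids, 15 stimuli).

The decorrelation experiment uses the full-circle battery. This is a
substantive choice: at the 8,000-neuron scale the +-40 deg battery cannot
expose feature-binding decorrelation, because every stimulus contains
orientations from one narrow band and the single subnetwork whose
components happen to fall in that band wins the recurrent competition for
every stimulus (measured: one subnetwork fully active for 13 of 15
stimuli). The full-circle battery distributes wins across subnetworks and
reproduces the expected contrast between rules.

Because the model is orientation- (not direction-) selective under the
doubled-angle convention, the 16-direction battery contains each stimulus
twice (directions d and d+180 inject identical currents) and the 45- and
135-deg plaid sets coincide in orientation space. The pipeline therefore
solves the deduplicated `orientation8_plaids` battery (8 gratings, eight
45-deg plaids, four 90-deg plaids). Tuning-vector correlations are
invariant to exact duplicates, but OSI computed over a duplicated grating
vector would be halved and starve the OSI > 0.3 pair filter; the
deduplicated battery measures OSI over unique orientations.

## Trial variability and response filtering

Model steady-state responses are treated as trial means; single trials
are `r_ij = rbar_i + N(0, sigma_hat * rbar_max)` with `T = 12` trials
(no clipping at zero — dF/F-like values may be negative). The canonical
noise level is `sigma_hat = 0.3`, a typical normalised single-trial
standard deviation for calcium-imaging responses; the source recordings
needed to estimate it directly are not available. `estimate_variability`
implements the printed pooled estimator (which conflates tuning spread
with trial noise) and, behind `residual=True`, the residual estimator
with a T/(T−1) correction that exactly inverts the generator — the
parameter-recovery tests use the latter.

The responsivity filter uses a synthetic neuropil stand-in: zero-mean
Gaussian samples at the population noise scale (`sigma_hat` times the
median peak response). `z_trial` is the 99th percentile of single
presentations, `z_max` of per-unit maximum trial means; a neuron is kept
iff its best mean response exceeds `z_max` and more than half its trials
at the best stimulus exceed `z_trial`. Pair statistics (`rho_g`, `rho_p`
and their squared correlation over pairs) are computed over at most 800
included neurons (pair counts grow quadratically; the subsample is
seeded).

## Synthetic ground-truth data

`synthetic` builds trial-structured datasets with known structure:
component populations (plaid mean = average of component grating means —
so no facilitation by construction), feature-binding populations
(subnetworks pair two protocol orientations; winners' matched plaid is
amplified by `gain = 1.5` applied to the best grating response, all other
plaids attenuated x0.6, and a 35% loser fraction is attenuated on every
plaid, spreading the modulation index over roughly [-0.45, 0.2]), and
random populations (plaid tuning independent of grating tuning).
Amplitudes are lognormal (log-std 0.35). These datasets emulate the
trial-to-trial statistics of imaging data but not temporal dynamics,
neuropil contamination, or correlated noise; passing tests on them
validates the analysis chain and the qualitative rule contrasts, not
quantitative agreement with any recording.

## Problem sizes and numerical defaults

The standard experiment and the acceptance script use 8,000-neuron
networks, `density_factor = 0.1`, the deduplicated 20-stimulus
full-circle battery, `sigma_hat = 0.3`, `T = 12`, up to 800 analysed
neurons, and 20-sample bootstrap controls at 200 neurons; the five-node
analyses are exact to solver tolerance (1e-12). The feature-binding R^2
is reported as the median over three independently wired networks
(measured wiring-seed spread 0.00-0.38 at this scale, against < 0.01 for
the other two rules), a lower-variance estimator of the same
reduced-scale quantity. Steady-state tolerance for large networks is
`1e-6` x the mean per-neuron input (measured end-to-end deviation below
1e-6 relative against a 100x tighter solve). The 80,000-neuron reference scale is
supported by the same code path.

## Known limitations

- The `IO` phase-diagram band requires slower inhibitory dynamics (see
  above); with the stated equal time constants it provably cannot occur.
- The printed 68%/27%/5% synapse decomposition of the feature-binding
  model is not reproducible from either parameter preset under any
  mixture algebra we could construct; the mixture-of-normalised-
  distributions interpretation yields 67.5% non-specific for the default
  preset but different like-to-like/binding shares.
- Reduced scale (8,000 neurons, ~0.7 mm torus) supports only a handful of
  independent winner-take-all domains; rule contrasts are robust under
  the full-circle battery but narrow-band batteries degenerate (see
  Stimuli).
- With the reference 75-um composition-field smoothing, the shrunken
  torus holds so few independent composition domains that roughly one
  draw in three produces subnetworks covering orientation space poorly,
  and the binding rule degenerates towards like-to-like (pipeline R^2
  spread 0.04-0.96 over nine networks). The pipeline therefore scales
  the composition-field correlation length with the torus
  (75 um x side / 2.2 mm), a parameter-free rule that preserves the
  reference model's number of independent composition domains; the
  feature-binding R^2 then spans 0.00-0.21 over six wiring seeds, and
  the like-to-like and random R^2 vary by under +-0.01 throughout.
  `generate_subnetwork_fields` keeps the 75-um default for
  reference-scale use.
- The canonical noise level is a package choice, not an estimate from the
  unavailable recordings; all downstream statistics are reported at that
  level.
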