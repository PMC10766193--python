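# Model and methods

`dynattractor` simulates a fully connected recurrent network of N rate
neurons in which memory assemblies form, grow, and are forgotten under the
joint action of an online covariance (Hebbian) learning rule, background
firing noise, neural adaptation, weight decay, and two compensatory input
normalizations. This note documents the model exactly as implemented, the
choices made where the design was genuinely open, and what the shipped
simulations do and do not demonstrate.

## Dynamics

Each neuron i carries a rate r_i, an adaptive threshold θ_i, and incoming
weights w_ij (from j to i; diag W = 0). One synchronous Euler step of size
dt applies:

- **Input field** h_i = S_R,i · S_W,i · Σ_{j≠i} w_ij r_j + I_i, where I is
  the external stimulation current.
- **Rates** τ_r dr/dt = −r + r_0 + φ(h − θ) with the sigmoid
  φ(x) = r_max / (1 + e^{−b x}), plus additive Gaussian noise C·ξ per step
  (ξ ~ N(μ, σ)).
- **Thresholds** τ_θ dθ/dt = −θ + θ_0 + D_θ r (adaptation: sustained firing
  raises the threshold to θ_0 + D_θ, which exceeds the maximal recurrent
  drive, so reverberating activity always self-terminates).
- **Weights** τ_w dw_ij/dt = η (r_i − ⟨r_i⟩)(r_j − ⟨r_j⟩) − β w_ij, hard
  clipped to [w_min, w_max] after every step. ⟨r⟩ is a box average over a
  window of length T_LR.

The two normalizations are S_W,i = 1/(1 + α_w Σ_{j≠i} w_ij H(w_ij − w_thr))
(heterosynaptic-style scaling by the summed *strong* incoming weights,
w_thr = w_max/6, H(0) = 0) and S_R,i = 1/(1 + α_r (γ/N) Σ_{j≠i} r_j)
(divisive scaling by network activity; the sum is floored at 0 so the
factor stays in (0, 1] when noise drives the mean rate slightly negative).

Defaults: N = 100, γ = 0.1, r_max = 1, r_0 = 0, b = 100, θ_0 = 0.15,
D_θ = 1, C = 0.006, μ = 0, σ = 1, η = 1, β = 0.0025, α_w = 1, α_r = 2,
w_max = 0.3, w_min = −0.05, τ_r = 1, τ_θ = 7, τ_w = 50, T_LR = 15, dt = 1,
I_0 = 1 (all times in arbitrary units).

## Design choices where the formulation is open

- **Normalization acts on the recurrent input only.** Writing
  h = S_R S_W (Σ w r + I) instead makes the stimulus unable to ignite its
  own pattern once the assembly exceeds ~21 neurons (S_W I_0 < θ_0), i.e.
  the network would go silent exactly in the size range the model is meant
  to reach. Treating the normalizations as synaptic mechanisms — scaling
  the recurrent drive but not the injected current — keeps ignition
  possible at any assembly size while the recurrent drive still saturates
  below θ_0 + D_θ r_max, preserving post-offset shut-off and the
  orthogonality-protecting role of S_W.
- **Centred covariance window.** The box average ⟨r⟩ is symmetric: the
  covariance compares the rate sample at the centre of the T_LR window with
  the window mean, so the weight update lags the rates by T_LR/2. With a
  one-sided (trailing) window, a 5 a.u. pulse against a 15 a.u. window
  yields a per-pulse within-pattern increment of ≈ 0.10, saturating the
  weights after 3 stimulations; the symmetric window yields ≈ 0.063,
  saturating after 5 stimulations with a ~130-step rise — the regime this
  model is built to operate in. Sustained activation longer than T_LR still
  produces no net learning under either choice.
- **Update order.** Rates update from the current field; thresholds update
  from pre-update rates; the fresh rate is pushed to the window buffer; the
  weight update then uses the centred sample and window mean. Any
  consistent ordering differs only at O(dt).
- **Noise discretization.** The per-step noise amplitude is
  C·sqrt(dt/τ_r) (Euler–Maruyama), equal to the printed C at the default
  dt = τ_r = 1.
- **Initialization.** r = 0, W = 0, θ = θ_0; the averaging buffer warm-starts
  on the available history (zero-padding would inject a spurious positive
  covariance at start-up).
- **Heaviside tie.** Weights exactly at w_thr do not contribute to S_W;
  the tie is measure-zero and the strict inequality avoids flicker at the
  clip boundary.
- **Probe read-out.** Membership reads the rate at exactly 2 a.u. after the
  1 a.u. test pulse (threshold r_thr = 0.5, strict). The alternative
  criterion — maximum rate over the remainder of the 5 a.u. read window —
  is available via `analysis.membership(..., criterion="max_after_2")`.
- **Recruitment debounce.** A neuron counts as recruited at the first probe
  where it is a member for 2 consecutive probes; single-probe flicker is an
  artifact of probe cadence, not of the weights.

## Experimental paradigms

All stimulation uses rectangular pulse trains (duration T = 5 a.u.,
intensity I_0 = 1). Every run begins with a 50,000 a.u. warm-up (noise and
learning on, no input) so the weight matrix reaches its stationary
noise-driven statistics, and ends with a 10,000 a.u. post phase; t = 0 is
the start of stimulation. Probes copy the state, disable learning and
noise, and never perturb the main trajectory (bit-identical with or
without probes).

Multi-pattern schedules interleave patterns round-robin with onsets offset
by (shortest period)/(number of patterns); construction fails if any two
pulses overlap. For the three-pattern reinforce-and-forget paradigm, phase
1 drives all patterns at f = 1/90 for 12 pulses (assemblies saturate well
within this), then phase 2 continues P1 at 1/60 and P2 at 1/120 while P3
receives nothing.

When the initial pattern size N·γ changes, w_max and C are rescaled by
(N γ)/(N' γ') and w_thr follows as w_max/6; low-frequency multi-assembly
schedules additionally divide β by 20.

## What the simulations show — and a known quantitative limitation

With the defaults the package reproduces, deterministically across seeds:
formation of a 10-neuron assembly whose mean internal weight saturates at
the 5th stimulation after a ≈ 133-step rise; first probe reverberation at
the 2nd–3rd stimulation; exponential forgetting of unstimulated assemblies
with time constant τ_w/β = 20,000 a.u.; recruitment of noise-correlated
outside neurons starting near t ≈ 2·10⁴ a.u.; zero pairwise overlap
between concurrently stimulated assemblies; and the ablation phenotypes of
unbounded weights without clipping, unbounded std(W) without decay, and
sustained post-offset activity without synaptic normalization. Removing
only the divisive normalization (α_w = 2, α_r = 0) does **not** destabilize
this formulation at any horizon we tested (≤ 3·10⁵ a.u.): with α_w = 2 the
recurrent drive is capped at 1/α_w = 0.5, well under the adaptation
ceiling, so activity always shuts off — the destabilizing role reported
for that configuration does not reproduce here.

Known limitation: beyond roughly 20 recruited neurons the recruitment rate
accelerates rather than saturating. Each recruit adds a coherent source of
covariance drive for the remaining outside neurons (the per-pulse kick on a
candidate's summed assembly weight grows with assembly size m, while the
ignition threshold grows only as 1 + α_r γ m / N), so growth is
super-linear and a single-pattern run driven at f = 1/60 merges most of
the network by t ≈ 1–2·10⁵ a.u.; after the merge the probe criterion
collapses because pattern completion from the 10 original seeds can no
longer ignite the (now network-sized, partially decayed) assembly. Slow,
saturating growth over ~4·10⁵ a.u. would require an additional brake on
the candidates' covariance accumulation whose form the model equations do
not determine; none of the documented parameters provides it. Long-horizon
assembly-size trajectories beyond the onset of this regime should
therefore be read qualitatively, not quantitatively.

## Numerical notes

- dt = 1 a.u. (= τ_r) by default; rates relax fully within a step,
  thresholds over ~7 steps. dt is configurable; dt ≤ τ_r is enforced.
- The sigmoid exponent is clipped at ±700 to avoid overflow; at b = 100
  this only touches drives |h − θ| > 7, far outside the operating range.
- The running-average ring buffer keeps an incremental sum, refreshed
  every 4096 pushes to cancel float drift over ~10⁶-step runs.
- Any non-finite rate aborts the run with a diagnostic; the model remains
  finite under all shipped parameter sets.
- Problem sizes in the test suite: formation runs use the full protocol
  (50,000 a.u. warm-up + 10 pulses); structural tests use horizons of
  0.6–2·10⁵ a.u. and 3–5 repetitions, which is where the phenomena they
  check live.
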