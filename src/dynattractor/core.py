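"""State and one-step update equations of the dynamic attractor network.

The network is a fully connected recurrent rate model.  Each neuron i has a
firing rate r_i, an adaptive firing threshold theta_i, and incoming weights
w_ij (from neuron j to neuron i; the diagonal is identically zero).  One
synchronous Euler step applies, in order:

1. the input field  h_i = S_R,i * S_W,i * sum_j w_ij r_j + I_i,
   where S_W is the synaptic (heterosynaptic-style) normalization and S_R
   the divisive normalization by network activity;
2. the rate update   tau_r  dr/dt     = -r + r0 + phi(h, theta)  (+ noise);
3. the threshold update tau_th dtheta/dt = -theta + theta0 + D_theta * r,
   driven by the pre-update rate;
4. a push of the updated rate onto the T_LR ring buffer;
5. the weight update tau_w dw_ij/dt = eta (r_i - <r_i>)(r_j - <r_j>) - beta w_ij,
   where the covariance compares the rate sample at the *centre* of the
   T_LR window against the window mean (a symmetric box average; the weight
   update therefore lags the rates by T_LR/2), followed by hard clipping to
   [w_min, w_max] and re-zeroing of the diagonal.

All operations are exposed as standalone functions so that each equation can
be tested against closed-form or numerically solved oracles.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams

__all__ = [
    "NetworkState",
    "RateHistory",
    "transfer",
    "synaptic_norm",
    "divisive_norm",
    "input_field",
    "step_rates",
    "step_thresholds",
    "step_weights",
    "step",
]

# exponent clip keeping exp() finite in float64
_EXP_CLIP = 700.0


class RateHistory:
    """Ring buffer of past rate vectors with an O(N) running mean.

    The buffer holds up to ``length`` vectors; until it is full, the mean is
    taken over the available history only (no zero padding, which would
    inject a spurious positive covariance at start-up).  An incremental sum
    is kept for speed and refreshed from scratch periodically to stop
    floating-point drift over long simulations.
    """

    _REFRESH = 4096

    def __init__(self, length: int, n: int):
        if length < 1:
            raise ValueError("history length must be >= 1")
        self._buf = np.zeros((length, n))
        self._sum = np.zeros(n)
        self._count = 0
        self._pos = 0
        self._pushes = 0

    @property
    def length(self) -> int:
        return self._buf.shape[0]

    @property
    def count(self) -> int:
        """Number of rate vectors currently stored."""
        return self._count

    def push(self, r: np.ndarray) -> None:
        buf = self._buf
        if self._count == buf.shape[0]:
            self._sum -= buf[self._pos]
        else:
            self._count += 1
        buf[self._pos] = r
        self._sum += r
        self._pos = (self._pos + 1) % buf.shape[0]
        self._pushes += 1
        if self._pushes % self._REFRESH == 0:
            self._sum = buf[: self._count].sum(axis=0)

    def mean(self, default: np.ndarray | None = None) -> np.ndarray:
        """Running average <r>; ``default`` is returned for an empty buffer."""
        if self._count == 0:
            if default is None:
                raise ValueError("running average of an empty history")
            return np.array(default, dtype=float, copy=True)
        return self._sum / self._count

    def center(self) -> np.ndarray:
        """The rate vector at the centre of the stored window.

        With the newest sample at relative index 0, this is the sample
        (count-1)//2 steps back, i.e. the middle of a full buffer.
        """
        if self._count == 0:
            raise ValueError("centre of an empty history")
        delay = (self._count - 1) // 2
        idx = (self._pos - 1 - delay) % self._buf.shape[0]
        return self._buf[idx]

    def copy(self) -> "RateHistory":
        new = RateHistory.__new__(RateHistory)
        new._buf = self._buf.copy()
        new._sum = self._sum.copy()
        new._count = self._count
        new._pos = self._pos
        new._pushes = self._pushes
        return new


class NetworkState:
    """Rates, thresholds, weight matrix, rate history and clock."""

    __slots__ = ("t", "r", "theta", "W", "history")

    def __init__(self, t: float, r: np.ndarray, theta: np.ndarray,
                 W: np.ndarray, history: RateHistory):
        self.t = t
        self.r = r
        self.theta = theta
        self.W = W
        self.history = history

    @classmethod
    def rest(cls, params: ModelParams, t: float = 0.0) -> "NetworkState":
        """Resting state: r = 0, W = 0, theta = theta0, empty history."""
        n = params.N
        return cls(
            t=t,
            r=np.zeros(n),
            theta=np.full(n, params.theta0),
            W=np.zeros((n, n)),
            history=RateHistory(params.history_length, n),
        )

    def copy(self) -> "NetworkState":
        return NetworkState(self.t, self.r.copy(), self.theta.copy(),
                            self.W.copy(), self.history.copy())


def transfer(h, theta, params: ModelParams):
    """Sigmoidal f-I curve  phi = r_max / (1 + exp(-b (h - theta))).

    Strictly increasing in h, decreasing in theta, with range (0, r_max).
    """
    x = np.clip(-params.b * (np.asarray(h, dtype=float) - theta),
                -_EXP_CLIP, _EXP_CLIP)
    return params.r_max / (1.0 + np.exp(x))


def synaptic_norm(W: np.ndarray, params: ModelParams):
    """Heterosynaptic input scaling  S_W = 1 / (1 + alpha_w * sum_strong).

    ``sum_strong`` sums, over the incoming weights of a neuron, those strictly
    above the threshold w_thr = w_max / 6 (H(0) = 0, so weights exactly at
    the threshold do not contribute).  Accepts a single weight row (returns a
    scalar) or the full matrix (returns one factor per neuron).  The zero
    diagonal never contributes since w_thr > 0.
    """
    W = np.asarray(W, dtype=float)
    if params.alpha_w == 0.0:
        return 1.0 if W.ndim == 1 else np.ones(W.shape[0])
    strong = np.where(W > params.w_thr, W, 0.0)
    s = strong.sum(axis=-1)
    return 1.0 / (1.0 + params.alpha_w * s)


def divisive_norm(r: np.ndarray, params: ModelParams):
    """Divisive input scaling  S_R,i = 1 / (1 + alpha_r (gamma/N) sum_{j!=i} r_j).

    Returns one factor per neuron; neuron i's own rate is excluded from the
    sum.  The summed activity is floored at zero so that the factor stays in
    (0, 1] even when background noise drives the mean rate slightly negative.
    """
    r = np.asarray(r, dtype=float)
    if params.alpha_r == 0.0:
        return np.ones_like(r)
    others = np.maximum(r.sum() - r, 0.0)
    return 1.0 / (1.0 + params.alpha_r * (params.gamma / params.N) * others)


def input_field(W: np.ndarray, r: np.ndarray, I: np.ndarray,
                params: ModelParams) -> np.ndarray:
    """Normalized input field  h_i = S_R,i S_W,i sum_{j!=i} w_ij r_j + I_i.

    Both compensatory factors act on the recurrent (synaptic) input; the
    external stimulation current is delivered unnormalized.  This keeps the
    stimulus able to ignite its pattern at any assembly size, while the
    recurrent drive saturates below theta0 + D_theta * r_max so that
    adaptation always terminates reverberating activity.  With
    alpha_w = alpha_r = 0 the field reduces exactly to the un-normalized
    field of the standard attractor model.
    """
    r = np.asarray(r, dtype=float)
    I = np.asarray(I, dtype=float)
    if I.shape != r.shape:
        raise ValueError(f"external input shape {I.shape} != rate shape {r.shape}")
    rec = W @ r  # diagonal is zero, so the self term is excluded
    sw = synaptic_norm(W, params)
    sr = divisive_norm(r, params)
    return sr * sw * rec + I


def _noise_amplitude(params: ModelParams) -> float:
    # The printed C already contains the dt/tau_r Euler factor for dt = 1,
    # tau_r = 1.  For other step sizes the per-step amplitude follows the
    # Euler-Maruyama sqrt(dt) convention, normalized so that dt = tau_r
    # reproduces C exactly.
    return params.C * np.sqrt(params.dt / params.tau_r)


def step_rates(r, h, theta, noise, params: ModelParams):
    """Forward-Euler rate update with additive Gaussian background activity.

    r <- r + (dt/tau_r) (-r + r0 + phi(h, theta)) + C_step * xi,
    where xi ~ Normal(mu, sigma) and C_step = C sqrt(dt/tau_r).
    """
    a = params.dt / params.tau_r
    r_new = r + a * (-r + params.r0 + transfer(h, theta, params))
    if noise is not None and params.C != 0.0:
        xi = params.mu + params.sigma * noise
        r_new = r_new + _noise_amplitude(params) * xi
    return r_new


def step_thresholds(theta, r, params: ModelParams):
    """Adaptive-threshold update  theta <- theta + (dt/tau_theta)(-theta + theta0 + D_theta r)."""
    return theta + (params.dt / params.tau_theta) * (
        -theta + params.theta0 + params.D_theta * r
    )


def step_weights(W: np.ndarray, r: np.ndarray, r_avg: np.ndarray,
                 params: ModelParams, out: np.ndarray | None = None) -> np.ndarray:
    """Covariance learning with forgetting, hard bounds and zero diagonal.

    w_ij <- clip( w_ij + (dt/tau_w) (eta (r_i - <r_i>)(r_j - <r_j>) - beta w_ij),
                  w_min, w_max ),  with diag(W) = 0.
    """
    d = r - r_avg
    g = params.dt / params.tau_w
    if out is None:
        out = np.empty_like(W)
    np.multiply(W, 1.0 - g * params.beta, out=out)
    out += (g * params.eta) * np.outer(d, d)
    np.clip(out, params.w_min, params.w_max, out=out)
    np.fill_diagonal(out, 0.0)
    return out


def step(state: NetworkState, I: np.ndarray, params: ModelParams,
         noise: np.ndarray | None = None, *, learn: bool = True) -> np.ndarray:
    """One synchronous update of the full network state (in place).

    ``noise`` is a vector of N standard-normal draws (or None for noiseless
    dynamics).  Returns the input-field vector h used for this step, so that
    callers can record it without recomputation.  Raises FloatingPointError
    if the state leaves the finite domain.
    """
    p = params
    r = state.r
    h = input_field(state.W, r, I, p)
    r_new = step_rates(r, h, state.theta, noise, p)
    if not np.all(np.isfinite(r_new)):
        raise FloatingPointError(
            f"non-finite rates at t={state.t + p.dt:.1f} "
            f"(max |h| = {np.max(np.abs(h)):.3g})"
        )
    theta_new = step_thresholds(state.theta, r, p)
    state.history.push(r_new)
    if learn:
        # The covariance term is centred: the rate sample at the middle of
        # the T_LR window is compared against the window mean, so the
        # box average is symmetric around the rate it is subtracted from
        # (the weight update lags the rates by T_LR/2).
        r_avg = state.history.mean()
        r_mid = state.history.center()
        step_weights(state.W, r_mid, r_avg, p, out=state.W)
    state.r = r_new
    state.theta = theta_new
    state.t += p.dt
    return h
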