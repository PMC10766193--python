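"""Model parameters and their rescaling rules.

The default constants describe a recurrent network of N = 100 rate neurons
with a sigmoidal transfer function, an adaptive firing threshold, Gaussian
background activity, an online covariance (Hebbian) learning rule with a
linear forgetting term, hard weight bounds, and two compensatory input
normalizations (heterosynaptic/"synaptic" and divisive).  All times are in
arbitrary units (a.u.); the Euler integration step ``dt`` defaults to 1 a.u.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ModelParams:
    """All constants of the dynamic attractor model.

    Attributes
    ----------
    N : int
        Network size (number of rate neurons).
    gamma : float
        Fraction of directly stimulated neurons (network sparseness);
        ``N * gamma`` is the initial pattern size.
    r_max : float
        Maximal firing rate (saturation of the sigmoid), dimensionless.
    r0 : float
        Baseline firing rate.
    b : float
        Slope of the sigmoidal f-I curve.
    theta0 : float
        Base firing threshold in the absence of firing.
    D_theta : float
        Strength of the threshold adaptation (theta tracks theta0 + D_theta*r).
    C : float
        Coupling constant of the per-step Gaussian background noise.  As
        printed it already contains the dt/tau_r factor of the Euler scheme
        for dt = 1 a.u.; see :func:`dynattractor.core.step_rates` for how it
        is rescaled at other step sizes.
    mu, sigma : float
        Mean and standard deviation of the Gaussian noise samples.
    eta : float
        Learning rate of the Hebbian covariance term.
    beta : float
        Forgetting rate (linear weight decay); the decay time constant of an
        unrefreshed weight is tau_w / beta a.u. (20,000 a.u. at defaults).
    alpha_w : float
        Synaptic-normalization constant (heterosynaptic-style scaling by the
        summed strong incoming weights).
    alpha_r : float
        Divisive-normalization constant (scaling by mean network activity).
    w_max, w_min : float
        Hard bounds of the synaptic weights.
    w_thr_override : float or None
        Heterosynaptic threshold above which an incoming weight contributes
        to the synaptic normalization.  ``None`` (the default) derives it as
        ``w_max / 6``; an explicit value decouples it from ``w_max`` (used
        e.g. when removing the weight bounds in ablation studies).
    tau_r, tau_theta, tau_w : float
        Time constants of the rate, threshold and weight dynamics (a.u.).
    T_LR : float
        Length of the box-shaped running-average window of the learning
        rule (a.u.); chosen longer than the 5 a.u. stimulus pulses so that
        sustained activation self-cancels in the covariance term.
    dt : float
        Euler integration step (a.u.).
    I0 : float
        Default intensity of the external stimulation.
    """

    N: int = 100
    gamma: float = 0.1
    r_max: float = 1.0
    r0: float = 0.0
    b: float = 100.0
    theta0: float = 0.15
    D_theta: float = 1.0
    C: float = 0.006
    mu: float = 0.0
    sigma: float = 1.0
    eta: float = 1.0
    beta: float = 0.0025
    alpha_w: float = 1.0
    alpha_r: float = 2.0
    w_max: float = 0.3
    w_min: float = -0.05
    w_thr_override: float | None = None
    tau_r: float = 1.0
    tau_theta: float = 7.0
    tau_w: float = 50.0
    T_LR: float = 15.0
    dt: float = 1.0
    I0: float = 1.0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")
        if not self.w_min < 0.0:
            raise ValueError("w_min must be negative")
        if not 0.0 < self.w_thr < self.w_max:
            raise ValueError("w_thr must lie in (0, w_max)")
        for name in ("tau_r", "tau_theta", "tau_w"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if self.dt <= 0.0:
            raise ValueError("dt must be positive")
        if self.dt > self.tau_r:
            raise ValueError("dt must not exceed tau_r (Euler stability)")
        if self.T_LR <= 0.0:
            raise ValueError("T_LR must be positive")

    @property
    def w_thr(self) -> float:
        """Heterosynaptic threshold; w_max / 6 unless explicitly overridden."""
        if self.w_thr_override is not None:
            return self.w_thr_override
        return self.w_max / 6.0

    @property
    def pattern_size(self) -> int:
        """Number of directly stimulated neurons, N * gamma."""
        return int(round(self.N * self.gamma))

    @property
    def history_length(self) -> int:
        """Number of past rate vectors in the running-average buffer."""
        return max(1, math.ceil(self.T_LR / self.dt))

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields changed."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


def scale_params(
    base: ModelParams,
    N_new: int,
    pattern_size_new: int,
    *,
    low_frequency: bool = False,
) -> ModelParams:
    """Rescale parameters for a different network / pattern size.

    When the initial pattern size ``N * gamma`` changes, the recurrent input
    that an assembly neuron receives from the rest of its assembly changes
    proportionally, and so does the mean connection a non-member needs in
    order to be recruited.  Both the weight ceiling and the noise coupling
    are therefore rescaled inversely with the pattern size::

        w_max' = (N * gamma) / (N' * gamma') * w_max
        C'     = (N * gamma) / (N' * gamma') * C

    with the heterosynaptic threshold following as ``w_max' / 6``.  For
    low-frequency multi-assembly schedules (where stimulation periods grow to
    avoid temporal overlap between assemblies) the forgetting rate must be
    slowed correspondingly; ``low_frequency=True`` divides ``beta`` by 20.
    """
    if pattern_size_new < 2:
        raise ValueError("pattern size after scaling must be at least 2")
    if N_new < pattern_size_new:
        raise ValueError("N_new must be at least the pattern size")
    factor = (base.N * base.gamma) / float(pattern_size_new)
    beta = base.beta / 20.0 if low_frequency else base.beta
    return base.replace(
        N=N_new,
        gamma=pattern_size_new / float(N_new),
        w_max=factor * base.w_max,
        C=factor * base.C,
        beta=beta,
        w_thr_override=None,
    )
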