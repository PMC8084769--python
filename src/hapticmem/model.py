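"""Variance propagation for the serial-integration observer model.

Haptic texture discrimination is modelled as stroke-wise Kalman filtering:
each lateral finger stroke across a grating yields a noisy estimate of its
spatial period, and successive estimates are combined by inverse-variance
weighting.  Two phases are chained within a 2IFC trial:

1. *Standard phase* — ``n1`` strokes across the standard build an integrated
   representation of its period.  Between strokes, process noise ``sigma2_w``
   is added to the integrated estimate; masking between strokes is modelled
   as a larger process-noise variance.
2. *Comparison phase* — ``n2`` strokes across the comparison each yield a
   difference score between the stored standard representation (whose
   variance grows with comparison-stroke index ``i`` as ``i**decay_exponent``,
   the sensory-memory decay) and the fresh comparison estimate.  Difference
   scores are again serially integrated, with process noise between steps.

The predicted just-noticeable difference (JND) is the standard deviation of
the final integrated difference estimate.  Only variances are propagated
here; mean-level responses are realised in :mod:`hapticmem.observer`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "VAR_FLOOR",
    "ModelParams",
    "ConditionSpec",
    "IntegrationTrace",
    "kalman_combine",
    "standard_phase_variance",
    "predict_jnd",
    "batch_inverse_variance",
]

#: Variances are clamped at this floor (mm^2) so that degenerate parameter
#: sweeps cannot divide by zero.
VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Free and fixed parameters of the integration model.

    Parameters
    ----------
    sigma2_single
        Variance of a single-stroke period estimate, mm^2.
    sigma2_w_mask
        Process-noise variance added per integration step when a mask is
        presented between strokes, mm^2.
    sigma2_w_ctrl
        Process-noise variance per step without masking, mm^2.
    decay_exponent
        Power applied to the comparison-stroke index to model the decay of
        the standard's representation while the comparison is explored.
    n2
        Number of strokes on the comparison stimulus (free exploration is
        summarised by a fixed typical count).
    """

    sigma2_single: float = 0.075
    sigma2_w_mask: float = 0.031
    sigma2_w_ctrl: float = 0.012
    decay_exponent: float = 0.442
    n2: int = 4

    def __post_init__(self) -> None:
        if not self.sigma2_single > 0:
            raise ValueError("sigma2_single must be > 0")
        if self.sigma2_w_mask < 0 or self.sigma2_w_ctrl < 0:
            raise ValueError("process-noise variances must be >= 0")
        if self.decay_exponent < 0:
            raise ValueError("decay_exponent must be >= 0")
        if int(self.n2) != self.n2 or self.n2 < 1:
            raise ValueError("n2 must be an integer >= 1")

    def process_noise(self, masked: bool) -> float:
        return self.sigma2_w_mask if masked else self.sigma2_w_ctrl


@dataclass(frozen=True)
class ConditionSpec:
    """One exploration condition: stroke count on the standard and masking.

    ``label`` is free text for reporting; two conditions with the same
    ``label`` compare equal only if ``n1`` and ``masked`` also agree.
    """

    n1: int
    masked: bool
    label: str = ""

    def __post_init__(self) -> None:
        if int(self.n1) != self.n1 or self.n1 < 1:
            raise ValueError("n1 must be an integer >= 1")

    def describe(self) -> str:
        if self.label:
            return self.label
        return f"{self.n1}-stroke {'mask' if self.masked else 'control'}"


@dataclass
class IntegrationTrace:
    """Per-step variances and gains of both filtering phases.

    Gains are the Kalman weights on the novel observation; the first step of
    each phase has an uninformative prior (``inf``) and gain 1.
    """

    standard_prior_vars: list[float] = field(default_factory=list)
    standard_post_vars: list[float] = field(default_factory=list)
    standard_gains: list[float] = field(default_factory=list)
    diff_obs_vars: list[float] = field(default_factory=list)
    diff_post_vars: list[float] = field(default_factory=list)
    diff_gains: list[float] = field(default_factory=list)
    predicted_jnd: float = math.nan


def kalman_combine(prior_var: float, obs_var: float) -> tuple[float, float]:
    """Combine a prior and an observation by inverse-variance weighting.

    Returns ``(posterior_var, gain)`` where ``gain`` is the weight on the
    observation: ``gain = prior_var / (prior_var + obs_var)`` and
    ``posterior_var = 1 / (1/prior_var + 1/obs_var)``.
    """
    if not prior_var > 0 or not obs_var > 0:
        raise ValueError("variances must be positive")
    if math.isinf(prior_var):
        return max(obs_var, VAR_FLOOR), 1.0
    gain = prior_var / (prior_var + obs_var)
    post = 1.0 / (1.0 / prior_var + 1.0 / obs_var)
    return max(post, VAR_FLOOR), gain


def standard_phase_variance(
    params: ModelParams, cond: ConditionSpec
) -> tuple[float, IntegrationTrace]:
    """Variance of the integrated standard representation after ``n1`` strokes.

    The first stroke sets the estimate (variance ``sigma2_single``); each
    further stroke first degrades the running estimate by the condition's
    process noise, then integrates a fresh single-stroke observation.
    """
    trace = IntegrationTrace()
    w = params.process_noise(cond.masked)
    v = max(params.sigma2_single, VAR_FLOOR)
    trace.standard_prior_vars.append(math.inf)
    trace.standard_post_vars.append(v)
    trace.standard_gains.append(1.0)
    for _ in range(2, cond.n1 + 1):
        prior = v + w
        v, gain = kalman_combine(prior, params.sigma2_single)
        trace.standard_prior_vars.append(prior)
        trace.standard_post_vars.append(v)
        trace.standard_gains.append(gain)
    return v, trace


def predict_jnd(
    params: ModelParams,
    cond: ConditionSpec,
    comparison_noise_mode: str = "condition",
) -> tuple[float, IntegrationTrace]:
    """Predicted JND (mm) for one condition, with the full variance trace.

    During the comparison phase the stored standard representation decays:
    the difference score on comparison stroke ``i`` has variance
    ``i**decay_exponent * var(standard) + sigma2_single``.  Difference scores
    are serially integrated with process noise between steps.

    ``comparison_noise_mode`` selects the process noise of the comparison
    phase: ``"condition"`` (default) reuses the condition's own level in both
    phases, matching the published model in which each masking condition has
    a single process-noise parameter; ``"control"`` always applies the
    no-mask level during the comparison phase, on the physical argument that
    the comparison stimulus itself is never masked.
    """
    if comparison_noise_mode not in ("control", "condition"):
        raise ValueError("comparison_noise_mode must be 'control' or 'condition'")
    v_s, trace = standard_phase_variance(params, cond)
    if comparison_noise_mode == "control":
        w = params.sigma2_w_ctrl
    else:
        w = params.process_noise(cond.masked)
    d = math.nan
    for i in range(1, params.n2 + 1):
        obs = float(i) ** params.decay_exponent * v_s + params.sigma2_single
        trace.diff_obs_vars.append(obs)
        if i == 1:
            prior = math.inf
        else:
            prior = d + w
        d, gain = kalman_combine(prior, obs)
        trace.diff_post_vars.append(d)
        trace.diff_gains.append(gain)
    trace.predicted_jnd = math.sqrt(d)
    return trace.predicted_jnd, trace


def batch_inverse_variance(variances) -> float:
    """Closed-form combined variance ``1 / sum(1/v_i)``.

    Oracle for the zero-process-noise limit of the recursive filter, where
    sequential Kalman combination reduces to pooling independent cues.
    """
    vs = list(variances)
    if not vs:
        raise ValueError("need at least one variance")
    if any(not v > 0 for v in vs):
        raise ValueError("variances must be positive")
    return 1.0 / sum(1.0 / v for v in vs)
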