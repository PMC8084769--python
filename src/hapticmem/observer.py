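"""Synthetic 2IFC experiment generator.

Builds the trial lists of the two masking experiments (method of constant
stimuli, two-interval forced choice on grating spatial period) and simulates
responses from an ideal-observer whose discrimination noise is the JND
predicted by the serial-integration model.

Experiment 1: three-stroke exploration with a high-energy mask, a low-energy
smooth surface, or no intermediate surface (plus a one-stroke control).
Experiment 2: one, three, five or seven strokes on the standard, with or
without a mask after every stroke.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import ConditionSpec, ModelParams, predict_jnd

__all__ = [
    "StimulusSeries",
    "ExperimentConfig",
    "ObserverParams",
    "make_comparison_series",
    "default_standards",
    "exp1_conditions",
    "exp2_conditions",
    "build_trial_list",
    "response_probability",
    "simulate_experiment",
]


@dataclass(frozen=True)
class StimulusSeries:
    """A constant-stimuli series: one standard and its comparison periods (mm)."""

    standard_period: float
    comparison_periods: tuple[float, ...]

    def __post_init__(self) -> None:
        comps = np.asarray(self.comparison_periods, dtype=float)
        if comps.size < 2:
            raise ValueError("need at least two comparison periods")
        steps = np.diff(comps)
        if np.any(steps <= 0):
            raise ValueError("comparison periods must be strictly increasing")
        if np.max(np.abs(steps - steps[0])) > 1e-9:
            raise ValueError("comparison periods must be equally spaced")
        mid = 0.5 * (comps[0] + comps[-1])
        if abs(mid - self.standard_period) > 1e-9:
            raise ValueError("series must be centered on the standard period")

    @property
    def step(self) -> float:
        c = self.comparison_periods
        return (c[-1] - c[0]) / (len(c) - 1)


def make_comparison_series(
    low: float, high: float, n: int = 9, standard_period: float | None = None
) -> StimulusSeries:
    """Equally spaced comparison series inclusive of both endpoints.

    The standard defaults to the series midpoint, matching the experiments'
    design of nine comparisons centered on each standard.
    """
    if high <= low:
        raise ValueError("high must exceed low")
    if n < 2:
        raise ValueError("need n >= 2")
    comps = tuple(np.linspace(low, high, n))
    if standard_period is None:
        standard_period = 0.5 * (low + high)
    return StimulusSeries(standard_period=standard_period, comparison_periods=comps)


def default_standards() -> tuple[StimulusSeries, StimulusSeries]:
    """The two grating series used in both experiments (standards 1.69, 1.95 mm)."""
    return (
        make_comparison_series(1.35, 2.03, 9),
        make_comparison_series(1.61, 2.29, 9),
    )


def exp1_conditions() -> tuple[ConditionSpec, ...]:
    return (
        ConditionSpec(1, False, "one-stroke control"),
        ConditionSpec(3, True, "mask"),
        ConditionSpec(3, False, "smooth"),
        ConditionSpec(3, False, "three-strokes control"),
    )


def exp2_conditions() -> tuple[ConditionSpec, ...]:
    return tuple(
        ConditionSpec(n1, masked, f"{n1}-strokes {'mask' if masked else 'control'}")
        for masked in (True, False)
        for n1 in (1, 3, 5, 7)
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of one simulated experiment.

    Defaults reproduce the two experiments' structure: 10 repetitions of each
    (condition, standard, comparison) cell, per-condition blocks whose order
    follows a cyclic Latin square across participants, trials split evenly
    over sessions.
    """

    conditions: tuple[ConditionSpec, ...]
    standards: tuple[StimulusSeries, ...]
    repetitions: int = 10
    n_participants: int = 1
    n_sessions: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")

    @classmethod
    def exp1(cls, n_participants: int = 15, seed: int = 0, repetitions: int = 10):
        return cls(
            conditions=exp1_conditions(),
            standards=default_standards(),
            repetitions=repetitions,
            n_participants=n_participants,
            n_sessions=2,
            seed=seed,
        )

    @classmethod
    def exp2(cls, n_participants: int = 11, seed: int = 0, repetitions: int = 10):
        return cls(
            conditions=exp2_conditions(),
            standards=default_standards(),
            repetitions=repetitions,
            n_participants=n_participants,
            n_sessions=4,
            seed=seed,
        )

    @property
    def trials_per_participant(self) -> int:
        n_comp = sum(len(s.comparison_periods) for s in self.standards)
        return len(self.conditions) * n_comp * self.repetitions


@dataclass(frozen=True)
class ObserverParams:
    """A simulated observer built on the integration model.

    ``base_pse_bias`` shifts the subjective standard upward everywhere (an
    adaptation-like order effect); ``mask_bias_high_standard`` is an extra
    downward shift for masked conditions at the higher-period standard,
    emulating the mask's high spatial-frequency content pulling the percept.
    ``participant_sd`` spreads ``sigma2_single`` log-normally across
    participants so exclusion rules and between-participant error bars can be
    exercised.
    """

    model: ModelParams = field(default_factory=ModelParams)
    base_pse_bias: float = 0.02
    mask_bias_high_standard: float = -0.10
    high_standard_threshold: float = 1.9
    lapse: float = 0.0
    participant_sd: float = 0.2
    comparison_noise_mode: str = "condition"

    def __post_init__(self) -> None:
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")
        if self.participant_sd < 0:
            raise ValueError("participant_sd must be >= 0")

    def pse_bias(self, cond: ConditionSpec, standard_period: float) -> float:
        bias = self.base_pse_bias
        if cond.masked and standard_period >= self.high_standard_threshold:
            bias += self.mask_bias_high_standard
        return bias

    def participant_model(self, seed: int, participant: int) -> ModelParams:
        """Participant-specific parameters (log-normal spread on sigma2_single)."""
        if self.participant_sd == 0:
            return self.model
        rng = np.random.default_rng([seed, participant, 7919])
        factor = float(np.exp(self.participant_sd * rng.standard_normal()))
        return replace(self.model, sigma2_single=self.model.sigma2_single * factor)


def _latin_square_order(n_conditions: int, participant: int) -> list[int]:
    # cyclic Latin square: each condition occupies each serial position once
    # per full cycle of participants
    return [(participant + k) % n_conditions for k in range(n_conditions)]


def build_trial_list(config: ExperimentConfig) -> pd.DataFrame:
    """All trial stubs of an experiment, responses unset.

    One row per (participant x condition x standard x comparison x repetition).
    Block order per participant is a row of a cyclic Latin square over
    conditions; trial order within each session block is randomised under the
    config seed; repetitions are split evenly over sessions.
    """
    rows = []
    for p in range(config.n_participants):
        rng = np.random.default_rng([config.seed, p, 104729])
        order = _latin_square_order(len(config.conditions), p)
        for session in range(1, config.n_sessions + 1):
            for block_pos, cond_idx in enumerate(order):
                cond = config.conditions[cond_idx]
                block = []
                for series in config.standards:
                    for comp in series.comparison_periods:
                        for rep in range(config.repetitions):
                            if rep * config.n_sessions // config.repetitions + 1 != session:
                                continue
                            block.append(
                                {
                                    "participant": p + 1,
                                    "session": session,
                                    "block": block_pos + 1,
                                    "condition": cond.describe(),
                                    "n1": cond.n1,
                                    "masked": cond.masked,
                                    "standard_period_mm": series.standard_period,
                                    "comparison_period_mm": float(comp),
                                    "side": "",
                                    "response": np.nan,
                                }
                            )
                if not block:
                    continue
                perm = rng.permutation(len(block))
                sides = rng.random(len(block)) < 0.5
                for j, k in enumerate(perm):
                    block[k]["side"] = "left" if sides[j] else "right"
                rows.extend(block[k] for k in perm)
    df = pd.DataFrame(rows)
    df.index = range(len(df))
    return df


def response_probability(
    comparison_period,
    standard_period,
    sigma_d: float,
    pse_bias: float = 0.0,
    lapse: float = 0.0,
):
    """P(comparison judged to have the higher spatial period).

    Probit decision rule: ``lapse/2 + (1-lapse) * Phi((comp - (std + bias)) / sigma_d)``
    where ``sigma_d`` is the model-predicted JND for the condition.
    """
    if not sigma_d > 0:
        raise ValueError("sigma_d must be positive")
    z = (np.asarray(comparison_period, dtype=float) - (standard_period + pse_bias)) / sigma_d
    return lapse / 2.0 + (1.0 - lapse) * norm.cdf(z)


def simulate_experiment(
    config: ExperimentConfig, observer: ObserverParams | None = None
) -> pd.DataFrame:
    """Simulate the full experiment; returns the trial table with responses.

    Each trial's response is an independent Bernoulli draw at the observer's
    response probability; randomness is split per participant so results are
    reproducible under (seed, participant).
    """
    if observer is None:
        observer = ObserverParams()
    trials = build_trial_list(config)
    trials["response"] = 0
    cond_by_label = {c.describe(): c for c in config.conditions}
    for p, idx in trials.groupby("participant").groups.items():
        rng = np.random.default_rng([config.seed, int(p), 15485863])
        pmodel = observer.participant_model(config.seed, int(p))
        sub = trials.loc[idx]
        probs = np.empty(len(sub))
        for label, cidx in sub.groupby("condition").groups.items():
            cond = cond_by_label[label]
            sigma_d, _ = predict_jnd(
                pmodel, cond, comparison_noise_mode=observer.comparison_noise_mode
            )
            rows = trials.loc[cidx]
            for std, sidx in rows.groupby("standard_period_mm").groups.items():
                bias = observer.pse_bias(cond, float(std))
                pvals = response_probability(
                    trials.loc[sidx, "comparison_period_mm"].to_numpy(),
                    float(std),
                    sigma_d,
                    pse_bias=bias,
                    lapse=observer.lapse,
                )
                pos = sub.index.get_indexer(sidx)
                probs[pos] = pvals
        draws = rng.random(len(sub))
        trials.loc[idx, "response"] = (draws < probs).astype(int)
    return trials
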