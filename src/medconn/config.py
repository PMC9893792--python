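"""Simulation configuration and seed discipline.

All randomness flows from a single master seed through
:func:`child_rng`, which derives independent, reproducible streams per
(table, subject, visit) via ``numpy.random.SeedSequence`` spawn keys.
Identical configs therefore yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .parcellation import NETWORK_SIZES

# stream codes for the seed tree (fixed; never reorder)
STREAM_PARCELLATION = 0
STREAM_TIMESERIES = 1
STREAM_FFQ = 2
STREAM_COGNITION = 3
STREAM_ROSTER = 4
STREAM_COVARIATES = 5
STREAM_ANALYSIS = 6

VISIT_CODES = {"baseline": 0, "followup": 1}


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Generator for the stream identified by ``key`` under ``seed``.

    ``key`` components are small non-negative integers (stream code,
    subject index, visit code, replicate index ...). The same
    ``(seed, key)`` always yields the same stream.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Connectivity targets are ROI-pair Pearson correlations; the follow-up
    targets sit slightly below baseline so overall summaries drift down by
    roughly 0.01–0.02 z-units over the follow-up interval, with per-subject
    jitter producing Δ standard deviations near 0.06–0.10.

    ``planted_betas`` are the group-specific slopes of memory change on
    Δ between-network connectivity; defaults are the moderation pattern the
    recovery experiments must detect (negative in the low-adherence group,
    near zero in the moderate group, positive in the high group).
    """

    n_subjects: int = 124
    n_volumes: int = 280  # ~9.5 min of BOLD at TR = 2 s, first volumes dropped

    network_spec: dict[str, int] = field(default_factory=lambda: dict(NETWORK_SIZES))
    coord_box: tuple[float, float, float] = (140.0, 170.0, 140.0)
    min_pair_distance: float = 10.0
    near_pair_fraction: float = 0.05

    r_within_baseline: float = 0.28
    r_within_followup: float = 0.265
    r_between_baseline: float = 0.12
    r_between_followup: float = 0.108
    conn_jitter_sd: float = 0.05  # per subject-visit shift of target correlations

    # memory-change moderation model: change = intercept + slope[group] * delta
    #   + covariate effects + N(0, noise_sd)
    planted_betas: dict[str, float] = field(
        default_factory=lambda: {"low": -4.397, "moderate": -0.751, "high": 3.287}
    )
    planted_intercept: float = -0.144
    covariate_betas: dict[str, float] = field(
        default_factory=lambda: {"age": -0.004, "education": 0.01, "nart_iq": 0.002}
    )
    noise_sd: float = 0.6

    # change-score distributions for domains with no planted interaction
    domain_change_means: dict[str, float] = field(
        default_factory=lambda: {"FLUID": -0.148, "SPEED": -0.178, "VOCAB": 0.065}
    )
    domain_change_sds: dict[str, float] = field(
        default_factory=lambda: {"FLUID": 0.117, "SPEED": 0.151, "VOCAB": 0.159}
    )

    # summary-level Δ-connectivity distribution (used when simulating the
    # merged analysis table directly, bypassing the time-series stage)
    delta_mean: float = -0.012
    delta_sd: float = 0.072

    # covariate distributions: mean/SD (or bounds / probabilities)
    covariate_params: dict[str, tuple] = field(
        default_factory=lambda: {
            "age": ("uniform", 20.0, 80.0),
            "education": ("normal_clip", 16.2, 2.33, 12.0, 22.0),
            "nart_iq": ("normal", 117.6, 7.9),
            "caloric_intake": ("normal_clip", 1356.0, 600.0, 500.0, 4500.0),
            "female": ("bernoulli", 0.49),
            "race": ("categorical", 0.597, 0.234, 0.169),  # white, black, other
            "scrub_pct": ("gamma", 1.0, 5.4),
            "cortical_thickness": ("normal", 2.56, 0.12),
            "total_brain_volume": ("normal", 0.0, 48000.0),  # mean-centered
            "wmh_volume": ("lognormal", 6.3, 1.0),
            "mean_fa": ("normal", 0.444, 0.020),
        }
    )

    # cognition task-score generation
    task_noise_sd: float = 0.3  # stable subject-by-task ability offset
    visit_noise_sd: float = 0.0  # visit-specific task noise (0 keeps composite
    # change exactly equal to the planted change)
    baseline_ability_sd: float = 1.0

    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.network_spec.values()) > 264:
            raise ValueError("network_spec ROI counts exceed 264")
        for name, n in NETWORK_SIZES.items():
            if self.network_spec.get(name) != n:
                raise ValueError(
                    f"network {name!r} must have {n} ROIs (got "
                    f"{self.network_spec.get(name)})"
                )
        for r in (
            self.r_within_baseline,
            self.r_within_followup,
            self.r_between_baseline,
            self.r_between_followup,
        ):
            if not -1.0 < r < 1.0:
                raise ValueError(f"target correlation {r} outside (-1, 1)")
        unknown = set(self.planted_betas) - {"low", "moderate", "high"}
        if unknown:
            raise ValueError(f"unknown MeDi group labels in planted_betas: {unknown}")

    def targets(self, visit: str) -> tuple[float, float]:
        """(r_within, r_between) targets for a visit."""
        if visit == "baseline":
            return self.r_within_baseline, self.r_between_baseline
        if visit == "followup":
            return self.r_within_followup, self.r_between_followup
        raise ValueError(f"unknown visit {visit!r}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "coord_box" in d:
            d["coord_box"] = tuple(d["coord_box"])
        if "covariate_params" in d:
            d["covariate_params"] = {
                k: tuple(v) for k, v in d["covariate_params"].items()
            }
        return cls(**d)
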