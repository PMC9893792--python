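"""Synthetic cohort generator for the diet–connectivity–cognition pipeline.

Generates every input the analysis consumes, with the statistical structure
the downstream stages assume:

* a 264-ROI parcellation with mm coordinates and network labels, including
  deliberately planted sub-20-mm ROI pairs to exercise the distance mask;
* per subject-visit ROI time series drawn from a zero-mean multivariate
  normal with block covariance (one target correlation within each named
  network, one between networks), with per-subject-visit jitter of the
  targets creating realistic between-subject variance in longitudinal
  connectivity change;
* an FFQ table (11 component serving frequencies + caloric intake) whose
  adherence scores span the 0–55 range;
* a cognitive task table (6 tasks x 4 domains x 2 visits) whose memory
  change carries a planted MeDi-group-specific slope on Δ connectivity;
* a follow-up/missingness roster reproducing a fixed exclusion cascade;
* a covariate table (demographics, IQ, motion, structural measures).

The time-series model is a stationary multivariate Gaussian: no temporal
autocorrelation is simulated, because the summaries depend only on the
spatial correlation structure. All draws derive from the master seed via
fixed spawn keys (:func:`medconn.config.child_rng`), so identical configs
give byte-identical outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ffq as ffq_mod
from .config import (
    STREAM_ANALYSIS,
    STREAM_COGNITION,
    STREAM_COVARIATES,
    STREAM_FFQ,
    STREAM_PARCELLATION,
    STREAM_TIMESERIES,
    VISIT_CODES,
    SimulationConfig,
    child_rng,
)
from .parcellation import N_ROIS, UNASSIGNED, Parcellation

GROUPS = ffq_mod.GROUPS

#: Task battery: per domain, six (task, native mean, native SD, direction)
#: tuples — three out-of-scanner tests and three in-scanner tasks. Values
#: are plausible native units (scaled scores, proportions correct, seconds,
#: milliseconds); ``lower_better`` marks the timed/reaction-time measures.
TASKS: dict[str, list[tuple[str, float, float, str]]] = {
    "FLUID": [
        ("block_design", 40.0, 12.0, "higher_better"),
        ("letter_number_sequencing", 11.0, 3.0, "higher_better"),
        ("matrix_reasoning", 14.0, 4.0, "higher_better"),
        ("paper_folding_pc", 0.65, 0.15, "higher_better"),
        ("matrix_reasoning_pc", 0.60, 0.15, "higher_better"),
        ("letter_sets_pc", 0.60, 0.15, "higher_better"),
    ],
    "SPEED": [
        ("digit_symbol", 55.0, 14.0, "higher_better"),
        ("trails_a_sec", 35.0, 12.0, "lower_better"),
        ("stroop_color", 70.0, 12.0, "higher_better"),
        ("digit_symbol_rt_ms", 900.0, 180.0, "lower_better"),
        ("letter_comparison_rt_ms", 1400.0, 300.0, "lower_better"),
        ("pattern_comparison_rt_ms", 1100.0, 250.0, "lower_better"),
    ],
    "MEMORY": [
        ("srt_long_term_storage", 45.0, 12.0, "higher_better"),
        ("srt_continuous_retrieval", 38.0, 13.0, "higher_better"),
        ("srt_last_trial", 9.0, 2.5, "higher_better"),
        ("logical_memory_pc", 0.60, 0.15, "higher_better"),
        ("word_order_pc", 0.70, 0.15, "higher_better"),
        ("paired_associates_pc", 0.55, 0.18, "higher_better"),
    ],
    "VOCAB": [
        ("wais_vocabulary", 45.0, 10.0, "higher_better"),
        ("wtar", 40.0, 8.0, "higher_better"),
        ("nart", 35.0, 9.0, "higher_better"),
        ("synonyms_pc", 0.70, 0.15, "higher_better"),
        ("antonyms_pc", 0.65, 0.15, "higher_better"),
        ("picture_naming_pc", 0.80, 0.12, "higher_better"),
    ],
}

#: Default exclusion cascade counts (enrolled cohort to analytic sample).
DEFAULT_ROSTER_COUNTS: dict[str, int] = {
    "enrolled": 562,
    "returned": 254,
    "missing_diet": 25,
    "missing_rsfc": 55,
    "missing_dti_fa": 49,
    "missing_wmh": 1,
}


# ---------------------------------------------------------------------------
# parcellation
# ---------------------------------------------------------------------------

def make_parcellation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Parcellation:
    """Place 264 ROI centers in a box and label them by network.

    Centers are sampled uniformly with rejection so no two lie closer than
    ``min_pair_distance`` mm; then ``near_pair_fraction`` of the ROIs are
    relocated next to a random partner at a separation in
    [min_pair_distance, 20) mm so the downstream distance mask has work to
    do. Labels fill the named networks in canonical order, remainder
    ``unassigned``.
    """
    spec = config.network_spec
    n_named = sum(spec.values())
    if n_named > N_ROIS:
        raise ValueError("network_spec ROI counts exceed 264")
    if config.near_pair_fraction > 0 and config.min_pair_distance >= 20.0:
        raise ValueError(
            "cannot plant sub-20-mm pairs with min_pair_distance >= 20 mm"
        )
    rng = rng or child_rng(config.seed, STREAM_PARCELLATION)
    box = np.asarray(config.coord_box, dtype=float)
    dmin = config.min_pair_distance

    coords = np.empty((N_ROIS, 3))
    n_placed = 0
    attempts = 0
    while n_placed < N_ROIS:
        cand = (rng.random(3) - 0.5) * box
        if n_placed == 0 or np.all(
            np.linalg.norm(coords[:n_placed] - cand, axis=1) >= dmin
        ):
            coords[n_placed] = cand
            n_placed += 1
        attempts += 1
        if attempts > 200_000:
            raise ValueError("coord_box too small for min_pair_distance")

    n_near = int(round(config.near_pair_fraction * N_ROIS))
    if n_near:
        movers = rng.choice(N_ROIS, size=n_near, replace=False)
        for i in movers:
            partners = np.setdiff1d(np.arange(N_ROIS), movers)
            j = int(rng.choice(partners))
            for _ in range(200):
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                d = rng.uniform(dmin, min(19.5, 2 * dmin if dmin < 10 else 19.5))
                cand = coords[j] + u * d
                others = np.delete(np.arange(N_ROIS), [i, j])
                if np.all(np.linalg.norm(coords[others] - cand, axis=1) >= dmin):
                    coords[i] = cand
                    break

    labels = []
    for net, count in spec.items():
        labels.extend([net] * count)
    labels.extend([UNASSIGNED] * (N_ROIS - n_named))

    table = pd.DataFrame(
        {
            "roi_id": np.arange(1, N_ROIS + 1),
            "x_mm": coords[:, 0],
            "y_mm": coords[:, 1],
            "z_mm": coords[:, 2],
            "network": labels,
        }
    )
    return Parcellation(table)


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

def block_covariance(
    labels: np.ndarray, r_within, r_between: float
) -> np.ndarray:
    """Block correlation matrix from network labels and target correlations.

    ``r_within`` is a scalar or a per-network mapping. Unassigned ROIs are
    uncorrelated with everything. Raises if the result is not positive
    definite or any target lies outside (−1, 1).
    """
    labels = np.asarray(labels)
    n = len(labels)
    named = [net for net in pd.unique(labels) if net != UNASSIGNED]
    rw = {net: (r_within[net] if isinstance(r_within, dict) else r_within)
          for net in named}
    for val in list(rw.values()) + [r_between]:
        if not -1.0 < val < 1.0:
            raise ValueError(f"target correlation {val} outside (-1, 1)")

    sigma = np.zeros((n, n))
    is_named = labels != UNASSIGNED
    sigma[np.ix_(is_named, is_named)] = r_between
    for net in named:
        ix = labels == net
        sigma[np.ix_(ix, ix)] = rw[net]
    np.fill_diagonal(sigma, 1.0)
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise ValueError("implied block covariance is not positive definite")
    return sigma


def _jittered_targets(
    config: SimulationConfig, visit: str, rng: np.random.Generator
) -> tuple[float, float]:
    """Per-subject-visit within/between targets with clipped jitter."""
    r_w, r_b = config.targets(visit)
    if config.conn_jitter_sd > 0:
        r_b = float(np.clip(r_b + rng.normal(0.0, config.conn_jitter_sd), 0.005, 0.6))
        r_w = float(np.clip(r_w + rng.normal(0.0, config.conn_jitter_sd),
                            r_b + 0.02, 0.8))
    return r_w, r_b


def simulate_timeseries(
    fixture: Parcellation,
    config: SimulationConfig,
    visit: str,
    subject_index: int = 0,
) -> pd.DataFrame:
    """One subject-visit ROI time-series table (n_volumes x 264).

    Stationary zero-mean multivariate normal draws under the jittered block
    covariance; the stream is keyed by (subject_index, visit) so every
    table is independently reproducible.
    """
    if visit not in VISIT_CODES:
        raise ValueError(f"unknown visit {visit!r}")
    rng = child_rng(
        config.seed, STREAM_TIMESERIES, subject_index, VISIT_CODES[visit]
    )
    r_w, r_b = _jittered_targets(config, visit, rng)
    sigma = block_covariance(fixture.labels, r_w, r_b)
    chol = np.linalg.cholesky(sigma)
    x = rng.standard_normal((config.n_volumes, len(fixture.table))) @ chol.T
    return pd.DataFrame(x, columns=fixture.roi_ids)


# ---------------------------------------------------------------------------
# FFQ
# ---------------------------------------------------------------------------

def _servings_for_band(
    band: np.ndarray, edges: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniform servings within each subject's target frequency band."""
    lo = np.where(band == 0, 0.0, edges[np.maximum(band - 1, 0)])
    hi = np.where(band >= 5, 2.0 * edges[-1], edges[np.minimum(band, 4)])
    return rng.uniform(lo, hi)


def simulate_ffq(
    config: SimulationConfig,
    band_config: dict | None = None,
    rng: np.random.Generator | None = None,
    adherence: np.ndarray | float | None = None,
    band_noise_sd: float = 1.3,
) -> pd.DataFrame:
    """FFQ table: servings/month for 11 components plus caloric intake.

    A latent adherence propensity per subject (Beta(2, 2) by default, or
    supplied via ``adherence``) drives favorable components up, unfavorable
    components down, and alcohol toward the moderate band, so the resulting
    totals span the scale and populate all tertiles. ``adherence=1.0`` with
    ``band_noise_sd=0`` pins every component at its most adherent band.
    """
    rng = rng or child_rng(config.seed, STREAM_FFQ)
    bands = band_config or ffq_mod.DEFAULT_BANDS
    n = config.n_subjects
    if n == 0:
        return pd.DataFrame(
            columns=["subject", *ffq_mod.COMPONENTS, "caloric_intake"]
        )
    if adherence is None:
        adherence = rng.beta(2.0, 2.0, size=n)
    else:
        adherence = np.broadcast_to(np.asarray(adherence, float), (n,))

    def band_noise(scale: float) -> np.ndarray:
        return rng.normal(0, scale, n) if band_noise_sd > 0 else np.zeros(n)

    data: dict[str, np.ndarray] = {"subject": np.arange(1, n + 1)}
    for comp in ffq_mod.FAVORABLE:
        band = np.clip(
            np.rint(5 * adherence + band_noise(band_noise_sd)), 0, 5
        ).astype(int)
        data[comp] = _servings_for_band(band, np.asarray(bands[comp], float), rng)
    for comp in ffq_mod.UNFAVORABLE:
        band = np.clip(
            np.rint(5 * (1 - adherence) + band_noise(band_noise_sd)), 0, 5
        ).astype(int)
        data[comp] = _servings_for_band(band, np.asarray(bands[comp], float), rng)

    alc_score = np.clip(
        np.rint(5 * adherence + band_noise(1.15 * band_noise_sd)), 0, 5
    ).astype(int)
    alc_lo = np.array([61.0, 31.0, 15.0, 5.0, 3.0, 1.0])[alc_score]
    alc_hi = np.array([90.0, 60.9, 30.9, 14.9, 4.9, 2.9])[alc_score]
    servings = rng.uniform(alc_lo, alc_hi)
    # half of the would-be heavy drinkers are abstainers (both score 0)
    abstain = (alc_score == 0) & (rng.random(n) < 0.5)
    data["alcohol"] = np.where(abstain, 0.0, servings)

    kind, m, sd, lo, hi = config.covariate_params["caloric_intake"]
    cal = rng.normal(m + 300.0 * (adherence - 0.5), sd)
    data["caloric_intake"] = np.clip(cal, lo, hi)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def _draw(spec: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], n)
    if kind == "normal":
        return rng.normal(spec[1], spec[2], n)
    if kind == "normal_clip":
        return np.clip(rng.normal(spec[1], spec[2], n), spec[3], spec[4])
    if kind == "bernoulli":
        return (rng.random(n) < spec[1]).astype(float)
    if kind == "gamma":
        return rng.gamma(spec[1], spec[2], n)
    if kind == "lognormal":
        return rng.lognormal(spec[1], spec[2], n)
    raise ValueError(f"unknown distribution kind {kind!r}")


def simulate_covariates(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Demographic, motion, and structural covariates per subject."""
    rng = rng or child_rng(config.seed, STREAM_COVARIATES)
    n = config.n_subjects
    p = config.covariate_params
    df = pd.DataFrame({"subject": np.arange(1, n + 1)})
    for name in (
        "age", "education", "nart_iq", "female", "scrub_pct",
        "cortical_thickness", "total_brain_volume", "wmh_volume", "mean_fa",
    ):
        df[name] = _draw(p[name], n, rng)
    probs = np.asarray(p["race"][1:], dtype=float)
    race = rng.choice(["white", "black", "other"], size=n, p=probs / probs.sum())
    df["race"] = race
    df["race_black"] = (race == "black").astype(float)
    df["race_other"] = (race == "other").astype(float)
    df["log_wmh"] = np.log(df["wmh_volume"])
    return df


# ---------------------------------------------------------------------------
# cognition
# ---------------------------------------------------------------------------

def planted_change(
    config: SimulationConfig,
    delta_rsfc: np.ndarray,
    medi_group: np.ndarray,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """True per-subject domain change scores under the planted model.

    MEMORY change = intercept + group slope x Δconnectivity + covariate
    effects + N(0, noise_sd); the other domains drift with their configured
    means/SDs and carry no planted interaction.
    """
    delta = np.asarray(delta_rsfc, dtype=float)
    groups = np.asarray(medi_group)
    n = len(delta)
    unknown = set(np.unique(groups)) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown MeDi group label(s): {sorted(unknown)}")
    slopes = np.array([config.planted_betas[g] for g in groups])
    mu = config.planted_intercept + slopes * delta
    for cov, beta in config.covariate_betas.items():
        mu = mu + beta * covariates[cov].to_numpy()
    noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0
    out = pd.DataFrame({"subject": covariates["subject"].to_numpy()})
    out["delta_MEMORY"] = mu + noise
    for dom in ("FLUID", "SPEED", "VOCAB"):
        m = config.domain_change_means[dom]
        s = config.domain_change_sds[dom]
        out[f"delta_{dom}"] = rng.normal(m, s, n)
    return out


def simulate_cognition(
    config: SimulationConfig,
    delta_rsfc: np.ndarray,
    medi_group: np.ndarray,
    covariates: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-visit task table consistent with the planted change scores.

    Each subject has a latent baseline ability per domain and a stable
    task-specific offset; follow-up ability is baseline plus the planted
    change. Task values are laid out in native units via the
    :data:`TASKS` means/SDs, with timed tasks reversed. With
    ``visit_noise_sd = 0`` the domain composites (standardized against the
    :func:`task_reference_params` parameters) change by exactly the
    planted amount.

    Returns (task table, truth table of planted change scores).
    """
    rng = rng or child_rng(config.seed, STREAM_COGNITION)
    truth = planted_change(config, delta_rsfc, medi_group, covariates, rng)
    n = len(truth)
    subjects = truth["subject"].to_numpy()

    records = []
    for domain, tasks in TASKS.items():
        latent_b = rng.normal(0.0, config.baseline_ability_sd, n)
        latent_f = latent_b + truth[f"delta_{domain}"].to_numpy()
        for task, mean, sd, direction in tasks:
            eps = rng.normal(0.0, config.task_noise_sd, n)
            for visit, latent in (("baseline", latent_b), ("followup", latent_f)):
                theta = latent + eps
                if config.visit_noise_sd > 0:
                    theta = theta + rng.normal(0.0, config.visit_noise_sd, n)
                value = mean + sd * (theta if direction == "higher_better" else -theta)
                records.append(
                    pd.DataFrame(
                        {
                            "subject": subjects,
                            "visit": visit,
                            "task": task,
                            "domain": domain,
                            "value": value,
                            "direction": direction,
                        }
                    )
                )
    return pd.concat(records, ignore_index=True), truth


def task_reference_params() -> pd.DataFrame:
    """True per-task mean/SD of the generator, as a standardization reference."""
    rows = {
        task: {"mean": mean, "sd": sd}
        for tasks in TASKS.values()
        for task, mean, sd, _ in tasks
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "task"
    return df


# ---------------------------------------------------------------------------
# roster
# ---------------------------------------------------------------------------

def simulate_roster(counts: dict[str, int] | None = None) -> pd.DataFrame:
    """Follow-up/missingness roster reproducing the exclusion cascade.

    Flags are assigned to leading blocks of returnee ids, which is
    deterministic and makes each exclusion category disjoint from the
    previous ones, so stepwise exclusion counts equal the requested counts
    exactly.
    """
    c = dict(DEFAULT_ROSTER_COUNTS)
    if counts:
        c.update(counts)
    n = c["enrolled"]
    if c["returned"] > n:
        raise ValueError("returned exceeds enrolled")
    after_diet_rsfc = c["returned"] - c["missing_diet"] - c["missing_rsfc"]
    if after_diet_rsfc < 0:
        raise ValueError("diet/rsFC missing counts exceed returnees")
    if c["missing_dti_fa"] > after_diet_rsfc:
        raise ValueError("DTI FA missing count exceeds remaining sample")
    if c["missing_wmh"] > after_diet_rsfc - c["missing_dti_fa"]:
        raise ValueError("WMH missing count exceeds remaining sample")

    df = pd.DataFrame({"subject": np.arange(1, n + 1)})
    df["returned_followup"] = df["subject"] <= c["returned"]
    for flag in ("has_diet", "has_rsfc_both_visits", "has_dti_fa", "has_wmh"):
        df[flag] = True
    lo = 0
    for flag, key in (
        ("has_diet", "missing_diet"),
        ("has_rsfc_both_visits", "missing_rsfc"),
        ("has_dti_fa", "missing_dti_fa"),
        ("has_wmh", "missing_wmh"),
    ):
        df.loc[lo : lo + c[key] - 1, flag] = False  # label-based, inclusive
        lo += c[key]
    return df


# ---------------------------------------------------------------------------
# merged analysis table (summary-level simulation)
# ---------------------------------------------------------------------------

def simulate_analysis_table(
    config: SimulationConfig, replicate: int = 0
) -> pd.DataFrame:
    """Merged analysis table simulated at the summary level.

    Covariates and MeDi groups are generated through the full FFQ scoring
    path; per-subject Δ connectivity is drawn directly from its
    subject-level distribution (``delta_mean``, ``delta_sd``) instead of
    re-running the time-series stage, and cognitive change comes from the
    planted model. Used by the recovery and calibration experiments.
    """
    rng_cov = child_rng(config.seed, STREAM_ANALYSIS, replicate, 0)
    rng_ffq = child_rng(config.seed, STREAM_ANALYSIS, replicate, 1)
    rng_delta = child_rng(config.seed, STREAM_ANALYSIS, replicate, 2)
    rng_cog = child_rng(config.seed, STREAM_ANALYSIS, replicate, 3)

    cov = simulate_covariates(config, rng=rng_cov)
    ffq = simulate_ffq(config, rng=rng_ffq)
    scores = ffq_mod.score_table(ffq)
    delta = rng_delta.normal(config.delta_mean, config.delta_sd, config.n_subjects)
    truth = planted_change(
        config, delta, scores["medi_group"].to_numpy(), cov, rng_cog
    )
    df = cov.merge(ffq[["subject", "caloric_intake"]], on="subject")
    df = df.merge(scores[["subject", "medi_total", "medi_group"]], on="subject")
    df["delta_overall_between"] = delta
    return df.merge(truth, on="subject")
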