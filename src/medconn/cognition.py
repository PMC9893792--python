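"""Reference-ability composites and longitudinal cognitive change scores.

Four broad cognitive domains — fluid reasoning (FLUID), episodic memory
(MEMORY), processing speed (SPEED) and vocabulary (VOCAB) — are each
measured by up to six tasks per visit. Each task is z-scored against
cohort reference parameters, reaction-time style tasks (``lower_better``)
are sign-flipped so that higher always means better, and the task z-scores
within a domain are averaged into one composite. Change scores are
follow-up minus baseline.

The reference mean/SD default to the baseline visit of the cohort and are
applied to both visits, so change scores reflect raw longitudinal change;
a pooled-visit reference is available. The SD estimator defaults to the
sample convention (n−1 denominator) and is configurable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DOMAINS = ("FLUID", "MEMORY", "SPEED", "VOCAB")
VISITS = ("baseline", "followup")
DIRECTIONS = ("higher_better", "lower_better")

TASK_COLUMNS = ("subject", "visit", "task", "domain", "value", "direction")


def zscore(values, ref_mean: float, ref_sd: float, task: str = "?"):
    """(value − reference mean) / reference SD."""
    if not ref_sd > 0:
        raise ValueError(f"non-positive reference SD for task {task!r}")
    return (np.asarray(values, dtype=float) - ref_mean) / ref_sd


def reference_params(
    task_table: pd.DataFrame, reference: str = "baseline", ddof: int = 1
) -> pd.DataFrame:
    """Per-task reference mean and SD from a long task table.

    ``reference`` is the visit (or ``"pooled"`` for both visits) whose
    observations define the standardization; ``ddof=1`` is the sample-SD
    convention, ``ddof=0`` the population one.
    """
    if reference == "pooled":
        sub = task_table
    elif reference in VISITS:
        sub = task_table[task_table["visit"] == reference]
    else:
        raise ValueError(f"unknown reference {reference!r}")
    grp = sub.groupby("task")["value"]
    out = pd.DataFrame({"mean": grp.mean(), "sd": grp.std(ddof=ddof)})
    zero = out.index[~(out["sd"] > 0)].tolist()
    if zero:
        raise ValueError(f"zero reference SD for task(s): {zero}")
    return out


def composite(z_scores, directions) -> tuple[float, int]:
    """Domain composite: mean of direction-aligned task z-scores.

    ``lower_better`` tasks are negated before averaging. Missing (NaN)
    tasks are dropped; returns (composite, n_tasks_used). All-missing
    yields (NaN, 0) and is logged, never silently zero.
    """
    z = np.asarray(z_scores, dtype=float)
    sign = np.array([-1.0 if d == "lower_better" else 1.0 for d in directions])
    if len(sign) != len(z):
        raise ValueError("z_scores and directions length mismatch")
    aligned = z * sign
    ok = ~np.isnan(aligned)
    if not ok.any():
        logger.warning("composite requested with no non-missing tasks")
        return float("nan"), 0
    return float(aligned[ok].mean()), int(ok.sum())


def build_composites(
    task_table: pd.DataFrame,
    reference: str = "baseline",
    ddof: int = 1,
    ref_params: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per subject-visit domain composites from a long task table.

    ``ref_params`` (per-task mean/sd) overrides the in-sample reference —
    useful when the standardization population is fixed externally.
    Output: one row per (subject, visit) with the four composites and the
    per-domain contributing-task counts.
    """
    missing = set(TASK_COLUMNS) - set(task_table.columns)
    if missing:
        raise ValueError(f"task table missing columns: {sorted(missing)}")
    ref = ref_params if ref_params is not None else reference_params(
        task_table, reference, ddof
    )
    df = task_table.merge(
        ref, left_on="task", right_index=True, how="left", validate="m:1"
    )
    unknown = df.loc[df["mean"].isna(), "task"].unique().tolist()
    if unknown:
        raise ValueError(f"no reference parameters for task(s): {unknown}")
    df["z"] = (df["value"] - df["mean"]) / df["sd"]
    df["z_aligned"] = np.where(df["direction"] == "lower_better", -df["z"], df["z"])

    rows = []
    for (subject, visit), g in df.groupby(["subject", "visit"], sort=True):
        row: dict = {"subject": subject, "visit": visit}
        for domain in DOMAINS:
            gz = g.loc[g["domain"] == domain, "z_aligned"]
            comp, n = composite(gz.to_numpy(), ["higher_better"] * len(gz))
            row[domain] = comp
            row[f"n_tasks_{domain}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def cognitive_change(composites: pd.DataFrame) -> pd.DataFrame:
    """Follow-up minus baseline per domain; subjects missing a visit drop."""
    wide = composites.pivot(index="subject", columns="visit", values=list(DOMAINS))
    rows = []
    for subject in wide.index:
        have = {
            v
            for v in VISITS
            if (DOMAINS[0], v) in wide.columns
            and not np.all(
                [np.isnan(wide.loc[subject, (d, v)]) for d in DOMAINS]
            )
        }
        if have != set(VISITS):
            logger.warning("subject %s missing a visit; dropped from changes", subject)
            continue
        row = {"subject": subject}
        for d in DOMAINS:
            row[f"delta_{d}"] = (
                wide.loc[subject, (d, "followup")] - wide.loc[subject, (d, "baseline")]
            )
        rows.append(row)
    return pd.DataFrame(rows)
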