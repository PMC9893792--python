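"""Mediterranean-diet adherence (MeDi) scoring from food-frequency data.

Eleven food categories are each scored 0–5 from monthly serving
frequencies, summing to a 0–55 adherence index:

* favorable components (non-refined cereals, potatoes, fruits, vegetables,
  legumes, fish, olive oil) score higher with higher intake;
* unfavorable components (poultry, red meat, full-fat dairy) are
  reverse-scored, so higher scores correspond to lower intake;
* alcohol is unimodal: 0 for no consumption, 5 down to 1 across the bands
  1–2, 3–4, 5–14, 15–30 and 31–60 servings/month, and 0 again above 60.

Band edges for the non-alcohol components are configuration, not a fixed
constant of the index; :data:`DEFAULT_BANDS` provides documented defaults
and every edge set must contain five strictly ascending values. Bands are
half-open ``[edge, next_edge)``, so a serving count equal to an edge falls
in the band that edge opens.

Cohort totals are split into low / moderate / high adherence groups at the
empirical 1/3 and 2/3 quantiles; subjects exactly at a cutpoint go to the
lower group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FAVORABLE = (
    "non_refined_cereals",
    "potatoes",
    "fruits",
    "vegetables",
    "legumes",
    "fish",
    "olive_oil",
)
UNFAVORABLE = ("poultry", "red_meat", "full_fat_dairy")
ALCOHOL = "alcohol"
COMPONENTS = FAVORABLE + UNFAVORABLE + (ALCOHOL,)

MAX_TOTAL = 55

GROUPS = ("low", "moderate", "high")

#: Default band edges (servings/month): five ascending edges per component,
#: giving six frequency bands scored 0–5 (or 5–0 for reverse-scored
#: components). Near-daily foods use wider bands than occasional foods.
DEFAULT_BANDS: dict[str, tuple[float, ...]] = {
    "non_refined_cereals": (1, 5, 12, 30, 60),
    "potatoes": (1, 4, 8, 12, 30),
    "fruits": (1, 5, 12, 30, 60),
    "vegetables": (1, 5, 12, 30, 60),
    "legumes": (1, 2, 4, 8, 12),
    "fish": (1, 2, 4, 8, 12),
    "olive_oil": (1, 5, 12, 30, 60),
    "poultry": (1, 2, 4, 8, 12),
    "red_meat": (1, 2, 4, 8, 12),
    "full_fat_dairy": (1, 5, 12, 30, 60),
}

# alcohol band lower edges; scores for the bands they open are 5,4,3,2,1,0
_ALCOHOL_EDGES = np.array([1.0, 3.0, 5.0, 15.0, 31.0, 61.0])
_ALCOHOL_SCORES = np.array([0, 5, 4, 3, 2, 1, 0])


@dataclass
class MeDiResult:
    """Component scores, 0–55 total, and (once assigned) tertile group."""

    subject: object
    component_scores: dict[str, int]
    total: int
    group: str | None = None

    @property
    def continuous_score(self) -> int:
        return self.total

    def __post_init__(self) -> None:
        if self.total != sum(self.component_scores.values()):
            raise ValueError("total does not equal the sum of component scores")
        if not 0 <= self.total <= MAX_TOTAL:
            raise ValueError(f"total {self.total} outside [0, {MAX_TOTAL}]")


def _check_bands(bands) -> np.ndarray:
    edges = np.asarray(bands, dtype=float)
    if edges.shape != (5,) or not np.all(np.diff(edges) > 0):
        raise ValueError("band edges must be 5 strictly ascending values")
    return edges


def score_component(component: str, servings, bands) -> int | np.ndarray:
    """Score one non-alcohol component 0–5 from servings/month.

    Favorable components score the band index directly; unfavorable
    components score ``5 - band``. Vectorized over ``servings``.
    """
    if component == ALCOHOL:
        raise ValueError("alcohol has a dedicated rule; use score_alcohol")
    if component not in FAVORABLE and component not in UNFAVORABLE:
        raise ValueError(f"unknown component {component!r}")
    edges = _check_bands(bands)
    s = np.asarray(servings, dtype=float)
    if np.any(s < 0):
        raise ValueError(f"negative servings for {component}")
    band = np.searchsorted(edges, s, side="right")
    score = band if component in FAVORABLE else 5 - band
    return int(score) if np.isscalar(servings) else score.astype(int)


def score_alcohol(servings) -> int | np.ndarray:
    """Unimodal alcohol score: 0, then 5..1 over the printed bands, then 0.

    Zero intake and intakes above 60 servings/month both score 0; intakes
    in (0, 1) fall below the lowest band and also score 0. Bands are
    half-open at their integer lower edges: [1,3)→5, [3,5)→4, [5,15)→3,
    [15,31)→2, [31,61)→1.
    """
    s = np.asarray(servings, dtype=float)
    if np.any(s < 0):
        raise ValueError("negative alcohol servings")
    score = _ALCOHOL_SCORES[np.searchsorted(_ALCOHOL_EDGES, s, side="right")]
    return int(score) if np.isscalar(servings) else score.astype(int)


def total_medi(record: dict, band_config: dict, subject=None) -> MeDiResult:
    """Total 0–55 MeDi score for one subject's FFQ record.

    ``record`` maps each of the 11 component names to servings/month
    (extra keys such as caloric intake are ignored). A missing component
    raises — there is no imputation.
    """
    scores: dict[str, int] = {}
    for comp in FAVORABLE + UNFAVORABLE:
        if comp not in record:
            raise ValueError(f"missing FFQ component {comp!r}")
        if comp not in band_config:
            raise ValueError(f"no band edges configured for {comp!r}")
        scores[comp] = int(score_component(comp, record[comp], band_config[comp]))
    if ALCOHOL not in record:
        raise ValueError(f"missing FFQ component {ALCOHOL!r}")
    scores[ALCOHOL] = int(score_alcohol(record[ALCOHOL]))
    return MeDiResult(subject, scores, sum(scores.values()))


def assign_tertiles(scores, labels: tuple[str, str, str] = GROUPS) -> np.ndarray:
    """Label each score low/moderate/high by empirical tertile cutpoints.

    Cutpoints are the 1/3 and 2/3 quantiles (linear interpolation); scores
    equal to a cutpoint go to the lower group, so all tied subjects share a
    label and the assignment is invariant to input order.
    """
    a = np.asarray(scores, dtype=float)
    if a.size < 3 or np.unique(a).size < 3:
        raise ValueError("tertiles require at least 3 distinct score values")
    q1, q2 = np.quantile(a, [1 / 3, 2 / 3])
    out = np.where(a <= q1, labels[0], np.where(a <= q2, labels[1], labels[2]))
    return out


def score_table(
    ffq: pd.DataFrame,
    band_config: dict | None = None,
    subject_col: str = "subject",
    assign_groups: bool = True,
) -> pd.DataFrame:
    """Score an FFQ table; returns per-subject component scores, total, group.

    Vectorized across subjects; columns must include the 11 component names.
    """
    bands = DEFAULT_BANDS if band_config is None else band_config
    missing = [c for c in COMPONENTS if c not in ffq.columns]
    if missing:
        raise ValueError(f"FFQ table missing components: {missing}")
    out = pd.DataFrame({subject_col: ffq[subject_col].to_numpy()})
    for comp in FAVORABLE + UNFAVORABLE:
        out[f"score_{comp}"] = score_component(
            comp, ffq[comp].to_numpy(), bands[comp]
        )
    out[f"score_{ALCOHOL}"] = score_alcohol(ffq[ALCOHOL].to_numpy())
    score_cols = [f"score_{c}" for c in COMPONENTS]
    out["medi_total"] = out[score_cols].sum(axis=1)
    if assign_groups:
        out["medi_group"] = assign_tertiles(out["medi_total"].to_numpy())
    return out
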