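"""Emotional-intelligence scoring and HRV-guided group-cutoff selection.

The EI task battery crosses 3 evaluation indices (self-awareness, others'
awareness, emotion discrimination) × 4 emotion categories × 10 stimulus
instances; each correct response scores 10 points, for a total in [0, 1200]
with at most 400 points per index.

The High/Low grouping cutoff is not fixed a priori: candidate cutoffs are
scanned at fixed intervals, and for each one a two-way Type III ANOVA
(sum-to-zero contrasts) of every HRV variable on EI-group × emotion tests
for an interaction. The selected cutoff maximizes the number of HRV
variables with a significant interaction while keeping group sizes
acceptably balanced; participants score *above* the cutoff into High, at or
below into Low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

N_EVAL_INDICES = 3
N_EMOTION_CATEGORIES = 4
N_STIMULUS_INSTANCES = 10
POINTS_PER_RESPONSE = 10


class DegenerateDesignError(ValueError):
    """Raised when an ANOVA design has empty cells or no residual df."""


@dataclass(frozen=True)
class EIResponseSet:
    """Correctness indicators for one participant's full EI task battery.

    ``indicators`` has shape (3, 4, 10): evaluation index × emotion category
    × stimulus instance, entries truthy for correct responses.
    """

    participant: str
    indicators: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.indicators)
        expected = (N_EVAL_INDICES, N_EMOTION_CATEGORIES, N_STIMULUS_INSTANCES)
        if arr.shape != expected:
            raise ValueError(
                f"response set must have shape {expected} (= 120 indicators), got {arr.shape}"
            )
        if np.isnan(arr.astype(float)).any():
            raise ValueError("response set contains missing indicators")
        object.__setattr__(self, "indicators", arr.astype(bool))


@dataclass(frozen=True)
class EIScore:
    """Total EI score (0–1200 in steps of 10) plus per-index subscores."""

    participant: str
    total: int
    index_subscores: tuple[int, int, int]


def score_ei(responses: EIResponseSet) -> EIScore:
    """Score a complete response set: 10 points per correct indicator."""
    per_index = POINTS_PER_RESPONSE * responses.indicators.sum(axis=(1, 2))
    return EIScore(
        participant=responses.participant,
        total=int(per_index.sum()),
        index_subscores=tuple(int(s) for s in per_index),
    )


def anova_interaction_p(values, group, emotion) -> float:
    """Type III two-way ANOVA interaction p-value with sum-to-zero contrasts.

    Fits ``value ~ group * emotion`` with Sum (deviation) coding and returns
    the p-value of the group × emotion interaction F-test from Type III sums
    of squares. Replicates within each group × emotion cell are treated as
    independent observations.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "grp": pd.Categorical(group),
            "emo": pd.Categorical(emotion),
        }
    )
    if df["value"].isna().any():
        raise ValueError("values contain NaN")
    cells = df.groupby(["grp", "emo"], observed=False).size()
    if (cells == 0).any():
        raise DegenerateDesignError("empty group × emotion cell")
    n_cells = df["grp"].nunique() * df["emo"].nunique()
    if len(df) <= n_cells:
        raise DegenerateDesignError("no residual degrees of freedom")
    if np.ptp(df["value"].to_numpy()) == 0.0:
        raise DegenerateDesignError("constant response values: F undefined")

    model = smf.ols("value ~ C(grp, Sum) * C(emo, Sum)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    p = float(table.loc["C(grp, Sum):C(emo, Sum)", "PR(>F)"])
    if not np.isfinite(p):
        raise DegenerateDesignError("interaction F-test undefined for this design")
    return p


def candidate_grid(ei_scores, step: float = 10.0, percentile_range=(10.0, 90.0)) -> np.ndarray:
    """Cutoff candidates: multiples of ``step`` between the given EI percentiles."""
    ei = np.asarray(ei_scores, dtype=float)
    lo, hi = np.percentile(ei, percentile_range)
    start = np.ceil(lo / step) * step
    return np.arange(start, hi + 1e-9, step)


def scan_cutoffs(
    hrv: pd.DataFrame,
    ei_scores: pd.Series,
    candidates,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Evaluate every candidate EI cutoff against the HRV table.

    Parameters
    ----------
    hrv
        Long-by-condition table: columns ``participant``, ``condition``, and
        one column per HRV variable.
    ei_scores
        Series of EI scores indexed by participant id.
    candidates
        Iterable of cutoff values on the 0–1200 scale.
    alpha
        Per-variable significance level for the interaction test.

    Returns
    -------
    One row per candidate: ``cutoff``, ``n_significant``, ``n_high``,
    ``n_low``, ``imbalance`` (= |n_high − n_low|), ``degenerate``. A
    candidate producing an empty group or an untestable design is flagged
    degenerate and not scored.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    hrv_vars = [c for c in hrv.columns if c not in ("participant", "condition")]
    if not hrv_vars:
        raise ValueError("HRV table has no feature columns")

    rows = []
    for cutoff in candidates:
        labels = assign_groups(ei_scores, cutoff)
        n_high = int((labels == "High").sum())
        n_low = int((labels == "Low").sum())
        rec = {
            "cutoff": float(cutoff),
            "n_high": n_high,
            "n_low": n_low,
            "imbalance": abs(n_high - n_low),
        }
        if n_high == 0 or n_low == 0:
            rec.update(n_significant=np.nan, degenerate=True)
            rows.append(rec)
            continue
        grp = hrv["participant"].map(labels)
        try:
            n_sig = sum(
                anova_interaction_p(hrv[var], grp, hrv["condition"]) < alpha
                for var in hrv_vars
            )
            rec.update(n_significant=n_sig, degenerate=False)
        except DegenerateDesignError:
            rec.update(n_significant=np.nan, degenerate=True)
        rows.append(rec)
    return pd.DataFrame(rows)


def select_cutoff(scan: pd.DataFrame, max_imbalance: float) -> float:
    """Pick the cutoff with the most significant interactions under balance.

    Among non-degenerate candidates with imbalance ≤ ``max_imbalance``,
    returns the one with maximal ``n_significant``; ties broken by smaller
    imbalance, then lower cutoff.
    """
    ok = scan[(~scan["degenerate"]) & (scan["imbalance"] <= max_imbalance)]
    if ok.empty:
        raise ValueError("no admissible cutoff candidate within the imbalance bound")
    ok = ok.sort_values(
        ["n_significant", "imbalance", "cutoff"], ascending=[False, True, True]
    )
    return float(ok.iloc[0]["cutoff"])


def assign_groups(ei_scores: pd.Series, cutoff: float) -> pd.Series:
    """Label participants High (score > cutoff) or Low (score ≤ cutoff)."""
    ei = pd.Series(ei_scores, dtype=float)
    return pd.Series(np.where(ei > cutoff, "High", "Low"), index=ei.index, name="group")
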