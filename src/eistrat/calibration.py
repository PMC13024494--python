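"""Type-I-error and power calibration of the group-comparison stack.

The comparison machinery (paired DeLong + Fisher + inverse-variance pooling
+ item-clustered GEE + BH-FDR) is exercised on evaluation tables simulated
directly at the score level, which makes hundreds of replicates affordable:

    raw score  s_{g,r,i} = b_g · y*_i + u_i + ε_{g,r,i}
    score      = sigmoid(s),   prediction = [s ≥ 0],   correct = [sign agrees]

with y*_i = ±1 the item's balanced binary label, u_i ~ N(0, τ²) a shared
item effect (inducing the within-item correlation across groups and
repetitions that the GEE is meant to absorb), ε ~ N(0, σ²) independent
model-specific noise, and b_g the group's signal strength.

* **null scenario** — all groups share one b: any rejection is a false
  positive, so the family-wise rejection rate estimates the stack's type-I
  error at the chosen α.
* **effect scenario** — one group's b is reduced by ``effect`` (the
  score-level consequence of training on less label-congruent data): the
  rate at which that contrast's GEE odds ratio is flagged below 1 estimates
  power.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import compare_groups

GROUPS = ("High", "Low", "Total")


def simulate_evaluation(
    n_items: int = 100,
    repetitions: int = 5,
    tasks=("arousal", "valence"),
    conditions=("baseline",),
    groups=GROUPS,
    signal: float = 1.0,
    item_sd: float = 1.0,
    noise_sd: float = 1.0,
    group_signal: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a repetition-level evaluation table at the score level.

    ``group_signal`` overrides the common ``signal`` per group; leaving it
    empty yields the exchangeable null in which every group's scores follow
    the same process on the shared items.
    """
    rng = np.random.default_rng([29, seed])
    b = {g: (group_signal or {}).get(g, signal) for g in groups}
    rows = []
    for task in tasks:
        for condition in conditions:
            y = np.tile([0, 1], n_items // 2 + 1)[:n_items]
            ystar = 2.0 * y - 1.0
            u = rng.normal(0.0, item_sd, n_items)
            items = [f"{task[:3]}-{condition[:4]}-{i:04d}" for i in range(n_items)]
            for rep in range(1, repetitions + 1):
                for g in groups:
                    s = b[g] * ystar + u + rng.normal(0.0, noise_sd, n_items)
                    score = 1.0 / (1.0 + np.exp(-s))
                    pred = (s >= 0.0).astype(int)
                    rows.append(
                        pd.DataFrame(
                            {
                                "task": task,
                                "condition": condition,
                                "group": g,
                                "repetition": rep,
                                "item": items,
                                "score": score,
                                "pred": pred,
                                "label": y,
                                "correct": (pred == y).astype(int),
                            }
                        )
                    )
    return pd.concat(rows, ignore_index=True)


def run_calibration(
    n_replicates: int = 200,
    scenario: str = "null",
    seed: int = 0,
    n_items: int = 100,
    repetitions: int = 5,
    tasks=("arousal", "valence"),
    conditions=("baseline",),
    effect: float = 0.6,
    disadvantaged: str = "Low",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate the full comparison pipeline on simulated evaluation tables.

    Returns (summary, replicate table). The summary has one row per
    multiplicity family (condition × task × statistic type) with the
    fraction of replicates in which any q-value in that family fell below
    ``alpha``; under the effect scenario it also reports, per contrast, the
    fraction of replicates flagging the disadvantaged group's GEE odds ratio
    (q < α and OR < 1).
    """
    if scenario not in ("null", "effect"):
        raise ValueError("scenario must be 'null' or 'effect'")
    if n_replicates < 2:
        import warnings

        warnings.warn("fewer than 2 replicates: rejection rates are degenerate")
    group_signal = None
    if scenario == "effect":
        group_signal = {disadvantaged: max(1.0 - effect, 0.0)}

    records = []
    for rep in range(n_replicates):
        table = simulate_evaluation(
            n_items=n_items,
            repetitions=repetitions,
            tasks=tasks,
            conditions=conditions,
            group_signal=group_signal,
            seed=seed * 100_003 + rep,
        )
        report = compare_groups(table, alpha=alpha)
        for row in report.table.itertuples(index=False):
            records.append(
                {
                    "replicate": rep,
                    "condition": row.condition,
                    "task": row.task,
                    "contrast": row.contrast,
                    "q_delong": row.q_delong,
                    "q_gee": row.q_gee,
                    "pooled_delta_auc": row.pooled_delta_auc,
                    "odds_ratio": row.odds_ratio,
                }
            )
    reps = pd.DataFrame(records)

    summaries = []
    for stat in ("delong", "gee"):
        fam = (
            reps.assign(reject=reps[f"q_{stat}"] < alpha)
            .groupby(["condition", "task", "replicate"])["reject"]
            .any()
            .groupby(["condition", "task"])
            .mean()
        )
        for (condition, task), rate in fam.items():
            summaries.append(
                {
                    "condition": condition,
                    "task": task,
                    "statistic": stat,
                    "family_rejection_rate": float(rate),
                }
            )
    summary = pd.DataFrame(summaries)
    if scenario == "effect":
        flagged = (
            reps[reps["contrast"] == disadvantaged]
            .assign(flag=lambda d: (d["q_gee"] < alpha) & (d["odds_ratio"] < 1.0))
            .groupby(["condition", "task"])["flag"]
            .mean()
            .rename("power_or_flagged")
            .reset_index()
        )
        summary = summary.merge(flagged, on=["condition", "task"], how="left")
    return summary, reps
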