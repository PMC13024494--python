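"""Repetition-level statistical comparison of classifiers on a fixed test set.

Competing models are evaluated on the *same* test items across R independent
training repetitions, so naive per-repetition comparisons are doubly
correlated: across models (shared items) and across repetitions (shared
items again). The stack implemented here follows standard practice for this
design:

* discrimination — within each repetition, a **paired DeLong test** on the
  correlated ROC-AUCs (structural-components covariance); across
  repetitions, **Fisher's method** combines the per-repetition p-values and
  a **fixed-effect inverse-variance** pool yields an overall ΔAUC with CI;
* correctness — a **binomial GEE** on the item-level correct/incorrect bit,
  with training group (High-EI reference) and repetition as fixed effects,
  an exchangeable working correlation clustered on test items, and robust
  (sandwich) standard errors, reported as odds ratios;
* multiplicity — **Benjamini–Hochberg FDR** within each family of
  comparisons (condition × task × statistic type, spanning the contrasts).

`compare_groups` drives the whole stack over a repetition-level evaluation
table and returns a results object shaped like a standard comparison table
(one row per condition × task × contrast).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

Z95 = 1.959963984540054
P_FLOOR = 1e-300

CONTRASTS = ("Low", "Total")


class InferenceError(ValueError):
    """Raised when a statistical comparison cannot be computed."""


# ---------------------------------------------------------------------------
# ROC-AUC and the paired DeLong test


def roc_auc(scores, labels) -> float:
    """Mann–Whitney ROC-AUC with half credit for tied scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise InferenceError("both classes required to compute ROC-AUC")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg)))


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components: positive-side and negative-side placements."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    cmp = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)  # V10 (per positive), V01 (per negative)


def auc_variance(scores, labels) -> float:
    """DeLong variance of a single ROC-AUC from its structural components."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    v10, v01 = _placements(scores, labels)
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise InferenceError("need at least two items per class for the AUC variance")
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


@dataclass(frozen=True)
class DeLongResult:
    """Paired comparison of two correlated ROC-AUCs on the same items."""

    auc_a: float
    auc_b: float
    delta: float  # AUC_A − AUC_B
    se: float
    ci: tuple[float, float]
    z: float
    p: float


def delong_paired(scores_a, scores_b, labels) -> DeLongResult:
    """Paired DeLong test for ΔAUC of two models scored on identical items.

    The variance of ΔAUC comes from the empirical covariance of the
    structural components (placement values) of the two models; p is
    two-sided normal. A degenerate SE of 0 with ΔAUC = 0 (e.g., two perfect
    scorers) yields p = 1 by convention.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise InferenceError("paired score vectors and labels must share one shape")
    m = int((labels == 1).sum())
    n = int((labels == 0).sum())
    if m == 0 or n == 0:
        raise InferenceError("both classes required for the DeLong test")

    v10_a, v01_a = _placements(scores_a, labels)
    v10_b, v01_b = _placements(scores_b, labels)
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())
    delta = auc_a - auc_b

    if m > 1:
        s10 = np.cov(np.vstack([v10_a, v10_b]))
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01_a, v01_b]))
    else:
        s01 = np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    se = float(np.sqrt(max(var, 0.0)))

    if se == 0.0:
        if delta == 0.0:
            z, p = 0.0, 1.0
        else:
            raise InferenceError("degenerate DeLong variance with nonzero ΔAUC")
    else:
        z = delta / se
        p = float(2.0 * sps.norm.sf(abs(z)))
    return DeLongResult(
        auc_a=auc_a,
        auc_b=auc_b,
        delta=delta,
        se=se,
        ci=(delta - Z95 * se, delta + Z95 * se),
        z=float(z),
        p=p,
    )


# ---------------------------------------------------------------------------
# Aggregation across repetitions


def fisher_combine(p_values) -> tuple[float, int, float]:
    """Fisher's method: statistic −2·Σ ln p ~ chi-square(2k) under the null.

    Returns (statistic, df, combined p). Zero p-values are clipped to a tiny
    floor with a warning.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise InferenceError("need at least one p-value to combine")
    if np.any((p < 0) | (p > 1)):
        raise InferenceError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn(f"p-values of 0 clipped to {P_FLOOR}")
        p = np.maximum(p, P_FLOOR)
    stat = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return stat, df, float(sps.chi2.sf(stat, df))


def pool_fixed_effect(deltas, ses) -> tuple[float, float, tuple[float, float]]:
    """Fixed-effect inverse-variance pooling of repetition-level ΔAUCs.

    Weights are 1/SE²; repetitions with SE = 0 are excluded with a warning.
    Returns (pooled estimate, pooled SE, 95% Wald CI).
    """
    deltas = np.asarray(list(deltas), dtype=float)
    ses = np.asarray(list(ses), dtype=float)
    if deltas.shape != ses.shape:
        raise InferenceError("deltas and SEs must have equal length")
    keep = ses > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} repetition(s) with zero SE from pooling")
    if not keep.any():
        raise InferenceError("all repetitions excluded: no positive SEs to pool")
    w = 1.0 / ses[keep] ** 2
    est = float(np.sum(w * deltas[keep]) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return est, se, (est - Z95 * se, est + Z95 * se)


# ---------------------------------------------------------------------------
# Binomial GEE on item-level correctness


@dataclass(frozen=True)
class GEEResult:
    """Odds ratio of correct classification for one group contrast."""

    contrast: str  # comparator group (reference = High)
    odds_ratio: float
    ci: tuple[float, float]
    p: float
    dep_correlation: float
    n_clusters: int
    unstable: bool = False


def gee_binomial(
    correctness: pd.DataFrame,
    contrasts=CONTRASTS,
    reference: str = "High",
    independence: bool = False,
) -> list[GEEResult]:
    """Fit the item-clustered binomial GEE and extract group odds ratios.

    ``correctness`` needs columns ``item``, ``group``, ``repetition``,
    ``correct`` (0/1). The mean model is logit P(correct) ~ group +
    repetition with ``reference`` as the baseline group; clustering is on
    ``item`` with an exchangeable working correlation (or independence when
    requested); CIs use robust sandwich standard errors. Complete separation
    within a group (all correct or all incorrect) is flagged ``unstable``.
    """
    df = correctness.copy()
    for col in ("item", "group", "repetition", "correct"):
        if col not in df.columns:
            raise InferenceError(f"correctness table missing column {col!r}")
    groups_present = set(df["group"])
    if reference not in groups_present:
        raise InferenceError(f"reference group {reference!r} absent from data")
    levels = [reference] + [g for g in contrasts if g in groups_present]
    df = df[df["group"].isin(levels)]
    df["group"] = pd.Categorical(df["group"], categories=levels)
    df["repetition"] = pd.Categorical(df["repetition"])

    if df["correct"].nunique() < 2:
        # All items correct (or all incorrect) for every group: the group
        # effect is unidentified. Report a unit OR flagged unstable.
        warnings.warn("correctness outcome is constant: GEE group effect unidentified")
        return [
            GEEResult(
                contrast=g,
                odds_ratio=1.0,
                ci=(float("nan"), float("nan")),
                p=1.0,
                dep_correlation=float("nan"),
                n_clusters=int(df["item"].nunique()),
                unstable=True,
            )
            for g in levels[1:]
        ]

    y = df["correct"].to_numpy(dtype=float)
    X = pd.get_dummies(df[["group", "repetition"]], drop_first=True, dtype=float)
    X = sm.add_constant(X)
    cov = sm.cov_struct.Independence() if independence else sm.cov_struct.Exchangeable()
    model = sm.GEE(y, X, groups=df["item"].to_numpy(), family=sm.families.Binomial(), cov_struct=cov)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=200, ctol=1e-8)
        except Exception as exc:  # noqa: BLE001 - surfaced as inference error
            raise InferenceError(f"GEE failed to converge: {exc}") from exc

    dep = 0.0 if independence else float(np.clip(cov.dep_params, -1.0, 1.0 - 1e-12))
    n_clusters = int(df["item"].nunique())
    sep_groups = {
        g for g, sub in df.groupby("group", observed=True) if sub["correct"].nunique() < 2
    }

    out = []
    ci = res.conf_int()
    for g in levels[1:]:
        name = f"group_{g}"
        if name not in X.columns:
            continue
        coef = float(res.params[name])
        lo, hi = (float(ci.loc[name, 0]), float(ci.loc[name, 1]))
        unstable = g in sep_groups or reference in sep_groups
        if unstable:
            warnings.warn(f"separation detected for contrast {reference} vs {g}: OR unstable")
        out.append(
            GEEResult(
                contrast=g,
                odds_ratio=float(np.exp(coef)),
                ci=(float(np.exp(lo)), float(np.exp(hi))),
                p=float(res.pvalues[name]),
                dep_correlation=dep,
                n_clusters=n_clusters,
                unstable=unstable,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Benjamini–Hochberg FDR


def bh_fdr(p_values, families=None) -> np.ndarray:
    """Benjamini–Hochberg q-values, computed within each family.

    ``families`` assigns each p-value to a multiplicity family (default: one
    family). Order of the input is preserved.
    """
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    fam = np.zeros(len(p)) if families is None else np.asarray(list(families))
    q = np.empty_like(p)
    for f in pd.unique(fam):
        idx = np.flatnonzero(fam == f)
        q[idx] = sm.stats.multipletests(p[idx], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# The full comparison report


@dataclass
class ComparisonReport:
    """Comparison-table results object.

    ``table`` has one row per (condition, task, contrast) with pooled ΔAUC
    (+ CI), the Fisher-combined repetition-level DeLong q-value, and the GEE
    odds ratio (+ robust CI) with its q-value. Sign convention: ΔAUC =
    High-group AUC − comparator AUC; OR compares the comparator against the
    High reference (OR < 1 = comparator less often correct).
    """

    table: pd.DataFrame
    alpha: float = 0.05
    details: dict = field(default_factory=dict, repr=False)

    def summary(self) -> str:
        cols = [
            "condition", "task", "contrast",
            "pooled_delta_auc", "delta_ci_lo", "delta_ci_hi", "q_delong",
            "odds_ratio", "or_ci_lo", "or_ci_hi", "q_gee",
        ]
        df = self.table[cols].copy()
        num = df.columns.difference(["condition", "task", "contrast"])
        df[num] = df[num].map(lambda x: f"{x:.4g}")
        title = "Group comparison: paired DeLong (pooled) and binomial GEE"
        return f"{title}\n{'=' * len(title)}\n{df.to_string(index=False)}"

    def significant(self) -> pd.DataFrame:
        t = self.table
        return t[(t["q_delong"] < self.alpha) | (t["q_gee"] < self.alpha)]


def compare_groups(
    evaluation: pd.DataFrame,
    contrasts=CONTRASTS,
    reference: str = "High",
    alpha: float = 0.05,
) -> ComparisonReport:
    """Run the full inference stack over a repetition-level evaluation table.

    ``evaluation`` holds one row per (task, condition, group, repetition,
    item) with columns ``score``, ``label``, ``correct``. For every
    (condition, task): each contrast gets per-repetition paired DeLong tests
    (reference vs comparator on identical items), Fisher combination and
    inverse-variance pooling across repetitions; one GEE per (condition,
    task) provides both contrasts' odds ratios. BH-FDR is applied within
    each (condition, task, statistic-type) family across the contrasts.
    """
    required = {"task", "condition", "group", "repetition", "item", "score", "label", "correct"}
    missing = required - set(evaluation.columns)
    if missing:
        raise InferenceError(f"evaluation table missing columns: {sorted(missing)}")

    rows = []
    details: dict = {}
    for (condition, task), cell in evaluation.groupby(["condition", "task"], sort=True):
        gee_results = {
            r.contrast: r
            for r in gee_binomial(cell, contrasts=contrasts, reference=reference)
        }
        for comparator in contrasts:
            per_rep = []
            for rep, rep_df in cell.groupby("repetition", sort=True):
                ref = rep_df[rep_df["group"] == reference].set_index("item")
                cmp_ = rep_df[rep_df["group"] == comparator].set_index("item")
                items = ref.index.sort_values()
                if not items.equals(cmp_.index.sort_values()):
                    raise InferenceError(
                        f"item sets differ between {reference} and {comparator} "
                        f"in ({condition}, {task}, rep {rep})"
                    )
                per_rep.append(
                    delong_paired(
                        ref.loc[items, "score"], cmp_.loc[items, "score"], ref.loc[items, "label"]
                    )
                )
            _, _, p_comb = fisher_combine([r.p for r in per_rep])
            if all(r.se == 0.0 and r.delta == 0.0 for r in per_rep):
                # Every repetition compared two identical perfect scorers
                # (ceiling): ΔAUC is exactly 0 with no sampling variability.
                pooled, pooled_se, ci = 0.0, 0.0, (0.0, 0.0)
            else:
                pooled, pooled_se, ci = pool_fixed_effect(
                    [r.delta for r in per_rep], [r.se for r in per_rep]
                )
            g = gee_results.get(comparator)
            if g is None:
                raise InferenceError(f"no GEE contrast for group {comparator!r}")
            rows.append(
                {
                    "condition": condition,
                    "task": task,
                    "contrast": comparator,
                    "pooled_delta_auc": pooled,
                    "pooled_se": pooled_se,
                    "delta_ci_lo": ci[0],
                    "delta_ci_hi": ci[1],
                    "p_delong": p_comb,
                    "odds_ratio": g.odds_ratio,
                    "or_ci_lo": g.ci[0],
                    "or_ci_hi": g.ci[1],
                    "p_gee": g.p,
                    "gee_unstable": g.unstable,
                }
            )
            details[(condition, task, comparator)] = per_rep

    table = pd.DataFrame(rows)
    fam = table["condition"].astype(str) + "|" + table["task"].astype(str)
    table["q_delong"] = bh_fdr(table["p_delong"], fam + "|delong")
    table["q_gee"] = bh_fdr(table["p_gee"], fam + "|gee")
    return ComparisonReport(table=table, alpha=alpha, details=details)
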