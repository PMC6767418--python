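"""Looking metrics and behavioural statistics for the change-detection task.

Per trial, coded looks to the left/right display yield four metrics:
total looking time (TLT, ms), mean look duration (MLD = TLT / number of
looks), switch rate (SR = switches / TLT × 1000, i.e. switches per second of
looking), and change preference (CP = looking time on the changing side /
TLT). CP above 0.5 indicates change detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "LookEvent",
    "TrialCoding",
    "TrialMetrics",
    "UncodableTrial",
    "classify_load",
    "compute_trial_metrics",
    "aggregate_participant",
    "chance_test",
    "load_anova",
    "forward_regression",
    "outlier_robustness",
]

LOADS = ("low", "medium", "high")

#: Age-banded item counts: (load label by position low→high)
ITEM_SETS = {"infant": (1, 2, 3), "older": (2, 4, 6)}


@dataclass(frozen=True)
class LookEvent:
    side: str  # "left" | "right"
    onset: float  # ms
    offset: float  # ms

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"bad side {self.side!r}")
        if self.offset <= self.onset:
            raise ValueError("look offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class TrialCoding:
    participant_id: str
    trial_index: int
    load_class: str
    n_items: int
    changing_side: str
    looks: list
    trial_duration: float = 10000.0  # ms

    def __post_init__(self):
        if self.load_class not in LOADS:
            raise ValueError(f"bad load {self.load_class!r}")
        if self.changing_side not in ("left", "right"):
            raise ValueError(f"bad changing side {self.changing_side!r}")
        looks = sorted(self.looks, key=lambda e: e.onset)
        for a, b in zip(looks, looks[1:]):
            if b.onset < a.offset:
                raise ValueError("look events overlap")
        self.looks = looks


@dataclass(frozen=True)
class TrialMetrics:
    tlt: float  # ms
    mld: float  # ms
    sr: float  # switches per second of looking
    cp: float  # ∈ [0, 1]
    n_looks: int
    n_switches: int


class UncodableTrial(ValueError):
    """Raised for trials with no coded looks (excluded, never zero-filled)."""


def classify_load(age_months: float, n_items: int) -> str:
    """Map item count to {low, medium, high} given the age band.

    Children under 24 months receive loads 1/2/3; older children 2/4/6.
    """
    band = "infant" if age_months < 24 else "older"
    items = ITEM_SETS[band]
    if n_items not in items:
        raise ValueError(
            f"{n_items} items invalid for age {age_months} months; "
            f"expected one of {items}"
        )
    return LOADS[items.index(n_items)]


def compute_trial_metrics(trial: TrialCoding) -> TrialMetrics:
    """TLT, MLD, SR and CP from coded looks.

    A switch is counted at every transition between consecutive coded looks
    on different sides (uncoded gaps between them do not cancel the switch).
    """
    if not trial.looks:
        raise UncodableTrial(f"trial {trial.trial_index} has no coded looks")
    durs = np.array([e.duration for e in trial.looks])
    sides = [e.side for e in trial.looks]
    tlt = float(durs.sum())
    n_looks = len(trial.looks)
    n_switches = sum(a != b for a, b in zip(sides, sides[1:]))
    changing_time = float(durs[[s == trial.changing_side for s in sides]].sum())
    return TrialMetrics(
        tlt=tlt,
        mld=tlt / n_looks,
        sr=n_switches / tlt * 1000.0,
        cp=changing_time / tlt,
        n_looks=n_looks,
        n_switches=n_switches,
    )


def aggregate_participant(trials: list, metrics: list | None = None) -> dict:
    """Per-load means of each metric plus inclusion flag.

    ``trials`` is a list of TrialCoding; uncodable trials are excluded.
    Returns {"means": DataFrame indexed by load, "counts": {...},
    "included": bool} — a participant is included only with ≥ 1 codable
    trial at every load.
    """
    rows = []
    for tr in trials:
        try:
            m = compute_trial_metrics(tr)
        except UncodableTrial:
            continue
        rows.append(
            {"load": tr.load_class, "tlt": m.tlt, "mld": m.mld,
             "sr": m.sr, "cp": m.cp}
        )
    df = pd.DataFrame(rows, columns=["load", "tlt", "mld", "sr", "cp"])
    counts = {ld: int((df["load"] == ld).sum()) for ld in LOADS}
    means = df.groupby("load").mean().reindex(LOADS)
    return {
        "means": means,
        "counts": counts,
        "included": all(c >= 1 for c in counts.values()),
    }


def chance_test(cp_values, chance: float = 0.5):
    """One-sample t against chance with a one-tailed (greater) p.

    Returns (t, one_tailed_p, cohens_d) with d = (mean − chance) / sample SD.
    """
    x = np.asarray(cp_values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; chance test degenerate")
    res = stats.ttest_1samp(x, chance, alternative="greater")
    d = (x.mean() - chance) / sd
    return float(res.statistic), float(res.pvalue), float(d)


def load_anova(table: pd.DataFrame, correction: str = "bonferroni") -> dict:
    """One-way repeated-measures ANOVA with load as the within factor.

    ``table`` is participants × loads (complete cases). Returns F, p,
    eta-squared (SS_effect / SS_total) and Bonferroni-corrected pairwise
    paired t-tests.
    """
    data = np.asarray(table, dtype=float)
    n, k = data.shape
    if k < 2 or n < 2:
        raise ValueError("need ≥ 2 loads and ≥ 2 participants")
    if np.any(~np.isfinite(data)):
        raise ValueError("complete cases required")
    grand = data.mean()
    ss_load = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_load - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_load, ms_err = ss_load / df1, ss_err / df2
    F = ms_load / ms_err if ms_err > 0 else (0.0 if ss_load == 0 else np.inf)
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    eta2 = ss_load / ss_tot if ss_tot > 0 else 0.0
    pairs = {}
    cols = list(table.columns) if hasattr(table, "columns") else list(range(k))
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            t, praw = stats.ttest_rel(data[:, i], data[:, j])
            pairs[(cols[i], cols[j])] = {
                "t": float(t),
                "p_corrected": min(float(praw) * n_pairs, 1.0),
            }
    return {"F": float(F), "p": p, "eta_squared": float(eta2),
            "df": (df1, df2), "pairwise": pairs}


def forward_regression(
    predictors: pd.DataFrame,
    outcome,
    entry_p: float = 0.05,
) -> dict:
    """Forward-selection linear regression.

    At each step the candidate with the smallest partial-F p-value enters if
    p ≤ ``entry_p``. Constant predictors are excluded with a warning. Returns
    the final model's terms, coefficients, F, p and R².
    """
    y = np.asarray(outcome, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("outcome has missing values")
    X = predictors.copy()
    for col in list(X.columns):
        if np.asarray(X[col]).std() == 0:
            warnings.warn(f"constant predictor {col!r} excluded")
            X = X.drop(columns=[col])
    selected: list = []
    remaining = list(X.columns)
    while remaining:
        best = None
        for cand in remaining:
            cols = selected + [cand]
            model = sm.OLS(y, sm.add_constant(X[cols].to_numpy())).fit()
            p_enter = model.pvalues[-1]
            if best is None or p_enter < best[1]:
                best = (cand, float(p_enter))
        if best is None or best[1] > entry_p:
            break
        selected.append(best[0])
        remaining.remove(best[0])
    if not selected:
        return {"terms": [], "coef": {}, "F": np.nan, "p": np.nan,
                "r_squared": 0.0, "model": None}
    final = sm.OLS(y, sm.add_constant(X[selected].to_numpy())).fit()
    coef = {"const": float(final.params[0])}
    coef.update({t: float(b) for t, b in zip(selected, final.params[1:])})
    return {
        "terms": list(selected),
        "coef": coef,
        "F": float(final.fvalue),
        "p": float(final.f_pvalue),
        "r_squared": float(final.rsquared),
        "model": final,
    }


def outlier_robustness(x, y, alpha: float = 0.05) -> dict:
    """Mean ± 3 SD outlier check on a bivariate association.

    Points with either coordinate outside mean ± 3 SD are removed and the
    Pearson correlation refit; the association is robust iff its significance
    status is retained after removal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need n ≥ 4")
    keep = np.ones(x.size, dtype=bool)
    for v in (x, y):
        mu, sd = v.mean(), v.std(ddof=1)
        if sd > 0:
            keep &= np.abs(v - mu) <= 3 * sd
    if keep.sum() < 3:
        raise ValueError("outlier removal left fewer than 3 points")
    r0, p0 = stats.pearsonr(x, y)
    r1, p1 = stats.pearsonr(x[keep], y[keep])
    sig0, sig1 = p0 < alpha, p1 < alpha
    robust = (not sig0) or sig1
    return {
        "robust": bool(robust),
        "r_original": float(r0),
        "p_original": float(p0),
        "r_refit": float(r1),
        "p_refit": float(p1),
        "n_removed": int((~keep).sum()),
    }
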