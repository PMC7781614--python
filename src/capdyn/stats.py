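"""Per-subject CAP occupancy frequencies and group comparisons.

Frequency of occurrence is the proportion of a subject's selected
frames assigned to each state, so each subject's row is a composition
summing to one. Groups are compared per state with a two-sample t test
(Welch by default) and with ordinary least squares controlling for
acquisition site, mean head motion, age and handedness; unadjusted p
values are reported by default, with Benjamini-Hochberg adjustment
across states available as an opt-in column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class StatsError(ValueError):
    pass


DEFAULT_COVARIATES = ("site", "mean_fd", "age", "handedness")
#: the alternative preset additionally adjusts for sex
EXTENDED_COVARIATES = DEFAULT_COVARIATES + ("sex",)

_CATEGORICAL = {"site", "handedness", "sex"}
_HANDEDNESS_REFERENCE = "right"


def frequency_table(
    cap_labels: Sequence[int],
    subject_index: Sequence[str],
    k: int,
    subjects: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Subjects x states table of occupancy proportions (rows sum to 1).

    ``subjects`` optionally fixes the expected roster; any listed
    subject without a single labeled frame raises an error naming it.
    """
    labels = np.asarray(cap_labels)
    subject_index = list(subject_index)
    if labels.size != len(subject_index):
        raise StatsError("labels and subject index lengths differ")
    if labels.size == 0:
        raise StatsError("no frames to tabulate")
    if labels.min() < 0 or labels.max() >= k:
        raise StatsError(f"state labels must lie in [0, {k})")
    df = pd.DataFrame({"participant_id": subject_index, "state": labels})
    counts = (
        df.groupby(["participant_id", "state"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=range(k), fill_value=0)
    )
    # preserve first-appearance subject order
    order = list(dict.fromkeys(subject_index))
    if subjects is not None:
        missing = [s for s in subjects if s not in set(order)]
        if missing:
            raise StatsError(f"subjects with zero selected frames: {missing}")
        order = list(subjects)
    counts = counts.loc[order]
    totals = counts.sum(axis=1)
    empty = totals[totals == 0]
    if len(empty):
        raise StatsError(f"subjects with zero selected frames: {list(empty.index)}")
    freq = counts.div(totals, axis=0)
    freq.columns = [f"state_{j + 1}" for j in range(k)]  # states 1..k in reports
    freq.index.name = "participant_id"
    return freq


def compare_groups_ttest(
    freq_table: pd.DataFrame,
    participants: pd.DataFrame,
    state: str,
    variant: str = "welch",
    group_col: str = "group",
) -> dict:
    """Two-sample t test on one state's frequencies.

    Returns statistic, two-sided p and per-group means/counts. When both
    groups are degenerate (zero variance) the p value is set to 1.0 for
    equal means and 0.0 otherwise, with ``degenerate=True`` flagged.
    """
    if variant not in ("welch", "pooled"):
        raise StatsError("variant must be 'welch' or 'pooled'")
    merged = freq_table[[state]].join(participants.set_index("participant_id"))
    groups = sorted(merged[group_col].unique())
    if len(groups) != 2:
        raise StatsError(f"expected 2 groups, found {groups}")
    a = merged.loc[merged[group_col] == groups[0], state].to_numpy()
    b = merged.loc[merged[group_col] == groups[1], state].to_numpy()
    if a.size < 2 or b.size < 2:
        raise StatsError("both groups need >= 2 subjects")
    out = {
        "groups": tuple(groups),
        "mean_by_group": {groups[0]: float(a.mean()), groups[1]: float(b.mean())},
        "n_by_group": {groups[0]: int(a.size), groups[1]: int(b.size)},
        "degenerate": False,
    }
    if a.std(ddof=1) < 1e-12 and b.std(ddof=1) < 1e-12:
        equal = np.isclose(a.mean(), b.mean())
        out.update(t=0.0 if equal else np.inf, p=1.0 if equal else 0.0,
                   degenerate=True)
        return out
    t, p = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    out.update(t=float(t), p=float(p))
    return out


def _design_matrix(
    participants: pd.DataFrame,
    covariates: Sequence[str],
    group_col: str,
    reference_group: str,
) -> tuple[pd.DataFrame, str]:
    """Intercept + group indicator + covariate columns (dummies for categoricals).

    Reference levels: the stated reference group; 'right' for
    handedness; first level alphabetically otherwise.
    """
    df = participants.set_index("participant_id")
    levels = sorted(df[group_col].unique())
    if reference_group not in levels:
        raise StatsError(f"reference group {reference_group!r} not in {levels}")
    case = [g for g in levels if g != reference_group]
    if len(case) != 1:
        raise StatsError(f"expected exactly 2 groups, found {levels}")
    case = case[0]
    x = pd.DataFrame(index=df.index)
    x["intercept"] = 1.0
    group_term = f"group[{case}]"
    x[group_term] = (df[group_col] == case).astype(float)
    for cov in covariates:
        if cov not in df.columns:
            raise StatsError(f"covariate {cov!r} missing from participants table")
        if df[cov].isna().any():
            raise StatsError(f"covariate {cov!r} has missing values")
        if cov in _CATEGORICAL:
            lv = sorted(df[cov].unique())
            ref = _HANDEDNESS_REFERENCE if cov == "handedness" and \
                _HANDEDNESS_REFERENCE in lv else lv[0]
            for level in lv:
                if level != ref:
                    x[f"{cov}[{level}]"] = (df[cov] == level).astype(float)
        else:
            x[cov] = df[cov].astype(float)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # identify columns involved in the collinearity
        bad = []
        for col in x.columns:
            if np.linalg.matrix_rank(x.drop(columns=[col]).to_numpy()) == rank:
                bad.append(col)
        raise StatsError(f"design matrix rank deficient; collinear columns: {bad}")
    return x, group_term


@dataclass(frozen=True)
class GroupComparisonResult:
    """Per-state group comparison: t test plus covariate-adjusted OLS."""

    table: pd.DataFrame  # one row per state
    covariates: tuple[str, ...]
    reference_group: str
    n_by_group: dict


def compare_groups_regression(
    freq_table: pd.DataFrame,
    participants: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    group_col: str = "group",
    reference_group: str | None = None,
    ttest_variant: str = "welch",
    fdr: bool = False,
) -> GroupComparisonResult:
    """OLS of each state's frequency on group + covariates, plus t tests.

    The reported group coefficient is the adjusted mean difference of
    the non-reference group relative to ``reference_group`` (first
    group alphabetically when unspecified).
    """
    merged_groups = sorted(participants[group_col].unique())
    if reference_group is None:
        reference_group = merged_groups[0]
    x, group_term = _design_matrix(participants, covariates, group_col, reference_group)
    missing = set(freq_table.index) - set(x.index)
    if missing:
        raise StatsError(f"subjects missing from participants table: {sorted(missing)}")
    x = x.loc[freq_table.index]

    rows = []
    for state in freq_table.columns:
        y = freq_table[state].to_numpy(dtype=float)
        fit = sm.OLS(y, x.to_numpy()).fit()
        j = list(x.columns).index(group_term)
        tt = compare_groups_ttest(
            freq_table, participants, state, variant=ttest_variant,
            group_col=group_col,
        )
        g0, g1 = tt["groups"]
        rows.append(
            {
                "state": state,
                f"mean_{g0}": tt["mean_by_group"][g0],
                f"mean_{g1}": tt["mean_by_group"][g1],
                "t": tt["t"],
                "t_p": tt["p"],
                "group_coef": float(fit.params[j]),
                "group_se": float(fit.bse[j]),
                "group_p": float(fit.pvalues[j]),
            }
        )
    table = pd.DataFrame(rows).set_index("state")
    if fdr:
        table["t_q"] = multipletests(table["t_p"], method="fdr_bh")[1]
        table["group_q"] = multipletests(table["group_p"], method="fdr_bh")[1]
    n_by_group = participants.groupby(group_col)["participant_id"].count().to_dict()
    return GroupComparisonResult(
        table=table,
        covariates=tuple(covariates),
        reference_group=reference_group,
        n_by_group=n_by_group,
    )
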