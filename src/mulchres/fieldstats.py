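"""Statistical comparison layer for percent-bare-soil areas.

Two analyses mirror the study protocol:

* **Paired method-vs-reference comparison.**  For each thresholding
  method, the per-image areas are compared with the expert-traced
  reference areas by a paired two-tailed Student's t-test; when
  Shapiro–Wilk rejects normality of the paired differences, the paired
  two-tailed Wilcoxon signed-rank test is used instead.
* **Per-mulch deterioration.**  One-way fixed-effects ANOVA on percent
  bare soil by mulch material, followed by Duncan's multiple range test
  at α = 0.05; mulches sharing a letter are not significantly
  different.  An optional squaring transform can be applied to the
  values before ANOVA (group summaries stay on the raw percent scale).

Convention notes: the normality gate uses its own significance level
(default 0.01 — see the methods documentation); Wilcoxon uses Pratt
zero handling and mid-ranks for ties, with the exact null distribution
when there are no zeros or ties and n ≤ 25, else the normal
approximation with continuity correction.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError

#: significance level of the Shapiro-Wilk gate that routes a paired
#: comparison to the Wilcoxon test
NORMALITY_ALPHA = 0.01

WILCOXON_EXACT_MAX_N = 25


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PairedTestResult:
    """Outcome of one paired method-vs-reference comparison."""

    n: int
    mean_g1: float
    mean_g2: float
    mean_diff: float
    sd_diff: float
    statistic: float
    p_value: float
    test_used: str  # "t" or "wilcoxon"
    normality_p: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclasses.dataclass(frozen=True)
class AnovaDuncanResult:
    """One-way ANOVA with Duncan's multiple range test letters."""

    group_ids: tuple
    group_means: tuple[float, ...]
    group_se: tuple[float, ...]
    F: float
    p_value: float
    letters: tuple[str, ...]
    transform: str
    alpha: float
    unbalanced: bool = False


# ---------------------------------------------------------------------------
# Paired comparisons
# ---------------------------------------------------------------------------

def shapiro_wilk(d: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W, p) on a sample."""
    d = np.asarray(d, dtype=float)
    if not 3 <= d.size <= 5000:
        raise InputError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(d) == 0:
        raise InputError("Shapiro-Wilk is undefined for a constant sample")
    res = stats.shapiro(d)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_paired(
    g1: Sequence[float], g2: Sequence[float]
) -> tuple[float, float]:
    """Paired two-tailed Wilcoxon signed-rank test.

    Zeros are handled by the Pratt method (kept in the ranking, then
    dropped); ties take mid-ranks.  The exact distribution is used when
    the differences contain no zeros or ties and n ≤ 25, otherwise the
    normal approximation with continuity correction.
    """
    d = np.asarray(g1, dtype=float) - np.asarray(g2, dtype=float)
    if np.count_nonzero(d) == 0:
        raise InputError("all paired differences are zero")
    if np.count_nonzero(d) < 3:
        raise InputError("need at least 3 non-zero differences")
    nz = d[d != 0]
    clean = d.size == nz.size and np.unique(np.abs(nz)).size == nz.size
    if clean and d.size <= WILCOXON_EXACT_MAX_N:
        res = stats.wilcoxon(d, zero_method="pratt", method="exact")
    else:
        res = stats.wilcoxon(
            d, zero_method="pratt", method="approx", correction=True
        )
    return float(res.statistic), float(res.pvalue)


def paired_compare(
    g1: Sequence[float],
    g2: Sequence[float],
    alpha: float = 0.05,
    normality_alpha: float = NORMALITY_ALPHA,
) -> PairedTestResult:
    """Compare two paired area series, gating the test on normality.

    Shapiro–Wilk is run on the differences d = g1 − g2; if its p-value
    is at least ``normality_alpha`` the paired t-test is used, else the
    Wilcoxon signed-rank test.  Identical series yield a degenerate,
    flagged result with p = 1.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 1:
        raise InputError("paired groups must be equal-length vectors")
    n = g1.size
    if n < 3:
        raise InputError("need at least 3 pairs")
    d = g1 - g2
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    if np.ptp(d) == 0 and mean_diff == 0.0:
        return PairedTestResult(
            n=n,
            mean_g1=float(g1.mean()),
            mean_g2=float(g2.mean()),
            mean_diff=0.0,
            sd_diff=0.0,
            statistic=float("nan"),
            p_value=1.0,
            test_used="t",
            normality_p=float("nan"),
            degenerate=True,
        )
    normality_p = shapiro_wilk(d)[1]
    if normality_p >= normality_alpha:
        res = stats.ttest_rel(g1, g2)
        statistic, p_value, used = float(res.statistic), float(res.pvalue), "t"
    else:
        statistic, p_value = wilcoxon_paired(g1, g2)
        used = "wilcoxon"
    return PairedTestResult(
        n=n,
        mean_g1=float(g1.mean()),
        mean_g2=float(g2.mean()),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        statistic=statistic,
        p_value=p_value,
        test_used=used,
        normality_p=normality_p,
    )


# ---------------------------------------------------------------------------
# Group summaries, ANOVA and Duncan's multiple range test
# ---------------------------------------------------------------------------

def group_summary(
    values: Sequence[float], groups: Sequence
) -> pd.DataFrame:
    """Per-group mean and standard error (sd/√n), indexed by group id."""
    df = pd.DataFrame({"value": np.asarray(values, float), "group": list(groups)})
    if (df.groupby("group")["value"].count() < 2).any():
        raise InputError("every group needs at least 2 observations")
    out = df.groupby("group")["value"].agg(
        mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count"
    )
    return out


def _duncan_letters(
    means_desc: np.ndarray, n_per_group: float, mse: float, df_error: int, alpha: float
) -> list[str]:
    """Assign compact letters by Duncan's stepwise range procedure.

    Means are given sorted in descending order.  A pair spanning p
    ranked means differs significantly when its difference exceeds
    R_p = q(α_p; p, df_error) · sqrt(MSE/n) with the Duncan protection
    level α_p = 1 − (1 − α)^(p−1) — unless the pair lies inside a span
    already declared non-significant (no range can be significant
    within a non-significant range).
    """
    k = means_desc.size
    ranges = np.zeros(k + 1)
    for p in range(2, k + 1):
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        q = stats.studentized_range.ppf(1.0 - alpha_p, p, df_error)
        ranges[p] = q * np.sqrt(mse / n_per_group)
    nonsig = np.eye(k, dtype=bool)
    # widest spans first so containment protection propagates inward
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if nonsig[i, j]:  # inside a span already declared non-significant
                continue
            if means_desc[i] - means_desc[j] <= ranges[span]:
                nonsig[i:j + 1, i:j + 1] = True
    letters = [""] * k
    next_letter = 0
    covered: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        if any(a <= i and j <= b for a, b in covered):
            continue
        covered.append((i, j))
        ch = chr(ord("a") + next_letter)
        next_letter += 1
        for idx in range(i, j + 1):
            letters[idx] += ch
    return letters


def anova_duncan(
    values: Sequence[float],
    groups: Sequence,
    alpha: float = 0.05,
    transform: str = "none",
) -> AnovaDuncanResult:
    """One-way ANOVA plus Duncan's multiple range test at level α.

    ``transform="square"`` squares the values before the ANOVA and the
    Duncan ranges (a variance-stabilizing device for proportions near
    the ends of the scale); group means and standard errors are always
    reported on the untransformed percent scale.  Unbalanced designs
    fall back to the harmonic mean of the group sizes for the Duncan
    ranges and are flagged.
    """
    if transform not in ("none", "square"):
        raise InputError(f"unknown transform {transform!r}")
    values = np.asarray(values, dtype=float)
    raw_summary = group_summary(values, groups)
    if len(raw_summary) < 2:
        raise InputError("need at least 2 groups")
    y = values**2 if transform == "square" else values
    df = pd.DataFrame({"y": y, "group": list(groups)})
    arrays = [sub["y"].to_numpy() for _, sub in df.groupby("group")]
    F, p_value = stats.f_oneway(*arrays)
    if not np.isfinite(F):  # all groups identical and constant
        F, p_value = 0.0, 1.0
    # error mean square of the one-way fit, for the Duncan ranges
    ns = np.array([a.size for a in arrays], dtype=float)
    df_error = int(ns.sum() - ns.size)
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    mse = sse / df_error
    unbalanced = len(set(ns)) > 1
    n_eff = ns.size / (1.0 / ns).sum() if unbalanced else float(ns[0])
    group_ids = list(raw_summary.index)
    trans_means = df.groupby("group")["y"].mean()
    order = np.argsort(-trans_means.to_numpy(), kind="stable")
    if mse > 0:
        letters_desc = _duncan_letters(
            trans_means.to_numpy()[order], n_eff, mse, df_error, alpha
        )
    else:
        distinct = {}
        for m in trans_means.to_numpy()[order]:
            distinct.setdefault(m, chr(ord("a") + len(distinct)))
        letters_desc = [distinct[m] for m in trans_means.to_numpy()[order]]
    letters = [""] * len(group_ids)
    for rank, idx in enumerate(order):
        letters[idx] = letters_desc[rank]
    return AnovaDuncanResult(
        group_ids=tuple(group_ids),
        group_means=tuple(raw_summary["mean"]),
        group_se=tuple(raw_summary["se"]),
        F=float(F),
        p_value=float(p_value),
        letters=tuple(letters),
        transform=transform,
        alpha=alpha,
        unbalanced=unbalanced,
    )


# ---------------------------------------------------------------------------
# Study-table reproductions from an area table
# ---------------------------------------------------------------------------

#: method columns compared against the reference, in presentation order
METHOD_AREA_COLUMNS = {"OT": "a_ot", "RC": "a_rc", "MT": "a_mt", "LE": "a_le"}

#: columns of the per-mulch deterioration table and the transform each uses
MULCH_TABLE_COLUMNS = {
    "a_r": "none",
    "a_ot": "none",
    "a_rc": "none",
    "a_le": "square",
}


def reproduce_paired_table(table: pd.DataFrame) -> pd.DataFrame:
    """Paired comparisons of each method column against the reference.

    One row per method: mean difference, group means, SD of the
    differences, the statistic of whichever test the normality gate
    selected, and its two-tailed p.
    """
    rows = []
    for method, col in METHOD_AREA_COLUMNS.items():
        res = paired_compare(table["a_r"], table[col])
        rows.append(
            {
                "g1": "A_R",
                "g2": f"A_{method}",
                "dif": res.mean_diff,
                "mean_g1": res.mean_g1,
                "mean_g2": res.mean_g2,
                "sd_dif": res.sd_diff,
                "test": res.test_used,
                "statistic": res.statistic,
                "p_bilateral": res.p_value,
                "normality_p": res.normality_p,
            }
        )
    return pd.DataFrame(rows)


def reproduce_mulch_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-mulch deterioration summary with ANOVA/Duncan letters.

    One row per mulch material; per area column the raw-scale
    mean ± SE and the Duncan letter, plus a trailing row of ANOVA
    p-values.  The entropy-method column is analyzed after the
    squaring transform, as in the study protocol.
    """
    out = pd.DataFrame(index=sorted(table["mulch"].unique()))
    out.index.name = "mulch"
    pvals = {}
    for col, transform in MULCH_TABLE_COLUMNS.items():
        res = anova_duncan(table[col], table["mulch"], transform=transform)
        cell = [
            f"{m:.2f} ± {se:.2f} {let}"
            for m, se, let in zip(res.group_means, res.group_se, res.letters)
        ]
        out[col] = pd.Series(cell, index=list(res.group_ids))
        pvals[col] = res.p_value
    out.loc["P-value"] = {c: f"{p:.4f}" for c, p in pvals.items()}
    return out
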