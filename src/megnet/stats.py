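"""Small-cohort group statistics.

Paired t-tests on metric change and on membership-count distributions, exact
McNemar tests of per-region membership change, Spearman rank correlations
(exact permutation p at small n) between baseline network metrics and the
drinking outcome, and Cohen's d effect sizes.  All tests are two-tailed; no
multiplicity correction is applied by default (a Holm adjustment is
available as an option).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupTestResult",
    "MembershipTable",
    "collapse_regions",
    "build_membership_table",
    "paired_t",
    "mcnemar_region",
    "spearman",
    "cohens_d_paired",
    "cohens_d_one_sample",
    "metric_outcome_screen",
    "holm_adjust",
]

EXACT_SPEARMAN_MAX_N = 8


@dataclass(frozen=True)
class GroupTestResult:
    test_name: str
    statistic: float
    df: float | None
    p_value: float
    effect_size: float | None = None
    flag: str | None = None

    def __post_init__(self) -> None:
        if not math.isnan(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def collapse_regions(
    member_labels: Iterable[str], collapse_map: Mapping[str, str]
) -> set[str]:
    """Collapse ROI-level membership to structure level by logical OR.

    A structure is a member iff any of its constituent ROI aspects (including
    left/right aspects) is a member.  Labels missing from the map are an
    error, listed explicitly.
    """
    labels = list(member_labels)
    unmapped = sorted(set(labels) - set(collapse_map))
    if unmapped:
        raise KeyError(f"labels missing from collapse map: {unmapped}")
    return {collapse_map[lab] for lab in labels}


@dataclass
class MembershipTable:
    """Region-by-timepoint membership counts across subjects.

    ``flags_t1``/``flags_t2`` are subject × region booleans (all regions
    present in the collapse map that met the inclusion rule); ``counts_*``
    are their column sums.  A region is included iff its count at either
    timepoint reaches ``min_count``.
    """

    regions: list[str]
    counts_t1: np.ndarray
    counts_t2: np.ndarray
    n_subjects: int
    kind: str
    min_count: int
    flags_t1: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]
    flags_t2: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts_t1 = np.asarray(self.counts_t1, int)
        self.counts_t2 = np.asarray(self.counts_t2, int)
        for c in (self.counts_t1, self.counts_t2):
            if np.any((c < 0) | (c > self.n_subjects)):
                raise ValueError("membership counts must lie in [0, n_subjects]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": self.regions, "t1": self.counts_t1, "t2": self.counts_t2}
        ).set_index("region")


def build_membership_table(
    members_t1: Mapping[str, Iterable[str]],
    members_t2: Mapping[str, Iterable[str]],
    collapse_map: Mapping[str, str],
    min_count: int = 3,
    kind: str = "rich_club",
    regions: Sequence[str] | None = None,
) -> MembershipTable:
    """Structure-level membership counts at two timepoints.

    ``members_t1``/``members_t2`` map subject id to the ROI labels that are
    members (hubs or rich-club nodes) at that timepoint; both must cover the
    same subjects.  Rows are filtered to regions whose count reaches
    ``min_count`` at either timepoint (hub tables conventionally use
    ``min_count=1``), unless an explicit ``regions`` list is given.
    """
    subjects = sorted(members_t1)
    if sorted(members_t2) != subjects:
        raise ValueError("the two timepoints must cover the same subjects")
    all_regions = sorted(set(collapse_map.values()))
    f1 = pd.DataFrame(False, index=subjects, columns=all_regions)
    f2 = pd.DataFrame(False, index=subjects, columns=all_regions)
    for s in subjects:
        for st in collapse_regions(members_t1[s], collapse_map):
            f1.loc[s, st] = True
        for st in collapse_regions(members_t2[s], collapse_map):
            f2.loc[s, st] = True
    c1 = f1.sum(axis=0)
    c2 = f2.sum(axis=0)
    if regions is None:
        keep = [r for r in all_regions if max(c1[r], c2[r]) >= min_count]
    else:
        keep = list(regions)
    return MembershipTable(
        regions=keep,
        counts_t1=c1[keep].to_numpy(),
        counts_t2=c2[keep].to_numpy(),
        n_subjects=len(subjects),
        kind=kind,
        min_count=min_count,
        flags_t1=f1[keep],
        flags_t2=f2[keep],
    )


def paired_t(x: Sequence[float], y: Sequence[float]) -> GroupTestResult:
    """Two-tailed paired-samples t-test on x - y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("paired t-test needs two equal-length vectors, n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        return GroupTestResult(
            "paired_t", float("nan"), n - 1, float("nan"), flag="zero difference variance"
        )
    t = d.mean() / (sd / math.sqrt(n))
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    return GroupTestResult("paired_t", float(t), n - 1, float(p))


def mcnemar_region(
    status_t1: Sequence[bool],
    status_t2: Sequence[bool],
    exact: bool = True,
) -> GroupTestResult:
    """McNemar test of marginal change in a paired binary status.

    The exact form (default, appropriate at cohort sizes of a handful of
    subjects) is the two-tailed binomial test on the discordant counts
    b (1→0) and c (0→1): ``p = min(1, 2 * BinomCDF(min(b, c); b + c, 1/2))``.
    ``exact=False`` gives the continuity-corrected chi-square approximation.
    With no discordant pairs the test is degenerate and p = 1.
    """
    s1 = np.asarray(status_t1, bool)
    s2 = np.asarray(status_t2, bool)
    if s1.shape != s2.shape or s1.ndim != 1 or s1.size < 1:
        raise ValueError("McNemar needs two equal-length binary vectors")
    b = int(np.sum(s1 & ~s2))
    c = int(np.sum(~s1 & s2))
    if b + c == 0:
        return GroupTestResult(
            "mcnemar_exact" if exact else "mcnemar_chi2",
            0.0,
            None,
            1.0,
            flag="no discordant pairs",
        )
    if exact:
        p = min(1.0, 2.0 * sps.binom.cdf(min(b, c), b + c, 0.5))
        return GroupTestResult("mcnemar_exact", float(min(b, c)), None, float(p))
    chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    p = sps.chi2.sf(chi2, df=1)
    return GroupTestResult("mcnemar_chi2", float(chi2), 1, float(p))


def _pearson_on_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def spearman(x: Sequence[float], y: Sequence[float]) -> GroupTestResult:
    """Spearman rank correlation, exact permutation p for n <= 8.

    rho is the Pearson correlation of average ranks.  The two-tailed p-value
    is exact — the fraction of all n! orderings of one variable with
    |rho| at least as large as observed — whenever n <= 8 (the t
    approximation is unreliable at the cohort sizes this pipeline targets);
    larger n falls back to the t approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 4:
        raise ValueError("Spearman needs two equal-length vectors, n >= 4")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return GroupTestResult(
            "spearman", float("nan"), None, float("nan"), flag="zero rank variance"
        )
    rho = _pearson_on_ranks(rx, ry)
    n = x.size
    if n <= EXACT_SPEARMAN_MAX_N:
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - ry.mean()
        rhos = (pc @ rxc) / math.sqrt((rxc**2).sum() * ((ry - ry.mean()) ** 2).sum())
        count = int(np.sum(np.abs(rhos) >= abs(rho) - 1e-12))
        p = count / len(perms)
        return GroupTestResult("spearman_exact", rho, None, float(p), effect_size=rho)
    t = rho * math.sqrt((n - 2) / (1 - rho**2)) if abs(rho) < 1 else math.inf
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return GroupTestResult("spearman_t", rho, n - 2, float(p), effect_size=rho)


def cohens_d_paired(x: Sequence[float], y: Sequence[float]) -> float:
    """Paired Cohen's d: mean(x - y) / sd(x - y).

    Identical vectors give 0 (no effect); a constant non-zero shift has zero
    difference SD and the effect size is undefined (NaN).
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0 if d.mean() == 0 else float("nan")
    return float(d.mean() / sd)


def cohens_d_one_sample(x: Sequence[float], mu0: float) -> float:
    """One-sample Cohen's d against a reference value: (mean(x) - mu0) / sd(x)."""
    x = np.asarray(x, float)
    sd = x.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float((x.mean() - mu0) / sd)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; the default analysis is unadjusted)."""
    p = np.asarray(p_values, float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def metric_outcome_screen(
    baseline_metrics: pd.DataFrame,
    outcomes: Mapping[str, float] | pd.Series,
    holm: bool = False,
) -> pd.DataFrame:
    """Spearman screen of baseline metrics against the drinking outcome.

    ``baseline_metrics`` is subject × metric; ``outcomes`` maps subject to
    the outcome (g/kg).  Returns one row per metric with rho and the
    two-tailed p (exact at small n); ``holm=True`` appends step-down adjusted
    p-values.  No correction is applied to the primary column.
    """
    outcomes = pd.Series(outcomes)
    subjects = [s for s in baseline_metrics.index if s in outcomes.index]
    if len(subjects) < 4:
        raise ValueError("the screen needs at least 4 subjects with outcomes")
    rows = []
    for metric in baseline_metrics.columns:
        res = spearman(
            baseline_metrics.loc[subjects, metric].to_numpy(),
            outcomes[subjects].to_numpy(),
        )
        rows.append(
            {"metric": metric, "rho": res.statistic, "p": res.p_value, "flag": res.flag}
        )
    out = pd.DataFrame(rows).set_index("metric")
    if holm:
        out["p_holm"] = holm_adjust(out["p"].fillna(1.0).to_numpy())
    return out
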