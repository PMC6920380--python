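"""Group-level statistics and reporting conversions.

Within each group, ipsilateral vs contralateral readings are compared
with a two-tailed paired Student's t-test; across groups, per-mouse
ipsi/contra ratios are compared with a one-way ANOVA followed by
Holm–Sidak-corrected pairwise comparisons. Group values can optionally
be screened for a single outlier with the Grubbs test before testing.
Reporting helpers convert tissue concentrations to percent injected
dose per gram and ELISA readings to ng per mg of total protein.

Degenerate inputs (zero-variance differences, all-identical ratios)
produce *flagged* results inside :func:`group_analysis` so batch runs
complete, while the individual test functions raise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .behavior import GrubbsResult, grubbs_test

__all__ = [
    "TestResult",
    "HolmSidakResult",
    "paired_t",
    "one_way_anova",
    "holm_sidak",
    "pct_injected_per_gram",
    "bdnf_per_total_protein",
    "summarize_mice",
    "group_analysis",
    "GroupAnalysisResult",
]


class ZeroVarianceError(ValueError):
    """Raised when a test statistic is undefined because of zero spread."""


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, df, raw and (optionally) adjusted p."""

    name: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    alpha: float = 0.05
    p_adjusted: float | None = None
    degenerate: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not self.degenerate:
            if not 0.0 <= self.p <= 1.0:
                raise ValueError(f"p outside [0, 1]: {self.p}")
            if self.p_adjusted is not None and self.p_adjusted < self.p - 1e-12:
                raise ValueError("adjusted p must be >= raw p")

    @property
    def significant(self) -> bool:
        if self.degenerate:
            return False
        p = self.p if self.p_adjusted is None else self.p_adjusted
        return p < self.alpha


def paired_t(
    values_a: Sequence[float], values_b: Sequence[float], alpha: float = 0.05,
    name: str = "paired t",
) -> TestResult:
    """Two-tailed paired Student's t-test.

    t = mean(d) / (SD(d) / sqrt(n)) on the paired differences d = a - b,
    with n-1 degrees of freedom.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = a - b
    if d.std(ddof=1) == 0:
        raise ZeroVarianceError("paired differences have zero SD")
    res = sps.ttest_rel(a, b)
    return TestResult(
        name=name, statistic=float(res.statistic), df=float(a.size - 1),
        p=float(res.pvalue), alpha=alpha,
    )


def one_way_anova(
    groups: Sequence[Sequence[float]], alpha: float = 0.05, name: str = "one-way ANOVA"
) -> TestResult:
    """One-way ANOVA; F = MS_between / MS_within."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(arrays)
    if pooled.std() == 0:
        raise ZeroVarianceError("all observations identical; F undefined")
    res = sps.f_oneway(*arrays)
    k = len(arrays)
    n = pooled.size
    return TestResult(
        name=name, statistic=float(res.statistic), df=(float(k - 1), float(n - k)),
        p=float(res.pvalue), alpha=alpha,
    )


@dataclass(frozen=True)
class HolmSidakResult:
    raw: tuple[float, ...]
    adjusted: tuple[float, ...]
    reject: tuple[bool, ...]
    alpha: float


def holm_sidak(raw_pvalues: Sequence[float], alpha: float = 0.05) -> HolmSidakResult:
    """Holm–Sidak step-down multiple-comparison adjustment.

    Sort the m raw p-values ascending; the i-th (1-based) is adjusted to
    ``1 - (1 - p_(i)) ** (m - i + 1)``, made monotone non-decreasing down
    the sorted list, and mapped back to input order. Hypotheses are
    rejected while the adjusted p stays below alpha.
    """
    p = np.asarray(raw_pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values given")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    exponents = m - np.arange(m)
    adj_sorted = np.where(
        exponents == 1, p[order], 1.0 - np.power(1.0 - p[order], exponents)
    )
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    adjusted = np.empty_like(adj_sorted)
    adjusted[order] = adj_sorted
    return HolmSidakResult(
        raw=tuple(float(v) for v in p),
        adjusted=tuple(float(v) for v in adjusted),
        reject=tuple(bool(v < alpha) for v in adjusted),
        alpha=alpha,
    )


def pct_injected_per_gram(
    tissue_conc_ug_per_g: float, injected_ug: float, decimals: int = 1,
    truncate: bool = True,
) -> float:
    """Percent of the injected dose recovered per gram of tissue.

    ``100 * tissue_conc / injected``, truncated (floored, not rounded) to
    the requested number of decimals to match conventional reporting;
    ``truncate=False`` rounds instead.
    """
    if injected_ug <= 0:
        raise ValueError("injected dose must be positive")
    if tissue_conc_ug_per_g < 0:
        raise ValueError("tissue concentration must be >= 0")
    pct = 100.0 * tissue_conc_ug_per_g / injected_ug
    scale = 10.0 ** decimals
    if truncate:
        # tiny guard against binary representation of exact decimals
        return math.floor(pct * scale + 1e-9) / scale
    return round(pct * scale) / scale


def bdnf_per_total_protein(bdnf_ng_per_ml: float, total_protein_mg_per_ml: float) -> float:
    """Neurotrophin content normalized to total protein (ng per mg)."""
    if total_protein_mg_per_ml <= 0:
        raise ValueError("total protein must be positive")
    return bdnf_ng_per_ml / total_protein_mg_per_ml


def summarize_mice(section_table: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse summary of a tidy per-section table.

    Expects columns ``mouse, group, region, section, ipsi, contra``;
    returns one row per mouse x region with hemisphere means and the
    ratio of means.
    """
    required = {"mouse", "group", "region", "ipsi", "contra"}
    missing = required - set(section_table.columns)
    if missing:
        raise ValueError(f"section table missing columns {sorted(missing)}")
    g = (
        section_table.groupby(["mouse", "group", "region"], sort=True)[["ipsi", "contra"]]
        .mean()
        .reset_index()
        .rename(columns={"ipsi": "ipsi_mean", "contra": "contra_mean"})
    )
    if np.any(g["contra_mean"] <= 0):
        raise ZeroDivisionError("a mouse has zero contralateral mean; ratio undefined")
    g["ratio"] = g["ipsi_mean"] / g["contra_mean"]
    return g


@dataclass
class GroupAnalysisResult:
    """Full results bundle for one region."""

    region: str
    paired: dict[str, TestResult]
    anova: TestResult
    pairwise: dict[tuple[str, str], TestResult]
    group_means: dict[str, float]
    group_sems: dict[str, float]
    grubbs: dict[str, GrubbsResult] = field(default_factory=dict)
    removed: dict[str, str] = field(default_factory=dict)   # group -> mouse id

    def to_dict(self) -> dict:
        def tr(t: TestResult) -> dict:
            return {
                "statistic": t.statistic,
                "df": t.df,
                "p": t.p,
                "p_adjusted": t.p_adjusted,
                "significant": t.significant,
                "degenerate": t.degenerate,
                "note": t.note,
            }

        return {
            "region": self.region,
            "paired": {g: tr(t) for g, t in self.paired.items()},
            "anova": tr(self.anova),
            "pairwise": {" vs ".join(k): tr(t) for k, t in self.pairwise.items()},
            "group_mean_ratio": self.group_means,
            "group_sem_ratio": self.group_sems,
            "removed_outliers": self.removed,
        }


def _degenerate(name: str, note: str, alpha: float) -> TestResult:
    return TestResult(
        name=name, statistic=float("nan"), df=float("nan"), p=float("nan"),
        alpha=alpha, degenerate=True, note=note,
    )


def group_analysis(
    mouse_table: pd.DataFrame,
    *,
    alpha: float = 0.05,
    pairs: Sequence[tuple[str, str]] | None = None,
    grubbs_alpha: float | None = None,
) -> dict[str, GroupAnalysisResult]:
    """Study-level statistics on a per-mouse table, one bundle per region.

    Expects columns ``mouse, group, region, ipsi_mean, contra_mean,
    ratio`` (see :func:`summarize_mice`). Per group a paired t compares
    ipsilateral vs contralateral means; across groups a one-way ANOVA on
    the ratios is followed by Holm–Sidak-corrected pooled-variance
    pairwise t-tests (default: all group pairs). ``grubbs_alpha``
    enables a single-pass Grubbs screen of each group's ratios before
    testing; removed mice are logged in the result.
    """
    required = {"mouse", "group", "region", "ipsi_mean", "contra_mean", "ratio"}
    missing = required - set(mouse_table.columns)
    if missing:
        raise ValueError(f"mouse table missing columns {sorted(missing)}")
    dup = mouse_table.groupby("mouse")["group"].nunique()
    if np.any(dup > 1):
        raise ValueError("each mouse must belong to exactly one group")

    results: dict[str, GroupAnalysisResult] = {}
    for region, tab in mouse_table.groupby("region"):
        groups = sorted(tab["group"].unique())
        if len(groups) < 2 or any(
            (tab["group"] == g).sum() < 2 for g in groups
        ):
            raise ValueError("need >= 2 groups with >= 2 mice each")

        grubbs_results: dict[str, GrubbsResult] = {}
        removed: dict[str, str] = {}
        kept = tab
        if grubbs_alpha is not None:
            keep_rows = []
            for g in groups:
                sub = tab[tab["group"] == g]
                try:
                    gr = grubbs_test(sub["ratio"].to_numpy(), alpha=grubbs_alpha)
                except ValueError:
                    keep_rows.append(sub)
                    continue
                grubbs_results[g] = gr
                if gr.is_outlier:
                    removed[g] = str(sub.iloc[gr.outlier_index]["mouse"])
                    sub = sub.drop(sub.index[gr.outlier_index])
                keep_rows.append(sub)
            kept = pd.concat(keep_rows)

        paired: dict[str, TestResult] = {}
        for g in groups:
            sub = kept[kept["group"] == g]
            try:
                paired[g] = paired_t(
                    sub["ipsi_mean"], sub["contra_mean"], alpha=alpha,
                    name=f"paired t ({g})",
                )
            except ZeroVarianceError as exc:
                paired[g] = _degenerate(f"paired t ({g})", str(exc), alpha)

        ratio_lists = [kept[kept["group"] == g]["ratio"].to_numpy() for g in groups]
        try:
            anova = one_way_anova(ratio_lists, alpha=alpha)
        except ZeroVarianceError as exc:
            anova = _degenerate("one-way ANOVA", str(exc), alpha)

        pair_list = list(pairs) if pairs is not None else [
            (a, b) for i, a in enumerate(groups) for b in groups[i + 1:]
        ]
        raw_tests: dict[tuple[str, str], TestResult] = {}
        for a, b in pair_list:
            xa = kept[kept["group"] == a]["ratio"].to_numpy()
            xb = kept[kept["group"] == b]["ratio"].to_numpy()
            if np.concatenate([xa, xb]).std() == 0:
                raw_tests[(a, b)] = _degenerate(
                    f"{a} vs {b}", "all ratios identical", alpha
                )
                continue
            res = sps.ttest_ind(xa, xb, equal_var=True)
            raw_tests[(a, b)] = TestResult(
                name=f"{a} vs {b}", statistic=float(res.statistic),
                df=float(xa.size + xb.size - 2), p=float(res.pvalue), alpha=alpha,
            )
        live = [k for k, t in raw_tests.items() if not t.degenerate]
        if live:
            hs = holm_sidak([raw_tests[k].p for k in live], alpha=alpha)
            for k, adj in zip(live, hs.adjusted):
                t = raw_tests[k]
                raw_tests[k] = TestResult(
                    name=t.name, statistic=t.statistic, df=t.df, p=t.p,
                    alpha=alpha, p_adjusted=adj,
                )

        means = {
            g: float(kept[kept["group"] == g]["ratio"].mean()) for g in groups
        }
        sems = {
            g: float(sps.sem(kept[kept["group"] == g]["ratio"])) for g in groups
        }
        results[str(region)] = GroupAnalysisResult(
            region=str(region), paired=paired, anova=anova, pairwise=raw_tests,
            group_means=means, group_sems=sems, grubbs=grubbs_results,
            removed=removed,
        )
    return results
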