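"""Nonparametric comparison of peptide levels across sample groups.

The workflow mirrors standard practice for small-n skin-region
comparisons: per-group Shapiro-Wilk normality testing routes the analysis
to the nonparametric path, where groups are compared with a tie-corrected
Kruskal-Wallis test followed by Dunn's post hoc pairwise z tests.

Kruskal-Wallis H (midranks, tie-corrected):

    H = [ 12 / (N(N+1)) * sum_i n_i (Rbar_i - (N+1)/2)^2 ] / (1 - sum(t^3 - t) / (N^3 - N))

with p from the chi-square distribution on k-1 df.  Dunn's z for groups
i, j:

    z = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - sum(t^3 - t)/(12(N-1))) * (1/n_i + 1/n_j) )

two-sided p from the standard normal, optionally Bonferroni/Holm adjusted
over the pairs.  Stars follow the usual thresholds: * p<0.05, ** p<0.01,
*** p<0.001.

Groups where a peptide was never detected are compared with their
empty/partial data flagged, never zero-imputed; pairwise significance is
only claimed when both groups carry at least ``min_detections`` values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupedRatios",
    "PairResult",
    "GroupComparison",
    "kruskal_wallis",
    "dunn_posthoc",
    "shapiro_wilk_gate",
    "compare_peptide",
    "compare_all",
    "grouped_ratios_from_results",
    "stars_for",
    "plot_group_comparison",
]

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_for(p: float) -> str:
    for cut, sym in STAR_THRESHOLDS:
        if p < cut:
            return sym
    return ""


@dataclass
class GroupedRatios:
    """Per-peptide ratios keyed by group label; absent values simply absent."""

    peptide: str
    groups: dict[str, list[float]]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need >= 2 groups")

    def nonempty(self) -> dict[str, list[float]]:
        return {g: v for g, v in self.groups.items() if len(v) > 0}


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All observations identical -> (0.0, 1.0): no rank variation, nothing
    to reject.
    """
    samples = [np.asarray(v, dtype=float) for v in groups.values() if len(v) > 0]
    if len(samples) < 2:
        raise ValueError("need >= 2 non-empty groups")
    n = np.array([len(s) for s in samples])
    N = int(n.sum())
    if N < 3:
        raise ValueError("need total N >= 3")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    ranks = stats.rankdata(pooled)  # midranks
    splits = np.split(ranks, np.cumsum(n)[:-1])
    rbar = np.array([s.mean() for s in splits])
    h = 12.0 / (N * (N + 1)) * float(np.sum(n * (rbar - (N + 1) / 2.0) ** 2))
    correction = 1.0 - _tie_term(pooled) / (N**3 - N)
    if correction <= 0:
        return 0.0, 1.0
    h /= correction
    p = float(stats.chi2.sf(h, df=len(samples) - 1))
    return h, p


@dataclass(frozen=True)
class PairResult:
    group_a: str
    group_b: str
    z: float | None
    raw_p: float | None
    adjusted_p: float | None
    stars: str
    skipped: bool = False
    note: str = ""


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]],
    adjustment: str = "bonferroni",
    min_detections: int = 1,
) -> list[PairResult]:
    """Dunn's pairwise z tests on the pooled midranks.

    Pairs involving a group below ``min_detections`` observations are
    emitted as skipped-and-flagged rather than silently dropped.
    Adjustment: "none", "bonferroni" or "holm", applied over the tested
    pairs only.
    """
    if adjustment not in ("none", "bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    labels = list(groups.keys())
    arrays = {g: np.asarray(groups[g], dtype=float) for g in labels}
    tested = [g for g in labels if len(arrays[g]) >= max(min_detections, 1)]
    pooled = np.concatenate([arrays[g] for g in tested]) if tested else np.array([])
    N = len(pooled)
    results: list[PairResult] = []
    raw_ps: list[float] = []
    pair_idx: list[int] = []
    if N >= 2 and len(tested) >= 2:
        ranks = stats.rankdata(pooled)
        sizes = np.array([len(arrays[g]) for g in tested])
        splits = np.split(ranks, np.cumsum(sizes)[:-1])
        rbar = {g: s.mean() for g, s in zip(tested, splits)}
        var_base = N * (N + 1) / 12.0 - _tie_term(pooled) / (12.0 * (N - 1))
    for a, b in itertools.combinations(labels, 2):
        na, nb = len(arrays[a]), len(arrays[b])
        if (
            a not in tested
            or b not in tested
            or na < min_detections
            or nb < min_detections
        ):
            results.append(
                PairResult(
                    a,
                    b,
                    None,
                    None,
                    None,
                    "",
                    skipped=True,
                    note=f"insufficient data (n={na}, n={nb})",
                )
            )
            continue
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = float((rbar[a] - rbar[b]) / se)
            p = float(2.0 * stats.norm.sf(abs(z)))
        results.append(PairResult(a, b, z, p, None, ""))
        raw_ps.append(p)
        pair_idx.append(len(results) - 1)
    # multiplicity adjustment over tested pairs
    m = len(raw_ps)
    if m:
        if adjustment == "none":
            adj = list(raw_ps)
        elif adjustment == "bonferroni":
            adj = [min(1.0, p * m) for p in raw_ps]
        else:  # holm step-down
            order = np.argsort(raw_ps)
            adj = [0.0] * m
            running = 0.0
            for rank, k in enumerate(order):
                running = max(running, (m - rank) * raw_ps[k])
                adj[k] = min(1.0, running)
        for k, idx in enumerate(pair_idx):
            r = results[idx]
            results[idx] = PairResult(
                r.group_a, r.group_b, r.z, r.raw_p, adj[k], stars_for(adj[k])
            )
    return results


def shapiro_wilk_gate(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> tuple[dict[str, float | None], str]:
    """Per-group Shapiro-Wilk p-values and the routing decision.

    Any group rejecting normality (p < alpha), or any group too small to
    test (n < 3), routes the comparison to the nonparametric path.
    """
    report: dict[str, float | None] = {}
    nonparametric = False
    for g, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if len(arr) < 3 or np.all(arr == arr[0]):
            report[g] = None  # untestable
            nonparametric = True
            continue
        _, p = stats.shapiro(arr)
        report[g] = float(p)
        if p < alpha:
            nonparametric = True
    return report, "nonparametric" if nonparametric else "parametric"


@dataclass
class GroupComparison:
    peptide: str
    normality_p: dict[str, float | None]
    route: str
    h_statistic: float | None
    kw_p_value: float | None
    pairwise: list[PairResult] = field(default_factory=list)

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        return [
            (r.group_a, r.group_b)
            for r in self.pairwise
            if not r.skipped and r.adjusted_p is not None and r.adjusted_p < alpha
        ]


def compare_peptide(
    grouped: GroupedRatios,
    adjustment: str = "bonferroni",
    alpha: float = 0.05,
    min_detections: int = 3,
) -> GroupComparison:
    """Shapiro-Wilk gate -> Kruskal-Wallis -> Dunn for one peptide.

    The omnibus test runs on groups with any data; pairwise significance
    requires ``min_detections`` per group (default 3) so that sparse
    detections cannot claim significance.
    """
    normality, route = shapiro_wilk_gate(grouped.groups, alpha)
    nonempty = grouped.nonempty()
    h = p = None
    total = sum(len(v) for v in nonempty.values())
    if len(nonempty) >= 2 and total >= 3:
        h, p = kruskal_wallis(nonempty)
    pairwise = dunn_posthoc(grouped.groups, adjustment, min_detections)
    return GroupComparison(
        peptide=grouped.peptide,
        normality_p=normality,
        route=route,
        h_statistic=h,
        kw_p_value=p,
        pairwise=pairwise,
    )


def grouped_ratios_from_results(
    quant_frame: pd.DataFrame, manifest: Mapping[str, str]
) -> list[GroupedRatios]:
    """Join a quantification table with a sample->group manifest.

    Expects ``results_to_frame`` columns; only detected rows contribute
    ratios.  Every (peptide, group) cell exists even when empty.
    """
    group_labels: list[str] = []
    for g in manifest.values():
        if g not in group_labels:
            group_labels.append(g)
    out = []
    for pep, sub in quant_frame.groupby("peptide", sort=True):
        groups: dict[str, list[float]] = {g: [] for g in group_labels}
        det = sub[sub["detected"].astype(bool)]
        for _, row in det.iterrows():
            g = manifest.get(str(row["sample_id"]))
            if g is not None and row["light_to_heavy_ratio"] is not None:
                if not np.isnan(row["light_to_heavy_ratio"]):
                    groups[g].append(float(row["light_to_heavy_ratio"]))
        out.append(GroupedRatios(peptide=str(pep), groups=groups))
    return out


def compare_all(
    quant_frame: pd.DataFrame,
    manifest: Mapping[str, str],
    adjustment: str = "bonferroni",
    alpha: float = 0.05,
    min_detections: int = 3,
) -> list[GroupComparison]:
    return [
        compare_peptide(g, adjustment, alpha, min_detections)
        for g in grouped_ratios_from_results(quant_frame, manifest)
    ]


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        for r in c.pairwise:
            rows.append(
                {
                    "peptide": c.peptide,
                    "H": c.h_statistic,
                    "kw_p": c.kw_p_value,
                    "group_a": r.group_a,
                    "group_b": r.group_b,
                    "dunn_z": r.z,
                    "raw_p": r.raw_p,
                    "adjusted_p": r.adjusted_p,
                    "stars": r.stars,
                    "skipped": r.skipped,
                    "note": r.note,
                }
            )
    return pd.DataFrame(rows)


def plot_group_comparison(
    grouped: GroupedRatios,
    comparison: GroupComparison,
    ax=None,
):
    """Bar plot of mean +/- SEM light-to-heavy ratios with significance stars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    labels = list(grouped.groups.keys())
    means, sems = [], []
    for g in labels:
        vals = np.asarray(grouped.groups[g], dtype=float)
        if len(vals) == 0:
            means.append(0.0)
            sems.append(0.0)
        else:
            means.append(float(vals.mean()))
            sems.append(float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0)
    x = np.arange(len(labels))
    ax.bar(x, means, yerr=sems, capsize=3, color="#6699cc")
    ax.set_xticks(x)
    ax.set_xticklabels(labels)
    ax.set_ylabel("light-to-heavy ratio")
    ax.set_title(grouped.peptide)
    top = max(m + s for m, s in zip(means, sems)) if means else 1.0
    step = 0.08 * top if top > 0 else 0.1
    level = top + step
    for r in comparison.pairwise:
        if r.skipped or not r.stars:
            continue
        i, j = labels.index(r.group_a), labels.index(r.group_b)
        ax.plot([i, i, j, j], [level, level + step / 3, level + step / 3, level], lw=0.8, c="k")
        ax.text((i + j) / 2, level + step / 3, r.stars, ha="center", va="bottom")
        level += step
    return ax
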