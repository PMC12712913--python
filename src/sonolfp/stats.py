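"""Group-comparison statistics for behavioral and electrophysiological measures.

The battery follows standard practice for small multi-group designs: each
group's sample is gated through Shapiro-Wilk normality (any failure at the
gate alpha switches the whole measure to the nonparametric branch);
normally-distributed measures get one-way ANOVA with Dunnett's test against
the control group, otherwise Kruskal-Wallis with two-sided Dunn's post-hoc
z-tests against control, Bonferroni-adjusted over the number of comparisons.
Levene's homogeneity test is reported as advisory. Significance stars follow
the usual 0.05 / 0.01 / 0.001 / 0.0001 ladder.

Dunn's test is implemented here (tie-corrected rank z-statistics); Dunnett's
test comes from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as ss

__all__ = ["StatReport", "Comparison", "compare_groups", "dunn_test", "stars"]


def stars(p: float) -> str:
    """Significance stars: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for thresh, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < thresh:
            return mark
    return "ns"


@dataclass
class Comparison:
    group: str
    statistic: float
    p_adj: float
    stars: str


@dataclass
class StatReport:
    """Outcome of the normality-gated group comparison."""

    measure: str
    normality_p: dict[str, float]
    levene_p: float
    test_used: str  # "anova+dunnett" or "kruskal+dunn"
    statistic: float
    p_omnibus: float
    comparisons: list[Comparison]

    def summary(self) -> str:
        lines = [f"{self.measure or 'measure'}: {self.test_used}"]
        lines.append(
            "  normality (Shapiro-Wilk p): "
            + ", ".join(f"{g}={p:.3g}" for g, p in self.normality_p.items())
        )
        lines.append(f"  Levene p = {self.levene_p:.3g} (advisory)")
        lines.append(f"  omnibus statistic = {self.statistic:.4g}, p = {self.p_omnibus:.3g}")
        for c in self.comparisons:
            lines.append(
                f"  vs {c.group}: stat = {c.statistic:.3g}, "
                f"adj p = {c.p_adj:.3g} {c.stars}"
            )
        return "\n".join(lines)


def _tie_correction(all_values: np.ndarray) -> float:
    _, counts = np.unique(all_values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def dunn_test(
    groups: dict[str, np.ndarray],
    control: str,
    adjust: str = "bonferroni",
) -> list[Comparison]:
    """Two-sided Dunn's post-hoc rank z-tests of each group against control.

    Pooled mid-ranks with tie correction; the z statistic for groups i, j is
    ``(Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))``
    where ``T = sum(t^3 - t)`` over tied values. Bonferroni adjustment over
    the number of vs-control comparisons (or none with ``adjust=None``).
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} missing")
    names = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(samples)
    n_total = len(pooled)
    ranks = ss.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    pos = 0
    for g, s in zip(names, samples):
        mean_ranks[g] = ranks[pos : pos + len(s)].mean()
        sizes[g] = len(s)
        pos += len(s)
    tie = _tie_correction(pooled)
    var_base = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    others = [g for g in names if g != control]
    k = len(others)
    out = []
    for g in others:
        se = np.sqrt(var_base * (1.0 / sizes[g] + 1.0 / sizes[control]))
        z = (mean_ranks[g] - mean_ranks[control]) / se
        p = 2.0 * ss.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * k)
        elif adjust is not None:
            raise ValueError(f"unknown adjustment {adjust!r}")
        out.append(Comparison(group=g, statistic=float(z), p_adj=float(p), stars=stars(p)))
    return out


def compare_groups(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    control: str = "CON",
    measure: str = "",
) -> StatReport:
    """Normality-gated omnibus + post-hoc comparison of groups vs control.

    All groups passing Shapiro-Wilk at ``alpha`` routes the measure through
    one-way ANOVA + Dunnett; any failure routes it through Kruskal-Wallis +
    Dunn (Bonferroni). Requires >= 2 groups of n >= 3 each.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if control not in groups:
        raise ValueError(f"control group {control!r} missing")
    samples = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in samples.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has n={len(v)} < 3")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {g!r} contains non-finite values")

    normality = {}
    for g, v in samples.items():
        if np.ptp(v) == 0:
            normality[g] = 1.0  # constant sample: Shapiro undefined, treat as pass
        else:
            normality[g] = float(ss.shapiro(v).pvalue)
    levene_p = float(ss.levene(*samples.values()).pvalue)
    all_normal = all(p > alpha for p in normality.values())

    others = [g for g in samples if g != control]
    if all_normal:
        stat, p_omni = ss.f_oneway(*samples.values())
        res = ss.dunnett(*(samples[g] for g in others), control=samples[control])
        comparisons = [
            Comparison(
                group=g,
                statistic=float(res.statistic[i]),
                p_adj=float(res.pvalue[i]),
                stars=stars(float(res.pvalue[i])),
            )
            for i, g in enumerate(others)
        ]
        test_used = "anova+dunnett"
    else:
        stat, p_omni = ss.kruskal(*samples.values())
        comparisons = dunn_test(samples, control=control)
        test_used = "kruskal+dunn"
    return StatReport(
        measure=measure,
        normality_p=normality,
        levene_p=levene_p,
        test_used=test_used,
        statistic=float(stat),
        p_omnibus=float(p_omni),
        comparisons=comparisons,
    )
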