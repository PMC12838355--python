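"""Cohort-level statistical comparison of quantification metrics.

Two tests are first-class, matching common practice for this kind of
imaging readout: one-way ANOVA with Tukey's HSD post-hoc for contrasts
across more than two conditions (the HWHM dispersion analysis), and the
two-sided Mann–Whitney U test for the two-age-group contrast.
Observations are treated as independent cells by default; a
donor-aggregated variant (per-donor medians) is available behind a flag
because cell-level pseudo-replication is a known hazard of imaging
cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

log = logging.getLogger(__name__)

TestName = Literal["anova_tukey", "mann_whitney"]

#: significance-star conventions
_STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def p_to_stars(p: float, alpha: float = 0.05) -> str:
    """Significance stars: **** <1e-4 ... * <0.05, else ``ns``."""
    if not np.isfinite(p):
        return "na"
    for level, stars in _STAR_LEVELS:
        if p < level:
            return stars
    return "ns" if p >= alpha else "*"


@dataclass(frozen=True)
class ComparisonSpec:
    """What to compare and how.

    ``response`` is a column of the quantification table (e.g.
    ``cyt_mfi``, ``nuc_hwhm``); ``grouping`` the factor column; ``strata``
    optional equality filters applied before testing.
    """

    response: str
    grouping: str = "group"
    strata: dict = field(default_factory=dict)
    test: TestName = "mann_whitney"
    alpha: float = 0.05
    donor_aggregate: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


@dataclass
class ComparisonResult:
    """Omnibus statistic, p-value and all-pairs table of one comparison."""

    test: str
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame
    n_per_group: dict
    n_dropped: int
    alpha: float

    @property
    def significant(self) -> bool:
        return bool(self.pvalue < self.alpha)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U.

    Exact enumeration of the U distribution for small, tie-free samples
    (both n <= 20); otherwise the normal approximation with tie correction
    and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _prepare_groups(
    records: pd.DataFrame, spec: ComparisonSpec
) -> tuple[list[str], list[np.ndarray], int]:
    df = records
    for col, val in spec.strata.items():
        df = df[df[col] == val]
    if spec.response not in df.columns:
        raise ValidationError(f"response column {spec.response!r} not found")

    # group membership is established before dropping missing responses so
    # that an all-missing group is reported by name, not silently lost
    names = list(pd.unique(df[spec.grouping]))
    if len(names) < 2:
        raise ValidationError(
            f"need >= 2 groups under {spec.grouping!r}; got {names}"
        )
    n_dropped = int(df[spec.response].isna().sum())
    if n_dropped:
        log.info("dropped %d records with missing %s", n_dropped, spec.response)

    groups = []
    for name in names:
        sub = df[df[spec.grouping] == name].dropna(subset=[spec.response])
        if len(sub) == 0:
            raise ValidationError(f"group {name!r} has all-missing response")
        if spec.donor_aggregate:
            vals = sub.groupby("donor")[spec.response].median().to_numpy()
        else:
            vals = sub[spec.response].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 values")
        groups.append(vals)
    return [str(n) for n in names], groups, n_dropped


def compare(records: pd.DataFrame, spec: ComparisonSpec) -> ComparisonResult:
    """Run the comparison described by ``spec`` on a quantification table.

    ``anova_tukey`` returns the one-way F statistic, omnibus p-value and a
    Tukey-HSD-adjusted all-pairs table; ``mann_whitney`` requires exactly
    two groups and returns U with a two-sided p (the pairwise table then
    holds that single pair).  Records with missing response are dropped
    and counted.
    """
    names, groups, n_dropped = _prepare_groups(records, spec)
    n_per_group = {n: int(g.size) for n, g in zip(names, groups)}

    if spec.test == "mann_whitney":
        if len(groups) != 2:
            raise ValidationError(
                f"mann_whitney needs exactly 2 groups; got {len(groups)}"
            )
        u, p = mann_whitney_u(groups[0], groups[1])
        pairwise = pd.DataFrame(
            [
                {
                    "group_a": names[0],
                    "group_b": names[1],
                    "estimate_diff": float(
                        np.median(groups[1]) - np.median(groups[0])
                    ),
                    "p_adj": p,
                    "significant": p < spec.alpha,
                }
            ]
        )
        return ComparisonResult(
            test="mann_whitney",
            statistic=u,
            pvalue=p,
            pairwise=pairwise,
            n_per_group=n_per_group,
            n_dropped=n_dropped,
            alpha=spec.alpha,
        )

    if spec.test != "anova_tukey":
        raise ValidationError(f"unknown test {spec.test!r}")

    f_stat, p_omni = sps.f_oneway(*groups)
    from itertools import combinations

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(groups)
    labels = np.concatenate(
        [np.full(g.size, n, dtype=object) for n, g in zip(names, groups)]
    )
    tukey = pairwise_tukeyhsd(values, labels, alpha=spec.alpha)
    # pairs come in combinations order over the sorted unique groups; use
    # the result attributes, not the summary table (which rounds p-values)
    uniq = [str(g) for g in tukey.groupsunique]
    pairs = list(combinations(uniq, 2))
    pairwise = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "estimate_diff": np.asarray(tukey.meandiffs, dtype=float),
            "p_adj": np.clip(
                np.asarray(tukey.pvalues, dtype=float), 0.0, 1.0
            ),
        }
    )
    pairwise["significant"] = pairwise["p_adj"] < spec.alpha
    return ComparisonResult(
        test="anova_tukey",
        statistic=float(f_stat),
        pvalue=float(p_omni),
        pairwise=pairwise,
        n_per_group=n_per_group,
        n_dropped=n_dropped,
        alpha=spec.alpha,
    )


def cohort_report(
    records: pd.DataFrame,
    metrics: Sequence[str] = ("mfi", "hwhm"),
    grouping: str = "group",
    test: TestName = "mann_whitney",
    alpha: float = 0.05,
    donor_aggregate: bool = False,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-(marker, cell type, compartment) two-group summary table.

    For each stratum and each metric the two groups are compared with
    ``test`` (Mann–Whitney by default, matching the two-age-group
    contrast) and annotated with descriptive medians and significance
    stars.  Strata with missing groups are skipped, never fabricated.  No
    multiple-testing correction is applied across strata by default; pass
    ``holm=True`` for a Holm adjustment over the emitted p-values.

    Returns an empty table for empty input.
    """
    columns = [
        "marker",
        "cell_type",
        "compartment",
        "metric",
        "group_a",
        "group_b",
        "n_a",
        "n_b",
        "median_a",
        "median_b",
        "statistic",
        "pvalue",
        "stars",
    ]
    if len(records) == 0:
        return pd.DataFrame(columns=columns)

    rows = []
    group_names = list(pd.unique(records[grouping]))
    for marker in pd.unique(records["marker"]):
        for cell_type in pd.unique(records["cell_type"]):
            for compartment, prefix in (("nuclear", "nuc"), ("cytoplasmic", "cyt")):
                for metric in metrics:
                    spec = ComparisonSpec(
                        response=f"{prefix}_{metric}",
                        grouping=grouping,
                        strata={"marker": marker, "cell_type": cell_type},
                        test=test,
                        alpha=alpha,
                        donor_aggregate=donor_aggregate,
                    )
                    try:
                        res = compare(records, spec)
                    except ValidationError as exc:
                        log.warning(
                            "stratum (%s, %s, %s, %s) skipped: %s",
                            marker, cell_type, compartment, metric, exc,
                        )
                        continue
                    sub = records[
                        (records["marker"] == marker)
                        & (records["cell_type"] == cell_type)
                    ]
                    med = {
                        g: float(
                            sub.loc[sub[grouping] == g, spec.response].median()
                        )
                        for g in group_names
                    }
                    rows.append(
                        {
                            "marker": marker,
                            "cell_type": cell_type,
                            "compartment": compartment,
                            "metric": metric,
                            "group_a": str(group_names[0]),
                            "group_b": str(group_names[1]),
                            "n_a": res.n_per_group[str(group_names[0])],
                            "n_b": res.n_per_group[str(group_names[1])],
                            "median_a": med[group_names[0]],
                            "median_b": med[group_names[1]],
                            "statistic": res.statistic,
                            "pvalue": res.pvalue,
                            "stars": p_to_stars(res.pvalue, alpha),
                        }
                    )
    report = pd.DataFrame(rows, columns=columns)
    if holm and len(report):
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(report["pvalue"], method="holm")
        report["pvalue_holm"] = p_adj
        report["stars"] = [p_to_stars(p, alpha) for p in p_adj]
    return report


def format_report(report: pd.DataFrame, alpha: float = 0.05) -> str:
    """Human-readable text rendering of :func:`cohort_report`."""
    lines = [
        "Nuclear/cytoplasmic staining comparison between groups",
        f"(two-sided tests; significance threshold p < {alpha:g}; "
        "* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001, ns not significant)",
        "",
    ]
    if len(report) == 0:
        lines.append("(no strata to report)")
        return "\n".join(lines) + "\n"
    for _, r in report.iterrows():
        lines.append(
            f"{r['marker']:>8s} {r['cell_type']:>4s} {r['compartment']:>12s} "
            f"{r['metric'].upper():>5s}: {r['group_a']} (n={r['n_a']}, "
            f"median={r['median_a']:.3f}) vs {r['group_b']} (n={r['n_b']}, "
            f"median={r['median_b']:.3f})  U={r['statistic']:.1f} "
            f"p={r['pvalue']:.4g} [{r['stars']}]"
        )
    return "\n".join(lines) + "\n"
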