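"""Per-stack aggregation and two-cohort nonparametric comparison.

The statistical unit is the per-stack mean waviness ratio (one value per
image stack, typically 10 control vs 11 diabetic stacks), not the individual
fragment: fragments within a stack are strongly correlated, and testing the
~10^5 fragment values directly would make any difference significant.  The
group comparison uses the two-sided Mann-Whitney-Wilcoxon rank-sum test with
continuity correction on the normal approximation; Shapiro-Wilk normality
p-values are reported as a diagnostic only and never gate the main test.
No multiple-testing correction is applied across regional scopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import WavinessRecord

log = logging.getLogger(__name__)

REGION_SCOPES = ("all", "thoracic", "abdominal", "arch")


@dataclass
class StackSummary:
    stack_id: str
    group_label: str | None
    region_label: str | None
    n_fragments: int
    mean_rec: float
    sd_rec: float


@dataclass
class RankSumResult:
    u_statistic: float
    p_value: float
    p_exact: float | None = None   # exact permutation p, small tie-free samples

    def __iter__(self):
        yield self.u_statistic
        yield self.p_value


@dataclass
class CohortComparison:
    group_a_label: str
    group_b_label: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    u_statistic: float
    p_value: float
    shapiro_p_a: float | None
    shapiro_p_b: float | None
    region_scope: str
    quantiles_a: dict[str, float] = field(default_factory=dict)
    quantiles_b: dict[str, float] = field(default_factory=dict)
    p_exact: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def summarize_stack(records: list[WavinessRecord],
                    group_label: str | None = None,
                    region_label: str | None = None) -> StackSummary:
    """Arithmetic mean and sample (n-1) SD of r_ec over one stack's records."""
    if not records:
        raise ValueError("cannot summarize a stack with no records")
    stack_ids = {r.stack_id for r in records}
    if len(stack_ids) != 1:
        raise ValueError(f"records span multiple stacks: {sorted(stack_ids)}")
    vals = np.array([r.r_ec for r in records], dtype=float)
    if len(vals) == 1:
        log.warning("stack %s has a single fragment; sd set to 0",
                    records[0].stack_id)
        sd = 0.0
    else:
        sd = float(vals.std(ddof=1))
    return StackSummary(stack_id=records[0].stack_id, group_label=group_label,
                        region_label=region_label, n_fragments=len(vals),
                        mean_rec=float(vals.mean()), sd_rec=sd)


def summarize_stacks(measurements: pd.DataFrame,
                     metadata: pd.DataFrame) -> list[StackSummary]:
    """Group a measurements table by stack and attach group/region labels.

    ``measurements`` needs columns stack_id and r_ec; ``metadata`` needs
    stack_id, group_label and (optionally) region_label.
    """
    need = {"stack_id", "r_ec"} - set(measurements.columns)
    if need:
        raise ValueError(f"measurements table missing columns: {sorted(need)}")
    if "stack_id" not in metadata.columns or "group_label" not in metadata.columns:
        raise ValueError("metadata table must have stack_id and group_label")
    meta = metadata.set_index("stack_id")
    out: list[StackSummary] = []
    for stack_id, grp in measurements.groupby("stack_id", sort=True):
        if stack_id not in meta.index:
            raise ValueError(f"stack {stack_id!r} absent from metadata")
        vals = grp["r_ec"].to_numpy(dtype=float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        region = meta.loc[stack_id].get("region_label", None)
        out.append(StackSummary(
            stack_id=str(stack_id),
            group_label=str(meta.loc[stack_id, "group_label"]),
            region_label=None if pd.isna(region) else str(region),
            n_fragments=len(vals), mean_rec=float(vals.mean()), sd_rec=sd))
    return out


def rank_sum_test(a, b) -> RankSumResult:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum test.

    U is the first sample's statistic from midrank assignment; the p-value
    uses the tie-corrected normal approximation with continuity correction
    (matching R's ``wilcox.test(correct = TRUE)``).  For small tie-free
    samples (n_a * n_b <= 400) the exact permutation p-value is computed as
    well and reported in ``p_exact``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        log.warning("all values identical across both groups; p = 1")
        return RankSumResult(u_statistic=len(a) * len(b) / 2.0, p_value=1.0)
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    p_exact = None
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if len(a) * len(b) <= 400 and not ties:
        p_exact = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                         method="exact").pvalue)
    return RankSumResult(u_statistic=float(res.statistic),
                         p_value=float(res.pvalue), p_exact=p_exact)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (diagnostic only)."""
    values = np.asarray(values, dtype=float)
    if not 3 <= len(values) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = sps.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def _quantiles(vals: np.ndarray) -> dict[str, float]:
    q = np.quantile(vals, [0.0, 0.25, 0.5, 0.75, 1.0])
    return {"min": float(q[0]), "q1": float(q[1]), "median": float(q[2]),
            "q3": float(q[3]), "max": float(q[4])}


def compare_cohorts(summaries: list[StackSummary], scope: str = "all",
                    group_a: str = "control", group_b: str = "diabetic",
                    ) -> CohortComparison:
    """Rank-sum comparison of per-stack mean r_ec between two groups.

    ``scope`` restricts to one anatomical region ("all" keeps every stack).
    Shapiro-Wilk p-values are included when group sizes permit (n >= 3).
    """
    if scope not in REGION_SCOPES:
        raise ValueError(f"scope must be one of {REGION_SCOPES}")
    pool = summaries if scope == "all" else [
        s for s in summaries if s.region_label == scope]
    vals_a = np.array([s.mean_rec for s in pool if s.group_label == group_a])
    vals_b = np.array([s.mean_rec for s in pool if s.group_label == group_b])
    for label, vals in ((group_a, vals_a), (group_b, vals_b)):
        if len(vals) == 0:
            raise ValueError(
                f"group {label!r} has no stacks in scope {scope!r}")
    test = rank_sum_test(vals_a, vals_b)
    sw_a = shapiro_wilk(vals_a)[1] if len(vals_a) >= 3 else None
    sw_b = shapiro_wilk(vals_b)[1] if len(vals_b) >= 3 else None
    return CohortComparison(
        group_a_label=group_a, group_b_label=group_b,
        n_a=len(vals_a), n_b=len(vals_b),
        mean_a=float(vals_a.mean()), sd_a=float(vals_a.std(ddof=1)) if len(vals_a) > 1 else 0.0,
        mean_b=float(vals_b.mean()), sd_b=float(vals_b.std(ddof=1)) if len(vals_b) > 1 else 0.0,
        u_statistic=test.u_statistic, p_value=test.p_value,
        shapiro_p_a=sw_a, shapiro_p_b=sw_b, region_scope=scope,
        quantiles_a=_quantiles(vals_a), quantiles_b=_quantiles(vals_b),
        p_exact=test.p_exact)


def plot_boxchart(summaries: list[StackSummary], path,
                  group_a: str = "control", group_b: str = "diabetic") -> None:
    """Box chart of per-stack mean r_ec for the two groups (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = [[s.mean_rec for s in summaries if s.group_label == g]
            for g in (group_a, group_b)]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot(vals, tick_labels=[group_a, group_b])
    ax.set_ylabel("per-stack mean $r_{ec}$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
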