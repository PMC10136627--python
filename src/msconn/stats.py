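"""Mixed-design repeated-measures ANOVA for the per-participant metrics.

Every metric the pipeline produces (rating, microstate duration, Cp,
Lp) ends up in the same long-format table — one value per participant
x condition — and is analysed the same way: a two-way mixed ANOVA with
Condition (Neg / Neu / Rea) as the within-subject factor and Group
(music / control) between subjects. Sphericity of the within-subject
covariance is checked with Mauchly's W; when it fails (p < alpha) the
within-effect degrees of freedom are multiplied by the
Greenhouse-Geisser epsilon, giving the fractional dfs reported in the
results. Post-hoc pairwise comparisons use Bonferroni-adjusted t-tests
with per-comparison error terms.

The ANOVA decomposition itself (sums of squares, Mauchly W, epsilon)
is delegated to pingouin; this module adds the conditional correction
policy, the interaction's corrected p-value, the report formatting and
the post-hoc layer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "validate_table",
    "mauchly_test",
    "gg_epsilon",
    "rm_anova_mixed",
    "bonferroni_posthoc",
    "analyze_metric",
    "AnovaResult",
]

_COLUMNS = ("participant", "group", "condition", "value")


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    epsilon: float = 1.0
    gg_applied: bool = False
    mauchly_w: float = float("nan")
    mauchly_p: float = float("nan")
    degenerate: bool = False
    posthoc: pd.DataFrame | None = None

    def report(self) -> str:
        """Format as ``F(df1, df2) = x.xxx, p = .xxx`` (GG dfs may be
        fractional)."""
        if self.degenerate:
            return f"{self.effect}: degenerate (no variance)"
        df1 = f"{self.df1:g}" if float(self.df1).is_integer() else f"{self.df1:.3f}"
        df2 = f"{self.df2:g}" if float(self.df2).is_integer() else f"{self.df2:.3f}"
        return f"{self.effect}: F({df1}, {df2}) = {self.F:.3f}, p = {self.p:.3g}"


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format measurement table: columns, complete cases,
    exactly one value per participant x condition."""
    missing = set(_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    t = table.loc[:, list(_COLUMNS)].copy()
    if t["value"].isna().any():
        raise ValueError("measurement table contains missing values (no imputation)")
    counts = t.groupby(["participant", "condition"]).size()
    if (counts != 1).any():
        raise ValueError("exactly one value per participant x condition required")
    per_part = t.groupby("participant")["condition"].nunique()
    if per_part.nunique() != 1:
        raise ValueError("unbalanced design: participants with missing conditions")
    return t


def _wide(table: pd.DataFrame) -> pd.DataFrame:
    return table.pivot(index="participant", columns="condition", values="value")


def mauchly_test(table: pd.DataFrame) -> tuple[float, float]:
    """Mauchly's sphericity test on the within-subject covariance.

    Returns (W, p). With 2 within levels sphericity holds trivially
    (W = 1, p = 1). A singular covariance (e.g. a duplicated level) is
    rejected.
    """
    t = validate_table(table)
    k = t["condition"].nunique()
    if k < 2:
        raise ValueError("need at least 2 within-subject levels")
    if k == 2:
        return 1.0, 1.0
    wide = _wide(t)
    if wide.shape[0] <= k:
        raise ValueError("need more participants than within-subject levels")
    cov = np.cov(wide.to_numpy(), rowvar=False)
    # covariance of k-1 orthonormal contrasts; a zero eigenvalue (e.g. a
    # duplicated level) makes Mauchly's W = 0 / undefined
    contrasts = np.linalg.qr(np.vstack([np.ones(k), np.eye(k - 1, k)]).T)[0][:, 1:]
    eig = np.linalg.eigvalsh(contrasts.T @ cov @ contrasts)
    if eig.min() < 1e-12 * max(eig.max(), 1.0):
        raise ValueError("singular within-subject covariance; Mauchly W undefined")
    res = pg.sphericity(
        data=t, dv="value", within="condition", subject="participant", method="mauchly"
    )
    return float(res.W), float(res.pval)


def gg_epsilon(table: pd.DataFrame) -> float:
    """Greenhouse-Geisser epsilon of the within-subject covariance,
    in (1/(k-1), 1]."""
    t = validate_table(table)
    return float(
        pg.epsilon(data=t, dv="value", within="condition", subject="participant", correction="gg")
    )


def rm_anova_mixed(
    table: pd.DataFrame, gg_policy: str = "mauchly", alpha: float = 0.05
) -> dict[str, AnovaResult]:
    """Two-way mixed ANOVA: Condition (within) x Group (between).

    ``gg_policy``: "mauchly" applies the Greenhouse-Geisser df
    correction to the within effects only when Mauchly's test rejects
    sphericity at ``alpha``; "always"/"never" force it on or off. The
    corrected denominator/numerator dfs are the uncorrected ones
    multiplied by epsilon, so they are generally fractional.
    """
    t = validate_table(table)
    groups_per_part = t.groupby("participant")["group"].nunique()
    if (groups_per_part != 1).any():
        raise ValueError("each participant must belong to exactly one group")
    if t["group"].nunique() < 2:
        raise ValueError("need two groups for a mixed design")
    k = t["condition"].nunique()

    if float(np.var(t["value"])) == 0.0:
        return {
            name: AnovaResult(
                effect=name, F=float("nan"), df1=float("nan"), df2=float("nan"),
                p=float("nan"), degenerate=True,
            )
            for name in ("Group", "Condition", "Interaction")
        }

    aov = pg.mixed_anova(
        data=t, dv="value", within="condition", subject="participant",
        between="group", correction=True,
    ).set_index("Source")

    if k > 2:
        w, p_sph = mauchly_test(t)
        eps = gg_epsilon(t)
    else:
        w, p_sph, eps = 1.0, 1.0, 1.0
    if gg_policy == "always":
        apply_gg = k > 2
    elif gg_policy == "never":
        apply_gg = False
    elif gg_policy == "mauchly":
        apply_gg = k > 2 and p_sph < alpha
    else:
        raise ValueError(f"unknown gg_policy {gg_policy!r}")

    out: dict[str, AnovaResult] = {}
    row = aov.loc["group"]
    out["Group"] = AnovaResult(
        effect="Group", F=float(row["F"]), df1=float(row["DF1"]), df2=float(row["DF2"]),
        p=float(row["p_unc"]),
    )
    for name, source in (("Condition", "condition"), ("Interaction", "Interaction")):
        row = aov.loc[source]
        f_val, df1, df2 = float(row["F"]), float(row["DF1"]), float(row["DF2"])
        if apply_gg:
            df1_c, df2_c = df1 * eps, df2 * eps
            p = float(sps.f.sf(f_val, df1_c, df2_c))
            out[name] = AnovaResult(
                effect=name, F=f_val, df1=df1_c, df2=df2_c, p=p, epsilon=eps,
                gg_applied=True, mauchly_w=w, mauchly_p=p_sph,
            )
        else:
            out[name] = AnovaResult(
                effect=name, F=f_val, df1=df1, df2=df2, p=float(row["p_unc"]),
                epsilon=eps, gg_applied=False, mauchly_w=w, mauchly_p=p_sph,
            )
    return out


def bonferroni_posthoc(table: pd.DataFrame, effect: str = "Condition") -> pd.DataFrame:
    """Bonferroni-corrected pairwise comparisons for one effect.

    * Condition: paired t-tests between condition pairs (m = C(k, 2));
    * Group: independent t-test between the two groups (m = 1);
    * Interaction: independent group comparisons within each condition
      (m = number of conditions).

    ``p_adj = min(1, m * p)`` with per-comparison error terms.
    """
    t = validate_table(table)
    rows = []
    if effect == "Condition":
        wide = _wide(t)
        pairs = list(itertools.combinations(sorted(wide.columns), 2))
        m = len(pairs)
        for a, b in pairs:
            res = sps.ttest_rel(wide[a], wide[b])
            rows.append(("Condition", f"{a} vs {b}", float(res.statistic),
                         float(res.df), float(res.pvalue)))
    elif effect == "Group":
        groups = sorted(t["group"].unique())
        pairs = list(itertools.combinations(groups, 2))
        m = len(pairs)
        means = t.groupby(["participant", "group"])["value"].mean().reset_index()
        for a, b in pairs:
            xa = means.loc[means["group"] == a, "value"]
            xb = means.loc[means["group"] == b, "value"]
            res = sps.ttest_ind(xa, xb)
            rows.append(("Group", f"{a} vs {b}", float(res.statistic),
                         float(res.df), float(res.pvalue)))
    elif effect == "Interaction":
        conds = sorted(t["condition"].unique())
        groups = sorted(t["group"].unique())
        if len(groups) != 2:
            raise ValueError("interaction post-hoc expects exactly 2 groups")
        m = len(conds)
        for c in conds:
            sub = t[t["condition"] == c]
            xa = sub.loc[sub["group"] == groups[0], "value"]
            xb = sub.loc[sub["group"] == groups[1], "value"]
            res = sps.ttest_ind(xa, xb)
            rows.append(("Interaction", f"{groups[0]} vs {groups[1]} @ {c}",
                         float(res.statistic), float(res.df), float(res.pvalue)))
    else:
        raise ValueError(f"unknown effect {effect!r}")
    df = pd.DataFrame(rows, columns=["effect", "comparison", "t", "df", "p_unc"])
    df["p_adj"] = np.minimum(1.0, m * df["p_unc"])
    return df


def analyze_metric(
    table: pd.DataFrame,
    metric_name: str = "value",
    gg_policy: str = "mauchly",
    alpha: float = 0.05,
) -> dict[str, AnovaResult]:
    """Full analysis of one metric: mixed ANOVA plus post-hoc tables
    attached to every non-degenerate effect."""
    results = rm_anova_mixed(table, gg_policy=gg_policy, alpha=alpha)
    for name, res in results.items():
        if not res.degenerate:
            res.posthoc = bonferroni_posthoc(table, effect=name)
    return results
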