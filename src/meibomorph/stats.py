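"""Cohort statistics for paired two-eye gland-deformation designs.

Implements the statistical machinery used to summarise central-10-gland
deformation coefficients: paired t-tests of treatment-minus-control
differences per gland, one-way ANOVA across the ten gland positions within
a group, Fisher LSD post-hoc comparisons with a compressed ordering
string, and reconstruction utilities (t, CI, n, F) that operate on
summary rows alone when raw data are unavailable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsError",
    "SummaryStat",
    "PairedTResult",
    "AnovaResult",
    "LsdResult",
    "paired_t",
    "t_from_summary",
    "ci_from_summary",
    "infer_n_from_summary",
    "anova_from_summary",
    "anova_raw",
    "lsd_posthoc",
    "independent_t",
    "construct_groups_from_summary",
    "emit_tables",
]


class StatsError(ValueError):
    """Raised for degenerate statistical inputs."""


@dataclass
class SummaryStat:
    """Mean/SD/SE/n/df of one summary-table cell row."""

    mean: float
    sd: float
    se: float | None = None
    n: int | None = None
    df: int | None = None

    def __post_init__(self) -> None:
        if self.n is not None:
            se = self.sd / np.sqrt(self.n)
            if self.se is None:
                self.se = se
            elif self.se > 0 and abs(self.se - se) / se > 0.01:
                raise StatsError("se inconsistent with sd/sqrt(n) beyond 1%")
            if self.df is None:
                self.df = self.n - 1


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    ci: tuple[float, float]
    mean: float
    sd: float
    se: float
    n: int


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    msw: float


@dataclass
class LsdResult:
    labels: list
    means: np.ndarray
    significant: np.ndarray  # (k, k) bool, pairwise p < alpha
    p_values: np.ndarray
    ordering: str
    blocks: list[list]
    unplaced: list


def paired_t(differences: Sequence[float], level: float = 0.95) -> PairedTResult:
    """Paired t-test from per-subject differences.

    t = mean / (sd/sqrt(n)), df = n-1, two-sided p, CI = mean +/-
    t_{(1+level)/2, df} * se.  Zero-variance input is an error.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise StatsError("need at least 2 differences")
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise StatsError("zero-variance differences")
    se = sd / np.sqrt(n)
    t = mean / se
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    tcrit = float(sps.t.ppf((1.0 + level) / 2.0, df))
    return PairedTResult(
        t=float(t), df=df, p=p, ci=(mean - tcrit * se, mean + tcrit * se),
        mean=mean, sd=sd, se=float(se), n=n,
    )


def t_from_summary(mean_diff: float, se: float) -> float:
    """t statistic from a printed mean difference and its SE."""
    if se <= 0:
        raise StatsError("se must be > 0")
    return mean_diff / se


def ci_from_summary(
    mean: float, se: float, df: int, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided CI from a printed mean, SE and df; always ascending."""
    if se <= 0:
        raise StatsError("se must be > 0")
    if df < 1:
        raise StatsError("df must be >= 1")
    tcrit = float(sps.t.ppf((1.0 + level) / 2.0, df))
    return (mean - tcrit * se, mean + tcrit * se)


def infer_n_from_summary(sd: float, se: float) -> tuple[int, float]:
    """Group size implied by printed SD and SE: n = (sd/se)^2.

    Returns (rounded n, unrounded estimate).
    """
    if sd <= 0 or se <= 0:
        raise StatsError("sd and se must be > 0")
    raw = (sd / se) ** 2
    return int(round(raw)), float(raw)


def anova_from_summary(
    means: Sequence[float], sds: Sequence[float], n_per_group: int
) -> AnovaResult:
    """One-way ANOVA from per-group means and SDs at equal group size n.

    MSB = n * sum((m_i - m_bar)^2) / (k-1); MSW = mean of the group
    variances; F = MSB/MSW.
    """
    m = np.asarray(means, dtype=float)
    s = np.asarray(sds, dtype=float)
    if m.size < 2 or m.size != s.size:
        raise StatsError("need >= 2 groups with matching means/sds")
    if n_per_group < 2:
        raise StatsError("n_per_group must be >= 2")
    k = m.size
    msb = n_per_group * np.sum((m - m.mean()) ** 2) / (k - 1)
    msw = float(np.mean(s**2))
    if msw == 0.0:
        raise StatsError("zero within-group variance")
    df_b, df_w = k - 1, k * (n_per_group - 1)
    f = float(msb / msw)
    return AnovaResult(F=f, df_between=df_b, df_within=df_w, p=float(sps.f.sf(f, df_b, df_w)), msw=msw)


def anova_raw(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way ANOVA from raw per-group values (groups may differ in size)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise StatsError("need >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(gs)
    grand = all_vals.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in gs)
    df_b = len(gs) - 1
    df_w = all_vals.size - len(gs)
    if ssw == 0.0:
        raise StatsError("zero within-group variance")
    f = float((ssb / df_b) / (ssw / df_w))
    return AnovaResult(
        F=f, df_between=df_b, df_within=df_w,
        p=float(sps.f.sf(f, df_b, df_w)), msw=float(ssw / df_w),
    )


def lsd_posthoc(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence | None = None,
) -> LsdResult:
    """Fisher LSD pairwise comparisons after a one-way ANOVA.

    Pairwise t uses the pooled within-group mean square:
    t_ij = (m_i - m_j) / sqrt(MSW * (1/n_i + 1/n_j)) with the within df.

    The compressed ordering string sorts group means descending and
    greedily builds blocks: a group joins the current block when it is
    non-significantly different from every member; it starts a new block
    when it differs significantly from every member; otherwise it is left
    unplaced.  Blocks are joined with " > ".  A single all-inclusive block
    yields an empty string (no separations to report).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    res = anova_raw(gs)
    k = len(gs)
    if labels is None:
        labels = list(range(1, k + 1))
    labels = list(labels)
    means = np.array([g.mean() for g in gs])
    ns = np.array([g.size for g in gs])

    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(res.msw * (1.0 / ns[i] + 1.0 / ns[j]))
            t = (means[i] - means[j]) / se
            p = float(2.0 * sps.t.sf(abs(t), res.df_within))
            pmat[i, j] = pmat[j, i] = p
    sig = pmat < alpha

    order = np.argsort(-means)
    blocks: list[list[int]] = []
    unplaced: list[int] = []
    current: list[int] = []
    for gi in order:
        if not current:
            current = [int(gi)]
            continue
        if not any(sig[gi, m] for m in current):
            current.append(int(gi))
        elif all(sig[gi, m] for m in current):
            blocks.append(current)
            current = [int(gi)]
        else:
            unplaced.append(int(gi))
    if current:
        blocks.append(current)

    if len(blocks) <= 1 and not unplaced:
        ordering = ""
    else:
        ordering = " > ".join(
            ", ".join(str(labels[m]) for m in sorted(b))
            for b in blocks
        )
    return LsdResult(
        labels=labels,
        means=means,
        significant=sig,
        p_values=pmat,
        ordering=ordering,
        blocks=[[labels[m] for m in b] for b in blocks],
        unplaced=[labels[m] for m in unplaced],
    )


def independent_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float, float]:
    """Two-sample t-test (pooled variance by default, Welch optional).

    Returns (t, df, p); the sign follows mean(a) - mean(b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs >= 2 values")
    if equal_var and a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        raise StatsError("zero pooled variance")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = a.size + b.size - 2.0
    else:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return float(t), float(df), float(p)


def construct_groups_from_summary(
    means: Sequence[float],
    sds: Sequence[float],
    n_per_group: int,
    seed: int = 0,
) -> list[np.ndarray]:
    """Raw groups whose sample mean and SD (ddof=1) match the summaries exactly.

    Random draws are affinely rescaled per group, so summary-level and
    raw-data routines can be compared on identical inputs.
    """
    rng = np.random.default_rng(seed)
    out = []
    for m, s in zip(means, sds):
        x = rng.normal(size=n_per_group)
        x = (x - x.mean()) / x.std(ddof=1)
        out.append(m + s * x)
    return out


def _complete_subjects(df: pd.DataFrame) -> pd.DataFrame:
    """Keep subjects with a full 10-gland record in both eyes; warn on the rest."""
    counts = df.groupby(["subject_id", "group"])["gland_index"].nunique().unstack(fill_value=0)
    for grp in ("treatment", "control"):
        if grp not in counts:
            counts[grp] = 0
    ok = counts.index[(counts["treatment"] == 10) & (counts["control"] == 10)]
    dropped = sorted(set(counts.index) - set(ok))
    if dropped:
        warnings.warn(f"excluding incomplete subjects: {dropped}", stacklevel=3)
    return df[df["subject_id"].isin(ok)]


def emit_tables(
    per_gland: pd.DataFrame,
    alpha: float = 0.05,
    fdr_correct: bool = False,
    level: float = 0.95,
) -> dict[str, pd.DataFrame]:
    """Summary tables from a per-gland long table.

    ``per_gland`` needs columns subject_id, group ("treatment"/"control"),
    gland_index (1..10) and D.  Subjects lacking a complete 10-gland record
    in both eyes are excluded with a warning.

    Returns ``{"paired": ..., "treatment_sites": ..., "control_sites": ...}``:
    per-gland paired differences (mean, SD, SE, CI, t, p) and per-group
    site summaries with the one-way ANOVA F and the LSD ordering string
    attached to the first row.  ``fdr_correct=True`` adds a
    Benjamini-Hochberg-adjusted p column to the paired table (off by
    default; the reference analysis applied no correction).
    """
    required = {"subject_id", "group", "gland_index", "D"}
    if not required.issubset(per_gland.columns):
        raise StatsError(f"per-gland table needs columns {sorted(required)}")
    df = _complete_subjects(per_gland)
    if df["subject_id"].nunique() < 2:
        raise StatsError("need >= 2 complete subjects")

    wide = df.pivot_table(index="subject_id", columns=["group", "gland_index"], values="D")
    paired_rows = []
    for g in range(1, 11):
        diffs = (wide[("treatment", g)] - wide[("control", g)]).to_numpy()
        try:
            r = paired_t(diffs, level=level)
        except StatsError as exc:
            raise StatsError(f"gland {g}: {exc}") from exc
        paired_rows.append(
            {
                "gland": g, "mean": r.mean, "sd": r.sd, "se": r.se,
                "ci_lo": r.ci[0], "ci_hi": r.ci[1], "t": r.t, "df": r.df, "p": r.p,
            }
        )
    paired = pd.DataFrame(paired_rows)
    if fdr_correct:
        paired["p_bh"] = sps.false_discovery_control(paired["p"].to_numpy())

    out = {"paired": paired}
    for grp in ("treatment", "control"):
        sub = df[df["group"] == grp]
        groups = [sub.loc[sub["gland_index"] == g, "D"].to_numpy() for g in range(1, 11)]
        res = anova_raw(groups)
        lsd = lsd_posthoc(groups, alpha=alpha, labels=list(range(1, 11)))
        rows = []
        for g, vals in zip(range(1, 11), groups):
            m, s = float(np.mean(vals)), float(np.std(vals, ddof=1))
            lo, hi = ci_from_summary(m, s / np.sqrt(len(vals)), len(vals) - 1, level)
            rows.append({"gland": g, "mean": m, "sd": s, "ci_lo": lo, "ci_hi": hi, "n": len(vals)})
        tab = pd.DataFrame(rows)
        tab["F"] = np.nan
        tab.loc[0, "F"] = res.F
        tab["p"] = np.nan
        tab.loc[0, "p"] = res.p
        tab["lsd"] = ""
        tab.loc[0, "lsd"] = lsd.ordering
        out[f"{grp}_sites"] = tab
    return out
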