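"""Within-subject inference on the cohort feature table.

The feature table is long-format: one row per subject x pressure condition
with the extracted physiological features and VAS ratings.  The inference
stage mirrors standard psychophysiology practice for a complete balanced
within-subject design:

* one-way repeated-measures ANOVA per feature
  (F = MS_condition / MS_{condition x subject}), with Greenhouse-Geisser
  epsilon and corrected p alongside the uncorrected (sphericity-assumed) p;
* post hoc paired t-tests between pressure pairs (uncorrected by default,
  Holm or Bonferroni on request);
* pooled Pearson correlation of each feature against the normalized VAS;
* assumption checks: per-condition Shapiro-Wilk normality and Mauchly's
  sphericity test.

Rendered tables follow the conventional layout: "mean ± SD" cells,
3-decimal statistics with a "0.000" display floor, and "*" flagging
p < alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps


class StatsError(ValueError):
    """Raised for invalid designs or degenerate data."""


FEATURE_COLUMNS = ["mean_scl_uS", "max_scr_amp_uS", "scr_count",
                   "sto2_decrease_pct", "vas_norm_pct"]

FEATURE_LABELS = {
    "mean_scl_uS": "Mean SCL [uS]",
    "max_scr_amp_uS": "Max Amplitude [uS]",
    "scr_count": "SCR Counts",
    "sto2_decrease_pct": "Decrease in StO2 [%]",
    "vas_raw": "VAS",
    "vas_norm_pct": "Normalized VAS [%]",
}


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the complete balanced within-subject design requirement."""
    for col in ("subject", "pressure_kPa"):
        if col not in table.columns:
            raise StatsError(f"feature table lacks required column {col!r}")
    counts = table.groupby(["subject", "pressure_kPa"]).size()
    if (counts != 1).any():
        raise StatsError("design not balanced: each subject needs each "
                         "pressure exactly once")
    per_subject = table.groupby("subject")["pressure_kPa"].nunique()
    if per_subject.nunique() != 1:
        raise StatsError("incomplete design: subjects differ in conditions")
    return table


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RMAnovaResult:
    feature: str
    f_value: float
    df_num: int
    df_den: int
    p_value: float
    gg_epsilon: float
    p_value_gg: float


@dataclass(frozen=True)
class PairedTestResult:
    feature: str
    pair: tuple[float, float]
    t_value: float
    df: int
    p_value: float
    significant: bool
    p_adjusted: float


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    r: float
    n: int
    p_value: float


@dataclass(frozen=True)
class AssumptionReport:
    feature: str
    normality: dict  # pressure -> (W, p)
    mauchly_w: float
    mauchly_p: float
    sphericity_ok: bool


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _wide(table: pd.DataFrame, feature: str) -> pd.DataFrame:
    validate_feature_table(table)
    if feature not in table.columns:
        raise StatsError(f"unknown feature {feature!r}")
    wide = table.pivot(index="subject", columns="pressure_kPa", values=feature)
    if wide.isna().any().any():
        raise StatsError(f"missing values for feature {feature!r}")
    return wide.sort_index(axis=1)


def rm_anova(table: pd.DataFrame, feature: str) -> RMAnovaResult:
    """One-way repeated-measures ANOVA for one feature.

    Degenerate inputs: if the condition sum of squares is (numerically)
    zero the null is exactly true and F=0, p=1 is returned; a zero error
    mean square with a real condition effect raises instead.
    """
    wide = _wide(table, feature)
    n, k = wide.shape
    if n < 2 or k < 2:
        raise StatsError("need at least 2 subjects and 2 conditions")
    data = wide.to_numpy(dtype=float)
    grand = data.mean()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    resid = data - data.mean(axis=1, keepdims=True) - data.mean(axis=0) + grand
    ss_err = (resid ** 2).sum()
    df_num, df_den = k - 1, (k - 1) * (n - 1)
    scale = max(grand ** 2, data.var() if data.size else 1.0, 1e-30)
    if ss_cond <= 1e-12 * scale * n * k:
        return RMAnovaResult(feature, 0.0, df_num, df_den, 1.0,
                             gg_epsilon=1.0, p_value_gg=1.0)
    if ss_err <= 1e-12 * scale * n * k:
        raise StatsError("zero error mean square: degenerate data")

    long = wide.reset_index().melt(id_vars="subject", var_name="pressure_kPa",
                                   value_name=feature)
    aov = pg.rm_anova(data=long, dv=feature, within="pressure_kPa",
                      subject="subject", correction=True)
    row = aov.iloc[0]
    # pingouin skips the GG correction when k == 2 (sphericity is trivial)
    eps = float(row.get("eps", 1.0)) if "eps" in aov.columns else 1.0
    p_gg = float(row["p_GG_corr"]) if "p_GG_corr" in aov.columns \
        and np.isfinite(row.get("p_GG_corr", np.nan)) else float(row["p_unc"])
    return RMAnovaResult(feature=feature, f_value=float(row["F"]),
                         df_num=int(row["ddof1"]), df_den=int(row["ddof2"]),
                         p_value=float(row["p_unc"]), gg_epsilon=eps,
                         p_value_gg=p_gg)


def paired_ttests(
    table: pd.DataFrame,
    feature: str,
    pairs: list[tuple[float, float]] | None = None,
    correction: str = "none",
    alpha: float = 0.05,
) -> list[PairedTestResult]:
    """Post hoc two-sided paired t-tests between pressure conditions.

    ``correction`` in {"none", "holm", "bonferroni"} adjusts the p-values
    used for the significance flag; raw p-values are always reported.
    Identical paired vectors give t=0, p=1; zero-variance differences with
    a nonzero mean are degenerate and raise.
    """
    if correction not in ("none", "holm", "bonferroni"):
        raise StatsError(f"unknown correction {correction!r}")
    wide = _wide(table, feature)
    if pairs is None:
        pairs = list(itertools.combinations(sorted(wide.columns), 2))
    raw: list[tuple[tuple[float, float], float, int, float]] = []
    for a, b in pairs:
        if a not in wide.columns or b not in wide.columns:
            raise StatsError(f"pair ({a}, {b}) not present for every subject")
        d = wide[b].to_numpy(dtype=float) - wide[a].to_numpy(dtype=float)
        n = d.size
        if np.allclose(d, 0.0):
            raw.append(((a, b), 0.0, n - 1, 1.0))
            continue
        if np.std(d, ddof=1) == 0.0:
            raise StatsError(f"zero-variance differences for pair ({a}, {b})")
        t, p = sps.ttest_rel(wide[b], wide[a])
        raw.append(((a, b), float(t), n - 1, float(p)))

    pvals = np.array([r[3] for r in raw])
    if correction == "none":
        p_adj = pvals
    else:
        _, p_adj = pg.multicomp(pvals, method=correction)
    return [PairedTestResult(feature=feature, pair=pair, t_value=t, df=df,
                             p_value=p, significant=bool(pa < alpha),
                             p_adjusted=float(pa))
            for (pair, t, df, p), pa in zip(raw, p_adj)]


def pearson_vs_vas(
    table: pd.DataFrame,
    feature: str,
    against: str = "vas_norm_pct",
) -> CorrelationResult:
    """Pooled Pearson correlation over all subject x condition rows."""
    if feature not in table.columns or against not in table.columns:
        raise StatsError(f"missing column for correlation: {feature!r}/{against!r}")
    sub = table[[feature, against]].dropna()
    x = sub[feature].to_numpy(dtype=float)
    y = sub[against].to_numpy(dtype=float)
    if x.size < 3:
        raise StatsError("need at least 3 complete pairs")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise StatsError("zero variance in a correlation variable")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(feature=feature, r=float(r), n=int(x.size),
                             p_value=float(p))


def check_assumptions(table: pd.DataFrame, feature: str,
                      alpha: float = 0.05) -> AssumptionReport:
    """Shapiro-Wilk normality per condition and Mauchly's sphericity test.

    With only two conditions there is a single difference variance, so
    sphericity holds trivially (W = 1).
    """
    wide = _wide(table, feature)
    n, k = wide.shape
    if n < 3:
        raise StatsError("need at least 3 subjects for assumption checks")
    normality = {}
    for col in wide.columns:
        w, p = sps.shapiro(wide[col])
        normality[float(col)] = (float(w), float(p))
    if k == 2:
        return AssumptionReport(feature, normality, mauchly_w=1.0,
                                mauchly_p=1.0, sphericity_ok=True)
    long = wide.reset_index().melt(id_vars="subject", var_name="pressure_kPa",
                                   value_name=feature)
    sph = pg.sphericity(data=long, dv=feature, within="pressure_kPa",
                        subject="subject")
    return AssumptionReport(feature, normality, mauchly_w=float(sph.W),
                            mauchly_p=float(sph.pval),
                            sphericity_ok=bool(sph.pval >= alpha))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def format_mean_sd(mean: float, sd: float, decimals: int = 2) -> str:
    return f"{mean:.{decimals}f} ± {sd:.{decimals}f}"


def format_stat(x: float, decimals: int = 3) -> str:
    return f"{x:.{decimals}f}"


def format_p(p: float, alpha: float | None = 0.05, decimals: int = 3) -> str:
    """Display-floor a p-value at 3 decimals ("0.000" for p < 0.0005) and
    star it when below alpha; stored values keep full precision."""
    cell = f"{p:.{decimals}f}"
    if alpha is not None and p < alpha:
        cell += " *"
    return cell


@dataclass
class CohortSummary:
    descriptives: pd.DataFrame
    anova: list[RMAnovaResult]
    pairwise: list[PairedTestResult]
    correlations: list[CorrelationResult]
    assumptions: list[AssumptionReport]
    alpha: float = 0.05
    features: list[str] = field(default_factory=list)


def summarize_cohort(
    table: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "none",
    vas_column: str = "vas_norm_pct",
) -> CohortSummary:
    """Full inference pass: descriptives, RM ANOVA, post hoc paired t-tests,
    and pooled correlations against the normalized VAS for every feature
    column present in the table."""
    if table.empty:
        raise StatsError("empty feature table")
    validate_feature_table(table)
    features = [c for c in FEATURE_COLUMNS
                if c in table.columns and c != vas_column]

    rows = []
    for p_kpa, grp in table.groupby("pressure_kPa"):
        row = {"pressure_kPa": p_kpa}
        for feat in features + ([vas_column] if vas_column in table.columns else []):
            dec = 1 if feat == "scr_count" else 2
            row[feat] = format_mean_sd(grp[feat].mean(), grp[feat].std(ddof=1), dec)
        rows.append(row)
    descriptives = pd.DataFrame(rows).set_index("pressure_kPa").sort_index()

    anova, pairwise, correlations, assumptions = [], [], [], []
    for feat in features:
        anova.append(rm_anova(table, feat))
        pairwise.extend(paired_ttests(table, feat, correction=correction,
                                      alpha=alpha))
        if vas_column in table.columns:
            correlations.append(pearson_vs_vas(table, feat, against=vas_column))
        assumptions.append(check_assumptions(table, feat, alpha=alpha))
    return CohortSummary(descriptives=descriptives, anova=anova,
                         pairwise=pairwise, correlations=correlations,
                         assumptions=assumptions, alpha=alpha,
                         features=features)


def render_report(summary: CohortSummary) -> str:
    """Markdown report with the four summary tables."""
    lines: list[str] = ["# Cohort summary", ""]
    feats = summary.features
    labels = [FEATURE_LABELS.get(f, f) for f in feats]

    lines += ["## Descriptives (mean ± SD per pressure condition)", ""]
    desc = summary.descriptives.rename(
        columns={c: FEATURE_LABELS.get(c, c) for c in summary.descriptives.columns})
    lines += [desc.to_markdown(), ""]

    if summary.anova:
        lines += ["## Repeated-measures ANOVA", "",
                  "| | " + " | ".join(labels) + " |",
                  "|---" * (len(feats) + 1) + "|"]
        fcells = [format_stat(a.f_value) for a in summary.anova]
        pcells = [format_p(a.p_value, summary.alpha) for a in summary.anova]
        lines += ["| F-value | " + " | ".join(fcells) + " |",
                  "| p-value | " + " | ".join(pcells) + " |", ""]
        eps = [f"{a.gg_epsilon:.3f}" for a in summary.anova]
        lines += ["Greenhouse-Geisser epsilon: "
                  + ", ".join(f"{l}={e}" for l, e in zip(labels, eps)), ""]

    if summary.pairwise:
        pairs = sorted({t.pair for t in summary.pairwise})
        lines += ["## Post hoc paired t-tests (p-values)", "",
                  "| Group | " + " | ".join(labels) + " |",
                  "|---" * (len(feats) + 1) + "|"]
        for pair in pairs:
            cells = []
            for f in feats:
                hit = [t for t in summary.pairwise if t.feature == f and t.pair == pair]
                cells.append(format_p(hit[0].p_value, summary.alpha) if hit else "")
            lines.append(f"| {pair[0]:g} kPa vs. {pair[1]:g} kPa | "
                         + " | ".join(cells) + " |")
        lines += ["", f"*: p < {summary.alpha:g}", ""]

    if summary.correlations:
        lines += ["## Pearson correlation vs. normalized VAS", "",
                  "| Feature | r | n | p |", "|---|---|---|---|"]
        for c in summary.correlations:
            lines.append(f"| {FEATURE_LABELS.get(c.feature, c.feature)} | "
                         f"{c.r:.2f} | {c.n} | {format_p(c.p_value, summary.alpha)} |")
        lines.append("")

    if summary.assumptions:
        lines += ["## Assumption checks", "",
                  "| Feature | Mauchly W | Mauchly p | sphericity | min Shapiro p |",
                  "|---|---|---|---|---|"]
        for a in summary.assumptions:
            min_p = min(p for _, p in a.normality.values())
            lines.append(f"| {FEATURE_LABELS.get(a.feature, a.feature)} | "
                         f"{a.mauchly_w:.3f} | {format_p(a.mauchly_p, None)} | "
                         f"{'ok' if a.sphericity_ok else 'violated'} | "
                         f"{format_p(min_p, None)} |")
        lines.append("")
    return "\n".join(lines)


def results_to_dict(summary: CohortSummary) -> dict:
    """Full-precision JSON-ready dump of a cohort summary."""
    desc = {}
    for p_kpa, row in summary.descriptives.iterrows():
        desc[f"{p_kpa:g}"] = dict(row)
    return {
        "alpha": summary.alpha,
        "descriptives": desc,
        "rm_anova": [vars(a) | {} for a in summary.anova],
        "paired_ttests": [
            {"feature": t.feature, "pair": list(t.pair), "t_value": t.t_value,
             "df": t.df, "p_value": t.p_value, "p_adjusted": t.p_adjusted,
             "significant": t.significant} for t in summary.pairwise],
        "correlations": [vars(c) | {} for c in summary.correlations],
        "assumptions": [
            {"feature": a.feature, "mauchly_w": a.mauchly_w,
             "mauchly_p": a.mauchly_p, "sphericity_ok": a.sphericity_ok,
             "normality": {f"{k:g}": list(v) for k, v in a.normality.items()}}
            for a in summary.assumptions],
    }


__all__ = [
    "StatsError", "FEATURE_COLUMNS", "FEATURE_LABELS",
    "RMAnovaResult", "PairedTestResult", "CorrelationResult",
    "AssumptionReport", "CohortSummary",
    "validate_feature_table", "rm_anova", "paired_ttests", "pearson_vs_vas",
    "check_assumptions", "summarize_cohort", "render_report",
    "results_to_dict", "format_mean_sd", "format_stat", "format_p",
]
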