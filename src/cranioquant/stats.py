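"""Longitudinal statistics: per-subject slopes, assumption-gated group
comparisons, and the ICV ~ thickness mixed-effects association.

The analysis follows the standard longitudinal-morphometry recipe:

* per subject and per age stratum (below / at-or-above 20 years, the age by
  which natural skull growth has levelled off), an ordinary least-squares
  slope of ICV (mL/year) and of median skull thickness (mm/year) versus age,
  requiring at least two scans at distinct ages;
* group comparisons of those slopes gated on assumptions — Shapiro-Wilk
  (n <= 50) or Lilliefors-corrected Kolmogorov-Smirnov (n > 50) for
  normality, Levene for variance homogeneity — choosing a t-test (two
  groups), one-way ANOVA, or Kruskal-Wallis with Dunn's post-hoc z-tests
  under Bonferroni correction (three groups);
* a linear mixed-effects model ICV ~ thickness + sex with a per-subject
  random intercept (REML), fitted within a group on adult scans only, whose
  thickness coefficient beta (mL per mm) quantifies how much intracranial
  volume is lost per millimetre of skull thickening.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.diagnostic import lilliefors

from .errors import InsufficientDataError, ParameterError

logger = logging.getLogger(__name__)

GROUPS = ("MLD", "MS", "control")
AGE_SPLIT_YEARS = 20.0
DEFAULT_ALPHA = 0.05
#: group size at which normality testing switches from Shapiro-Wilk to
#: Kolmogorov-Smirnov (Lilliefors, parameters estimated from the sample)
SHAPIRO_MAX_N = 50

SCAN_COLUMNS = ["subject_id", "group", "sex", "age_years", "icv_ml", "thickness_mm"]


@dataclass
class GroupComparisonResult:
    design: str                      # "two_group_t" | "anova" | "kruskal_wallis"
    statistic: float
    p_value: float
    assumption_report: dict
    posthoc: list[tuple[tuple[str, str], float, float]] | None = None

    def significant_pairs(self, alpha: float = DEFAULT_ALPHA) -> list[tuple[str, str]]:
        if not self.posthoc:
            return []
        return [pair for pair, _, p in self.posthoc if p < alpha]


@dataclass
class LmmResult:
    beta_thickness_ml_per_mm: float
    beta_sex_ml: float
    intercept_ml: float
    se_thickness: float
    p_thickness: float
    var_random_intercept: float
    var_residual: float
    n_obs: int
    n_subjects: int
    converged: bool
    notes: list[str] = field(default_factory=list)

    def ci_thickness(self, level: float = 0.95) -> tuple[float, float]:
        z = sps.norm.ppf(0.5 + level / 2)
        b, se = self.beta_thickness_ml_per_mm, self.se_thickness
        return (b - z * se, b + z * se)


def fit_subject_slope(ages: np.ndarray, values: np.ndarray) -> float:
    """OLS slope of ``values`` on ``ages`` (per year); needs >= 2 distinct ages."""
    ages = np.asarray(ages, float)
    values = np.asarray(values, float)
    ok = np.isfinite(ages) & np.isfinite(values)
    ages, values = ages[ok], values[ok]
    if len(ages) < 2 or np.ptp(ages) == 0:
        raise InsufficientDataError("need >= 2 scans at distinct ages to fit a slope")
    a = ages - ages.mean()
    return float(a @ (values - values.mean()) / (a @ a))


def stratify_scans(records: pd.DataFrame, age_split: float = AGE_SPLIT_YEARS) -> pd.DataFrame:
    """Assign each scan to the under-20 or over-20 stratum (boundary age goes up)."""
    df = records.copy()
    df["stratum"] = np.where(df["age_years"] < age_split, "under20", "over20")
    return df


def compute_slopes(records: pd.DataFrame, age_split: float = AGE_SPLIT_YEARS) -> pd.DataFrame:
    """Per-subject, per-stratum slopes of ICV and thickness versus age.

    Returns one row per (subject, stratum) with >= 2 scans at distinct ages:
    columns subject_id, group, stratum, d_icv_ml_per_year,
    d_thickness_mm_per_year (NaN when thickness is missing on < 2 scans),
    n_scans_used. Subjects with enough scans in both strata contribute a
    slope to each. Missing thickness rows are dropped per-measure, never
    imputed.
    """
    _require_columns(records)
    df = stratify_scans(records, age_split)
    rows = []
    for (sid, stratum), sub in df.groupby(["subject_id", "stratum"], sort=True):
        ages = sub["age_years"].to_numpy(float)
        if len(ages) < 2 or np.ptp(ages) == 0:
            continue
        row = {
            "subject_id": sid,
            "group": sub["group"].iloc[0],
            "stratum": stratum,
            "n_scans_used": len(ages),
            "d_icv_ml_per_year": fit_subject_slope(ages, sub["icv_ml"].to_numpy(float)),
        }
        thick = sub[["age_years", "thickness_mm"]].dropna()
        if len(thick) >= 2 and np.ptp(thick["age_years"].to_numpy()) > 0:
            row["d_thickness_mm_per_year"] = fit_subject_slope(
                thick["age_years"].to_numpy(float), thick["thickness_mm"].to_numpy(float)
            )
        else:
            row["d_thickness_mm_per_year"] = np.nan
        rows.append(row)
    if not rows:
        raise InsufficientDataError("no subject has >= 2 scans in any stratum")
    return pd.DataFrame(rows)


def _require_columns(records: pd.DataFrame) -> None:
    missing = [c for c in SCAN_COLUMNS if c not in records.columns]
    if missing:
        raise ParameterError(f"scan table is missing columns {missing}")


def _normality_pvalues(groups: dict[str, np.ndarray]) -> dict[str, tuple[str, float]]:
    out = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, float)
        if np.ptp(vals) == 0:
            out[name] = ("degenerate", 0.0)  # constant sample: treat as non-normal
            continue
        if len(vals) <= SHAPIRO_MAX_N:
            out[name] = ("shapiro_wilk", float(sps.shapiro(vals).pvalue))
        else:
            out[name] = ("kolmogorov_smirnov", float(lilliefors(vals, dist="norm")[1]))
    return out


def choose_test(groups: dict[str, np.ndarray], alpha: float = DEFAULT_ALPHA) -> tuple[str, dict]:
    """Pick the comparison design from the assumption checks.

    Two groups: t-test, Welch-corrected when Levene rejects equal variances.
    Three groups: one-way ANOVA only when every group passes normality and
    Levene passes; otherwise Kruskal-Wallis. Zero-variance degeneracies fall
    through to the nonparametric branch with a logged note.
    """
    groups = {k: np.asarray(v, float)[np.isfinite(np.asarray(v, float))] for k, v in groups.items()}
    if len(groups) not in (2, 3):
        raise ParameterError("choose_test expects 2 or 3 groups")
    for name, vals in groups.items():
        if len(vals) < 3:
            raise InsufficientDataError(f"group {name!r} has {len(vals)} slopes (< 3)")
    normality = _normality_pvalues(groups)
    all_constant = all(np.ptp(v) == 0 for v in groups.values())
    if all_constant:
        logger.warning("all groups constant: variance test degenerate, using nonparametric design")
        levene_p = float("nan")
    else:
        levene_p = float(sps.levene(*groups.values()).pvalue)
    report = {
        "normality": normality,
        "levene_p": levene_p,
        "alpha": alpha,
        "group_n": {k: len(v) for k, v in groups.items()},
    }
    normal_ok = all(p > alpha for _, p in normality.values())
    var_ok = (not np.isnan(levene_p)) and levene_p > alpha
    if len(groups) == 2:
        design = "two_group_t"
        report["welch"] = not var_ok
    else:
        design = "anova" if (normal_ok and var_ok) else "kruskal_wallis"
    report["design"] = design
    return design, report


def _dunn_posthoc(
    groups: dict[str, np.ndarray], bonferroni_m: int | None = None
) -> list[tuple[tuple[str, str], float, float]]:
    """Dunn's pairwise z-tests on pooled mid-ranks with tie correction.

    For groups i, j:  z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with tie term T = sum(t^3 - t) / (12 (N - 1)). Two-sided p, Bonferroni
    multiplied by the number of pairs and capped at 1.
    """
    names = list(groups)
    pooled = np.concatenate([groups[n] for n in names])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    mean_ranks, sizes, start = {}, {}, 0
    for n in names:
        size = len(groups[n])
        mean_ranks[n] = ranks[start : start + size].mean()
        sizes[n] = size
        start += size
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(names, 2))
    m = bonferroni_m if bonferroni_m is not None else len(pairs)
    out = []
    for a, b in pairs:
        se = np.sqrt(variance_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        out.append(((a, b), float(z), float(min(1.0, p_raw * m))))
    return out


def compare_groups(
    groups: dict[str, np.ndarray],
    design: str | None = None,
    alpha: float = DEFAULT_ALPHA,
    always_posthoc: bool = False,
) -> GroupComparisonResult:
    """Omnibus comparison of slope sets, with Dunn's post-hoc when warranted.

    ``design`` defaults to the :func:`choose_test` selection. Post-hoc
    pairwise tests are run for the Kruskal-Wallis design when the omnibus p
    is below ``alpha`` (or unconditionally with ``always_posthoc``).
    """
    clean = {k: np.asarray(v, float)[np.isfinite(np.asarray(v, float))] for k, v in groups.items()}
    if design is None:
        design, report = choose_test(clean, alpha)
    else:
        _, report = choose_test(clean, alpha)
        report["design"] = design
    vals = list(clean.values())
    posthoc = None
    if design == "two_group_t":
        welch = report.get("welch", report["levene_p"] < alpha)
        if np.ptp(np.concatenate(vals)) == 0:
            stat, p = 0.0, 1.0
        else:
            res = sps.ttest_ind(vals[0], vals[1], equal_var=not welch)
            stat, p = float(res.statistic), float(res.pvalue)
    elif design == "anova":
        res = sps.f_oneway(*vals)
        stat, p = float(res.statistic), float(res.pvalue)
    elif design == "kruskal_wallis":
        if np.ptp(np.concatenate(vals)) == 0:
            stat, p = 0.0, 1.0  # rank-degenerate: identical data in all groups
        else:
            res = sps.kruskal(*vals)
            stat, p = float(res.statistic), float(res.pvalue)
        if always_posthoc or p < alpha:
            posthoc = _dunn_posthoc(clean)
    else:
        raise ParameterError(f"unknown design {design!r}")
    return GroupComparisonResult(
        design=design, statistic=stat, p_value=p, assumption_report=report, posthoc=posthoc
    )


def fit_icv_thickness_lmm(
    records: pd.DataFrame,
    group: str | None = None,
    min_age: float = AGE_SPLIT_YEARS,
    min_subjects: int = 10,
) -> LmmResult:
    """REML fit of icv_ml ~ thickness_mm + sex with a per-subject random intercept.

    Restricted to scans at ``min_age`` or older (adult skulls, where growth
    has stopped) and, when ``group`` is given, to that group. Sex is coded
    female = 0, male = 1, so ``beta_sex_ml`` is the male ICV offset. Rows
    with missing thickness are dropped. The thickness p-value is a Wald test.
    """
    _require_columns(records)
    df = records.copy()
    if group is not None:
        df = df[df["group"] == group]
    df = df[df["age_years"] >= min_age].dropna(subset=["thickness_mm", "icv_ml"])
    n_subjects = df["subject_id"].nunique()
    if n_subjects < min_subjects:
        raise InsufficientDataError(
            f"{n_subjects} subjects with usable adult scans (< {min_subjects})"
        )
    df["sex_male"] = (df["sex"].astype(str).str.lower().str[0] == "m").astype(float)
    exog = np.c_[np.ones(len(df)), df["thickness_mm"].to_numpy(float), df["sex_male"].to_numpy()]
    notes: list[str] = []
    model = MixedLM(df["icv_ml"].to_numpy(float), exog, groups=df["subject_id"].to_numpy())
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit = model.fit(reml=True)
        for w in caught:
            notes.append(str(w.message))
    converged = bool(getattr(fit, "converged", True)) and not any(
        "convergence" in n.lower() and "failed" in n.lower() for n in notes
    )
    var_ri = float(np.squeeze(fit.cov_re))
    if var_ri < 1e-10:
        notes.append("random-intercept variance pinned at 0 (singular fit)")
    return LmmResult(
        beta_thickness_ml_per_mm=float(fit.params[1]),
        beta_sex_ml=float(fit.params[2]),
        intercept_ml=float(fit.params[0]),
        se_thickness=float(fit.bse[1]),
        p_thickness=float(fit.pvalues[1]),
        var_random_intercept=max(0.0, var_ri),
        var_residual=float(fit.scale),
        n_obs=len(df),
        n_subjects=int(n_subjects),
        converged=converged,
        notes=notes,
    )


def regional_slope_homogeneity(
    regional_slopes: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> GroupComparisonResult:
    """Within one group, test whether thickness slopes differ across regions.

    ``regional_slopes`` has columns region and d_thickness_mm_per_year (one
    row per subject x region, temporal excluded upstream as unreliable). The
    regions play the role of groups in the choose_test -> compare_groups
    machinery; a non-significant result means the thickening is global
    rather than region-specific.
    """
    groups = {
        str(region): sub["d_thickness_mm_per_year"].to_numpy(float)
        for region, sub in regional_slopes.groupby("region")
    }
    return compare_groups(groups, alpha=alpha)
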