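"""Statistical stage: cohort tests, covariate-adjusted group comparison of
lateralization indices, FDR correction, age correlation, social-emotional
subgrouping, and the two-proportion sample-size computation.

Group comparisons of network measures and asymmetry scores use an ordinary
least-squares general linear model: outcome ~ group + covariates, with the
group-indicator coefficient as the adjusted effect and its two-sided t-test
p-value as the raw p. Multiple testing is corrected with Benjamini-Hochberg
within analysis families that mirror how the comparisons are reported: one
family for the five global-metric asymmetries, one for the four
fronto-limbic betweenness asymmetries, and one family per auxiliary analysis
(age correlation, subgroup comparison).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .atlas import ROI_NAMES
from .errors import ConfigurationError, InputError
from .metrics import GLOBAL_METRICS

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("sex", "age_at_mri", "bpd")
SUBGROUP_COVARIATES = ("gestational_age", "age_at_mri")

DEFAULT_FAMILIES: dict[str, tuple[str, ...]] = {
    "global": tuple(GLOBAL_METRICS),
    "roi": tuple(ROI_NAMES),
}


@dataclass
class ComparisonResult:
    """Adjusted group comparison for one outcome."""

    outcome: str
    effect: float
    p_raw: float
    p_fdr: float
    covariates: list[str] = field(default_factory=list)
    n_per_group: tuple[int, int] = (0, 0)
    n_dropped: int = 0


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sum of hypergeometric point probabilities not exceeding the observed
    table's probability (the convention of R and SPSS).
    """
    counts = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in counts):
        raise InputError(f"counts must be nonnegative integers, got {counts}")
    if min(a + b, c + d, a + c, b + d) == 0:
        raise InputError(f"table {counts} has an empty margin")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def chi_square_2x2(a: int, b: int, c: int, d: int, yates: bool = False
                   ) -> tuple[float, float]:
    """Pearson chi-square statistic and p for a 2x2 table, optionally with
    the Yates continuity correction."""
    if min(a + b, c + d, a + c, b + d) == 0:
        raise InputError(f"table {(a, b, c, d)} has an empty margin")
    stat, p, _, _ = sps.chi2_contingency([[a, b], [c, d]], correction=yates)
    return float(stat), float(p)


def group_test(x, y, method: str = "student_t") -> float:
    """Two-sided two-sample p-value.

    ``student_t`` is the pooled-variance Student's t-test; ``mann_whitney``
    the Mann-Whitney U-test (exact for small samples without ties, normal
    approximation with tie correction otherwise, midranks for ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InputError("each group needs at least 2 observations")
    if method == "student_t":
        return float(sps.ttest_ind(x, y, equal_var=True).pvalue)
    if method == "mann_whitney":
        return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    raise InputError(f"unknown method {method!r}")


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _encode_column(series: pd.Series, name: str) -> pd.Series:
    """Numeric passthrough; two-level categorical/bool to a 0/1 indicator."""
    if series.dtype == bool:
        return series.astype(float)
    if pd.api.types.is_numeric_dtype(series):
        return series.astype(float)
    levels = sorted(series.dropna().unique())
    if len(levels) != 2:
        raise InputError(
            f"covariate {name!r} must be numeric or two-level, "
            f"found levels {levels}"
        )
    return (series == levels[1]).astype(float)


def glm_adjusted_compare(
    outcome: pd.Series,
    cohort: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    group_col: str = "group",
    groups: tuple[str, str] | None = ("preterm", "term"),
    outcome_name: str = "",
) -> ComparisonResult:
    """OLS of outcome on a group indicator plus covariates.

    ``outcome`` is indexed by subject_id; ``cohort`` must carry
    ``subject_id``, the group column, and the covariates. The effect is the
    group coefficient (first group minus second), its two-sided t-test gives
    the raw p; ``p_fdr`` is NaN until a family correction is applied.
    Subjects with missing outcome (undefined asymmetry) are dropped with a
    logged count. Rank-deficient designs raise :class:`InputError` naming
    the collinear columns.
    """
    df = cohort.set_index("subject_id").loc[outcome.index.intersection(
        cohort["subject_id"])].copy()
    y = outcome.reindex(df.index).astype(float)
    keep = y.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("glm %s: dropped %d subjects with undefined outcome",
                 outcome_name, n_dropped)
    df, y = df[keep], y[keep]
    gcol = df[group_col]
    if groups is None:
        groups = tuple(sorted(gcol.dropna().unique(), reverse=True))[:2]
    g1, g2 = groups
    in_groups = gcol.isin([g1, g2])
    df, y, gcol = df[in_groups], y[in_groups], gcol[in_groups]
    design = pd.DataFrame(index=df.index)
    design["const"] = 1.0
    design["group"] = (gcol == g1).astype(float)
    for cov in covariates:
        if cov not in df.columns:
            raise InputError(f"covariate {cov!r} not in cohort table")
        design[cov] = _encode_column(df[cov], cov)
    x = design.to_numpy()
    if np.linalg.matrix_rank(x) < x.shape[1]:
        _, r = np.linalg.qr(x)
        bad = [design.columns[i] for i in range(x.shape[1])
               if abs(r[i, i]) < 1e-10]
        raise InputError(f"design matrix is rank-deficient; collinear "
                         f"columns: {bad}")
    fit = sm.OLS(y.to_numpy(), x).fit()
    i_group = list(design.columns).index("group")
    return ComparisonResult(
        outcome=outcome_name,
        effect=float(fit.params[i_group]),
        p_raw=float(fit.pvalues[i_group]),
        p_fdr=math.nan,
        covariates=list(covariates),
        n_per_group=(int((gcol == g1).sum()), int((gcol == g2).sum())),
        n_dropped=n_dropped,
    )


def _as_wide(as_table: pd.DataFrame) -> pd.DataFrame:
    """Defined asymmetry records pivoted to subject x metric."""
    defined = as_table[as_table["defined"]]
    return defined.pivot(index="subject_id", columns="metric", values="AS")


def compare_lateralization(
    as_table: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    group_col: str = "group",
    groups: tuple[str, str] | None = ("preterm", "term"),
    families: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Adjusted group comparison of every asymmetry outcome, BH-corrected
    within families. Returns one row per outcome."""
    families = DEFAULT_FAMILIES if families is None else families
    wide = _as_wide(as_table)
    rows = []
    for family, metrics in families.items():
        results = []
        for metric in metrics:
            if metric not in wide.columns:
                continue
            # reindex to the full cohort so undefined records are counted
            series = wide[metric].reindex(cohort["subject_id"])
            res = glm_adjusted_compare(
                series, cohort, covariates=covariates,
                group_col=group_col, groups=groups, outcome_name=metric,
            )
            results.append((family, res))
        if not results:
            continue
        adj = fdr_bh([r.p_raw for _, r in results])
        for (family_name, res), p_adj in zip(results, adj):
            res.p_fdr = float(p_adj)
            rows.append(
                {"family": family_name, "outcome": res.outcome,
                 "effect": res.effect, "p_raw": res.p_raw, "p_fdr": res.p_fdr,
                 "n_group1": res.n_per_group[0], "n_group2": res.n_per_group[1],
                 "n_dropped": res.n_dropped,
                 "covariates": ",".join(res.covariates)}
            )
    return pd.DataFrame(rows)


def correlate_with_age(as_table: pd.DataFrame, cohort: pd.DataFrame,
                       age_col: str = "age_at_mri") -> pd.DataFrame:
    """Pearson correlation of each asymmetry outcome with age at MRI,
    BH-corrected across outcomes. Zero-variance outcomes are flagged as
    undefined and excluded from the correction family."""
    wide = _as_wide(as_table)
    age = cohort.set_index("subject_id")[age_col]
    rows = []
    for metric in wide.columns:
        vals = wide[metric].dropna()
        if len(vals) < 3:
            rows.append({"outcome": metric, "r": math.nan, "p_raw": math.nan,
                         "n": len(vals), "defined": False})
            continue
        a = age.reindex(vals.index)
        if np.std(vals) == 0 or np.std(a) == 0:
            rows.append({"outcome": metric, "r": math.nan, "p_raw": math.nan,
                         "n": len(vals), "defined": False})
            continue
        r, p = sps.pearsonr(vals, a)
        rows.append({"outcome": metric, "r": float(r), "p_raw": float(p),
                     "n": len(vals), "defined": True})
    out = pd.DataFrame(rows)
    out["p_fdr"] = math.nan
    ok = out["defined"] & out["p_raw"].notna() & (out["p_raw"] > 0)
    if ok.any():
        out.loc[ok, "p_fdr"] = fdr_bh(out.loc[ok, "p_raw"])
    return out


def subgroup_compare(
    as_table: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates=SUBGROUP_COVARIATES,
) -> pd.DataFrame:
    """Abnormal (< 85) vs normal Bayley social-emotional subgroups among
    assessed preterm infants, adjusted for gestational age and age at MRI,
    one BH family across all outcomes."""
    preterm = cohort[(cohort["group"] == "preterm")
                     & cohort["assessed_flag"].astype(bool)].copy()
    if preterm.empty:
        raise InputError("no assessed preterm subjects in cohort")
    preterm["se_group"] = np.where(preterm["se_abnormal"].astype(bool),
                                   "abnormal", "normal")
    families = {"subgroup": tuple(GLOBAL_METRICS) + tuple(ROI_NAMES)}
    return compare_lateralization(
        as_table[as_table["subject_id"].isin(preterm["subject_id"])],
        preterm,
        covariates=covariates,
        group_col="se_group",
        groups=("abnormal", "normal"),
        families=families,
    )


def sample_size_two_proportions(
    p1: float,
    p2: float,
    alpha: float = 0.05,
    power: float = 0.8,
    dropout: float = 0.10,
) -> dict:
    """Per-group and total n for detecting a difference of two proportions.

    Normal-approximation formula
    ``n = (z_{1-a/2} sqrt(2 pbar qbar) + z_{1-b} sqrt(p1 q1 + p2 q2))^2 /
    (p1 - p2)^2`` per group, ceiled, then inflated by ``1/(1 - dropout)``.
    Returns both pre- and post-dropout counts.
    """
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ConfigurationError("proportions must lie in (0, 1)")
    if p1 == p2:
        raise ConfigurationError("p1 and p2 must differ")
    if not (0 < alpha < 1 and 0 < power < 1 and 0 <= dropout < 1):
        raise ConfigurationError("invalid alpha / power / dropout")
    za = sps.norm.ppf(1 - alpha / 2)
    zb = sps.norm.ppf(power)
    pbar = (p1 + p2) / 2
    n = (za * math.sqrt(2 * pbar * (1 - pbar))
         + zb * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))) ** 2 / (p1 - p2) ** 2
    per_group = math.ceil(n)
    per_group_inflated = math.ceil(per_group / (1 - dropout))
    return {
        "n_per_group": per_group,
        "n_total": 2 * per_group,
        "n_per_group_dropout": per_group_inflated,
        "n_total_dropout": 2 * per_group_inflated,
    }


def analytic_sample_size(recruited: int, exclusions) -> int:
    """Cohort attrition accounting: recruited minus successive exclusion
    counts, validated to stay nonnegative at every step."""
    n = int(recruited)
    if n < 0:
        raise InputError("recruited count must be nonnegative")
    for step, x in enumerate(exclusions):
        x = int(x)
        if x < 0:
            raise InputError(f"exclusion count at step {step} is negative")
        n -= x
        if n < 0:
            raise InputError(
                f"exclusions exceed remaining sample at step {step}"
            )
    return n


def proportion_pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage as printed in cohort tables (rounded)."""
    if denominator <= 0:
        raise InputError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)
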