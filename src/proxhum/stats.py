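"""Statistical stage: normality, group comparisons, correlations, ICC.

The comparisons mirror a classic morphometry study design: pooled-variance
independent-samples t-tests for sex differences (pooled rather than Welch —
recomputing the reference tables from their printed per-sex summaries
reproduces the printed t-values only under pooled variance), paired t-tests
between imaging modalities, Pearson correlations among the 3-D parameters,
Lilliefors-corrected Kolmogorov-Smirnov normality screening (the normal's
parameters are estimated from the sample), and two-way random-effects
absolute-agreement single-measures ICC (ICC(2,1)) for intra- and
inter-observer reproducibility, with Bonett's precision-based planning of
the reliability-subset size.  No multiple-testing adjustment is applied
(alpha = 0.05 throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

from .errors import SchemaError, ValidationError

__all__ = [
    "SummaryStats",
    "ComparisonResult",
    "ICCResult",
    "summarize",
    "t_independent_pooled",
    "t_paired",
    "pearson_r",
    "ks_normality",
    "icc_two_way",
    "bonett_ci_width",
    "icc_sample_size",
    "build_study_tables",
]


@dataclass(frozen=True)
class SummaryStats:
    """n / mean / SD of one group, as printed in a summary table."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError(f"need n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValidationError(f"negative SD {self.sd}")


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    df: float
    p_value: float
    test_kind: str

    def __post_init__(self):
        if self.df <= 0:
            raise ValidationError(f"non-positive degrees of freedom {self.df}")
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    design: str
    n_subjects: int
    n_raters: int

    def __post_init__(self):
        if not -1.0 - 1e-9 <= self.icc <= 1.0 + 1e-9:
            raise ValidationError(f"ICC {self.icc} outside [-1, 1]")
        if self.ci_low > self.icc + 1e-9 or self.ci_high < self.icc - 1e-9:
            raise ValidationError("confidence interval does not contain the estimate")


def summarize(x) -> SummaryStats:
    x = np.asarray(x, dtype=float)
    return SummaryStats(n=len(x), mean=float(x.mean()), sd=float(x.std(ddof=1)))


def _coerce_summary(g) -> SummaryStats:
    if isinstance(g, SummaryStats):
        return g
    return summarize(g)


def t_independent_pooled(a, b) -> ComparisonResult:
    """Pooled-variance two-sample t-test from raw values or summaries.

    df = n1 + n2 - 2; two-sided p.  With zero pooled variance the statistic
    is flagged +/-inf (p = 0) unless the means also coincide (t = 0).
    """
    sa, sb = _coerce_summary(a), _coerce_summary(b)
    df = sa.n + sb.n - 2
    sp2 = ((sa.n - 1) * sa.sd**2 + (sb.n - 1) * sb.sd**2) / df
    diff = sa.mean - sb.mean
    if sp2 == 0:
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        se = math.sqrt(sp2 * (1.0 / sa.n + 1.0 / sb.n))
        t = diff / se
        p = 2.0 * sps.t.sf(abs(t), df)
    return ComparisonResult(statistic=t, df=df, p_value=p, test_kind="independent_pooled")


def t_paired(x, y) -> ComparisonResult:
    """Paired t-test on the differences x - y; df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(
            f"paired samples must be 1-D and equal length, got {x.shape} vs {y.shape}"
        )
    n = len(x)
    if n < 2:
        raise ValidationError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        m = d.mean()
        t = 0.0 if m == 0 else math.copysign(math.inf, m)
        p = 1.0 if m == 0 else 0.0
    else:
        t = d.mean() / (sd / math.sqrt(n))
        p = 2.0 * sps.t.sf(abs(t), n - 1)
    return ComparisonResult(statistic=float(t), df=n - 1, p_value=float(p), test_kind="paired")


def pearson_r(x, y):
    """Pearson correlation and its two-sided p (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("pearson_r needs equal-length samples of n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def ks_normality(x):
    """Kolmogorov-Smirnov normality test with Lilliefors correction.

    The null normal's mean/SD are estimated from the sample, so the plain
    KS distribution would be anti-conservative; Lilliefors' corrected
    quantiles are used instead.  Returns (D, p).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValidationError("normality screening needs n >= 5")
    D, p = _lilliefors(x, dist="norm")
    return float(D), float(p)


def icc_two_way(table, design: str = "inter") -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``table`` is subjects x columns (sessions for the intra-observer
    design, raters for the inter-observer design); the table must be
    complete.  The confidence interval is the standard F-based one.
    """
    if design not in ("intra", "inter"):
        raise ValidationError(f"design must be 'intra' or 'inter', got {design!r}")
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2:
        raise SchemaError(f"measurement table must be 2-D, got shape {tab.shape}")
    n, k = tab.shape
    if n < 5:
        raise SchemaError(f"need at least 5 subjects, got {n}")
    if k < 2:
        raise SchemaError(f"need at least 2 measurement columns, got {k}")
    if not np.all(np.isfinite(tab)):
        raise SchemaError("incomplete measurement table (non-finite cells)")

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": tab.ravel(),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        res = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
    # absolute-agreement, single measures: "ICC2" in older pingouin,
    # "ICC(A,1)" in newer releases
    key = "ICC(A,1)" if "ICC(A,1)" in res.index else "ICC2"
    row = res.loc[key]
    icc = float(row["ICC"])
    ci = row["CI95%"] if "CI95%" in row.index else row["CI95"]
    lo, hi = float(ci[0]), float(ci[1])
    if not np.isfinite(icc):
        raise SchemaError("ICC undefined for this table")
    if not (np.isfinite(lo) and np.isfinite(hi)):
        lo, hi = icc, icc
    lo, hi = min(lo, icc), max(hi, icc)
    return ICCResult(
        icc=icc, ci_low=lo, ci_high=hi, design=design, n_subjects=n, n_raters=k
    )


def bonett_ci_width(rho: float, n: int, k: int, confidence: float = 0.95) -> float:
    """Approximate expected CI width for an ICC estimated from n subjects,
    k raters (Bonett's 2002 large-sample variance)."""
    if not 0 < rho < 1:
        raise ValidationError(f"planning ICC must lie in (0, 1), got {rho}")
    if n < 2 or k < 2:
        raise ValidationError("need n >= 2 subjects and k >= 2 raters")
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    var = 2.0 * (1 - rho) ** 2 * (1 + (k - 1) * rho) ** 2 / (k * (k - 1) * (n - 1))
    return float(2.0 * z * math.sqrt(var))


def icc_sample_size(
    rho_planning: float,
    ci_width: float,
    n_raters: int = 3,
    confidence: float = 0.95,
    max_n: int = 10**6,
) -> int:
    """Smallest subject count whose expected ICC CI is narrower than target.

    Scans n upward using the same width approximation as
    :func:`bonett_ci_width`; a closed-form seed keeps the scan short.
    """
    if not 0 < rho_planning < 1:
        raise ValidationError(f"planning ICC must lie in (0, 1), got {rho_planning}")
    if not 0 < ci_width < 1:
        raise ValidationError(f"target CI width must lie in (0, 1), got {ci_width}")
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    k = n_raters
    seed = (
        8.0
        * z**2
        * (1 - rho_planning) ** 2
        * (1 + (k - 1) * rho_planning) ** 2
        / (k * (k - 1) * ci_width**2)
    )
    n = max(2, int(seed) - 2)
    while n <= max_n:
        if bonett_ci_width(rho_planning, n, k, confidence) <= ci_width:
            return n
        n += 1
    raise ValidationError(
        f"target width {ci_width} unattainable within n <= {max_n}"
    )


# ---------------------------------------------------------------------------
# study tables
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = {"subject_id", "sex", "parameter", "modality", "rater", "session", "value"}
_PARAM_ORDER = ("NSA", "TSH", "HHT", "cASD", "aASD")


def _check_schema(cohort: pd.DataFrame) -> None:
    missing = _TABLE_COLUMNS - set(cohort.columns)
    if missing:
        raise SchemaError(f"cohort table missing columns: {sorted(missing)}")


def _primary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Main-examiner first-session measurements, one row per subject/param."""
    sel = (cohort["rater"] == 1) & (cohort["session"] == 1)
    return cohort.loc[sel]


def build_study_tables(cohort: pd.DataFrame) -> dict:
    """Summaries, sex tests, modality tests, correlations and ICCs.

    ``cohort`` is the long measurement table (subject_id, sex, parameter,
    modality in {3d, xray}, rater, session, value).  Returns a dict of
    DataFrames: ``table1`` (per-sex summaries + pooled t), ``table2``
    (paired 3-D vs radiograph tests), ``table3_r``/``table3_p`` (3-D
    correlation matrix), ``icc`` (intra/inter reproducibility per
    parameter and modality).
    """
    _check_schema(cohort)
    main = _primary(cohort)

    rows1 = []
    for modality in ("3d", "xray"):
        for param in _PARAM_ORDER:
            sub = main[(main["modality"] == modality) & (main["parameter"] == param)]
            if sub.empty:
                continue
            male = sub.loc[sub["sex"] == "M", "value"].to_numpy()
            female = sub.loc[sub["sex"] == "F", "value"].to_numpy()
            cmp_ = t_independent_pooled(male, female)
            rows1.append(
                {
                    "modality": modality,
                    "parameter": param,
                    "n_total": len(sub),
                    "mean_total": sub["value"].mean(),
                    "sd_total": sub["value"].std(ddof=1),
                    "mean_male": male.mean(),
                    "sd_male": male.std(ddof=1),
                    "mean_female": female.mean(),
                    "sd_female": female.std(ddof=1),
                    "t_value": cmp_.statistic,
                    "p_value": cmp_.p_value,
                }
            )
    table1 = pd.DataFrame(rows1)

    rows2 = []
    wide = main.pivot_table(
        index="subject_id", columns=["parameter", "modality"], values="value"
    )
    for param in ("NSA", "TSH", "HHT", "cASD"):
        if (param, "3d") not in wide.columns or (param, "xray") not in wide.columns:
            continue
        pair = wide[[(param, "3d"), (param, "xray")]].dropna()
        cmp_ = t_paired(pair[(param, "3d")].to_numpy(), pair[(param, "xray")].to_numpy())
        rows2.append(
            {
                "parameter": param,
                "n": len(pair),
                "mean_3d": pair[(param, "3d")].mean(),
                "mean_xray": pair[(param, "xray")].mean(),
                "t_value": cmp_.statistic,
                "p_value": cmp_.p_value,
            }
        )
    table2 = pd.DataFrame(rows2)

    w3 = main[main["modality"] == "3d"].pivot_table(
        index="subject_id", columns="parameter", values="value"
    )
    present = [p for p in _PARAM_ORDER if p in w3.columns]
    r_mat = pd.DataFrame(np.eye(len(present)), index=present, columns=present)
    p_mat = pd.DataFrame(np.zeros((len(present), len(present))), index=present, columns=present)
    for i, a in enumerate(present):
        for j, b in enumerate(present):
            if j <= i:
                continue
            r, p = pearson_r(w3[a].to_numpy(), w3[b].to_numpy())
            r_mat.loc[a, b] = r_mat.loc[b, a] = r
            p_mat.loc[a, b] = p_mat.loc[b, a] = p

    icc_rows = []
    for modality in ("3d", "xray"):
        for param in _PARAM_ORDER:
            sub = cohort[
                (cohort["modality"] == modality) & (cohort["parameter"] == param)
            ]
            if sub.empty:
                continue
            intra = sub[sub["rater"] == 1].pivot_table(
                index="subject_id", columns="session", values="value"
            ).dropna()
            inter = sub[sub["session"] == 1].pivot_table(
                index="subject_id", columns="rater", values="value"
            ).dropna()
            for design, tab in (("intra", intra), ("inter", inter)):
                if tab.shape[1] < 2 or tab.shape[0] < 5:
                    continue
                res = icc_two_way(tab.to_numpy(), design=design)
                icc_rows.append(
                    {
                        "modality": modality,
                        "parameter": param,
                        "design": design,
                        "icc": res.icc,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "n_subjects": res.n_subjects,
                        "n_raters": res.n_raters,
                    }
                )
    icc = pd.DataFrame(icc_rows)

    return {
        "table1": table1,
        "table2": table2,
        "table3_r": r_mat,
        "table3_p": p_mat,
        "icc": icc,
    }
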