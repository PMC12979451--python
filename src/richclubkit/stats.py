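"""Group inference and clinical statistics for connectome class metrics.

Covers: CTQ-based childhood-maltreatment classification, label-permutation
tests on group mean differences (with the add-one p estimator of Phipson &
Smyth so p is never zero), Benjamini-Hochberg FDR, partial correlation with
nuisance regression, and reconstruction of ANOVA / Tukey HSD / two-sample t /
chi-squared statistics from published group summaries (means, SDs, counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Childhood Trauma Questionnaire subscale cut-offs; meeting or exceeding any
#: one classifies a subject as maltreatment-exposed (CM).
CTQ_CUTOFFS: dict[str, int] = {"EA": 13, "PA": 10, "SA": 8, "EN": 15, "PN": 10}


@dataclass(frozen=True)
class PermutationResult:
    observed_diff: float
    p_value: float
    n_perm: int
    seed: int
    group_pair: tuple[str, str] = ("a", "b")
    metric_name: str = ""


def classify_ctq(scores: Mapping[str, float]) -> str:
    """CM if any CTQ subscale meets or exceeds its cut-off, else nCM.

    ``scores`` must provide all five subscales (EA, PA, SA, EN, PN); the
    boundary is inclusive (EA = 13 alone is CM).
    """
    missing = [k for k in CTQ_CUTOFFS if k not in scores or scores[k] is None]
    if missing:
        raise ValueError(f"missing CTQ subscale(s): {missing}")
    return "CM" if any(scores[k] >= cut for k, cut in CTQ_CUTOFFS.items()) else "nCM"


def permutation_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perm: int = 10000,
    seed: int = 0,
    statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
    group_pair: tuple[str, str] = ("a", "b"),
    metric_name: str = "",
) -> PermutationResult:
    """Two-sided label-permutation test on the difference of group means.

    The default statistic is |mean(a) - mean(b)|; any pluggable statistic
    computed on the two relabeled samples may be supplied. The p value uses
    the add-one estimator p = (1 + #{perm >= observed}) / (n_perm + 1), so
    p in [1/(n_perm+1), 1]. Deterministic given ``seed``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n_a, n_b = a.size, b.size
    count = 0
    if statistic is None:
        observed = abs(float(np.mean(a)) - float(np.mean(b)))
        total = pooled.sum()
        # vectorized row-wise permutations, chunked to bound memory
        chunk = max(1, 2_000_000 // pooled.size)
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            idx = rng.random((m, pooled.size)).argsort(axis=1)
            sums_a = pooled[idx[:, :n_a]].sum(axis=1)
            stat = np.abs(sums_a / n_a - (total - sums_a) / n_b)
            count += int((stat >= observed - 1e-12).sum())
            done += m
    else:
        observed = statistic(a, b)
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if statistic(perm[:n_a], perm[n_a:]) >= observed:
                count += 1
    p = (1 + count) / (n_perm + 1)
    signed = float(np.mean(a)) - float(np.mean(b))
    return PermutationResult(signed, p, n_perm, seed, group_pair, metric_name)


def fdr_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        bad = p[(p < 0) | (p > 1)][0]
        raise ValueError(f"p value outside [0, 1]: {bad}")
    return multipletests(p, method="fdr_bh")[1]


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Correlation of x and y after regressing nuisance covariates out of both.

    Each variable is residualized on [intercept | covariates] by least
    squares; r is the Pearson correlation of the residuals and p comes from
    the t distribution with n - 2 - n_covariates degrees of freedom
    (two-sided). Collinear covariate columns raise an error naming the column.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    names: list[str] = []
    if covariates is None:
        cov = np.empty((n, 0))
    elif isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        cov = covariates.to_numpy(dtype=float)
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        names = [f"cov{i}" for i in range(cov.shape[1])]
    # constant columns are absorbed by the intercept
    keep = [j for j in range(cov.shape[1]) if np.ptp(cov[:, j]) > 0]
    cov = cov[:, keep]
    names = [names[j] for j in keep]
    design = np.column_stack([np.ones(n), cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        for j in range(1, design.shape[1]):
            sub = design[:, list(range(j)) + [j]]
            if np.linalg.matrix_rank(sub) < np.linalg.matrix_rank(design[:, :j]) + 1:
                raise ValueError(f"covariate column {names[j - 1]!r} is collinear")
        raise ValueError("covariate matrix rank-deficient")
    n_effective_cov = design.shape[1] - 1
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    # a variable fully explained by the covariates has only numerical noise
    # left; its partial correlation is 0 by definition
    for res, orig in ((rx, x), (ry, y)):
        scale = max((orig**2).sum(), 1.0)
        if (res**2).sum() <= 1e-20 * scale:
            return 0.0, 1.0
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return 0.0, 1.0
    r = float((rx * ry).sum() / denom)
    r = max(-1.0, min(1.0, r))
    df = n - 2 - n_effective_cov
    if df <= 0:
        raise ValueError(f"not enough samples: df = {df}")
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), df)
    return r, float(p)


def _check_summary(means, sds, ns, min_groups: int = 2):
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if not (means.size == sds.size == ns.size):
        raise ValueError("means, sds, ns must have equal length")
    if means.size < min_groups:
        raise ValueError(f"need at least {min_groups} groups, got {means.size}")
    if (ns < 2).any():
        raise ValueError(f"every group needs n >= 2, got {ns.tolist()}")
    return means, sds, ns


def anova_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> tuple[float, float]:
    """One-way ANOVA F (and p) reconstructed from per-group mean, SD, n.

    Uses SSB = sum n_i (m_i - grand mean)^2 and SSW = sum (n_i - 1) s_i^2,
    which equals the raw-data F exactly when the summaries are exact.
    """
    means, sds, ns = _check_summary(means, sds, ns)
    g, n_total = means.size, int(ns.sum())
    grand = float((ns * means).sum() / n_total)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    if ssw == 0:
        return (float("inf") if ssb > 0 else 0.0), (0.0 if ssb > 0 else 1.0)
    f = (ssb / (g - 1)) / (ssw / (n_total - g))
    p = float(sps.f.sf(f, g - 1, n_total - g))
    return f, p


def two_sample_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance two-sample Student t (and two-sided p) from summaries;
    the sign follows m1 - m2. Zero pooled variance with unequal means returns
    a signed infinite t."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if pooled_var == 0:
        if m1 == m2:
            return 0.0, 1.0
        return float(np.sign(m1 - m2)) * float("inf"), 0.0
    t = (m1 - m2) / np.sqrt(pooled_var * (1 / n1 + 1 / n2))
    return float(t), float(2 * sps.t.sf(abs(t), df))


def chi_squared_independence(counts: np.ndarray | Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-squared statistic (and p) without continuity correction,
    df = (rows-1)(cols-1). Zero row/column marginals are rejected."""
    table = np.asarray(counts, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def tukey_hsd_from_summary(
    means: Sequence[float],
    sds: Sequence[float],
    ns: Sequence[int],
    group_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons from group summaries.

    Uses the pooled within-group variance from the summary ANOVA and the
    studentized range distribution; for unequal group sizes the
    Tukey-Kramer harmonic form of the standard error is used.
    """
    means, sds, ns = _check_summary(means, sds, ns, min_groups=3)
    g, n_total = means.size, int(ns.sum())
    if group_names is None:
        group_names = [f"g{i}" for i in range(g)]
    df_within = n_total - g
    msw = float(((ns - 1) * sds**2).sum()) / df_within
    rows = []
    for i in range(g):
        for j in range(i + 1, g):
            diff = float(means[i] - means[j])
            se = np.sqrt(msw / 2 * (1 / ns[i] + 1 / ns[j]))
            if se == 0:
                q = float("inf") if diff != 0 else 0.0
            else:
                q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, g, df_within)) if np.isfinite(q) else 0.0
            rows.append(
                {
                    "group_a": group_names[i],
                    "group_b": group_names[j],
                    "mean_diff": diff,
                    "q": q,
                    "p_adj": min(p, 1.0),
                }
            )
    return pd.DataFrame(rows)


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-subject phenotype table and derive the 4-level group.

    Required columns: subject_id, diagnosis (MDD/HC), age, sex (F/M),
    education, CTQ, EA, PA, SA, EN, PN; HAMD/HAMA may be NaN for controls.
    The maltreatment label is derived from the CTQ subscales via
    :func:`classify_ctq` and the combined group column is added.
    """
    required = ["subject_id", "diagnosis", "age", "sex", "education",
                "CTQ", "EA", "PA", "SA", "EN", "PN"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {missing}")
    bad_dx = set(table["diagnosis"]) - {"MDD", "HC"}
    if bad_dx:
        raise ValueError(f"unknown diagnosis value(s): {sorted(bad_dx)}")
    bad_sex = set(table["sex"]) - {"F", "M"}
    if bad_sex:
        raise ValueError(f"unknown sex value(s): {sorted(bad_sex)}")
    subscales = table[list(CTQ_CUTOFFS)]
    if (subscales.lt(5)).any().any():
        raise ValueError("CTQ subscales are scored 5-25; found value below 5")
    if (table["CTQ"] + 1e-9 < subscales.max(axis=1)).any():
        raise ValueError("CTQ total below one of its subscales")
    out = table.copy()
    out["maltreatment"] = [
        classify_ctq(row) for row in subscales.to_dict("records")
    ]
    out["group"] = out["diagnosis"] + "-" + out["maltreatment"]
    return out
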