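"""Differential-abundance statistics.

Covers the whole statistical layer of the benchmark: prevalence filtering,
Benjamini-Hochberg FDR, median-of-ratios size factors, a negative-binomial
Wald test for case/control differences in function counts, the
minimum-imputation + log + t-test route for measured (and regression-
predicted) metabolite intensities, and the Wilcoxon rank-sum route for signed
community-metabolic-potential matrices.

The count test is a deliberately transparent stand-in for DESeq2: size
factors by median-of-ratios, per-feature method-of-moments dispersion (no
shrinkage, no independent filtering), and a Wald test on the group
coefficient of a log-link NB GLM fitted by IRLS.  Genuine DESeq2 output can
be consumed instead via :func:`import_differential`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable

__all__ = [
    "Thresholds",
    "prevalence_filter",
    "bh_adjust",
    "size_factors",
    "nb_wald_diff_functions",
    "import_differential",
    "diff_metabolites_ttest",
    "diff_metabolites_ranksum",
    "significant_features",
]

#: tolerance below which a community-metabolic-potential score counts as absent
PRESENCE_EPS = 1e-12

DIFF_COLUMNS = ["log2fc", "stat", "pvalue", "padj", "significant"]


@dataclass
class Thresholds:
    """All cutoffs of the benchmark, serialized with every run for provenance.

    ``alpha_fdr`` — BH-adjusted p cutoff for every differential test (0.2);
    ``prevalence_functions`` / ``prevalence_metabolites`` — fraction of
    samples a feature must be detected in (5%); ``ml_prevalence`` /
    ``ml_mean_relabund`` — training filters for the regression pipeline
    (10% prevalence, 0.01% mean relative abundance, strict inequalities);
    ``n_null`` — permutation-null replicates (99); ``min_model_size`` —
    regression models with fewer selected predictors are dropped (2);
    ``n_procrustes_perm`` — sample-label permutations for the Procrustes
    significance test.
    """

    alpha_fdr: float = 0.2
    prevalence_functions: float = 0.05
    prevalence_metabolites: float = 0.05
    ml_prevalence: float = 0.10
    ml_mean_relabund: float = 0.0001
    n_null: int = 99
    min_model_size: int = 2
    n_procrustes_perm: int = 999

    def __post_init__(self) -> None:
        for name in ("alpha_fdr", "prevalence_functions", "prevalence_metabolites",
                     "ml_prevalence", "ml_mean_relabund"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_null < 1 or self.n_procrustes_perm < 1 or self.min_model_size < 1:
            raise ValueError("counts must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def prevalence_filter(table: AbundanceTable, min_frac: float) -> AbundanceTable:
    """Keep features detected in at least ``min_frac`` of samples.

    "Detected in fewer than ``min_frac``" features are removed, so a feature
    detected in *exactly* the threshold fraction is retained.  Detection is
    ``|value| > 1e-12``, which makes the same rule work for signed
    community-metabolic-potential matrices.
    """
    detected = (table.data.abs() > PRESENCE_EPS).mean(axis=1)
    keep = detected[detected >= min_frac].index
    return table.subset_features(keep)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def size_factors(counts: AbundanceTable | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Per-feature geometric means are computed over features nonzero in every
    sample; each sample's factor is the median of its ratios to those means.
    """
    df = counts.data if isinstance(counts, AbundanceTable) else counts
    all_nonzero = (df > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no feature is nonzero in every sample; add a pseudocount or "
            "filter samples before computing size factors"
        )
    sub = df.loc[all_nonzero]
    gm = np.exp(np.log(sub).mean(axis=1))
    ratios = sub.div(gm, axis=0)
    factors = ratios.median(axis=0)
    return factors / np.exp(np.log(factors).mean())  # geometric mean 1


# ---------------------------------------------------------------------------
# negative-binomial Wald test
# ---------------------------------------------------------------------------

_MU_FLOOR = 0.125  # smallest fitted group mean on the normalized-count scale
_ETA_CAP = 30.0


def _mom_dispersion(q: np.ndarray, case: np.ndarray, inv_s: np.ndarray) -> np.ndarray:
    """Pooled method-of-moments NB dispersion per feature.

    ``q`` are size-factor-normalized counts (features x samples).  Within each
    group, Var(q) ~= mu * mean(1/s) + alpha * mu^2; residual variances are
    pooled across the two groups.
    """
    alphas_num = np.zeros(q.shape[0])
    alphas_den = np.zeros(q.shape[0])
    for mask in (case, ~case):
        n = mask.sum()
        if n < 2:
            continue
        sub = q[:, mask]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        c = inv_s[mask].mean()
        alphas_num += (n - 1) * (var - mu * c)
        alphas_den += (n - 1) * mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(alphas_den > 0, alphas_num / alphas_den, 0.0)
    return np.clip(alpha, 1e-8, 10.0)


def _nb_irls(
    k: np.ndarray, s: np.ndarray, case: np.ndarray, alpha: np.ndarray,
    max_iter: int = 60, tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for a log-link NB GLM with design [1, case] and
    offset log(s), one independent fit per feature.

    Returns (b0, b1, se_b1).  Group means are floored at ``_MU_FLOOR``
    normalized counts so all-zero groups keep a finite, testable coefficient.
    """
    n_feat = k.shape[0]
    log_s = np.log(s)
    g = case.astype(float)

    # moment initialisation from group means of normalized counts
    q = k / s
    mu_ctrl = np.maximum(q[:, ~case].mean(axis=1), _MU_FLOOR)
    mu_case = np.maximum(q[:, case].mean(axis=1), _MU_FLOOR)
    b0 = np.log(mu_ctrl)
    b1 = np.log(mu_case) - np.log(mu_ctrl)

    lo, hi = np.log(_MU_FLOOR), _ETA_CAP
    for _ in range(max_iter):
        eta0 = np.clip(b0, lo, hi)
        eta1 = np.clip(b0 + b1, lo, hi)
        eta = eta0[:, None] + (eta1 - eta0)[:, None] * g[None, :] + log_s[None, :]
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - log_s[None, :]) + (k - mu) / mu
        # 2x2 weighted normal equations per feature
        sw = w.sum(axis=1)
        swg = (w * g).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swgz = (w * g * z).sum(axis=1)
        det = sw * swg - swg**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        new_b0 = (swg * swz - swg * swgz) / det
        new_b1 = (sw * swgz - swg * swz) / det
        new_b0 = np.clip(new_b0, lo, hi)
        new_b1 = np.clip(new_b1, lo - hi, hi - lo)
        new_b1 = np.clip(new_b0 + new_b1, lo, hi) - new_b0
        delta = np.nanmax(np.abs(new_b0 - b0) + np.abs(new_b1 - b1))
        b0, b1 = new_b0, new_b1
        if delta < tol:
            break

    eta = b0[:, None] + b1[:, None] * g[None, :] + log_s[None, :]
    mu = np.exp(np.clip(eta, -_ETA_CAP, _ETA_CAP))
    w = mu / (1.0 + alpha[:, None] * mu)
    sw = w.sum(axis=1)
    swg = (w * g).sum(axis=1)
    det = sw * swg - swg**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = np.where(det > 0, sw / det, np.inf)
    return b0, b1, np.sqrt(var_b1)


def nb_wald_diff_functions(
    counts: AbundanceTable,
    groups: pd.Series | None = None,
    alpha: float = 0.2,
    case: str | None = None,
    control: str | None = None,
) -> pd.DataFrame:
    """Per-function NB Wald test of case vs. control on raw counts.

    Counts are normalized by median-of-ratios size factors (entering the GLM
    as an offset), dispersion is estimated per feature by pooled method of
    moments, and the group coefficient is tested with a two-sided normal
    Wald statistic followed by BH adjustment.  ``groups`` maps sample ->
    label; by default the table's ``group`` metadata with labels ``case`` /
    ``control`` is used.  Positive ``log2fc`` means enriched in cases.
    """
    if groups is None:
        if case is None or control is None:
            raise ValueError("pass `groups` or case/control labels")
        groups = counts.groups(case, control)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    case_label = case if case is not None else labels[0]
    sub = counts.subset_samples(list(groups.index))
    is_case = (groups.loc[sub.samples] == case_label).to_numpy()
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("each group needs at least two samples")

    k = sub.data.to_numpy(dtype=float)
    try:
        s = size_factors(sub).to_numpy()
    except ValueError:
        warnings.warn(
            "no all-nonzero feature; size factors computed with a 0.5 "
            "pseudocount",
            stacklevel=2,
        )
        s = size_factors(sub.data + 0.5).to_numpy()

    disp = _mom_dispersion(k / s, is_case, 1.0 / s)
    _, b1, se = _nb_irls(k, s, is_case, disp)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, b1 / se, 0.0)
    z = np.where(np.isfinite(z), z, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    padj = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "log2fc": b1 / np.log(2.0),
            "stat": z,
            "pvalue": pvals,
            "padj": padj,
            "significant": padj <= alpha,
        },
        index=sub.data.index,
    )


def import_differential(results_file: str | Path, alpha: float = 0.2) -> set[str]:
    """Differential function IDs from an external results TSV.

    Expects columns ``feature_id`` and ``padj`` (case-insensitive); rows with
    ``padj <= alpha`` are returned.  This is the fidelity path for consuming
    genuine DESeq2 output in place of the built-in count test.
    """
    df = pd.read_csv(Path(results_file), sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "feature_id" not in cols or "padj" not in cols:
        raise ValueError(
            "expected header with 'feature_id' and 'padj' columns, got "
            f"{list(df.columns)}"
        )
    padj = pd.to_numeric(df[cols["padj"]], errors="coerce")
    return set(df.loc[padj <= alpha, cols["feature_id"]].astype(str))


def _resolve_groups(
    table: AbundanceTable, groups: pd.Series | None, case: str | None, control: str | None
) -> tuple[AbundanceTable, np.ndarray]:
    if groups is None:
        if case is None or control is None:
            raise ValueError("pass `groups` or case/control labels")
        groups = table.groups(case, control)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    case_label = case if case is not None else labels[0]
    sub = table.subset_samples(list(groups.index))
    is_case = (groups.loc[sub.samples] == case_label).to_numpy()
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("each group needs at least two samples")
    return sub, is_case


def diff_metabolites_ttest(
    metab: AbundanceTable,
    groups: pd.Series | None = None,
    alpha: float = 0.2,
    case: str | None = None,
    control: str | None = None,
) -> pd.DataFrame:
    """Differential metabolites by minimum-imputation + log + Student's t.

    Zeros are imputed with each metabolite's minimum nonzero value across
    *all* samples, intensities are natural-log transformed, and a two-sided
    pooled-variance t-test compares case vs. control, followed by BH
    adjustment.  All-zero metabolites are excluded with a warning (they have
    no minimum nonzero value).  ``log2fc`` is the case-minus-control mean
    log-intensity difference expressed in log2 units.
    """
    sub, is_case = _resolve_groups(metab, groups, case, control)
    values = sub.data.to_numpy(dtype=float)
    nonzero_min = np.where(values > 0, values, np.inf).min(axis=1)
    all_zero = ~np.isfinite(nonzero_min)
    if all_zero.any():
        warnings.warn(
            f"{all_zero.sum()} all-zero metabolites excluded from the t-test",
            stacklevel=2,
        )
    values = values[~all_zero]
    nonzero_min = nonzero_min[~all_zero]
    index = sub.data.index[~all_zero]

    imputed = np.where(values > 0, values, nonzero_min[:, None])
    logged = np.log(imputed)
    a, b = logged[:, is_case], logged[:, ~is_case]
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    constant = np.isnan(t)
    t = np.where(constant, 0.0, t)
    p = np.where(constant, 1.0, p)
    padj = bh_adjust(p)
    return pd.DataFrame(
        {
            "log2fc": (a.mean(axis=1) - b.mean(axis=1)) / np.log(2.0),
            "stat": t,
            "pvalue": p,
            "padj": padj,
            "significant": padj <= alpha,
        },
        index=index,
    )


def diff_metabolites_ranksum(
    pred: AbundanceTable,
    groups: pd.Series | None = None,
    alpha: float = 0.2,
    case: str | None = None,
    control: str | None = None,
) -> pd.DataFrame:
    """Differential compounds in a signed score matrix by Wilcoxon rank-sum.

    Community-metabolic-potential matrices mix positive and negative values,
    so the distribution-free two-sided rank-sum test replaces the t-test:
    exact when the combined sample count is <= 20 and the data are tie-free,
    otherwise the normal approximation with tie correction.  ``log2fc`` here
    holds the case-minus-control *median difference* (a signed score has no
    fold change).
    """
    sub, is_case = _resolve_groups(pred, groups, case, control)
    values = sub.data.to_numpy(dtype=float)
    a, b = values[:, is_case], values[:, ~is_case]
    n = values.shape[1]
    stat_out = np.empty(values.shape[0])
    p_out = np.empty(values.shape[0])
    for i in range(values.shape[0]):
        row_a, row_b = a[i], b[i]
        if np.ptp(values[i]) == 0:  # every value tied
            stat_out[i], p_out[i] = 0.0, 1.0
            continue
        has_ties = len(np.unique(values[i])) < n
        method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(row_a, row_b, alternative="two-sided", method=method)
        stat_out[i], p_out[i] = res.statistic, res.pvalue
    padj = bh_adjust(p_out)
    return pd.DataFrame(
        {
            "log2fc": np.median(a, axis=1) - np.median(b, axis=1),
            "stat": stat_out,
            "pvalue": p_out,
            "padj": np.minimum(padj, 1.0),
            "significant": padj <= alpha,
        },
        index=sub.data.index,
    )


def significant_features(diff: pd.DataFrame) -> set[str]:
    """Feature IDs flagged significant in a differential table."""
    return set(diff.index[diff["significant"]])


def write_diff_table(diff: pd.DataFrame, path: str | Path) -> None:
    out = diff.copy()
    out.index.name = "feature"
    out.to_csv(Path(path), sep="\t")
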