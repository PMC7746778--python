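"""Scoring predicted metabolomes against measured ones.

Occurrence is scored as set overlap (precision/recall/F1) after 5%
prevalence filtering of both sides; abundance similarity by Procrustes
superimposition of the two sample ordinations (Euclidean distance ->
principal coordinates -> least-squares fit, reporting the m12^2 residual);
differential-metabolite identification by P/R/F1 of the predicted vs.
measured differential sets.  Two permutation nulls calibrate the scores: a
random draw from the chemical dictionary for occurrence, and label-shuffling
(gene labels for linkage-based prediction, predicted-metabolite labels for
abundance-based prediction) for the differential comparison, 99 replicates
each with the add-one empirical p-value convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import procrustes as _procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa

from .diffstats import (
    Thresholds,
    diff_metabolites_ranksum,
    diff_metabolites_ttest,
    nb_wald_diff_functions,
    prevalence_filter,
    significant_features,
)
from .predict import mangosteen_differential
from .reference import ReferenceMap
from .tables import AbundanceTable

__all__ = [
    "EvalMetrics",
    "ProcrustesResult",
    "NullDistribution",
    "occurrence_from_abundance",
    "set_metrics",
    "procrustes_compare",
    "null_coverage",
    "null_differential",
    "compare_pipelines_signed_rank",
]


@dataclass
class EvalMetrics:
    """Precision/recall/F1 with the underlying confusion counts."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
        }


@dataclass
class ProcrustesResult:
    """Least-squares superimposition fit of two sample ordinations.

    ``m12_squared`` is the residual sum of squares after optimal
    translation/rotation/reflection/scaling of unit-normalized
    configurations (0 = identical shapes, near 1 = unrelated);
    ``correlation = sqrt(1 - m12_squared)``.
    """

    m12_squared: float
    p_value: float
    n_permutations: int

    @property
    def correlation(self) -> float:
        return float(np.sqrt(max(0.0, 1.0 - self.m12_squared)))

    def to_dict(self) -> dict:
        return {
            "m12_squared": self.m12_squared,
            "correlation": self.correlation,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
        }


@dataclass
class NullDistribution:
    """Permutation-null replicate values of a metric plus the observed value.

    Empirical p uses the add-one convention,
    ``(1 + #{replicates >= observed}) / (n_null + 1)``, so 99 replicates can
    never yield p = 0.
    """

    replicates: np.ndarray
    observed: float

    @property
    def n_null(self) -> int:
        return len(self.replicates)

    @property
    def empirical_p(self) -> float:
        return (1 + int(np.sum(self.replicates >= self.observed))) / (self.n_null + 1)

    def to_dict(self, include_replicates: bool = False) -> dict:
        out = {
            "observed": self.observed,
            "null_mean": float(np.mean(self.replicates)) if self.n_null else None,
            "n_null": self.n_null,
            "empirical_p": self.empirical_p,
        }
        if include_replicates:
            out["replicates"] = [float(v) for v in self.replicates]
        return out


def occurrence_from_abundance(
    table: AbundanceTable, min_frac: float = 0.05
) -> set[str]:
    """Compound occurrence set: features surviving the prevalence filter.

    Presence means ``|value| > 1e-12`` so signed community-metabolic-potential
    matrices are handled identically to intensity tables.
    """
    return set(prevalence_filter(table, min_frac).features)


def set_metrics(predicted: set[str], measured: set[str]) -> EvalMetrics:
    """Occurrence-style confusion metrics between two compound sets."""
    if not predicted and not measured:
        warnings.warn("both compound sets empty; metrics defined as 0", stacklevel=2)
    return EvalMetrics(
        tp=len(predicted & measured),
        fp=len(predicted - measured),
        fn=len(measured - predicted),
    )


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------

def _pcoa_coords(table: AbundanceTable, samples: list[str]) -> np.ndarray:
    """Sample coordinates from Euclidean distance -> principal coordinates.

    Only axes with positive eigenvalues are retained (negative-eigenvalue
    axes of a non-Euclidean correction carry no configuration information
    for a Euclidean input anyway).
    """
    points = table.data[samples].to_numpy(dtype=float).T
    dm = DistanceMatrix(squareform(pdist(points, metric="euclidean")), ids=samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ord_res = pcoa(dm, method="eigh")
    eig = ord_res.eigvals.to_numpy()
    keep = eig > max(eig.max(), 0) * 1e-10
    coords = ord_res.samples.to_numpy()[:, keep]
    if coords.shape[1] == 0:  # all samples coincide
        coords = np.zeros((len(samples), 1))
    return coords


def _pad_columns(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    width = max(a.shape[1], b.shape[1])
    pad = lambda m: np.hstack([m, np.zeros((m.shape[0], width - m.shape[1]))])
    return pad(a), pad(b)


def procrustes_m12sq(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric Procrustes residual m12^2 between two configurations."""
    x, y = _pad_columns(np.asarray(x, float), np.asarray(y, float))
    _, _, disparity = _procrustes(x, y)
    return float(disparity)


def procrustes_compare(
    pred: AbundanceTable,
    meas: AbundanceTable,
    n_perm: int = 999,
    seed: int | None = None,
) -> ProcrustesResult:
    """Procrustes comparison of predicted and measured sample configurations.

    Both matrices are restricted to their shared samples; each is turned into
    a sample ordination (Euclidean distance, then classical multidimensional
    scaling), and the ordinations are superimposed by least squares.
    Significance comes from permuting the sample labels of one configuration
    ``n_perm`` times, with empirical p on the fit statistic ``1 - m12^2``.
    """
    shared = [s for s in meas.samples if s in set(pred.samples)]
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared samples, got {len(shared)}")
    x = _pcoa_coords(pred, shared)
    y = _pcoa_coords(meas, shared)
    x, y = _pad_columns(x, y)
    m12sq = procrustes_m12sq(x, y)

    rng = np.random.default_rng(seed)
    observed_fit = 1.0 - m12sq
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(shared))
        if 1.0 - procrustes_m12sq(x, y[perm]) >= observed_fit:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return ProcrustesResult(m12_squared=m12sq, p_value=p, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# permutation nulls
# ---------------------------------------------------------------------------

def null_coverage(
    dictionary: set[str],
    k: int,
    measured: set[str],
    observed: EvalMetrics | None = None,
    n_null: int = 99,
    seed: int | None = None,
) -> dict[str, NullDistribution]:
    """Random-draw occurrence null: k compounds sampled from the dictionary.

    Each replicate draws ``k`` compounds uniformly without replacement from
    the chemical dictionary and scores them against the measured set.
    Returns one null distribution per metric; the observed pipeline metrics
    (when given) provide the empirical p.
    """
    if k > len(dictionary):
        raise ValueError(f"k={k} exceeds dictionary size {len(dictionary)}")
    rng = np.random.default_rng(seed)
    universe = np.asarray(sorted(dictionary))
    reps = {"precision": [], "recall": [], "f1": []}
    for _ in range(n_null):
        draw = set(rng.choice(universe, size=k, replace=False))
        m = set_metrics(draw, measured)
        reps["precision"].append(m.precision)
        reps["recall"].append(m.recall)
        reps["f1"].append(m.f1)
    obs = {
        "precision": observed.precision if observed else np.nan,
        "recall": observed.recall if observed else np.nan,
        "f1": observed.f1 if observed else np.nan,
    }
    return {
        name: NullDistribution(np.asarray(vals), obs[name])
        for name, vals in reps.items()
    }


def _relabel(table: AbundanceTable, rng: np.random.Generator) -> AbundanceTable:
    """Permute the feature-ID labels of a table's rows."""
    labels = np.asarray(table.features)
    return AbundanceTable(
        table.data.set_axis(rng.permutation(labels), axis=0), table.metadata
    )


def null_differential(
    mode: str,
    metab: AbundanceTable,
    groups: pd.Series,
    funcs: AbundanceTable | None = None,
    ref: ReferenceMap | None = None,
    pred: AbundanceTable | None = None,
    predicted_test: str = "ttest",
    thresholds: Thresholds | None = None,
    n_null: int = 99,
    seed: int | None = None,
) -> dict[str, NullDistribution]:
    """Label-shuffling null for differential-metabolite identification.

    ``mode="shuffle-genes"`` (linkage pipeline): permute the function-ID row
    labels of the function count table, rerun differential-function
    detection, map the flagged functions to compounds, and score against the
    measured differential set.  ``mode="shuffle-metabolites"`` (abundance
    pipelines): permute the compound-ID row labels of the predicted matrix
    and rerun the differential test (``predicted_test`` = ``"ttest"`` for
    regression output, ``"ranksum"`` for signed scores) and scoring.
    The unshuffled data give the observed metrics.
    """
    th = thresholds or Thresholds()
    if mode not in ("shuffle-genes", "shuffle-metabolites"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "shuffle-genes" and (funcs is None or ref is None):
        raise ValueError("shuffle-genes mode needs `funcs` and `ref`")
    if mode == "shuffle-metabolites" and pred is None:
        raise ValueError("shuffle-metabolites mode needs `pred`")
    if predicted_test not in ("ttest", "ranksum"):
        raise ValueError(f"unknown predicted_test {predicted_test!r}")

    measured_filtered = prevalence_filter(metab, th.prevalence_metabolites)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        measured_diff = significant_features(
            diff_metabolites_ttest(measured_filtered, groups, th.alpha_fdr)
        )

    def predicted_diff_set(table: AbundanceTable) -> set[str]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if mode == "shuffle-genes":
                filtered = prevalence_filter(table, th.prevalence_functions)
                diff = nb_wald_diff_functions(filtered, groups, th.alpha_fdr)
                return mangosteen_differential(significant_features(diff), ref)
            filtered = prevalence_filter(table, th.prevalence_metabolites)
            test = diff_metabolites_ttest if predicted_test == "ttest" else diff_metabolites_ranksum
            return significant_features(test(filtered, groups, th.alpha_fdr))

    source = funcs if mode == "shuffle-genes" else pred
    observed = set_metrics(predicted_diff_set(source), measured_diff)

    rng = np.random.default_rng(seed)
    reps = {"precision": [], "recall": [], "f1": []}
    for _ in range(n_null):
        m = set_metrics(predicted_diff_set(_relabel(source, rng)), measured_diff)
        reps["precision"].append(m.precision)
        reps["recall"].append(m.recall)
        reps["f1"].append(m.f1)
    obs = {"precision": observed.precision, "recall": observed.recall, "f1": observed.f1}
    out = {
        name: NullDistribution(np.asarray(vals), obs[name])
        for name, vals in reps.items()
    }
    out["observed_metrics"] = observed  # type: ignore[assignment]
    return out


def compare_pipelines_signed_rank(metric_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank p-values across pipelines.

    ``metric_table`` holds one metric (e.g. F1) as pipelines x datasets;
    missing pairs are dropped pairwise, zero differences are dropped per the
    classic convention, the distribution is exact for n <= 25, and a pair
    with fewer than two nonzero differences reports NaN.
    """
    pipelines = list(metric_table.index)
    out = pd.DataFrame(np.nan, index=pipelines, columns=pipelines, dtype=float)
    for i, a in enumerate(pipelines):
        for b in pipelines[i + 1:]:
            paired = metric_table.loc[[a, b]].dropna(axis=1)
            diffs = (paired.loc[a] - paired.loc[b]).to_numpy(dtype=float)
            nonzero = diffs[diffs != 0]
            if len(nonzero) < 2:
                continue
            res = stats.wilcoxon(nonzero, zero_method="wilcox", mode="auto")
            out.loc[a, b] = out.loc[b, a] = res.pvalue
    return out
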