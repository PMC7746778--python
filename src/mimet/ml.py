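"""Elastic-net metabolome regression from microbial function profiles.

One regularized linear model per metabolite maps community function relative
abundances to metabolite relative abundances, after arcsine-square-root
variance stabilization of both sides.  Sparse models with a single selected
predictor are pruned (a lone KO "predicting" a metabolite is usually a
spurious association), and cross-study generalization is measured by
leave-one-study-out validation: each study is held out in turn, the model is
trained on the rest, and the held-out metabolome is predicted on the
original relative-abundance scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .tables import AbundanceTable

__all__ = [
    "ElasticNetMetabolomeRegressor",
    "ModelSet",
    "filter_training_features",
    "transform_relative_abundance",
    "inverse_transform_relative_abundance",
    "fit_models",
    "prune_models",
    "predict_metabolome",
    "loso_predict",
]

#: elastic-net mixing grid searched by internal cross-validation
DEFAULT_L1_RATIOS = (0.1, 0.5, 0.7, 0.9, 0.95, 1.0)


def filter_training_features(
    metab: AbundanceTable,
    funcs: AbundanceTable,
    prevalence_min: float = 0.10,
    mean_relabund_min: float = 0.0001,
) -> tuple[AbundanceTable, AbundanceTable]:
    """Training filters: prevalence and mean relative abundance.

    Both tables are first converted to per-sample relative abundance and
    restricted to their shared samples; a feature survives iff it is present
    (>0) in strictly more than ``prevalence_min`` of samples *and* its mean
    relative abundance is strictly greater than ``mean_relabund_min``.
    Returns the filtered (metabolites, functions) relative-abundance tables.
    """
    shared = [s for s in metab.samples if s in set(funcs.samples)]
    if not shared:
        raise ValueError("metabolite and function tables share no samples")

    out = []
    for table in (metab, funcs):
        rel = table.subset_samples(shared).relative_abundance()
        prevalence = (rel.data > 0).mean(axis=1)
        mean_ra = rel.data.mean(axis=1)
        keep = rel.data.index[(prevalence > prevalence_min) & (mean_ra > mean_relabund_min)]
        out.append(rel.subset_features(keep))
    return out[0], out[1]


def transform_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Arcsine-square-root variance stabilization, elementwise arcsin(sqrt(x))."""
    values = table.data.to_numpy(dtype=float)
    if values.size and (values.min() < 0 or values.max() > 1):
        raise ValueError("relative abundances must lie in [0, 1]")
    return AbundanceTable(np.arcsin(np.sqrt(table.data)), table.metadata)


def inverse_transform_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Inverse of the arcsine-square-root transform, sin(y)^2.

    Predictions below 0 (which would back-transform to spurious positives)
    are clipped to 0, and values beyond pi/2 to the transform's range cap.
    """
    clipped = table.data.clip(lower=0.0, upper=np.pi / 2)
    return AbundanceTable(np.sin(clipped) ** 2, table.metadata)


@dataclass
class ModelSet:
    """Fitted per-metabolite models: a sparse weight table plus provenance.

    ``coefficients`` is metabolites x functions (zeros = not selected);
    ``model_size`` counts nonzero coefficients per metabolite.
    """

    coefficients: pd.DataFrame
    intercepts: pd.Series
    training_studies: list[str] = field(default_factory=list)
    seed: int | None = None

    @property
    def model_size(self) -> pd.Series:
        return (self.coefficients != 0).sum(axis=1)

    @property
    def metabolites(self) -> list[str]:
        return list(self.coefficients.index)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "functions": list(self.coefficients.columns),
            "metabolites": list(self.coefficients.index),
            "coefficients": [
                self.coefficients.loc[m].to_list() for m in self.coefficients.index
            ],
            "intercepts": [float(self.intercepts.loc[m]) for m in self.coefficients.index],
            "training_studies": self.training_studies,
            "seed": self.seed,
        }
        text = json.dumps(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelSet":
        text = str(source)
        if isinstance(source, Path) or not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        doc = json.loads(text)
        coef = pd.DataFrame(
            doc["coefficients"], index=doc["metabolites"], columns=doc["functions"],
            dtype=float,
        )
        return cls(
            coefficients=coef,
            intercepts=pd.Series(doc["intercepts"], index=coef.index, dtype=float),
            training_studies=list(doc["training_studies"]),
            seed=doc["seed"],
        )


class ElasticNetMetabolomeRegressor(BaseEstimator, RegressorMixin):
    """Per-metabolite elastic net with internal cross-validated penalties.

    Works on samples x features frames (sklearn orientation): ``X`` holds
    arcsine-sqrt-transformed function relative abundances, ``Y`` the
    equally transformed metabolite relative abundances.  One independent
    ``ElasticNetCV`` is fitted per metabolite column — models are
    embarrassingly parallel and their results do not depend on fit order.

    Parameters
    ----------
    l1_ratios : sequence of float
        Mixing grid searched by internal CV (1.0 = lasso).
    cv : int
        Internal cross-validation folds for the penalty strength.
    n_alphas : int
        Length of the regularization path per l1_ratio.
    min_model_size : int
        Metabolites whose fitted model selects fewer functions are dropped
        by :meth:`prune` (size-1 models are considered spurious).
    random_state : int or None
        Seeds the CV fold shuffling; fixing it makes fits bit-reproducible.

    Attributes
    ----------
    coef_ : DataFrame, metabolites x functions, after :meth:`fit`.
    intercept_ : Series per metabolite.
    model_size_ : Series of nonzero-coefficient counts.
    skipped_ : list of constant metabolites that could not be modelled.
    """

    def __init__(
        self,
        l1_ratios: tuple[float, ...] = DEFAULT_L1_RATIOS,
        cv: int = 5,
        n_alphas: int = 30,
        min_model_size: int = 2,
        random_state: int | None = None,
    ):
        self.l1_ratios = l1_ratios
        self.cv = cv
        self.n_alphas = n_alphas
        self.min_model_size = min_model_size
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, Y: pd.DataFrame):  # noqa: N803 - sklearn API
        X = pd.DataFrame(X)
        Y = pd.DataFrame(Y)
        if len(X) != len(Y):
            raise ValueError("X and Y must have the same samples")
        if len(X) < 10:
            raise ValueError(f"need >= 10 samples to fit, got {len(X)}")
        x = X.to_numpy(dtype=float)
        coef = {}
        intercepts = {}
        self.skipped_: list[str] = []
        for metabolite in Y.columns:
            y = Y[metabolite].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                self.skipped_.append(metabolite)
                continue
            folds = KFold(
                n_splits=self.cv, shuffle=True, random_state=self.random_state
            )
            model = ElasticNetCV(
                l1_ratio=list(self.l1_ratios),
                alphas=self.n_alphas,  # int = length of the generated path
                cv=folds,
                max_iter=5000,
                random_state=self.random_state,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # convergence chatter on tiny folds
                model.fit(x, y)
            coef[metabolite] = model.coef_
            intercepts[metabolite] = model.intercept_
        if self.skipped_:
            warnings.warn(
                f"{len(self.skipped_)} constant metabolites skipped", stacklevel=2
            )
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        self.coef_ = pd.DataFrame.from_dict(
            coef, orient="index", columns=list(X.columns), dtype=float
        )
        self.intercept_ = pd.Series(intercepts, dtype=float)
        self.model_size_ = (self.coef_ != 0).sum(axis=1)
        return self

    def prune(self) -> "ElasticNetMetabolomeRegressor":
        """Drop fitted models smaller than ``min_model_size`` (in place)."""
        keep = self.model_size_[self.model_size_ >= self.min_model_size].index
        self.coef_ = self.coef_.loc[keep]
        self.intercept_ = self.intercept_.loc[keep]
        self.model_size_ = self.model_size_.loc[keep]
        return self

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:  # noqa: N803
        """Predicted transformed metabolite abundances, samples x metabolites.

        Functions unseen at training time are ignored; trained functions
        absent from ``X`` contribute zero.
        """
        X = pd.DataFrame(X)
        aligned = X.reindex(columns=self.coef_.columns, fill_value=0.0)
        pred = aligned.to_numpy(dtype=float) @ self.coef_.to_numpy().T
        pred += self.intercept_.to_numpy()[None, :]
        return pd.DataFrame(pred, index=X.index, columns=self.coef_.index)

    def to_model_set(self, training_studies: list[str] | None = None) -> ModelSet:
        return ModelSet(
            coefficients=self.coef_.copy(),
            intercepts=self.intercept_.copy(),
            training_studies=list(training_studies or []),
            seed=self.random_state,
        )


def fit_models(
    metab: AbundanceTable,
    funcs: AbundanceTable,
    seed: int | None = None,
    **estimator_kwargs,
) -> ModelSet:
    """Fit per-metabolite elastic nets on filtered + transformed tables."""
    est = ElasticNetMetabolomeRegressor(random_state=seed, **estimator_kwargs)
    est.fit(funcs.data.T, metab.data.T)
    return est.to_model_set()


def prune_models(models: ModelSet, min_size: int = 2) -> ModelSet:
    """Drop every model with fewer than ``min_size`` selected functions."""
    keep = models.model_size[models.model_size >= min_size].index
    return ModelSet(
        coefficients=models.coefficients.loc[keep],
        intercepts=models.intercepts.loc[keep],
        training_studies=models.training_studies,
        seed=models.seed,
    )


def predict_metabolome(models: ModelSet, funcs: AbundanceTable) -> AbundanceTable:
    """Predict a metabolome from a raw function table using fitted models.

    The function table is converted to relative abundance and arcsine-sqrt
    transformed, trained functions missing from it contribute zero, and the
    linear predictions are back-transformed to the relative-abundance scale
    (negatives clipped to zero).  Output is compounds x samples.
    """
    rel = funcs.relative_abundance()
    x = transform_relative_abundance(rel)
    aligned = x.data.reindex(models.coefficients.columns, fill_value=0.0)
    pred = models.coefficients.to_numpy() @ aligned.to_numpy()
    pred += models.intercepts.to_numpy()[:, None]
    pred_df = pd.DataFrame(pred, index=models.metabolites, columns=funcs.samples)
    return inverse_transform_relative_abundance(
        AbundanceTable(pred_df, funcs.metadata)
    )


def loso_predict(
    metab: AbundanceTable,
    funcs: AbundanceTable,
    seed: int | None = None,
    prevalence_min: float = 0.10,
    mean_relabund_min: float = 0.0001,
    min_model_size: int = 2,
    **estimator_kwargs,
) -> tuple[AbundanceTable, dict[str, ModelSet]]:
    """Leave-one-study-out prediction of the metabolome.

    For each study S: filter and transform the other studies' paired tables,
    fit, prune, then predict S's metabolome.  Every sample is predicted
    exactly once; compounds never modelled in a fold are reported as 0 for
    that fold's samples.  Returns the combined compounds x samples prediction
    table and the per-study ModelSets.
    """
    if funcs.metadata is None or "study" not in funcs.metadata:
        raise ValueError("function table needs `study` metadata")
    studies = list(pd.unique(funcs.metadata["study"]))
    if len(studies) < 2:
        raise ValueError(
            "leave-one-study-out needs >= 2 studies; use a plain train/test "
            "split for a single study"
        )

    per_fold: dict[str, ModelSet] = {}
    columns: dict[str, pd.Series] = {}
    for held_out in studies:
        test_samples = funcs.metadata.index[funcs.metadata["study"] == held_out]
        train_samples = [s for s in funcs.samples if s not in set(test_samples)]
        m_train = metab.subset_samples(train_samples)
        f_train = funcs.subset_samples(train_samples)
        m_filt, f_filt = filter_training_features(
            m_train, f_train, prevalence_min, mean_relabund_min
        )
        models = fit_models(
            transform_relative_abundance(m_filt),
            transform_relative_abundance(f_filt),
            seed=seed,
            min_model_size=min_model_size,
            **estimator_kwargs,
        )
        models = prune_models(models, min_model_size)
        models.training_studies = [s for s in studies if s != held_out]
        per_fold[held_out] = models
        pred = predict_metabolome(models, funcs.subset_samples(test_samples))
        for sample in pred.samples:
            columns[sample] = pred.data[sample]

    combined = pd.DataFrame(columns).fillna(0.0)
    combined = combined[[s for s in funcs.samples if s in combined.columns]]
    combined = combined.sort_index()
    return AbundanceTable(combined, funcs.metadata), per_fold
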