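"""Reference-based metabolite prediction.

Two strategies operate on the relationship graph:

* **Mangosteen-style linkage** — pure set prediction: every compound linked
  to an observed (or differential) function is reported, with no abundance
  attached.  If a function links to multiple metabolites, all are reported.
* **Community metabolic potential (CMP)** — a signed compounds x samples
  score matrix ``CMP[c, s] = sum_r coef(c, r) * sum_{f -> r} abundance(f, s)``
  computed from single-copy-marker-normalized gene abundances; positive means
  net predicted production, negative net consumption.  The CMP matrix serves
  as a predicted metabolome.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .reference import ReferenceMap, compounds_for_functions, reactions_for_function
from .tables import AbundanceTable

__all__ = [
    "mangosteen_occurrence",
    "mangosteen_differential",
    "single_copy_normalize",
    "compute_cmp",
    "CommunityMetabolicPotential",
]


def mangosteen_occurrence(table: AbundanceTable, ref: ReferenceMap) -> set[str]:
    """Compounds linked to any function observed in the table.

    A function counts as observed when its abundance is nonzero in at least
    one sample; the result is therefore presence-based — invariant to sample
    order and to any positive rescaling of the counts.
    """
    if table.shape[0] == 0 or table.shape[1] == 0:
        warnings.warn("empty abundance table: no compounds predicted", stacklevel=2)
        return set()
    observed = table.data.index[(table.data != 0).any(axis=1)]
    return compounds_for_functions(ref, observed)


def mangosteen_differential(diff_functions: Iterable[str], ref: ReferenceMap) -> set[str]:
    """Compounds linked to a set of differential functions.

    All compounds linked to any input function are reported as differential;
    no abundance or direction is attached.
    """
    return compounds_for_functions(ref, diff_functions)


def single_copy_normalize(table: AbundanceTable, markers: set[str]) -> AbundanceTable:
    """Normalize gene abundances by universal single-copy marker medians.

    Divides each sample's column by the median abundance of the marker genes
    in that sample, so abundances read as copies per genome (the inter-sample
    core of marker-based correction).  Postcondition: per-sample marker
    median is 1.
    """
    present = [m for m in markers if m in table.data.index]
    if not present:
        raise ValueError("no marker functions present in table")
    medians = table.data.loc[present].median(axis=0)
    zero = medians.index[medians <= 0]
    if len(zero):
        raise ValueError(
            f"zero marker median in sample(s) {list(zero)[:5]}; cannot normalize"
        )
    return AbundanceTable(table.data / medians, table.metadata)


def compute_cmp(
    table: AbundanceTable,
    ref: ReferenceMap,
    default_coefficient: float | None = 1.0,
) -> AbundanceTable:
    """Community-metabolic-potential matrix from normalized gene abundances.

    ``CMP[c, s] = sum_{r: c in r} coef(c, r) * sum_{f linked to r} abund(f, s)``

    Function -> reaction resolution follows the linkage rule of the
    relationship graph (direct annotations, EC route only as fallback);
    transporter edges carry no stoichiometry and do not contribute.  Compounds
    with no linked function in the table are omitted.  Edges lacking a
    stoichiometric coefficient use ``default_coefficient`` (with a warning);
    pass ``None`` to make missing coefficients an error instead.
    """
    # per-reaction summed abundance of the functions linked to it
    rxn_abund: dict[str, np.ndarray] = {}
    for f in table.data.index:
        for rxn in reactions_for_function(ref, f):
            if rxn not in ref.rxn_to_cpd:
                continue
            row = table.data.loc[f].to_numpy()
            if rxn in rxn_abund:
                rxn_abund[rxn] = rxn_abund[rxn] + row
            else:
                rxn_abund[rxn] = row.copy()

    n_missing = 0
    scores: dict[str, np.ndarray] = {}
    for rxn, abund in rxn_abund.items():
        for cpd, coef in ref.rxn_to_cpd[rxn].items():
            if coef is None:
                n_missing += 1
                if default_coefficient is None:
                    raise ValueError(
                        f"reaction {rxn} -> {cpd} has no stoichiometric "
                        "coefficient and no default policy was given"
                    )
                coef = default_coefficient
            if cpd in scores:
                scores[cpd] = scores[cpd] + coef * abund
            else:
                scores[cpd] = coef * abund
    if n_missing:
        warnings.warn(
            f"{n_missing} reaction->compound edges had no stoichiometric "
            f"coefficient; defaulted to {default_coefficient:+g}",
            stacklevel=2,
        )
    cmp_df = pd.DataFrame(scores, index=table.data.columns).T
    cmp_df = cmp_df.sort_index()
    return AbundanceTable(cmp_df, table.metadata)


class CommunityMetabolicPotential(BaseEstimator, TransformerMixin):
    """Transformer wrapping :func:`compute_cmp` (and optional marker
    normalization) so CMP scoring composes with sklearn pipelines.

    Parameters
    ----------
    ref : ReferenceMap
        Relationship graph with stoichiometric coefficients.
    markers : set of function IDs, optional
        Universal single-copy markers; when given, each sample is divided by
        its marker median before scoring.
    default_coefficient : float or None
        Coefficient for edges without stoichiometry (``None`` = error).
    """

    def __init__(
        self,
        ref: ReferenceMap,
        markers: set[str] | None = None,
        default_coefficient: float | None = 1.0,
    ):
        self.ref = ref
        self.markers = markers
        self.default_coefficient = default_coefficient

    def fit(self, X: AbundanceTable, y=None):  # noqa: N803 - sklearn API
        self.n_features_in_ = X.shape[0]
        return self

    def transform(self, X: AbundanceTable) -> AbundanceTable:  # noqa: N803
        table = X
        if self.markers:
            table = single_copy_normalize(table, self.markers)
        return compute_cmp(table, self.ref, self.default_coefficient)
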