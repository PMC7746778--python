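"""Synthetic references and paired cohorts with known ground truth.

Real paired microbiome-metabolome cohorts hang off licensed reference
databases and external sequence archives; everything here is generated from
scratch so the whole benchmark runs without downloads.  The generator
emulates the statistical structure the evaluation procedures assume:

* a random function -> reaction -> compound linkage graph with signed
  stoichiometry, an EC-only fallback subset, transporter links and
  never-linked decoy compounds in the dictionary;
* overdispersed (negative-binomial) function counts around lognormal
  baselines with per-sample library sizes and planted case/control fold
  changes;
* metabolite intensities as noisy linear mixes of the relative abundances of
  their linked functions, plus host-derived metabolites independent of the
  community, with a detection limit and a random untargeted-coverage panel
  censoring which compounds are "measured".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import ReferenceMap, build_relationship_table, compounds_for_function
from .tables import AbundanceTable

__all__ = ["GroundTruth", "make_reference", "simulate_paired_cohort", "methods_fixture"]


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must rediscover."""

    planted: dict[str, float]                 # function -> fold change in cases
    truly_differential: set[str]              # compounds driven by planted functions
    weights: dict[str, dict[str, float]]      # compound -> {function: weight}
    detection_mask: set[str]                  # compounds the measured panel observes
    seed: int | None
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "planted": self.planted,
            "truly_differential": sorted(self.truly_differential),
            "weights": {c: self.weights[c] for c in sorted(self.weights)},
            "detection_mask": sorted(self.detection_mask),
            "seed": self.seed,
            "params": self.params,
        }
        text = json.dumps(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def make_reference(
    n_ko: int = 60,
    n_rxn: int = 80,
    n_cpd: int = 150,
    edge_density: float = 0.025,
    frac_ec_only: float = 0.2,
    frac_transporter: float = 0.1,
    decoy_frac: float = 0.2,
    seed: int | None = None,
) -> ReferenceMap:
    """Random relationship graph exercising every linkage route.

    A ``frac_ec_only`` share of KOs reach reactions only through EC numbers
    (the fallback route), a ``frac_transporter`` share are transporters with
    direct compound links, and the chemical dictionary carries an extra
    ``decoy_frac`` of compounds never linked to anything — so random-coverage
    null draws include unlinkable compounds, as a real dictionary would.
    """
    if min(n_ko, n_rxn, n_cpd) < 1:
        raise ValueError("graph sizes must be positive")
    for name, v in (("edge_density", edge_density), ("frac_ec_only", frac_ec_only),
                    ("frac_transporter", frac_transporter)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name}={v} outside [0, 1]")
    n_transporter = int(round(frac_transporter * n_ko))
    n_ec_only = int(round(frac_ec_only * n_ko))
    if n_transporter + n_ec_only > n_ko:
        raise ValueError("frac_ec_only + frac_transporter exceed 1")
    if n_ko - n_transporter - n_ec_only == 0 and n_ec_only == 0:
        raise ValueError("parameters leave no function linked to any reaction")

    rng = np.random.default_rng(seed)
    compounds = [f"cpd:C9{i:04d}" for i in range(n_cpd)]
    decoys = [f"cpd:C8{i:04d}" for i in range(int(np.ceil(decoy_frac * n_cpd)))]
    reactions = [f"rxn:R9{i:04d}" for i in range(n_rxn)]
    kos = [f"ko:K9{i:04d}" for i in range(n_ko)]

    records: list[dict] = [{"kind": "dictionary", "compound": c} for c in compounds + decoys]
    for rxn in reactions:
        n_edges = int(rng.integers(2, 6))
        for cpd in rng.choice(compounds, size=min(n_edges, n_cpd), replace=False):
            coef = float(rng.choice([-2.0, -1.0, 1.0, 2.0]))
            records.append(
                {"kind": "rxn_to_cpd", "source": rxn, "target": str(cpd), "coefficient": coef}
            )

    transporters = kos[:n_transporter]
    ec_only = kos[n_transporter:n_transporter + n_ec_only]
    direct = kos[n_transporter + n_ec_only:]

    for ko in transporters:
        for cpd in rng.choice(compounds, size=int(rng.integers(1, 4)), replace=False):
            records.append({"kind": "transporter_to_cpd", "source": ko, "target": str(cpd)})
    for i, ko in enumerate(ec_only):
        ec = f"ec:9.{i // 10}.{i % 10}.{int(rng.integers(1, 100))}"
        records.append({"kind": "ko_to_ec", "source": ko, "target": ec})
        for rxn in rng.choice(reactions, size=int(rng.integers(1, 4)), replace=False):
            records.append({"kind": "ec_to_rxn", "source": ec, "target": str(rxn)})
    for ko in direct:
        n_edges = max(1, int(rng.binomial(n_rxn, edge_density)))
        for rxn in rng.choice(reactions, size=min(n_edges, n_rxn), replace=False):
            records.append({"kind": "ko_to_rxn", "source": ko, "target": str(rxn)})

    return build_relationship_table(records)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_paired_cohort(
    ref: ReferenceMap,
    n_case: int = 30,
    n_ctrl: int = 30,
    n_studies: int = 2,
    n_planted: int = 10,
    fold_change: float = 4.0,
    noise_sd: float = 0.3,
    detect_frac: float = 0.7,
    rare_frac: float = 0.15,
    dispersion: float = 0.3,
    lib_size: float = 5e4,
    seed: int | None = None,
) -> tuple[AbundanceTable, AbundanceTable, GroundTruth]:
    """Paired function-count and metabolite-intensity cohort.

    Function counts are negative-binomial around lognormal baselines scaled
    by lognormal library sizes; ``n_planted`` compound-linked functions are
    multiplied by ``fold_change`` in cases.  A ``rare_frac`` share of
    functions is forced to very low baseline abundance so the 5%/10%
    prevalence filters downstream actually bite.  Each linked compound's
    latent intensity is a positive-weight linear mix of its linked functions'
    relative abundances times lognormal noise (sd ``noise_sd`` on the log
    scale); dictionary decoy compounds become "host" metabolites independent
    of the community.  A detection limit zeroes faint intensities and the
    measured panel is a random ``detect_frac`` subset of the dictionary
    (untargeted-coverage censoring applied to compounds, not samples).
    Study labels are assigned in blocks balanced over case/control.
    """
    if n_case < 2 or n_ctrl < 2 or n_studies < 1:
        raise ValueError("need >= 2 samples per group and >= 1 study")
    if not 0 < detect_frac <= 1:
        raise ValueError("detect_frac must lie in (0, 1]")
    if fold_change <= 0 or noise_sd < 0:
        raise ValueError("fold_change must be positive, noise_sd non-negative")

    rng = np.random.default_rng(seed)
    functions = sorted(
        ref.ko_to_rxn.keys() | ref.ko_to_ec.keys() | ref.transporter_to_cpd.keys()
    )
    if not functions:
        raise ValueError("reference has no functions")
    linked = [f for f in functions if compounds_for_function(ref, f)]
    if n_planted > len(linked):
        raise ValueError(f"n_planted={n_planted} exceeds {len(linked)} linked functions")

    n_f = len(functions)
    baseline = np.exp(rng.normal(0.0, 1.5, size=n_f))
    rare = rng.random(n_f) < rare_frac
    baseline[rare] *= 1e-5
    baseline /= baseline.sum()

    # plant only on sub-dominant functions: if planted features carried a
    # large share of the library, a strong one-directional fold change would
    # violate the most-features-unchanged assumption every size-factor
    # estimator rests on, and the whole community would look differential
    non_rare = np.asarray([f for f in linked if not rare[functions.index(f)]])
    bl = np.asarray([baseline[functions.index(f)] for f in non_rare])
    eligible = non_rare[bl <= np.median(bl)]
    if n_planted > len(eligible):
        eligible = non_rare
    planted = sorted(rng.choice(eligible, size=n_planted, replace=False))
    # balanced directions: half the planted functions are enriched in cases,
    # half depleted, as in real dysbiosis signatures — a one-directional
    # block of changed features would itself bias size-factor estimation
    planted_fold = {
        f: (fold_change if i % 2 == 0 else 1.0 / fold_change)
        for i, f in enumerate(planted)
    }

    # samples: balanced case/control blocks per study
    sample_ids, group, study = [], [], []
    for label, n in (("case", n_case), ("control", n_ctrl)):
        blocks = np.array_split(np.arange(n), n_studies)
        for b, block in enumerate(blocks):
            for i in block:
                sample_ids.append(f"{label[:2]}{i:03d}")
                group.append(label)
                study.append(f"study{b + 1}")
    order = np.argsort(study, kind="stable")  # samples blocked by study
    sample_ids = [sample_ids[i] for i in order]
    group = [group[i] for i in order]
    study = [study[i] for i in order]
    is_case = np.asarray([g == "case" for g in group])
    n_s = len(sample_ids)

    libs = lib_size * np.exp(rng.normal(0.0, 0.3, size=n_s))
    mu = baseline[:, None] * libs[None, :]
    case_cols = np.where(is_case)[0]
    for f, fc in planted_fold.items():
        mu[np.ix_([functions.index(f)], case_cols)] *= fc
    counts = _nb_counts(rng, mu, dispersion).astype(float)
    funcs = AbundanceTable(
        pd.DataFrame(counts, index=functions, columns=sample_ids),
        pd.DataFrame({"group": group, "study": study}, index=pd.Index(sample_ids)),
    )

    # latent metabolome: linear mix of linked functions' relative abundances
    relab = counts / np.maximum(counts.sum(axis=0), 1.0)
    weights: dict[str, dict[str, float]] = {}
    compound_scale: dict[str, float] = {}
    linked_compounds: set[str] = set()
    for f in linked:
        linked_compounds |= compounds_for_function(ref, f)
    contributors = {
        c: [f for f in linked if c in compounds_for_function(ref, f)]
        for c in sorted(linked_compounds)
    }
    latent = {}
    for c, fs in contributors.items():
        # a metabolite's level tracks a few dominant enzymes, not every
        # function its reactions touch: weight a sparse subset of 1-3
        k = min(len(fs), int(rng.integers(1, 4)))
        chosen = rng.choice(np.asarray(fs), size=k, replace=False)
        w = {str(f): float(rng.uniform(0.5, 1.5)) for f in chosen}
        weights[c] = w
        compound_scale[c] = float(np.exp(rng.normal(0.0, 1.0)))
        signal = np.zeros(n_s)
        for f, wf in w.items():
            signal += wf * relab[functions.index(f)]
        noise = np.exp(rng.normal(0.0, noise_sd, size=n_s)) if noise_sd > 0 else 1.0
        latent[c] = 1e6 * compound_scale[c] * signal * noise

    host = sorted(ref.dictionary - linked_compounds)
    for c in host:
        latent[c] = np.exp(rng.normal(np.log(1e4), 1.0, size=n_s))

    metab_df = pd.DataFrame(latent, index=sample_ids).T
    # detection limit: intensities below a low quantile of the nonzero pool
    # read as undetected, creating realistic metabolome sparsity
    nonzero = metab_df.to_numpy()[metab_df.to_numpy() > 0]
    if nonzero.size:
        limit = np.quantile(nonzero, 0.10)
        metab_df = metab_df.mask(metab_df < limit, 0.0)

    universe = np.asarray(sorted(ref.dictionary))
    panel = set(
        rng.choice(universe, size=int(round(detect_frac * len(universe))), replace=False)
    )
    measured_rows = [c for c in metab_df.index if c in panel]
    metab = AbundanceTable(metab_df.loc[measured_rows], funcs.metadata)

    truly_diff = {
        c for c, w in weights.items() if any(f in set(planted) for f in w)
    } if fold_change != 1 else set()
    truth = GroundTruth(
        planted=planted_fold,
        truly_differential=truly_diff,
        weights=weights,
        detection_mask=panel,
        seed=seed,
        params={
            "n_case": n_case, "n_ctrl": n_ctrl, "n_studies": n_studies,
            "n_planted": n_planted, "fold_change": fold_change,
            "noise_sd": noise_sd, "detect_frac": detect_frac,
            "rare_frac": rare_frac, "dispersion": dispersion,
            "lib_size": lib_size,
        },
    )
    return funcs, metab, truth


def methods_fixture() -> ReferenceMap:
    """Tiny hand-built reference encoding the canonical linkage examples.

    K24443 carries two direct reactions whose compounds union to five; K00046
    carries no reaction but one EC number leading to two reactions and seven
    compounds (the fallback route); one synthetic transporter KO links
    straight to a compound.  Stoichiometric signs are arbitrary but fixed so
    community-metabolic-potential scoring works on the fixture.
    """
    records = [
        {"kind": "ko_to_rxn", "source": "ko:K24443", "target": "rxn:R02428"},
        {"kind": "ko_to_rxn", "source": "ko:K24443", "target": "rxn:R02526"},
        {"kind": "rxn_to_cpd", "source": "rxn:R02428", "target": "cpd:C02753", "coefficient": -1},
        {"kind": "rxn_to_cpd", "source": "rxn:R02428", "target": "cpd:C00001", "coefficient": -1},
        {"kind": "rxn_to_cpd", "source": "rxn:R02428", "target": "cpd:C00502", "coefficient": 1},
        {"kind": "rxn_to_cpd", "source": "rxn:R02526", "target": "cpd:C01114", "coefficient": 1},
        {"kind": "rxn_to_cpd", "source": "rxn:R02526", "target": "cpd:C00545", "coefficient": -1},
        {"kind": "rxn_to_cpd", "source": "rxn:R02526", "target": "cpd:C00001", "coefficient": -1},
        {"kind": "ko_to_ec", "source": "ko:K00046", "target": "ec:1.1.1.69"},
        {"kind": "ec_to_rxn", "source": "ec:1.1.1.69", "target": "rxn:R01738"},
        {"kind": "ec_to_rxn", "source": "ec:1.1.1.69", "target": "rxn:R01740"},
        {"kind": "rxn_to_cpd", "source": "rxn:R01738", "target": "cpd:C00257", "coefficient": 1},
        {"kind": "rxn_to_cpd", "source": "rxn:R01738", "target": "cpd:C00003", "coefficient": -1},
        {"kind": "rxn_to_cpd", "source": "rxn:R01738", "target": "cpd:C01062", "coefficient": -1},
        {"kind": "rxn_to_cpd", "source": "rxn:R01738", "target": "cpd:C00004", "coefficient": 1},
        {"kind": "rxn_to_cpd", "source": "rxn:R01738", "target": "cpd:C00080", "coefficient": 1},
        {"kind": "rxn_to_cpd", "source": "rxn:R01740", "target": "cpd:C00257", "coefficient": 1},
        {"kind": "rxn_to_cpd", "source": "rxn:R01740", "target": "cpd:C00006", "coefficient": -1},
        {"kind": "rxn_to_cpd", "source": "rxn:R01740", "target": "cpd:C01062", "coefficient": -1},
        {"kind": "rxn_to_cpd", "source": "rxn:R01740", "target": "cpd:C00005", "coefficient": 1},
        {"kind": "transporter_to_cpd", "source": "ko:K99901", "target": "cpd:C00031"},
    ]
    # dictionary entries for every compound referenced above
    cpds = sorted({r["target"] for r in records if r["kind"].endswith("_to_cpd")})
    records = [{"kind": "dictionary", "compound": c} for c in cpds] + records
    return build_relationship_table(records)
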