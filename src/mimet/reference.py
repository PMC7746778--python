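"""Relationship graph linking microbial functions (KOs, reactions) to compounds.

The graph mirrors how gene-to-metabolite reference pipelines link a KEGG
ortholog (KO) or a BioCyc reaction to the compounds its reactions produce or
consume.  Three routes exist:

* **direct** — a KO annotated with one or more reactions links to every
  compound of those reactions;
* **EC fallback** — a KO with *no* reaction annotation but one or more Enzyme
  Commission (EC) numbers links through EC -> reaction -> compound;
* **transporter** — a transporter KO links straight to the compounds it moves.

Reaction directionality is deliberately ignored for linkage (many gut
reactions are reversible in vivo), but signed stoichiometric coefficients are
retained on the reaction->compound edges because community-metabolic-potential
scoring needs them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ReferenceMap",
    "MalformedIdentifierError",
    "build_relationship_table",
    "compounds_for_function",
    "compounds_for_functions",
    "reactions_for_function",
]

#: namespaces understood by the graph; the prefix decides which linkage
#: routes apply to an identifier.
KNOWN_NAMESPACES = frozenset({"ko", "rxn", "cpd", "ec", "biocyc"})

#: record kinds accepted by :func:`build_relationship_table`.
RECORD_KINDS = (
    "ko_to_rxn",
    "ko_to_ec",
    "ec_to_rxn",
    "rxn_to_cpd",
    "transporter_to_cpd",
    "dictionary",
)


class MalformedIdentifierError(ValueError):
    """An identifier is empty or missing its namespace prefix."""


def _check_id(ident: str, location: str = "?") -> str:
    if not isinstance(ident, str) or not ident:
        raise MalformedIdentifierError(f"empty identifier at {location}")
    ns, sep, rest = ident.partition(":")
    if not sep or not rest or ns not in KNOWN_NAMESPACES:
        raise MalformedIdentifierError(
            f"identifier {ident!r} at {location} lacks a known namespace "
            f"prefix (one of {sorted(KNOWN_NAMESPACES)})"
        )
    return ident


@dataclass
class ReferenceMap:
    """The function/EC/reaction -> compound linkage graph plus the chemical
    dictionary (the compound universe random-coverage draws come from).

    ``rxn_to_cpd`` stores an optional signed stoichiometric coefficient per
    edge (``None`` when the source records carried none); positive means net
    production, negative net consumption.
    """

    ko_to_rxn: dict[str, set[str]] = field(default_factory=dict)
    ko_to_ec: dict[str, set[str]] = field(default_factory=dict)
    ec_to_rxn: dict[str, set[str]] = field(default_factory=dict)
    rxn_to_cpd: dict[str, dict[str, float | None]] = field(default_factory=dict)
    transporter_to_cpd: dict[str, set[str]] = field(default_factory=dict)
    dictionary: set[str] = field(default_factory=set)
    orphan_reactions: set[str] = field(default_factory=set)

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        for rxn, cpds in self.rxn_to_cpd.items():
            for cpd, coef in cpds.items():
                if cpd not in self.dictionary:
                    raise ValueError(f"{cpd} of {rxn} missing from dictionary")
                if coef is not None and coef == 0:
                    raise ValueError(f"zero stoichiometry on {rxn} -> {cpd}")
        for cpds in self.transporter_to_cpd.values():
            if not cpds <= self.dictionary:
                raise ValueError("transporter compound missing from dictionary")
        referenced = set().union(*self.ko_to_rxn.values(), set()) | set().union(
            *self.ec_to_rxn.values(), set()
        )
        unresolved = referenced - self.rxn_to_cpd.keys() - self.orphan_reactions
        if unresolved:
            raise ValueError(f"reactions without compound entries: {sorted(unresolved)[:5]}")

    @property
    def functions(self) -> set[str]:
        """Every function that has at least one linkage route."""
        return (
            self.ko_to_rxn.keys()
            | self.ko_to_ec.keys()
            | self.transporter_to_cpd.keys()
            | self.rxn_to_cpd.keys()
        )

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize to JSON with sorted keys (byte-stable round-trips)."""
        doc = {
            "ko_to_rxn": {k: sorted(v) for k, v in self.ko_to_rxn.items()},
            "ko_to_ec": {k: sorted(v) for k, v in self.ko_to_ec.items()},
            "ec_to_rxn": {k: sorted(v) for k, v in self.ec_to_rxn.items()},
            "rxn_to_cpd": {
                r: {c: coef for c, coef in sorted(v.items())}
                for r, v in self.rxn_to_cpd.items()
            },
            "transporter_to_cpd": {
                k: sorted(v) for k, v in self.transporter_to_cpd.items()
            },
            "dictionary": sorted(self.dictionary),
            "orphan_reactions": sorted(self.orphan_reactions),
        }
        text = json.dumps(doc, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ReferenceMap":
        text = str(source)
        if isinstance(source, Path) or not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        doc = json.loads(text)
        ref = cls(
            ko_to_rxn={k: set(v) for k, v in doc["ko_to_rxn"].items()},
            ko_to_ec={k: set(v) for k, v in doc["ko_to_ec"].items()},
            ec_to_rxn={k: set(v) for k, v in doc["ec_to_rxn"].items()},
            rxn_to_cpd={
                r: {c: (None if coef is None else float(coef)) for c, coef in v.items()}
                for r, v in doc["rxn_to_cpd"].items()
            },
            transporter_to_cpd={
                k: set(v) for k, v in doc["transporter_to_cpd"].items()
            },
            dictionary=set(doc["dictionary"]),
            orphan_reactions=set(doc.get("orphan_reactions", [])),
        )
        ref.validate()
        return ref


def _records_from_tsv_dir(directory: str | Path) -> list[dict]:
    """Read one TSV per mapping kind (``<kind>.tsv``, 2-3 columns, no header)."""
    records: list[dict] = []
    directory = Path(directory)
    for kind in RECORD_KINDS:
        path = directory / f"{kind}.tsv"
        if not path.exists():
            continue
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            rec: dict = {"kind": kind, "location": f"{path.name}:{lineno}"}
            if kind == "dictionary":
                rec["compound"] = parts[0]
            elif kind == "rxn_to_cpd":
                rec["source"], rec["target"] = parts[0], parts[1]
                if len(parts) > 2 and parts[2] != "":
                    rec["coefficient"] = float(parts[2])
            else:
                rec["source"], rec["target"] = parts[0], parts[1]
            records.append(rec)
    return records


def build_relationship_table(
    records: Iterable[Mapping] | str | Path,
) -> ReferenceMap:
    """Build a deduplicated :class:`ReferenceMap` from mapping records.

    Parameters
    ----------
    records
        Either an iterable of dicts with keys ``kind`` (one of
        ``ko_to_rxn``, ``ko_to_ec``, ``ec_to_rxn``, ``rxn_to_cpd``,
        ``transporter_to_cpd``, ``dictionary``), ``source``/``target`` (or
        ``compound`` for dictionary records) and optional ``coefficient``,
        or a path to a directory of per-kind TSV files.

    Duplicate records collapse to one edge.  Reactions referenced by a KO or
    EC edge but carrying no compound entry are recorded as orphans (logged,
    not fatal).  Compounds referenced by an edge but absent from the supplied
    dictionary are auto-added with a warning.
    """
    if isinstance(records, (str, Path)):
        records = _records_from_tsv_dir(records)

    ref = ReferenceMap()
    auto_added: set[str] = set()
    for i, rec in enumerate(records):
        kind = rec.get("kind")
        loc = rec.get("location", f"record {i}")
        if kind not in RECORD_KINDS:
            raise ValueError(f"unknown record kind {kind!r} at {loc}")
        if kind == "dictionary":
            ref.dictionary.add(_check_id(rec["compound"], loc))
            continue
        src = _check_id(rec["source"], loc)
        tgt = _check_id(rec["target"], loc)
        if kind == "ko_to_rxn":
            ref.ko_to_rxn.setdefault(src, set()).add(tgt)
        elif kind == "ko_to_ec":
            ref.ko_to_ec.setdefault(src, set()).add(tgt)
        elif kind == "ec_to_rxn":
            ref.ec_to_rxn.setdefault(src, set()).add(tgt)
        elif kind == "transporter_to_cpd":
            ref.transporter_to_cpd.setdefault(src, set()).add(tgt)
            if tgt not in ref.dictionary:
                auto_added.add(tgt)
                ref.dictionary.add(tgt)
        elif kind == "rxn_to_cpd":
            coef = rec.get("coefficient")
            if coef is not None:
                coef = float(coef)
                if coef == 0:
                    raise ValueError(f"zero stoichiometric coefficient at {loc}")
            ref.rxn_to_cpd.setdefault(src, {})[tgt] = coef
            if tgt not in ref.dictionary:
                auto_added.add(tgt)
                ref.dictionary.add(tgt)

    if auto_added:
        warnings.warn(
            f"{len(auto_added)} compounds referenced by edges were absent from "
            "the supplied dictionary and were auto-added",
            stacklevel=2,
        )
    referenced = set()
    for rxns in ref.ko_to_rxn.values():
        referenced |= rxns
    for rxns in ref.ec_to_rxn.values():
        referenced |= rxns
    ref.orphan_reactions = referenced - ref.rxn_to_cpd.keys()
    ref.validate()
    return ref


def reactions_for_function(
    ref: ReferenceMap, f: str, ec_fallback: str = "fallback"
) -> set[str]:
    """Reactions a function resolves to.

    Reaction-namespace identifiers resolve to themselves.  A KO uses its
    direct reaction annotations; only when it has none does the EC route
    apply (``ec_fallback="fallback"``, the default); ``"always"`` unions the
    two routes instead.
    """
    if f in ref.rxn_to_cpd:
        return {f}
    direct = set(ref.ko_to_rxn.get(f, ()))
    if direct and ec_fallback == "fallback":
        return direct
    via_ec: set[str] = set()
    for ec in ref.ko_to_ec.get(f, ()):
        via_ec |= ref.ec_to_rxn.get(ec, set())
    return direct | via_ec


def compounds_for_function(
    ref: ReferenceMap, f: str, ec_fallback: str = "fallback"
) -> set[str]:
    """All compounds linked to one function.

    Union of (i) compounds of the function's reactions (direct annotations,
    or the EC route when it has none) and (ii) its transporter compounds.
    An unknown function yields the empty set.
    """
    _check_id(f)
    cpds: set[str] = set()
    for rxn in reactions_for_function(ref, f, ec_fallback):
        cpds |= ref.rxn_to_cpd.get(rxn, {}).keys()
    cpds |= ref.transporter_to_cpd.get(f, set())
    return cpds


def compounds_for_functions(
    ref: ReferenceMap, fs: Iterable[str], ec_fallback: str = "fallback"
) -> set[str]:
    """Union of :func:`compounds_for_function` over ``fs``."""
    out: set[str] = set()
    for f in fs:
        out |= compounds_for_function(ref, f, ec_fallback)
    return out
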