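"""Abundance tables: features x samples matrices with sample metadata.

The on-disk dialect is plain TSV — first column feature ID, header row of
sample IDs — which is how function-count and metabolite-intensity tables
circulate in microbiome work.  Sample metadata (case/control group, study ID)
travels in a companion frame indexed by sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["AbundanceTable", "read_table", "write_table", "read_metadata", "write_metadata"]


@dataclass
class AbundanceTable:
    """Features x samples numeric matrix plus optional per-sample metadata.

    ``data`` rows are features (functions or compounds), columns samples.
    ``metadata``, when present, is indexed by sample ID and carries ``group``
    (case/control label) and ``study`` columns.  Values must be finite;
    non-negativity is expected for counts/intensities but not enforced, since
    signed community-metabolic-potential matrices reuse this container.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes[:5]}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValueError("non-finite values in abundance table")
        self.data = self.data.astype(float)
        if self.metadata is not None:
            missing = self.data.columns.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"samples missing from metadata: {list(missing)[:5]}")
            self.metadata = self.metadata.loc[self.data.columns]

    # -- convenience -----------------------------------------------------
    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def groups(self, case: str, control: str) -> pd.Series:
        """Sample -> group series restricted to the two contrast labels."""
        if self.metadata is None or "group" not in self.metadata:
            raise ValueError("table has no group metadata")
        g = self.metadata["group"]
        return g[g.isin([case, control])]

    def subset_samples(self, samples: Iterable[str]) -> "AbundanceTable":
        samples = [s for s in samples if s in self.data.columns]
        meta = self.metadata.loc[samples] if self.metadata is not None else None
        return AbundanceTable(self.data[samples], meta)

    def subset_features(self, features: Iterable[str]) -> "AbundanceTable":
        features = [f for f in features if f in self.data.index]
        return AbundanceTable(self.data.loc[features], self.metadata)

    def relative_abundance(self) -> "AbundanceTable":
        """Per-sample relative abundance (columns sum to 1; all-zero columns stay 0)."""
        sums = self.data.sum(axis=0)
        safe = sums.replace(0.0, 1.0)
        return AbundanceTable(self.data / safe, self.metadata)

    def __eq__(self, other: object) -> bool:  # used by round-trip tests
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        same_data = self.data.equals(other.data)
        if self.metadata is None or other.metadata is None:
            return same_data and (self.metadata is None) == (other.metadata is None)
        return same_data and self.metadata.equals(other.metadata)


def read_table(path: str | Path, metadata: pd.DataFrame | None = None) -> AbundanceTable:
    """Read a features-x-samples TSV.

    Raises on duplicate feature/sample IDs, ragged rows and numeric parse
    failures (reported with row and column).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.isna().any() or df.isna().any().any():
        bad = np.argwhere(df.isna().to_numpy())
        where = f"row {bad[0][0] + 2}" if len(bad) else "index"
        raise ValueError(f"ragged or missing cells in {path} ({where})")
    try:
        numeric = df.astype(float)
    except ValueError:
        for i, row in enumerate(df.itertuples(index=True)):
            for j, cell in enumerate(row[1:]):
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"numeric parse failure in {path} at row {i + 2} "
                        f"(feature {row[0]!r}), column {df.columns[j]!r}: {cell!r}"
                    ) from None
        raise
    return AbundanceTable(numeric, metadata)


def write_table(table: AbundanceTable, path: str | Path) -> None:
    """Write the TSV dialect; full float repr so round-trips are lossless."""
    df = table.data.copy()
    df.index.name = "feature_id"
    df.to_csv(Path(path), sep="\t", float_format="%.17g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV: first column sample ID, then group/study columns."""
    meta = pd.read_csv(Path(path), sep="\t", index_col=0, dtype=str)
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample IDs in metadata")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(Path(path), sep="\t")
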