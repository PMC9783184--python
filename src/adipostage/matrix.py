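"""Feature-by-sample abundance/expression container with sample metadata.

The same container carries lipid species abundances (features = lipid
shorthand names) and gene expression (features = gene symbols).  Values are
a pandas DataFrame (features x samples); per-sample metadata is a second
DataFrame indexed by sample id with at least a ``group`` column and optional
``batch`` and ``day`` columns (``day`` applies to differentiation
time-course samples such as SVF cultures).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_COL = "group"
BATCH_COL = "batch"
DAY_COL = "day"


@dataclass
class FeatureMatrix:
    values: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(
                {GROUP_COL: ["unknown"] * self.values.shape[1]},
                index=self.values.columns,
            )
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if not v.columns.equals(self.samples.index):
            missing = v.columns.difference(self.samples.index).tolist()
            if missing:
                raise ValueError(f"samples without metadata: {missing[:5]}")
            # reorder metadata to match the value columns
            self.samples = self.samples.loc[v.columns]
        if GROUP_COL not in self.samples.columns:
            raise ValueError("sample metadata must have a 'group' column")
        if self.samples[GROUP_COL].isna().any():
            bad = self.samples.index[self.samples[GROUP_COL].isna()].tolist()
            raise ValueError(f"samples with no group label: {bad[:5]}")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValueError("values must be finite")

    # -- accessors --------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self) -> list[str]:
        return sorted(self.samples[GROUP_COL].unique().tolist())

    def samples_in_group(self, group: str) -> list[str]:
        mask = self.samples[GROUP_COL] == group
        return self.samples.index[mask].tolist()

    def group_values(self, group: str) -> pd.DataFrame:
        ids = self.samples_in_group(group)
        if not ids:
            raise KeyError(f"no samples in group {group!r}")
        return self.values[ids]

    def subset_features(self, feature_ids) -> "FeatureMatrix":
        return FeatureMatrix(self.values.loc[list(feature_ids)], self.samples.copy())

    def subset_samples(self, sample_ids) -> "FeatureMatrix":
        ids = list(sample_ids)
        return FeatureMatrix(self.values[ids], self.samples.loc[ids])

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_tsv(cls, values_path, meta_path=None, sep=None) -> "FeatureMatrix":
        """Read a delimited table (TSV default, comma autodetected).

        First column = feature id, header row = sample ids.  ``meta_path``
        points at a matching sample sheet (first column = sample id).
        """
        values = pd.read_csv(values_path, sep=sep or _sniff_sep(values_path), index_col=0)
        values.index = values.index.astype(str)
        samples = None
        if meta_path is not None:
            samples = pd.read_csv(meta_path, sep=sep or _sniff_sep(meta_path), index_col=0)
            samples.index = samples.index.astype(str)
        return cls(values, samples)

    def to_tsv(self, values_path, meta_path=None) -> None:
        self.values.to_csv(values_path, sep="\t", float_format="%.10g")
        if meta_path is not None:
            self.samples.to_csv(meta_path, sep="\t")


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "," if ("," in header and "\t" not in header) else "\t"
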