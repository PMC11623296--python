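"""Core in-memory containers for the transcriptomic-distance pipeline.

Everything downstream operates on three objects: a gene x sample
:class:`ExpressionMatrix` with a declared normalization state, a per-tissue
:class:`ReferenceProfile` (the central expression vector a tumor sample is
compared against), and a named :class:`GeneSetCollection` (e.g. MSigDB
hallmark pathways read from GMT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allowed normalization states of an expression matrix.  ``log_space``
#: means values are already log-transformed; every other state is linear.
VALID_STATES = ("counts", "cpm", "tmm_cpm", "uq", "log_space")


class ZeroVarianceError(ValueError):
    """Raised when an expression vector is constant after log transform."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix with a declared normalization state.

    Parameters
    ----------
    data:
        DataFrame indexed by unique gene symbols with unique sample-id
        columns.  Values are finite, and non-negative unless
        ``state == "log_space"``.
    state:
        One of :data:`VALID_STATES`.
    """

    data: pd.DataFrame
    state: str

    def __post_init__(self) -> None:
        if self.state not in VALID_STATES:
            raise ValueError(f"unknown normalization state {self.state!r}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dupes[:5]}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        values = self.data.to_numpy()
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        if self.state != "log_space" and (values < 0).any():
            raise ValueError(f"negative values not allowed in state {self.state!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = set(genes) - set(self.data.index)
        if missing:
            raise KeyError(f"unknown genes: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)].copy(), self.state)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        missing = set(samples) - set(self.data.columns)
        if missing:
            raise KeyError(f"unknown samples: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.data[list(samples)].copy(), self.state)


@dataclass
class ReferenceProfile:
    """One tissue's central (median or mean) expression vector.

    Shares gene order and normalization state with the cohort matrix it
    was derived from; used as the OT or TT comparator in distance
    computations.
    """

    tissue: str
    values: pd.Series
    statistic: str  # "median" or "mean"
    state: str = "cpm"

    def __post_init__(self) -> None:
        if self.statistic not in ("median", "mean"):
            raise ValueError(f"statistic must be median or mean, got {self.statistic!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class GeneSetCollection:
    """Ordered mapping of gene-set name -> unique gene symbols."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) < 1:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()
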