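"""Core domain types for the two-group expression analysis.

The analysis operates on a probes-or-genes × samples expression matrix,
a two-group (case/control) sample design, an optional probe→gene map, and
named gene sets annotated with the axonemal substructure they belong to
(outer dynein arms, inner dynein arms, radial spokes, intraflagellar
transport).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GroupDesign",
    "ProbeGeneMap",
    "GeneSet",
    "CATEGORIES",
    "ValidationError",
]

#: recognised ultrastructural category tokens for gene sets
CATEGORIES = ("ODA", "IDA", "radial_spoke", "IFT", "other")


class ValidationError(ValueError):
    """An input violates a structural invariant of the analysis."""


@dataclass
class ExpressionMatrix:
    """Expression values with an explicit log2-scale flag.

    Parameters
    ----------
    data:
        DataFrame of shape (n_rows, n_samples); the index holds probe or
        gene identifiers, the columns hold sample identifiers.
    is_log2:
        True once values are on the log2 scale.  Linear-scale matrices
        must be non-negative.
    """

    data: pd.DataFrame
    is_log2: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate row identifiers: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        if self.data.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if not self.is_log2 and (self.data.to_numpy() < 0).any():
            raise ValidationError("linear-scale expression values must be >= 0")

    @property
    def row_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy(), self.is_log2)


@dataclass
class GroupDesign:
    """Assignment of each sample to the case or control group."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {s: g for s, g in self.labels.items() if g not in ("case", "control")}
        if bad:
            raise ValidationError(f"labels must be 'case' or 'control', got {bad}")
        if self.n_case < 1 or self.n_control < 1:
            raise ValidationError("both groups need at least one sample")

    @property
    def case_samples(self) -> list[str]:
        return [s for s, g in self.labels.items() if g == "case"]

    @property
    def control_samples(self) -> list[str]:
        return [s for s, g in self.labels.items() if g == "control"]

    @property
    def n_case(self) -> int:
        return len(self.case_samples)

    @property
    def n_control(self) -> int:
        return len(self.control_samples)

    def validate_against(self, m: ExpressionMatrix) -> None:
        missing = [s for s in self.labels if s not in m.data.columns]
        if missing:
            raise ValidationError(f"design samples absent from matrix: {missing}")

    def drop_sample(self, sample_id: str) -> "GroupDesign":
        if sample_id not in self.labels:
            raise KeyError(sample_id)
        return GroupDesign({s: g for s, g in self.labels.items() if s != sample_id})


@dataclass
class ProbeGeneMap:
    """Many-to-one map from probe identifiers to gene identifiers."""

    entries: Mapping[str, str]

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.entries.values():
            seen.setdefault(g, None)
        return list(seen)


@dataclass
class GeneSet:
    """A named list of gene identifiers with an ultrastructural category.

    ``category`` is one of ``ODA`` (outer dynein arms), ``IDA`` (inner
    dynein arms), ``radial_spoke``, ``IFT`` (intraflagellar transport) or
    ``other``.
    """

    name: str
    members: Sequence[str]
    category: str = "other"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"gene set {self.name!r} has duplicate members")
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"category {self.category!r} not in {CATEGORIES}"
            )
        self.members = list(self.members)

    def __len__(self) -> int:
        return len(self.members)
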