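"""Readers and writers for expression tables, designs, probe maps and GMT
gene sets, plus loaders for the packaged study fixtures.

Expression matrices travel as TSV with row identifiers in the first column
and a header row of sample identifiers (the series-matrix convention).
Gene sets use the standard GMT layout: set name, description, then
tab-separated member identifiers.  The packaged fixtures transcribe the
study's two printed result tables at full precision: 37 ciliary genes with
per-gene one-tailed rank-test p-values and four per-category combined
p-values, and 24 disease genes with t-test p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .datamodel import (
    CATEGORIES,
    ExpressionMatrix,
    GeneSet,
    GroupDesign,
    ProbeGeneMap,
    ValidationError,
)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_group_design",
    "write_group_design",
    "read_probe_gene_map",
    "read_gene_sets",
    "write_gene_sets",
    "Table3Fixture",
    "Table4Fixture",
    "load_table3_fixture",
    "load_table4_fixture",
    "load_ciliary_gene_sets",
]

PathLike = Union[str, Path]


def _data_path(name: str):
    return resources.files("ciliashift.data").joinpath(name)


def read_expression_matrix(path: PathLike, is_log2: bool = False) -> ExpressionMatrix:
    """Read a TSV expression table (row ids in column 1, samples in header).

    Raises a parse error naming the offending row and column for any
    non-numeric cell, and a :class:`ValidationError` for duplicated ids.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)

    def _parse(cell):
        # float() is correctly rounded, so write→read round-trips exactly
        try:
            return float(cell)
        except (TypeError, ValueError):
            return float("nan")

    numeric = df.map(_parse)
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        row = bad.any(axis=1).idxmax()
        col = bad.loc[row].idxmax()
        raise ValueError(
            f"non-numeric expression value at row {row!r}, column {col!r}: "
            f"{df.loc[row, col]!r}"
        )
    if numeric.isna().any().any():
        row = numeric.isna().any(axis=1).idxmax()
        raise ValidationError(f"missing value in row {row!r}")
    return ExpressionMatrix(numeric, is_log2=is_log2)


def write_expression_matrix(m: ExpressionMatrix, path: PathLike) -> None:
    """Write a TSV round-trippable by :func:`read_expression_matrix`."""
    out = m.data.copy()
    out.index.name = "id"
    # repr-precision floats so that write→read is value-identical
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_group_design(path: PathLike) -> GroupDesign:
    """Read a two-column TSV (sample_id, label in {case, control})."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("group design needs columns: sample_id, label")
    labels = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return GroupDesign(labels)


def write_group_design(d: GroupDesign, path: PathLike) -> None:
    pd.DataFrame(
        {"sample_id": list(d.labels), "label": list(d.labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_probe_gene_map(path: PathLike) -> ProbeGeneMap:
    """Read a two-column TSV (probe_id, gene_id); one gene per probe."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    probes = df.iloc[:, 0]
    if probes.duplicated().any():
        dups = probes[probes.duplicated()].tolist()
        raise ValidationError(f"probes mapped more than once: {dups}")
    return ProbeGeneMap(dict(zip(probes, df.iloc[:, 1])))


def read_gene_sets(path: PathLike) -> list[GeneSet]:
    """Parse a GMT file into gene sets.

    The description field doubles as the category when it matches one of
    the known ultrastructural tokens (ODA, IDA, radial_spoke, IFT);
    anything else falls back to ``other``.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need name, description "
                    f"and at least one member (got {len(fields)} fields)"
                )
            name, description, *members = fields
            members = [g for g in members if g]
            category = description if description in CATEGORIES else "other"
            sets.append(
                GeneSet(name=name, members=members, category=category,
                        description=description)
            )
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: PathLike) -> None:
    with open(path, "w") as fh:
        for s in sets:
            desc = s.description or s.category
            fh.write("\t".join([s.name, desc, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# packaged study fixtures


@dataclass
class Table3Fixture:
    """The 37 ciliary genes: per-gene group log2 means, fold changes and
    one-tailed rank-test p-values, plus the four per-category combined
    p-values."""

    table: pd.DataFrame           # indexed by gene symbol
    combined_p: dict[str, float]  # category -> printed combined p-value

    @property
    def rows(self) -> dict[str, pd.Series]:
        """Per-gene rows with attribute access (``rows["DNAH1"].fold_change``)."""
        return {g: self.table.loc[g] for g in self.table.index}

    def genes(self, category: str | None = None) -> list[str]:
        if category is None:
            return self.table.index.tolist()
        return self.table.index[self.table["category"] == category].tolist()

    def per_gene_p(self, category: str) -> list[float]:
        """One-tailed per-gene p-values for one ultrastructural category."""
        sub = self.table[self.table["category"] == category]
        if sub.empty:
            raise KeyError(category)
        return sub["p_wilcoxon"].tolist()

    @property
    def categories(self) -> list[str]:
        return list(dict.fromkeys(self.table["category"]))


@dataclass
class Table4Fixture:
    """The 24 disease-gene rows with group log2 means, fold changes and
    two-sample t-test p-values."""

    table: pd.DataFrame

    @property
    def rows(self) -> dict[str, pd.Series]:
        return {g: self.table.loc[g] for g in self.table.index}


def load_table3_fixture() -> Table3Fixture:
    with resources.as_file(_data_path("table3_ciliary_genes.tsv")) as p:
        table = pd.read_csv(p, sep="\t", index_col="gene")
    table["alias"] = table["alias"].fillna("")
    with resources.as_file(_data_path("table3_combined_p.tsv")) as p:
        comb = pd.read_csv(p, sep="\t", index_col="category")
    return Table3Fixture(table=table, combined_p=comb["p_combined"].to_dict())


def load_table4_fixture() -> Table4Fixture:
    with resources.as_file(_data_path("table4_pcd_genes.tsv")) as p:
        table = pd.read_csv(p, sep="\t", index_col="gene")
    table["alias"] = table["alias"].fillna("")
    return Table4Fixture(table=table)


def load_ciliary_gene_sets() -> list[GeneSet]:
    """The four packaged axonemal gene sets (ODA, IDA, radial spokes, IFT)."""
    with resources.as_file(_data_path("ciliary_sets.gmt")) as p:
        return read_gene_sets(p)
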