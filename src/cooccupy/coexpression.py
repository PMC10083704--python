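"""Age-binned single-cell co-expression analysis.

Each nucleus carries a continuous developmental-age score (a neural-net
age estimate in the source atlas); scores are binned to integers and raw
counts are averaged per bin to give per-gene expression trajectories.
Co-expression of a gene pair is assessed by partitioning nuclei into
double-positive cells (>= 1 count for BOTH genes) versus the rest, and by
counting double-positives inside an age window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellRecord",
    "AgeBinnedExpression",
    "CoexpressionPartition",
    "read_cell_table",
    "write_cell_table",
    "bin_age",
    "expression_trajectory",
    "partition_double_positive",
    "count_double_positive_in_window",
    "age_distribution_summary",
]


@dataclass(frozen=True)
class CellRecord:
    """One nucleus: id, developmental-age score, raw gene counts."""

    cell_id: str
    age: float
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not math.isfinite(self.age):
            raise ValueError(f"non-finite age for cell {self.cell_id!r}")
        for g, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {g!r} in {self.cell_id!r}")


@dataclass
class AgeBinnedExpression:
    """Per integer age bin: number of cells and mean raw count per gene.

    ``table`` is indexed by bin with an ``n_cells`` column plus one column
    per queried gene; bins with zero cells are omitted rather than
    reported as zero expression.
    """

    table: pd.DataFrame
    genes: list[str]

    @property
    def bins(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def mean(self, gene: str) -> pd.Series:
        return self.table[gene]

    def argmax_bin(self, gene: str) -> int:
        """Bin with the highest mean count (ties: earliest bin)."""
        return int(self.table[gene].idxmax())


@dataclass
class CoexpressionPartition:
    """Exhaustive, disjoint split of cell ids into double-positive
    ("positive") cells and everything else ("negative")."""

    positive: list[str]
    negative: list[str]
    gene_a: str
    gene_b: str


def bin_age(age: float, rounding: str = "nearest") -> int:
    """Integer developmental-stage bin for an age score.

    ``rounding="nearest"`` (default) rounds to the nearest integer with
    halves away from zero (4.4 -> 4, 4.5 -> 5); ``rounding="ceil"`` takes
    the ceiling, the literal reading of "rounded up".
    """
    if not math.isfinite(age):
        raise ValueError("age must be finite")
    if rounding == "nearest":
        return int(math.floor(abs(age) + 0.5)) * (1 if age >= 0 else -1)
    if rounding == "ceil":
        return int(math.ceil(age))
    raise ValueError(f"unknown rounding {rounding!r}")


def _gene_known(cells: Sequence[CellRecord], gene: str) -> bool:
    return any(gene in c.counts for c in cells)


def expression_trajectory(
    cells: Sequence[CellRecord],
    genes: Sequence[str],
    rounding: str = "nearest",
) -> AgeBinnedExpression:
    """Mean raw count per gene per integer age bin.

    Counts are averaged as-is (no normalization; the source tables are raw
    count matrices). A gene absent from every cell's count map is an
    error; a gene merely uncounted in some cells contributes 0 there.
    """
    if not cells:
        raise ValueError("no cells")
    for g in genes:
        if not _gene_known(cells, g):
            raise ValueError(f"gene {g!r} absent from all cells")
    rows = {
        "bin": [bin_age(c.age, rounding) for c in cells],
        **{g: [c.counts.get(g, 0) for c in cells] for g in genes},
    }
    df = pd.DataFrame(rows)
    grouped = df.groupby("bin").agg(
        n_cells=("bin", "size"), **{g: (g, "mean") for g in genes}
    )
    grouped = grouped.sort_index()
    return AgeBinnedExpression(grouped, list(genes))


def partition_double_positive(
    cells: Sequence[CellRecord], gene_a: str, gene_b: str
) -> CoexpressionPartition:
    """Split cells into double-positive (>= 1 count for BOTH genes) vs rest."""
    for g in (gene_a, gene_b):
        if not _gene_known(cells, g):
            raise ValueError(f"gene {g!r} absent from all cells")
    pos, neg = [], []
    for c in cells:
        if c.counts.get(gene_a, 0) >= 1 and c.counts.get(gene_b, 0) >= 1:
            pos.append(c.cell_id)
        else:
            neg.append(c.cell_id)
    return CoexpressionPartition(pos, neg, gene_a, gene_b)


def count_double_positive_in_window(
    cells: Sequence[CellRecord],
    gene_a: str,
    gene_b: str,
    age_lo: float,
    age_hi: float,
) -> int:
    """Number of double-positive cells with age in [age_lo, age_hi)."""
    if not age_lo < age_hi:
        raise ValueError("age_lo must be < age_hi")
    return sum(
        1
        for c in cells
        if age_lo <= c.age < age_hi
        and c.counts.get(gene_a, 0) >= 1
        and c.counts.get(gene_b, 0) >= 1
    )


#: quantile levels reported for the violin-style age summaries
AGE_QUANTILES = (0.0, 0.025, 0.25, 0.5, 0.75, 0.975, 1.0)


def age_distribution_summary(
    partition: CoexpressionPartition, cells: Sequence[CellRecord]
) -> dict[str, dict[str, float]]:
    """Age quantiles (min, 2.5%, 25%, 50%, 75%, 97.5%, max) per group.

    Quantiles use linear interpolation; an empty group is absent from the
    result rather than an error.
    """
    ages = {c.cell_id: c.age for c in cells}
    labels = ("min", "q2.5", "q25", "median", "q75", "q97.5", "max")
    out: dict[str, dict[str, float]] = {}
    for group, ids in (("positive", partition.positive), ("negative", partition.negative)):
        if not ids:
            continue
        vals = np.array([ages[i] for i in ids])
        qs = np.quantile(vals, AGE_QUANTILES, method="linear")
        out[group] = dict(zip(labels, map(float, qs)))
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_cell_table(
    counts_path: str | Path,
    ages_path: str | Path,
) -> list[CellRecord]:
    """Read a cells x genes count TSV (or MatrixMarket triplet) plus a
    two-column cell/age TSV into CellRecords.

    For MatrixMarket input (``.mtx``), row and column names are read from
    sibling files ``<stem>.rows`` (cell ids) and ``<stem>.cols`` (gene
    ids). Cell ids must match one-to-one between counts and ages.
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        from scipy.io import mmread

        mat = mmread(str(counts_path)).tocsr()
        cells_f = counts_path.with_suffix(".rows")
        genes_f = counts_path.with_suffix(".cols")
        cell_ids = cells_f.read_text().split()
        gene_ids = genes_f.read_text().split()
        counts_df = pd.DataFrame.sparse.from_spmatrix(
            mat, index=cell_ids, columns=gene_ids
        ).sparse.to_dense()
    else:
        counts_df = pd.read_csv(counts_path, sep="\t", index_col=0)
    ages_df = pd.read_csv(
        ages_path, sep="\t", header=None, names=["cell", "age"], comment="#"
    )
    # tolerate a header row
    if ages_df.iloc[0]["cell"] in {"cell", "cell_id"}:
        ages_df = ages_df.iloc[1:]
    ages = pd.Series(
        ages_df["age"].astype(float).to_numpy(), index=ages_df["cell"].astype(str)
    )
    count_ids = set(map(str, counts_df.index))
    age_ids = set(ages.index)
    if count_ids != age_ids:
        missing_age = len(count_ids - age_ids)
        missing_counts = len(age_ids - count_ids)
        raise ValueError(
            f"cell id mismatch between counts and ages: {missing_age} cells "
            f"lack an age, {missing_counts} ages lack counts"
        )
    genes = list(map(str, counts_df.columns))
    records = []
    values = counts_df.to_numpy()
    for i, cid in enumerate(map(str, counts_df.index)):
        counts = {g: int(v) for g, v in zip(genes, values[i])}
        records.append(CellRecord(cid, float(ages[cid]), counts))
    return records


def write_cell_table(
    cells: Sequence[CellRecord],
    counts_path: str | Path,
    ages_path: str | Path,
) -> None:
    genes = sorted({g for c in cells for g in c.counts})
    df = pd.DataFrame(
        [[c.counts.get(g, 0) for g in genes] for c in cells],
        index=[c.cell_id for c in cells],
        columns=genes,
    )
    df.index.name = "cell"
    df.to_csv(counts_path, sep="\t")
    with open(ages_path, "w") as fh:
        for c in cells:
            fh.write(f"{c.cell_id}\t{c.age!r}\n")
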