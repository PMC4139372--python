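"""Bipartite ant x plant incidence matrices and their elementary descriptors.

The central object is :class:`InteractionMatrix`: a labelled table of
non-negative interaction counts with ants on the rows and plants on the
columns.  A cell holds the number of tagged plant individuals (out of
``n_individuals_per_plant`` per plant species) on which the ant was
recorded; binarizing it yields the qualitative presence/absence network.

Descriptors follow the standard vocabulary of mutualistic-network
ecology: species degree *k* (number of partner species), connectance
(realized fraction of the I x J possible links, in percent), and web
asymmetry W = (I - J)/(I + J) balancing plant richness I against ant
richness J.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InteractionMatrix",
    "NetworkMetrics",
    "read_matrix",
    "write_matrix",
    "binarize",
    "degree",
    "average_degree",
    "connectance",
    "web_asymmetry",
    "occupancy",
    "full_degree_species",
    "truncate2",
]

Axis = Literal["ants", "plants"]


def truncate2(x: float) -> float:
    """Truncate toward zero at two decimals (reporting convention).

    Printed network tables in this literature truncate rather than round:
    17/35 = 0.4857... is reported as 0.48, and 126/234 as 53.84%.
    """
    return math.trunc(x * 100) / 100


@dataclass(frozen=True)
class InteractionMatrix:
    """Labelled ant x plant count matrix.

    Parameters
    ----------
    ant_labels, plant_labels
        Unique species labels; order fixes the row/column order.
    counts
        Integer array of shape ``(n_ants, n_plants)``, all cells >= 0.
    n_individuals_per_plant
        Number of tagged individuals per plant species (30 in the field
        study); when set, no cell may exceed it.
    period_label
        Free-text tag for the census period (e.g. ``"2009"``).
    """

    ant_labels: tuple[str, ...]
    plant_labels: tuple[str, ...]
    counts: np.ndarray = field(repr=False)
    n_individuals_per_plant: int | None = None
    period_label: str = "combined"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "ant_labels", tuple(self.ant_labels))
        object.__setattr__(self, "plant_labels", tuple(self.plant_labels))
        if counts.shape != (len(self.ant_labels), len(self.plant_labels)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.ant_labels)} ants x {len(self.plant_labels)} plants"
            )
        if counts.shape[0] < 1 or counts.shape[1] < 1:
            raise ValueError("matrix needs at least one row and one column")
        for name, labels in (("ant", self.ant_labels), ("plant", self.plant_labels)):
            if len(set(labels)) != len(labels):
                dupes = sorted({l for l in labels if list(labels).count(l) > 1})
                raise ValueError(f"duplicate {name} labels: {dupes}")
        if (counts < 0).any():
            raise ValueError("negative cell count")
        if self.n_individuals_per_plant is not None:
            cap = int(self.n_individuals_per_plant)
            if cap <= 0:
                raise ValueError("n_individuals_per_plant must be positive")
            if (counts > cap).any():
                raise ValueError(
                    f"cell count exceeds n_individuals_per_plant = {cap}"
                )

    # -- convenience ---------------------------------------------------

    @property
    def n_ants(self) -> int:
        return len(self.ant_labels)

    @property
    def n_plants(self) -> int:
        return len(self.plant_labels)

    @property
    def grand_total(self) -> int:
        """m: total number of recorded associations."""
        return int(self.counts.sum())

    @property
    def n_links(self) -> int:
        """L: number of realized (positive) ant-plant links."""
        return int(np.count_nonzero(self.counts))

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.counts, (0, 1)).all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.ant_labels), columns=list(self.plant_labels)
        )

    def row(self, ant_label: str) -> np.ndarray:
        try:
            i = self.ant_labels.index(ant_label)
        except ValueError:
            raise KeyError(f"unknown ant label: {ant_label!r}") from None
        return self.counts[i]

    def subset_ants(self, keep: Sequence[str]) -> "InteractionMatrix":
        """Restrict to the given ant species, preserving row order."""
        keep_set = set(keep)
        unknown = keep_set - set(self.ant_labels)
        if unknown:
            raise KeyError(f"unknown ant labels: {sorted(unknown)}")
        idx = [i for i, a in enumerate(self.ant_labels) if a in keep_set]
        return replace(
            self,
            ant_labels=tuple(self.ant_labels[i] for i in idx),
            counts=self.counts[idx],
        )


@dataclass
class NetworkMetrics:
    """One-network summary record (the shape of a published metrics table)."""

    period_label: str
    n_ants: int
    n_plants: int
    n_links: int
    n_associations: int
    mean_degree_plants: float
    se_degree_plants: float | None
    mean_degree_ants: float
    se_degree_ants: float | None
    connectance_pct: float
    web_asymmetry: float
    web_asymmetry_abs: float
    h2_prime: float | None = None
    nodf: float | None = None
    nodf_p: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# -- IO ----------------------------------------------------------------


def read_matrix(
    source: str | Path,
    dialect: Literal["matrix", "edgelist"] = "matrix",
    n_individuals_per_plant: int | None = None,
    period_label: str = "combined",
) -> InteractionMatrix:
    """Read an interaction matrix from CSV (matrix) or TSV (edge list).

    Matrix dialect: header ``ant,<plant labels...>``, one row per ant,
    integer cells.  Edge-list dialect: TSV with columns ``ant plant count``;
    duplicate (ant, plant) pairs are summed and missing pairs are zero.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "matrix":
        df = pd.read_csv(path, index_col=0)
        if df.index.has_duplicates:
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise ValueError(f"duplicate ant labels in {path.name}: {dupes}")
        if df.columns.has_duplicates:
            dupes = sorted(df.columns[df.columns.duplicated()].unique())
            raise ValueError(f"duplicate plant labels in {path.name}: {dupes}")
        try:
            counts = df.to_numpy(dtype=np.int64)
        except (ValueError, TypeError):
            bad = df.map(lambda v: not _parses_as_int(v))
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"malformed numeric cell at row {df.index[r]!r}, "
                f"column {df.columns[c]!r} in {path.name}"
            ) from None
        return InteractionMatrix(
            ant_labels=tuple(str(a) for a in df.index),
            plant_labels=tuple(str(p) for p in df.columns),
            counts=counts,
            n_individuals_per_plant=n_individuals_per_plant,
            period_label=period_label,
        )
    elif dialect == "edgelist":
        df = pd.read_csv(path, sep="\t")
        required = {"ant", "plant", "count"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"edge list missing columns: {sorted(missing)}")
        if not pd.api.types.is_numeric_dtype(df["count"]):
            bad = df.loc[~df["count"].map(_parses_as_int)].iloc[0]
            raise ValueError(
                f"malformed count for pair ({bad['ant']!r}, {bad['plant']!r})"
            )
        wide = (
            df.pivot_table(index="ant", columns="plant", values="count", aggfunc="sum")
            .fillna(0)
            .astype(np.int64)
        )
        # pivot_table sorts labels; restore first-appearance order
        wide = wide.reindex(
            index=df["ant"].drop_duplicates(), columns=df["plant"].drop_duplicates()
        )
        return InteractionMatrix(
            ant_labels=tuple(str(a) for a in wide.index),
            plant_labels=tuple(str(p) for p in wide.columns),
            counts=wide.to_numpy(),
            n_individuals_per_plant=n_individuals_per_plant,
            period_label=period_label,
        )
    raise ValueError(f"unknown dialect: {dialect!r}")


def _parses_as_int(v) -> bool:
    try:
        int(v)
        return True
    except (ValueError, TypeError):
        return False


def write_matrix(
    M: InteractionMatrix,
    path: str | Path,
    dialect: Literal["matrix", "edgelist"] = "matrix",
) -> None:
    """Write a matrix in either dialect; round-trips exactly via read_matrix."""
    path = Path(path)
    if dialect == "matrix":
        M.to_frame().rename_axis("ant").to_csv(path)
    elif dialect == "edgelist":
        rows = [
            (a, p, int(M.counts[i, j]))
            for i, a in enumerate(M.ant_labels)
            for j, p in enumerate(M.plant_labels)
            if M.counts[i, j] > 0
        ]
        pd.DataFrame(rows, columns=["ant", "plant", "count"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


# -- descriptors -------------------------------------------------------


def binarize(M: InteractionMatrix) -> InteractionMatrix:
    """Qualitative (presence/absence) matrix: positive cells become 1."""
    return replace(M, counts=(M.counts > 0).astype(np.int64))


def degree(M: InteractionMatrix, axis: Axis) -> np.ndarray:
    """Species degree k: number of partners with a positive count.

    Order follows the axis labels (row order for ants, column order for
    plants).
    """
    if axis == "ants":
        return np.count_nonzero(M.counts, axis=1)
    if axis == "plants":
        return np.count_nonzero(M.counts, axis=0)
    raise ValueError(f"axis must be 'ants' or 'plants', got {axis!r}")


def average_degree(M: InteractionMatrix, axis: Axis) -> tuple[float, float | None]:
    """Mean degree on one axis with its standard error.

    SE is the sample (n-1) standard deviation over sqrt(n species); with a
    single species on the axis the SE is undefined and returned as None.
    """
    k = degree(M, axis)
    mean = float(k.mean())
    if k.size < 2:
        return mean, None
    return mean, float(k.std(ddof=1) / math.sqrt(k.size))


def connectance(M: InteractionMatrix) -> float:
    """Percentage of possible ant-plant links realized: 100 L / (I J)."""
    return 100.0 * M.n_links / (M.n_ants * M.n_plants)


def web_asymmetry(n_plants: int, n_ants: int) -> float:
    """W = (I - J)/(I + J); positive when plants outnumber ants.

    Zero for balanced webs, bounded on [-1, 1].  Published tables print
    the magnitude |W|; use :func:`abs` (and :func:`truncate2` for the
    two-decimal reporting convention) on the returned signed value.
    """
    if n_plants + n_ants == 0:
        raise ValueError("web asymmetry undefined for an empty network")
    return (n_plants - n_ants) / (n_plants + n_ants)


def occupancy(M: InteractionMatrix, ant_label: str) -> float:
    """Percentage of all tagged plant individuals on which an ant occurred.

    Requires ``n_individuals_per_plant``: the denominator is the total
    number of tagged individuals across plant species.
    """
    if M.n_individuals_per_plant is None:
        raise ValueError("occupancy requires n_individuals_per_plant")
    total = int(M.row(ant_label).sum())
    return 100.0 * total / (M.n_plants * M.n_individuals_per_plant)


def full_degree_species(M: InteractionMatrix) -> list[str]:
    """Ant species interacting with every plant species, in row order."""
    k = degree(M, "ants")
    return [a for a, d in zip(M.ant_labels, k) if d == M.n_plants]
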