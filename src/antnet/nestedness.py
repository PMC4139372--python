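"""NODF nestedness and its Monte-Carlo significance under the Ce null model.

NODF (nestedness metric based on overlap and decreasing fill) scores, for
every unordered pair of rows and of columns of a presence/absence matrix,
the percentage of the less-filled line's presences that are shared with
the more-filled line — but only when the two fills strictly differ; equal
fills contribute exactly zero.  The index is the mean of all these paired
overlaps, on a 0–100 scale, with 100 attained by a perfectly nested
matrix with strictly decreasing fills.

Significance is assessed against the probabilistic "Ce" (type II) null
model, in which the probability that ant i interacts with plant j is the
average of the fill proportions of its row and column:

    p_ij = 1/2 (k_i / C + k_j / R)

where k_i and k_j are the observed row/column degrees and R, C the matrix
dimensions.  Summed over all cells this reproduces the observed number of
links L exactly, so the null conserves connectance in expectation while
letting individual degrees vary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import InteractionMatrix, binarize

__all__ = [
    "NullEnsemble",
    "nodf",
    "nodf_from_array",
    "null_ce_probabilities",
    "sample_null",
    "nestedness_significance",
]


@dataclass(frozen=True)
class NullEnsemble:
    """Observed statistic with its Monte-Carlo null distribution."""

    observed: float
    null_values: np.ndarray
    null_mean: float
    null_sd: float
    z: float
    p: float
    seed: int
    n_randomizations: int
    n_degenerate_discarded: int

    def __post_init__(self) -> None:
        if len(self.null_values) != self.n_randomizations:
            raise ValueError("null_values length must equal n_randomizations")


def _as_binary_array(B: InteractionMatrix | np.ndarray) -> np.ndarray:
    if isinstance(B, InteractionMatrix):
        arr = B.counts
    else:
        arr = np.asarray(B)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(
            "NODF is defined on presence/absence matrices; binarize() first"
        )
    return arr.astype(np.int64)


def _pair_overlap_mean_and_count(B: np.ndarray) -> tuple[float, int]:
    """Sum and count of paired overlaps over all unordered row pairs of B."""
    fills = B.sum(axis=1)
    shared = B @ B.T  # shared[i, j] = co-occurrences of rows i and j
    n = B.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    f_i, f_j = fills[iu], fills[ju]
    min_fill = np.minimum(f_i, f_j)
    # decreasing-fill requirement: equal fills score 0; an empty line
    # shares nothing, so guard the 0/0 with the same mask
    valid = (f_i != f_j) & (min_fill > 0)
    overlaps = np.zeros(iu.size)
    overlaps[valid] = 100.0 * shared[iu, ju][valid] / min_fill[valid]
    return float(overlaps.sum()), iu.size


def nodf_from_array(B: np.ndarray) -> float:
    """NODF of a binary numpy array (internal fast path)."""
    if B.shape[0] < 2 or B.shape[1] < 2:
        raise ValueError("NODF needs at least 2 rows and 2 columns")
    row_sum, n_row_pairs = _pair_overlap_mean_and_count(B)
    col_sum, n_col_pairs = _pair_overlap_mean_and_count(B.T)
    return (row_sum + col_sum) / (n_row_pairs + n_col_pairs)


def nodf(B: InteractionMatrix | np.ndarray) -> float:
    """NODF of a binary matrix, in [0, 100]."""
    return nodf_from_array(_as_binary_array(B))


def null_ce_probabilities(B: InteractionMatrix | np.ndarray) -> np.ndarray:
    """Cell probabilities of the Ce (type II) null model.

    p_ij = 1/2 (k_i/C + k_j/R); all values lie in [0, 1] and their sum
    equals the observed link count exactly.
    """
    arr = _as_binary_array(B)
    R, C = arr.shape
    row_deg = arr.sum(axis=1)
    col_deg = arr.sum(axis=0)
    return 0.5 * (row_deg[:, None] / C + col_deg[None, :] / R)


def sample_null(
    probabilities: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """One Bernoulli draw per cell (PCG64 generator), reproducible by seed."""
    p = np.asarray(probabilities, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.random(p.shape) < p).astype(np.int64)


def nestedness_significance(
    B: InteractionMatrix | np.ndarray,
    n_randomizations: int = 1000,
    seed: int = 0,
) -> NullEnsemble:
    """Monte-Carlo significance of NODF under the Ce null model.

    Draws ``n_randomizations`` matrices from the Ce cell probabilities and
    scores each with NODF.  Null matrices with empty rows or columns are
    kept and scored (their empty lines contribute zero overlaps); only the
    count of fully degenerate all-empty draws is reported, and those score
    zero.  The one-tailed p-value uses the add-one rule
    p = (1 + #{null >= observed}) / (1 + n), so p is never exactly zero
    and the smallest reportable value at n = 1000 is < 0.001.
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    arr = _as_binary_array(B)
    observed = nodf_from_array(arr)
    probs = null_ce_probabilities(arr)
    rng = np.random.default_rng(seed)
    null_values = np.empty(n_randomizations)
    n_degenerate = 0
    for r in range(n_randomizations):
        draw = (rng.random(probs.shape) < probs).astype(np.int64)
        if draw.sum() == 0:
            n_degenerate += 1
            null_values[r] = 0.0
        else:
            null_values[r] = nodf_from_array(draw)
    null_mean = float(null_values.mean())
    null_sd = float(null_values.std(ddof=1)) if n_randomizations > 1 else float("nan")
    z = (observed - null_mean) / null_sd if null_sd and null_sd > 0 else float("nan")
    p = (1 + int((null_values >= observed).sum())) / (1 + n_randomizations)
    return NullEnsemble(
        observed=observed,
        null_values=null_values,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        p=float(p),
        seed=seed if isinstance(seed, int) else -1,
        n_randomizations=n_randomizations,
        n_degenerate_discarded=n_degenerate,
    )
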