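"""Network-level specialization H2' from quantitative interaction matrices.

H2' rescales the two-dimensional Shannon entropy of the interaction
proportions p_ij = a_ij / m between the extremes achievable with the
observed marginal totals held fixed:

    H2' = (H2_max - H2) / (H2_max - H2_min)

so 0 means the most generalized network the marginals allow (cells at the
independence values r_i c_j / m) and 1 the most specialized (interactions
concentrated on as few cells as the marginals permit).  Natural
logarithms throughout.

H2_max is the entropy of the continuous independence table, which
separates into marginal entropies H(rows) + H(cols).  H2_min is computed
by the standard greedy concentration heuristic: repeatedly place
min(largest remaining row total, largest remaining column total) in the
corresponding cell and decrement, until the mass is exhausted.  The
greedy table is not guaranteed to be the exact integer minimum, but at
the grand totals typical of field matrices (hundreds of associations)
the discrepancy is negligible; the test suite checks it against
exhaustive enumeration on small tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import InteractionMatrix

__all__ = ["H2Result", "shannon_h2", "h2_bounds", "h2_prime"]

_DEGENERACY_TOL = 1e-9


@dataclass(frozen=True)
class H2Result:
    h2: float
    h2_min: float
    h2_max: float
    h2_prime: float


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy (nats) of a probability vector; zero cells skipped."""
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def shannon_h2(M: InteractionMatrix | np.ndarray) -> float:
    """Two-dimensional Shannon entropy H2 = -sum p_ij ln p_ij."""
    counts = M.counts if isinstance(M, InteractionMatrix) else np.asarray(M)
    m = counts.sum()
    if m <= 0:
        raise ValueError("H2 undefined for an all-zero matrix")
    return _entropy(counts.ravel() / m)


def greedy_min_table(row_totals: np.ndarray, col_totals: np.ndarray) -> np.ndarray:
    """Maximally concentrated table with the given marginals (greedy).

    Ties between equal totals break toward the lowest index.
    """
    r = np.asarray(row_totals, dtype=float).copy()
    c = np.asarray(col_totals, dtype=float).copy()
    table = np.zeros((r.size, c.size))
    while True:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        alloc = min(r[i], c[j])
        if alloc <= 0:
            break
        table[i, j] += alloc
        r[i] -= alloc
        c[j] -= alloc
    return table


def h2_bounds(
    row_totals: np.ndarray, col_totals: np.ndarray
) -> tuple[float, float]:
    """(H2_min, H2_max) achievable with fixed marginal totals.

    H2_max is the entropy of the independence table r_i c_j / m (equal to
    the sum of the two marginal entropies); H2_min the entropy of the
    greedy concentration table.
    """
    r = np.asarray(row_totals, dtype=float)
    c = np.asarray(col_totals, dtype=float)
    m_r, m_c = r.sum(), c.sum()
    if not np.isclose(m_r, m_c):
        raise ValueError(f"marginal totals disagree: rows {m_r}, columns {m_c}")
    if m_r <= 0:
        raise ValueError("bounds undefined for zero total")
    h2_max = _entropy(r / m_r) + _entropy(c / m_c)
    h2_min = _entropy(greedy_min_table(r, c).ravel() / m_r)
    return h2_min, h2_max


def h2_prime(M: InteractionMatrix | np.ndarray) -> H2Result:
    """Network specialization H2' in [0, 1].

    0 = extreme generalization (observed entropy at its marginal-constrained
    maximum), 1 = extreme specialization.  When the marginals leave no room
    (H2_max - H2_min below tolerance) H2' is defined as 0.
    """
    counts = M.counts if isinstance(M, InteractionMatrix) else np.asarray(M)
    h2 = shannon_h2(counts)
    h2_min, h2_max = h2_bounds(counts.sum(axis=1), counts.sum(axis=0))
    spread = h2_max - h2_min
    if spread < _DEGENERACY_TOL:
        prime = 0.0
    else:
        prime = float(np.clip((h2_max - h2) / spread, 0.0, 1.0))
    return H2Result(h2=h2, h2_min=h2_min, h2_max=h2_max, h2_prime=prime)
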