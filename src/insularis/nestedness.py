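"""NODF nestedness and the CE (proportional-proportional) null model.

NODF — nestedness measure based on overlap and decreasing fill — scores a
binary presence/absence matrix between 0 and 100.  After sorting rows and
columns by decreasing marginal totals (stable sort, original order breaks
ties), every ordered pair of columns (u before v) contributes

    0                               if total(u) ≤ total(v) or total(v) = 0
    100 · overlap(u, v) / total(v)  otherwise (paired overlap)

and likewise for row pairs.  NODF-columns and NODF-rows are the means over
column and row pairs; whole-matrix NODF is the grand sum of contributions
divided by the total number of pairs.  The strict decreasing-fill rule
(equal marginals contribute zero) follows the index's canonical definition.

Significance is assessed against the CE null model: each null matrix cell
(i, j) is an independent Bernoulli draw with

    p_ij = ½ · (row_total_i / n_cols + col_total_j / n_rows)

so occupancy probability is proportional to both the species' frequency and
the island's richness.  The expected fill of a null equals the observed
fill.  Effect sizes over ``n`` null matrices with NODF values Ns and
observed value Nr:

    Z  = (Nr − mean(Ns)) / stdev(Ns)     (sample stdev, n−1)
    RN = (Nr − mean(Ns)) / mean(Ns)      ("relative nestedness")

and the p-value is the one-tailed proportion of nulls with NODF ≥ Nr, with
the (k+1)/(n+1) continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_data import IncidenceMatrix
from .errors import UndefinedMatrixError

logger = logging.getLogger(__name__)


def _as_binary_array(m) -> np.ndarray:
    arr = m.values() if isinstance(m, IncidenceMatrix) else np.asarray(m)
    if arr.ndim != 2 or arr.size == 0:
        raise UndefinedMatrixError("NODF needs a nonempty 2-D matrix")
    if not np.isin(arr, (0, 1)).all():
        raise UndefinedMatrixError("NODF is defined for binary matrices only")
    return arr.astype(np.float64)


def _axis_contributions(arr: np.ndarray) -> tuple[float, int]:
    """Sum of paired NODF contributions over ordered row pairs, and pair count."""
    totals = arr.sum(axis=1)
    order = np.argsort(-totals, kind="stable")
    arr = arr[order]
    t = totals[order]
    n = len(t)
    if n < 2:
        return 0.0, 0
    overlap = arr @ arr.T
    iu, iv = np.triu_indices(n, k=1)
    tv = t[iv]
    valid = (t[iu] > tv) & (tv > 0)
    denom = np.where(tv > 0, tv, 1.0)
    contrib = np.where(valid, 100.0 * overlap[iu, iv] / denom, 0.0)
    return float(contrib.sum()), len(iu)


def nodf(m) -> tuple[float, float, float]:
    """(NODF-matrix, NODF-rows, NODF-cols) of a binary matrix.

    Accepts an :class:`IncidenceMatrix` or any binary array-like.  Rows are
    species, columns are islands.  A 1×1 matrix has no pairs and raises
    :class:`UndefinedMatrixError`.
    """
    arr = _as_binary_array(m)
    row_sum, row_pairs = _axis_contributions(arr)
    col_sum, col_pairs = _axis_contributions(arr.T)
    if row_pairs + col_pairs == 0:
        raise UndefinedMatrixError("NODF undefined for a single-row, single-column matrix")
    nodf_rows = row_sum / row_pairs if row_pairs else float("nan")
    nodf_cols = col_sum / col_pairs if col_pairs else float("nan")
    nodf_matrix = (row_sum + col_sum) / (row_pairs + col_pairs)
    return nodf_matrix, nodf_rows, nodf_cols


def ce_probabilities(m) -> np.ndarray:
    """Cell occupancy probabilities of the CE null for a binary matrix."""
    arr = _as_binary_array(m)
    n_rows, n_cols = arr.shape
    row_p = arr.sum(axis=1) / n_cols
    col_p = arr.sum(axis=0) / n_rows
    return np.clip(0.5 * (row_p[:, None] + col_p[None, :]), 0.0, 1.0)


def ce_null(m, n_null: int, seed: int | np.random.Generator = 0) -> list[np.ndarray]:
    """Draw `n_null` CE null matrices (independent Bernoulli cells).

    Null matrices keep the shape of the input; empty rows or columns that
    arise by chance are kept as drawn.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = ce_probabilities(m)
    return [(rng.random(p.shape) < p).astype(np.int8) for _ in range(n_null)]


@dataclass
class NestednessResult:
    """Observed NODF with CE-null effect sizes.

    ``z`` is NaN when the null NODF values have zero variance (degenerate
    matrices); ``rn`` is still reported in that case.
    """

    nodf_matrix: float
    nodf_rows: float
    nodf_cols: float
    null_values: np.ndarray = field(repr=False)
    z: float
    rn: float
    p_value: float
    n_null: int
    seed: int
    n_redrawn: int = 0

    @property
    def nr(self) -> float:
        """Observed whole-matrix NODF (alias)."""
        return self.nodf_matrix


def nestedness_test(m, n_null: int = 100, seed: int = 0) -> NestednessResult:
    """Observed NODF plus Z, RN and p against `n_null` CE null matrices.

    Null draws whose NODF is undefined (possible only for degenerate
    shapes) are redrawn and counted.
    """
    nodf_matrix, nodf_rows, nodf_cols = nodf(m)
    rng = np.random.default_rng(seed)
    p_cells = ce_probabilities(m)
    null_vals = []
    n_redrawn = 0
    while len(null_vals) < n_null:
        null = (rng.random(p_cells.shape) < p_cells).astype(np.int8)
        try:
            null_vals.append(nodf(null)[0])
        except UndefinedMatrixError:
            n_redrawn += 1
            if n_redrawn > 100 * n_null:
                raise
    if n_redrawn:
        logger.info("redrew %d null matrices with undefined NODF", n_redrawn)
    ns = np.asarray(null_vals)
    mean_ns = ns.mean()
    sd_ns = ns.std(ddof=1) if n_null > 1 else 0.0
    if sd_ns > 0:
        z = (nodf_matrix - mean_ns) / sd_ns
    else:
        z = float("nan")
        logger.warning("null NODF distribution has zero variance; Z undefined")
    if nodf_matrix == mean_ns:
        rn = 0.0  # observed equals the null mean (degenerate matrices included)
    elif mean_ns > 0:
        rn = (nodf_matrix - mean_ns) / mean_ns
    else:
        rn = float("nan")
    p = (np.sum(ns >= nodf_matrix) + 1) / (n_null + 1)
    return NestednessResult(nodf_matrix=nodf_matrix, nodf_rows=nodf_rows,
                            nodf_cols=nodf_cols, null_values=ns, z=float(z),
                            rn=float(rn), p_value=float(p), n_null=n_null,
                            seed=seed, n_redrawn=n_redrawn)
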