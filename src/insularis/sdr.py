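"""SDR simplex partitioning of pairwise beta diversity.

For two species sets with richness S_i, S_j, shared count S_ij and pooled
richness S_t = S_i + S_j − S_ij, pairwise beta diversity splits into three
complementary fractions:

    S (similarity)          = S_ij / S_t                (Jaccard)
    D (richness difference) = |S_i − S_j| / S_t
    R (species replacement) = 2·min(S_i − S_ij, S_j − S_ij) / S_t

which sum to 1 exactly, so every pair is a point on a ternary simplex.
The same decomposition applies to one island's two census periods
(cross-temporal similarity), where S_t is the island's cumulative richness
over both periods.

Pairs with S_t = 0 are undefined and are excluded from summaries with a
logged warning rather than coerced to zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import pandas as pd

from .core_data import IncidenceMatrix
from .errors import UndefinedPairError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SDRTriple:
    """One (S, D, R) decomposition; components are fractions summing to 1."""

    similarity: float
    richness_difference: float
    replacement: float
    context: tuple[str, str]

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.similarity, self.richness_difference, self.replacement)


@dataclass(frozen=True)
class SimplexSummary:
    """Mean (S, D, R) over all pairs of a matrix, as percentages."""

    n_pairs: int
    mean_similarity_pct: float
    mean_richness_difference_pct: float
    mean_replacement_pct: float
    matrix_fill_pct: float
    n_undefined: int = 0


def sdr_from_counts(s_i: int, s_j: int, s_ij: int,
                    context: tuple[str, str] = ("a", "b")) -> SDRTriple:
    """Compute the (S, D, R) triple from richness and shared counts."""
    if not (0 <= s_ij <= min(s_i, s_j)):
        raise ValueError(f"shared count {s_ij} inconsistent with richness ({s_i}, {s_j})")
    s_t = s_i + s_j - s_ij
    if s_t == 0:
        raise UndefinedPairError(f"pair {context}: pooled richness is zero")
    return SDRTriple(
        similarity=s_ij / s_t,
        richness_difference=abs(s_i - s_j) / s_t,
        replacement=2 * min(s_i - s_ij, s_j - s_ij) / s_t,
        context=context,
    )


def pairwise_sdr(m: IncidenceMatrix, island_a: str, island_b: str) -> SDRTriple:
    """(S, D, R) for one island pair of an incidence matrix."""
    col_a = m.data[island_a]
    col_b = m.data[island_b]
    s_i = int(col_a.sum())
    s_j = int(col_b.sum())
    s_ij = int((col_a & col_b).sum())
    return sdr_from_counts(s_i, s_j, s_ij, context=(island_a, island_b))


def simplex_table(m: IncidenceMatrix) -> tuple[pd.DataFrame, SimplexSummary]:
    """All-pairs SDR table plus the percentage summary for one matrix.

    One row per unordered island pair; undefined pairs (both islands empty)
    are excluded from the table and the means, and counted in the summary.
    """
    if m.n_islands < 2:
        raise ValueError("simplex table needs at least 2 islands")
    rows = []
    n_undefined = 0
    for a, b in itertools.combinations(m.island_ids, 2):
        try:
            t = pairwise_sdr(m, a, b)
        except UndefinedPairError:
            logger.warning("pair (%s, %s) undefined (no species); excluded from summary", a, b)
            n_undefined += 1
            continue
        rows.append({"island_a": a, "island_b": b, "similarity": t.similarity,
                     "richness_difference": t.richness_difference,
                     "replacement": t.replacement})
    pairs = pd.DataFrame(rows, columns=["island_a", "island_b", "similarity",
                                        "richness_difference", "replacement"])
    summary = SimplexSummary(
        n_pairs=len(pairs),
        mean_similarity_pct=100 * pairs["similarity"].mean(),
        mean_richness_difference_pct=100 * pairs["richness_difference"].mean(),
        mean_replacement_pct=100 * pairs["replacement"].mean(),
        matrix_fill_pct=100 * m.fill,
        n_undefined=n_undefined,
    )
    return pairs, summary


def cross_temporal_sdr(m1: IncidenceMatrix, m2: IncidenceMatrix, island: str) -> SDRTriple:
    """(S, D, R) between one island's floras in two census periods.

    S_t is the island's cumulative richness over both periods and S_ij the
    number of species it hosts in both; S then measures how similar the
    island is to itself across time.
    """
    set1 = m1.species_on(island)
    set2 = m2.species_on(island)
    return sdr_from_counts(len(set1), len(set2), len(set1 & set2),
                           context=(island, f"{m1.period_id}->{m2.period_id}"))


def cross_temporal_table(m1: IncidenceMatrix, m2: IncidenceMatrix,
                         areas: pd.Series | None = None) -> pd.DataFrame:
    """Per-island cross-temporal (S, D, R) with optional island areas joined."""
    rows = []
    for island in m1.island_ids:
        if island not in m1.data.columns or island not in m2.data.columns:
            continue
        try:
            t = cross_temporal_sdr(m1, m2, island)
        except UndefinedPairError:
            logger.warning("island %s empty in both periods; excluded", island)
            continue
        stable, gained, lost = turnover_counts(m1, m2, island)
        rows.append({"island": island, "similarity": t.similarity,
                     "richness_difference": t.richness_difference,
                     "replacement": t.replacement,
                     "stable": stable, "gained": gained, "lost": lost})
    out = pd.DataFrame(rows)
    if areas is not None and not out.empty:
        out.insert(1, "area_km2", out["island"].map(areas))
    return out


def turnover_counts(m1: IncidenceMatrix, m2: IncidenceMatrix,
                    island: str | None = None) -> tuple[int, int, int]:
    """(stable, gained, lost) species counts between two periods.

    With an island id, the counts refer to that island's flora; with
    ``island=None`` they refer to the archipelago-level species sets (union
    over all islands).
    """
    if island is None:
        set1 = set(m1.data.index[m1.data.any(axis=1)])
        set2 = set(m2.data.index[m2.data.any(axis=1)])
    else:
        set1 = m1.species_on(island)
        set2 = m2.species_on(island)
    stable = len(set1 & set2)
    gained = len(set2 - set1)
    lost = len(set1 - set2)
    return stable, gained, lost


def plot_simplex(pairs: pd.DataFrame, path, title: str = "") -> None:
    """Ternary scatter of SDR triples (S top, D lower-left, R lower-right).

    Barycentric coordinates are projected to the plane as
    x = R + S/2, y = S·√3/2, the standard equilateral-triangle embedding.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = pairs["similarity"].to_numpy()
    r = pairs["replacement"].to_numpy()
    x = r + s / 2
    y = s * (3 ** 0.5) / 2
    fig, ax = plt.subplots(figsize=(5, 4.5))
    ax.plot([0, 1, 0.5, 0], [0, 0, 3 ** 0.5 / 2, 0], color="0.3", lw=1)
    ax.scatter(x, y, s=18, alpha=0.7, edgecolor="none")
    ax.text(0.5, 3 ** 0.5 / 2 + 0.03, "S", ha="center", va="bottom")
    ax.text(-0.03, -0.02, "D", ha="right", va="top")
    ax.text(1.03, -0.02, "R", ha="left", va="top")
    ax.set_xlim(-0.1, 1.1)
    ax.set_ylim(-0.1, 1.0)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
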