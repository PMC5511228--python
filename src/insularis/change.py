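"""Richness and composition change between two census periods.

Archipelago-level comparisons (richness per period, shared species, Jaccard
similarity, percentage change, gains and losses), G-tests of compositional
shifts, the inter-period OLS of island richness (period 2 regressed on
period 1, null expectation intercept 0 and slope 1 under a
richness-preserving turnover), and per-island relative change versus area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import xlogy

from .core_data import (
    IslandTable,
    OccurrenceTable,
    SpeciesTraits,
    build_incidence,
    richness_by_island,
)
from .errors import EmptyGroupError, FormatError


def jaccard_from_counts(richness_a: int, richness_b: int, shared: int) -> float:
    """Jaccard similarity of two species sets from their counts."""
    union = richness_a + richness_b - shared
    if union <= 0:
        raise ValueError("pooled richness must be positive")
    return shared / union


def pct_change(before: float, after: float) -> float:
    """Relative change in percent, 100·(after − before)/before."""
    if before == 0:
        raise ValueError("percentage change undefined for a zero baseline")
    return 100.0 * (after - before) / before


@dataclass(frozen=True)
class PeriodComparison:
    """Archipelago-level comparison of one species group across two periods."""

    group: str
    period_1: str
    period_2: str
    richness_p1: int
    richness_p2: int
    shared: int
    gained: int
    lost: int
    jaccard: float
    pct_change: float

    @classmethod
    def from_counts(cls, richness_p1: int, richness_p2: int, shared: int,
                    group: str = "total", period_1: str = "P1",
                    period_2: str = "P2") -> "PeriodComparison":
        """Build a comparison from published/summary counts alone."""
        return cls(group=group, period_1=period_1, period_2=period_2,
                   richness_p1=richness_p1, richness_p2=richness_p2, shared=shared,
                   gained=richness_p2 - shared, lost=richness_p1 - shared,
                   jaccard=jaccard_from_counts(richness_p1, richness_p2, shared),
                   pct_change=pct_change(richness_p1, richness_p2))


def compare_periods(occ: OccurrenceTable, period_1: str, period_2: str,
                    traits: SpeciesTraits | None = None,
                    origin: str | None = None,
                    functional_type: str | None = None) -> PeriodComparison:
    """Archipelago-level richness change for one species group.

    Richness is the size of the union over islands of the period's species
    set, restricted to the requested group.
    """
    set1 = occ.species_set(period_1)
    set2 = occ.species_set(period_2)
    group = "total"
    if origin is not None or functional_type is not None:
        if traits is None:
            raise FormatError("a trait table is required to filter by group")
        keep = traits.select(origin=origin, functional_type=functional_type)
        set1 &= keep
        set2 &= keep
        group = "/".join(x for x in (origin, functional_type) if x is not None)
    if not set1 and not set2:
        raise EmptyGroupError(f"group {group!r} has no species in either period")
    return PeriodComparison.from_counts(len(set1), len(set2), len(set1 & set2),
                                        group=group, period_1=period_1, period_2=period_2)


@dataclass(frozen=True)
class GTestResult:
    """Log-likelihood-ratio (G) test of independence on an r×c count table."""

    g: float
    df: int
    p_value: float
    observed: np.ndarray = field(repr=False)
    expected: np.ndarray = field(repr=False)


def g_test(observed) -> GTestResult:
    """G-test of independence: G = 2·Σ O·ln(O/E), df = (r−1)(c−1).

    Expected counts come from the independence (marginal product) model; a
    zero observed cell contributes 0 (the x·ln x → 0 limit).  The p-value
    uses the χ² approximation without small-sample corrections.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise FormatError("G-test needs an r×c table with r, c >= 2")
    if (obs < 0).any():
        raise FormatError("counts must be non-negative")
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    if (row_tot == 0).any() or (col_tot == 0).any():
        raise FormatError("G-test undefined with a zero row or column marginal")
    expected = np.outer(row_tot, col_tot) / obs.sum()
    g = 2.0 * float(np.sum(xlogy(obs, obs / expected)))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(g, df))
    return GTestResult(g=g, df=df, p_value=p, observed=obs, expected=expected)


@dataclass
class InterPeriodOLS:
    """OLS of period-2 island richness on period-1 richness.

    Under richness-preserving turnover the expectation is intercept 0 and
    slope 1.  ``residual_table`` carries per-island observed, predicted and
    relative residuals (observed − predicted)/predicted.
    """

    intercept: float
    slope: float
    r2: float
    adj_r2: float
    p_value: float
    residual_table: pd.DataFrame = field(repr=False)


def interperiod_regression(richness_p1: pd.Series, richness_p2: pd.Series) -> InterPeriodOLS:
    """Regress per-island period-2 richness on period-1 richness (OLS).

    Both series must be indexed by island id; islands missing from either
    side are dropped.
    """
    joined = pd.concat({"p1": richness_p1, "p2": richness_p2}, axis=1).dropna()
    if len(joined) < 3:
        raise FormatError("inter-period regression needs at least 3 islands")
    x = joined["p1"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise FormatError("zero variance in period-1 richness; regression undefined")
    y = joined["p2"].to_numpy(dtype=float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    predicted = model.predict(sm.add_constant(x))
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(predicted != 0, (y - predicted) / predicted, np.nan)
    table = pd.DataFrame({"island": joined.index, "richness_p1": x.astype(int),
                          "richness_p2": y.astype(int), "predicted": predicted,
                          "residual": y - predicted, "relative_residual": rel})
    return InterPeriodOLS(intercept=float(model.params[0]), slope=float(model.params[1]),
                          r2=float(model.rsquared), adj_r2=float(model.rsquared_adj),
                          p_value=float(model.f_pvalue), residual_table=table)


def relative_change_by_area(occ: OccurrenceTable, islands: IslandTable,
                            period_1: str, period_2: str,
                            traits: SpeciesTraits | None = None,
                            origin: str | None = None,
                            functional_type: str | None = None) -> pd.DataFrame:
    """Per-island relative richness change (%) joined with island area.

    Islands empty in period 1 get NaN change and are flagged undefined.
    """
    m1 = build_incidence(occ, islands, period_1, traits=traits,
                         origin=origin, functional_type=functional_type)
    m2 = build_incidence(occ, islands, period_2, traits=traits,
                         origin=origin, functional_type=functional_type)
    r1 = richness_by_island(m1).set_index("island")["richness"]
    r2 = richness_by_island(m2).set_index("island")["richness"]
    out = pd.DataFrame({"island": islands.island_ids})
    out["area_km2"] = out["island"].map(islands.areas)
    out["richness_p1"] = out["island"].map(r1).fillna(0).astype(int)
    out["richness_p2"] = out["island"].map(r2).fillna(0).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        change = 100.0 * (out["richness_p2"] - out["richness_p1"]) / out["richness_p1"]
    out["relative_change_pct"] = change.replace([np.inf, -np.inf], np.nan)
    out["undefined"] = out["richness_p1"] == 0
    return out


def composition_shares(occ: OccurrenceTable, traits: SpeciesTraits, period: str,
                       classifier: str = "origin") -> dict:
    """Archipelago-level and per-island class shares (%) for one period.

    `classifier` is ``"origin"`` or ``"functional_type"``.  Returns a dict
    with the archipelago-level shares, the per-island share table, and the
    per-island means.
    """
    if classifier not in ("origin", "functional_type"):
        raise FormatError("classifier must be 'origin' or 'functional_type'")
    species = occ.species_set(period)
    if not species:
        raise EmptyGroupError(f"period {period!r} has no species")
    cls = traits.table.set_index("species")[classifier]
    labels = sorted(cls.unique())
    counts = cls.loc[cls.index.intersection(species)].value_counts()
    total = int(counts.sum())
    archipelago = {lab: 100.0 * counts.get(lab, 0) / total for lab in labels}

    sub = occ.records[occ.records["period"] == period]
    per_island_rows = []
    for island, grp in sub.groupby("island"):
        sp = grp["species"]
        known = cls.reindex(sp).dropna()
        n = len(known)
        row = {"island": island, "n_species": n}
        for lab in labels:
            row[lab] = 100.0 * (known == lab).sum() / n if n else np.nan
        per_island_rows.append(row)
    per_island = pd.DataFrame(per_island_rows)
    means = {lab: float(per_island[lab].mean()) for lab in labels} if len(per_island) else {}
    return {"archipelago_pct": archipelago, "per_island": per_island,
            "per_island_mean_pct": means, "n_species": total}


def group_counts(occ: OccurrenceTable, traits: SpeciesTraits, periods: list[str],
                 classifier: str = "origin") -> pd.DataFrame:
    """Class × period count table of archipelago species, for G-tests."""
    cls = traits.table.set_index("species")[classifier]
    labels = sorted(cls.unique())
    data = {}
    for period in periods:
        species = occ.species_set(period)
        counts = cls.loc[cls.index.intersection(species)].value_counts()
        data[period] = [int(counts.get(lab, 0)) for lab in labels]
    return pd.DataFrame(data, index=labels)
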