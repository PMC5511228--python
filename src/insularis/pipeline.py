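"""End-to-end analysis pipeline.

``run_all`` takes a :class:`RunConfig` (loadable from YAML), obtains the
three input tables (from files or from the synthetic generator), and writes
every stage's output as delimited text into the output directory:
incidence matrices, the ISAR parameter table, period-comparison and G-test
reports, the inter-period OLS table, SDR simplex tables and ternary plots,
the cross-temporal SDR-versus-area table, and the nestedness report, plus
one key=value run summary.  Every stochastic step is seeded from the
config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .change import (
    compare_periods,
    composition_shares,
    g_test,
    group_counts,
    interperiod_regression,
    relative_change_by_area,
)
from .core_data import (
    IslandTable,
    OccurrenceTable,
    SpeciesTraits,
    build_incidence,
    load_islands,
    load_occurrences,
    load_traits,
    richness_by_island,
    validate_dataset,
)
from .errors import ConfigError, EmptyGroupError, InsularisError
from .isar import fit_all_groups
from .nestedness import nestedness_test
from .sdr import cross_temporal_table, plot_simplex, simplex_table
from .synthetic import ArchipelagoConfig, generate, truth_report

logger = logging.getLogger(__name__)

GROUP_FILTERS = {
    "total": {},
    "native": {"origin": "native"},
    "alien": {"origin": "alien"},
    "AH": {"functional_type": "AH"},
    "PH": {"functional_type": "PH"},
    "W": {"functional_type": "W"},
}


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Either the three input paths or a ``simulate`` block must be given.
    ``periods`` declares the two census labels in temporal order; the order
    is never inferred from the labels themselves.
    """

    periods: tuple[str, str]
    occurrences: str | None = None
    islands: str | None = None
    traits: str | None = None
    simulate: ArchipelagoConfig | None = None
    groups: tuple[str, ...] = ("total", "native", "alien", "AH", "PH", "W")
    n_null: int = 100
    seed: int = 0
    strict: bool = True
    output_dir: str = "insularis_out"
    plots: bool = True

    def __post_init__(self):
        if len(self.periods) != 2 or self.periods[0] == self.periods[1]:
            raise ConfigError("exactly two distinct period labels are required, in order")
        have_files = all(x is not None for x in (self.occurrences, self.islands, self.traits))
        if not have_files and self.simulate is None:
            missing = [n for n in ("occurrences", "islands", "traits")
                       if getattr(self, n) is None]
            raise ConfigError(f"missing input paths {missing} and no simulate block")
        unknown = set(self.groups) - set(GROUP_FILTERS)
        if unknown:
            raise ConfigError(f"unknown groups: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            for key in ("area_range", "functional_mix", "period_labels"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["simulate"] = ArchipelagoConfig(**sim)
        for key in ("periods", "groups"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            return str(obj)
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)  # hash the analysis, not its destination
        return hashlib.sha256(
            json.dumps(payload, default=enc, sort_keys=True).encode()
        ).hexdigest()[:12]


def _load_inputs(config: RunConfig, outdir: Path):
    if config.simulate is not None:
        occ, islands, traits, truth = generate(config.simulate)
        (outdir / "truth.txt").write_text(truth_report(truth))
        occ.write(outdir / "occurrences.csv")
        islands.write(outdir / "islands.csv")
        traits.write(outdir / "traits.csv")
        return occ, islands, traits
    for name in ("occurrences", "islands", "traits"):
        path = getattr(config, name)
        if not Path(path).exists():
            raise ConfigError(f"missing input file for '{name}': {path}")
    occ = load_occurrences(config.occurrences)
    islands = load_islands(config.islands)
    traits = load_traits(config.traits)
    validate_dataset(occ, islands, traits, strict=config.strict)
    return occ, islands, traits


def _stage(name):
    """Label pipeline-stage failures so a run aborts with context."""
    class _StageContext:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, InsularisError):
                raise InsularisError(f"[stage {name}] {exc}") from exc
            return False
    return _StageContext()


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns the run summary (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "insularis_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "period_1": config.periods[0],
        "period_2": config.periods[1],
    }
    p1, p2 = config.periods

    with _stage("load"):
        occ, islands, traits = _load_inputs(config, outdir)
    summary["n_islands"] = len(islands)
    summary["n_periods"] = 2
    summary["n_species"] = len(occ.species)
    summary["n_occurrences"] = len(occ)

    with _stage("incidence"):
        matrices = {}
        for period in config.periods:
            m = build_incidence(occ, islands, period)
            matrices[period] = m
            m.data.to_csv(outdir / f"incidence_{period}.csv")
            richness_by_island(m).to_csv(outdir / f"richness_{period}.csv", index=False)
            summary[f"richness_{period}"] = m.n_species
            summary[f"matrix_fill_{period}_pct"] = round(100 * m.fill, 4)

    with _stage("isar"):
        isar_table = fit_all_groups(occ, traits, islands, list(config.periods),
                                    groups={g: (GROUP_FILTERS[g].get("origin"),
                                                GROUP_FILTERS[g].get("functional_type"))
                                            for g in config.groups})
        isar_table.to_csv(outdir / "isar_fits.csv", index=False)

    with _stage("change"):
        comp_rows = []
        for group in config.groups:
            try:
                comp = compare_periods(occ, p1, p2, traits=traits, **GROUP_FILTERS[group])
            except EmptyGroupError:
                continue
            comp_rows.append(dataclasses.asdict(comp))
        pd.DataFrame(comp_rows).to_csv(outdir / "period_comparison.csv", index=False)
        gt_rows = []
        for classifier in ("origin", "functional_type"):
            counts = group_counts(occ, traits, list(config.periods), classifier=classifier)
            gt = g_test(counts.to_numpy().T)  # periods as rows
            gt_rows.append({"classifier": classifier, "G": gt.g, "df": gt.df,
                            "p": gt.p_value})
            summary[f"g_{classifier}"] = round(gt.g, 3)
        pd.DataFrame(gt_rows).to_csv(outdir / "g_tests.csv", index=False)

        ols_rows = []
        for group in ("native", "alien"):
            r1 = richness_by_island(build_incidence(
                occ, islands, p1, traits=traits, **GROUP_FILTERS[group])
            ).set_index("island")["richness"]
            r2 = richness_by_island(build_incidence(
                occ, islands, p2, traits=traits, **GROUP_FILTERS[group])
            ).set_index("island")["richness"]
            ols = interperiod_regression(r1, r2)
            ols_rows.append({"group": group, "R2": ols.r2, "AdjR2": ols.adj_r2,
                             "p": ols.p_value, "intercept": ols.intercept,
                             "slope": ols.slope})
            ols.residual_table.merge(islands.table, on="island").to_csv(
                outdir / f"ols_residuals_{group}.csv", index=False)
            relative_change_by_area(occ, islands, p1, p2, traits=traits,
                                    **GROUP_FILTERS[group]).to_csv(
                outdir / f"relative_change_{group}.csv", index=False)
        pd.DataFrame(ols_rows).to_csv(outdir / "interperiod_ols.csv", index=False)

    with _stage("sdr"):
        for period, m in matrices.items():
            pairs, sdr_summary = simplex_table(m)
            pairs.to_csv(outdir / f"sdr_pairs_{period}.csv", index=False)
            summary[f"sdr_mean_similarity_{period}_pct"] = round(
                sdr_summary.mean_similarity_pct, 2)
            summary[f"sdr_mean_richness_difference_{period}_pct"] = round(
                sdr_summary.mean_richness_difference_pct, 2)
            summary[f"sdr_mean_replacement_{period}_pct"] = round(
                sdr_summary.mean_replacement_pct, 2)
            if config.plots:
                plot_simplex(pairs, outdir / f"sdr_simplex_{period}.png",
                             title=f"SDR simplex, {period}")
        ct = cross_temporal_table(matrices[p1], matrices[p2], areas=islands.areas)
        ct.to_csv(outdir / "sdr_cross_temporal.csv", index=False)

    with _stage("nestedness"):
        nest_rows = []
        for i, period in enumerate(config.periods):
            res = nestedness_test(matrices[period], n_null=config.n_null,
                                  seed=config.seed + i)
            nest_rows.append({"period": period, "nodf_matrix": res.nodf_matrix,
                              "nodf_rows": res.nodf_rows, "nodf_cols": res.nodf_cols,
                              "Z": res.z, "RN": res.rn, "p": res.p_value,
                              "n_null": res.n_null, "seed": res.seed})
            summary[f"nodf_{period}"] = round(res.nodf_matrix, 3)
            summary[f"nestedness_z_{period}"] = round(res.z, 3)
            summary[f"nestedness_rn_{period}"] = round(res.rn, 3)
        pd.DataFrame(nest_rows).to_csv(outdir / "nestedness.csv", index=False)

    with _stage("shares"):
        share_rows = []
        for period in config.periods:
            for classifier in ("origin", "functional_type"):
                shares = composition_shares(occ, traits, period, classifier=classifier)
                for label, value in shares["archipelago_pct"].items():
                    share_rows.append({"period": period, "classifier": classifier,
                                       "class": label, "archipelago_pct": value})
        pd.DataFrame(share_rows).to_csv(outdir / "composition_shares.csv", index=False)

    lines = "".join(f"{k}={summary[k]}\n" for k in summary)
    (outdir / "run_summary.txt").write_text(lines)
    logger.info("run complete: %s", outdir)
    return summary
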