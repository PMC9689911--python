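"""End-to-end orchestration: ingest -> counts -> enrichment -> PRS -> regression.

A run is described by a TOML config (all values overridable from the CLI),
executed into an output directory containing the harmonized model, count
tables, the signed enrichment matrix with heatmap, the divergence-filtered
SNP list, per-population expected PRS with bar chart, the regression report
with scatter plots, and a JSON manifest that records versions, seed, the
config hash and every methodological switch in force — enough to rerun the
pipeline identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

import prscape
from prscape import catalog as _catalog
from prscape import enrichment as _enrichment
from prscape import frequencies as _frequencies
from prscape import prs as _prs
from prscape import regression as _regression
from prscape.errors import ConfigError, StageError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    catalog: Path
    out_dir: Path
    vcf: Path | None = None
    sample_map: Path | None = None
    frequency_tables: dict[str, Path] = field(default_factory=dict)
    epidemiology: Path | None = None
    trait_filter: list[str] | None = None
    cutoff: float = 60.0  # divergence threshold; the figure preset uses 100
    pop_pair: tuple[str, str] = ("AFR", "EAS")
    holdout_populations: list[str] = field(default_factory=list)
    default_n: int = 2000
    beta_to_or: bool = True
    seed: int = 0

    def validate(self) -> list[str]:
        errors = []
        if not Path(self.catalog).exists():
            errors.append(f"catalog path does not exist: {self.catalog}")
        if self.vcf is not None and not Path(self.vcf).exists():
            errors.append(f"vcf path does not exist: {self.vcf}")
        if self.vcf is not None and self.sample_map is None:
            errors.append("vcf given without a sample_map")
        if self.sample_map is not None and not Path(self.sample_map).exists():
            errors.append(f"sample_map path does not exist: {self.sample_map}")
        for pop, path in self.frequency_tables.items():
            if not Path(path).exists():
                errors.append(f"frequency table for {pop} does not exist: {path}")
        if self.epidemiology is not None and not Path(self.epidemiology).exists():
            errors.append(f"epidemiology path does not exist: {self.epidemiology}")
        if self.vcf is None and not self.frequency_tables:
            errors.append("need a vcf (+sample_map) or at least one frequency table")
        if not self.cutoff > 0:
            errors.append(f"cutoff must be positive, got {self.cutoff}")
        if len(self.pop_pair) != 2:
            errors.append("pop_pair must name exactly two populations")
        return errors


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run config, reporting *all* errors at once."""
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError([f"unparseable TOML: {exc}"]) from exc
    inputs = raw.get("inputs", {})
    params = raw.get("params", {})
    errors: list[str] = []
    if "catalog" not in inputs:
        errors.append("inputs.catalog is required")
    base = Path(path).parent

    def _path(value: str | None) -> Path | None:
        return None if value is None else base / value

    cfg = RunConfig(
        catalog=_path(inputs.get("catalog", "MISSING")),
        out_dir=_path(raw.get("out_dir", "run")),
        vcf=_path(inputs.get("vcf")),
        sample_map=_path(inputs.get("sample_map")),
        frequency_tables={
            pop: base / p for pop, p in inputs.get("frequency_tables", {}).items()
        },
        epidemiology=_path(inputs.get("epidemiology")),
        trait_filter=params.get("trait_filter"),
        cutoff=float(params.get("cutoff", 60.0)),
        pop_pair=tuple(params.get("pop_pair", ("AFR", "EAS"))),
        holdout_populations=list(params.get("holdout_populations", [])),
        default_n=int(params.get("default_n", 2000)),
        beta_to_or=bool(params.get("beta_to_or", True)),
        seed=int(params.get("seed", 0)),
    )
    errors.extend(cfg.validate())
    if errors:
        raise ConfigError(errors)
    return cfg


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(asdict(cfg), default=str, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _stage(name: str, code: str, out_dir: Path):
    """Context manager: on failure, write a FAILED marker and re-raise as
    a StageError carrying the stage name."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s started", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (out_dir / "FAILED").write_text(f"{name}: {exc}\n")
                raise StageError(name, code, str(exc)) from exc
            logger.info("stage %s finished", name)
            return False

    return _Ctx()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    If no epidemiology table is configured, the regression stage is skipped
    with a logged notice and all upstream outputs are still produced.
    """
    errors = cfg.validate()
    if errors:
        raise ConfigError(errors)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("ingest", "E_INGEST", out):
        parsed = _catalog.parse_gwas_catalog(cfg.catalog, trait_filter=cfg.trait_filter)
        model = _catalog.harmonize_risk_model(
            parsed.associations, beta_to_or=cfg.beta_to_or
        )

    with _stage("counts", "E_COUNTS", out):
        counts_by_pop: dict[str, _frequencies.PopulationAlleleCounts] = {}
        if cfg.vcf is not None:
            sample_map = _frequencies.read_sample_map(cfg.sample_map)
            vcf_counts, _missing = _frequencies.read_vcf_counts(
                cfg.vcf, sample_map, model
            )
            counts_by_pop.update(vcf_counts)
        for pop, path in cfg.frequency_tables.items():
            counts_by_pop[pop] = _frequencies.read_frequency_table(
                path, pop, default_n=cfg.default_n
            )
        available = set()
        for counts in counts_by_pop.values():
            available.update(counts.rsids)
        model, dropped = _catalog.intersect_with_panel(model, available)
        model.to_tsv(out / "risk_model.tsv")
        _frequencies.counts_to_long(counts_by_pop).to_csv(
            out / "counts.tsv", sep="\t", index=False
        )

    with _stage("enrichment", "E_ENRICH", out):
        matrix = _enrichment.build_enrichment_matrix(model, counts_by_pop)
        matrix.scores.rename_axis("rsid").to_csv(out / "enrichment_scores.tsv", sep="\t")
        matrix.to_long().to_csv(out / "enrichment_long.tsv", sep="\t", index=False)
        _enrichment.plot_heatmap(matrix, out / "heatmap.png")
        pop_a, pop_b = cfg.pop_pair
        if pop_a in matrix.populations and pop_b in matrix.populations:
            divergent = _enrichment.divergence_filter(matrix, pop_a, pop_b, cfg.cutoff)
            pd.Series(divergent, name="rsid").to_csv(
                out / "divergent_snps.tsv", sep="\t", index=False
            )
        else:
            divergent = None
            logger.warning(
                "populations %s/%s not in matrix; divergence filter skipped",
                pop_a,
                pop_b,
            )

    with _stage("prs", "E_PRS", out):
        prs_table = _prs.population_prs_table(model, counts_by_pop)
        prs_table.to_csv(out / "population_prs.tsv", sep="\t", index=False)
        _plot_prs_bar(prs_table, out / "prs_bar.png")

    regression_done = False
    if cfg.epidemiology is None:
        logger.info("no epidemiology table configured; regression stage skipped")
    else:
        with _stage("regression", "E_REGRESS", out):
            epi = _regression.read_epidemiology(cfg.epidemiology)
            prs_by_pop = prs_table.set_index("population")["prs"]
            fit_pops = [
                p
                for p in prs_by_pop.index
                if p in epi.index and p not in cfg.holdout_populations
            ]
            report, notes = _regression.covariate_report(
                epi.loc[fit_pops], prs_by_pop.loc[fit_pops]
            )
            report.to_csv(out / "regression_report.tsv", sep="\t", index=False)
            (out / "regression_notes.txt").write_text("\n".join(notes) + "\n")
            predictions = []
            for response in ("incidence", "mortality"):
                fit = _regression.fit_linear(
                    prs_by_pop.loc[fit_pops],
                    epi.loc[fit_pops, response],
                    predictor="PRS",
                    response=response,
                )
                holdout = {}
                for pop in cfg.holdout_populations:
                    if pop not in prs_by_pop.index:
                        continue
                    observed = (
                        float(epi.loc[pop, response]) if pop in epi.index else None
                    )
                    holdout[pop] = (float(prs_by_pop[pop]), observed)
                    predictions.append(
                        {
                            "population": pop,
                            "response": response,
                            "prs": float(prs_by_pop[pop]),
                            "predicted": _regression.predict(fit, prs_by_pop[pop]),
                            "observed": observed,
                        }
                    )
                _regression.plot_fit(
                    fit,
                    prs_by_pop.loc[fit_pops],
                    epi.loc[fit_pops, response],
                    out / f"prs_vs_{response}.png",
                    holdout=holdout or None,
                )
            if predictions:
                pd.DataFrame(predictions).to_csv(
                    out / "holdout_predictions.tsv", sep="\t", index=False
                )
            regression_done = True

    manifest = {
        "package": "prscape",
        "version": prscape.__version__,
        "versions": _library_versions(),
        "seed": cfg.seed,
        "config": json.loads(json.dumps(asdict(cfg), default=str)),
        "config_hash": _config_hash(cfg),
        "model_snps": model.I,
        "snps_dropped_at_intersection": len(dropped),
        "populations": sorted(counts_by_pop),
        "divergence_filter": None
        if divergent is None
        else {"pair": list(cfg.pop_pair), "cutoff": cfg.cutoff, "n_selected": len(divergent)},
        "regression_done": regression_done,
        "flags": {
            "beta_to_or": cfg.beta_to_or,
            "prs_denominator": "2*sum(beta_i)",
            "comparison_pool_excludes_focal": True,
            "fisher_sidedness": "two-sided probability ordering",
            "p_floor": _enrichment.P_FLOOR,
            "clustering": "complete linkage, Euclidean, missing-as-zero",
            "multiple_testing": "none (Bonferroni column informational)",
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _plot_prs_bar(prs_table: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = prs_table.sort_values("prs", ascending=False)
    fig, ax = plt.subplots(figsize=(1 + 0.8 * len(ordered), 4))
    ax.bar(ordered["population"], ordered["prs"], color="tab:gray")
    ax.set_ylabel("expected PRS")
    lo, hi = ordered["prs"].min(), ordered["prs"].max()
    pad = 0.1 * max(hi - lo, 1e-3)
    ax.set_ylim(max(0.0, lo - pad), min(1.0, hi + pad))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _library_versions() -> dict[str, str]:
    import numpy
    import scipy
    import statsmodels

    return {
        "numpy": numpy.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
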