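"""Synthetic study generator with known ground truth.

Emulates the three inputs the pipeline consumes, without any downloads:

* a GWAS-catalog-style association table (lognormal odds ratios, a
  configurable fraction of duplicate-rsid and beta-reporting rows);
* population allele frequencies diverged from a common ancestral frequency
  under the Balding-Nichols model — population frequency
  ~ Beta(p(1-F)/F, (1-p)(1-F)/F), so E = p and Var = F p(1-p) with F the
  population's FST-like divergence;
* diploid Hardy-Weinberg genotype panels (dosage ~ Binomial(2, f)) written
  as a VCF plus sample map, and an epidemiology table generated as a linear
  function of the true population expected PRS plus Gaussian noise.

Every generator is a pure function of (config, seed); per-stage random
streams are derived from the config seed so stages stay reproducible
independently of each other.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class PopulationSpec:
    code: str
    fst: float
    n_samples: int

    def __post_init__(self) -> None:
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")


# 1000GP-phase-3-like preset: five super-populations with unequal sample
# sizes and divergence chosen so AFR and EAS sit at the extremes.
# Illustrative only; F values are not estimates of real human FST per group.
_DEFAULT_POPULATIONS = (
    PopulationSpec("AFR", 0.15, 661),
    PopulationSpec("EAS", 0.10, 504),
    PopulationSpec("EUR", 0.08, 503),
    PopulationSpec("SAS", 0.09, 489),
    PopulationSpec("AMR", 0.11, 347),
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults define the standard conditions.

    Epidemiology rates are on the age-adjusted per-100,000 scale: with the
    default slope/intercept the populations land in the tens-to-~200 range
    and the between-population genetic signal dominates the rate noise.
    """

    n_snps: int = 200
    populations: tuple[PopulationSpec, ...] = _DEFAULT_POPULATIONS
    or_log_sd: float = 0.1
    dup_fraction: float = 0.04
    beta_fraction: float = 0.1
    trait_label: str = "prostate carcinoma"
    epi_slope: float = 1500.0
    epi_intercept: float = -500.0
    mort_slope: float = 400.0
    mort_intercept: float = -140.0
    epi_noise_sd: float = 5.0
    dht_slope: float = 0.2
    dht_intercept: float = 0.02
    dht_noise_sd: float = 0.01
    vitd_slope: float = -100.0
    vitd_intercept: float = 110.0
    vitd_noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.or_log_sd < 0 or self.epi_noise_sd < 0:
            raise ValueError("spread parameters must be non-negative")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


def preset_1000gp_like(seed: int = 0, **overrides) -> SimulationConfig:
    """The five-super-population preset with unequal panel sizes."""
    return SimulationConfig(seed=seed, **overrides)


def _rsids(cfg: SimulationConfig) -> list[str]:
    return [f"rs{1000001 + i}" for i in range(cfg.n_snps)]


def simulate_snp_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Ground-truth SNP annotation: coordinates, alleles and the true mean OR.

    ``effect_is_ref`` records whether the effect allele was planted as the
    VCF REF allele (exercising the allele-flip path in the VCF reader).
    """
    rng = cfg.rng(stage=1)
    effect = rng.choice(_BASES, size=cfg.n_snps)
    other = np.array(
        [rng.choice([b for b in _BASES if b != e]) for e in effect]
    )
    return pd.DataFrame(
        {
            "rsid": _rsids(cfg),
            "chrom": [str(1 + i % 22) for i in range(cfg.n_snps)],
            "pos": [10_000 + 1_000 * i for i in range(cfg.n_snps)],
            "effect_allele": effect,
            "other_allele": other,
            "effect_is_ref": rng.random(cfg.n_snps) < 0.5,
            "true_or": np.exp(rng.normal(0.0, cfg.or_log_sd, size=cfg.n_snps)),
        }
    )


def simulate_catalog(
    cfg: SimulationConfig, snp_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Association rows in NHGRI-EBI download format.

    One base row per SNP plus ``round(dup_fraction * n_snps)`` duplicate-rsid
    rows from a second study; a ``beta_fraction`` of rows report log-OR betas
    (EFFECT_KIND column) instead of ORs, exercising the exp(beta) path.
    """
    if snp_table is None:
        snp_table = simulate_snp_table(cfg)
    rng = cfg.rng(stage=2)
    rows = []
    for i, snp in enumerate(snp_table.itertuples()):
        rows.append(
            {
                "SNPS": snp.rsid,
                "STRONGEST SNP-RISK ALLELE": f"{snp.rsid}-{snp.effect_allele}",
                "CHR_ID": snp.chrom,
                "CHR_POS": snp.pos,
                "OR or BETA": snp.true_or,
                "EFFECT_KIND": "odds_ratio",
                "MAPPED_TRAIT": cfg.trait_label,
                "STUDY ACCESSION": f"GCST{900000 + i}",
            }
        )
    n_dup = int(round(cfg.dup_fraction * cfg.n_snps))
    if n_dup:
        dup_idx = rng.choice(len(snp_table), size=n_dup, replace=False)
        for j, i in enumerate(sorted(dup_idx)):
            snp = snp_table.iloc[i]
            rows.append(
                {
                    "SNPS": snp["rsid"],
                    "STRONGEST SNP-RISK ALLELE": f"{snp['rsid']}-{snp['effect_allele']}",
                    "CHR_ID": snp["chrom"],
                    "CHR_POS": snp["pos"],
                    "OR or BETA": float(np.exp(rng.normal(0.0, cfg.or_log_sd))),
                    "EFFECT_KIND": "odds_ratio",
                    "MAPPED_TRAIT": cfg.trait_label,
                    "STUDY ACCESSION": f"GCST{800000 + j}",
                }
            )
    catalog = pd.DataFrame(rows)
    beta_rows = rng.random(len(catalog)) < cfg.beta_fraction
    catalog.loc[beta_rows, "OR or BETA"] = np.log(
        catalog.loc[beta_rows, "OR or BETA"].astype(float)
    )
    catalog.loc[beta_rows, "EFFECT_KIND"] = "beta"
    return catalog


def simulate_frequencies(
    cfg: SimulationConfig, snp_table: pd.DataFrame | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Balding-Nichols population frequencies of the effect allele.

    Returns the ancestral frequencies (Uniform(0.05, 0.95) per SNP) and a
    rsid x population frame of diverged frequencies drawn from
    Beta(p(1-F)/F, (1-p)(1-F)/F) with each population's own F.
    """
    if snp_table is None:
        snp_table = simulate_snp_table(cfg)
    rng = cfg.rng(stage=3)
    rsids = snp_table["rsid"].tolist()
    ancestral = pd.Series(
        rng.uniform(0.05, 0.95, size=len(rsids)), index=rsids, name="ancestral"
    )
    freqs = {}
    for pop in cfg.populations:
        scale = (1.0 - pop.fst) / pop.fst
        freqs[pop.code] = rng.beta(ancestral * scale, (1.0 - ancestral) * scale)
    return ancestral, pd.DataFrame(freqs, index=rsids)


def balding_nichols_draw(
    p: float, fst: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Replicate draws of a diverged population frequency (for calibration)."""
    scale = (1.0 - fst) / fst
    return rng.beta(p * scale, (1.0 - p) * scale, size=size)


def simulate_dosages(
    freqs: Sequence[float] | np.ndarray,
    n_samples: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """HWE effect-allele dosage panel: (n_samples x n_snps), Binomial(2, f)."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    f = np.asarray(freqs, dtype=float)
    if ((f < 0) | (f > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    return rng.binomial(2, f, size=(n_samples, f.shape[0]))


_GT = np.array(["0/0", "0/1", "1/1"])


def simulate_genotypes(
    freqs: pd.DataFrame,
    populations: Mapping[str, int],
    vcf_path: str | Path,
    sample_map_path: str | Path,
    seed: int,
    snp_table: pd.DataFrame | None = None,
) -> tuple[Path, Path]:
    """Write an HWE genotype panel as a plain VCF plus a sample->population map.

    ``freqs`` is a rsid x population frame of *effect-allele* frequencies;
    ``snp_table`` (from :func:`simulate_snp_table`) supplies coordinates,
    alleles and whether the effect allele is REF. Without it, the effect
    allele is written as ALT of an A>G SNP on sequential chr1 positions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    rsids = freqs.index.tolist()
    if snp_table is not None:
        info = snp_table.set_index("rsid").loc[rsids]
    else:
        info = pd.DataFrame(
            {
                "chrom": "1",
                "pos": [10_000 + 1_000 * i for i in range(len(rsids))],
                "effect_allele": "G",
                "other_allele": "A",
                "effect_is_ref": False,
            },
            index=rsids,
        )

    samples: list[str] = []
    sample_pops: list[str] = []
    for pop, n in populations.items():
        for i in range(n):
            samples.append(f"{pop}_{i:04d}")
            sample_pops.append(pop)

    # dosages of the effect allele per population block
    dosage_blocks = {
        pop: simulate_dosages(freqs[pop].to_numpy(), n, rng)
        for pop, n in populations.items()
    }

    vcf_path, sample_map_path = Path(vcf_path), Path(sample_map_path)
    contigs = sorted(set(info["chrom"].astype(str)), key=lambda c: (len(c), c))
    with open(vcf_path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##source=prscape-simulate\n")
        for contig in contigs:
            out.write(f"##contig=<ID={contig}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        order = info.assign(_pos=info["pos"].astype(int)).sort_values(["chrom", "_pos"])
        for rsid in order.index:
            row = info.loc[rsid]
            j = rsids.index(rsid)
            effect_dos = np.concatenate(
                [dosage_blocks[pop][:, j] for pop in populations]
            )
            if row["effect_is_ref"]:
                ref, alt = row["effect_allele"], row["other_allele"]
                alt_dos = 2 - effect_dos
            else:
                ref, alt = row["other_allele"], row["effect_allele"]
                alt_dos = effect_dos
            gts = "\t".join(_GT[alt_dos])
            out.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{rsid}\t{ref}\t{alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )
    pd.DataFrame({"sample": samples, "population": sample_pops}).to_csv(
        sample_map_path, sep="\t", index=False, header=False
    )
    return vcf_path, sample_map_path


def simulate_epidemiology(
    pop_prs: pd.Series, cfg: SimulationConfig
) -> pd.DataFrame:
    """Epidemiology rates as a linear function of true population PRS.

    incidence = epi_intercept + epi_slope * E[PRS] + N(0, epi_noise_sd),
    mortality analogous with its own slope/intercept; rates are floored at 0.
    DHT:T and vitamin D covariates are coupled to the PRS much more weakly
    than the rates are (their noise dwarfs their slope signal).
    """
    if len(pop_prs) < 3:
        raise ValueError("need at least 3 populations for an epidemiology table")
    rng = cfg.rng(stage=5)
    prs = pop_prs.to_numpy(dtype=float)
    n = len(prs)
    incidence = cfg.epi_intercept + cfg.epi_slope * prs + rng.normal(0, cfg.epi_noise_sd, n)
    mortality = cfg.mort_intercept + cfg.mort_slope * prs + rng.normal(0, cfg.epi_noise_sd, n)
    dht = cfg.dht_intercept + cfg.dht_slope * prs + rng.normal(0, cfg.dht_noise_sd, n)
    vitd = cfg.vitd_intercept + cfg.vitd_slope * prs + rng.normal(0, cfg.vitd_noise_sd, n)
    return pd.DataFrame(
        {
            "population": pop_prs.index,
            "incidence": np.maximum(incidence, 0.0),
            "mortality": np.maximum(mortality, 0.0),
            "dht_t_ratio": np.maximum(dht, 0.0),
            "vit_d": np.maximum(vitd, 0.0),
        }
    )


def simulate_study(cfg: SimulationConfig, out_dir: str | Path) -> dict:
    """Generate a complete synthetic study directory.

    Writes catalog.tsv, per-population frequency tables (freq_<POP>.tsv with
    an allele-number column), genotypes.vcf + samples.tsv, epidemiology.tsv
    and truth.json. The "true" population PRS driving the epidemiology is
    computed from the panel-quantized frequency tables (counts over
    2 x n_samples alleles), i.e. exactly what the frequency-table analysis
    path recovers.
    """
    from prscape.catalog import harmonize_risk_model, parse_gwas_catalog
    from prscape.frequencies import read_frequency_table
    from prscape.prs import population_expected_prs

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    snp_table = simulate_snp_table(cfg)
    catalog = simulate_catalog(cfg, snp_table)
    catalog_path = out / "catalog.tsv"
    catalog.to_csv(catalog_path, sep="\t", index=False)

    ancestral, freqs = simulate_frequencies(cfg, snp_table)
    freq_paths: dict[str, Path] = {}
    for pop in cfg.populations:
        path = out / f"freq_{pop.code}.tsv"
        pd.DataFrame(
            {
                "rsid": freqs.index,
                "eaf": freqs[pop.code].to_numpy(),
                "an": 2 * pop.n_samples,
            }
        ).to_csv(path, sep="\t", index=False)
        freq_paths[pop.code] = path

    vcf_path, sample_map_path = simulate_genotypes(
        freqs,
        {pop.code: pop.n_samples for pop in cfg.populations},
        out / "genotypes.vcf",
        out / "samples.tsv",
        seed=cfg.seed,
        snp_table=snp_table,
    )

    model = harmonize_risk_model(parse_gwas_catalog(catalog_path).associations)
    true_prs = pd.Series(
        {
            pop.code: population_expected_prs(
                model, read_frequency_table(freq_paths[pop.code], pop.code)
            ).value
            for pop in cfg.populations
        }
    )
    epi = simulate_epidemiology(true_prs, cfg)
    epi_path = out / "epidemiology.tsv"
    epi.to_csv(epi_path, sep="\t", index=False)

    truth = {
        "config": {
            **{k: v for k, v in asdict(cfg).items() if k != "populations"},
            "populations": [asdict(p) for p in cfg.populations],
        },
        "true_population_prs": true_prs.to_dict(),
        "ancestral_frequencies_mean": float(ancestral.mean()),
        "files": {
            "catalog": catalog_path.name,
            "vcf": vcf_path.name,
            "sample_map": sample_map_path.name,
            "epidemiology": epi_path.name,
            "frequency_tables": {k: p.name for k, p in freq_paths.items()},
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
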