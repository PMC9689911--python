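"""Per-population effect-allele counts from genotype VCFs or frequency tables.

Counts are stored as integers (effect-allele count / total called haplotype
count) so that downstream exact tests stay well defined. Genotypes are read
with cyvcf2; the VCF's own ploidy encoding is trusted, so a haploid call on
chrX contributes one haplotype and a diploid call two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from prscape.errors import MissingSnpError, PrscapeError, ZeroTotalError

if TYPE_CHECKING:
    from prscape.catalog import RiskModel

logger = logging.getLogger(__name__)

_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass
class PopulationAlleleCounts:
    """Effect-allele counts for one population.

    ``counts`` is indexed by rsid with integer columns ``eac`` (effect allele
    count) and ``tac`` (total called alleles) plus a string ``flags`` column
    (``allele_mismatch``, ``strand_ambiguous``, ``reconstructed_counts``...).
    """

    population: str
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if "flags" not in c.columns:
            c = c.assign(flags="")
        c = c.astype({"eac": np.int64, "tac": np.int64})
        if (c["eac"] < 0).any() or (c["eac"] > c["tac"]).any():
            raise ValueError("need 0 <= eac <= tac for every SNP")
        self.counts = c

    @property
    def rsids(self) -> list[str]:
        return self.counts.index.tolist()

    def frequency(self, rsid: str) -> float:
        return effect_allele_frequency(self, rsid)

    def frequencies(self) -> pd.Series:
        """Effect-allele frequency per SNP (NaN where the total is zero)."""
        with np.errstate(invalid="ignore"):
            f = self.counts["eac"] / self.counts["tac"].replace(0, np.nan)
        return f.rename(self.population)


def read_sample_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> population TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.iloc[0, 0].lower() in {"sample", "sample_id"}:
        df = df.iloc[1:]
    mapping: dict[str, str] = {}
    for sample, pop in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if sample in mapping and mapping[sample] != pop:
            raise PrscapeError(f"sample {sample} mapped to two populations")
        mapping[sample] = pop
    return mapping


def _effect_allele_index(variant, effect_allele: str) -> int | None:
    alleles = [variant.REF] + list(variant.ALT)
    try:
        return alleles.index(effect_allele)
    except ValueError:
        return None


def _is_strand_ambiguous(variant) -> bool:
    if len(variant.ALT) != 1:
        return False
    return {variant.REF, variant.ALT[0]} in _AMBIGUOUS_PAIRS


def _match_model_variants(vcf, model: "RiskModel"):
    """Yield (model row, variant) pairs, matching by ID then by chrom:pos."""
    by_rsid = {row.rsid: row for row in model.table.itertuples()}
    by_pos = {
        (str(row.chrom), int(row.pos)): row
        for row in model.table.itertuples()
        if row.chrom is not None and not pd.isna(row.pos)
    }
    for variant in vcf:
        row = by_rsid.get(variant.ID)
        if row is None:
            row = by_pos.get((str(variant.CHROM).removeprefix("chr"), variant.POS))
        if row is not None:
            yield row, variant


def read_vcf_counts(
    vcf_path: str | Path,
    sample_map: Mapping[str, str],
    model: "RiskModel",
    on_unmapped: Literal["drop", "error"] = "drop",
) -> tuple[dict[str, PopulationAlleleCounts], list[str]]:
    """Count effect alleles per population for every model SNP in a VCF.

    Missing allele calls are excluded from both numerator and denominator.
    A SNP whose effect allele matches neither REF nor ALT is counted as
    0/total and flagged ``allele_mismatch``. Returns the per-population
    counts and the list of model rsids absent from the VCF.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = vcf.samples
    unmapped = [s for s in samples if s not in sample_map]
    if unmapped:
        if on_unmapped == "error":
            raise PrscapeError(f"VCF samples absent from sample map: {unmapped}")
        logger.warning("dropping %d unmapped VCF samples", len(unmapped))

    pop_indices: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        if s in sample_map:
            pop_indices.setdefault(sample_map[s], []).append(i)

    records: dict[str, list[dict]] = {pop: [] for pop in pop_indices}
    seen: set[str] = set()
    for row, variant in _match_model_variants(vcf, model):
        seen.add(row.rsid)
        eff_idx = _effect_allele_index(variant, row.effect_allele)
        flags = []
        if eff_idx is None:
            flags.append("allele_mismatch")
        if _is_strand_ambiguous(variant):
            flags.append("strand_ambiguous")
        genotypes = variant.genotypes  # [a1, a2, phased] or [a1, phased]
        for pop, idxs in pop_indices.items():
            eac = tac = 0
            for i in idxs:
                for call in genotypes[i][:-1]:
                    if call < 0:  # missing allele call
                        continue
                    tac += 1
                    if eff_idx is not None and call == eff_idx:
                        eac += 1
            records[pop].append(
                {"rsid": row.rsid, "eac": eac, "tac": tac, "flags": ",".join(flags)}
            )

    missing = [r for r in model.rsids if r not in seen]
    if missing:
        logger.info("%d model SNPs absent from VCF", len(missing))
    out = {}
    for pop, recs in records.items():
        frame = pd.DataFrame(recs, columns=["rsid", "eac", "tac", "flags"])
        out[pop] = PopulationAlleleCounts(pop, frame.set_index("rsid"))
    return out, missing


def read_vcf_dosages(
    vcf_path: str | Path,
    model: "RiskModel",
    hemizygous: Literal["double", "as_is"] = "double",
) -> pd.DataFrame:
    """Effect-allele dosage matrix (samples x model SNPs) from a VCF.

    Diploid calls give dosages in {0, 1, 2}; a hemizygous (haploid) call
    contributes {0, 2} by default so the PRS keeps its [0, 1] range, or
    {0, 1} with ``hemizygous="as_is"``. Missing calls give NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = vcf.samples
    data: dict[str, np.ndarray] = {}
    for row, variant in _match_model_variants(vcf, model):
        eff_idx = _effect_allele_index(variant, row.effect_allele)
        dos = np.full(len(samples), np.nan)
        for i, g in enumerate(variant.genotypes):
            calls = [c for c in g[:-1] if c >= 0]
            if not calls:
                continue
            d = float(sum(c == eff_idx for c in calls)) if eff_idx is not None else 0.0
            if len(calls) == 1 and hemizygous == "double":
                d *= 2.0
            dos[i] = d
        data[row.rsid] = dos
    frame = pd.DataFrame(data, index=samples)
    return frame.reindex(columns=[r for r in model.rsids if r in frame.columns])


def read_frequency_table(
    path: str | Path,
    population: str,
    default_n: int = 2000,
    columns: Mapping[str, str] | None = None,
) -> PopulationAlleleCounts:
    """Read a pre-aggregated (KRGDB-style) effect-allele frequency TSV.

    Expected columns: ``rsid``, ``eaf`` (effect-allele frequency in [0, 1])
    and optionally ``an`` (allele number). When only frequencies are given,
    integer counts are reconstructed as ``round(eaf * default_n) / default_n``
    and flagged ``reconstructed_counts``.
    """
    cols = {"rsid": "rsid", "eaf": "eaf", "an": "an"}
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype={cols["rsid"]: str})
    for key in ("rsid", "eaf"):
        if cols[key] not in df.columns:
            raise PrscapeError(f"column {cols[key]!r} missing from {path}")
    eaf = df[cols["eaf"]].astype(float)
    if ((eaf < 0) | (eaf > 1)).any():
        bad = df.loc[(eaf < 0) | (eaf > 1), cols["rsid"]].tolist()
        raise PrscapeError(f"frequencies outside [0, 1] for {bad}")
    if cols["an"] in df.columns:
        an = df[cols["an"]].astype(float)
        reconstructed = an.isna()
        an = an.fillna(default_n)
    else:
        an = pd.Series(float(default_n), index=df.index)
        reconstructed = pd.Series(True, index=df.index)
    counts = pd.DataFrame(
        {
            "rsid": df[cols["rsid"]],
            "eac": np.rint(eaf * an).astype(np.int64),
            "tac": an.astype(np.int64),
            "flags": np.where(reconstructed, "reconstructed_counts", ""),
        }
    ).set_index("rsid")
    return PopulationAlleleCounts(population, counts)


def effect_allele_frequency(counts: PopulationAlleleCounts, rsid: str) -> float:
    """Effect-allele frequency ``eac / tac`` for one SNP."""
    if rsid not in counts.counts.index:
        raise MissingSnpError(f"{rsid} absent from population {counts.population}")
    row = counts.counts.loc[rsid]
    if row["tac"] == 0:
        raise ZeroTotalError(
            f"{rsid} has zero called alleles in population {counts.population}"
        )
    return float(row["eac"]) / float(row["tac"])


def pool_counts(
    members: Sequence[PopulationAlleleCounts], population: str | None = None
) -> PopulationAlleleCounts:
    """Sum counts across populations (outer union; absent SNPs contribute 0/0)."""
    if not members:
        raise PrscapeError("cannot pool an empty list of populations")
    frames = [m.counts[["eac", "tac"]] for m in members]
    total = frames[0]
    for f in frames[1:]:
        total = total.add(f, fill_value=0)
    name = population or "+".join(m.population for m in members)
    return PopulationAlleleCounts(name, total.assign(flags=""))


def counts_to_long(counts_by_pop: Mapping[str, PopulationAlleleCounts]) -> pd.DataFrame:
    """Long-format (population, rsid, eac, tac, flags) table for serialization."""
    rows = []
    for pop, counts in counts_by_pop.items():
        frame = counts.counts.reset_index()
        frame.insert(0, "population", pop)
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def counts_from_long(df: pd.DataFrame) -> dict[str, PopulationAlleleCounts]:
    """Inverse of :func:`counts_to_long`."""
    out = {}
    for pop, sub in df.groupby("population", sort=False):
        frame = sub.drop(columns="population").set_index("rsid")
        if "flags" in frame.columns:
            frame["flags"] = frame["flags"].fillna("")
        out[str(pop)] = PopulationAlleleCounts(str(pop), frame)
    return out
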