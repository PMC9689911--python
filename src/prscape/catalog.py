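"""GWAS-catalog ingestion and harmonization into a per-SNP risk model.

An association table (one row per study x SNP association, NHGRI-EBI download
headers by default) is parsed into :class:`SnpAssociation` records, then
collapsed into a :class:`RiskModel`: one entry per unique rsid with a single
positive odds-ratio weight ``beta_i`` (the arithmetic mean of the reported ORs
for that SNP, with reported logistic betas optionally mapped through
``exp(beta)`` so all weights live on the OR scale).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from prscape.errors import CatalogError, DegenerateModelError

logger = logging.getLogger(__name__)

_RSID_RE = re.compile(r"^rs\d+$")

#: Sentinel for an unreported / ambiguous effect allele ("rs123-?" rows).
UNKNOWN_ALLELE = "?"

#: Default column names, matching the NHGRI-EBI GWAS catalog download format.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "rsid": "SNPS",
    "risk_allele": "STRONGEST SNP-RISK ALLELE",
    "effect_size": "OR or BETA",
    "trait": "MAPPED_TRAIT",
    "study": "STUDY ACCESSION",
    "chrom": "CHR_ID",
    "pos": "CHR_POS",
    # Optional: per-row effect-size kind ("odds_ratio" / "beta"). The real
    # catalog does not carry this column; absent it, values are read as ORs.
    "kind": "EFFECT_KIND",
}

EffectSizeKind = Literal["odds_ratio", "beta", "missing"]


@dataclass(frozen=True)
class SnpAssociation:
    """One study-level SNP-trait association row."""

    rsid: str
    chrom: str | None
    pos: int | None
    effect_allele: str  # A/C/G/T or UNKNOWN_ALLELE
    effect_size_kind: EffectSizeKind
    effect_size: float | None
    study_accession: str
    trait_label: str

    def __post_init__(self) -> None:
        if not _RSID_RE.match(self.rsid):
            raise ValueError(f"malformed rsid {self.rsid!r}")
        if self.effect_size_kind == "odds_ratio" and not (
            self.effect_size is not None and self.effect_size > 0
        ):
            raise ValueError(f"{self.rsid}: odds ratio must be positive")


@dataclass
class ParseResult:
    associations: list[SnpAssociation]
    n_dropped: int
    dropped: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class RiskModel:
    """Deduplicated per-SNP risk model with mean-OR weights.

    ``table`` has one row per unique rsid, in first-appearance order, with
    columns rsid, chrom, pos, effect_allele, beta_i, n_studies, flags
    (comma-joined strings such as ``allele_conflict`` or ``no_effect_size``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.table) < 1:
            raise DegenerateModelError("risk model must contain at least one SNP")
        if self.table["rsid"].duplicated().any():
            raise ValueError("risk model rsids must be unique")
        if not (self.table["beta_i"] > 0).all():
            raise ValueError("every beta_i must be positive")
        self.table = self.table.reset_index(drop=True)

    @property
    def I(self) -> int:  # noqa: E743 - the field's symbol for model size
        return len(self.table)

    @property
    def rsids(self) -> list[str]:
        return self.table["rsid"].tolist()

    @property
    def betas(self) -> np.ndarray:
        return self.table["beta_i"].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RiskModel":
        table = pd.read_csv(
            path, sep="\t", dtype={"rsid": str, "chrom": str, "flags": str}
        )
        table["flags"] = table["flags"].fillna("")
        if "pos" not in table.columns:
            table["pos"] = np.nan
        return cls(table)


def _split_risk_allele(value: object) -> tuple[str | None, str]:
    """Split a GWAS-catalog ``rs123-A`` string into (rsid, effect allele)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None, UNKNOWN_ALLELE
    text = str(value).strip()
    rsid, _, allele = text.partition("-")
    rsid = rsid.strip()
    allele = allele.strip().upper()
    if allele not in {"A", "C", "G", "T"}:
        allele = UNKNOWN_ALLELE
    return (rsid if _RSID_RE.match(rsid) else None), allele


def parse_gwas_catalog(
    path: str | Path,
    trait_filter: Iterable[str] | None = None,
    columns: Mapping[str, str] | None = None,
) -> ParseResult:
    """Parse an association TSV into :class:`SnpAssociation` records.

    Rows without a well-formed ``rs\\d+`` identifier (taken from the rsid
    column, falling back to the risk-allele string) are dropped and counted.
    ``trait_filter`` matches trait labels case-insensitively. Missing
    mandatory columns raise :class:`CatalogError` naming the column; so does
    an empty result after filtering.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for key in ("rsid", "risk_allele", "effect_size", "trait"):
        if cols[key] not in df.columns:
            raise CatalogError(f"mandatory column {cols[key]!r} missing from {path}")

    if trait_filter is not None:
        wanted = {t.strip().lower() for t in trait_filter}
        mask = df[cols["trait"]].fillna("").str.strip().str.lower().isin(wanted)
        df = df[mask]

    associations: list[SnpAssociation] = []
    dropped: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        allele_rsid, allele = _split_risk_allele(row.get(cols["risk_allele"]))
        rsid = str(row.get(cols["rsid"], "") or "").strip()
        if not _RSID_RE.match(rsid):
            rsid = allele_rsid or ""
        if not _RSID_RE.match(rsid):
            dropped.append((int(idx), "malformed or absent rsID"))
            continue

        raw = row.get(cols["effect_size"])
        kind_raw = str(row.get(cols["kind"], "") or "").strip().lower()
        effect_size: float | None
        kind: EffectSizeKind
        try:
            effect_size = float(raw)
            if math.isnan(effect_size):
                raise ValueError
        except (TypeError, ValueError):
            effect_size, kind = None, "missing"
        else:
            kind = "beta" if kind_raw == "beta" else "odds_ratio"
        if kind == "odds_ratio" and effect_size is not None and effect_size <= 0:
            dropped.append((int(idx), f"non-positive odds ratio {effect_size}"))
            continue

        chrom = str(row.get(cols["chrom"], "") or "").strip() or None
        pos_raw = str(row.get(cols["pos"], "") or "").strip()
        pos = int(float(pos_raw)) if pos_raw else None
        associations.append(
            SnpAssociation(
                rsid=rsid,
                chrom=chrom,
                pos=pos,
                effect_allele=allele,
                effect_size_kind=kind,
                effect_size=effect_size,
                study_accession=str(row.get(cols["study"], "") or "").strip(),
                trait_label=str(row.get(cols["trait"], "") or "").strip(),
            )
        )

    if dropped:
        logger.warning("dropped %d unusable rows from %s", len(dropped), path)
    if not associations:
        raise CatalogError(f"no usable associations in {path} after filtering")
    return ParseResult(associations, n_dropped=len(dropped), dropped=dropped)


def harmonize_risk_model(
    assocs: Sequence[SnpAssociation],
    beta_to_or: bool = True,
    strict_unknown: bool = False,
) -> RiskModel:
    """Collapse associations into one weighted entry per unique rsid.

    Per rsid, the weight ``beta_i`` is the arithmetic mean of the reported
    odds ratios; logistic betas contribute ``exp(beta)`` when ``beta_to_or``
    is true and are dropped otherwise. Groups with no usable effect size get
    a neutral weight of 1.0 and a ``no_effect_size`` flag. Conflicting effect
    alleles across studies keep the allele from the study whose OR is
    furthest from 1 (flag ``allele_conflict``). Unknown effect alleles are
    retained with an ``unknown_allele`` flag unless ``strict_unknown`` drops
    them.
    """
    if not assocs:
        raise DegenerateModelError("cannot harmonize an empty association list")

    if strict_unknown:
        assocs = [a for a in assocs if a.effect_allele != UNKNOWN_ALLELE]
        if not assocs:
            raise DegenerateModelError("all associations had unknown effect alleles")

    order: list[str] = []
    groups: dict[str, list[SnpAssociation]] = {}
    for a in assocs:
        if a.rsid not in groups:
            groups[a.rsid] = []
            order.append(a.rsid)
        groups[a.rsid].append(a)

    rows = []
    for rsid in order:
        group = groups[rsid]
        ors: list[float] = []
        for a in group:
            if a.effect_size_kind == "odds_ratio":
                ors.append(float(a.effect_size))
            elif a.effect_size_kind == "beta" and beta_to_or:
                ors.append(math.exp(float(a.effect_size)))
        flags: list[str] = []
        if ors:
            beta_i = float(np.mean(ors))
        else:
            beta_i, flags = 1.0, ["no_effect_size"]

        alleles = {a.effect_allele for a in group}
        known = alleles - {UNKNOWN_ALLELE}
        if len(known) > 1:
            # keep the allele backed by the OR furthest from neutral
            def _magnitude(a: SnpAssociation) -> float:
                if a.effect_size_kind == "odds_ratio":
                    return abs(math.log(a.effect_size))
                if a.effect_size_kind == "beta" and a.effect_size is not None:
                    return abs(a.effect_size)
                return -math.inf

            winner = max(
                (a for a in group if a.effect_allele != UNKNOWN_ALLELE),
                key=_magnitude,
            )
            allele = winner.effect_allele
            flags.append("allele_conflict")
        elif known:
            allele = next(iter(known))
        else:
            allele = UNKNOWN_ALLELE
        if allele == UNKNOWN_ALLELE:
            flags.append("unknown_allele")

        chrom = next((a.chrom for a in group if a.chrom), None)
        pos = next((a.pos for a in group if a.pos is not None), None)
        rows.append(
            {
                "rsid": rsid,
                "chrom": chrom,
                "pos": pos,
                "effect_allele": allele,
                "beta_i": beta_i,
                "n_studies": len(group),
                "flags": ",".join(flags),
            }
        )

    model = RiskModel(pd.DataFrame(rows))
    n_flagged = int((model.table["flags"] != "").sum())
    if n_flagged:
        logger.warning("%d of %d model SNPs carry flags", n_flagged, model.I)
    return model


def intersect_with_panel(
    model: RiskModel, available_rsids: Iterable[str]
) -> tuple[RiskModel, list[str]]:
    """Restrict the model to rsids present in a genotype panel.

    Returns the sub-model (input order preserved) and the list of dropped
    rsids; an empty intersection is a hard error.
    """
    available = set(available_rsids)
    keep = model.table["rsid"].isin(available)
    dropped = model.table.loc[~keep, "rsid"].tolist()
    if not keep.any():
        raise DegenerateModelError(
            "no model SNP is present in the panel (empty intersection)"
        )
    if dropped:
        logger.info("panel intersection dropped %d SNPs", len(dropped))
    sub = replace(model, table=model.table[keep].reset_index(drop=True))
    return sub, dropped
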