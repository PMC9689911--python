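"""Normalized polygenic risk score for individuals and populations.

The individual score is PRS = sum_i(beta_i * X_i) / (2 * sum_i(beta_i)),
where X_i in {0, 1, 2} counts copies of the effect allele at SNP i and
beta_i > 0 is the SNP's mean odds-ratio weight. This normalization pins the
score to [0, 1] with the calibration points the model promises: 1 when every
SNP is homozygous for the effect allele, 0 with no effect alleles, and
expectation 0.5 when dosages are uniform on {0, 1, 2} — for *arbitrary*
positive weights. (A literal denominator of 2I, the unweighted SNP count, is
available via ``literal_denominator=True``; it satisfies the calibration
points only when the weights average to 1.)

The population-level expected score substitutes E[X_i] = 2 f_i under
Hardy-Weinberg equilibrium, giving E[PRS] = sum(beta_i f_i) / sum(beta_i)
from allele frequencies alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from prscape.errors import DegenerateModelError
from prscape.frequencies import PopulationAlleleCounts

if TYPE_CHECKING:
    from prscape.catalog import RiskModel


@dataclass(frozen=True)
class PrsValue:
    """A normalized risk score with bookkeeping of contributing SNPs."""

    value: float
    n_used: int
    n_missing: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("PRS value must be finite")


def _as_dosage_array(g: Sequence[float | None] | np.ndarray, I: int) -> np.ndarray:
    x = np.asarray(g, dtype=float)
    if x.shape != (I,):
        raise DegenerateModelError(
            f"genotype vector length {x.shape} does not match model size {I}"
        )
    observed = ~np.isnan(x)
    if not np.isin(x[observed], (0.0, 1.0, 2.0)).all():
        bad = sorted(set(x[observed]) - {0.0, 1.0, 2.0})
        raise ValueError(f"dosages must be 0, 1 or 2 (got {bad})")
    return x


def individual_prs(
    model: "RiskModel",
    genotype: Sequence[float | None] | np.ndarray,
    literal_denominator: bool = False,
) -> PrsValue:
    """Normalized PRS for one individual's dosage vector.

    ``genotype`` is aligned with the model's SNP order; NaN marks a missing
    call. Missing SNPs are excluded from numerator and denominator
    (renormalization). All SNPs missing is an error.
    """
    x = _as_dosage_array(genotype, model.I)
    used = ~np.isnan(x)
    if not used.any():
        raise DegenerateModelError("all genotypes missing; PRS undefined")
    beta = model.betas[used]
    dosage = x[used]
    denom = 2.0 * (used.sum() if literal_denominator else beta.sum())
    return PrsValue(
        value=float(np.dot(beta, dosage) / denom),
        n_used=int(used.sum()),
        n_missing=int(model.I - used.sum()),
    )


def population_expected_prs(
    model: "RiskModel", freqs: PopulationAlleleCounts
) -> PrsValue:
    """Expected PRS of a population from its effect-allele frequencies.

    Under HWE, E[X_i] = 2 f_i, so E[PRS] = sum(beta_i f_i) / sum(beta_i).
    Model SNPs without a frequency (absent or zero-total) are excluded from
    both sums.
    """
    f = freqs.frequencies().reindex(model.rsids)
    used = f.notna().to_numpy()
    if not used.any():
        raise DegenerateModelError(
            f"no model SNP has a frequency in population {freqs.population}"
        )
    beta = model.betas[used]
    value = float(np.dot(beta, f.to_numpy(dtype=float)[used]) / beta.sum())
    return PrsValue(value=value, n_used=int(used.sum()), n_missing=int(model.I - used.sum()))


def panel_mean_prs(
    model: "RiskModel",
    genotypes: pd.DataFrame | np.ndarray,
    literal_denominator: bool = False,
) -> float:
    """Mean individual PRS over a panel (rows = individuals).

    A DataFrame is aligned to the model by column name; missing model SNPs
    become missing calls for every individual.
    """
    if isinstance(genotypes, pd.DataFrame):
        matrix = genotypes.reindex(columns=model.rsids).to_numpy(dtype=float)
    else:
        matrix = np.asarray(genotypes, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise DegenerateModelError("panel must contain at least one individual")
    values = [
        individual_prs(model, matrix[i], literal_denominator=literal_denominator).value
        for i in range(matrix.shape[0])
    ]
    return float(np.mean(values))


def population_prs_table(
    model: "RiskModel", counts_by_pop: Mapping[str, PopulationAlleleCounts]
) -> pd.DataFrame:
    """Expected PRS per population as a tidy frame (population, prs, n_used,
    n_missing), in input order."""
    rows = []
    for pop, counts in counts_by_pop.items():
        v = population_expected_prs(model, counts)
        rows.append(
            {
                "population": pop,
                "prs": v.value,
                "n_used": v.n_used,
                "n_missing": v.n_missing,
            }
        )
    return pd.DataFrame(rows)
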