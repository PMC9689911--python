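"""Signed -log10 Fisher exact enrichment scores per SNP and population.

Each population's effect-allele count at a SNP is exact-tested against the
pooled counts of the *other* populations (a valid 2x2 test needs disjoint
groups, so the comparison pool excludes the focal population; with several
super-populations the pooled frequency differs negligibly from the global
one). The score is -log10(p) when the focal frequency exceeds the pool's,
+log10(p) (negative) when it is below, and 0 when the two proportions are
equal — so the score's sign encodes enrichment vs depletion and its
magnitude the exact-test evidence.

The two-sided p-value follows the conventional probability-ordering
definition: the sum of hypergeometric probabilities of all tables with the
observed margins whose probability does not exceed the observed table's
(with a 1e-7 relative tie tolerance, as in R's fisher.test). It is computed
from log-space pmf values so large allele counts stay stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.special import gammaln, logsumexp

from prscape.errors import UntestableTableError
from prscape.frequencies import PopulationAlleleCounts, pool_counts

if TYPE_CHECKING:
    from prscape.catalog import RiskModel

logger = logging.getLogger(__name__)

#: p-values are floored here before taking log10, capping |score| at 300.
P_FLOOR = 1e-300

#: Relative tolerance for probability ties in the two-sided sum.
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Allele-count table: focal population (row 1) vs comparison pool (row 2),
    effect allele (column 1) vs non-effect (column 2)."""

    a: int  # focal, effect
    b: int  # focal, non-effect
    c: int  # rest, effect
    d: int  # rest, non-effect

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def focal_total(self) -> int:
        return self.a + self.b

    @property
    def rest_total(self) -> int:
        return self.c + self.d

    @property
    def testable(self) -> bool:
        return self.focal_total > 0 and self.rest_total > 0

    @property
    def focal_freq(self) -> float:
        return self.a / self.focal_total

    @property
    def rest_freq(self) -> float:
        return self.c / self.rest_total


@dataclass
class EnrichmentMatrix:
    """SNP x population matrix of signed scores, with raw p-values alongside.

    Untestable cells are NaN. ``metadata`` records the sign convention and
    every methodological switch in force.
    """

    scores: pd.DataFrame
    pvalues: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def rsids(self) -> list[str]:
        return self.scores.index.tolist()

    @property
    def populations(self) -> list[str]:
        return self.scores.columns.tolist()

    def to_long(self) -> pd.DataFrame:
        """Long-format table with score, raw p and a Bonferroni column.

        The Bonferroni-adjusted p is informational only; no filtering in the
        package uses it.
        """
        n_tests = int(self.pvalues.notna().sum().sum())
        long = (
            self.scores.stack()
            .rename("score")
            .to_frame()
            .join(self.pvalues.stack().rename("p_value"))
            .reset_index()
        )
        long.columns = ["rsid", "population", "score", "p_value"]
        long["p_bonferroni"] = np.minimum(long["p_value"] * n_tests, 1.0)
        return long


def build_contingency(
    focal: PopulationAlleleCounts, pooled_rest: PopulationAlleleCounts, rsid: str
) -> ContingencyTable2x2:
    """2x2 allele-count table for one SNP; the pool must exclude the focal
    population. Raises :class:`UntestableTableError` on a zero total."""
    fa, ft = (int(focal.counts.at[rsid, "eac"]), int(focal.counts.at[rsid, "tac"]))
    ra, rt = (
        int(pooled_rest.counts.at[rsid, "eac"]),
        int(pooled_rest.counts.at[rsid, "tac"]),
    )
    if ft == 0 or rt == 0:
        raise UntestableTableError(
            f"{rsid}: zero total alleles in {'focal' if ft == 0 else 'comparison'} group"
        )
    return ContingencyTable2x2(fa, ft - fa, ra, rt - ra)


def _log_hypergeom_pmf(k: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(n=r1+r2, K=c1, draws=r1)."""
    n = r1 + r2
    return (
        gammaln(r1 + 1)
        - gammaln(k + 1)
        - gammaln(r1 - k + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - k + 1)
        - gammaln(r2 - (c1 - k) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_two_sided_p(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by probability ordering, in log space."""
    if not t.testable:
        raise UntestableTableError("both row totals must be positive")
    r1, r2, c1 = t.focal_total, t.rest_total, t.a + t.c
    n = r1 + r2
    if c1 == 0 or c1 == n:
        return 1.0
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logp = _log_hypergeom_pmf(k, r1, r2, c1)
    log_obs = logp[t.a - k[0]]
    keep = logp <= log_obs + _TIE_RTOL
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def signed_score(t: ContingencyTable2x2, p: float | None = None) -> float:
    """Signed -log10 p: positive for enrichment of the effect allele in the
    focal population, negative for depletion, 0 at equal proportions."""
    if p is None:
        p = fisher_two_sided_p(t)
    ff, rf = t.focal_freq, t.rest_freq
    if ff == rf:
        return 0.0
    magnitude = -np.log10(max(p, P_FLOOR)) + 0.0  # +0.0 normalizes -0.0
    return float(magnitude if ff > rf else -magnitude)


def build_enrichment_matrix(
    model: "RiskModel", counts_by_pop: Mapping[str, PopulationAlleleCounts]
) -> EnrichmentMatrix:
    """Score every (model SNP, population) pair against the leave-one-out pool."""
    pops = list(counts_by_pop)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations to build an enrichment matrix")
    rsids = [r for r in model.rsids]
    scores = pd.DataFrame(np.nan, index=rsids, columns=pops)
    pvals = pd.DataFrame(np.nan, index=rsids, columns=pops)
    for pop in pops:
        focal = counts_by_pop[pop]
        rest = pool_counts(
            [counts_by_pop[q] for q in pops if q != pop], population=f"rest-of({pop})"
        )
        for rsid in rsids:
            if rsid not in focal.counts.index or rsid not in rest.counts.index:
                continue
            try:
                table = build_contingency(focal, rest, rsid)
                p = fisher_two_sided_p(table)
            except UntestableTableError:
                continue
            pvals.at[rsid, pop] = p
            scores.at[rsid, pop] = signed_score(table, p)
    n_missing = int(scores.isna().sum().sum())
    if n_missing:
        logger.info("%d untestable or missing matrix cells", n_missing)
    metadata = {
        "sign_convention": "positive = effect allele enriched vs pool",
        "comparison_pool": "all populations except the focal one",
        "sidedness": "two-sided, probability ordering",
        "p_floor": P_FLOOR,
        "multiple_testing": "none applied; Bonferroni column emitted for information",
    }
    return EnrichmentMatrix(scores, pvals, metadata)


def divergence_filter(
    m: EnrichmentMatrix, pop_a: str, pop_b: str, cutoff: float
) -> list[str]:
    """SNPs whose |score| in two populations sums strictly above ``cutoff``.

    With pop_a=AFR, pop_b=EAS this selects the most strongly diverged risk
    SNPs (|AFR| + |EAS| > cutoff); untestable cells disqualify a SNP.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    for pop in (pop_a, pop_b):
        if pop not in m.populations:
            raise KeyError(f"population {pop} not in matrix")
    total = m.scores[pop_a].abs() + m.scores[pop_b].abs()
    return total.index[total > cutoff].tolist()


def cluster_order(m: EnrichmentMatrix) -> tuple[list[int], list[int]]:
    """Leaf orders from complete-linkage Euclidean hierarchical clustering of
    rows and columns (missing cells imputed as 0 for ordering only)."""
    X = m.scores.fillna(0.0).to_numpy(dtype=float)

    def _order(matrix: np.ndarray) -> list[int]:
        if matrix.shape[0] < 2:
            return list(range(matrix.shape[0]))
        return leaves_list(linkage(matrix, method="complete", metric="euclidean")).tolist()

    return _order(X), _order(X.T)


def plot_heatmap(
    m: EnrichmentMatrix,
    path: str | Path,
    max_rows: int | None = 100,
) -> None:
    """Clustered heatmap, red = enriched, blue = depleted, white = 0.

    When the matrix has more than ``max_rows`` SNPs, the rows with the
    largest total |score| are shown.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = m.scores
    if max_rows is not None and len(scores) > max_rows:
        top = scores.abs().sum(axis=1).nlargest(max_rows).index
        scores = scores.loc[top]
        m = EnrichmentMatrix(scores, m.pvalues.loc[top], m.metadata)
    row_order, col_order = cluster_order(m)
    ordered = scores.iloc[row_order, col_order]
    vmax = float(np.nanmax(np.abs(ordered.to_numpy()))) or 1.0
    fig, ax = plt.subplots(figsize=(2 + 0.5 * len(ordered.columns), 6))
    im = ax.imshow(
        ordered.fillna(0.0).to_numpy(),
        aspect="auto",
        cmap="bwr",
        vmin=-vmax,
        vmax=vmax,
        interpolation="nearest",
    )
    ax.set_xticks(range(len(ordered.columns)), ordered.columns, rotation=90)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(ordered)} SNPs (clustered)")
    fig.colorbar(im, ax=ax, label="signed $-\\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
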