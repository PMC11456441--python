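"""Burden and carrier association testing.

Two analyses are provided, mirroring a standard rare-variant case-control
workflow:

* **Per-individual burden** — each individual's count of qualifying
  (rare, deleterious) variants, compared between cases and controls with a
  one-tailed two-sample test.  The test is selected adaptively: Student's
  t when both groups look normal (Shapiro-Wilk) with homogeneous variances
  (Levene), Welch's t when normal with unequal variances, Mann-Whitney U
  otherwise.  The alternative is always "cases exceed controls".

* **Carrier association** — at the variant level, a 2x2 table of carriers
  vs non-carriers in cases and controls; at the gene level, the same table
  after collapsing (an individual is a gene carrier when they carry any
  qualifying variant of the gene).  Enrichment in cases is assessed with a
  one-tailed Fisher exact test (the hypergeometric upper tail), and raw
  p-values receive both Benjamini-Hochberg and Bonferroni adjustment
  within each analysis level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import MISSING, GenotypeMatrix, VariantRecord

__all__ = [
    "ContingencyTable",
    "TestSelection",
    "BurdenResult",
    "AssociationResult",
    "individual_burden",
    "select_burden_test",
    "burden_test",
    "carrier_table",
    "fisher_one_tailed",
    "adjust_pvalues",
    "run_association",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier / non-carrier counts in cases and controls."""

    case_carriers: int
    case_noncarriers: int
    control_carriers: int
    control_noncarriers: int

    def __post_init__(self) -> None:
        cells = (
            self.case_carriers,
            self.case_noncarriers,
            self.control_carriers,
            self.control_noncarriers,
        )
        if any(c < 0 for c in cells):
            raise ValueError(f"contingency counts must be nonnegative, got {cells}")

    @property
    def n_cases(self) -> int:
        return self.case_carriers + self.case_noncarriers

    @property
    def n_controls(self) -> int:
        return self.control_carriers + self.control_noncarriers

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls


@dataclass(frozen=True)
class TestSelection:
    """Adaptive-test decision: which test, and the p-values that drove it.

    Normality is assessed per group with Shapiro-Wilk and variance
    homogeneity with Levene's test, each at ``alpha``.  ``chosen`` follows
    the decision table: both groups normal + homogeneous -> ``student_t``;
    both normal + heterogeneous -> ``welch_t``; otherwise ``mann_whitney``.
    """

    chosen: str
    normality_p_case: float
    normality_p_control: float
    variance_p: float
    alpha: float = 0.05


@dataclass(frozen=True)
class BurdenResult:
    """Group burden distributions plus the one-tailed test outcome."""

    case_counts: tuple[int, ...]
    control_counts: tuple[int, ...]
    selection: TestSelection
    statistic: float
    p_one_tailed: float

    @property
    def case_mean(self) -> float:
        return float(np.mean(self.case_counts))

    @property
    def control_mean(self) -> float:
        return float(np.mean(self.control_counts))


@dataclass(frozen=True)
class AssociationResult:
    """One tested unit (variant or gene) with raw and adjusted p-values."""

    unit_id: str
    level: str
    table: ContingencyTable
    p_fisher: float
    p_bh: float
    p_bonf: float


def individual_burden(
    matrix: GenotypeMatrix,
    qualifying_variants: Iterable[str],
    mode: str = "variants",
) -> np.ndarray:
    """Per-sample count of qualifying variants carried.

    ``variants`` mode counts each carried variant once (dosage >= 1);
    ``alleles`` mode sums alt-allele dosages.  Missing genotypes count 0.
    """
    if mode not in ("variants", "alleles"):
        raise ValueError(f"mode must be 'variants' or 'alleles', got {mode!r}")
    ids = list(qualifying_variants)
    idx = [matrix.variant_index(v) for v in ids]  # raises on unknown id
    if not idx:
        return np.zeros(matrix.n_samples, dtype=np.int64)
    g = matrix.genotypes[:, idx].astype(np.int64)
    g[g == MISSING] = 0
    if mode == "variants":
        return (g >= 1).sum(axis=1)
    return g.sum(axis=1)


def select_burden_test(
    case_counts: Sequence[float],
    control_counts: Sequence[float],
    alpha: float = 0.05,
) -> TestSelection:
    """Pick the two-sample test per the normality/variance decision table."""
    case = np.asarray(case_counts, dtype=float)
    control = np.asarray(control_counts, dtype=float)
    if len(case) < 3 or len(control) < 3:
        raise ValueError("need at least 3 samples per group to assess normality")

    if np.ptp(case) == 0 and np.ptp(control) == 0:
        logger.warning("both groups have zero variance; falling back to Mann-Whitney")
        return TestSelection("mann_whitney", 0.0, 0.0, 1.0, alpha)

    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return 0.0  # a constant sample is treated as non-normal
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(stats.shapiro(x).pvalue)

    p_case = _shapiro_p(case)
    p_control = _shapiro_p(control)
    p_var = float(stats.levene(case, control).pvalue)

    if p_case > alpha and p_control > alpha:
        chosen = "student_t" if p_var > alpha else "welch_t"
    else:
        chosen = "mann_whitney"
    return TestSelection(chosen, p_case, p_control, p_var, alpha)


def burden_test(
    case_counts: Sequence[float],
    control_counts: Sequence[float],
    selection: Optional[TestSelection] = None,
    alpha: float = 0.05,
) -> BurdenResult:
    """One-tailed test of "case burdens exceed control burdens"."""
    case = np.asarray(case_counts, dtype=float)
    control = np.asarray(control_counts, dtype=float)
    if len(case) == 0 or len(control) == 0:
        raise ValueError("both groups must be nonempty")
    if selection is None:
        selection = select_burden_test(case, control, alpha)

    if selection.chosen in ("student_t", "welch_t"):
        res = stats.ttest_ind(
            case, control, equal_var=(selection.chosen == "student_t"), alternative="greater"
        )
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        stat, p = _mann_whitney_greater(case, control)

    # guard the open-interval contract: p in (0, 1]
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return BurdenResult(
        tuple(case_counts), tuple(control_counts), selection, stat, p
    )


def _mann_whitney_greater(case: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U, alternative case > control.

    Exact enumeration when both groups have <= 20 observations and no ties;
    otherwise the normal approximation with tie correction.
    """
    pooled = np.concatenate([case, control])
    if np.ptp(pooled) == 0:
        logger.warning("all burden values tied; Mann-Whitney p set to 1")
        u = len(case) * len(control) / 2.0
        return u, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(case), len(control)) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(case, control, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def carrier_table(
    matrix: GenotypeMatrix,
    variant_ids: Iterable[str],
    unit_id: str = "",
    mode: str = "carriers",
) -> ContingencyTable:
    """2x2 carrier table for one unit (a variant, or a gene's variant set).

    ``carriers`` mode (collapsing, default) counts an individual once if
    they carry any of the unit's variants.  ``alleles`` mode counts alt
    alleles rather than individuals, which inflates the margins for
    multi-variant units; it is provided for the gene-level tally variant
    of the analysis.
    """
    ids = list(variant_ids)
    if not ids:
        raise ValueError(f"unit {unit_id!r} has no qualifying variants")
    if mode not in ("carriers", "alleles"):
        raise ValueError(f"mode must be 'carriers' or 'alleles', got {mode!r}")
    idx = [matrix.variant_index(v) for v in ids]
    g = matrix.genotypes[:, idx].astype(np.int64)
    g[g == MISSING] = 0
    case_mask = matrix.group_mask("case")
    control_mask = matrix.group_mask("control")
    if mode == "carriers":
        carries = (g >= 1).any(axis=1)
        cc = int(carries[case_mask].sum())
        uc = int(carries[control_mask].sum())
        return ContingencyTable(
            cc, int(case_mask.sum()) - cc, uc, int(control_mask.sum()) - uc
        )
    alleles = g.sum(axis=1)
    cc = int(alleles[case_mask].sum())
    uc = int(alleles[control_mask].sum())
    return ContingencyTable(
        cc, 2 * len(ids) * int(case_mask.sum()) - cc,
        uc, 2 * len(ids) * int(control_mask.sum()) - uc,
    )


def fisher_one_tailed(table: ContingencyTable) -> float:
    """Exact upper-tail probability of the observed case-carrier count.

    With margins fixed, the case-carrier count follows a hypergeometric
    distribution (population ``total``, ``K`` total carriers, ``n_cases``
    draws); the p-value is P(X >= case_carriers).  Degenerate margins give 1.
    """
    K = table.case_carriers + table.control_carriers
    if table.total == 0 or table.case_carriers == 0:
        return 1.0
    p = stats.hypergeom.sf(
        table.case_carriers - 1, table.total, K, table.n_cases
    )
    return float(min(p, 1.0))


def adjust_pvalues(ps: Sequence[float], method: str) -> np.ndarray:
    """Benjamini-Hochberg (``bh``) or Bonferroni adjustment, order-preserving."""
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        return ps.copy()
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(ps, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(1.0, ps * ps.size)
    raise ValueError(f"method must be 'bh' or 'bonferroni', got {method!r}")


def run_association(
    matrix: GenotypeMatrix,
    records: Sequence[VariantRecord] | Mapping[str, str],
    level: str = "variant",
    qualifying_variants: Optional[Iterable[str]] = None,
    mode: str = "carriers",
) -> list[AssociationResult]:
    """Carrier association over all units at one level, with both corrections.

    ``records`` supplies the variant -> gene assignment (a list of
    :class:`VariantRecord` or a mapping).  ``qualifying_variants`` restricts
    the analysis; by default every variant present in the matrix is tested.
    BH and Bonferroni are applied within this level's family of tests.
    """
    if level not in ("variant", "gene"):
        raise ValueError(f"level must be 'variant' or 'gene', got {level!r}")
    if isinstance(records, Mapping):
        gene_of = dict(records)
    else:
        gene_of = {r.variant_id: r.gene for r in records}
    qualifying = [
        v for v in (qualifying_variants if qualifying_variants is not None else matrix.variant_ids)
        if v in set(matrix.variant_ids)
    ]
    if level == "variant":
        units = [(v, [v]) for v in qualifying]
    else:
        by_gene: dict[str, list[str]] = {}
        for v in qualifying:
            by_gene.setdefault(gene_of[v], []).append(v)
        units = sorted(by_gene.items())

    if not units:
        return []
    tables = [carrier_table(matrix, vids, unit_id=u, mode=mode) for u, vids in units]
    raw = [fisher_one_tailed(t) for t in tables]
    bh = adjust_pvalues(raw, "bh")
    bonf = adjust_pvalues(raw, "bonferroni")
    return [
        AssociationResult(u, level, t, p, float(b), float(bf))
        for (u, _), t, p, b, bf in zip(units, tables, raw, bh, bonf)
    ]
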