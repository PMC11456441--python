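"""Case-exclusivity screening, prevalence comparison, category and overlap reports.

The exclusivity screen retains rare-deleterious variants carried by at
least one affected individual and by nobody in a configured set of
comparison groups (for a family-structured cohort: controls, siblings,
fathers and mothers; for a plain case-control cohort: controls only).
Category summaries aggregate deleterious variants over the pathway
catalog's functional classes; set-overlap and cross-reference operations
treat externally supplied gene lists (e.g. virtual-knockout perturbed-gene
sets) as plain symbol sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import ContingencyTable, fisher_one_tailed
from .data_model import MISSING, GenotypeMatrix, GeneCatalogEntry, VariantRecord

__all__ = [
    "ExclusivityPolicy",
    "ExclusiveVariantReport",
    "CategorySummary",
    "OverlapSummary",
    "exclusivity_screen",
    "exclusivity_screen_counts",
    "carrier_prevalence",
    "category_summary",
    "set_overlap",
    "cross_reference",
    "load_exclusive_variant_fixture",
    "load_susceptibility_catalog",
]

#: Comparison groups that must be carrier-free, per cohort design.
FAMILY_ZERO_GROUPS = ("control", "sibling", "father", "mother")
CASE_CONTROL_ZERO_GROUPS = ("control",)


@dataclass(frozen=True)
class ExclusivityPolicy:
    """Which groups must have zero carriers, and which count as cases."""

    zero_groups: tuple[str, ...] = CASE_CONTROL_ZERO_GROUPS
    case_groups: tuple[str, ...] = ("case",)


@dataclass(frozen=True)
class ExclusiveVariantReport:
    """Screen outcome: retained variants with per-group carrier counts."""

    rows: pd.DataFrame
    policy: ExclusivityPolicy

    def __len__(self) -> int:
        return len(self.rows)


def _group_carrier_counts(
    matrix: GenotypeMatrix, variant_id: str, groups: Iterable[str]
) -> dict[str, int]:
    dosages = matrix.dosages(variant_id)
    out = {}
    for g in groups:
        mask = matrix.group_mask(g)
        out[g] = int(((dosages >= 1) & mask).sum())
    return out


def exclusivity_screen(
    matrix: GenotypeMatrix,
    records: Sequence[VariantRecord],
    qualifying_variants: Iterable[str],
    policy: ExclusivityPolicy | None = None,
) -> ExclusiveVariantReport:
    """Screen a cohort matrix for case-exclusive qualifying variants.

    Retains variants with >= 1 carrier in some case group and 0 carriers in
    every ``policy.zero_groups`` group; output ordered by (chrom, pos).
    """
    policy = policy if policy is not None else ExclusivityPolicy()
    present_groups = {s.group for s in matrix.samples}
    absent = [g for g in policy.zero_groups + policy.case_groups if g not in present_groups]
    if absent:
        raise ValueError(f"exclusivity policy names groups absent from cohort: {absent}")
    rec_of = {r.variant_id: r for r in records}
    rows = []
    for vid in qualifying_variants:
        rec = rec_of[vid]
        counts = _group_carrier_counts(
            matrix, vid, list(policy.case_groups) + list(policy.zero_groups)
        )
        if all(counts[g] == 0 for g in policy.zero_groups) and any(
            counts[g] >= 1 for g in policy.case_groups
        ):
            row = {
                "variant_id": vid,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "gene": rec.gene,
                "domain_annotation": rec.domain_annotation,
            }
            row.update({f"n_{g}": counts[g] for g in counts})
            rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return ExclusiveVariantReport(df, policy)


def exclusivity_screen_counts(
    table: pd.DataFrame,
    case_count_columns: Sequence[str],
    zero_count_columns: Sequence[str] = (),
    gene: Optional[str] = None,
) -> pd.DataFrame:
    """Replay the screen on a table of pre-computed per-group carrier counts.

    Used to replay published case-exclusive variant tables, whose rows carry
    carrier counts per cohort (missing = no carriers).  Retains rows with a
    nonzero count in at least one ``case_count_columns`` column and zero in
    every ``zero_count_columns`` column, optionally restricted to one gene.
    """
    absent = [c for c in list(case_count_columns) + list(zero_count_columns)
              if c not in table.columns]
    if absent:
        raise ValueError(f"count columns absent from table: {absent}")
    df = table.copy()
    if gene is not None:
        df = df[df["gene"].str.upper() == gene.upper()]
    counts = df[list(case_count_columns)].fillna(0)
    keep = (counts > 0).any(axis=1)
    if zero_count_columns:
        keep &= (df[list(zero_count_columns)].fillna(0) == 0).all(axis=1)
    return df[keep].reset_index(drop=True)


def carrier_prevalence(
    matrix: GenotypeMatrix, qualifying_variants: Iterable[str]
) -> tuple[dict[str, float], float]:
    """Per-group fraction of individuals carrying >= 1 qualifying variant.

    Returns the per-group prevalences and the one-tailed Fisher p for
    case-vs-control carrier enrichment.  An empty qualifying set gives all
    zero prevalences and p = 1.
    """
    ids = list(qualifying_variants)
    groups = sorted({s.group for s in matrix.samples})
    if not ids:
        return {g: 0.0 for g in groups}, 1.0
    idx = [matrix.variant_index(v) for v in ids]
    g = matrix.genotypes[:, idx]
    carries = (g >= 1) & (g != MISSING)
    carrier = carries.any(axis=1)
    prevalences = {}
    for grp in groups:
        mask = matrix.group_mask(grp)
        prevalences[grp] = float(carrier[mask].mean()) if mask.any() else 0.0
    case_mask = matrix.group_mask("case")
    control_mask = matrix.group_mask("control")
    if not case_mask.any() or not control_mask.any():
        return prevalences, 1.0
    cc = int(carrier[case_mask].sum())
    uc = int(carrier[control_mask].sum())
    table = ContingencyTable(
        cc, int(case_mask.sum()) - cc, uc, int(control_mask.sum()) - uc
    )
    return prevalences, fisher_one_tailed(table)


@dataclass(frozen=True)
class CategorySummary:
    """Per-category deleterious-variant counts and percentage shares."""

    counts: Mapping[str, int]
    percentages: Mapping[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def category_summary(
    deleterious_variants: Sequence[VariantRecord],
    catalog: Mapping[str, GeneCatalogEntry],
) -> CategorySummary:
    """Count deleterious variants per pathway functional category.

    Percentages are 100*count/total rounded half-away-from-zero to one
    decimal.  Raises on a variant whose gene is not in the catalog.
    """
    counts: dict[str, int] = {}
    for rec in deleterious_variants:
        if rec.gene not in catalog:
            raise KeyError(f"gene {rec.gene!r} not in pathway catalog")
        cat = catalog[rec.gene].category
        counts[cat] = counts.get(cat, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return CategorySummary({}, {})
    percentages = {
        cat: float(np.floor(1000.0 * n / total + 0.5)) / 10.0 for cat, n in counts.items()
    }
    return CategorySummary(counts, percentages)


@dataclass(frozen=True)
class OverlapSummary:
    """Two-set overlap: sizes, intersection, mutual percentages, optional p."""

    size_a: int
    size_b: int
    size_intersection: int
    pct_of_a: float
    pct_of_b: float
    hypergeometric_p: Optional[float] = None


def set_overlap(
    genes_a: Iterable[str], genes_b: Iterable[str], universe: Optional[int] = None
) -> OverlapSummary:
    """Overlap of two gene-symbol sets (case-normalized to upper).

    With a ``universe`` size, also reports the hypergeometric upper-tail
    enrichment p of the observed intersection.
    """
    a = {str(g).upper() for g in genes_a}
    b = {str(g).upper() for g in genes_b}
    inter = a & b
    p = None
    if universe is not None:
        if universe < len(a | b):
            raise ValueError(
                f"universe size {universe} smaller than union size {len(a | b)}"
            )
        p = float(stats.hypergeom.sf(len(inter) - 1, universe, len(a), len(b)))
    return OverlapSummary(
        len(a),
        len(b),
        len(inter),
        100.0 * len(inter) / len(a) if a else 0.0,
        100.0 * len(inter) / len(b) if b else 0.0,
        p,
    )


def cross_reference(genes: Iterable[str], susceptibility_catalog: pd.DataFrame) -> pd.DataFrame:
    """Annotate the intersection of a gene set with a susceptibility catalog.

    Matching is case-insensitive on the catalog's ``gene`` column; the
    returned frame carries all catalog columns for matched genes.
    """
    if susceptibility_catalog["gene"].str.upper().duplicated().any():
        raise ValueError("susceptibility catalog has duplicate gene symbols")
    wanted = {str(g).upper() for g in genes}
    mask = susceptibility_catalog["gene"].str.upper().isin(wanted)
    return susceptibility_catalog[mask].reset_index(drop=True)


def load_exclusive_variant_fixture() -> pd.DataFrame:
    """The packaged case-exclusive variant table (16 rows, two ASD cohorts)."""
    ref = resources.files("harmburden.data") / "table2_exclusive_variants.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", na_values=["."])
    return df


def load_susceptibility_catalog() -> pd.DataFrame:
    """The packaged 18-gene autism susceptibility catalog."""
    ref = resources.files("harmburden.data") / "table3_susceptibility.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"gene": str, "sfari_score": str})
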