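"""End-to-end orchestration: score -> burden/association -> screen.

Thin glue over the stage modules, shared by the command-line interface and
by library callers who want the whole analysis in one call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .association import (
    burden_test,
    individual_burden,
    run_association,
)
from .data_model import GenotypeMatrix, VariantRecord
from .deleteriousness import ToolRegistry, default_registry, is_deleterious, score_variant
from .rarity_qc import (
    QCPolicy,
    RarityPolicy,
    apply_qc,
    call_rate,
    control_allele_frequency,
    is_rare,
)
from .screens import ExclusivityPolicy, exclusivity_screen

__all__ = ["ScoredVariants", "score_variants", "burden_and_association", "screen_exclusive"]


@dataclass
class ScoredVariants:
    """Per-variant scoring table plus the QC-filtered matrix it refers to."""

    table: pd.DataFrame
    matrix: GenotypeMatrix
    qc_report: pd.DataFrame
    rule: str

    @property
    def qualifying_ids(self) -> list[str]:
        """Variants that are both rare and deleterious (and passed QC)."""
        if self.table.empty:
            return []
        mask = self.table["rare"] & self.table["deleterious"]
        return list(self.table.loc[mask, "variant_id"])


def score_variants(
    matrix: GenotypeMatrix,
    records: Sequence[VariantRecord],
    rarity_policy: Optional[RarityPolicy] = None,
    qc_policy: Optional[QCPolicy] = None,
    rule: str = "both",
    registry: Optional[ToolRegistry] = None,
) -> ScoredVariants:
    """Apply QC, consensus scoring and the rarity rule to every variant.

    The returned table has one row per QC-surviving variant with columns
    variant_id, gene, nD, nP, nT, n_missing, harm, crit1, crit2,
    control_af, rare, call_rate, deleterious.
    """
    rarity_policy = rarity_policy if rarity_policy is not None else RarityPolicy()
    qc_policy = qc_policy if qc_policy is not None else QCPolicy()
    registry = registry if registry is not None else default_registry()
    rec_of = {r.variant_id: r for r in records}

    rates = {v: call_rate(matrix, v) for v in matrix.variant_ids}
    filtered, qc_report = apply_qc(matrix, qc_policy)

    rows = []
    for vid in filtered.variant_ids:
        if vid not in rec_of:
            continue
        rec = rec_of[vid]
        score = score_variant(rec.tool_calls, registry)
        caf = control_allele_frequency(filtered, vid)
        rare = is_rare(rec, caf, rarity_policy)
        deleterious = is_deleterious(score, rule)
        rows.append(
            {
                "variant_id": vid,
                "gene": rec.gene,
                "nD": score.nD,
                "nP": score.nP,
                "nT": score.nT,
                "n_missing": score.n_missing,
                "harm": score.harm,
                "crit1": score.crit1,
                "crit2": score.crit2,
                "control_af": caf,
                "rare": rare,
                "call_rate": rates[vid],
                "deleterious": deleterious,
            }
        )
    columns = [
        "variant_id", "gene", "nD", "nP", "nT", "n_missing", "harm",
        "crit1", "crit2", "control_af", "rare", "call_rate", "deleterious",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return ScoredVariants(table, filtered, qc_report, rule)


def burden_and_association(
    scored: ScoredVariants,
    records: Sequence[VariantRecord],
    burden_mode: str = "variants",
    gene_mode: str = "carriers",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual burden test plus variant- and gene-level association.

    Returns (burden report, association report) as DataFrames; the
    association report concatenates both levels, each corrected within its
    own family of tests.
    """
    matrix = scored.matrix
    qualifying = scored.qualifying_ids
    burdens = individual_burden(matrix, qualifying, mode=burden_mode)
    case = burdens[matrix.group_mask("case")]
    control = burdens[matrix.group_mask("control")]
    if len(case) >= 3 and len(control) >= 3:
        res = burden_test(case, control)
        burden_df = pd.DataFrame(
            [
                {
                    "n_cases": len(case),
                    "n_controls": len(control),
                    "case_mean": res.case_mean,
                    "control_mean": res.control_mean,
                    "normality_p_case": res.selection.normality_p_case,
                    "normality_p_control": res.selection.normality_p_control,
                    "variance_p": res.selection.variance_p,
                    "chosen_test": res.selection.chosen,
                    "statistic": res.statistic,
                    "p_one_tailed": res.p_one_tailed,
                    "burden_mode": burden_mode,
                }
            ]
        )
    else:
        burden_df = pd.DataFrame()

    assoc_rows = []
    for level, mode in (("variant", "carriers"), ("gene", gene_mode)):
        for r in run_association(
            matrix, list(records), level=level, qualifying_variants=qualifying, mode=mode
        ):
            assoc_rows.append(
                {
                    "unit": r.unit_id,
                    "level": r.level,
                    "case_carriers": r.table.case_carriers,
                    "case_noncarriers": r.table.case_noncarriers,
                    "control_carriers": r.table.control_carriers,
                    "control_noncarriers": r.table.control_noncarriers,
                    "p_fisher": r.p_fisher,
                    "p_bh": r.p_bh,
                    "p_bonf": r.p_bonf,
                }
            )
    return burden_df, pd.DataFrame(assoc_rows)


def screen_exclusive(
    scored: ScoredVariants,
    records: Sequence[VariantRecord],
    policy: Optional[ExclusivityPolicy] = None,
):
    """Case-exclusivity screen over the qualifying variants."""
    return exclusivity_screen(scored.matrix, list(records), scored.qualifying_ids, policy)
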