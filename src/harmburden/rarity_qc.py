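"""Rarity classification and call-rate quality control.

A variant is *rare* when its allele frequency is below a cutoff (default
0.01) in the study's control cohort AND the public-database condition
holds over a configured list of population databases.  A variant passes QC
when its call rate (fraction of cohort samples with a non-missing
genotype) strictly exceeds a threshold (default 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import MISSING, GenotypeMatrix, VariantRecord

__all__ = [
    "DEFAULT_DB_NAMES",
    "RarityPolicy",
    "QCPolicy",
    "control_allele_frequency",
    "is_rare",
    "call_rate",
    "apply_qc",
]

#: The six public allele-frequency databases consulted by default.
DEFAULT_DB_NAMES: tuple[str, ...] = (
    "1000g_ALL",
    "1000g_EAS",
    "esp6500siv2_all",
    "ExAC_ALL",
    "gnomad_controls",
    "gnomad_controls_EAS",
)


class UndefinedFrequencyError(ValueError):
    """No called control samples: the control AF is undefined."""


@dataclass(frozen=True)
class RarityPolicy:
    """Rarity rule: control-cohort AF cutoff plus a public-database condition.

    ``db_rule`` selects how the database list is combined: ``any_db``
    (default) requires at least one database AF below the cutoff; ``all_dbs``
    requires every database to be below.  A database with no record for the
    variant counts as satisfying the condition when ``missing_db_af_is_rare``
    (absence from a population database is evidence of rarity).
    """

    af_threshold: float = 0.01
    db_names: tuple[str, ...] = DEFAULT_DB_NAMES
    db_rule: str = "any_db"
    missing_db_af_is_rare: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.af_threshold < 1.0):
            raise ValueError(f"af_threshold must be in (0, 1), got {self.af_threshold}")
        if not self.db_names:
            raise ValueError("db_names must be nonempty")
        if self.db_rule not in ("any_db", "all_dbs"):
            raise ValueError(f"db_rule must be 'any_db' or 'all_dbs', got {self.db_rule!r}")


@dataclass(frozen=True)
class QCPolicy:
    """Call-rate filter: retain variants with call rate strictly above the cutoff."""

    min_call_rate: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_call_rate <= 1.0):
            raise ValueError(f"min_call_rate must be in [0, 1], got {self.min_call_rate}")


def control_allele_frequency(matrix: GenotypeMatrix, variant_id: str) -> float:
    """Alt-allele frequency among called control samples.

    Computed as (sum of alt dosages over controls with calls) divided by
    (2 x number of called controls); missing genotypes drop out of both
    numerator and denominator.
    """
    dosages = matrix.dosages(variant_id)[matrix.group_mask("control")]
    called = dosages != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        raise UndefinedFrequencyError(
            f"variant {variant_id}: no called control samples, AF undefined"
        )
    return float(dosages[called].sum()) / (2 * n_called)


def is_rare(variant: VariantRecord, control_af: float, policy: RarityPolicy | None = None) -> bool:
    """Apply the rarity rule to one variant given its control-cohort AF."""
    policy = policy if policy is not None else RarityPolicy()
    if not (0.0 <= control_af <= 1.0):
        raise ValueError(f"control_af must be in [0, 1], got {control_af}")
    if control_af >= policy.af_threshold:
        return False
    hits = []
    for name in policy.db_names:
        af = variant.db_afs.get(name)
        if af is None:
            hits.append(policy.missing_db_af_is_rare)
        else:
            hits.append(af < policy.af_threshold)
    return any(hits) if policy.db_rule == "any_db" else all(hits)


def call_rate(matrix: GenotypeMatrix, variant_id: str) -> float:
    """Fraction of all cohort samples (cases and controls alike) with a call."""
    dosages = matrix.dosages(variant_id)
    if dosages.size == 0:
        return 0.0
    return float((dosages != MISSING).mean())


def apply_qc(
    matrix: GenotypeMatrix, policy: QCPolicy | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants whose call rate does not strictly exceed the cutoff.

    Returns the filtered matrix and an exclusion report with one row per
    dropped variant (``variant_id``, ``call_rate``).
    """
    policy = policy if policy is not None else QCPolicy()
    if matrix.n_samples == 0:
        rates = np.zeros(matrix.n_variants)
    else:
        rates = (matrix.genotypes != MISSING).mean(axis=0)
    keep = rates > policy.min_call_rate
    kept_ids = [v for v, k in zip(matrix.variant_ids, keep) if k]
    report = pd.DataFrame(
        {
            "variant_id": [v for v, k in zip(matrix.variant_ids, keep) if not k],
            "call_rate": [float(r) for r, k in zip(rates, keep) if not k],
        }
    )
    return matrix.subset_variants(kept_ids), report
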