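"""Core record types shared by every pipeline stage.

The pipeline operates on three kinds of objects: annotated variants
(:class:`VariantRecord`), a sample-by-variant genotype matrix with cohort
group labels (:class:`GenotypeMatrix`), and a pathway gene catalog
(:class:`GeneCatalogEntry`).  Genotypes are unphased alt-allele dosages in
``{0, 1, 2}``; ``-1`` encodes a missing call.  A *carrier* is an individual
with dosage >= 1.  Coordinates are 1-based and fully closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GROUPS",
    "CATEGORIES",
    "VariantRecord",
    "SampleInfo",
    "GenotypeMatrix",
    "GeneCatalogEntry",
    "make_variant_id",
    "validate_catalog",
    "load_default_catalog",
]

#: Sentinel for a missing genotype call in :class:`GenotypeMatrix` arrays.
MISSING: int = -1

#: Closed set of cohort group labels.
GROUPS = frozenset({"case", "control", "sibling", "father", "mother", "other"})

#: Closed set of pathway functional categories.
CATEGORIES = frozenset({"IGFBPs", "IGFs", "IGF-Rs", "PI3K/AKT", "MAPK"})


class ValidationError(ValueError):
    """Raised when an input record violates a structural invariant."""


def make_variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Build the canonical ``chrom:pos:ref:alt`` key for one variant.

    Parameters
    ----------
    chrom, pos, ref, alt
        1-based coordinate and the two allele strings.

    Raises
    ------
    ValidationError
        If an allele is empty, ``pos < 1``, or ``ref == alt``.
    """
    if not chrom:
        raise ValidationError("chrom must be nonempty")
    if not ref or not alt:
        raise ValidationError("ref and alt alleles must be nonempty")
    if pos < 1:
        raise ValidationError(f"pos must be >= 1, got {pos}")
    if ref == alt:
        raise ValidationError(f"ref and alt must differ, both are {ref!r}")
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant.

    ``db_afs`` maps public-database names (e.g. ``1000g_ALL``,
    ``gnomad_controls``) to allele frequencies; a database absent from the
    mapping has no record for this variant.  ``tool_calls`` maps predictor
    ids to raw categorical codes or numeric scores; absent tools made no
    call.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    db_afs: Mapping[str, float] = field(default_factory=dict)
    tool_calls: Mapping[str, object] = field(default_factory=dict)
    domain_annotation: Optional[str] = None

    def __post_init__(self) -> None:
        make_variant_id(self.chrom, self.pos, self.ref, self.alt)
        for name, af in self.db_afs.items():
            if not (0.0 <= af <= 1.0):
                raise ValidationError(
                    f"{self.variant_id}: database AF {name}={af} outside [0, 1]"
                )

    @classmethod
    def build(cls, chrom: str, pos: int, ref: str, alt: str, gene: str, **kw) -> "VariantRecord":
        return cls(make_variant_id(chrom, pos, ref, alt), chrom, pos, ref, alt, gene, **kw)


@dataclass(frozen=True)
class SampleInfo:
    """Identity, cohort group and cohort label of one individual."""

    sample_id: str
    group: str
    cohort: str = "default"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"sample {self.sample_id}: group {self.group!r} not in {sorted(GROUPS)}"
            )


class GenotypeMatrix:
    """Sample-by-variant alt-allele dosage matrix with group labels.

    Values are ``0``, ``1``, ``2`` or :data:`MISSING`.  Rows follow
    ``samples`` order, columns follow ``variant_ids`` order.
    """

    def __init__(
        self,
        samples: Sequence[SampleInfo],
        variant_ids: Sequence[str],
        genotypes: np.ndarray,
    ) -> None:
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.shape != (len(samples), len(variant_ids)):
            raise ValidationError(
                f"genotype array shape {genotypes.shape} does not match "
                f"{len(samples)} samples x {len(variant_ids)} variants"
            )
        allowed = {0, 1, 2, MISSING}
        present = set(np.unique(genotypes).tolist()) if genotypes.size else set()
        if not present <= allowed:
            raise ValidationError(f"genotype values {present - allowed} not allowed")
        ids = list(variant_ids)
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate variant_ids in matrix")
        sids = [s.sample_id for s in samples]
        if len(set(sids)) != len(sids):
            raise ValidationError("duplicate sample_ids in matrix")
        self.samples = list(samples)
        self.variant_ids = ids
        self.genotypes = genotypes
        self._vidx = {v: j for j, v in enumerate(ids)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._vidx[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None

    def group_mask(self, group: str) -> np.ndarray:
        """Boolean row mask selecting samples of one cohort group."""
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}")
        return np.array([s.group == group for s in self.samples], dtype=bool)

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.variant_index(v) for v in variant_ids]
        return GenotypeMatrix(self.samples, list(variant_ids), self.genotypes[:, idx])

    def dosages(self, variant_id: str) -> np.ndarray:
        return self.genotypes[:, self.variant_index(variant_id)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.variant_ids == other.variant_ids
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass(frozen=True)
class GeneCatalogEntry:
    """One pathway gene: Ensembl id, symbol, functional category, localization."""

    ensembl_id: str
    symbol: str
    category: str
    localization: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"gene {self.symbol}: category {self.category!r} not in {sorted(CATEGORIES)}"
            )


def validate_catalog(entries: Iterable[GeneCatalogEntry]) -> dict[str, GeneCatalogEntry]:
    """Key catalog entries by symbol, rejecting duplicates.

    Category membership is validated by :class:`GeneCatalogEntry` itself;
    this adds the uniqueness check and returns a symbol-keyed mapping.
    """
    catalog: dict[str, GeneCatalogEntry] = {}
    for entry in entries:
        if entry.symbol in catalog:
            raise ValidationError(f"duplicate gene symbol {entry.symbol!r} in catalog")
        catalog[entry.symbol] = entry
    return catalog


def _read_catalog_tsv(path_or_buf) -> dict[str, GeneCatalogEntry]:
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str)
    required = {"ensembl_id", "symbol", "category", "localization"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"catalog file missing columns: {sorted(missing)}")
    entries = [
        GeneCatalogEntry(r.ensembl_id, r.symbol, r.category, r.localization)
        for r in df.itertuples(index=False)
    ]
    return validate_catalog(entries)


def load_catalog(path) -> dict[str, GeneCatalogEntry]:
    """Read a gene-catalog TSV (columns ensembl_id, symbol, category, localization)."""
    return _read_catalog_tsv(path)


def load_default_catalog() -> dict[str, GeneCatalogEntry]:
    """The packaged 18-gene IGF signaling pathway catalog."""
    ref = resources.files("harmburden.data") / "table1_catalog.tsv"
    with resources.as_file(ref) as path:
        return _read_catalog_tsv(path)
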