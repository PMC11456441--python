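"""Synthetic case-control exome cohorts with a known truth ledger.

The generator emulates the statistical structure the downstream analysis
assumes: per-variant allele frequencies drawn from a log-uniform spectrum,
Hardy-Weinberg genotypes, uniform genotype missingness, public-database
frequencies equal to the true frequency times log-normal noise, and
per-tool deleteriousness calls of configurable concordance with a planted
truth flag.  Two kinds of effects can be planted: a case-vs-control gap in
qualifying-carrier prevalence, and case-exclusive variants with a fixed
carrier count.  Every planted quantity is recorded in a
:class:`SimulationTruth` ledger so recovery tests can compare pipeline
output against ground truth.

What the generator does **not** emulate: linkage disequilibrium, realistic
site-frequency spectra, pedigree transmission and de-novo events.  Family
groups (siblings/parents) carry labels only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import (
    MISSING,
    GenotypeMatrix,
    SampleInfo,
    VariantRecord,
    load_default_catalog,
    make_variant_id,
)
from .deleteriousness import ToolRegistry, default_registry
from .io_formats import (
    DEFAULT_DIALECT,
    AnnotationTableDialect,
    write_genotypes_vcf,
    write_sample_table,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_cohort",
    "simulate_tool_calls",
    "write_simulated_inputs",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings.

    Cohort sizes default to 263 cases / 294 controls (the case-control
    cohort geometry the analysis was designed around).  ``prevalence_gap``
    plants an additive case-vs-control difference in the probability of
    carrying >= 1 qualifying (truth-deleterious, truth-rare) variant;
    0 is the null.  ``tool_concordance`` is the per-tool probability that a
    variant's call matches its truth flag; a ``p_level_fraction`` of
    discordant calls on truth-deleterious variants (and concordant misses
    on benign ones) are emitted as probably-deleterious where the tool has
    a P level.  ``exclusive_carrier_count`` case carriers are planted on
    each case-exclusive variant.
    """

    n_cases: int = 263
    n_controls: int = 294
    n_siblings: int = 0
    n_fathers: int = 0
    n_mothers: int = 0
    n_variants: int = 100
    af_min: float = 1e-4
    af_max: float = 0.05
    deleterious_fraction: float = 0.36
    prevalence_gap: float = 0.0
    n_exclusive_planted: int = 0
    exclusive_carrier_count: int = 1
    tool_concordance: float = 0.9
    p_level_fraction: float = 0.2
    missing_rate: float = 0.02
    db_noise_sigma: float = 0.3
    db_missing_rate: float = 0.1
    rare_af_threshold: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "deleterious_fraction",
            "prevalence_gap",
            "tool_concordance",
            "p_level_fraction",
            "missing_rate",
            "db_missing_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_exclusive_planted > self.n_variants:
            raise ValueError("cannot plant more exclusive variants than variants")
        if self.n_exclusive_planted > 0 and self.exclusive_carrier_count > self.n_cases:
            raise ValueError(
                f"infeasible plant: {self.exclusive_carrier_count} exclusive carriers "
                f"but only {self.n_cases} cases"
            )
        if not (0 < self.af_min <= self.af_max < 1):
            raise ValueError("need 0 < af_min <= af_max < 1")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth ledger covering every simulated variant and sample."""

    variants: pd.DataFrame  # variant_id, gene, true_af, truth_deleterious, planted_exclusive
    expected_burden: pd.DataFrame  # sample_id, group, expected_burden
    planted_prevalence: dict[str, float]  # expected qualifying-carrier prevalence per group

    @property
    def qualifying_ids(self) -> list[str]:
        """Truth-qualifying variants: deleterious and below the rare-AF cutoff."""
        v = self.variants
        return list(v.loc[v.truth_qualifying, "variant_id"])


_CATEGORICAL_LEVEL_CODES: dict[str, dict[str, str]] = {}


def _level_codes(registry: ToolRegistry, tool_id: str) -> dict[str, str]:
    """First raw code mapping to each level, per tool."""
    crit = registry[tool_id]
    codes: dict[str, str] = {}
    for code, level in crit.categorical_map.items():
        if level is not None and level not in codes:
            codes[level] = code
    return codes


def simulate_tool_calls(
    truth_deleterious: bool,
    concordance: float,
    registry: ToolRegistry,
    rng: np.random.Generator,
    p_level_fraction: float = 0.2,
) -> dict[str, object]:
    """Draw one variant's raw per-tool predictions.

    A truth-deleterious variant receives a deleterious-level call from each
    tool independently with probability ``concordance``; otherwise a
    tolerable-level call, except that a ``p_level_fraction`` of those
    misses become probably-deleterious where the tool supports it.  A
    truth-benign variant is the mirror image (tolerable with probability
    ``concordance``).
    """
    calls: dict[str, object] = {}
    for tool_id in registry.tool_ids:
        crit = registry[tool_id]
        concordant = rng.random() < concordance
        if truth_deleterious:
            level = "D" if concordant else ("P" if rng.random() < p_level_fraction else "T")
        else:
            level = "T" if concordant else ("P" if rng.random() < p_level_fraction else "D")
        if crit.kind == "numeric_threshold":
            # CADD-style PHRED score: above/below the cutoff; no P level
            if level == "P":
                level = "T" if truth_deleterious else "D"
            if level == "D":
                calls[tool_id] = float(crit.threshold + rng.uniform(0.0, 25.0))
            else:
                calls[tool_id] = float(crit.threshold * rng.uniform(0.0, 0.999))
        else:
            codes = _level_codes(registry, tool_id)
            if level == "P" and "P" not in codes:
                level = "T"
            calls[tool_id] = codes[level]
    return calls


def _hardy_weinberg_genotypes(
    rng: np.random.Generator, afs: np.ndarray, n_samples: int
) -> np.ndarray:
    """n_samples x n_variants dosage draws under Hardy-Weinberg."""
    u = rng.random((n_samples, afs.size))
    p_hom_ref = (1.0 - afs) ** 2
    p_not_homalt = 1.0 - afs**2
    g = np.ones_like(u, dtype=np.int8)
    g[u < p_hom_ref] = 0
    g[u >= p_not_homalt] = 2
    return g


def simulate_cohort(
    config: SimulationConfig,
    catalog_symbols: Optional[list[str]] = None,
    registry: Optional[ToolRegistry] = None,
) -> tuple[GenotypeMatrix, list[VariantRecord], SimulationTruth]:
    """Generate a cohort, its annotated variants, and the truth ledger.

    Identical config (including seed) yields bit-identical output.  Named
    substreams (genotypes, tool calls, database AFs, missingness, planting)
    are spawned from the single root seed so one component's draw count
    does not perturb the others.
    """
    registry = registry if registry is not None else default_registry()
    if catalog_symbols is None:
        catalog_symbols = sorted(load_default_catalog())

    root = np.random.SeedSequence(config.seed)
    (ss_af, ss_geno, ss_tools, ss_db, ss_miss, ss_plant) = root.spawn(6)
    rng_af = np.random.default_rng(ss_af)
    rng_geno = np.random.default_rng(ss_geno)
    rng_tools = np.random.default_rng(ss_tools)
    rng_db = np.random.default_rng(ss_db)
    rng_miss = np.random.default_rng(ss_miss)
    rng_plant = np.random.default_rng(ss_plant)

    # -- samples ---------------------------------------------------------
    samples: list[SampleInfo] = []
    for group, n in (
        ("case", config.n_cases),
        ("control", config.n_controls),
        ("sibling", config.n_siblings),
        ("father", config.n_fathers),
        ("mother", config.n_mothers),
    ):
        samples.extend(
            SampleInfo(f"{group}_{i:04d}", group, "simulated") for i in range(n)
        )
    n_samples = len(samples)
    group_of = np.array([s.group for s in samples])
    case_idx = np.flatnonzero(group_of == "case")
    noncase_idx = np.flatnonzero(group_of != "case")

    # -- variant frame ---------------------------------------------------
    nv = config.n_variants
    afs = np.exp(
        rng_af.uniform(np.log(config.af_min), np.log(config.af_max), size=nv)
    )
    genes = rng_af.choice(catalog_symbols, size=nv) if nv else np.array([], dtype=object)
    truth_del = rng_af.random(nv) < config.deleterious_fraction
    exclusive = np.zeros(nv, dtype=bool)
    if config.n_exclusive_planted:
        chosen = rng_plant.choice(nv, size=config.n_exclusive_planted, replace=False)
        exclusive[chosen] = True
        truth_del[chosen] = True  # planted exclusives are always truth-deleterious
        afs[chosen] = np.minimum(afs[chosen], config.rare_af_threshold / 2)

    genotypes = _hardy_weinberg_genotypes(rng_geno, afs, n_samples)

    # -- plant the prevalence gap ---------------------------------------
    truth_qualifying = truth_del & (afs < config.rare_af_threshold)
    qual_idx = np.flatnonzero(truth_qualifying)
    if config.prevalence_gap > 0 and qual_idx.size:
        boosted = rng_plant.random(case_idx.size) < config.prevalence_gap
        for si in case_idx[boosted]:
            j = rng_plant.choice(qual_idx)
            if genotypes[si, j] == 0:
                genotypes[si, j] = 1

    # -- plant case-exclusive variants ----------------------------------
    for j in np.flatnonzero(exclusive):
        genotypes[:, j] = 0
        carriers = rng_plant.choice(
            case_idx, size=config.exclusive_carrier_count, replace=False
        )
        genotypes[carriers, j] = 1
    # A planted-exclusive run guarantees the ledger is the complete set of
    # case-exclusive qualifying variants: any other variant that came out
    # case-only by chance receives one control carrier.
    if config.n_exclusive_planted and len(noncase_idx):
        for j in np.flatnonzero(~exclusive):
            col = genotypes[:, j]
            if (col[case_idx] >= 1).any() and not (col[noncase_idx] >= 1).any():
                col[rng_plant.choice(noncase_idx)] = 1

    # -- truth ledger (before missingness) ------------------------------
    variant_ids = [
        make_variant_id("chr1", 1_000_000 + 10 * j, "A", "G") for j in range(nv)
    ]
    p_carrier = 1.0 - (1.0 - afs) ** 2
    p_carrier[exclusive] = 0.0
    base_burden = float(p_carrier[qual_idx].sum()) if qual_idx.size else 0.0
    base_prev = 1.0 - float(np.prod(1.0 - p_carrier[qual_idx])) if qual_idx.size else 0.0
    expected_burden = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "group": group_of,
            "expected_burden": [
                base_burden + (config.prevalence_gap if g == "case" else 0.0)
                for g in group_of
            ],
        }
    )
    planted_prevalence = {
        g: (
            base_prev + config.prevalence_gap * (1.0 - base_prev)
            if g == "case"
            else base_prev
        )
        for g in sorted(set(group_of))
    }

    # -- missingness -----------------------------------------------------
    if config.missing_rate > 0 and genotypes.size:
        mask = rng_miss.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = MISSING

    matrix = GenotypeMatrix(samples, variant_ids, genotypes)

    # -- annotations -----------------------------------------------------
    records: list[VariantRecord] = []
    from .rarity_qc import DEFAULT_DB_NAMES

    for j, vid in enumerate(variant_ids):
        db_afs = {}
        for name in DEFAULT_DB_NAMES:
            if rng_db.random() < config.db_missing_rate:
                continue
            noisy = afs[j] * float(
                np.exp(rng_db.normal(0.0, config.db_noise_sigma))
            )
            db_afs[name] = float(min(noisy, 1.0))
        calls = simulate_tool_calls(
            bool(truth_del[j]),
            config.tool_concordance,
            registry,
            rng_tools,
            config.p_level_fraction,
        )
        chrom, pos, ref, alt = vid.split(":")
        records.append(
            VariantRecord(
                vid, chrom, int(pos), ref, alt, str(genes[j]),
                db_afs=db_afs, tool_calls=calls,
            )
        )

    truth = SimulationTruth(
        variants=pd.DataFrame(
            {
                "variant_id": variant_ids,
                "gene": genes,
                "true_af": afs,
                "truth_deleterious": truth_del,
                "planted_exclusive": exclusive,
                "truth_qualifying": truth_qualifying | exclusive,
            }
        ),
        expected_burden=expected_burden,
        planted_prevalence=planted_prevalence,
    )
    return matrix, records, truth


def _annotation_frame(
    records: list[VariantRecord], dialect: AnnotationTableDialect
) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            dialect.chrom: r.chrom,
            dialect.pos: r.pos,
            dialect.ref: r.ref,
            dialect.alt: r.alt,
            dialect.gene: r.gene,
        }
        if dialect.domain_column:
            row[dialect.domain_column] = r.domain_annotation or dialect.missing_token
        for db, col in dialect.db_columns.items():
            row[col] = (
                f"{r.db_afs[db]:.6g}" if db in r.db_afs else dialect.missing_token
            )
        for tool, col in dialect.tool_columns.items():
            if tool in r.tool_calls:
                v = r.tool_calls[tool]
                row[col] = f"{v:.4g}" if isinstance(v, float) else str(v)
            else:
                row[col] = dialect.missing_token
        rows.append(row)
    return pd.DataFrame(rows)


def write_simulated_inputs(
    matrix: GenotypeMatrix,
    records: list[VariantRecord],
    truth: SimulationTruth,
    directory,
    dialect: AnnotationTableDialect | None = None,
) -> dict[str, Path]:
    """Emit VCF, annotation TSV, sample table and truth JSON into a directory.

    The files round-trip through :mod:`harmburden.io_formats`: reading them
    back reproduces the in-memory objects.
    """
    dialect = dialect if dialect is not None else DEFAULT_DIALECT
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": directory / "genotypes.vcf",
        "annotations": directory / "annotations.tsv",
        "samples": directory / "samples.tsv",
        "truth": directory / "truth.json",
    }
    write_genotypes_vcf(matrix, paths["vcf"])
    _annotation_frame(records, dialect).to_csv(paths["annotations"], sep="\t", index=False)
    write_sample_table(matrix.samples, paths["samples"])
    payload = {
        "variants": truth.variants.to_dict(orient="list"),
        "expected_burden": truth.expected_burden.to_dict(orient="list"),
        "planted_prevalence": truth.planted_prevalence,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1, default=lambda o: bool(o) if isinstance(o, np.bool_) else o)
    return paths
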