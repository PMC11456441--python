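"""Readers and writers: annotation tables, VCF genotypes, result TSVs.

The annotation-table reader consumes an ANNOVAR-multianno-style TSV through
a configurable :class:`AnnotationTableDialect`, because upstream annotation
pipelines differ in column naming.  Genotypes come from VCF 4.x through
pysam; only the GT subfield is consulted (depth/quality filtering happens
upstream of this artifact's inputs).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .data_model import (
    MISSING,
    GenotypeMatrix,
    SampleInfo,
    VariantRecord,
    make_variant_id,
)
from .rarity_qc import DEFAULT_DB_NAMES

__all__ = [
    "AnnotationTableDialect",
    "DEFAULT_DIALECT",
    "read_annotation_table",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_sample_table",
    "write_sample_table",
    "write_results_table",
]

logger = logging.getLogger(__name__)


class AnnotationFormatError(ValueError):
    """Malformed annotation table (bad header or unparseable cell)."""


@dataclass(frozen=True)
class AnnotationTableDialect:
    """Mapping from semantic fields to source column names.

    ``chrom``/``pos``/``ref``/``alt``/``gene`` are mandatory; ``db_columns``
    and ``tool_columns`` map database and tool ids to their columns;
    ``domain_column`` is optional.  Cells equal to ``missing_token`` are
    treated as absent.
    """

    chrom: str = "Chr"
    pos: str = "Start"
    ref: str = "Ref"
    alt: str = "Alt"
    gene: str = "Gene.refGene"
    domain_column: Optional[str] = "Protein_domain"
    db_columns: Mapping[str, str] = field(
        default_factory=lambda: {name: name for name in DEFAULT_DB_NAMES}
    )
    tool_columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "SIFT": "SIFT_pred",
            "Polyphen2_HDIV": "Polyphen2_HDIV_pred",
            "Polyphen2_HVAR": "Polyphen2_HVAR_pred",
            "LRT": "LRT_pred",
            "MutationTaster": "MutationTaster_pred",
            "MutationAssessor": "MutationAssessor_pred",
            "FATHMM": "FATHMM_pred",
            "PROVEAN": "PROVEAN_pred",
            "fathmm-MKL_coding": "fathmm-MKL_coding_pred",
            "MetaSVM": "MetaSVM_pred",
            "MetaLR": "MetaLR_pred",
            "CADD": "CADD_phred",
        }
    )
    missing_token: str = "."
    #: tool ids whose column holds a numeric score rather than a code
    numeric_tools: tuple[str, ...] = ("CADD",)

    def mandatory_columns(self) -> list[str]:
        return [self.chrom, self.pos, self.ref, self.alt, self.gene]


DEFAULT_DIALECT = AnnotationTableDialect()


def read_annotation_table(
    path, dialect: AnnotationTableDialect | None = None
) -> list[VariantRecord]:
    """Parse an annotation TSV into :class:`VariantRecord` objects.

    Raises :class:`AnnotationFormatError` naming the offending line for
    row-level problems (AF outside [0, 1], non-numeric AF or position) and
    for header-level problems (a mapped column missing from the file).
    """
    dialect = dialect if dialect is not None else DEFAULT_DIALECT
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mapped = dialect.mandatory_columns() + list(dialect.db_columns.values()) + list(
        dialect.tool_columns.values()
    )
    if dialect.domain_column:
        mapped.append(dialect.domain_column)
    absent = [c for c in mapped if c not in df.columns]
    if absent:
        raise AnnotationFormatError(f"{path}: mapped columns missing from header: {absent}")

    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        row = dict(zip(df.columns, row))
        try:
            pos = int(row[dialect.pos])
        except ValueError:
            raise AnnotationFormatError(
                f"{path} line {i}: non-integer position {row[dialect.pos]!r}"
            ) from None
        db_afs: dict[str, float] = {}
        for db, col in dialect.db_columns.items():
            cell = row[col]
            if cell == dialect.missing_token or cell == "":
                continue
            try:
                af = float(cell)
            except ValueError:
                raise AnnotationFormatError(
                    f"{path} line {i}: non-numeric AF {cell!r} in column {col}"
                ) from None
            if not (0.0 <= af <= 1.0):
                raise AnnotationFormatError(
                    f"{path} line {i}: AF {af} in column {col} outside [0, 1]"
                )
            db_afs[db] = af
        tool_calls: dict[str, object] = {}
        for tool, col in dialect.tool_columns.items():
            cell = row[col]
            if cell == dialect.missing_token or cell == "":
                continue
            if tool in dialect.numeric_tools:
                try:
                    tool_calls[tool] = float(cell)
                except ValueError:
                    raise AnnotationFormatError(
                        f"{path} line {i}: non-numeric score {cell!r} in column {col}"
                    ) from None
            else:
                tool_calls[tool] = cell
        domain = None
        if dialect.domain_column:
            cell = row[dialect.domain_column]
            if cell not in (dialect.missing_token, ""):
                domain = cell
        records.append(
            VariantRecord.build(
                row[dialect.chrom],
                pos,
                row[dialect.ref],
                row[dialect.alt],
                row[dialect.gene],
                db_afs=db_afs,
                tool_calls=tool_calls,
                domain_annotation=domain,
            )
        )
    return records


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def _dosage(gt: tuple, allele_index: int) -> int:
    """Alt-allele dosage from one GT tuple; half-calls are missing."""
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return MISSING
    return sum(1 for a in gt if a == allele_index)


def read_genotypes_vcf(path, sample_table: Sequence[SampleInfo]) -> GenotypeMatrix:
    """Read GT fields into a :class:`GenotypeMatrix`.

    Multi-allelic records are split into biallelic variants (one per alt
    allele, in alt order).  ``0/0`` -> 0, ``0/1``/``1/0`` -> 1, ``1/1`` -> 2,
    ``./.`` and half-calls -> missing.  Phased separators are accepted and
    treated as unphased.
    """
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        wanted = [s.sample_id for s in sample_table]
        absent = [s for s in wanted if s not in set(vcf_samples)]
        if absent:
            raise ValueError(f"{path}: samples missing from VCF header: {absent}")
        variant_ids: list[str] = []
        columns: list[np.ndarray] = []
        for rec in vcf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                vid = make_variant_id(rec.chrom, rec.pos, rec.ref, alt)
                col = np.empty(len(wanted), dtype=np.int8)
                for si, sid in enumerate(wanted):
                    try:
                        gt = rec.samples[sid].get("GT")
                    except Exception:  # malformed GT
                        logger.warning("%s: malformed GT at %s for %s", path, vid, sid)
                        gt = None
                    col[si] = _dosage(gt, ai)
                variant_ids.append(vid)
                columns.append(col)
    genotypes = (
        np.stack(columns, axis=1) if columns else np.zeros((len(wanted), 0), dtype=np.int8)
    )
    return GenotypeMatrix(list(sample_table), variant_ids, genotypes)


def write_genotypes_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT fields mirroring the matrix."""
    contigs: list[str] = []
    parsed = []
    for vid in matrix.variant_ids:
        chrom, pos, ref, alt = vid.split(":")
        parsed.append((chrom, int(pos), ref, alt))
        if chrom not in contigs:
            contigs.append(chrom)
    gt_repr = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        sample_ids = [s.sample_id for s in matrix.samples]
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for j, (chrom, pos, ref, alt) in enumerate(parsed):
            gts = "\t".join(gt_repr[int(g)] for g in matrix.genotypes[:, j])
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n")


def read_sample_table(path) -> list[SampleInfo]:
    """Sample table TSV: columns sample_id, group, cohort."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: sample table needs columns {sorted(required)}")
    cohorts = df["cohort"] if "cohort" in df.columns else ["default"] * len(df)
    return [
        SampleInfo(sid, grp, coh)
        for sid, grp, coh in zip(df["sample_id"], df["group"], cohorts)
    ]


def write_sample_table(samples: Sequence[SampleInfo], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "group": [s.group for s in samples],
            "cohort": [s.cohort for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def _format_cell(value, missing_token: str) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return missing_token
    if isinstance(value, bool) or isinstance(value, np.bool_):
        return str(bool(value))
    if isinstance(value, (float, np.floating)):
        return f"{value:.6g}"
    return str(value)


def write_results_table(rows, path, missing_token: str = ".") -> None:
    """Write homogeneous result records (dataclasses, dicts or a DataFrame)
    as a TSV: header row, floats at 6 significant digits, input row order,
    missing values as ``missing_token``.  Zero rows still produce a header
    when the schema is known (DataFrame input)."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        dicts = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r) for r in rows
        ]
        df = pd.DataFrame(dicts)
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_format_cell(v, missing_token) for v in row) + "\n")
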