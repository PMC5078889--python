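"""Reading, filtering and indexing somatic mutation calls from MAF files.

The Mutation Annotation Format (MAF) is the tab-separated somatic-variant
table used by TCGA.  This module turns a MAF into a :class:`Cohort` — the
per-sample index of retained mutations from which the actual total mutation
load (ATML: the count of somatic, non-synonymous, exonic mutations per
tumor) is computed.  The variant-class whitelist defines exactly which
mutations count toward the ATML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Columns a MAF must provide to be parsed at all.
REQUIRED_MAF_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")

#: Optional allele columns; absent columns yield empty alleles (records then
#: count toward the ATML but cannot be classified into substitution classes).
ALLELE_COLUMNS = ("Reference_Allele", "Tumor_Seq_Allele2")

#: The recognized MAF Variant_Classification vocabulary (TCGA dialect).
MAF_VARIANT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Silent",
        "Splice_Site",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Translation_Start_Site",
        "RNA",
        "Intron",
        "IGR",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "Nonstop",
        "De_novo_Start_InFrame",
        "De_novo_Start_OutOfFrame",
        "Targeted_Region",
    }
)

#: Default non-synonymous exonic whitelist.  Silent mutations are excluded;
#: Splice_Site is excluded by default because splice-site changes are not
#: exonic substitutions, but the whitelist is user-overridable since
#: TCGA-era analyses differ on this point.
DEFAULT_NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Translation_Start_Site",
    }
)

TCGA_PATIENT_BARCODE_LENGTH = 12


class MAFFormatError(ValueError):
    """A MAF file violates the expected dialect (e.g. missing column)."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call.

    Parameters
    ----------
    sample_id
        Tumor sample barcode.
    gene
        HUGO symbol, upper-cased on construction by :func:`read_maf`.
    variant_class
        MAF ``Variant_Classification`` value; values outside the recognized
        vocabulary are kept but flagged via :attr:`is_recognized_class`.
    ref_allele, alt_allele
        Reference / tumor alleles (``A/C/G/T/-`` or multi-base); empty when
        the source MAF lacked allele columns.
    """

    sample_id: str
    gene: str
    variant_class: str
    ref_allele: str = ""
    alt_allele: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not self.gene:
            raise ValueError("gene must be non-empty")

    @property
    def is_recognized_class(self) -> bool:
        return self.variant_class in MAF_VARIANT_CLASSES

    @property
    def is_snv(self) -> bool:
        """True when ref/alt are single, distinct standard bases."""
        bases = {"A", "C", "G", "T"}
        return (
            self.ref_allele in bases
            and self.alt_allele in bases
            and self.ref_allele != self.alt_allele
        )


@dataclass
class Cohort:
    """Filtered mutation records indexed by sample.

    Invariants (checked by :func:`build_cohort`):

    * ``atml[s]`` equals the number of retained records for sample ``s``;
    * every gene in ``gene_carriers`` has at least one carrier;
    * the per-(sample, gene) counts sum to the total record count.
    """

    records: tuple[MutationRecord, ...]
    samples: frozenset[str]
    atml: dict[str, int] = field(default_factory=dict)
    gene_carriers: dict[str, frozenset[str]] = field(default_factory=dict)
    gene_mutation_count: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_carriers)

    def atml_frame(self) -> pd.DataFrame:
        """Per-sample ATML table with columns ``sample_id``, ``atml``."""
        rows = sorted(self.atml.items())
        return pd.DataFrame(rows, columns=["sample_id", "atml"])


def read_maf(
    path: str | Path,
    *,
    truncate_tcga_barcode: bool = False,
) -> list[MutationRecord]:
    """Read a TCGA-dialect MAF into :class:`MutationRecord` objects.

    Tab-separated; lines starting with ``#`` are comments.  Gene symbols are
    upper-cased so that panel matching is case-insensitive.  With
    ``truncate_tcga_barcode`` the ``Tumor_Sample_Barcode`` is cut to the
    12-character TCGA patient stem; by default barcodes are used verbatim.

    Raises
    ------
    MAFFormatError
        If a required column is missing.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            dtype=str,
            keep_default_na=False,
            na_filter=False,
        )
    except pd.errors.EmptyDataError:
        logger.warning("MAF %s contains no data rows", path)
        return []

    missing = [c for c in REQUIRED_MAF_COLUMNS if c not in frame.columns]
    if missing:
        raise MAFFormatError(f"MAF {path} is missing required column(s): {', '.join(missing)}")
    if frame.empty:
        logger.warning("MAF %s contains no data rows", path)
        return []

    has_ref = "Reference_Allele" in frame.columns
    has_alt = "Tumor_Seq_Allele2" in frame.columns

    records: list[MutationRecord] = []
    for row in frame.itertuples(index=False):
        sample = getattr(row, "Tumor_Sample_Barcode")
        if truncate_tcga_barcode:
            sample = sample[:TCGA_PATIENT_BARCODE_LENGTH]
        records.append(
            MutationRecord(
                sample_id=sample,
                gene=getattr(row, "Hugo_Symbol").upper(),
                variant_class=getattr(row, "Variant_Classification"),
                ref_allele=getattr(row, "Reference_Allele").upper() if has_ref else "",
                alt_allele=getattr(row, "Tumor_Seq_Allele2").upper() if has_alt else "",
            )
        )
    return records


def write_maf(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Serialize records back to the same MAF dialect read by :func:`read_maf`."""
    frame = pd.DataFrame(
        {
            "Hugo_Symbol": [r.gene for r in records],
            "Tumor_Sample_Barcode": [r.sample_id for r in records],
            "Variant_Classification": [r.variant_class for r in records],
            "Reference_Allele": [r.ref_allele for r in records],
            "Tumor_Seq_Allele2": [r.alt_allele for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def filter_nonsynonymous(
    records: Sequence[MutationRecord],
    whitelist: frozenset[str] | set[str] = DEFAULT_NONSYNONYMOUS_CLASSES,
) -> list[MutationRecord]:
    """Keep records whose variant class is in the whitelist, preserving order.

    Any somatic mutation is included regardless of recurrence status; silent
    mutations (and anything else outside the whitelist) are dropped.  Unknown
    classes are excluded and counted in a log summary rather than erroring.
    """
    if not whitelist:
        raise ValueError("variant-class whitelist must be non-empty")
    kept = [r for r in records if r.variant_class in whitelist]
    n_unknown = sum(
        1 for r in records if not r.is_recognized_class and r.variant_class not in whitelist
    )
    if n_unknown:
        logger.info(
            "filter_nonsynonymous: excluded %d record(s) with unrecognized variant class",
            n_unknown,
        )
    return kept


def build_cohort(
    records: Sequence[MutationRecord],
    sample_universe: Optional[Iterable[str]] = None,
) -> Cohort:
    """Index already-filtered records into a :class:`Cohort`.

    ``sample_universe`` lets mutation-free samples enter the cohort with
    ATML 0 (they matter for the regression step of weight derivation).  A
    record whose sample is outside a supplied universe signals a sample-sheet
    mismatch and raises.
    """
    universe = None if sample_universe is None else frozenset(sample_universe)
    atml: dict[str, int] = {}
    carriers: dict[str, set[str]] = {}
    counts: dict[tuple[str, str], int] = {}

    for rec in records:
        if universe is not None and rec.sample_id not in universe:
            raise ValueError(
                f"record sample {rec.sample_id!r} is not in the supplied sample universe"
            )
        atml[rec.sample_id] = atml.get(rec.sample_id, 0) + 1
        carriers.setdefault(rec.gene, set()).add(rec.sample_id)
        key = (rec.sample_id, rec.gene)
        counts[key] = counts.get(key, 0) + 1

    samples = frozenset(atml) if universe is None else universe
    for s in samples:
        atml.setdefault(s, 0)

    return Cohort(
        records=tuple(records),
        samples=samples,
        atml=atml,
        gene_carriers={g: frozenset(c) for g, c in carriers.items()},
        gene_mutation_count=counts,
    )


def cohort_from_maf(
    path: str | Path,
    *,
    whitelist: frozenset[str] | set[str] = DEFAULT_NONSYNONYMOUS_CLASSES,
    sample_universe: Optional[Iterable[str]] = None,
    truncate_tcga_barcode: bool = False,
) -> Cohort:
    """Convenience pipeline: read → filter → index."""
    records = read_maf(path, truncate_tcga_barcode=truncate_tcga_barcode)
    return build_cohort(filter_nonsynonymous(records, whitelist), sample_universe)


def write_atml_summary(cohort: Cohort, path: str | Path) -> None:
    """Export the per-sample ATML as a two-column TSV."""
    cohort.atml_frame().to_csv(path, sep="\t", index=False)
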