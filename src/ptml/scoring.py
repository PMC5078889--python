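"""Scoring panel mutation calls into predicted total mutation loads.

A sample's PTML is the sum, over its mutated panel genes, of the adjusted
gene mutation value times the number of mutations in the gene.  Tumors are
dichotomized at PTML <= 100 ("low") versus > 100 ("high"), the threshold at
which a zero panel score reliably indicates a lightly mutated tumor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .maf_io import (
    Cohort,
    DEFAULT_NONSYNONYMOUS_CLASSES,
    MutationRecord,
    build_cohort,
    filter_nonsynonymous,
    read_maf,
)
from .weights import GenePanel, WeightTable

DEFAULT_THRESHOLD = 100

LOW = "low"
HIGH = "high"


@dataclass(frozen=True)
class PanelCalls:
    """Per-sample panel mutation calls: gene -> number of mutations (>= 1)."""

    sample_id: str
    gene_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for gene, count in self.gene_counts.items():
            if count < 1:
                raise ValueError(f"count for gene {gene} must be >= 1, got {count}")
            if gene != gene.upper():
                raise ValueError(f"gene symbols must be upper-cased: {gene!r}")


@dataclass(frozen=True)
class PTMLResult:
    """PTML score and class for one sample.

    ``unknown_genes`` holds called genes absent from the weight table (either
    excluded at derivation time or off-panel); they contribute 0 to the score
    and are surfaced rather than erroring, because panel versions drift.
    """

    sample_id: str
    ptml: int
    ptml_class: str
    threshold: int
    unknown_genes: frozenset[str] = frozenset()


def classify(ptml: int, threshold: int = DEFAULT_THRESHOLD) -> str:
    """Dichotomize a score: low iff ptml <= threshold (inclusive)."""
    return LOW if ptml <= threshold else HIGH


def score_sample(
    calls: PanelCalls,
    weights: WeightTable,
    threshold: int = DEFAULT_THRESHOLD,
) -> PTMLResult:
    """PTML = sum of adjusted[g] * count[g] over genes known to the table."""
    ptml = 0
    unknown: set[str] = set()
    for gene, count in calls.gene_counts.items():
        value = weights.adjusted.get(gene)
        if value is None:
            unknown.add(gene)
        else:
            ptml += value * count
    return PTMLResult(
        sample_id=calls.sample_id,
        ptml=ptml,
        ptml_class=classify(ptml, threshold),
        threshold=threshold,
        unknown_genes=frozenset(unknown),
    )


def calls_from_cohort(cohort: Cohort, panel: GenePanel) -> list[PanelCalls]:
    """Restrict a cohort's mutation counts to panel genes, one PanelCalls per sample."""
    panel_set = set(panel.genes)
    per_sample: dict[str, dict[str, int]] = {s: {} for s in cohort.samples}
    for (sample, gene), count in cohort.gene_mutation_count.items():
        if gene in panel_set:
            per_sample[sample][gene] = count
    return [PanelCalls(s, counts) for s, counts in sorted(per_sample.items())]


def score_cohort(
    cohort: Cohort,
    panel: GenePanel,
    weights: WeightTable,
    threshold: int = DEFAULT_THRESHOLD,
) -> list[PTMLResult]:
    """Score every cohort sample, including mutation-free samples (PTML 0).

    The weight table may deliberately originate from a different cancer type;
    cross-application is how the specificity of cancer-specific weights is
    demonstrated (the correlation with true load degrades).
    """
    return [
        score_sample(calls, weights, threshold)
        for calls in calls_from_cohort(cohort, panel)
    ]


def scores_frame(results: Sequence[PTMLResult], cohort: Optional[Cohort] = None) -> pd.DataFrame:
    """Tidy per-sample score table; adds the ATML column when a cohort is given."""
    frame = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "ptml": [r.ptml for r in results],
            "ptml_class": [r.ptml_class for r in results],
            "n_unknown_genes": [len(r.unknown_genes) for r in results],
        }
    )
    if cohort is not None:
        frame["atml"] = frame["sample_id"].map(cohort.atml)
    return frame


def read_calls(
    path: str | Path,
    *,
    whitelist: frozenset[str] | set[str] = DEFAULT_NONSYNONYMOUS_CLASSES,
) -> list[PanelCalls]:
    """Read per-sample panel calls from a MAF or a gene,count table.

    A file whose header contains ``Hugo_Symbol`` is treated as a MAF and run
    through the non-synonymous filter.  Otherwise a TSV/CSV with columns
    ``gene`` and ``count`` (single sample, named after the file) or
    ``sample_id``, ``gene``, ``count`` is accepted — the shape in which
    clinical panel results are typically reported.
    """
    path = Path(path)
    with open(path) as handle:
        header = handle.readline()
    if "Hugo_Symbol" in header:
        records = filter_nonsynonymous(read_maf(path), whitelist)
        cohort = build_cohort(records)
        per_sample: dict[str, dict[str, int]] = {}
        for (sample, gene), count in cohort.gene_mutation_count.items():
            per_sample.setdefault(sample, {})[gene] = count
        for sample in cohort.samples:
            per_sample.setdefault(sample, {})
        return [PanelCalls(s, counts) for s, counts in sorted(per_sample.items())]

    sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(path, sep=sep, dtype={"gene": str})
    if "gene" not in frame.columns or "count" not in frame.columns:
        raise ValueError(
            f"calls table {path} must have columns gene,count (optionally sample_id)"
        )
    frame["gene"] = frame["gene"].str.upper()
    if "sample_id" in frame.columns:
        grouped = frame.groupby("sample_id", sort=True)
        return [
            PanelCalls(str(sample), dict(zip(g["gene"], g["count"].astype(int))))
            for sample, g in grouped
        ]
    return [PanelCalls(path.stem, dict(zip(frame["gene"], frame["count"].astype(int))))]


def write_scores(results: Sequence[PTMLResult], path: str | Path) -> None:
    scores_frame(results).to_csv(path, sep="\t", index=False)
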