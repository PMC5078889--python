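"""Derivation of per-gene adjusted mutation values (the PTML weight table).

The predicted total mutation load is

    PTML = sum over mutated panel genes k of RND(unadjusted_k / slope) * count_k

where ``unadjusted_k`` is the lowest ATML among derivation-cohort samples
carrying a mutation in gene ``k`` (so recurrently mutated driver genes,
present even in lightly mutated tumors, earn small values, while genes only
ever hit as passengers in hypermutated tumors earn large ones), ``slope`` is
the least-squares slope of the per-sample unadjusted total against the
ATML, and RND rounds half away from zero.  Panel genes with no carrier in
the derivation cohort are excluded from the table.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .maf_io import Cohort

logger = logging.getLogger(__name__)

REGRESSION_MODES = ("ols_intercept", "ols_through_origin")


class DegenerateRegressionError(ValueError):
    """The derivation cohort yields an unusable regression (flat x or slope <= 0)."""


@dataclass(frozen=True)
class GenePanel:
    """An ordered gene panel (symbols upper-cased, no duplicates)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("panel must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if list(self.genes).count(g) > 1})
            raise ValueError(f"panel contains duplicate symbols: {dupes}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


def read_panel(path: str | Path, name: Optional[str] = None) -> GenePanel:
    """Read a panel file: one gene symbol per line, ``#`` comments allowed."""
    path = Path(path)
    genes: list[str] = []
    seen = set()
    for line in path.read_text().splitlines():
        symbol = line.split("#", 1)[0].strip().upper()
        if not symbol:
            continue
        if symbol in seen:
            raise ValueError(f"duplicate gene symbol in panel file: {symbol}")
        seen.add(symbol)
        genes.append(symbol)
    return GenePanel(name=name or path.stem, genes=tuple(genes))


def write_panel(panel: GenePanel, path: str | Path) -> None:
    Path(path).write_text("\n".join(panel.genes) + "\n")


@dataclass
class WeightTable:
    """Derived per-gene adjusted mutation values plus derivation metadata."""

    cancer_label: str
    slope: float
    regression_mode: str
    unadjusted: dict[str, int]
    adjusted: dict[str, int]
    excluded_genes: frozenset[str]
    derivation_n_samples: int
    derivation_r2: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.regression_mode not in REGRESSION_MODES:
            raise ValueError(f"unknown regression mode {self.regression_mode!r}")
        if set(self.adjusted) != set(self.unadjusted):
            raise ValueError("adjusted and unadjusted must cover the same genes")
        if set(self.adjusted) & self.excluded_genes:
            raise ValueError("a gene cannot be both weighted and excluded")

    @property
    def panel_genes(self) -> frozenset[str]:
        return frozenset(self.adjusted) | self.excluded_genes

    def to_tsv(self, path: str | Path) -> None:
        """Serialize with metadata header lines; bit-exact round-trip."""
        lines = [
            f"#cancer_label={self.cancer_label}",
            f"#slope={self.slope!r}",
            f"#regression_mode={self.regression_mode}",
            f"#derivation_n_samples={self.derivation_n_samples}",
            f"#derivation_r2={self.derivation_r2!r}",
            "gene\tunadjusted_value\tadjusted_value",
        ]
        for gene in sorted(self.adjusted):
            lines.append(f"{gene}\t{self.unadjusted[gene]}\t{self.adjusted[gene]}")
        for gene in sorted(self.excluded_genes):
            lines.append(f"{gene}\tNA\tNA")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "WeightTable":
        meta: dict[str, str] = {}
        unadjusted: dict[str, int] = {}
        adjusted: dict[str, int] = {}
        excluded: set[str] = set()
        header_seen = False
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key] = value
                continue
            if not header_seen:
                if line.split("\t")[:1] != ["gene"]:
                    raise ValueError(f"unexpected weight-table header line: {line!r}")
                header_seen = True
                continue
            gene, unadj, adj = line.split("\t")
            if unadj == "NA":
                excluded.add(gene)
            else:
                unadjusted[gene] = int(unadj)
                adjusted[gene] = int(adj)
        return cls(
            cancer_label=meta["cancer_label"],
            slope=float(meta["slope"]),
            regression_mode=meta["regression_mode"],
            unadjusted=unadjusted,
            adjusted=adjusted,
            excluded_genes=frozenset(excluded),
            derivation_n_samples=int(meta["derivation_n_samples"]),
            derivation_r2=float(meta["derivation_r2"]),
        )


def rnd_half_away_from_zero(x: float) -> int:
    """The equation's RND: round half away from zero (half-up for positives)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def unadjusted_gene_value(cohort: Cohort, gene: str) -> Optional[int]:
    """Minimum ATML among samples carrying a retained mutation in ``gene``.

    Returns None for genes with no carrier (handled by exclusion during
    derivation).  A carrier's ATML is >= 1 by construction.
    """
    carriers = cohort.gene_carriers.get(gene)
    if not carriers:
        return None
    return min(cohort.atml[s] for s in carriers)


def unadjusted_sample_total(
    cohort: Cohort,
    panel: GenePanel,
    sample: str,
    unadjusted: Mapping[str, int],
    *,
    use_multiplicity: bool = True,
) -> int:
    """Sum of unadjusted values over the sample's mutated panel genes.

    With ``use_multiplicity`` (default) each gene's value is multiplied by
    the number of mutations the sample carries in that gene, mirroring the
    scoring rule.
    """
    if sample not in cohort.samples:
        raise KeyError(f"sample {sample!r} not in cohort")
    total = 0
    for gene in panel.genes:
        value = unadjusted.get(gene)
        if value is None:
            continue
        count = cohort.gene_mutation_count.get((sample, gene), 0)
        if count:
            total += value * (count if use_multiplicity else 1)
    return total


def fit_slope(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "ols_intercept",
) -> tuple[float, float]:
    """Least-squares slope of y (unadjusted total) on x (ATML).

    ``ols_intercept`` fits and discards an intercept; ``ols_through_origin``
    constrains the line through the origin.  The returned r² is the squared
    Pearson correlation of x and y under either mode.

    Raises
    ------
    DegenerateRegressionError
        If x is constant or the fitted slope is not positive.
    """
    if mode not in REGRESSION_MODES:
        raise ValueError(f"unknown regression mode {mode!r}")
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape or x_arr.ndim != 1:
        raise ValueError("x and y must be one-dimensional and the same length")
    if x_arr.size < 2:
        raise ValueError("at least two samples are required for the regression")
    if np.ptp(x_arr) == 0:
        raise DegenerateRegressionError("ATML values are constant; slope is undefined")

    if mode == "ols_intercept":
        result = stats.linregress(x_arr, y_arr)
        slope = float(result.slope)
        r2 = float(result.rvalue) ** 2
    else:
        slope = float(np.dot(x_arr, y_arr) / np.dot(x_arr, x_arr))
        if np.ptp(y_arr) == 0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(x_arr, y_arr)[0, 1]) ** 2
    if slope <= 0:
        raise DegenerateRegressionError(
            f"regression slope {slope:.4g} is not positive; derivation cohort unusable"
        )
    return slope, r2


def derive_weights(
    cohort: Cohort,
    panel: GenePanel,
    *,
    mode: str = "ols_intercept",
    cancer_label: str = "",
    use_multiplicity: bool = True,
) -> WeightTable:
    """Run the full weight-derivation procedure on a WES cohort.

    Steps: (1) per-gene unadjusted value = minimum carrier ATML; panel genes
    with no carrier are excluded; (2) per-sample unadjusted total over the
    remaining genes; (3) regression of unadjusted total on ATML across all
    cohort samples (ATML-0 samples contribute the point (0, 0));
    (4) adjusted value = RND(unadjusted / slope).  Deterministic.
    """
    unadjusted: dict[str, int] = {}
    excluded: set[str] = set()
    for gene in panel.genes:
        value = unadjusted_gene_value(cohort, gene)
        if value is None:
            excluded.add(gene)
        else:
            unadjusted[gene] = value
    if not unadjusted:
        raise ValueError("every panel gene lacks a carrier in the derivation cohort")

    samples = sorted(cohort.samples)
    x = [cohort.atml[s] for s in samples]
    y = [
        unadjusted_sample_total(
            cohort, panel, s, unadjusted, use_multiplicity=use_multiplicity
        )
        for s in samples
    ]
    slope, r2 = fit_slope(x, y, mode)

    adjusted = {g: rnd_half_away_from_zero(v / slope) for g, v in unadjusted.items()}
    n_zero = sum(1 for v in adjusted.values() if v == 0)
    if n_zero:
        logger.warning(
            "derive_weights: %d gene(s) rounded to an adjusted value of 0", n_zero
        )
    return WeightTable(
        cancer_label=cancer_label or panel.name,
        slope=slope,
        regression_mode=mode,
        unadjusted=unadjusted,
        adjusted=adjusted,
        excluded_genes=frozenset(excluded),
        derivation_n_samples=len(samples),
        derivation_r2=r2,
    )


def derive_recurrent_panel(cohort: Cohort, k: int, name: str = "recurrent") -> GenePanel:
    """The k most recurrently mutated genes of a cohort, as an alternative panel.

    Genes are ranked by number of carrier samples; ties are broken by total
    mutation count, then lexicographic symbol order, so the output is
    deterministic across runs.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    mutated = sorted(cohort.gene_carriers)
    if k > len(mutated):
        raise ValueError(
            f"k={k} exceeds the {len(mutated)} mutated gene(s) in the cohort"
        )
    totals = {g: 0 for g in mutated}
    for (sample, gene), count in cohort.gene_mutation_count.items():
        totals[gene] += count
    ranked = sorted(
        mutated,
        key=lambda g: (-len(cohort.gene_carriers[g]), -totals[g], g),
    )
    return GenePanel(name=name, genes=tuple(ranked[:k]))
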