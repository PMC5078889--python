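"""Synthetic tumor-cohort generator with the structure panel-based load
prediction assumes.

Each simulated cohort has: (i) a wide per-sample mutation-load distribution
(two-component lognormal mixture) with a lightly mutated subpopulation under
100 mutations; (ii) a small set of driver genes mutated quasi-independently
of load — the BRAF-like recurrent oncogenes that appear even in low-load
tumors and must therefore earn small adjusted values; (iii) panel passenger
genes hit in proportion to load (with a mutability enrichment reflecting
that clinical panels select large, frequently mutated cancer genes);
(iv) substitution classes whose C>T (UV-proxy) fraction rises with load via
a logistic in log-load; and (v) survival times whose hazard depends on the
low/high mutation-load class.  All randomness flows from a single seed via
``numpy.random.SeedSequence`` spawning, so every draw is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .maf_io import MutationRecord
from .signatures import SUBSTITUTION_CLASSES, UV_CLASS
from .weights import GenePanel

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class LoadMixture:
    """Two-component lognormal mixture for the latent per-sample load.

    Defaults put ~25% of samples in a low component (median 30 mutations)
    and the rest in a heavy-tailed high component (median 600), giving loads
    spanning roughly 1–5,000 with ~25–30% of samples at or under 100.
    """

    weight_low: float = 0.25
    mu_low: float = math.log(30.0)
    sigma_low: float = 0.8
    mu_high: float = math.log(600.0)
    sigma_high: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_low <= 1.0:
            raise ValueError("weight_low must be in [0, 1]")
        if self.sigma_low <= 0 or self.sigma_high <= 0:
            raise ValueError("mixture sigmas must be positive")

    def mean(self) -> float:
        """Analytic mean of the (unrounded) mixture."""
        low = math.exp(self.mu_low + self.sigma_low**2 / 2)
        high = math.exp(self.mu_high + self.sigma_high**2 / 2)
        return self.weight_low * low + (1 - self.weight_low) * high


@dataclass(frozen=True)
class PanelSpec:
    """Panel composition: driver block plus enriched passenger block.

    ``driver_offset`` rotates which block of the shared panel gene list acts
    as the driver set, so two "cancer types" with disjoint drivers but an
    identical panel can be simulated (the cross-application experiment).
    ``panel_enrichment`` is the mutability multiplier of panel passenger
    genes relative to an average background gene.
    """

    n_driver: int = 8
    driver_base_prob: float = 0.12
    n_passenger_panel: int = 162
    panel_enrichment: float = 3.0
    driver_offset: int = 0

    def __post_init__(self) -> None:
        if self.n_driver <= 0 or self.n_passenger_panel <= 0:
            raise ValueError("panel gene counts must be positive")
        if not 0.0 <= self.driver_base_prob <= 1.0:
            raise ValueError("driver_base_prob must be in [0, 1]")
        if self.panel_enrichment <= 0:
            raise ValueError("panel_enrichment must be positive")
        n_panel = self.n_driver + self.n_passenger_panel
        if not 0 <= self.driver_offset <= n_panel - self.n_driver:
            raise ValueError("driver_offset places drivers outside the panel")

    @property
    def n_panel(self) -> int:
        return self.n_driver + self.n_passenger_panel


@dataclass(frozen=True)
class UVCoupling:
    """Logistic link from log-load to the per-SNV C>T probability."""

    slope: float = 1.5
    midpoint_log_load: float = math.log(150.0)
    floor: float = 0.10
    ceiling: float = 0.85

    def __post_init__(self) -> None:
        if not 0.0 <= self.floor < self.ceiling <= 1.0:
            raise ValueError("need 0 <= floor < ceiling <= 1")

    def ct_probability(self, load: float) -> float:
        z = self.slope * (math.log(max(load, 1.0)) - self.midpoint_log_load)
        return self.floor + (self.ceiling - self.floor) / (1.0 + math.exp(-z))


@dataclass(frozen=True)
class SurvivalSpec:
    """Exponential event and censoring model with class-dependent hazard.

    Baseline hazard ln(2)/600 per day gives the high-load class a 600-day
    median; low-load tumors have hazard multiplied by
    ``hazard_ratio_low_vs_high`` (poorer outcome under immunotherapy).
    """

    baseline_hazard: float = math.log(2.0) / 600.0
    hazard_ratio_low_vs_high: float = 2.5
    censoring_rate: float = 5e-4

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0 or self.hazard_ratio_low_vs_high <= 0:
            raise ValueError("hazards must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 300
    load_mixture: LoadMixture = field(default_factory=LoadMixture)
    exome_gene_count: int = 18000
    panel_spec: PanelSpec = field(default_factory=PanelSpec)
    uv_coupling: UVCoupling = field(default_factory=UVCoupling)
    survival_spec: SurvivalSpec = field(default_factory=SurvivalSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.exome_gene_count <= self.panel_spec.n_panel:
            raise ValueError("exome_gene_count must exceed the panel size")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in (
            ("load_mixture", LoadMixture),
            ("panel_spec", PanelSpec),
            ("uv_coupling", UVCoupling),
            ("survival_spec", SurvivalSpec),
        ):
            if key in kwargs:
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def panel_gene_names(spec: PanelSpec) -> tuple[str, ...]:
    """The shared panel gene list; a fixed naming scheme across configs."""
    return tuple(f"PGENE{i:04d}" for i in range(1, spec.n_panel + 1))


def driver_gene_names(spec: PanelSpec) -> tuple[str, ...]:
    genes = panel_gene_names(spec)
    return genes[spec.driver_offset : spec.driver_offset + spec.n_driver]


def simulated_panel(config: SimulationConfig, name: str = "simulated-panel") -> GenePanel:
    return GenePanel(name=name, genes=panel_gene_names(config.panel_spec))


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[MutationRecord], pd.DataFrame]:
    """Generate MAF-style records plus a per-sample truth table.

    Per sample: a latent load L from the mixture; each driver gene mutated
    with ``driver_base_prob`` independently of L; L passenger mutations
    distributed multinomially over non-driver genes (panel passengers carry
    ``panel_enrichment``-fold weight); each SNV's substitution class drawn
    with a load-coupled C>T probability and serialized with consistent
    ref/alt on a random strand.  The realized load (= emitted row count) is
    the driver hits plus L.

    The truth table has columns ``sample_id``, ``true_load`` (realized),
    ``latent_load``, ``uv_fraction`` (the C>T probability used), and one
    0/1 column per driver gene.
    """
    spec = config.panel_spec
    root = np.random.SeedSequence(config.seed)
    rng_load, rng_driver, rng_assign, rng_sig = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    mix = config.load_mixture
    n = config.n_samples
    is_low = rng_load.random(n) < mix.weight_low
    mu = np.where(is_low, mix.mu_low, mix.mu_high)
    sigma = np.where(is_low, mix.sigma_low, mix.sigma_high)
    latent = np.maximum(np.rint(np.exp(rng_load.normal(mu, sigma))), 0).astype(int)

    panel = panel_gene_names(spec)
    drivers = list(driver_gene_names(spec))
    driver_set = set(drivers)
    passengers = [g for g in panel if g not in driver_set]
    n_background = config.exome_gene_count - spec.n_panel
    background = [f"BGENE{i:05d}" for i in range(1, n_background + 1)]
    passenger_universe = passengers + background
    weights = np.concatenate(
        [
            np.full(len(passengers), spec.panel_enrichment),
            np.ones(n_background),
        ]
    )
    probs = weights / weights.sum()

    records: list[MutationRecord] = []
    truth_rows = []
    for i in range(n):
        sample = f"SIM{i + 1:05d}"
        load = int(latent[i])
        driver_hits = rng_driver.random(spec.n_driver) < spec.driver_base_prob
        gene_hits: list[tuple[str, int]] = [
            (g, 1) for g, hit in zip(drivers, driver_hits) if hit
        ]
        if load > 0:
            counts = rng_assign.multinomial(load, probs)
            hit_idx = np.nonzero(counts)[0]
            gene_hits.extend(
                (passenger_universe[j], int(counts[j])) for j in hit_idx
            )
        realized = int(driver_hits.sum()) + load

        p_ct = config.uv_coupling.ct_probability(max(load, 1))
        p_other = (1.0 - p_ct) / 5.0
        class_probs = [p_ct if c == UV_CLASS else p_other for c in SUBSTITUTION_CLASSES]
        n_mut = sum(k for _, k in gene_hits)
        class_draws = rng_sig.choice(len(SUBSTITUTION_CLASSES), size=n_mut, p=class_probs)
        flip = rng_sig.random(n_mut) < 0.5

        j = 0
        for gene, count in gene_hits:
            for _ in range(count):
                ref, alt = SUBSTITUTION_CLASSES[class_draws[j]].split(">")
                if flip[j]:
                    ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
                records.append(
                    MutationRecord(
                        sample_id=sample,
                        gene=gene,
                        variant_class="Missense_Mutation",
                        ref_allele=ref,
                        alt_allele=alt,
                    )
                )
                j += 1

        row = {
            "sample_id": sample,
            "true_load": realized,
            "latent_load": load,
            "uv_fraction": p_ct,
        }
        row.update({g: int(hit) for g, hit in zip(drivers, driver_hits)})
        truth_rows.append(row)

    return records, pd.DataFrame(truth_rows)


def simulate_outcomes(
    classes: Mapping[str, str],
    spec: SurvivalSpec,
    seed: int,
) -> pd.DataFrame:
    """Draw per-sample survival outcomes given low/high class labels.

    Event times are exponential with hazard baseline x (HR if low else 1);
    censoring times are independent exponentials at ``censoring_rate`` (no
    censoring when the rate is 0).  Returns a survival table with columns
    sample_id, time, event, group.
    """
    if not classes:
        raise ValueError("classes must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    samples = sorted(classes)
    hazards = np.array(
        [
            spec.baseline_hazard
            * (spec.hazard_ratio_low_vs_high if classes[s] == "low" else 1.0)
            for s in samples
        ]
    )
    event_times = rng.exponential(1.0 / hazards)
    if spec.censoring_rate > 0:
        censor_times = rng.exponential(1.0 / spec.censoring_rate, size=len(samples))
    else:
        censor_times = np.full(len(samples), np.inf)
    observed = event_times <= censor_times
    times = np.minimum(event_times, censor_times)
    return pd.DataFrame(
        {
            "sample_id": samples,
            "time": times,
            "event": observed.astype(int),
            "group": [classes[s] for s in samples],
        }
    )
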