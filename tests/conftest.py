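import numpy as np
import pytest

from ptml import (
    GenePanel,
    MutationRecord,
    SimulationConfig,
    build_cohort,
    derive_weights,
    filter_nonsynonymous,
    score_cohort,
    scores_frame,
    simulate_cohort,
    simulated_panel,
)


def missense(sample, gene, ref="C", alt="T"):
    return MutationRecord(
        sample_id=sample,
        gene=gene,
        variant_class="Missense_Mutation",
        ref_allele=ref,
        alt_allele=alt,
    )


def toy_records():
    """Three-sample fixture: S0 mutation-free, S1 load 10 (G1 mutated),
    S2 load 20 (G1 and G2 mutated); fillers pad the loads.

    With panel {G1, G2}: unadjusted G1=10, G2=20; per-sample unadjusted
    totals (0, 10, 30) against loads (0, 10, 20) give OLS slope 1.5, hence
    adjusted G1=7, G2=13.
    """
    records = [missense("S1", "G1")]
    records += [missense("S1", f"F{i:02d}") for i in range(1, 10)]
    records += [missense("S2", "G1"), missense("S2", "G2")]
    records += [missense("S2", f"F{i:02d}") for i in range(1, 19)]
    return records


@pytest.fixture
def toy_cohort():
    return build_cohort(toy_records(), sample_universe={"S0", "S1", "S2"})


@pytest.fixture
def toy_panel():
    return GenePanel(name="toy", genes=("G1", "G2"))


@pytest.fixture(scope="session")
def recovery_run():
    """Default-configuration train/held-out simulation shared across tests:
    weights derived on 300 training samples, applied to 300 held-out ones."""
    train_cfg = SimulationConfig(seed=0)
    heldout_cfg = SimulationConfig(seed=1)
    panel = simulated_panel(train_cfg)

    train_records, _ = simulate_cohort(train_cfg)
    train_cohort = build_cohort(filter_nonsynonymous(train_records))
    weights = derive_weights(train_cohort, panel, cancer_label="sim-train")

    heldout_records, heldout_truth = simulate_cohort(heldout_cfg)
    heldout_cohort = build_cohort(filter_nonsynonymous(heldout_records))
    results = score_cohort(heldout_cohort, panel, weights)
    frame = scores_frame(results, heldout_cohort)
    frame = frame.merge(
        heldout_truth[["sample_id", "true_load"]], on="sample_id", validate="1:1"
    )
    return {
        "panel": panel,
        "train_cohort": train_cohort,
        "weights": weights,
        "heldout_cohort": heldout_cohort,
        "heldout_records": heldout_records,
        "scores": frame,
    }
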