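"""Quantification: round scheduling, redistribution, quality factor, reports."""

import numpy as np
import pandas as pd
import pytest

from allfoodseq import (
    Genome,
    GenomePanel,
    GenomeSpec,
    MixtureSpec,
    QuantConfig,
    accuracy_from_truth,
    generate_panel,
    iterative_map,
    proportions,
    quality_correct,
    redistribute_multi,
    run_quant,
    saturation_curve,
    simulate_reads,
)
from allfoodseq.mapper import SeedIndex
from allfoodseq.quantify import AssignmentTable
from allfoodseq.synthgen import TaggedReadSet, apply_n_mask


def make_table(masks, names, rounds=None):
    masks = np.asarray(masks, dtype=np.int64)
    if rounds is None:
        rounds = np.where(masks != 0, 0, -1)
    ids = np.array([f"r{i}" for i in range(masks.size)], dtype=object)
    return AssignmentTable(ids, masks, rounds, names)


def test_quant_config_schedules():
    assert QuantConfig(strategy="spec").mismatch_schedule == (0,)
    assert QuantConfig(strategy="quant").mismatch_schedule == (0, 1, 2, 3)
    with pytest.raises(ValueError):
        QuantConfig(mismatch_schedule=(1, 1))
    with pytest.raises(ValueError):
        QuantConfig(mismatch_schedule=())


def test_error_free_reads_all_unique_at_k0(small_panel, small_index):
    mix = MixtureSpec({"alpha": 100.0}, total_reads=500, error_rate=0.0, seed=1)
    reads = simulate_reads(small_panel, mix)
    table = iterative_map(reads, small_index, QuantConfig(strategy="spec",
                                                          apply_quality_factor=False))
    counts = table.status_counts()
    assert counts["unique"] == 500 and counts["unmapped"] == 0
    assert table.unique_counts()["alpha"] == 500


def test_two_error_read_resolves_in_round_two(small_panel, small_index):
    g = small_panel["beta"]
    window = g.codes[3000:3100].copy()
    window[5] = (window[5] + 1) % 4
    window[60] = (window[60] + 2) % 4
    reads = TaggedReadSet(np.array(["r0"], dtype=object), window[None, :])
    table = iterative_map(reads, small_index, QuantConfig(strategy="quant"))
    assert table.round_idx[0] == 2
    assert table.status_counts()["unique"] == 1


def test_duplicate_read_ids_rejected(small_index):
    reads = TaggedReadSet(
        np.array(["dup", "dup"], dtype=object), np.zeros((2, 100), dtype=np.uint8)
    )
    with pytest.raises(ValueError, match="duplicate"):
        iterative_map(reads, small_index, QuantConfig(strategy="spec"))


def test_single_mismatch_round_leaves_binomial_tail_unmapped():
    # P(>= 2 errors | Bin(100, 0.01)) = 0.264: reads failing a k=1-only round
    panel = generate_panel([GenomeSpec("a", 50_000, seed=1)], shared_ancestor_seed=2)
    index = SeedIndex(panel, read_length=100, k_max=1)
    mix = MixtureSpec({"a": 100.0}, total_reads=20_000, error_rate=0.01, seed=3)
    reads = simulate_reads(panel, mix)
    table = iterative_map(reads, index, QuantConfig(mismatch_schedule=(1,)))
    frac = table.status_counts()["unmapped"] / len(reads)
    assert frac == pytest.approx(0.264, abs=0.01)


def test_conservation_every_round(small_panel, small_index, small_reads):
    for schedule in [(0,), (1,), (0, 1, 2, 3)]:
        table = iterative_map(
            small_reads, small_index, QuantConfig(mismatch_schedule=schedule)
        )
        assert sum(table.status_counts().values()) == len(small_reads)


def test_redistribution_proportional_rule():
    # U = {A: 300, B: 100}; one multi read {A,B} -> A += 0.75, B += 0.25
    masks = [0b01] * 300 + [0b10] * 100 + [0b11]
    aug = redistribute_multi(make_table(masks, ["A", "B"]))
    assert aug["A"] == pytest.approx(300.75)
    assert aug["B"] == pytest.approx(100.25)


def test_redistribution_uniform_fallback():
    aug = redistribute_multi(make_table([0b11], ["A", "B"]))
    assert aug["A"] == aug["B"] == pytest.approx(0.5)


def test_redistribution_conserves_mapped_reads(rng):
    # 10000 random multi reads over 4 genomes: sum augmented = unique + multi
    uniq_masks = (np.int64(1) << rng.integers(0, 4, size=500)).tolist()
    multi = []
    while len(multi) < 10_000:
        m = int(rng.integers(1, 16))
        if bin(m).count("1") >= 2:
            multi.append(m)
    aug = redistribute_multi(make_table(uniq_masks + multi, list("ABCD")))
    assert aug.sum() == pytest.approx(500 + 10_000, abs=1e-9)


def test_quality_factor_closed_form():
    quality = pd.DataFrame(
        {"c": [1_000_000, 1_000_000], "n": [0, 100_000], "f": [1.0, 1.1]},
        index=["A", "B"],
    )
    counts = pd.Series({"A": 1000.0, "B": 1000.0})
    out = quality_correct(counts, quality)
    assert out["A"] == 1000.0 and out["B"] == pytest.approx(1100.0)
    assert quality_correct(counts, quality, apply=False).equals(counts)
    with pytest.raises(ValueError, match="quality record"):
        quality_correct(pd.Series({"Z": 1.0}), quality)


def test_panel_quality_invariants(small_panel):
    q = small_panel.quality()
    assert (q["f"] >= 1.0).all()
    assert (q["n"] <= q["c"]).all()
    assert ((q["f"] == 1.0) == (q["n"] == 0)).all()


def test_quality_factor_compensates_incomplete_reference():
    """Reads from a complete organism mapped to a 10%-N draft: the species is
    undercounted (~47.4/52.6) until the f = (n+c)/c correction restores ~50/50."""
    specs = [
        GenomeSpec("a", 200_000, divergence=0.05, ancestor="x", seed=1),
        GenomeSpec("b", 200_000, divergence=0.05, ancestor="x", seed=2),
    ]
    source = generate_panel(specs, shared_ancestor_seed=11)
    rng = np.random.default_rng(12)
    draft_b = Genome("b", apply_n_mask(source["b"].codes, 0.10, rng, mean_block=5000))
    mapping_panel = GenomePanel([source["a"], draft_b])
    mix = MixtureSpec({"a": 50.0, "b": 50.0}, total_reads=30_000, error_rate=0.0,
                      seed=13)
    reads = simulate_reads(source, mix)  # drawn from the complete genomes
    index = SeedIndex(mapping_panel, read_length=100, k_max=0)
    table = iterative_map(reads, index, QuantConfig(strategy="spec"))
    counts = redistribute_multi(table)

    raw = proportions(counts).proportions
    assert raw["b"] == pytest.approx(47.4, abs=1.5)
    corrected = proportions(
        quality_correct(counts, mapping_panel.quality())
    ).proportions
    assert corrected["b"] == pytest.approx(50.0, abs=1.0)
    assert corrected["a"] == pytest.approx(50.0, abs=1.0)


def test_proportions_basic():
    rep = proportions(pd.Series({"A": 600.0, "B": 400.0}))
    assert rep.proportions["A"] == 60.0 and rep.proportions["B"] == 40.0
    assert proportions(pd.Series({"A": 5.0})).proportions["A"] == 100.0
    with pytest.raises(ValueError):
        proportions(pd.Series({"A": 0.0}))


def test_proportions_sum_to_100(small_panel, small_index, small_reads):
    table = iterative_map(small_reads, small_index, QuantConfig())
    rep = proportions(redistribute_multi(table))
    assert rep.proportions.sum() == pytest.approx(100.0, abs=1e-6)


def test_omitted_genome_reports_zero_and_target_difference():
    # a species declared in the targets but absent from the panel counts
    rep = proportions(
        pd.Series({"A": 900.0, "B": 100.0}),
        targets={"A": 85.0, "B": 9.11, "C": 5.89},
    )
    assert rep.table.loc["C", "proportion_pct"] == 0.0
    assert rep.table.loc["C", "diff_abs_pct"] == pytest.approx(5.89)
    assert rep.table.loc["C", "diff_rel_pct"] == pytest.approx(100.0)


def test_relative_difference_na_for_zero_target(tmp_path):
    rep = proportions(
        pd.Series({"A": 990.0, "decoy": 10.0}), targets={"A": 100.0, "decoy": 0.0}
    )
    assert np.isnan(rep.table.loc["decoy", "diff_rel_pct"])
    frame = rep.to_frame()
    assert frame.loc["decoy", "diff_rel_pct"] == "n.a."
    text = rep.to_tsv(tmp_path / "r.tsv").read_text()
    assert "n.a." in text


def test_accuracy_trivial_cases():
    names = ["A", "B"]
    table = make_table([0b01] * 999 + [0b10], names)
    origins = np.array(["A"] * 1000, dtype=object)
    overall, per = accuracy_from_truth(table, origins)
    assert overall == pytest.approx(99.9)
    all_right = make_table([0b01] * 10, names)
    assert accuracy_from_truth(all_right, np.array(["A"] * 10, dtype=object))[0] == 100.0
    with pytest.raises(ValueError):
        accuracy_from_truth(table, None)


def test_saturation_full_pool_equals_full_run(small_panel, small_index, small_reads):
    targets = {"alpha": 20.0, "beta": 30.0, "gamma": 50.0}
    cfg = QuantConfig(mismatch_schedule=(1,), apply_quality_factor=False)
    curve = saturation_curve(
        small_reads, small_index, cfg, targets, sizes=[len(small_reads)], seed=3
    )
    _, full = run_quant(small_reads, small_index, cfg, targets=targets)
    assert curve["mean_deviation"].iloc[0] == pytest.approx(full.sum_abs_deviation())
    assert curve["sd_deviation"].iloc[0] == 0.0


def test_saturation_deviation_shrinks_with_size(small_panel, small_index, small_reads):
    targets = {"alpha": 20.0, "beta": 30.0, "gamma": 50.0}
    cfg = QuantConfig(mismatch_schedule=(1,), apply_quality_factor=False)
    curve = saturation_curve(
        small_reads, small_index, cfg, targets,
        sizes=[300, 6000], replicates=5, seed=4,
    )
    means = curve["mean_deviation"].to_numpy()
    assert means[0] >= means[1]
    with pytest.raises(ValueError, match="exceeds"):
        saturation_curve(small_reads, small_index, cfg, targets, sizes=[10_000])
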