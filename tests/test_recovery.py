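import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solvselect import (
    RecoverySimSpec,
    compute_all_recoveries,
    compute_recovery,
    fold_change,
    normalize_and_sum,
    simulate_peak_areas,
    summarize_recoveries,
)
from solvselect.datasets import load_equisplash_recoveries, recoveries_as_results
from solvselect.errors import IncompleteDesignError, SolvselectError
from solvselect.recovery import RecoveryResult, assign_tier


def areas_table(pre, post, lipid="L1", method="m"):
    rows = []
    for i, a in enumerate(pre):
        rows.append((lipid, method, i + 1, "pre", a))
    for i, a in enumerate(post):
        rows.append((lipid, method, i + 1, "post", a))
    return pd.DataFrame(
        rows, columns=["lipid_id", "method", "replicate", "spike_timing", "area"]
    )


def test_equal_pre_and_post_gives_full_recovery():
    result = compute_recovery(areas_table([7.0, 8.0, 9.0], [7.0, 8.0, 9.0]), "L1", "m")
    assert result.recovery_pct == pytest.approx(100.0)


def test_exact_half_recovery_with_zero_dispersion():
    result = compute_recovery(areas_table([50.0] * 3, [100.0] * 3), "L1", "m")
    assert result.recovery_pct == pytest.approx(50.0)
    assert result.dispersion_pct == pytest.approx(0.0)
    assert (result.n_pre, result.n_post) == (3, 3)


def test_dispersion_propagates_group_cvs():
    pre = np.array([90.0, 100.0, 110.0])
    post = np.array([190.0, 200.0, 210.0])
    result = compute_recovery(areas_table(pre, post), "L1", "m")
    cv_pre = pre.std(ddof=1) / pre.mean()
    cv_post = post.std(ddof=1) / post.mean()
    expected = result.recovery_pct * np.sqrt(cv_pre**2 + cv_post**2)
    assert result.dispersion_pct == pytest.approx(expected)


@given(st.floats(min_value=0.01, max_value=1e6))
@settings(max_examples=30, derandomize=True, deadline=None)
def test_recovery_invariant_under_block_rescaling(scale):
    base = areas_table([40.0, 50.0, 60.0], [90.0, 100.0, 110.0])
    scaled = base.assign(area=base["area"] * scale)
    a = compute_recovery(base, "L1", "m")
    b = compute_recovery(scaled, "L1", "m")
    assert b.recovery_pct == pytest.approx(a.recovery_pct, rel=1e-9)
    assert b.dispersion_pct == pytest.approx(a.dispersion_pct, rel=1e-9)


def test_missing_timing_group_raises():
    table = areas_table([1.0], [2.0]).query("spike_timing == 'pre'")
    with pytest.raises(IncompleteDesignError):
        compute_recovery(table, "L1", "m")


def test_nonpositive_area_rejected():
    with pytest.raises(SolvselectError):
        compute_recovery(areas_table([1.0, -1.0], [2.0, 2.0]), "L1", "m")


def test_summary_reproduces_published_method_averages():
    """Bundled per-lipid recoveries summarize to the published column means."""
    results = recoveries_as_results(load_equisplash_recoveries())
    assert summarize_recoveries(results, "chloroform").rounded()[0] == 96
    assert summarize_recoveries(results, "tame").rounded()[0] == 59


def test_summary_is_permutation_invariant():
    results = recoveries_as_results(load_equisplash_recoveries())
    shuffled = list(results)[::-1]
    a = summarize_recoveries(shuffled, "cpme")
    b = summarize_recoveries(results, "cpme")
    assert a.mean_pct == pytest.approx(b.mean_pct)
    assert a.sd_pct == pytest.approx(b.sd_pct)
    assert a.n_lipids == b.n_lipids


def test_summary_single_lipid_flags_undefined_sd():
    only = [RecoveryResult("L1", "m", 88.0, 2.0, 3, 3)]
    summary = summarize_recoveries(only, "m")
    assert summary.mean_pct == pytest.approx(88.0)
    assert summary.sd_pct == 0.0
    assert not summary.sd_defined


def species_table(rows):
    return pd.DataFrame(
        rows, columns=["species", "lipid_class", "method", "replicate", "area"]
    )


def test_single_species_matching_standard_gives_unit_class_sum():
    table = species_table(
        [
            ("sp1", "PC", "m", 1, 500.0),
            ("IS_PC", "PC", "m", 1, 500.0),
        ]
    )
    norm, excluded = normalize_and_sum(table, {"PC": "IS_PC"})
    assert excluded == []
    assert norm["value"].tolist() == pytest.approx([1.0])


def test_normalization_invariant_to_global_doubling():
    table = species_table(
        [
            ("sp1", "PC", "m", 1, 300.0),
            ("sp2", "PC", "m", 1, 700.0),
            ("IS_PC", "PC", "m", 1, 400.0),
        ]
    )
    doubled = table.assign(area=table["area"] * 2)
    a, _ = normalize_and_sum(table, {"PC": "IS_PC"})
    b, _ = normalize_and_sum(doubled, {"PC": "IS_PC"})
    assert a["value"].tolist() == pytest.approx(b["value"].tolist())


def test_class_sums_match_hand_arithmetic():
    table = species_table(
        [
            ("a1", "A", "m", 1, 100.0),
            ("a2", "A", "m", 1, 300.0),
            ("IS_A", "A", "m", 1, 200.0),
            ("b1", "B", "m", 1, 50.0),
            ("IS_B", "B", "m", 1, 25.0),
            ("c1", "C", "m", 1, 10.0),
        ]
    )
    norm, excluded = normalize_and_sum(table, {"A": "IS_A", "B": "IS_B"})
    values = dict(zip(norm["lipid_class"], norm["value"]))
    assert values == {"A": pytest.approx(2.0), "B": pytest.approx(2.0)}
    assert excluded == ["C"]  # no matched standard -> reported, not summed


def test_absent_standard_measurement_raises():
    table = species_table([("sp1", "PC", "m", 1, 500.0)])
    with pytest.raises(SolvselectError, match="IS_PC"):
        normalize_and_sum(table, {"PC": "IS_PC"})


def norm_table(class_values):
    rows = []
    for (lipid_class, method), values in class_values.items():
        for i, v in enumerate(values):
            rows.append((lipid_class, method, i + 1, v))
    return pd.DataFrame(rows, columns=["lipid_class", "method", "replicate", "value"])


def test_fold_change_of_reference_is_identity():
    norm = norm_table({("PC", "ref"): [1.0, 1.1, 0.9]})
    (result,) = fold_change(norm, "ref", "ref")
    assert result.fold_change == pytest.approx(1.0)
    assert result.p_value == pytest.approx(1.0)
    assert result.tier == "ns"


def test_fold_change_exact_ratio():
    norm = norm_table(
        {("PC", "m"): [2.0] * 6, ("PC", "ref"): [1.0] * 6}
    )
    (result,) = fold_change(norm, "m", "ref")
    assert result.fold_change == pytest.approx(2.0)


def test_tiers_monotone_in_p_value():
    labels = [assign_tier(p) for p in (0.0005, 0.003, 0.008, 0.03, 0.2)]
    assert labels == ["****", "***", "**", "*", "ns"]


def test_single_replicate_not_assessable():
    norm = norm_table({("PC", "m"): [2.0], ("PC", "ref"): [1.0, 1.1]})
    (result,) = fold_change(norm, "m", "ref")
    assert result.tier == "not-assessable"
    assert result.p_value is None


def test_planted_class_effect_recovered_with_significance():
    """A planted 1.45-fold class effect at 5% noise, n=6, is estimated within
    simulation tolerance and flagged significant."""
    spec = RecoverySimSpec(
        class_effect={("LPC", "mmc_cpme"): 1.45},
        cv=0.05,
        n_replicates=6,
        seed=41,
    )
    sim = simulate_peak_areas(spec)
    norm, _ = normalize_and_sum(sim.species, dict(sim.standards))
    results = {r.lipid_class: r for r in fold_change(norm, "mmc_cpme", "folch_chcl3")}
    assert results["LPC"].fold_change == pytest.approx(1.45, abs=0.15)
    assert results["LPC"].tier != "ns"
    # classes without a planted effect stay near unity
    assert results["PC"].fold_change == pytest.approx(1.0, abs=0.15)


def test_all_recoveries_covers_every_pair():
    sim = simulate_peak_areas(RecoverySimSpec(seed=3))
    results = compute_all_recoveries(sim.areas)
    assert len(results) == len(sim.spec.lipids) * len(sim.spec.methods)
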