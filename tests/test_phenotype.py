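import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import chemscreen as cs


def _table(lib, **cols):
    counts = pd.DataFrame(cols, index=pd.Index(lib.table.sgrna_id, name="sgrna_id"))
    roles = {"t0": "t0", "untreated": "untreated", "treated": "treated"}
    samples = {name: cs.SampleInfo(name, roles[name]) for name in cols}
    return cs.CountTable(counts, samples)


PARAMS = cs.PhenotypeParams(doublings_untreated=10.0, doubling_difference=6.1)


def test_log2_enrichment_hand_example():
    """(30,10) vs (10,30) at pseudocount 10 -> frequencies (2/3,1/3) vs
    (1/3,2/3) -> e = (+1, -1)."""
    e = cs.log2_enrichment(pd.Series([30, 10]), pd.Series([10, 30]), pseudocount=10)
    assert np.allclose(e, [1.0, -1.0])


def test_log2_enrichment_identity_and_antisymmetry():
    a = pd.Series([5, 50, 500])
    assert np.allclose(cs.log2_enrichment(a, a), 0.0)
    b = pd.Series([100, 10, 1])
    assert np.allclose(cs.log2_enrichment(a, b), -cs.log2_enrichment(b, a))


@given(st.integers(2, 64))
def test_log2_enrichment_scale_invariance_at_negligible_pseudocount(factor):
    a = pd.Series([30, 10, 250, 4])
    b = pd.Series([10, 30, 100, 90])
    base = cs.log2_enrichment(a, b, pseudocount=1e-9)
    scaled = cs.log2_enrichment(a * factor, b * factor, pseudocount=1e-9)
    assert np.allclose(base, scaled, atol=1e-6)


def test_log2_enrichment_scale_invariance_first_order_at_default_pseudocount():
    # at depths >> pseudocount the default pseudocount perturbs e by O(pc/depth)
    rng = np.random.default_rng(0)
    a = pd.Series(rng.integers(5000, 20000, 50))
    b = pd.Series(rng.integers(5000, 20000, 50))
    base = cs.log2_enrichment(a, b, pseudocount=10)
    scaled = cs.log2_enrichment(2 * a, 2 * b, pseudocount=10)
    assert np.allclose(base, scaled, atol=5e-3)


def test_identical_samples_give_zero_phenotypes(toy_library):
    rng = np.random.default_rng(1)
    col = rng.integers(10, 1000, len(toy_library))
    counts = _table(toy_library, t0=col, untreated=col, treated=col)
    res = cs.compute_phenotypes(counts, toy_library, PARAMS)
    assert np.allclose(res.table.gamma, 0.0)
    assert np.allclose(res.table.rho, 0.0)


def _mini_library():
    return cs.SgRNALibrary.from_frame(pd.DataFrame({
        "sgrna_id": ["tgt", "n1", "n2", "n3"],
        "sequence": ["AAAA", "CCCC", "GGGG", "TTTT"],
        "gene": ["G1", "x", "x", "x"],
        "tss": ["P1", "x", "x", "x"],
        "is_nontargeting": [False, True, True, True],
    }))


def test_gamma_hand_arithmetic():
    """Pseudocounted frequencies worked by hand: t0 uniform, untreated
    (60,20,20,20), pc=10 -> e_target = log2(7/4), e_NT = log2(3/4);
    gamma = (e_target - median e_NT) / D_u = log2(7/3) / 10."""
    lib = _mini_library()
    counts = cs.CountTable(
        pd.DataFrame({"t0": [10, 10, 10, 10], "untreated": [60, 20, 20, 20]},
                     index=pd.Index(lib.table.sgrna_id, name="sgrna_id")),
        {"t0": cs.SampleInfo("t0", "t0"),
         "untreated": cs.SampleInfo("untreated", "untreated")},
    )
    res = cs.compute_gamma(counts, lib, cs.PhenotypeParams(doublings_untreated=10.0))
    assert res.table.loc[0, "gamma"] == pytest.approx(np.log2(7 / 3) / 10)
    assert np.allclose(res.table.loc[1:, "gamma"], 0.0)


def test_rho_hand_arithmetic_with_doubling_difference():
    """Treated vs untreated enrichment of exactly -2.44 log2 units after NT
    centering, divided by dD = 6.1, gives rho = -0.4."""
    lib = _mini_library()
    # totals cancel in the NT-centered difference, so only the per-sgRNA
    # pseudocounted ratios matter: NT ratio 1, target ratio
    # (2349+10)/(12790+10) = 0.1842969 ~ 2^-2.44 (rel. 2e-5)
    counts = cs.CountTable(
        pd.DataFrame({"untreated": [12790, 12790, 12790, 12790],
                      "treated": [2349, 12790, 12790, 12790]},
                     index=pd.Index(lib.table.sgrna_id, name="sgrna_id")),
        {"untreated": cs.SampleInfo("untreated", "untreated"),
         "treated": cs.SampleInfo("treated", "treated")},
    )
    res = cs.compute_rho(counts, lib, cs.PhenotypeParams(doubling_difference=6.1))
    assert res.table.loc[0, "rho"] == pytest.approx(-2.44 / 6.1, rel=1e-3)
    assert res.table.loc[0, "rho"] == pytest.approx(-0.4, rel=1e-3)


def test_nontargeting_median_is_exactly_zero(sim_screen):
    _, lib, counts, _ = sim_screen
    res = cs.compute_phenotypes(counts, lib, PARAMS)
    nt = res.table.loc[res.table.is_nontargeting]
    assert float(np.median(nt.gamma)) == 0.0
    assert float(np.median(nt.rho)) == 0.0


def test_nontargeting_median_exact_zero_even_count(toy_library):
    # drop one NT sgRNA so the median is an even-count interpolation
    rng = np.random.default_rng(2)
    counts = _table(
        toy_library,
        t0=rng.integers(50, 500, len(toy_library)),
        untreated=rng.integers(50, 500, len(toy_library)),
        treated=rng.integers(50, 500, len(toy_library)),
    )
    lib10 = cs.SgRNALibrary.from_frame(toy_library.table.iloc[:-1])
    counts10 = cs.CountTable(counts.counts.iloc[:-1], counts.samples)
    res = cs.compute_phenotypes(counts10, lib10, PARAMS)
    nt = res.table.loc[res.table.is_nontargeting]
    assert len(nt) == 10
    assert float(np.median(nt.gamma)) == 0.0
    assert float(np.median(nt.rho)) == 0.0


def test_uniform_depth_artifact_cancels_in_gamma(toy_library):
    """A uniform depth-change artifact in one sample drops out: frequencies
    absorb the scale and the NT-median subtraction removes any residual
    constant enrichment shift (exact in the pseudocount-negligible regime)."""
    rng = np.random.default_rng(3)
    n = len(toy_library)
    t0 = rng.integers(1000, 5000, n)
    untreated = rng.integers(1000, 5000, n)
    params = cs.PhenotypeParams(pseudocount=1e-9, doublings_untreated=10.0)
    base = cs.compute_gamma(_table(toy_library, t0=t0, untreated=untreated),
                            toy_library, params)
    scaled = cs.compute_gamma(_table(toy_library, t0=t0, untreated=untreated * 8),
                              toy_library, params)
    assert np.allclose(base.table.gamma, scaled.table.gamma, atol=1e-9)


def test_sign_contract_depletion_under_drug_is_negative_rho(toy_library):
    counts = _table(
        toy_library,
        t0=np.full(len(toy_library), 1000),
        untreated=np.full(len(toy_library), 1000),
        treated=np.where(toy_library.table.gene == "ALPHA", 100, 1000),
    )
    res = cs.compute_phenotypes(counts, toy_library, PARAMS)
    alpha = res.table.loc[res.table.gene == "ALPHA", "rho"]
    assert (alpha < 0).all()


def test_rho_requires_doubling_difference(toy_library):
    counts = _table(toy_library, t0=np.full(len(toy_library), 10),
                    untreated=np.full(len(toy_library), 10),
                    treated=np.full(len(toy_library), 10))
    with pytest.raises(ValueError, match="doubling_difference"):
        cs.compute_rho(counts, toy_library, cs.PhenotypeParams())
    with pytest.raises(ValueError, match="doublings_untreated"):
        cs.compute_gamma(counts, toy_library, cs.PhenotypeParams())


def test_min_reads_filter_flags_rows_without_editing_survivors(toy_library):
    rng = np.random.default_rng(5)
    t0 = rng.integers(0, 200, len(toy_library))
    t0[:4] = [0, 3, 5, 9]
    counts = _table(toy_library, t0=t0,
                    untreated=rng.integers(50, 200, len(toy_library)),
                    treated=rng.integers(50, 200, len(toy_library)))
    loose = cs.compute_phenotypes(counts, toy_library, PARAMS)
    strict_params = cs.PhenotypeParams(pseudocount=10, min_reads=10,
                                       doublings_untreated=10.0,
                                       doubling_difference=6.1)
    strict = cs.compute_phenotypes(counts, toy_library, strict_params)
    assert strict.table.filtered[:4].all()
    assert strict.table.loc[strict.table.filtered, "rho"].isna().all()
    surv = ~strict.table.filtered
    # surviving values identical to the unfiltered run: rows removed, never edited
    assert np.allclose(strict.table.loc[surv, "rho"], loose.table.loc[surv, "rho"])
    assert np.array_equal(np.sign(strict.table.loc[surv, "e_tr_ut"]),
                          np.sign(loose.table.loc[surv, "e_tr_ut"]))


def test_replicates_are_averaged_and_retained(toy_library):
    rng = np.random.default_rng(6)
    n = len(toy_library)
    counts = pd.DataFrame(
        {
            "t0": rng.integers(100, 1000, n),
            "treatedA": rng.integers(100, 1000, n),
            "treatedB": rng.integers(100, 1000, n),
            "untr": rng.integers(100, 1000, n),
        },
        index=pd.Index(toy_library.table.sgrna_id, name="sgrna_id"),
    )
    samples = {
        "t0": cs.SampleInfo("t0", "t0"),
        "treatedA": cs.SampleInfo("treatedA", "treated"),
        "treatedB": cs.SampleInfo("treatedB", "treated"),
        "untr": cs.SampleInfo("untr", "untreated"),
    }
    table = cs.CountTable(counts, samples)
    res = cs.compute_phenotypes(table, toy_library, PARAMS)
    rep_cols = [c for c in res.replicates.columns if c.startswith("rho[")]
    assert len(rep_cols) == 2
    assert np.allclose(res.replicates[rep_cols].mean(axis=1), res.table.rho)


def test_recovered_rho_centered_on_truth_for_nontargeting(sim_screen):
    _, lib, counts, truth = sim_screen
    res = cs.compute_phenotypes(counts, lib, PARAMS)
    nt = res.table.loc[res.table.is_nontargeting, "rho"]
    assert abs(nt.mean()) < 0.02


# -- BFP re-test enrichment ------------------------------------------------


def test_retest_constant_fraction_gives_unit_enrichment():
    tab = pd.DataFrame({"treated": [0.5, 0.5, 0.5], "untreated": [0.5, 0.5, 0.5]},
                       index=[0, 4, 8])
    out = cs.retest_enrichment(tab)
    assert np.allclose(out[["treated", "untreated", "relative"]], 1.0)


def test_retest_depletion_under_drug():
    tab = pd.DataFrame({"untreated": [0.5, 0.5], "treated": [0.5, 0.25]},
                       index=[0, 6])
    out = cs.retest_enrichment(tab)
    assert out.loc[6, "relative"] == pytest.approx(0.5)


def test_retest_label_swap_inverts_relative_enrichment():
    tab = pd.DataFrame({"untreated": [0.4, 0.3], "treated": [0.4, 0.6]}, index=[0, 5])
    fwd = cs.retest_enrichment(tab)
    swapped = cs.retest_enrichment(tab.rename(columns={"untreated": "treated",
                                                       "treated": "untreated"}))
    assert np.allclose(fwd["relative"], 1.0 / swapped["relative"])


def test_retest_degenerate_baseline_rejected():
    tab = pd.DataFrame({"untreated": [1.0, 0.5], "treated": [0.5, 0.25]}, index=[0, 6])
    with pytest.raises(ValueError, match="\\(0, 1\\)"):
        cs.retest_enrichment(tab)
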