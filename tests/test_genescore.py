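import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import chemscreen as cs
from oracles import exact_rank_sum_p, top_k_signed_mean


# -- top-3 collapse --------------------------------------------------------


def test_collapse_examples():
    assert cs.collapse_gene([0.1, 0.2, 0.3]) == pytest.approx(0.2)
    assert cs.collapse_gene([-0.50, 0.40, -0.45, 0.01, -0.02]) == pytest.approx(
        (-0.50 - 0.45 + 0.40) / 3
    )
    assert cs.collapse_gene([0.0, 0.0, 0.0, 0.0]) == 0.0
    assert cs.collapse_gene([0.3, -0.2]) == pytest.approx(0.05)  # fewer than k


@given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=9))
def test_collapse_matches_brute_force_oracle(values):
    assert cs.collapse_gene(values) == pytest.approx(top_k_signed_mean(values), abs=1e-12)


@given(st.permutations(range(6)))
def test_collapse_invariant_to_sgrna_order(perm):
    vals = np.array([-0.50, 0.40, -0.45, 0.01, -0.02, 0.33])
    ids = np.array([f"sg{i}" for i in range(6)])
    perm = np.array(perm)
    ref = cs.collapse_gene(vals, ids)
    assert cs.collapse_gene(vals[perm], ids[perm]) == ref


def test_collapse_tie_break_is_deterministic_by_id():
    # |0.2| tie between sg_a(+0.2) and sg_b(-0.2): lexicographic id order wins
    vals = [0.5, -0.4, 0.2, -0.2]
    ids = ["sg1", "sg2", "sg_a", "sg_b"]
    got = cs.collapse_gene(vals, ids, k=3)
    assert got == pytest.approx((0.5 - 0.4 + 0.2) / 3)


# -- Mann-Whitney ----------------------------------------------------------


def test_complete_separation_3v3_exact_p():
    assert cs.rank_sum_p([2.0, 2.1, 2.2], [-0.1, 0.0, 0.1]) == pytest.approx(0.1)
    assert exact_rank_sum_p([2.0, 2.1, 2.2], [-0.1, 0.0, 0.1]) == pytest.approx(0.1)


def test_total_tie_gives_p_one():
    assert cs.rank_sum_p([3.0, 3.0, 3.0], [3.0, 3.0, 3.0]) == 1.0


def test_rank_sum_symmetry_and_empty_group_error():
    x, y = [1.0, 4.0, 2.5], [0.5, 3.0, 8.0, 9.0]
    assert cs.rank_sum_p(x, y) == cs.rank_sum_p(y, x)
    with pytest.raises(ValueError):
        cs.rank_sum_p([], y)


@given(st.integers(2, 6), st.integers(2, 6), st.integers(0, 10_000))
def test_exact_p_matches_enumeration_oracle(m, n, seed):
    rng = np.random.default_rng(seed)
    pooled = rng.normal(size=m + n)
    while np.unique(pooled).size < m + n:  # pragma: no cover - ties ~impossible
        pooled = rng.normal(size=m + n)
    x, y = pooled[:m], pooled[m:]
    assert cs.rank_sum_p(x, y) == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)


def test_exact_path_used_below_crossover_and_approximation_quality():
    """Groups of size <= 8 take the exact path, so the normal approximation is
    never substituted there; and where group sizes reach 5-8 the
    continuity-corrected approximation itself stays within 0.02 of the exact
    p (exhaustively, over every achievable U)."""
    from oracles import exact_p_two_sided, exact_u_distribution

    # implementation == enumeration everywhere in the exact regime
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=8), rng.normal(size=8)
    assert cs.rank_sum_p(x, y) == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)

    worst = 0.0
    for m in range(5, 9):
        for n in range(m, 9):
            dist = exact_u_distribution(m, n)
            mu, sd = m * n / 2, np.sqrt(m * n * (m + n + 1) / 12)
            for u in dist:
                p_exact = exact_p_two_sided(dist, u, m, n)
                z = (u - mu - np.sign(u - mu) * 0.5) / sd if u != mu else 0.0
                p_apx = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
                worst = max(worst, abs(p_exact - p_apx))
    assert worst < 0.02


# -- negative-control pseudo-genes ----------------------------------------


def test_pseudo_gene_membership_and_determinism(toy_library):
    ncg = cs.make_negative_control_genes(toy_library, n_pseudo=4, size=5, seed=2)
    nt = set(toy_library.nontargeting_ids)
    assert len(ncg) == 4 and ncg.size == 5
    for grp in ncg.groups:
        assert len(set(grp)) == 5 and set(grp) <= nt
    again = cs.make_negative_control_genes(toy_library, n_pseudo=4, size=5, seed=2)
    assert again.groups == ncg.groups
    member_sets = {frozenset(g) for g in ncg.groups}
    assert len(member_sets) == 4  # no duplicated member sets


def test_pseudo_gene_size_exceeding_pool_is_an_error(toy_library):
    with pytest.raises(ValueError, match="non-targeting"):
        cs.make_negative_control_genes(toy_library, n_pseudo=2, size=12, seed=0)


def test_pseudo_gene_member_usage_is_uniform(sim_screen):
    """Chi-square goodness of fit on pooled membership over many pseudo-genes
    (large non-targeting pool so distinct member sets exist in abundance)."""
    _, lib, _, _ = sim_screen
    ncg = cs.make_negative_control_genes(lib, n_pseudo=10_000, size=5, seed=3)
    counts = pd.Series([m for g in ncg.groups for m in g]).value_counts()
    counts = counts.reindex(lib.nontargeting_ids, fill_value=0)
    stat, p = sps.chisquare(counts)
    assert p > 1e-3


# -- gene scoring ----------------------------------------------------------


def _phenotypes(lib, rho):
    return pd.DataFrame(
        {
            "sgrna_id": lib.table.sgrna_id,
            "gene": lib.table.gene,
            "tss": lib.table.tss,
            "is_nontargeting": lib.table.is_nontargeting,
            "rho": rho,
        }
    )


def test_discriminant_worked_example_hits_at_threshold():
    """z = 3.5 at p = 0.01 -> discriminant 3.5 * 2 = 7.0 >= 7 -> hit."""
    z, p = 3.5, 0.01
    disc = abs(z) * -np.log10(p)
    assert disc == pytest.approx(7.0)
    assert disc >= 7.0


def test_score_genes_null_screen_has_no_hits(toy_library):
    rng = np.random.default_rng(4)
    rho = rng.normal(0, 0.01, len(toy_library))
    ncg = cs.make_negative_control_genes(toy_library, 20, 5, seed=5)
    res = cs.score_genes(_phenotypes(toy_library, rho), ncg)
    assert not res.collapsed.is_hit.any()
    assert res.hits.empty


def test_score_genes_recovers_strong_sensitizer(sim_screen):
    _, lib, counts, truth = sim_screen
    params = cs.PhenotypeParams(doublings_untreated=10.0, doubling_difference=6.1)
    phen = cs.compute_phenotypes(counts, lib, params)
    ncg = cs.make_negative_control_genes(lib, 60, 5, seed=6)
    res = cs.score_genes(phen.table, ncg)
    strong = set(truth.genes.loc[truth.genes.true_rho.abs() >= 0.3, "gene"])
    assert strong <= set(res.hits.gene)
    # direction agrees with the sign of the planted effect
    merged = res.hits.merge(truth.genes, on="gene")
    sens = merged.loc[merged.true_rho < 0, "direction"]
    assert (sens == "sensitizing").all()


def test_discriminant_recomputable_and_monotone(sim_screen):
    _, lib, counts, _ = sim_screen
    params = cs.PhenotypeParams(doublings_untreated=10.0, doubling_difference=6.1)
    phen = cs.compute_phenotypes(counts, lib, params)
    ncg = cs.make_negative_control_genes(lib, 60, 5, seed=7)
    res = cs.score_genes(phen.table, ncg)
    tab = res.collapsed
    assert np.allclose(tab.discriminant,
                       tab.z.abs() * -np.log10(tab.p_value), equal_nan=True)
    assert tab.is_hit.equals(tab.discriminant >= res.threshold)


@given(st.floats(0.5, 5), st.floats(1.01, 2))
def test_discriminant_monotone_in_z_and_p(z, factor):
    p = 0.01
    base = abs(z) * -np.log10(p)
    assert abs(z * factor) * -np.log10(p) >= base
    assert abs(z) * -np.log10(p / factor) >= base


def test_sigma_zero_controls_rejected(toy_library):
    rho = np.zeros(len(toy_library))
    ncg = cs.make_negative_control_genes(toy_library, 10, 5, seed=8)
    with pytest.raises(ValueError, match="sigma_NCG"):
        cs.score_genes(_phenotypes(toy_library, rho), ncg)


def test_permuting_sgrnas_within_gene_leaves_scores_unchanged(toy_library):
    rng = np.random.default_rng(9)
    phen = _phenotypes(toy_library, rng.normal(0, 0.1, len(toy_library)))
    ncg = cs.make_negative_control_genes(toy_library, 20, 5, seed=10)
    ref = cs.score_genes(phen, ncg)
    shuffled = phen.sample(frac=1.0, random_state=11).reset_index(drop=True)
    got = cs.score_genes(shuffled, ncg)
    pd.testing.assert_frame_equal(ref.collapsed, got.collapsed)


# -- TSS collapse ----------------------------------------------------------


def _tss_rows(rows):
    cols = ["gene", "tss", "phenotype", "p_value", "z", "discriminant",
            "n_sgrnas_used", "is_hit", "direction", "bh_fdr"]
    base = {"z": 1.0, "discriminant": 1.0, "n_sgrnas_used": 5, "is_hit": False,
            "direction": "none", "bh_fdr": np.nan}
    return pd.DataFrame([{**base, **r} for r in rows])[cols]


def test_collapse_tss_selects_lowest_p_row_verbatim():
    tab = _tss_rows([
        {"gene": "G", "tss": "P1", "phenotype": -0.2, "p_value": 0.01},
        {"gene": "G", "tss": "P2", "phenotype": -0.5, "p_value": 0.2},
        {"gene": "H", "tss": "P1", "phenotype": 0.1, "p_value": 0.5},
    ])
    out = cs.collapse_tss(tab)
    g = out.set_index("gene").loc["G"]
    assert g.tss == "P1" and g.phenotype == -0.2 and g.p_value == 0.01
    assert len(out) == 2  # single-TSS gene H passes through unchanged


def test_collapse_tss_tie_break_prefers_larger_effect_then_label():
    tab = _tss_rows([
        {"gene": "G", "tss": "P2", "phenotype": 0.1, "p_value": 0.05},
        {"gene": "G", "tss": "P1", "phenotype": -0.3, "p_value": 0.05},
        {"gene": "K", "tss": "P2", "phenotype": 0.2, "p_value": 0.5},
        {"gene": "K", "tss": "P1", "phenotype": -0.2, "p_value": 0.5},
    ])
    out = cs.collapse_tss(tab).set_index("gene")
    assert out.loc["G"].tss == "P1"          # |−0.3| beats |0.1|
    assert out.loc["K"].tss == "P1"          # full tie: label order


def test_volcano_export_matches_score_table_bitwise(sim_screen):
    _, lib, counts, _ = sim_screen
    params = cs.PhenotypeParams(doublings_untreated=10.0, doubling_difference=6.1)
    phen = cs.compute_phenotypes(counts, lib, params)
    ncg = cs.make_negative_control_genes(lib, 60, 5, seed=12)
    res = cs.score_genes(phen.table, ncg)
    vol = cs.volcano_table(res)
    genes = vol.loc[vol.kind == "gene"].set_index("gene")
    for _, row in res.collapsed.iterrows():
        assert genes.at[row.gene, "phenotype"] == row.phenotype
        assert genes.at[row.gene, "neglog10_p"] == -np.log10(row.p_value)
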