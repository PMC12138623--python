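import numpy as np
import pandas as pd
import pytest

from gutmetab.diversity import (
    alpha_diversity,
    alpha_diversity_table,
    bray_curtis,
    group_tests,
    pcoa,
    top_taxa_composition,
)


# --- alpha diversity --------------------------------------------------------

def test_uniform_composition_closed_forms():
    r = alpha_diversity([0.25, 0.25, 0.25, 0.25])
    assert r.shannon == pytest.approx(np.log(4), abs=1e-9)
    assert r.simpson == pytest.approx(0.75, abs=1e-9)
    assert r.observed_richness == 4


def test_single_taxon_sample():
    r = alpha_diversity([1, 0, 0])
    assert r.shannon == 0.0
    assert r.simpson == 0.0
    assert r.observed_richness == 1


def test_shannon_direct_summation():
    r = alpha_diversity([0.5, 0.25, 0.25])
    assert r.shannon == pytest.approx(1.5 * np.log(2), abs=1e-9)  # = 1.0397


def test_all_zero_sample_rejected():
    with pytest.raises(ValueError):
        alpha_diversity([0, 0, 0])


def test_shannon_bounds_on_random_simplex():
    """Shannon <= ln(richness) with equality iff uniform; Simpson <= 1 - 1/S."""
    rng = np.random.default_rng(1)
    for _ in range(200):
        k = int(rng.integers(2, 12))
        p = rng.dirichlet(np.ones(k))
        r = alpha_diversity(p)
        assert r.shannon <= np.log(r.observed_richness) + 1e-12
        assert r.simpson <= 1 - 1 / r.observed_richness + 1e-12


# --- Bray-Curtis ------------------------------------------------------------

def test_bray_curtis_identity_disjoint_and_hand_value():
    m = pd.DataFrame({"s1": [2.0, 2.0], "s2": [1.0, 3.0], "s3": [2.0, 2.0],
                      "s4": [4.0, 0.0], "s5": [0.0, 4.0]}, index=["t1", "t2"])
    d = bray_curtis(m)
    assert d.loc["s1", "s3"] == 0.0
    assert d.loc["s4", "s5"] == 1.0
    assert d.loc["s1", "s2"] == pytest.approx(0.25)  # (1+1)/8


def test_bray_curtis_metric_properties_random_pairs():
    rng = np.random.default_rng(2)
    m = pd.DataFrame(rng.uniform(0, 10, (6, 50)))
    d = bray_curtis(m).to_numpy()
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0)
    assert (d >= 0).all() and (d <= 1).all()


def test_bray_curtis_rejects_two_empty_samples():
    m = pd.DataFrame({"s1": [0.0], "s2": [0.0]}, index=["t"])
    with pytest.raises(ValueError):
        bray_curtis(m)


# --- PCoA -------------------------------------------------------------------

def test_pcoa_two_points():
    d = pd.DataFrame([[0, 0.8], [0.8, 0]], index=["a", "b"], columns=["a", "b"])
    res = pcoa(d)
    coords = res.coordinates.iloc[:, 0].to_numpy()
    assert np.allclose(np.abs(coords), 0.4, atol=1e-9)


def test_pcoa_roundtrips_euclidean_configuration():
    """Distances from 2-D points are reproduced by the embedding within 1e-8."""
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(7, 2))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    res = pcoa(pd.DataFrame(d))
    emb = res.coordinates.to_numpy()
    d2 = np.sqrt(((emb[:, None] - emb[None, :]) ** 2).sum(-1))
    assert np.allclose(d, d2, atol=1e-8)


def test_pcoa_equilateral_simplex_eigenvalues():
    d = pd.DataFrame(1 - np.eye(3))
    res = pcoa(d)
    assert res.eigenvalues.size == 2
    assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])


def test_pcoa_agrees_with_skbio():
    """Independent cross-check against scikit-bio's implementation."""
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.ordination import pcoa as skbio_pcoa

    rng = np.random.default_rng(4)
    pts = rng.normal(size=(6, 3))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    ours = pcoa(pd.DataFrame(d))
    theirs = skbio_pcoa(DistanceMatrix(d), method="eigh")
    k = ours.eigenvalues.size
    assert np.allclose(ours.eigenvalues, theirs.eigvals.to_numpy()[:k], atol=1e-8)
    assert np.allclose(np.abs(ours.coordinates.to_numpy()),
                       np.abs(theirs.samples.to_numpy()[:, :k]), atol=1e-6)


def test_pcoa_rejects_asymmetric_input():
    with pytest.raises(ValueError):
        pcoa(pd.DataFrame([[0, 1], [2, 0]]))


# --- composition and group tests -------------------------------------------

def _toy_abundance():
    rng = np.random.default_rng(5)
    m = pd.DataFrame(rng.uniform(0, 1, (12, 10)),
                     index=[f"t{i}" for i in range(12)],
                     columns=[f"s{i}" for i in range(10)])
    groups = pd.Series(["A"] * 5 + ["B"] * 5, index=m.columns)
    return m / m.sum(), groups


def test_top_taxa_bars_sum_to_100():
    m, groups = _toy_abundance()
    comp = top_taxa_composition(m, groups, k=9)
    assert np.allclose(comp.sum(axis=0), 100.0, atol=1e-6)
    assert "Other" in comp.index and comp.shape[0] == 10


def test_top_taxa_k_equal_all_lumps_nothing():
    m, groups = _toy_abundance()
    comp = top_taxa_composition(m, groups, k=12)
    assert "Other" not in comp.index


def test_top_taxa_k1_selects_dominant_taxon():
    m = pd.DataFrame({"s1": [0.7, 0.2, 0.1], "s2": [0.8, 0.1, 0.1]}, index=["big", "mid", "small"])
    comp = top_taxa_composition(m, pd.Series({"s1": "A", "s2": "A"}), k=1)
    assert list(comp.index) == ["big", "Other"]


def test_group_tests_identical_values_no_signal():
    vals = pd.Series([1.0] * 8, index=[f"s{i}" for i in range(8)])
    groups = pd.Series(["A"] * 4 + ["B"] * 4, index=vals.index)
    res = group_tests(vals, groups)
    assert res.omnibus_statistic == 0.0
    assert res.omnibus_p == 1.0


def test_group_tests_four_groups_threshold_is_bonferroni():
    """Four groups -> six pairs -> per-comparison threshold 0.05/6 = 0.0083."""
    rng = np.random.default_rng(6)
    vals = pd.Series(rng.normal(size=12), index=[f"s{i}" for i in range(12)])
    groups = pd.Series(sum([[g] * 3 for g in "ABCD"], []), index=vals.index)
    res = group_tests(vals, groups)
    assert len(res.pairwise) == 6
    assert res.per_comparison_threshold == pytest.approx(0.05 / 6)


def test_group_tests_shifted_group_is_detected():
    vals = pd.Series([1, 2, 3, 2, 1, 30, 31, 32, 33, 29], index=[f"s{i}" for i in range(10)])
    groups = pd.Series(["A"] * 5 + ["B"] * 5, index=vals.index)
    res = group_tests(vals, groups)
    assert res.omnibus_p < 0.05
    assert res.pairwise[("A", "B")].p_value == pytest.approx(2 / 252)


def test_group_tests_rejects_tiny_group():
    vals = pd.Series([1, 2, 3], index=["s1", "s2", "s3"])
    groups = pd.Series(["A", "A", "B"], index=vals.index)
    with pytest.raises(ValueError):
        group_tests(vals, groups)


def test_planted_shift_detected_across_seeds():
    """With the generator's default 5-fold effect, the omnibus test flags the
    differential taxon's relative abundance in most seeds."""
    from gutmetab.simulate import SimulationDesign, generate_asv_data, generate_reference_db

    detected = 0
    n_seeds = 25
    for seed in range(n_seeds):
        design = SimulationDesign(seed=seed)
        ref = generate_reference_db(design.n_ref_taxa, design.seed)
        _, counts, truth = generate_asv_data(ref, design)
        rel = counts / counts.sum()
        d = truth.differential_taxa[0]
        asvs = [a for a, t in truth.asv_to_taxon.items() if t == d["taxon"]]
        vals = rel.loc[asvs].sum()
        groups = pd.Series([s.rsplit("__", 1)[0] for s in vals.index], index=vals.index)
        if group_tests(vals, groups).omnibus_p < 0.05:
            detected += 1
    assert detected >= 0.8 * n_seeds
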