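import numpy as np
import pytest

from gutmetab.masses import monoisotopic_mass
from gutmetab.network import (
    NetworkParams,
    SpectrumRecord,
    annotate_mass_shift,
    build_network,
    find_biotransformation_candidates,
    mirror_data,
    modified_cosine,
    read_mgf,
    write_mgf,
)
from oracles import optimal_assignment_cosine


def _random_spectrum(rng, fid="s", precursor=None, n_peaks=None):
    n = n_peaks or int(rng.integers(5, 13))
    prec = precursor or float(rng.uniform(200, 800))
    return SpectrumRecord(fid, prec, rng.uniform(50, prec, n), rng.uniform(1e3, 1e6, n))


def test_self_similarity_is_one():
    rng = np.random.default_rng(0)
    s = _random_spectrum(rng)
    cos, n = modified_cosine(s, s)
    assert cos == pytest.approx(1.0, abs=1e-9)
    assert n == s.n_peaks


def test_disjoint_spectra_score_zero():
    a = SpectrumRecord("a", 500.0, np.array([100.0, 200.0]), np.array([1.0, 1.0]))
    b = SpectrumRecord("b", 500.0, np.array([150.0, 250.0]), np.array([1.0, 1.0]))
    cos, n = modified_cosine(a, b)
    assert cos == 0.0 and n == 0


def test_shifted_spectrum_matches_via_precursor_delta():
    """A spectrum with every peak and the precursor shifted by a constant
    still scores 1 through shifted matching."""
    rng = np.random.default_rng(1)
    a = _random_spectrum(rng, "a", 400.0, 8)
    shift = 137.0146
    b = SpectrumRecord("b", a.precursor_mz + shift, a.mz + shift, a.intensity)
    cos, n = modified_cosine(a, b)
    assert cos == pytest.approx(1.0, abs=1e-9)
    assert n == a.n_peaks


def test_cosine_symmetric_and_bounded_on_random_pairs():
    rng = np.random.default_rng(2)
    for _ in range(200):
        a, b = _random_spectrum(rng, "a"), _random_spectrum(rng, "b")
        cab, nab = modified_cosine(a, b)
        cba, nba = modified_cosine(b, a)
        assert cab == pytest.approx(cba, abs=1e-9)
        assert nab == nba
        assert 0.0 <= cab <= 1.0


def test_greedy_close_to_optimal_assignment():
    """Greedy matching stays within 5% of the exact Hungarian optimum."""
    rng = np.random.default_rng(3)
    params = NetworkParams(fragment_tol=0.5)  # wide tolerance forces conflicts
    worst = 1.0
    for _ in range(300):
        a = _random_spectrum(rng, "a", 300.0)
        b = _random_spectrum(rng, "b", 320.0)
        greedy, _ = modified_cosine(a, b, params)
        optimal = optimal_assignment_cosine(a, b, params)
        if optimal > 0:
            worst = min(worst, greedy / optimal)
    assert worst >= 0.95


def test_matchms_cross_check():
    """Independent check of the score against matchms' ModifiedCosine on a
    conflict-free constructed pair (raw intensities, no sqrt weighting)."""
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import ModifiedCosine

    mz_a = np.array([100.0, 150.0, 200.0, 250.0, 300.0])
    int_a = np.array([1e4, 5e4, 2e4, 8e4, 3e4])
    mz_b = np.array([100.001, 150.0, 210.0, 250.002, 310.0])
    int_b = np.array([2e4, 4e4, 1e4, 6e4, 2e4])
    ours, n_ours = modified_cosine(
        SpectrumRecord("a", 400.0, mz_a, int_a),
        SpectrumRecord("b", 400.0, mz_b, int_b),
        NetworkParams(fragment_tol=0.005, sqrt_transform=False),
    )
    sa = matchms.Spectrum(mz=mz_a, intensities=int_a, metadata={"precursor_mz": 400.0})
    sb = matchms.Spectrum(mz=mz_b, intensities=int_b, metadata={"precursor_mz": 400.0})
    res = ModifiedCosine(tolerance=0.005).pair(sa, sb)
    assert ours == pytest.approx(float(res["score"]), abs=1e-6)
    assert n_ours == int(res["matches"])


# --- network construction ---------------------------------------------------

def test_planted_pair_forms_edge(study):
    from gutmetab.simulate import PARENT_ID, PRODUCT_ID

    edges = build_network(study.spectra)
    assert any({e.source, e.target} == {PARENT_ID, PRODUCT_ID} for e in edges)


def test_unattainable_cosine_gives_empty_network():
    rng = np.random.default_rng(4)
    spectra = [_random_spectrum(rng, f"s{i}") for i in range(5)]
    assert build_network(spectra, NetworkParams(cosine_min=1.01)) == []


def test_raising_min_matches_never_adds_edges():
    rng = np.random.default_rng(5)
    spectra = [_random_spectrum(rng, f"s{i}", 300.0 + i * 0.001) for i in range(8)]
    loose = build_network(spectra, NetworkParams(fragment_tol=1.0, cosine_min=0.1, min_matches=2))
    strict = build_network(spectra, NetworkParams(fragment_tol=1.0, cosine_min=0.1, min_matches=4))
    loose_pairs = {(e.source, e.target) for e in loose}
    assert {(e.source, e.target) for e in strict} <= loose_pairs


# --- mass-shift annotation --------------------------------------------------

def _pair(parent_mz, product_mz):
    rng = np.random.default_rng(6)
    a = _random_spectrum(rng, "parent", parent_mz)
    b = _random_spectrum(rng, "product", product_mz)
    return a, b


def test_moiety_delta_within_ppm_yields_candidate():
    a, b = _pair(283.1540, 283.1540 + 137.0147)
    cands = annotate_mass_shift(a, b, ["C3H7NO3S"], ppm_tol=10)
    assert len(cands) == 1
    assert cands[0].variant == "M"
    assert abs(cands[0].ppm_error) < 10


def test_zero_delta_matches_no_moiety():
    a, b = _pair(300.0, 300.0)
    assert annotate_mass_shift(a, b, ["C3H6NO3S", "H2"], ppm_tol=10) == []


def test_dihydro_reduction_candidate():
    h2 = monoisotopic_mass("H2")
    a, b = _pair(283.1540, 283.1540 + h2)
    cands = annotate_mass_shift(a, b, ["H2"], ppm_tol=10)
    assert [c.moiety for c in cands if c.variant == "M"] == ["H2"]


def test_hydrogen_ambiguity_variants():
    """A delta of moiety+H is caught by the M+H variant."""
    m = monoisotopic_mass("C3H6NO3S")
    a, b = _pair(283.1540, 283.1540 + m + monoisotopic_mass("H"))
    cands = annotate_mass_shift(a, b, ["C3H6NO3S"], ppm_tol=10)
    assert [c.variant for c in cands] == ["M+H"]


def test_empty_moiety_list_rejected():
    a, b = _pair(100.0, 200.0)
    with pytest.raises(ValueError):
        annotate_mass_shift(a, b, [], ppm_tol=10)


def test_unique_direction_consistent_candidate(study):
    from gutmetab.features import blank_filter, fold_change
    from gutmetab.simulate import PARENT_ID, PRODUCT_ID

    fc = fold_change(blank_filter(study.feature_table))
    cands = find_biotransformation_candidates(
        study.spectra, ["C3H6NO3S", "H2"], 10.0, fc)
    consistent = [(c.parent_id, c.product_id) for c in cands if c.direction_consistent]
    assert consistent == [(PARENT_ID, PRODUCT_ID)]


# --- mirror data and MGF round trip -----------------------------------------

def test_mirror_matches_equal_cosine_match_count():
    rng = np.random.default_rng(7)
    a = _random_spectrum(rng, "a", 300.0)
    b = SpectrumRecord("b", 310.0, a.mz + 10.0, a.intensity * 0.9)
    _, n = modified_cosine(a, b)
    mir = mirror_data(a, b)
    top = mir[mir.spectrum == "top"]
    bottom = mir[mir.spectrum == "bottom"]
    assert top.matched.sum() == n and bottom.matched.sum() == n
    assert (bottom.intensity <= 0).all() and (top.intensity >= 0).all()


def test_mgf_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    spectra = [_random_spectrum(rng, f"FT_{i}") for i in range(4)]
    path = tmp_path / "spec.mgf"
    write_mgf(spectra, path)
    back = read_mgf(path)
    assert [s.feature_id for s in back] == [s.feature_id for s in spectra]
    for s1, s2 in zip(spectra, back):
        assert s1.precursor_mz == pytest.approx(s2.precursor_mz, abs=1e-6)
        assert np.allclose(s1.mz, s2.mz)
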