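"""Unit and property tests for the seven GRM constructions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from asvgrm import (
    AlleleFrequencies,
    DegenerateRelatednessError,
    GenotypeMatrix,
    allele_frequencies,
    asv_scaling_factor,
    build_grm,
    center_markers,
    grm_asv,
    grm_astle_balding,
    grm_endelman_jannink,
    grm_gn,
    grm_ibs,
    grm_vanraden,
    grm_yang,
    kbar,
    observed_heterozygosity,
)

dosage_matrices = arrays(
    dtype=np.int64,
    shape=st.tuples(st.integers(3, 12), st.integers(1, 15)),
    elements=st.integers(0, 2),
).map(lambda a: a.astype(float))


def polymorphic(arr):
    return np.any(arr.max(axis=0) != arr.min(axis=0))


# ---------------------------------------------------------------------------
# marker statistics


@pytest.mark.parametrize(
    "column, expected",
    [([0, 2], 0.5), ([2, 2, 2], 1.0), ([0, 1, 2], 0.5), ([0, 0, 0], 0.0)],
)
def test_allele_frequencies_column_means(column, expected):
    G = GenotypeMatrix.from_array(np.asarray(column, dtype=float)[:, None])
    p = allele_frequencies(G)
    assert p.source == "observed"
    assert p.p[0] == pytest.approx(expected)


@pytest.mark.parametrize(
    "dosages, expected",
    [
        (np.ones((3, 4)), 1.0),
        (np.array([[0.0, 2.0], [2.0, 0.0]]), 0.0),
        (np.array([[0.0, 1.0], [1.0, 2.0]]), 0.5),
    ],
)
def test_observed_heterozygosity_counts_dosage_one(dosages, expected):
    assert observed_heterozygosity(GenotypeMatrix.from_array(dosages)) == expected


def test_center_markers_matches_projector_and_is_idempotent(random_g):
    Zc = center_markers(random_g)
    n = random_g.n
    P = np.eye(n) - np.ones((n, n)) / n
    np.testing.assert_allclose(Zc, P @ random_g.dosages, atol=1e-12)
    np.testing.assert_allclose(Zc.mean(axis=0), 0.0, atol=1e-12)
    # re-centering is a no-op (the projector is idempotent)
    np.testing.assert_allclose(Zc - Zc.mean(axis=0), Zc, atol=1e-12)


def test_genotype_matrix_validation_and_imputation():
    with pytest.raises(ValueError):
        GenotypeMatrix.from_array(np.array([[0.0, 3.0], [1.0, 2.0]]))
    with pytest.raises(ValueError):
        GenotypeMatrix.from_array(np.array([[0.5], [1.0]]))
    G = GenotypeMatrix.from_array(np.array([[0.0, np.nan], [2.0, 2.0], [1.0, 0.0]]))
    assert G.n_imputed == 1
    assert G.dosages[0, 1] == pytest.approx(1.0)  # mean of the observed 2 and 0


# ---------------------------------------------------------------------------
# hand-evaluated matrices


def test_kbar_hand_example(toy_g):
    expected = np.array([[1, 0, -1], [0, 0, 0], [-1, 0, 1]], dtype=float)
    K = kbar(toy_g)
    np.testing.assert_allclose(K.values, expected, atol=1e-12)
    np.testing.assert_allclose(K.values.sum(axis=1), 0.0, atol=1e-12)


def test_kbar_identical_rows_is_zero():
    G = GenotypeMatrix.from_array(np.tile([0.0, 1.0, 2.0], (4, 1)))
    np.testing.assert_allclose(kbar(G).values, 0.0, atol=1e-12)


def test_asv_hand_examples(toy_g):
    np.testing.assert_allclose(
        grm_asv(toy_g).values, [[1, 0, -1], [0, 0, 0], [-1, 0, 1]], atol=1e-12
    )
    G2 = GenotypeMatrix.from_array([[0.0], [2.0]])
    np.testing.assert_allclose(grm_asv(G2).values, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-12)


def test_vanraden_hand_example(toy_g):
    K = grm_vanraden(toy_g)
    np.testing.assert_allclose(K.values, [[2, 0, -2], [0, 0, 0], [-2, 0, 2]], atol=1e-12)


def test_yang_hand_examples():
    # all-heterozygous column: diagonal 1 + (1 - 2 + 0.5)/0.5 = 0, off-diagonal 0
    G_het = GenotypeMatrix.from_array([[1.0], [1.0]])
    np.testing.assert_allclose(grm_yang(G_het).values, 0.0, atol=1e-12)
    # opposite homozygotes: off-diagonal (0-1)(2-1)/0.5 = -2
    G_hom = GenotypeMatrix.from_array([[0.0], [2.0]])
    K = grm_yang(G_hom)
    assert K.values[0, 1] == pytest.approx(-2.0)
    np.testing.assert_allclose(np.diag(K.values), 2.0, atol=1e-12)


def test_astle_balding_hand_example():
    G = GenotypeMatrix.from_array([[0.0], [2.0]])
    np.testing.assert_allclose(grm_astle_balding(G).values, [[2, -2], [-2, 2]], atol=1e-12)


def test_ibs_hand_examples():
    G = GenotypeMatrix.from_array([[0.0], [2.0]])
    np.testing.assert_allclose(grm_ibs(G).values, np.eye(2), atol=1e-12)
    G_het = GenotypeMatrix.from_array([[1.0], [1.0]])
    np.testing.assert_allclose(grm_ibs(G_het).values, 0.5, atol=1e-12)


# ---------------------------------------------------------------------------
# scaling factor and exact construction invariants


def test_asv_scaling_factor_identity_and_toy(toy_g):
    from asvgrm import RelationshipMatrix

    for n in (2, 5, 9):
        K = RelationshipMatrix(np.eye(n), tuple(f"E{i}" for i in range(n)))
        assert asv_scaling_factor(K) == pytest.approx(1.0)  # tr(P) = n - 1
    assert asv_scaling_factor(kbar(toy_g)) == pytest.approx(1.0)


def test_asv_scaling_factor_degenerate_error():
    with pytest.raises(DegenerateRelatednessError):
        grm_asv(GenotypeMatrix.from_array(np.full((3, 2), 2.0)))


@settings(deadline=None, derandomize=True, max_examples=30)
@given(dosage_matrices)
def test_construction_exactness_properties(arr):
    """tr(K_ASV)=n-1, zero row sums, unit scaling factor, GN relation, traces."""
    if not polymorphic(arr):
        return
    G = GenotypeMatrix.from_array(arr)
    n = G.n
    Kb = kbar(G)
    Ka = grm_asv(G)
    Kg = grm_gn(G)
    assert np.trace(Ka.values) == pytest.approx(n - 1, abs=1e-10)
    np.testing.assert_allclose(Ka.values.sum(axis=1), 0.0, atol=1e-9)
    assert asv_scaling_factor(Ka) == pytest.approx(1.0, abs=1e-10)
    assert np.trace(Kg.values) == pytest.approx(n, abs=1e-10)
    # normalized matrix differs from the ASV matrix by n/(n-1) exactly
    np.testing.assert_allclose(Kg.values * (n - 1) / n, Ka.values, atol=1e-10)
    # tr(Z Z' P) = tr(Zbar Zbar') computed both ways
    Z = G.dosages
    P = np.eye(n) - np.ones((n, n)) / n
    assert np.trace(Z @ Z.T @ P) == pytest.approx(np.trace(Kb.values), rel=1e-9, abs=1e-9)
    # mean diagonal of K_ASV is forced to (n-1)/n
    assert np.diag(Ka.values).mean() == pytest.approx((n - 1) / n, abs=1e-10)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(dosage_matrices)
def test_vanraden_observed_p_proportional_to_asv(arr):
    if not polymorphic(arr):
        return
    G = GenotypeMatrix.from_array(arr)
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Kv = grm_vanraden(G)
    Ka = grm_asv(G)
    mask = np.abs(Ka.values) > 1e-9
    if mask.any():
        ratios = Kv.values[mask] / Ka.values[mask]
        assert ratios.max() - ratios.min() == pytest.approx(0.0, abs=1e-8 * abs(ratios.mean()))
        assert ratios.mean() > 0


@settings(deadline=None, derandomize=True, max_examples=25)
@given(dosage_matrices)
def test_symmetry_and_psd(arr):
    """All GRMs symmetric; all but Yang/EJ PSD up to round-off."""
    if not polymorphic(arr):
        return
    import warnings

    G = GenotypeMatrix.from_array(arr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("asv", "gn", "vr", "ab", "ibs", "yang", "ej"):
            K = build_grm(G, method)
            np.testing.assert_allclose(K.values, K.values.T, atol=1e-10)
            if method not in ("yang", "ej"):
                eigs = np.linalg.eigvalsh(K.values)
                assert eigs.min() >= -1e-8 * max(eigs.max(), 1.0)


def test_shift_invariance_of_centered_grms_and_ibs_convention(rng):
    """Adding a constant to a marker leaves Kbar/ASV/GN unchanged; IBS changes."""
    base = rng.integers(0, 2, size=(10, 8)).astype(float)  # dosages in {0,1}
    shifted = base.copy()
    shifted[:, 0] += 1.0  # still within {0,1,2}
    G1, G2 = GenotypeMatrix.from_array(base), GenotypeMatrix.from_array(shifted)
    np.testing.assert_allclose(kbar(G1).values, kbar(G2).values, atol=1e-10)
    np.testing.assert_allclose(grm_asv(G1).values, grm_asv(G2).values, atol=1e-10)
    np.testing.assert_allclose(grm_gn(G1).values, grm_gn(G2).values, atol=1e-10)
    assert np.abs(grm_ibs(G1).values - grm_ibs(G2).values).max() > 1e-6


def test_endelman_jannink_delta_zero_equals_vanraden(random_g):
    Kej, delta = grm_endelman_jannink(random_g, force_delta=0.0)
    assert delta == 0.0
    np.testing.assert_allclose(Kej.values, grm_vanraden(random_g).values, atol=1e-10)


def test_endelman_jannink_delta_in_unit_interval(rng):
    for _ in range(5):
        G = GenotypeMatrix.from_array(rng.integers(0, 3, size=(15, 40)).astype(float))
        _, delta = grm_endelman_jannink(G)
        assert 0.0 <= delta <= 1.0


def test_yang_ab_share_offdiagonals(random_g):
    Ky = grm_yang(random_g)
    Kab = grm_astle_balding(random_g)
    off = ~np.eye(random_g.n, dtype=bool)
    np.testing.assert_allclose(Ky.values[off], Kab.values[off], atol=1e-10)


def test_monomorphic_markers_warned_and_skipped():
    arr = np.array([[0.0, 2.0], [1.0, 2.0], [2.0, 2.0]])  # second marker monomorphic
    G = GenotypeMatrix.from_array(arr)
    with pytest.warns(UserWarning, match="monomorphic"):
        Kv = grm_vanraden(G)
    with pytest.warns(UserWarning, match="monomorphic"):
        Ky = grm_yang(G)
    # equal to dropping the monomorphic marker up front
    G1 = GenotypeMatrix.from_array(arr[:, :1])
    np.testing.assert_allclose(Kv.values, grm_vanraden(G1).values, atol=1e-12)
    np.testing.assert_allclose(Ky.values, grm_yang(G1).values, atol=1e-12)


def test_ibs_values_bounded(random_g):
    K = grm_ibs(random_g)
    assert K.values.min() >= 0.0 and K.values.max() <= 1.0


def test_build_grm_dispatch_and_bad_method(random_g):
    assert build_grm(random_g, "ASV").method == "asv"
    with pytest.raises(ValueError, match="unknown GRM method"):
        build_grm(random_g, "pedigree")


def test_supplied_frequencies_used():
    G = GenotypeMatrix.from_array([[0.0], [1.0], [2.0]])
    p = AlleleFrequencies(np.array([0.25]), source="supplied")
    K = grm_vanraden(G, p)  # centered on 0.5, denominator 2*0.1875
    Zc = G.dosages - 0.5
    np.testing.assert_allclose(K.values, Zc @ Zc.T / 0.375, atol=1e-12)


def test_vanraden_mean_diagonal_under_full_inbreeding():
    """At H = 0 the mean VanRaden diagonal approaches 1 + f = 2."""
    from asvgrm import simulate_genotypes

    G = simulate_genotypes(300, 500, H=0.0, seed=3)
    K = grm_vanraden(G)
    assert np.diag(K.values).mean() == pytest.approx(2.0, abs=0.05)


def test_vanraden_mean_diagonal_under_hwe():
    from asvgrm import simulate_genotypes

    G = simulate_genotypes(300, 500, H=0.5, seed=4)
    K = grm_vanraden(G)
    assert np.diag(K.values).mean() == pytest.approx(1.0, abs=0.05)
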