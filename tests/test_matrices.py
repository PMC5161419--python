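import numpy as np
import pytest

import gremlkin as gk
from gremlkin import GenotypeMatrix, RelationshipMatrix
from gremlkin.pedigree import Pedigree


def test_grm_hand_example():
    """Two samples, one SNP, dosages 0 and 2 at p=0.5 give +/-2 entries."""
    g = GenotypeMatrix(["a", "b"], ["s1"], np.array([[0.0], [2.0]]))
    G = gk.compute_grm(g, maf_min=0.0)
    assert np.allclose(G.values, [[2, -2], [-2, 2]])


def test_monomorphic_snps_excluded():
    g = GenotypeMatrix(["a", "b"], ["s1", "s2"],
                       np.array([[0.0, 0.0], [2.0, 0.0]]))
    G = gk.compute_grm(g, maf_min=0.0)  # s2 is monomorphic, only s1 counts
    assert np.allclose(G.values, [[2, -2], [-2, 2]])
    mono = GenotypeMatrix(["a", "b"], ["s2"], np.array([[0.0], [0.0]]))
    with pytest.raises(ValueError, match="no informative SNPs"):
        gk.compute_grm(mono)


def test_grm_expectation_on_hwe_unrelateds():
    """Unrelated samples at HWE SNPs: diagonal ~1, off-diagonal ~0."""
    rng = np.random.default_rng(2024)
    n, m = 500, 5000
    p = rng.uniform(0.05, 0.5, size=m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(float)
    g = GenotypeMatrix([f"i{i}" for i in range(n)],
                       [f"s{j}" for j in range(m)], dosages)
    G = gk.compute_grm(g)
    off = G.values[np.triu_indices(n, k=1)]
    assert abs(np.diag(G.values).mean() - 1) < 0.05
    assert abs(off.mean()) < 0.01


def test_grm_missing_policies():
    d = np.array([[0.0, 2.0], [2.0, np.nan], [1.0, 0.0], [1.0, 2.0]])
    g = GenotypeMatrix(list("abcd"), ["s1", "s2"], d)
    G = gk.compute_grm(g, maf_min=0.0)
    assert G.pair_counts[0, 1] == 1  # one shared non-missing SNP
    Gp = gk.compute_grm(g, maf_min=0.0, missing_policy="pairwise")
    # pairwise divides by the pair count instead of total SNPs
    assert Gp.values[0, 1] == pytest.approx(G.values[0, 1] * 2 / 1)


@pytest.mark.parametrize("g_val,expected", [(0.02, 0.0), (0.05, 0.05), (0.30, 0.30)])
def test_threshold_kinship_offdiagonal(g_val, expected):
    vals = np.array([[1.02, g_val], [g_val, 0.98]])
    G = RelationshipMatrix(["a", "b"], vals, kind="G")
    K = gk.threshold_kinship(G, threshold=0.05)
    assert K.values[0, 1] == expected
    assert K.values[0, 0] == 1.02  # diagonal untouched


def test_threshold_negative_infinity_is_identity_map():
    rng = np.random.default_rng(5)
    vals = rng.normal(0, 0.1, (6, 6))
    vals = (vals + vals.T) / 2
    G = RelationshipMatrix([f"i{i}" for i in range(6)], vals, kind="G")
    K = gk.threshold_kinship(G, threshold=-np.inf)
    assert np.array_equal(K.values, G.values)
    with pytest.raises(ValueError, match="threshold"):
        gk.threshold_kinship(G, threshold=-1.0)


def test_erm_trio_enumeration(trio_pedigree):
    C = gk.build_erm(trio_pedigree, "C")
    S = gk.build_erm(trio_pedigree, "S")
    F = gk.build_erm(trio_pedigree, "F")
    assert C.values.sum() == 3 + 2  # diagonal + one couple pair
    assert np.array_equal(S.values, np.eye(3))
    assert np.array_equal(F.values, np.ones((3, 3)))


def test_erm_singletons_are_identity():
    ped = Pedigree([(f"i{i}", None, None, 0) for i in range(4)])
    for kind in "FS":
        assert np.array_equal(gk.build_erm(ped, kind).values, np.eye(4))
    with pytest.warns(UserWarning, match="no couple"):
        C = gk.build_erm(ped, "C")
    assert np.array_equal(C.values, np.eye(4))


def test_erm_dominance_ordering(matrices):
    """F indicates every couple and sib pair: F >= max(S, C) elementwise."""
    F, S, C = (matrices[k].values for k in "FSC")
    assert (F >= np.maximum(S, C)).all()


def test_pcs_block_structure_and_orthogonality():
    block = np.full((5, 5), 0.5) + 0.5 * np.eye(5)
    # centered GRMs carry small negative cross-family entries
    cross = np.full((5, 5), -0.1)
    G = RelationshipMatrix([f"i{i}" for i in range(10)],
                           np.block([[block, cross], [cross, block]]), kind="G")
    pcs = gk.compute_pcs(G, k=3)
    # PC1 separates the two family blocks with opposite signs
    assert np.sign(pcs[:5, 0]).mean() * np.sign(pcs[5:, 0]).mean() < 0
    assert np.allclose(pcs.T @ pcs, np.eye(3), atol=1e-8)
    assert all(pcs[np.argmax(np.abs(pcs[:, j])), j] > 0 for j in range(3))
    with pytest.raises(ValueError, match="smaller than n"):
        gk.compute_pcs(G, k=10)


def test_matrix_correlation_cases(matrices):
    S, C, F = matrices["S"], matrices["C"], matrices["F"]
    assert gk.matrix_correlation(S, S) == pytest.approx(1.0)
    # disjoint indicator supports correlate non-positively
    assert gk.matrix_correlation(C, S) <= 0
    union = RelationshipMatrix(F.sample_ids, np.maximum(S.values, C.values))
    ped_like = gk.matrix_correlation(F, union)
    assert ped_like <= 1.0
    with pytest.raises(ValueError, match="at least 3"):
        two = RelationshipMatrix(["a", "b"], np.eye(2))
        gk.matrix_correlation(two, two)


def test_matrix_correlation_f_is_union_for_couples_and_sibs():
    """With no parent-offspring pairs sampled, F equals the C/S union."""
    ped = Pedigree([
        ("Pa", None, None, 1), ("Pb", None, None, 2),
        ("c1", "Pa", "Pb", 1), ("c2", "Pa", "Pb", 2),
    ])
    ids = ["Pa", "Pb", "c1", "c2"]
    F = gk.build_erm(ped, "F", sample_ids=ids)
    S = gk.build_erm(ped, "S", sample_ids=ids)
    C = gk.build_erm(ped, "C", sample_ids=ids)
    po = np.eye(4)
    po[0, 2] = po[0, 3] = po[1, 2] = po[1, 3] = 1
    po = np.maximum(po, po.T)
    union = np.maximum(np.maximum(S.values, C.values), po)
    assert np.array_equal(F.values, union)
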