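"""REMatch kernel: Sinkhorn matching, limits, symmetry, kernel distance."""

from itertools import permutations

import numpy as np
import pytest

from confnav.descriptors import SoapParams
from confnav.rematch import (
    DistanceMatrix,
    EnvSimilarityMatrix,
    KernelMatrix,
    REMatchKernel,
    env_similarity,
    kernel_matrix,
    kernel_to_distance,
    load_distance,
    load_kernel,
    rematch_kernel,
    save_distance,
    save_kernel,
    sinkhorn,
    sinkhorn_objective,
)
from confnav.structures import Dataset, Structure
from conftest import LIGHT, random_structure


def best_match_value(C: np.ndarray) -> float:
    """Exhaustive-permutation matching score (1/N) max_pi sum C[i, pi(i)]."""
    n = C.shape[0]
    return max(
        sum(C[i, p[i]] for i in range(n)) for p in permutations(range(n))
    ) / n


class TestSinkhorn:
    def test_constant_matrix_gives_uniform_plan(self):
        C = np.full((3, 5), 0.7)
        plan = sinkhorn(C, gamma=0.5)
        np.testing.assert_allclose(plan.values, 1.0 / 15.0, atol=1e-12)

    def test_large_gamma_near_uniform(self, rng):
        C = rng.random((4, 4))
        plan = sinkhorn(C, gamma=100.0)
        assert np.abs(plan.values - 1.0 / 16.0).max() < 1e-3

    def test_small_gamma_identity_matrix(self):
        plan = sinkhorn(np.eye(2), gamma=0.01)
        np.testing.assert_allclose(plan.values, np.diag([0.5, 0.5]), atol=1e-6)

    def test_marginals_within_tol(self, rng):
        for _ in range(10):
            na, nb = rng.integers(2, 8, size=2)
            plan = sinkhorn(rng.random((na, nb)), gamma=0.1, tol=1e-6)
            assert np.abs(plan.values.sum(axis=1) - 1.0 / na).max() < 1e-6
            assert np.abs(plan.values.sum(axis=0) - 1.0 / nb).max() < 1e-6

    def test_no_overflow_at_tiny_gamma(self):
        # log-domain scaling: exp(C/gamma) would overflow at gamma = 1e-4
        plan = sinkhorn(np.eye(3), gamma=1e-4)
        assert np.all(np.isfinite(plan.values))
        np.testing.assert_allclose(plan.values, np.eye(3) / 3.0, atol=1e-8)

    def test_nonconvergence_raises_with_residual(self, rng):
        with pytest.raises(RuntimeError, match="residual"):
            sinkhorn(rng.random((5, 5)), gamma=0.01, tol=1e-12, max_iter=3)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            sinkhorn(np.eye(2), gamma=0.0)
        with pytest.raises(ValueError):
            sinkhorn(np.eye(2), gamma=0.1, tol=0.0)

    def test_converged_plan_beats_feasible_alternatives(self, rng):
        """The converged plan minimizes the entropic objective: it is no worse
        than the uniform plan or any permutation plan on the feasible set."""
        for _ in range(5):
            n = int(rng.integers(2, 5))
            C = rng.random((n, n))
            gamma = 0.2
            plan = sinkhorn(C, gamma=gamma, tol=1e-10, max_iter=100000)
            obj = sinkhorn_objective(plan.values, C, gamma)
            uniform = np.full((n, n), 1.0 / n**2)
            assert obj <= sinkhorn_objective(uniform, C, gamma) + 1e-8
            for p in permutations(range(n)):
                P = np.zeros((n, n))
                P[np.arange(n), p] = 1.0 / n
                assert obj <= sinkhorn_objective(P, C, gamma) + 1e-8


class TestEnvSimilarity:
    def test_self_diagonal_is_one(self, rng, light_params):
        s = random_structure(rng, n_atoms=4)
        C = env_similarity(s, s, light_params)
        np.testing.assert_allclose(np.diag(C.values), 1.0, atol=1e-10)

    def test_identical_environments_all_ones(self, light_params):
        s = Structure("iso", ["C", "C"], [[0.0, 0.0, 0.0], [60.0, 0.0, 0.0]])
        C = env_similarity(s, s, light_params)
        np.testing.assert_allclose(C.values, 1.0, atol=1e-10)

    def test_matches_environment_kernel_loop(self, rng, light_params):
        from confnav.descriptors import compute_descriptors, environment_kernel

        a = random_structure(rng, n_atoms=4, sid="a")
        b = random_structure(rng, n_atoms=3, sid="b")
        alphabet = sorted(set(a.species) | set(b.species))
        C = env_similarity(a, b, light_params, species_alphabet=alphabet)
        da = compute_descriptors(a, light_params, species_alphabet=alphabet)
        db = compute_descriptors(b, light_params, species_alphabet=alphabet)
        expected = np.array(
            [[environment_kernel(x, y, light_params.zeta) for y in db] for x in da]
        )
        np.testing.assert_allclose(C.values, expected, atol=1e-12)

    def test_entries_validated(self):
        with pytest.raises(ValueError):
            EnvSimilarityMatrix(np.array([[1.5]]))


class TestRematchKernel:
    def test_identical_environments_give_one(self, light_params):
        s = Structure("iso", ["C", "C"], [[0.0, 0.0, 0.0], [60.0, 0.0, 0.0]])
        assert rematch_kernel(s, s, light_params, gamma=0.1) == pytest.approx(
            1.0, abs=1e-8
        )

    def test_large_gamma_is_mean_of_C(self, rng, light_params):
        # entropy dominates at gamma=100 and the kernel tends to mean(C); the
        # first-order deviation is Var(C)/gamma, so any moderate-contrast C
        # sits well within 1e-3 of the limit
        a = random_structure(rng, n_atoms=4, sid="a", species_pool=("C",))
        b = random_structure(rng, n_atoms=5, sid="b", species_pool=("C",))
        C = env_similarity(a, b, light_params, species_alphabet=["C"])
        K = rematch_kernel(
            a, b, light_params, gamma=100.0, species_alphabet=["C"]
        )
        assert K == pytest.approx(C.values.mean(), abs=1e-3)

    def test_small_gamma_is_best_match(self, light_params):
        """With chemically distinct atoms the optimal assignment is well
        separated and the entropic kernel at gamma=0.01 reaches it."""
        rng = np.random.default_rng(5)
        base = Structure(
            "a", ["C", "N", "O", "H"], rng.normal(scale=1.3, size=(4, 3))
        )
        other = Structure("b", list(base.species), base.coords + rng.normal(scale=0.05, size=(4, 3)))
        C = env_similarity(base, other, light_params).values
        K = rematch_kernel(
            base, other, light_params, gamma=0.01, tol=1e-4, max_iter=100000
        )
        assert K == pytest.approx(best_match_value(C), abs=1e-3)

    def test_gamma_interpolates_between_limits(self, rng, light_params):
        a = random_structure(rng, n_atoms=4, sid="a")
        b = random_structure(rng, n_atoms=4, sid="b")
        alphabet = sorted(set(a.species) | set(b.species))
        C = env_similarity(a, b, light_params, species_alphabet=alphabet).values
        lo, hi = C.mean(), best_match_value(C)
        for gamma in (0.1, 0.3, 1.0):
            K = rematch_kernel(
                a, b, light_params, gamma=gamma, tol=1e-6, max_iter=100000,
                species_alphabet=alphabet,
            )
            assert lo - 1e-6 <= K <= hi + 1e-6


class TestKernelMatrix:
    def test_single_structure_normalized(self, rng, light_params):
        ds = Dataset([random_structure(rng, n_atoms=3, sid="only")])
        K = kernel_matrix(ds, light_params, normalize=True)
        np.testing.assert_allclose(K.values, [[1.0]], atol=1e-12)

    def test_duplicate_structure_off_diagonal_one(self, rng, light_params):
        s = random_structure(rng, n_atoms=4, sid="a")
        dup = Structure("b", list(s.species), s.coords.copy())
        K = kernel_matrix(Dataset([s, dup]), light_params, normalize=True)
        assert K.values[0, 1] == pytest.approx(1.0, abs=1e-8)

    def test_matches_elementwise_rematch(self, toy_dataset, light_params):
        alphabet = toy_dataset.species_alphabet()
        K = kernel_matrix(toy_dataset, light_params, gamma=0.1, normalize=False)
        for i in range(len(toy_dataset)):
            for j in range(i, len(toy_dataset)):
                kij = rematch_kernel(
                    toy_dataset[i], toy_dataset[j], light_params, gamma=0.1,
                    species_alphabet=alphabet,
                )
                assert K.values[i, j] == pytest.approx(kij, abs=1e-9)

    def test_symmetric(self, toy_dataset, light_params):
        K = kernel_matrix(toy_dataset, light_params)
        assert np.abs(K.values - K.values.T).max() < 1e-10

    def test_atom_order_invariance(self, rng, light_params):
        s1 = random_structure(rng, n_atoms=5, sid="a")
        s2 = random_structure(rng, n_atoms=5, sid="b")
        perm = rng.permutation(5)
        s1p = Structure("a", [s1.species[i] for i in perm], s1.coords[perm])
        K1 = kernel_matrix(Dataset([s1, s2]), light_params)
        K2 = kernel_matrix(Dataset([s1p, s2]), light_params)
        np.testing.assert_allclose(K1.values, K2.values, atol=1e-10)


class TestKernelDistance:
    def test_trivial_values(self):
        K = KernelMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), normalized=True)
        D = kernel_to_distance(K)
        assert D.values[0, 0] == 0.0
        assert D.values[0, 1] == pytest.approx(1.0)
        K0 = KernelMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]), normalized=True)
        assert kernel_to_distance(K0).values[0, 1] == pytest.approx(np.sqrt(2.0))

    def test_negative_radicand_clamped_and_counted(self):
        K = KernelMatrix(np.array([[1.0, 1.2], [1.2, 1.0]]), normalized=False)
        D = kernel_to_distance(K)
        assert D.values[0, 1] == 0.0
        assert D.n_clamped == 1

    def test_normalized_self_kernels(self, toy_dataset, light_params):
        K = kernel_matrix(toy_dataset, light_params, normalize=True)
        np.testing.assert_allclose(np.diag(K.values), 1.0, atol=1e-8)
        D = kernel_to_distance(K)
        assert np.all(np.diag(D.values) == 0.0)
        assert np.abs(D.values - D.values.T).max() == 0.0


def test_hdf5_round_trips(tmp_path, toy_dataset, light_params):
    K = kernel_matrix(toy_dataset, light_params)
    D = kernel_to_distance(K)
    save_kernel(tmp_path / "k.h5", K, light_params, 0.1)
    save_distance(tmp_path / "d.h5", D, light_params, 0.1)
    K2 = load_kernel(tmp_path / "k.h5")
    D2 = load_distance(tmp_path / "d.h5")
    np.testing.assert_array_equal(K.values, K2.values)
    np.testing.assert_array_equal(D.values, D2.values)
    assert K2.ids == toy_dataset.ids
    assert D2.ids == toy_dataset.ids
    assert K2.normalized is True
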