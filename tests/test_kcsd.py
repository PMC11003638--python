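import numpy as np
import pytest

from lfpunmix import (
    BasisConfig,
    ElectrodeGrid,
    EvokedPotential,
    GaussianSource,
    Region,
    build_kernels,
    estimate_csd,
    expand_with_margin,
    fit,
    gaussian_source_potential,
    interp_potential,
    place_basis,
    select_lambda,
)
from lfpunmix.exceptions import ValidationError
from lfpunmix.forward import csd_basis_matrix
from lfpunmix.kcsd import default_lambda_candidates


def make_ep(grid, values, dt=0.5):
    times = np.arange(values.shape[1]) * dt
    return EvokedPotential(
        grid=grid, times=times, values=values, sampling_rate=1000.0 / dt
    )


@pytest.fixture
def kernels(small_grid, medium):
    region = Region("est", [[[-0.5, -0.5, 0.5], [2.0, 0.5, 3.0]]])
    basis = place_basis(region, spacing=0.5, width=0.4)
    return build_kernels(basis, small_grid, medium)


class TestPlaceBasis:
    def test_lattice_count(self, unit_box):
        basis = place_basis(unit_box, spacing=0.5, width=0.3)
        assert basis.n_sources == 27
        assert set(basis.region_labels) == {"box"}

    def test_faces_included_on_exact_division(self, unit_box):
        basis = place_basis(unit_box, spacing=0.5, width=0.3)
        zs = np.unique(basis.centers[:, 2])
        assert np.allclose(zs, [0.0, 0.5, 1.0])

    def test_degenerate_spacing_midpoint(self, unit_box):
        basis = place_basis(unit_box, spacing=2.0, width=0.3)
        assert basis.n_sources == 1
        assert np.allclose(basis.centers[0], [0.5, 0.5, 0.5])

    def test_disjoint_cuboids_additive(self):
        r = Region(
            "two", [[[0, 0, 0], [1, 1, 1]], [[5, 5, 5], [6, 6, 6]]]
        )
        basis = place_basis(r, spacing=0.5, width=0.3)
        assert basis.n_sources == 54

    def test_invalid_args(self, unit_box):
        with pytest.raises(ValidationError):
            place_basis(unit_box, spacing=0.0, width=0.3)
        with pytest.raises(ValidationError):
            place_basis(unit_box, spacing=0.5, width=-0.1)


class TestExpandWithMargin:
    def test_zero_margin_identity(self, unit_box):
        out = expand_with_margin(unit_box, 0.0)
        assert np.array_equal(out.cuboids[0], unit_box.cuboids[0])

    def test_one_mm_margin(self, unit_box):
        out = expand_with_margin(unit_box, 1.0)
        assert np.array_equal(out.cuboids[0], [[-1, -1, -1], [2, 2, 2]])

    def test_half_mm_margin(self, unit_box):
        # the margin used for the thalamic-only reconstruction space
        out = expand_with_margin(unit_box, 0.5)
        assert np.array_equal(out.cuboids[0], [[-0.5, -0.5, -0.5], [1.5, 1.5, 1.5]])

    def test_negative_margin_rejected(self, unit_box):
        with pytest.raises(ValidationError):
            expand_with_margin(unit_box, -0.1)


class TestBuildKernels:
    def test_rank_one_kernel(self, small_grid, medium):
        basis = BasisConfig(centers=np.array([[0.7, 0.0, 2.0]]), width=0.3)
        ks = build_kernels(basis, small_grid, medium)
        b = ks.B[:, 0]
        assert np.allclose(ks.K, np.outer(b, b), rtol=1e-12)

    def test_permutation_consistency(self, small_grid, medium, kernels):
        perm = np.random.default_rng(3).permutation(16)
        grid2 = ElectrodeGrid(
            [small_grid.channel_ids[i] for i in perm],
            small_grid.positions[perm],
            small_grid.broken[perm],
        )
        ks2 = build_kernels(kernels.basis, grid2, medium)
        assert np.allclose(ks2.K, kernels.K[np.ix_(perm, perm)], rtol=1e-12)

    def test_partition_identity(self, small_grid, medium, kernels):
        # K = K1 + K2 for any split of the basis sources
        M = kernels.basis.n_sources
        idx1 = np.arange(M // 2)
        idx2 = np.arange(M // 2, M)
        K1 = kernels.B[:, idx1] @ kernels.B[:, idx1].T
        K2 = kernels.B[:, idx2] @ kernels.B[:, idx2].T
        assert np.allclose(kernels.K, K1 + K2, rtol=1e-10, atol=1e-12)

    def test_kernel_symmetric_psd(self, kernels):
        assert np.allclose(kernels.K, kernels.K.T, rtol=1e-10)
        eigs = np.linalg.eigvalsh(kernels.K)
        assert eigs.min() >= -1e-8 * np.abs(eigs).max()


class TestFit:
    def test_zero_data_zero_coefficients(self, small_grid, kernels):
        ep = make_ep(small_grid, np.zeros((16, 5)))
        f = fit(ep, kernels, 0.1)
        assert np.all(f.beta == 0.0)

    def test_ridge_shrinkage_monotone(self, small_grid, kernels):
        rng = np.random.default_rng(4)
        ep = make_ep(small_grid, rng.normal(size=(16, 3)))
        norms = [
            np.linalg.norm(fit(ep, kernels, lam).beta)
            for lam in (0.01, 0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_known_coefficients_recovered(self, small_grid, kernels):
        # oracle: V constructed as K @ c must return beta = c at lambda = 0
        rng = np.random.default_rng(5)
        c = rng.normal(size=(16, 4))
        ep = make_ep(small_grid, kernels.K @ c)
        f = fit(ep, kernels, 0.0)
        assert np.allclose(f.beta, c, rtol=1e-6, atol=1e-8)

    def test_residual_contract(self, small_grid, kernels):
        rng = np.random.default_rng(6)
        ep = make_ep(small_grid, rng.normal(size=(16, 4)))
        lam = 0.5
        f = fit(ep, kernels, lam)
        resid = (kernels.K + lam * np.eye(16)) @ f.beta - ep.values
        assert np.linalg.norm(resid) <= 1e-8 * np.linalg.norm(ep.values)

    def test_singular_kernel_advises_regularization(self, medium):
        pos = np.column_stack([np.zeros(3), np.zeros(3), np.arange(3.0)])
        grid = ElectrodeGrid(["a", "b", "c"], pos, np.zeros(3, dtype=bool))
        basis = BasisConfig(centers=np.array([[0.0, 0.0, 10.0]]), width=0.1)
        ks = build_kernels(basis, grid, medium)  # rank-1, singular
        ep = make_ep(grid, np.ones((3, 2)))
        with pytest.raises(np.linalg.LinAlgError, match="lambda > 0"):
            fit(ep, ks, 0.0)

    def test_negative_lambda_rejected(self, small_grid, kernels):
        ep = make_ep(small_grid, np.zeros((16, 2)))
        with pytest.raises(ValidationError):
            fit(ep, kernels, -1.0)

    def test_linearity_in_data(self, small_grid, kernels):
        rng = np.random.default_rng(7)
        va = rng.normal(size=(16, 3))
        vb = rng.normal(size=(16, 3))
        fa = fit(make_ep(small_grid, va), kernels, 0.3)
        fb = fit(make_ep(small_grid, vb), kernels, 0.3)
        fab = fit(make_ep(small_grid, va + vb), kernels, 0.3)
        assert np.allclose(fab.beta, fa.beta + fb.beta, rtol=1e-10, atol=1e-12)


class TestEstimateCsd:
    def test_zero_data_zero_csd(self, small_grid, kernels):
        ep = make_ep(small_grid, np.zeros((16, 3)))
        f = fit(ep, kernels, 0.1)
        pts = kernels.basis.centers[:5]
        assert np.all(estimate_csd(f, pts) == 0.0)

    def test_single_source_peak_recovery(self, medium):
        # noiseless potential of one unit basis source sampled by a 3D
        # electrode lattice; lambda = 0 must recover the ground-truth CSD
        # peak within 1 %
        ax = np.arange(6) * 0.25
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        pos = np.column_stack([X.ravel(), Y.ravel(), Z.ravel() + 1.0])
        grid = ElectrodeGrid(
            [f"c{i}" for i in range(216)], pos, np.zeros(216, dtype=bool)
        )
        c = ax.mean()
        region = Region(
            "est", [[[c - 0.8, c - 0.8, 1.0 + c - 0.8], [c + 0.8, c + 0.8, 1.0 + c + 0.8]]]
        )
        basis = place_basis(region, spacing=0.25, width=0.35)
        ks = build_kernels(basis, grid, medium)
        target = np.array([c, c, 1.0 + c])
        i0 = int(np.argmin(np.linalg.norm(basis.centers - target, axis=1)))
        src = GaussianSource(tuple(basis.centers[i0]), width=0.35, amplitude=1.0)
        v = gaussian_source_potential(src, medium, grid.active_positions)
        ep = make_ep(grid, np.repeat(v[:, None], 2, axis=1))
        f = fit(ep, ks, 0.0)
        got = estimate_csd(f, basis.centers[i0 : i0 + 1])[0, 0]
        truth = 1.0 / ((2 * np.pi) ** 1.5 * 0.35**3)
        assert got == pytest.approx(truth, rel=0.01)

    def test_cross_kernel_equals_alpha_expansion(self, small_grid, kernels):
        # C(x) = K~(x,.) (K+lI)^-1 V  ==  sum_i alpha_i b~_i(x)
        rng = np.random.default_rng(8)
        ep = make_ep(small_grid, rng.normal(size=(16, 4)))
        f = fit(ep, kernels, 0.2)
        pts = rng.uniform([-0.3, -0.3, 0.6], [1.8, 0.3, 2.8], size=(10, 3))
        via_cross = estimate_csd(f, pts)
        via_alpha = csd_basis_matrix(pts, kernels.basis.centers, kernels.basis.width) @ f.alpha
        assert np.allclose(via_cross, via_alpha, rtol=1e-8, atol=1e-12)

    def test_outside_region_warns(self, small_grid, kernels):
        ep = make_ep(small_grid, np.ones((16, 2)))
        f = fit(ep, kernels, 0.1)
        with pytest.warns(UserWarning, match="outside"):
            estimate_csd(f, np.array([[50.0, 50.0, 50.0]]))


class TestInterpPotential:
    def test_reproduces_measurements_at_lambda_zero(self, small_grid, kernels):
        rng = np.random.default_rng(9)
        ep = make_ep(small_grid, kernels.K @ rng.normal(size=(16, 3)))
        f = fit(ep, kernels, 0.0)
        vstar = interp_potential(f, small_grid.active_positions)
        assert np.allclose(vstar, ep.values, rtol=1e-6, atol=1e-9)

    def test_mismatch_grows_with_lambda(self, small_grid, kernels):
        rng = np.random.default_rng(10)
        ep = make_ep(small_grid, rng.normal(size=(16, 3)))
        errs = []
        for lam in (0.01, 0.1, 1.0, 10.0):
            f = fit(ep, kernels, lam)
            vstar = interp_potential(f, small_grid.active_positions)
            errs.append(np.linalg.norm(vstar - ep.values))
        assert all(a < b for a, b in zip(errs, errs[1:]))

    def test_self_consistency_with_forward_projection(self, small_grid, kernels):
        # forward-projecting the alpha coefficients through the unit-basis
        # fields equals kernel interpolation at the electrodes
        rng = np.random.default_rng(11)
        ep = make_ep(small_grid, rng.normal(size=(16, 3)))
        f = fit(ep, kernels, 0.5)
        via_kernel = interp_potential(f, small_grid.active_positions)
        via_alpha = kernels.B @ f.alpha
        assert np.allclose(via_kernel, via_alpha, rtol=1e-6, atol=1e-12)


class TestSelectLambda:
    def test_single_candidate_returned(self, small_grid, kernels):
        ep = make_ep(small_grid, np.ones((16, 2)))
        assert select_lambda(ep, kernels, candidates=[0.42]) == 0.42

    def test_noiseless_residual_below_one_percent(self, small_grid, kernels):
        rng = np.random.default_rng(12)
        ep = make_ep(small_grid, kernels.K @ rng.normal(size=(16, 5)))
        lam = select_lambda(ep, kernels, method="lcurve")
        f = fit(ep, kernels, lam)
        resid = np.linalg.norm(kernels.K @ f.beta - ep.values)
        assert resid / np.linalg.norm(ep.values) < 0.01

    def test_chosen_lambda_member_of_candidates(self, small_grid, kernels):
        rng = np.random.default_rng(13)
        ep = make_ep(small_grid, rng.normal(size=(16, 3)))
        cands = default_lambda_candidates(kernels)
        for method in ("lcurve", "cv"):
            lam = select_lambda(ep, kernels, method=method, candidates=cands)
            assert lam in cands

    def test_noise_increases_median_lambda(self, small_grid, kernels):
        # over 20 seeds the median chosen lambda grows with the noise level
        clean = kernels.K @ np.random.default_rng(0).normal(size=(16, 20))
        scale = np.sqrt((clean**2).mean())
        chosen = {0.0: [], 0.2: []}
        for noise in chosen:
            for seed in range(20):
                rng = np.random.default_rng(100 + seed)
                v = clean + noise * scale * rng.standard_normal(clean.shape)
                ep = make_ep(small_grid, v)
                chosen[noise].append(select_lambda(ep, kernels, method="lcurve"))
        assert np.median(chosen[0.2]) > np.median(chosen[0.0])

    def test_degenerate_curve_returns_smallest(self, small_grid, kernels, caplog):
        ep = make_ep(small_grid, np.zeros((16, 2)))
        cands = default_lambda_candidates(kernels)
        with caplog.at_level("WARNING"):
            lam = select_lambda(ep, kernels, candidates=cands)
        assert lam == cands[0]

    def test_invalid_method(self, small_grid, kernels):
        ep = make_ep(small_grid, np.ones((16, 2)))
        with pytest.raises(ValidationError):
            select_lambda(ep, kernels, method="magic")


class TestRobustness:
    def test_missing_node_bounded_change(self, small_grid, medium):
        region = Region("est", [[[-0.5, -0.5, 0.5], [2.0, 0.5, 3.0]]])
        basis = place_basis(region, spacing=0.5, width=0.4)
        src = GaussianSource((0.7, 0.0, 1.7), width=0.4, amplitude=1.0)
        v = gaussian_source_potential(src, medium, small_grid.positions)

        def run(grid, vals):
            ks = build_kernels(basis, grid, medium)
            ep = make_ep(grid, np.repeat(vals[:, None], 2, axis=1))
            f = fit(ep, ks, 0.01)
            return estimate_csd(f, np.array([[0.7, 0.0, 1.7]]))[0, 0]

        full = run(small_grid, v)
        broken = small_grid.broken.copy()
        broken[5] = True
        grid2 = ElectrodeGrid(small_grid.channel_ids, small_grid.positions, broken)
        dropped = run(grid2, v[~broken])
        assert dropped == pytest.approx(full, rel=0.25)

    def test_grid_shape_agnosticism(self, medium):
        # same scene on a regular grid and a zig-zag grid: interior CSD maps
        # correlate > 0.95
        region = Region("est", [[[-0.6, -0.3, -0.6], [2.1, 0.3, 2.1]]])
        basis = place_basis(region, spacing=0.3, width=0.3)
        src1 = GaussianSource((0.7, 0.0, 0.7), width=0.3, amplitude=1.0)
        src2 = GaussianSource((0.9, 0.0, 1.1), width=0.3, amplitude=-1.0)

        xs, zs = np.meshgrid(np.arange(8) * 0.2, np.arange(8) * 0.2)
        reg_pos = np.column_stack([xs.ravel(), np.zeros(64), zs.ravel()])
        k = np.arange(64)
        zig_pos = np.column_stack(
            [((k % 2) * 0.1), np.zeros(64), k * 0.022]
        )
        zig_pos[:, 0] += 0.65  # center laterally on the sources

        maps = []
        eval_pts = np.column_stack(
            [
                np.linspace(0.4, 1.2, 9),
                np.zeros(9),
                np.linspace(0.4, 1.4, 9),
            ]
        )
        for pos in (reg_pos, zig_pos):
            grid = ElectrodeGrid(
                [f"c{i}" for i in range(64)], pos, np.zeros(64, dtype=bool)
            )
            v = gaussian_source_potential(
                src1, medium, grid.positions
            ) + gaussian_source_potential(src2, medium, grid.positions)
            ks = build_kernels(basis, grid, medium)
            f = fit(make_ep(grid, np.repeat(v[:, None], 2, axis=1)), ks, 1e-4 * np.trace(ks.K) / 64)
            maps.append(estimate_csd(f, eval_pts)[:, 0])
        r = np.corrcoef(maps[0], maps[1])[0, 1]
        assert r > 0.95
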