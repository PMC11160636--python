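import numpy as np
import pytest

from mpfm.core_io import BOLDDataset, BOLDRun, ModeDecomposition, preprocess
from mpfm.evaluation import match_to_truth
from mpfm.pfm_inference import (
    GroupModel,
    InferenceConfig,
    backproject_maps,
    fit,
    initialise_group,
    migp,
    step_size,
    update_group,
    update_subject,
)
from mpfm.synthetic_data import SimulationConfig, simulate_dataset


def principal_angles(A, B):
    """Largest principal angle (degrees) between the column spaces."""
    Qa, _ = np.linalg.qr(A)
    Qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return np.degrees(np.arccos(np.clip(s.min(), -1, 1)))


class TestStepSize:
    def test_closed_form(self):
        cfg = InferenceConfig(n_modes=2, forget_rate_beta=0.6, delay_tau=5.0)
        assert step_size(1, cfg) == pytest.approx(6 ** -0.6, abs=1e-12)
        assert step_size(1, cfg) == pytest.approx(0.3413, abs=5e-4)

    def test_harmonic_limit(self):
        cfg = InferenceConfig(n_modes=2, forget_rate_beta=1.0, delay_tau=0.0)
        for t in (1, 2, 10):
            assert step_size(t, cfg) == pytest.approx(1.0 / t)

    def test_strictly_decreasing(self):
        cfg = InferenceConfig(n_modes=2)
        vals = [step_size(t, cfg) for t in range(1, 50)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestMIGP:
    def test_single_subject_exact(self, rng):
        data = rng.normal(size=(80, 40))
        run = preprocess(BOLDRun(data=data, tr=1.0, subject_id="s",
                                 run_id="r"))
        ds = BOLDDataset(runs=[run])
        basis = migp(ds, 10, 0)
        _, _, vt = np.linalg.svd(run.data.T, full_matrices=False)
        assert principal_angles(basis.T, vt[:10].T) < 1e-4

    def test_duplicated_subject_same_subspace(self, rng):
        data = rng.normal(size=(80, 40))
        runs = [preprocess(BOLDRun(data=data, tr=1.0, subject_id=s,
                                   run_id="r")) for s in ("a", "b")]
        ds = BOLDDataset(runs=runs)
        basis = migp(ds, 10, 0)
        single = migp(BOLDDataset(runs=runs[:1]), 10, 0)
        assert principal_angles(basis.T, single.T) < 1e-4

    def test_approximates_concatenated_svd(self, rng):
        # low-rank shared structure + noise across 10 subjects
        shared = rng.normal(size=(200, 6))
        runs = []
        for s in range(10):
            tc = rng.normal(size=(6, 50))
            data = shared @ tc + 0.1 * rng.normal(size=(200, 50))
            runs.append(preprocess(BOLDRun(data=data, tr=1.0,
                                           subject_id=f"s{s}", run_id="r")))
        ds = BOLDDataset(runs=runs)
        basis = migp(ds, 12, 0)  # 2x the target rank
        concat = np.concatenate([r.data for r in ds.runs], axis=1)
        _, _, vt = np.linalg.svd(concat.T, full_matrices=False)
        assert principal_angles(basis[:6].T, vt[:6].T) < 5.0

    def test_too_many_components_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            migp(tiny_dataset, 100, 0)


class TestInitialiseGroup:
    def test_recovers_well_separated_modes_noiselessly(self, rng):
        # 12 disjoint block modes, tiny noise: the MIGP + ICA chain should
        # hand back the generating maps nearly unchanged
        V, M, T = 1500, 12, 150
        maps = np.zeros((V, M))
        width = V // M
        for j in range(M):
            maps[j * width:j * width + width - 10, j] = \
                rng.gamma(3.0, 0.5, width - 10)
        runs = []
        for s in range(6):
            tc = rng.normal(size=(M, T))
            data = maps @ tc + 0.3 * rng.normal(size=(V, T))
            runs.append(BOLDRun(data=data, tr=0.72, subject_id=f"s{s}",
                                run_id="r"))
        pre = BOLDDataset(runs=runs).map(preprocess)
        basis = migp(pre, 36, 0)
        group = initialise_group(basis, M, 0)
        from mpfm.mode_taxonomy import pair_modes

        pairing = pair_modes(group.map_mean, maps)
        assert np.mean(np.abs(pairing.correlations)) > 0.8

    def test_deterministic_and_valid(self, rng):
        # structured basis: mixed sparse sources (ICA-separable)
        sources = rng.normal(size=(300, 5)) * (rng.uniform(size=(300, 5)) > 0.8)
        mixing = rng.normal(size=(20, 5))
        basis = (sources @ mixing.T).T + 0.05 * rng.normal(size=(20, 300))
        g1 = initialise_group(basis, 5, 3)
        g2 = initialise_group(basis, 5, 3)
        assert np.array_equal(g1.map_mean, g2.map_mean)
        assert np.array_equal(g1.membership_prob, g2.membership_prob)
        assert np.all((g1.membership_prob >= 0) & (g1.membership_prob <= 1))
        g1.validate()


def _self_consistent_case(rng, V=300, M=4, T=200, n_runs=2):
    """Group model + data generated exactly from it (no noise)."""
    maps = np.zeros((V, M))
    for j in range(M):
        maps[j * (V // M):(j + 1) * (V // M), j] = \
            rng.gamma(3.0, 0.5, V // M)
    membership = (maps > 0).astype(float) * 0.97 + 0.01
    group = GroupModel(
        map_mean=maps, map_var=np.full((V, M), 0.05),
        membership_prob=membership, noise_map_var=0.01,
        wishart_scale=np.eye(M) / (M + 10), wishart_dof=M + 10,
        amp_mean=np.zeros(M), amp_var=np.full(M, 4.0),
        obs_noise_var=0.05,
    )
    # timecourses drawn inside the HRF-bandlimited subspace the model
    # constrains them to (the model's own generative assumption)
    from mpfm.core_io import hrf_temporal_basis

    B = hrf_temporal_basis(T, 0.72)
    runs = []
    for r in range(n_runs):
        tc = rng.normal(size=(M, B.shape[1])) @ B.T
        tc -= tc.mean(axis=1, keepdims=True)
        tc /= tc.std(axis=1, keepdims=True)
        runs.append(BOLDRun(data=maps @ tc, tr=0.72, subject_id="s",
                            run_id=f"run{r}"))
    return group, runs


class TestUpdateSubject:
    def test_self_consistent_reconstruction(self, rng):
        group, runs = _self_consistent_case(rng)
        cfg = InferenceConfig(n_modes=4, inner_iters=6, seed=0)
        post = update_subject(runs, group, cfg)
        for run in runs:
            recon = (post.map_mean
                     * post.amplitude[run.run_id][None, :]) @ \
                post.tc_mean[run.run_id]
            r = np.corrcoef(recon.ravel(), run.data.ravel())[0, 1]
            assert r > 0.99

    def test_reconstruction_error_never_increases(self, rng):
        group, runs = _self_consistent_case(rng)
        cfg = InferenceConfig(n_modes=4, inner_iters=8, seed=0)
        post = update_subject(runs, group, cfg)
        hist = post.recon_history
        assert all(b <= a + 1e-6 for a, b in zip(hist, hist[1:]))

    def test_zero_membership_mode_shrinks(self, rng):
        group, runs = _self_consistent_case(rng)
        # data has no contribution from a 5th mode with zero membership
        V, M = group.map_mean.shape
        group.map_mean = np.hstack([group.map_mean, np.zeros((V, 1))])
        group.map_var = np.hstack([group.map_var, np.full((V, 1), 0.05)])
        group.membership_prob = np.hstack(
            [group.membership_prob, np.zeros((V, 1))])
        group.wishart_scale = np.eye(M + 1) / (M + 10)
        group.amp_mean = np.zeros(M + 1)
        group.amp_var = np.full(M + 1, 0.25)
        cfg = InferenceConfig(n_modes=5, inner_iters=4, seed=0)
        post = update_subject(runs, group, cfg)
        assert np.max(np.abs(post.map_mean[:, -1])) < 0.05

    def test_scale_equivariance(self, rng):
        group, runs = _self_consistent_case(rng)
        cfg = InferenceConfig(n_modes=4, inner_iters=6, seed=0)
        post1 = update_subject(runs, group, cfg)
        doubled = [BOLDRun(data=2.0 * r.data, tr=r.tr,
                           subject_id=r.subject_id, run_id=r.run_id)
                   for r in runs]
        post2 = update_subject(doubled, group, cfg)
        for rid in ("run0", "run1"):
            ratio = post2.amplitude[rid] / post1.amplitude[rid]
            assert np.all(np.abs(ratio - 2.0) < 0.1)
            for j in range(4):
                r = np.corrcoef(post1.tc_mean[rid][j],
                                post2.tc_mean[rid][j])[0, 1]
                assert abs(r) > 0.99


class TestUpdateGroup:
    def _posterior(self, rng, V=50, M=3):
        from mpfm.pfm_inference import SubjectPosterior

        p = SubjectPosterior(
            map_mean=rng.normal(size=(V, M)),
            map_var=np.abs(rng.normal(size=(V, M))) + 0.01,
            map_membership=rng.uniform(size=(V, M)),
        )
        p.precision = np.eye(M) * (1 + rng.uniform())
        p.amplitude["run1"] = np.abs(rng.normal(size=M)) + 0.5
        p.residual_var["run1"] = 0.3
        return p

    def _group(self, V=50, M=3):
        return GroupModel(
            map_mean=np.zeros((V, M)), map_var=np.ones((V, M)),
            membership_prob=np.full((V, M), 0.5), noise_map_var=0.1,
            wishart_scale=np.eye(M) / (M + 10), wishart_dof=M + 10,
            amp_mean=np.zeros(M), amp_var=np.ones(M), obs_noise_var=0.5,
        )

    def test_full_replacement_at_rho_one(self, rng):
        batch = [self._posterior(rng) for _ in range(4)]
        out = update_group(self._group(), batch, 1.0)
        expect = np.mean([p.map_mean for p in batch], axis=0)
        assert np.allclose(out.map_mean, expect)
        assert np.allclose(out.membership_prob,
                           np.mean([p.map_membership for p in batch], axis=0))

    def test_convex_combination_algebra(self, rng):
        batch = [self._posterior(rng) for _ in range(3)]
        g = self._group()
        twice = update_group(update_group(g, batch, 0.5), batch, 0.5)
        once = update_group(g, batch, 0.75)
        assert np.allclose(twice.map_mean, once.map_mean)

    def test_variance_positivity_under_many_updates(self, rng):
        g = self._group()
        for _ in range(200):
            g = update_group(g, [self._posterior(rng)], 0.3)
            assert np.all(g.map_var > 0)
            assert g.noise_map_var > 0
            assert np.linalg.eigvalsh(g.wishart_scale).min() > 0

    def test_invalid_rho(self, rng):
        with pytest.raises(ValueError):
            update_group(self._group(), [self._posterior(rng)], 0.0)


class TestFit:
    def test_rank_one_noiseless(self, rng):
        true_map = np.abs(rng.normal(size=(200, 1))) * (
            rng.uniform(size=(200, 1)) > 0.6)
        runs = []
        for s in range(4):
            tc = rng.normal(size=(1, 60))
            runs.append(BOLDRun(data=true_map @ tc
                                + 1e-6 * rng.normal(size=(200, 60)),
                                tr=0.72, subject_id=f"s{s}", run_id="r"))
        ds = BOLDDataset(runs=runs)
        cfg = InferenceConfig(n_modes=1, seed=0, min_group_updates=10,
                              migp_dim=4)
        # fit on the raw (non-standardised) data so the generating map's
        # weight profile is preserved exactly; the ungated posterior mean
        # is the factorisation estimate
        dec = fit(ds, cfg, preprocess_data=False)
        r = np.corrcoef(dec.raw_group_maps[:, 0], true_map[:, 0])[0, 1]
        assert abs(r) > 0.999

    def test_deterministic(self, micro_sim):
        _, dataset, _ = micro_sim
        cfg = InferenceConfig(n_modes=4, seed=5, min_group_updates=6,
                              inner_iters=1, migp_dim=12)
        d1 = fit(dataset, cfg)
        d2 = fit(dataset, cfg)
        assert np.array_equal(d1.group_maps, d2.group_maps)
        k = sorted(d1.timecourses)[0]
        assert np.array_equal(d1.timecourses[k], d2.timecourses[k])


class TestBackprojection:
    def test_recovers_maps_from_generating_data(self, rng):
        V, M, T = 150, 3, 400
        maps = rng.normal(size=(V, M))
        tcs, amps, runs = {}, {}, []
        tc = rng.normal(size=(M, T))
        h = np.abs(rng.normal(size=M)) + 0.5
        data = maps @ (h[:, None] * tc) + 0.01 * rng.normal(size=(V, T))
        runs.append(BOLDRun(data=data, tr=1.0, subject_id="s", run_id="r"))
        tcs[("s", "r")] = tc
        amps[("s", "r")] = h
        subject_maps, group_map = backproject_maps(
            tcs, amps, BOLDDataset(runs=runs), ridge=1e-8)
        for j in range(M):
            r = np.corrcoef(group_map[:, j], maps[:, j])[0, 1]
            assert abs(r) > 0.99

    def test_orthonormal_design_betas_are_inner_products(self, rng):
        V, M, T = 40, 3, 200
        X, _ = np.linalg.qr(rng.normal(size=(T, M)))  # orthonormal columns
        tc = X.T
        data = rng.normal(size=(V, T))
        run = BOLDRun(data=data, tr=1.0, subject_id="s", run_id="r")
        _, group_map = backproject_maps(
            {("s", "r"): tc}, {("s", "r"): np.ones(M)},
            BOLDDataset(runs=[run]), ridge=0.0)
        # independent oracle: OLS betas = D X; t = beta / se
        betas = data @ X
        resid = data - betas @ X.T
        sig2 = np.sum(resid**2, axis=1) / (T - M)
        t_expect = betas / np.sqrt(sig2[:, None])
        assert np.allclose(group_map, t_expect, atol=1e-8)

    def test_infinite_ridge_kills_betas(self, rng):
        V, M, T = 30, 2, 100
        tc = rng.normal(size=(M, T))
        run = BOLDRun(data=rng.normal(size=(V, T)), tr=1.0,
                      subject_id="s", run_id="r")
        _, group_map = backproject_maps(
            {("s", "r"): tc}, {("s", "r"): np.ones(M)},
            BOLDDataset(runs=[run]), ridge=1e12, as_tstats=False)
        assert np.max(np.abs(group_map)) < 1e-3

    def test_singular_design_needs_ridge(self, rng):
        T = 50
        tc = np.ones((2, T))  # perfectly collinear
        run = BOLDRun(data=rng.normal(size=(10, T)), tr=1.0,
                      subject_id="s", run_id="r")
        with pytest.raises(ValueError, match="ridge"):
            backproject_maps({("s", "r"): tc}, {("s", "r"): np.ones(2)},
                             BOLDDataset(runs=[run]), ridge=0.0)
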