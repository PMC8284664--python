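"""Sequential Bayesian learning: likelihood, priors, MAP, Laplace update."""

import numpy as np
import pytest

from sblnet.network import (
    NetworkParams,
    NetworkSpec,
    forward,
    grow_spec,
    layout,
    n_params,
    sensitivities,
    unpack,
)
from sblnet.sbl import (
    FactorisedGaussian,
    OptimiserConfig,
    avg_trial_likelihood,
    block_log_likelihood,
    init_prior,
    laplace_precision_update,
    linear_gaussian_sbl,
    log_joint,
    log_prior,
    log_prior_grad,
    map_estimate,
    transfer_prior,
)
from sblnet.simulation import make_dataset
from sblnet.task_env import TrialBlock, generate_trials, reward_map


def small_block(seed=0, n=30, task=1, map_id="Sub1"):
    return generate_trials(map_id, task, n, policy="random", rng=seed)


class TestLikelihood:
    def test_chance_network_log_likelihood(self):
        spec = NetworkSpec(h1=1, n_tasks=1)
        params = NetworkParams.zeros(spec)
        block = TrialBlock(u1=[1, 2], u2=[3, 4], task=[1, 1], decision=[1, 2], reward=[1, 0])
        assert block_log_likelihood(params, block) == pytest.approx(2 * np.log(0.5))
        assert avg_trial_likelihood(params, block) == pytest.approx(0.5)

    def test_matches_per_trial_loop_oracle(self):
        spec = NetworkSpec(h1=2, n_tasks=2)
        rng = np.random.default_rng(4)
        params = unpack(rng.standard_normal(n_params(spec)) * 0.4, spec)
        b1 = small_block(seed=1, task=1)
        b2 = small_block(seed=2, task=2, map_id="Add2")
        block = TrialBlock.concatenate([b1, b2])
        total = 0.0
        for i in range(len(block)):
            v1 = forward(params, block.stimuli[i], int(block.task[i]))["v1"][0]
            vk = v1 if block.decision[i] == 1 else 1 - v1
            r = block.reward[i]
            total += r * np.log(vk) + (1 - r) * np.log(1 - vk)
        assert block_log_likelihood(params, block) == pytest.approx(total, rel=1e-12)

    def test_avg_trial_likelihood_is_exp_of_mean(self):
        spec = NetworkSpec(h1=1, n_tasks=1)
        rng = np.random.default_rng(9)
        params = unpack(rng.standard_normal(n_params(spec)) * 0.3, spec)
        block = small_block(seed=5)
        ll = block_log_likelihood(params, block)
        assert avg_trial_likelihood(params, block) == pytest.approx(np.exp(ll / len(block)))
        assert 0 < avg_trial_likelihood(params, block) < 1

    def test_saturated_values_are_clamped_with_warning(self):
        spec = NetworkSpec(h1=1, n_tasks=1)
        params = NetworkParams.zeros(spec)
        params.b_out[0] = 60.0  # sigmoid saturates to 1 numerically
        block = TrialBlock(u1=[1], u2=[1], task=[1], decision=[1], reward=[0])
        with pytest.warns(RuntimeWarning):
            ll = block_log_likelihood(params, block)
        assert np.isfinite(ll)


class TestPrior:
    def test_standard_normal_log_density_at_mode(self):
        prior = FactorisedGaussian(m=np.zeros(1), lam=np.ones(1))
        assert log_prior(np.zeros(1), prior) == pytest.approx(-0.5 * np.log(2 * np.pi))
        assert log_prior_grad(np.zeros(1), prior)[0] == 0.0

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        prior = FactorisedGaussian(m=rng.standard_normal(6), lam=rng.uniform(0.5, 4, 6))
        theta = rng.standard_normal(6)
        g = log_prior_grad(theta, prior)
        h = 1e-6
        for i in range(6):
            e = np.zeros(6)
            e[i] = h
            fd = (log_prior(theta + e, prior) - log_prior(theta - e, prior)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_non_positive_precision_rejected(self):
        with pytest.raises(ValueError):
            FactorisedGaussian(m=np.zeros(2), lam=np.array([1.0, 0.0]))

    def test_init_prior_fan_in_rule(self):
        spec = NetworkSpec(h1=2, n_tasks=2)
        prior = init_prior(spec)
        assert np.all(prior.m == 0)
        segs = {seg.key: seg for seg in layout(spec)}
        w1 = segs[("W1", None)]
        assert np.all(prior.lam[w1.start : w1.stop] == 3)  # fan-in = D
        w2 = segs[("W2", 1)]
        assert np.all(prior.lam[w2.start : w2.stop] == 2)  # fan-in = H1
        bo = segs[("b_out", 2)]
        assert np.all(prior.lam[bo.start : bo.stop] == 1)

    def test_prior_samples_have_matching_scale(self):
        spec = NetworkSpec(h1=1, n_tasks=1)
        prior = init_prior(spec)
        rng = np.random.default_rng(0)
        draws = np.array([prior.sample(rng) for _ in range(4000)])
        assert np.allclose(draws.std(axis=0), 1 / np.sqrt(prior.lam), atol=0.05)


class TestLogJoint:
    def test_gradient_matches_finite_differences(self):
        spec = NetworkSpec(h1=1, n_tasks=1)
        rng = np.random.default_rng(8)
        prior = init_prior(spec)
        block = small_block(seed=3)
        # mild scale keeps every value away from the clamp region, where the
        # analytic gradient intentionally ignores the clip
        theta = 0.5 * prior.sample(rng)
        J, g = log_joint(theta, block, prior, spec)
        h = 1e-6
        for i in range(len(theta)):
            e = np.zeros_like(theta)
            e[i] = h
            fd = (
                log_joint(theta + e, block, prior, spec)[0]
                - log_joint(theta - e, block, prior, spec)[0]
            ) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-6, abs=1e-6)

    def test_stronger_prior_pulls_optimum_toward_mean(self):
        # 1-D toy: scalar output bias only, graded against a grid search
        spec = NetworkSpec(h1=1, n_tasks=1)
        block = small_block(seed=6, n=20)
        grid = np.linspace(-3, 3, 2001)

        def argmax_b(lam):
            prior = init_prior(spec)
            prior.lam[:] = 1e6  # pin everything except the output bias
            segs = {seg.key: seg for seg in layout(spec)}
            i = segs[("b_out", 1)].start
            prior.lam[i] = lam
            best, best_J = None, -np.inf
            for b in grid:
                theta = prior.m.copy()
                theta[i] = b
                J, _ = log_joint(theta, block, prior, spec)
                if J > best_J:
                    best, best_J = b, J
            return abs(best)

        assert argmax_b(100.0) < argmax_b(0.1) + 1e-9


class TestMapEstimate:
    def test_ascent_never_decreases_log_joint(self):
        spec = NetworkSpec(h1=1, n_tasks=1)
        prior = init_prior(spec)
        block = small_block(seed=10, n=50)
        rng = np.random.default_rng(0)
        theta0 = prior.sample(np.random.default_rng(0))
        J0, _ = log_joint(theta0, block, prior, spec)
        fit = map_estimate(block, prior, OptimiserConfig(maxstarts=1), rng, spec)
        assert fit.log_joint >= J0 - 1e-9

    def test_deterministic_given_seed(self):
        spec = NetworkSpec(h1=1, n_tasks=1)
        prior = init_prior(spec)
        block = small_block(seed=11, n=50)
        fits = [
            map_estimate(block, prior, OptimiserConfig(), np.random.default_rng(42), spec)
            for _ in range(2)
        ]
        assert np.array_equal(fits[0].theta, fits[1].theta)
        assert fits[0].avg_trial_likelihood == fits[1].avg_trial_likelihood

    def test_zero_iterations_returns_prior_sample(self):
        spec = NetworkSpec(h1=1, n_tasks=1)
        prior = init_prior(spec)
        block = small_block(seed=12, n=30)
        cfg = OptimiserConfig(max_iter=0, maxstarts=1)
        fit = map_estimate(block, prior, cfg, np.random.default_rng(1), spec)
        expected = prior.sample(np.random.default_rng(1))
        assert np.array_equal(fit.theta, expected)

    def test_ridge_toy_recovers_closed_form(self):
        # Gaussian regression through the shared ascent: matches ridge exactly
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        y = 1.7 * x + rng.normal(scale=0.5, size=60)
        tau = 1 / 0.25
        prior = FactorisedGaussian(m=np.zeros(1), lam=np.array([2.0]))
        post = linear_gaussian_sbl(x, y, n_blocks=1, prior=prior, noise_precision=tau)
        closed = (tau * np.sum(x * y)) / (2.0 + tau * np.sum(x * x))
        assert post.m[0] == pytest.approx(closed, abs=1e-6)

    def test_trace_records_iterations(self):
        from sblnet.sbl import trace_to_frame

        spec = NetworkSpec(h1=1, n_tasks=1)
        prior = init_prior(spec)
        block = small_block(seed=13, n=30)
        fit = map_estimate(
            block, prior, OptimiserConfig(maxstarts=1), np.random.default_rng(5), spec,
            keep_trace=True,
        )
        frame = trace_to_frame(fit)
        assert list(frame.columns) == ["iteration", "log_joint", "step"]
        assert (frame["log_joint"].diff().dropna() >= -1e-9).all()


class TestLaplaceUpdate:
    def test_no_trials_leaves_precision_unchanged(self):
        spec = NetworkSpec(h1=1, n_tasks=1)
        prior = init_prior(spec)
        params = NetworkParams.zeros(spec)
        assert np.array_equal(
            laplace_precision_update(prior.lam, params, None), prior.lam
        )

    def test_single_chance_trial_increment(self):
        # v = 0.5 and eta = 1 on the output bias: increment 0.25 there
        spec = NetworkSpec(h1=1, n_tasks=1)
        params = NetworkParams.zeros(spec)
        block = TrialBlock(u1=[3], u2=[3], task=[1], decision=[1], reward=[1])
        lam0 = np.ones(n_params(spec))
        lam1 = laplace_precision_update(lam0, params, block)
        segs = {seg.key: seg for seg in layout(spec)}
        i = segs[("b_out", 1)].start
        assert lam1[i] == pytest.approx(1.25)

    def test_matches_dense_outer_product_hessian_diagonal(self):
        spec = NetworkSpec(h1=2, n_tasks=2)
        rng = np.random.default_rng(21)
        params = unpack(rng.standard_normal(n_params(spec)) * 0.5, spec)
        b1 = small_block(seed=14, n=15, task=1)
        b2 = small_block(seed=15, n=15, task=2, map_id="Add2")
        block = TrialBlock.concatenate([b1, b2])
        lam0 = np.full(n_params(spec), 0.7)
        lam1 = laplace_precision_update(lam0, params, block)
        # dense oracle: -H = sum_t v(1-v) eta eta'
        H = np.zeros((n_params(spec), n_params(spec)))
        for i in range(len(block)):
            task = int(block.task[i])
            cache = forward(params, block.stimuli[i], task)
            eta = sensitivities(params, block.stimuli[i], task, cache)[0]
            w = float(cache["v1"][0] * (1 - cache["v1"][0]))
            H += w * np.outer(eta, eta)
        assert np.allclose(lam1, lam0 + np.diag(H), rtol=1e-10, atol=1e-12)

    def test_precision_never_decreases(self):
        spec = NetworkSpec(h1=1, n_tasks=1)
        rng = np.random.default_rng(30)
        params = unpack(rng.standard_normal(n_params(spec)), spec)
        lam0 = init_prior(spec).lam
        lam1 = laplace_precision_update(lam0, params, small_block(seed=16, n=40))
        assert np.all(lam1 >= lam0)


class TestSequentialEquivalence:
    def test_blockwise_equals_single_batch_conjugate_posterior(self):
        # linear-Gaussian limit: SBL over J blocks == one-shot Bayesian regression
        rng = np.random.default_rng(17)
        x = rng.normal(size=120)
        y = 0.8 * x + rng.normal(scale=1.3, size=120)
        tau = 1 / 1.3**2
        prior = FactorisedGaussian(m=np.array([0.3]), lam=np.array([1.5]))
        seq = linear_gaussian_sbl(x, y, n_blocks=6, prior=prior, noise_precision=tau)
        lam_batch = 1.5 + tau * np.sum(x * x)
        m_batch = (1.5 * 0.3 + tau * np.sum(x * y)) / lam_batch
        assert seq.m[0] == pytest.approx(m_batch, abs=1e-8)
        assert seq.lam[0] == pytest.approx(lam_batch, abs=1e-8)


class TestTransferPrior:
    def test_shared_segments_carry_posterior_new_segments_get_init(self):
        spec1 = NetworkSpec(h1=1, n_tasks=1)
        spec2 = grow_spec(spec1)
        rng = np.random.default_rng(1)
        post = FactorisedGaussian(
            m=rng.standard_normal(n_params(spec1)),
            lam=rng.uniform(5, 500, n_params(spec1)),
        )
        prior2 = transfer_prior(post, spec1, spec2)
        segs1 = {seg.key: seg for seg in layout(spec1)}
        segs2 = {seg.key: seg for seg in layout(spec2)}
        for key, seg2 in segs2.items():
            if key in segs1:
                seg1 = segs1[key]
                assert np.array_equal(prior2.m[seg2.start : seg2.stop], post.m[seg1.start : seg1.stop])
                assert np.array_equal(
                    prior2.lam[seg2.start : seg2.stop], post.lam[seg1.start : seg1.stop]
                )
            else:
                assert np.all(prior2.m[seg2.start : seg2.stop] == 0)

    def test_reduced_precision_resets_precisions_but_keeps_means(self):
        spec1 = NetworkSpec(h1=1, n_tasks=1)
        spec2 = grow_spec(spec1)
        rng = np.random.default_rng(2)
        post = FactorisedGaussian(
            m=rng.standard_normal(n_params(spec1)),
            lam=rng.uniform(50, 900, n_params(spec1)),
        )
        prior2 = transfer_prior(post, spec1, spec2, reduced_precision=True)
        init1 = init_prior(spec1)
        segs1 = {seg.key: seg for seg in layout(spec1)}
        segs2 = {seg.key: seg for seg in layout(spec2)}
        for key, seg2 in segs2.items():
            if key in segs1:
                seg1 = segs1[key]
                assert np.array_equal(
                    prior2.lam[seg2.start : seg2.stop], init1.lam[seg1.start : seg1.stop]
                )
                assert np.array_equal(
                    prior2.m[seg2.start : seg2.stop], post.m[seg1.start : seg1.stop]
                )


class TestSubspaceRecovery:
    def test_learned_first_layer_aligns_with_subtraction_feature(self):
        # after a successful Sub1 fit the bottleneck weight vector should be
        # close to +/-[1, -1, 0] (cosine > 0.9) in most runs
        spec = NetworkSpec(h1=1, n_tasks=1)
        target = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)
        hits, successes = 0, 0
        for child in np.random.SeedSequence(2024).spawn(8):
            rng = np.random.default_rng(child)
            prior = init_prior(spec)
            dec = unpack(prior.sample(rng), spec)
            block = make_dataset(reward_map("Sub1"), 1, 100, dec, rng)
            fit = map_estimate(block, prior, OptimiserConfig(), rng, spec)
            if not fit.reached_threshold:
                continue
            successes += 1
            row = unpack(fit.theta, spec).W1[0]
            cos = abs(row @ target) / np.linalg.norm(row)
            hits += cos > 0.9
        assert successes >= 3
        assert hits > successes / 2
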