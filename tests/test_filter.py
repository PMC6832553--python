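"""GLMB filter: association weights, Gibbs sampling, and the joint
prediction-update against exhaustive-enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import glmbtrack as g
from glmbtrack.filter import (
    FilterSettings,
    GLMBDensity,
    GLMBHypothesis,
    Scan,
    Track,
    empty_density,
    gibbs_sample_assignments,
    log_tbd_ratio,
    normalize_truncate,
)
from glmbtrack.models import Label, RectSupport


def make_prior(track_specs, frame=0):
    """Build a single-hypothesis prior from (label, mean, cov) specs."""
    tracks = tuple(
        Track(
            label=lab,
            birth_frame=lab.time,
            birth_state=g.GaussianComponent(mean, cov),
            history=tuple([1] * (frame - lab.time + 1)),
            comp=g.GaussianComponent(mean, cov),
        )
        for lab, mean, cov in track_specs
    )
    return GLMBDensity([GLMBHypothesis(0.0, tracks)], frame)


def posterior_weight_map(post):
    """hypothesis -> weight keyed by the per-label current association."""
    out = {}
    for h in post.hypotheses:
        key = frozenset((t.label, int(t.history[-1])) for t in h.tracks)
        out[key] = out.get(key, 0.0) + math.exp(h.log_weight)
    return out


def total_variation(a, b):
    keys = set(a) | set(b)
    return 0.5 * sum(abs(a.get(k, 0.0) - b.get(k, 0.0)) for k in keys)


def enumerate_standard_posterior(track_specs, birth_specs, Z, models):
    """Exhaustive enumeration oracle for the standard joint predict-update.

    Decision per existing track: -1 die, 0 miss, j detect; per birth
    candidate: -1 absent, 0 miss, j detect.  Returns the same weight map as
    :func:`posterior_weight_map`."""
    det, clut, obs, motion = models.detection, models.clutter, models.obs, models.motion
    kappa = [clut.intensity(z) for z in Z]
    cands = []
    for lab, mean, cov in track_specs:
        mp = motion.F @ mean
        Pp = motion.F @ cov @ motion.F.T + motion.Q
        S = obs.H @ Pp @ obs.H.T + obs.R
        zh = obs.H @ mp
        opts = {-1: det.q_s, 0: det.p_s * det.q_d}
        for j, z in enumerate(Z, start=1):
            gz = multivariate_normal.pdf(z, zh, S)
            opts[j] = det.p_s * det.p_d * gz / kappa[j - 1]
        cands.append((lab, opts))
    for bc in birth_specs:
        S = obs.H @ bc.cov @ obs.H.T + obs.R
        zh = obs.H @ bc.mean
        opts = {-1: 1.0 - bc.r, 0: bc.r * det.q_d}
        for j, z in enumerate(Z, start=1):
            gz = multivariate_normal.pdf(z, zh, S)
            opts[j] = bc.r * det.p_d * gz / kappa[j - 1]
        cands.append((Label(1, bc.index), opts))
    weights = {}
    option_lists = [
        [(j, w) for j, w in opts.items() if w > 0.0] for _, opts in cands
    ]
    for combo in itertools.product(*option_lists):
        used = [j for j, _ in combo if j > 0]
        if len(used) != len(set(used)):
            continue
        w = 1.0
        key = []
        for (lab, _), (j, wj) in zip(cands, combo):
            w *= wj
            if j >= 0:
                key.append((lab, j))
        key = frozenset(key)
        weights[key] = weights.get(key, 0.0) + w
    tot = sum(weights.values())
    return {k: v / tot for k, v in weights.items()}


@pytest.fixture
def world(small_linear_models):
    return small_linear_models


class TestAssociationWeight:
    def test_miss_weights(self, world):
        comp = g.GaussianComponent(np.zeros(4), np.eye(4))
        det0 = g.DetectionModel(p_d=0.0, p_s=1.0)
        det1 = g.DetectionModel(p_d=1.0, p_s=1.0)
        Z = np.array([[0.0, 0.0]])
        assert g.association_weight(comp, 0, Z, det0, world.clutter, world.obs) == 1.0
        assert g.association_weight(comp, 0, Z, det1, world.clutter, world.obs) == 0.0

    def test_scalar_normal_density_oracle(self):
        # H=1, R=1, predictive mean 0 var 1 -> innovation N(0; 0, 2)
        obs = g.ObservationModel(kind="linear", H=np.eye(1), R=np.eye(1))
        clut = g.ClutterModel(1.0, RectSupport([-50.0], [50.0]))  # kappa = 0.01
        det = g.DetectionModel(p_d=0.95, p_s=1.0)
        comp = g.GaussianComponent([0.0], [[1.0]])
        got = g.association_weight(comp, 1, np.array([[0.0]]), det, clut, obs)
        want = 0.95 * (1.0 / math.sqrt(2 * math.pi * 2.0)) / 0.01
        assert got == pytest.approx(want, rel=1e-12)

    def test_index_out_of_range(self, world):
        comp = g.GaussianComponent(np.zeros(4), np.eye(4))
        with pytest.raises(ValueError):
            g.association_weight(comp, 3, np.zeros((1, 2)), world.detection, world.clutter, world.obs)


class TestGibbs:
    def test_degenerate_single_option(self, rng):
        costs = np.array([[-np.inf, 0.0]])  # one variable, only "miss" feasible
        out = gibbs_sample_assignments(costs, 100, np.array([1]), rng)
        assert out.shape == (1, 2)[:1] + (1,)
        assert out[0, 0] == 1

    def test_single_iteration_includes_init(self, rng):
        costs = np.zeros((2, 4))
        init = np.array([1, 1])
        out = gibbs_sample_assignments(costs, 1, init, rng)
        assert any((row == init).all() for row in out)

    def test_infeasible_init_rejected(self, rng):
        costs = np.zeros((2, 3))
        with pytest.raises(ValueError):
            gibbs_sample_assignments(costs, 10, np.array([2, 2]), rng)

    def test_chain_frequencies_match_stationary_distribution(self, rng):
        # 2 variables x {miss, z1, z2}; stationary distribution enumerated
        logc = np.log(
            np.array([[1e-12, 0.5, 1.2, 0.4], [1e-12, 0.8, 0.3, 1.5]])
        )
        n_sweeps = 10_000
        uniq, counts = gibbs_sample_assignments(
            logc, n_sweeps, np.array([1, 1]), rng, return_counts=True
        )
        emp = {tuple(row): c / n_sweeps for row, c in zip(uniq, counts)}
        target = {}
        for o1 in range(1, 4):
            for o2 in range(1, 4):
                if o1 >= 2 and o1 == o2:
                    continue
                target[(o1, o2)] = math.exp(logc[0, o1] + logc[1, o2])
        tot = sum(target.values())
        target = {k: v / tot for k, v in target.items()}
        tv = total_variation(emp, target)
        assert tv < 0.05


class TestJointPredictUpdate:
    def test_vacuous_prior_empty_scan(self, world, rng):
        post = g.joint_predict_update(
            empty_density(0), Scan(1, np.zeros((0, 2))), world,
            FilterSettings(h_max=10, gibbs_sweeps=10), rng,
        )
        assert len(post.hypotheses) == 1
        assert post.hypotheses[0].cardinality == 0
        assert post.hypotheses[0].log_weight == pytest.approx(0.0)

    def test_all_measurements_can_be_clutter(self, world, rng):
        post = g.joint_predict_update(
            empty_density(0), Scan(1, np.array([[1.0, 2.0], [3.0, -4.0]])), world,
            FilterSettings(h_max=10, gibbs_sweeps=50), rng,
        )
        assert len(post.hypotheses) == 1 and post.hypotheses[0].cardinality == 0

    def test_one_label_one_birth_one_measurement_vs_enumeration(self, world, rng):
        world.detection.p_d, world.detection.p_s = 0.9, 1.0
        specs = [(Label(0, 1), np.array([0.0, 0.0, 0.5, 0.0]), np.eye(4))]
        birth = [
            g.BirthComponent(r=0.1, mean=np.array([10.0, 10.0, 0, 0]), cov=np.eye(4), index=1)
        ]
        Z = np.array([[0.6, 0.1]])
        prior = make_prior(specs, frame=0)
        post = g.joint_predict_update(
            prior, Scan(1, Z), world, FilterSettings(h_max=100, gibbs_sweeps=20000),
            rng, birth_components=birth,
        )
        got = posterior_weight_map(post)
        want = enumerate_standard_posterior(specs, birth, Z, world)
        assert total_variation(got, want) <= 0.02

    def test_two_labels_two_measurements_vs_enumeration(self, world, rng):
        world.detection.p_d, world.detection.p_s = 0.85, 1.0
        specs = [
            (Label(0, 1), np.array([0.0, 0.0, 0.0, 0.0]), np.eye(4)),
            (Label(0, 2), np.array([5.0, 5.0, 0.0, 0.0]), np.eye(4)),
        ]
        Z = np.array([[0.4, -0.2], [5.2, 4.8]])
        prior = make_prior(specs, frame=0)
        post = g.joint_predict_update(
            prior, Scan(1, Z), world, FilterSettings(h_max=100, gibbs_sweeps=20000), rng,
        )
        got = posterior_weight_map(post)
        want = enumerate_standard_posterior(specs, [], Z, world)
        # pS = 1: the 7 valid association maps of the 1-1 constraint
        assert len(want) == 7
        assert total_variation(got, want) <= 0.02

    def test_generic_three_way_problem_vs_enumeration(self, world, rng):
        world.detection.p_d, world.detection.p_s = 0.8, 0.9
        specs = [
            (Label(0, 1), np.array([0.0, 0.0, 0, 0]), np.eye(4)),
            (Label(0, 2), np.array([8.0, 0.0, 0, 0]), np.eye(4)),
            (Label(0, 3), np.array([0.0, 8.0, 0, 0]), np.eye(4)),
        ]
        birth = [
            g.BirthComponent(r=0.2, mean=np.array([-8.0, -8.0, 0, 0]), cov=np.eye(4), index=1)
        ]
        Z = np.array([[0.5, 0.3], [7.7, -0.4], [-7.9, -8.2]])
        prior = make_prior(specs, frame=0)
        post = g.joint_predict_update(
            prior, Scan(1, Z), world, FilterSettings(h_max=2000, gibbs_sweeps=20000),
            rng, birth_components=birth,
        )
        got = posterior_weight_map(post)
        want = enumerate_standard_posterior(specs, birth, Z, world)
        assert total_variation(got, want) <= 0.02

    def test_posterior_invariants(self, world, rng):
        specs = [
            (Label(0, 1), np.array([0.0, 0.0, 0, 0]), np.eye(4)),
            (Label(0, 2), np.array([6.0, 6.0, 0, 0]), np.eye(4)),
        ]
        Z = np.array([[0.1, 0.1], [6.2, 5.9], [-20.0, 13.0]])
        post = g.joint_predict_update(
            make_prior(specs, 0), Scan(1, Z), world,
            FilterSettings(h_max=50, gibbs_sweeps=2000), rng,
        )
        assert math.fsum(math.exp(h.log_weight) for h in post.hypotheses) == pytest.approx(1.0, abs=1e-9)
        rho = post.cardinality_distribution()
        assert rho.sum() == pytest.approx(1.0, abs=1e-12)
        for h in post.hypotheses:
            labels = [t.label for t in h.tracks]
            assert len(set(labels)) == len(labels)
            assigned = [t.history[-1] for t in h.tracks if t.history[-1] > 0]
            assert len(set(assigned)) == len(assigned)  # positive 1-1 map

    def test_frame_mismatch_rejected(self, world, rng):
        with pytest.raises(ValueError):
            g.joint_predict_update(
                empty_density(0), Scan(5, np.zeros((0, 2))), world,
                FilterSettings(h_max=5, gibbs_sweeps=5), rng,
            )


class TestTBDRatio:
    def _psf(self, intensity=2 * math.pi, sigma_h=1.0, sigma_y=1.0, radius=None):
        return g.make_image_psf_model(intensity, sigma_h, sigma_y, 10, 10, radius)

    def test_zero_intensity_gives_unit_ratio(self, rng):
        obs = self._psf(intensity=0.0)
        img = rng.normal(size=(10, 10))
        comp = g.GaussianComponent(np.array([5.0, 5.0, 0, 0]), np.eye(4))
        assert g.tbd_likelihood_ratio(img, comp, obs) == pytest.approx(1.0)

    def test_noiseless_template_closed_form(self):
        # image == template  =>  log sigma_T = sum h_i^2 / (2 sigma_y^2)
        obs = self._psf(intensity=4.0, sigma_h=1.5)
        mean = np.array([5.0, 6.0, 0, 0])
        a = np.arange(1, 11, dtype=float)
        A, B = np.meshgrid(a, a)
        tmpl = obs.template_value(mean[0], mean[1], A, B)
        comp = g.GaussianComponent(mean, np.eye(4))
        got = log_tbd_ratio(tmpl, mean, obs)
        r = obs.template_radius
        sel = (np.abs(A - mean[0]) <= math.ceil(r) + 1) & (np.abs(B - mean[1]) <= math.ceil(r) + 1)
        # oracle restricted to the same truncated template box
        a_lo, a_hi = max(1, math.floor(mean[0] - r)), min(10, math.ceil(mean[0] + r))
        b_lo, b_hi = max(1, math.floor(mean[1] - r)), min(10, math.ceil(mean[1] + r))
        box = (A >= a_lo) & (A <= a_hi) & (B >= b_lo) & (B <= b_hi)
        want = float(np.sum(tmpl[box] ** 2) / (2 * obs.sigma_y**2))
        assert got == pytest.approx(want, rel=1e-12)

    def test_peak_template_value(self):
        obs = self._psf(intensity=8.0, sigma_h=4.0)
        assert obs.peak_amplitude == pytest.approx(8.0 / (2 * math.pi * 4.0))
        assert obs.template_value(5.0, 5.0, np.array([5.0]), np.array([5.0]))[0] == pytest.approx(
            obs.peak_amplitude
        )


class TestHybridUpdate:
    def test_flat_image_equals_standard_update(self, world, rng):
        world.image_obs = g.make_image_psf_model(0.0, 2.0, 1.0, 20, 20)
        specs = [(Label(0, 1), np.array([5.0, 5.0, 0, 0]), np.eye(4))]
        Z = np.array([[5.2, 4.9], [-1.0, 2.0]])
        img = np.zeros((20, 20))
        r1, r2 = np.random.default_rng(7), np.random.default_rng(7)
        std = g.joint_predict_update(
            make_prior(specs, 0), Scan(1, Z), world,
            FilterSettings(h_max=50, gibbs_sweeps=5000), r1,
        )
        hyb = g.hybrid_joint_predict_update(
            make_prior(specs, 0), Scan(1, Z, image=img), world,
            FilterSettings(h_max=50, gibbs_sweeps=5000), r2,
        )
        a, b = posterior_weight_map(std), posterior_weight_map(hyb)
        assert set(a) == set(b)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12)

    def test_single_pixel_template_scales_miss_weight_by_e(self, world, rng):
        # template radius 0 -> one pixel; choose y so log sigma_T = 1 exactly
        sigma_h = 1.0
        world.image_obs = g.make_image_psf_model(
            2 * math.pi * sigma_h, sigma_h, 1.0, 10, 10, template_radius=0.0
        )
        world.detection.p_d, world.detection.p_s = 0.5, 0.9
        img = np.zeros((10, 10))
        img[4, 4] = 1.5  # pixel (a=5, b=5): (2*1.5*1 - 1)/2 = 1
        specs = [(Label(0, 1), np.array([5.0, 5.0, 0, 0]), 1e-9 * np.eye(4))]
        r1, r2 = np.random.default_rng(3), np.random.default_rng(3)
        std = g.joint_predict_update(
            make_prior(specs, 0), Scan(1, np.zeros((0, 2))), world,
            FilterSettings(h_max=10, gibbs_sweeps=2000), r1,
        )
        hyb = g.hybrid_joint_predict_update(
            make_prior(specs, 0), Scan(1, np.zeros((0, 2)), image=img), world,
            FilterSettings(h_max=10, gibbs_sweeps=2000), r2,
        )

        def ratio(post):
            w = posterior_weight_map(post)
            key_miss = frozenset({(Label(0, 1), 0)})
            key_die = frozenset()
            return w[key_miss] / w[key_die]

        # prediction moves the mean; evaluate sigma_T where the filter does
        pred_mean = world.motion.F @ specs[0][1]
        expected = math.exp(log_tbd_ratio(img, pred_mean, world.image_obs))
        assert ratio(hyb) / ratio(std) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(math.e, rel=1e-6)

    def test_missing_image_is_an_error(self, world, rng):
        world.image_obs = g.make_image_psf_model(1.0, 2.0, 1.0, 10, 10)
        with pytest.raises(ValueError, match="joint_predict_update"):
            g.hybrid_joint_predict_update(
                empty_density(0), Scan(1, np.zeros((0, 2))), world, None, rng
            )

    def test_default_tbd_configuration_runs(self, rng):
        cfg = g.default_config("tbd", K=3)
        truth, scans = g.generate_tbd_scenario(cfg, seed=5)
        models = g.build_models(cfg)
        post = empty_density(0)
        for scan in scans:
            post = g.hybrid_joint_predict_update(
                post, scan, models, FilterSettings(h_max=200, gibbs_sweeps=200), rng
            )
            assert math.fsum(math.exp(h.log_weight) for h in post.hypotheses) == pytest.approx(
                1.0, abs=1e-9
            )


class TestNormalizeTruncate:
    def _density(self, weights):
        hyps = [
            GLMBHypothesis(math.log(w), (Track(Label(1, i + 1), 1, g.GaussianComponent(np.zeros(2), np.eye(2)), (0,), g.GaussianComponent(np.zeros(2), np.eye(2))),))
            for i, w in enumerate(weights)
        ]
        return GLMBDensity(hyps, 1)

    def test_under_cap_only_normalizes(self):
        d = normalize_truncate(self._density([0.2, 0.1, 0.1]), 5)
        assert len(d.hypotheses) == 3
        assert math.fsum(math.exp(h.log_weight) for h in d.hypotheses) == pytest.approx(1.0)

    def test_forced_arithmetic(self):
        d = normalize_truncate(self._density([0.5, 0.3, 0.2]), 2)
        w = sorted(math.exp(h.log_weight) for h in d.hypotheses)
        assert w == pytest.approx([0.375, 0.625])

    def test_matches_full_sort(self, rng):
        weights = rng.uniform(0.01, 1.0, 100)
        d = self._density(weights)
        labels_by_weight = [
            d.hypotheses[i].tracks[0].label
            for i in np.argsort(-weights, kind="stable")[:10]
        ]
        out = normalize_truncate(d, 10)
        assert [h.tracks[0].label for h in out.hypotheses] == labels_by_weight

    def test_duplicate_merge(self):
        t = Track(Label(1, 1), 1, g.GaussianComponent(np.zeros(2), np.eye(2)), (0,), g.GaussianComponent(np.zeros(2), np.eye(2)))
        d = GLMBDensity([GLMBHypothesis(math.log(0.4), (t,)), GLMBHypothesis(math.log(0.6), (t,))], 1)
        out = normalize_truncate(d, 10)
        assert len(out.hypotheses) == 1
        assert out.hypotheses[0].log_weight == pytest.approx(0.0, abs=1e-12)

    def test_empty_density_rejected(self):
        with pytest.raises(ValueError):
            normalize_truncate(GLMBDensity([], 0), 5)


class TestSpawning:
    def _cell_world(self, p_t):
        motion = g.make_cv_model(1.0, 1.0)
        obs = g.make_linear_position_model(1.5, state_dim=4)
        clutter = g.ClutterModel(1.0, RectSupport([-50.0, -50.0], [50.0, 50.0]))
        det = g.DetectionModel(p_d=0.9, p_s=0.95)
        spawn = g.SpawnModel(p_t=p_t, Q_t=np.diag([9.0, 9.0, 1.0, 1.0]))
        return g.ModelSet(
            motion=motion, obs=obs, birth=g.BirthModel(components=[]),
            clutter=clutter, detection=det, spawn=spawn,
        )

    def test_zero_spawn_probability_equals_standard(self):
        world = self._cell_world(0.0)
        specs = [(Label(0, 1), np.array([0.0, 0.0, 1.0, 0.0]), np.eye(4))]
        Z = np.array([[1.1, 0.2], [12.0, -3.0]])
        r1, r2 = np.random.default_rng(11), np.random.default_rng(11)
        std = g.joint_predict_update(
            make_prior(specs, 0), Scan(1, Z), world,
            FilterSettings(h_max=100, gibbs_sweeps=5000), r1,
        )
        spw = g.spawning_joint_predict_update(
            make_prior(specs, 0), Scan(1, Z), world,
            FilterSettings(h_max=100, gibbs_sweeps=5000), r2,
        )
        a, b = posterior_weight_map(std), posterior_weight_map(spw)
        assert set(a) == set(b)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9)

    def test_one_parent_one_spawn_vs_enumeration(self):
        world = self._cell_world(0.3)
        det, sp, obs, motion = world.detection, world.spawn, world.obs, world.motion
        m = np.array([0.0, 0.0, 1.0, 0.0])
        P = np.eye(4)
        Z = np.array([[1.2, 0.3], [0.5, -0.8]])
        kappa = [world.clutter.intensity(z) for z in Z]
        lab = Label(0, 1)
        prior = make_prior([(lab, m, P)], frame=0)
        post = g.spawning_joint_predict_update(
            prior, Scan(1, Z), world, FilterSettings(h_max=500, gibbs_sweeps=20000),
            np.random.default_rng(2),
        )
        got = posterior_weight_map(post)

        # oracle: joint parent-daughter Gaussian, all 14 decision pairs
        F, Q, Qt, H, R = motion.F, motion.Q, sp.Q_t, obs.H, obs.R
        mp, md = F @ m, m.copy()
        Pj = np.block([[F @ P @ F.T + Q, F @ P], [P @ F.T, P + Qt]])
        mj = np.concatenate([mp, md])
        Hp = np.hstack([H, np.zeros_like(H)])
        Hd = np.hstack([np.zeros_like(H), H])
        want = {}
        slab = Label(1, 1, parent=lab)
        for dp in (-1, 0, 1, 2):
            for dd in (-1, 0, 1, 2):
                if dp > 0 and dp == dd:
                    continue
                w = det.q_s if dp < 0 else det.p_s * (det.q_d if dp == 0 else det.p_d)
                w *= sp.q_t if dd < 0 else sp.p_t * (det.q_d if dd == 0 else det.p_d)
                Hs, zs = [], []
                if dp > 0:
                    Hs.append(Hp)
                    zs.append(Z[dp - 1])
                    w /= kappa[dp - 1]
                if dd > 0:
                    Hs.append(Hd)
                    zs.append(Z[dd - 1])
                    w /= kappa[dd - 1]
                if Hs:
                    Hs = np.vstack(Hs)
                    zs = np.concatenate(zs)
                    S = Hs @ Pj @ Hs.T + np.kron(np.eye(len(zs) // 2), R)
                    w *= multivariate_normal.pdf(zs, Hs @ mj, S)
                key = []
                if dp >= 0:
                    key.append((lab, dp))
                if dd >= 0:
                    key.append((slab, dd))
                want[frozenset(key)] = want.get(frozenset(key), 0.0) + w
        tot = sum(want.values())
        want = {k: v / tot for k, v in want.items()}
        assert len(want) == 14
        assert total_variation(got, want) <= 0.02

    def test_spawn_labels_encode_parent(self):
        world = self._cell_world(0.5)
        specs = [(Label(0, 1), np.array([0.0, 0.0, 0.0, 0.0]), np.eye(4))]
        Z = np.array([[0.5, 0.5], [3.0, -2.0]])
        post = g.spawning_joint_predict_update(
            make_prior(specs, 0), Scan(1, Z), world,
            FilterSettings(h_max=200, gibbs_sweeps=5000), np.random.default_rng(4),
        )
        seen_spawn = False
        for h in post.hypotheses:
            for t in h.tracks:
                if t.label.is_spawn:
                    seen_spawn = True
                    assert t.label.parent == Label(0, 1)
                    assert t.label.time == 1
        assert seen_spawn

    def test_interleaved_spawn_covariance_accepted(self):
        from glmbtrack.scenarios import interleaved_to_canonical

        qt = np.diag(interleaved_to_canonical([400.0, 5.0, 400.0, 5.0, np.pi / 90]))
        sp = g.SpawnModel(p_t=0.035, Q_t=qt)
        assert sp.Q_t[0, 0] == 400.0 and sp.Q_t[1, 1] == 400.0
        assert sp.Q_t[2, 2] == 5.0 and sp.Q_t[4, 4] == pytest.approx(np.pi / 90)
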