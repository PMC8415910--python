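"""Two-block constitutive network: structure, exactness, determinism, persistence."""

import numpy as np
import pytest

from viscocann.kinematics import NeoHookean, uniaxial_nominal_stress
from viscocann.model import FEATURES, CompositionVector, FeatureScaler, ViscoCANN
from viscocann.qlv import PronySet, recursive_stress
from viscocann.synthetic import ProtocolSpec, sample_composition
from viscocann.training import TrainConfig, train_fold, _SpecimenBatch, _specimen_loss_and_grads
from viscocann.io import SpecimenData


@pytest.fixture(scope="module")
def model():
    comps = np.stack([c.values for c in sample_composition("C", 8, 5)])
    m = ViscoCANN.initialize(seed=17, scaler=FeatureScaler().fit(comps))
    return m


@pytest.fixture(scope="module")
def comp():
    return sample_composition("TH", 1, 9)[0]


class TestCompositionVector:
    def test_feature_count_enforced(self):
        with pytest.raises(ValueError, match="11 features"):
            CompositionVector(values=np.ones(10), region="C")

    def test_negative_concentration_rejected(self):
        v = np.ones(11)
        v[3] = -0.1
        with pytest.raises(ValueError, match=">= 0"):
            CompositionVector(values=v, region="C")

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="unknown region"):
            CompositionVector(values=np.ones(11), region="XX")


class TestFeatureScaler:
    def test_round_trip_and_training_statistics(self):
        rng = np.random.default_rng(0)
        C = rng.uniform(0.1, 10.0, size=(20, 11))
        sc = FeatureScaler().fit(C)
        Z = sc.transform(C)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-12)
        sc2 = FeatureScaler.from_dict(sc.to_dict())
        assert np.allclose(sc2.transform(C), Z)

    def test_use_before_fit_rejected(self):
        with pytest.raises(RuntimeError, match="fit"):
            FeatureScaler().transform(np.ones((1, 11)))


class TestForward:
    def test_stress_free_at_identity_for_any_parameters(self, comp):
        for seed in range(5):
            comps = np.stack([c.values for c in sample_composition("C", 5, seed)])
            m = ViscoCANN.initialize(seed=seed, scaler=FeatureScaler().fit(comps))
            z = m.scale_composition(comp)
            assert m.quasi_elastic_stress(1.0, z)[0] == 0.0

    def test_inference_is_deterministic(self, model, comp):
        psi1 = model.forward_energy(np.array([1.1]), comp)
        psi2 = model.forward_energy(np.array([1.1]), comp)
        assert np.array_equal(psi1, psi2)
        t = np.linspace(0.0, 10.0, 50)
        lam = 1.0 + 0.1 * np.sin(t)
        P1 = model.predict_stress(t, lam, comp).P
        P2 = model.predict_stress(t, lam, comp).P
        assert np.array_equal(P1, P2)

    def test_energy_derivatives_match_finite_differences(self, model, comp):
        z = model.scale_composition(comp)
        lam = np.array([0.9, 1.1])
        d1, d2 = model.energy_derivatives(lam, z)
        from viscocann.kinematics import invariants
        from viscocann.model import INVARIANT_SCALE

        eps = 1e-6
        for k, dk in enumerate((d1, d2)):
            # dPsi/dI_k equals the net's tangent w.r.t. its scaled input channel
            Xp = model.energy_inputs(lam, z).copy()
            Xm = Xp.copy()
            Xp[:, k] += eps
            Xm[:, k] -= eps
            fd = (model.energy_net(Xp)[:, 0] - model.energy_net(Xm)[:, 0]) / (2 * eps)
            assert np.allclose(dk, fd, rtol=1e-5, atol=1e-10)

    def test_prony_output_is_valid_for_random_parameters(self, comp):
        for seed in range(10):
            comps = np.stack([c.values for c in sample_composition("BG", 4, seed)])
            m = ViscoCANN.initialize(seed=seed + 50, scaler=FeatureScaler().fit(comps))
            ps = m.forward_prony(comp)  # __post_init__ validates
            assert ps.g0 > 0.0
            assert ps.terms[0][1] < ps.terms[1][1]


class TestPredictStress:
    def test_identity_kernel_reproduces_quasi_elastic_path(self, model, comp):
        t, lam = ProtocolSpec(kind="cyclic").path()
        z = model.scale_composition(comp)
        P0 = model.quasi_elastic_stress(lam, z)
        identity = PronySet(1.0, ((0.0, 1.0), (0.0, 100.0)))
        assert np.allclose(recursive_stress(t, P0, identity).P, P0, atol=1e-14)

    def test_hysteresis_iff_transient_terms(self, model, comp):
        """The quasi-elastic path closes (loop area at the grid's discretization
        floor) while the viscoelastic prediction opens a clearly larger loop."""
        t, lam = ProtocolSpec(kind="cyclic").path()
        z = model.scale_composition(comp)
        P0 = model.quasi_elastic_stress(lam, z)
        area_el = abs(np.trapezoid(P0, lam))
        P = model.predict_stress(t, lam, comp).P
        area_ve = abs(np.trapezoid(P, lam))
        scale = np.max(np.abs(P0)) * 0.3  # stress x stretch span
        # up/down branches sample slightly different stretches, so the closed
        # elastic loop only cancels to the trapezoid error O(dlam^2)
        assert area_el < 1e-3 * scale
        assert area_ve > 20.0 * area_el


class TestGradients:
    def test_training_gradient_matches_finite_differences(self, tiny_dataset):
        sp = tiny_dataset.specimens
        comps = np.stack([s.composition.values for s in sp])
        model = ViscoCANN.initialize(seed=3, scaler=FeatureScaler().fit(comps))
        batch = _SpecimenBatch(sp[0], model)
        mask = model.energy_net.dropout_mask(np.random.default_rng(5))
        _, grads = _specimen_loss_and_grads(model, batch, mask)
        rng = np.random.default_rng(0)
        for p, g in zip(model.parameters(), grads):
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                eps = 1e-6 * max(1.0, abs(p[idx]))
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = _specimen_loss_and_grads(model, batch, mask)
                p[idx] = orig - eps
                lm, _ = _specimen_loss_and_grads(model, batch, mask)
                p[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert g[idx] == pytest.approx(fd, rel=5e-4, abs=1e-9)


class TestTrainingRecovery:
    def test_neo_hookean_recovery(self):
        """Trained on clean neo-Hookean elastic data, the network recovers the
        tension stress at the protocol extreme within 5%.

        Regularization is turned down for this fit: on a noise-free
        single-specimen curve the residual loss converges to ~1e-5, and the
        default penalties would dominate the remaining gradient signal.
        """
        spec = ProtocolSpec(kind="cyclic")
        t, lam = spec.path()
        P_exp = uniaxial_nominal_stress(NeoHookean(mu=1.0), lam)
        comp = sample_composition("C", 1, 2)[0]
        sp = SpecimenData("NH-0", comp, {"cyclic": (t, lam, P_exp)})
        config = TrainConfig(epochs=4000, seed=1, l2_weight=0.0, energy_norm_weight=1e-3)
        fr = train_fold([sp], sp, config)
        P_pred = fr.model.predict_stress(t, lam, comp).P
        k = int(np.where(np.isclose(lam, 1.15))[0][-1])  # final, conditioned peak
        assert P_pred[k] == pytest.approx(0.3938563, rel=0.05)


class TestPersistence:
    def test_checkpoint_round_trip(self, model, comp, tmp_path):
        path = tmp_path / "ckpt.json"
        model.save(path)
        loaded = ViscoCANN.load(path)
        t, lam = ProtocolSpec(kind="cyclic").path()
        assert np.allclose(
            loaded.predict_stress(t, lam, comp).P,
            model.predict_stress(t, lam, comp).P,
            atol=1e-12,
        )

    def test_non_checkpoint_rejected(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text('{"hello": 1}')
        with pytest.raises(ValueError, match="not a viscocann checkpoint"):
            ViscoCANN.load(bad)
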