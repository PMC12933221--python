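import dataclasses
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from scipy import stats

from hrmsqc import (
    HistoryStore,
    PeakMeasurement,
    QCConfig,
    block_features,
    evaluate_mspc,
    fit_block_model,
    pairwise_ratios,
    project_sample,
)
from hrmsqc.mspc import NOCModel, build_noc, t2_limit_f

T0 = datetime(2024, 6, 1, tzinfo=timezone.utc)


def _measurements(heights, rts=None, errs=None):
    ids = [f"is{i}" for i in range(len(heights))]
    return [
        PeakMeasurement(
            cid,
            detected=h is not None,
            height=h or 0.0,
            apex_rt=(rts[i] if rts else 300.0 + 10 * i) if h is not None else None,
            mass_error=(errs[i] if errs else 0.0) if h is not None else None,
        )
        for i, (cid, h) in enumerate(zip(ids, heights))
    ], ids


class TestPairwiseRatios:
    def test_equal_values_give_half(self):
        names, vals = pairwise_ratios([5.0, 5.0], ["a", "b"])
        assert names == ["R(a,b)"] and vals[0] == pytest.approx(0.5)

    def test_direct_arithmetic(self):
        _, vals = pairwise_ratios([100.0, 300.0], ["a", "b"])
        assert vals[0] == pytest.approx(0.25)

    def test_eight_standards_give_28_features(self):
        names, vals = pairwise_ratios(list(range(1, 9)), [f"c{i}" for i in range(8)])
        assert len(names) == len(vals) == 28

    def test_complementary_orientations_sum_to_one(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(1, 100, 6)
        names = [f"c{i}" for i in range(6)]
        fwd_names, fwd = pairwise_ratios(v, names)
        rev_names, rev = pairwise_ratios(v[::-1], names[::-1])
        rev_by_name = dict(zip(rev_names, rev))
        for name, value in zip(fwd_names, fwd):
            a, b = name[2:-1].split(",")
            assert value + rev_by_name[f"R({b},{a})"] == pytest.approx(1.0)

    def test_both_zero_gives_zero(self):
        _, vals = pairwise_ratios([0.0, 0.0, 3.0], ["a", "b", "c"])
        assert vals[0] == 0.0  # R(a,b) with both missing

    def test_common_gain_leaves_every_ratio_unchanged(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(1e4, 1e6, 8)
        names = [f"c{i}" for i in range(8)]
        _, base = pairwise_ratios(v, names)
        for gain in (0.1, 2.5, 37.0):
            _, scaled = pairwise_ratios(gain * v, names)
            np.testing.assert_allclose(scaled, base, rtol=1e-12)

    def test_missing_value_feature_vector_is_zero_imputed(self):
        ms, ids = _measurements([100.0, None, 300.0])
        fv = block_features(ms, ids, "height")
        assert fv.values[0] == pytest.approx(1.0)   # R(is0, is1) = 100/(100+0)
        assert fv.values[2] == pytest.approx(0.0)   # R(is1, is2) = 0/(0+300)


def _random_model(rng, n=60, p=8, k=3, alpha=0.05 / 6):
    A = rng.normal(size=(p, p))
    cov = A @ A.T + 0.5 * np.eye(p)
    X = rng.multivariate_normal(np.zeros(p), cov, size=n)
    cfg = QCConfig(n_pcs=k)
    model = fit_block_model(X, [f"f{i}" for i in range(p)], cfg,
                            block="mass_error", alpha_corrected=alpha)
    return X, model


class TestFitAndProject:
    def test_loadings_orthonormal_and_variances_non_increasing(self):
        rng = np.random.default_rng(2)
        _, model = _random_model(rng)
        P = model.loadings
        np.testing.assert_allclose(P.T @ P, np.eye(P.shape[1]), atol=1e-8)
        assert np.all(np.diff(model.score_variances) <= 1e-12)

    def test_autoscaled_noc_columns_standardised(self):
        rng = np.random.default_rng(3)
        X, model = _random_model(rng)
        Xs = (X - model.means) / model.sds
        np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(Xs.std(axis=0, ddof=1), 1.0, atol=1e-6)

    def test_sample_at_noc_mean_scores_zero(self):
        rng = np.random.default_rng(4)
        _, model = _random_model(rng)
        res = project_sample(model.means.copy(), model)
        assert res.t2 == pytest.approx(0.0, abs=1e-16)
        assert res.spe == pytest.approx(0.0, abs=1e-16)

    def test_t2_equals_bruteforce_mahalanobis_on_50_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(25, 90))
            p = int(rng.integers(5, 12))
            X, model = _random_model(rng, n=n, p=p, k=min(3, p))
            x = rng.normal(size=p) * model.sds + model.means
            res = project_sample(x, model)
            Xs = (X - model.means) / model.sds
            noc_scores = Xs @ model.loadings
            cov = np.cov(noc_scores.T)
            xs = (x - model.means) / model.sds
            t = xs @ model.loadings
            brute = float(t @ np.linalg.solve(cov, t))
            assert res.t2 == pytest.approx(brute, rel=1e-8)

    def test_energy_conservation_at_full_rank(self):
        rng = np.random.default_rng(6)
        p = 5
        X = rng.normal(size=(40, p))
        cfg = QCConfig(n_pcs=p)
        model = fit_block_model(X, [f"f{i}" for i in range(p)], cfg)
        x = rng.normal(size=p)
        res = project_sample(x * model.sds + model.means, model)
        assert res.spe + float(res.scores @ res.scores) == pytest.approx(
            float(x @ x), rel=1e-10
        )

    def test_contributions_are_score_times_loading(self):
        rng = np.random.default_rng(7)
        _, model = _random_model(rng)
        x = rng.normal(size=model.loadings.shape[0]) * model.sds + model.means
        res = project_sample(x, model)
        expected = res.scores[:, None] * model.loadings.T
        np.testing.assert_allclose(res.contributions, expected)

    def test_zero_variance_feature_dropped_and_charged_to_spe(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 4))
        X = np.hstack([X, np.full((40, 1), 7.0)])  # constant fifth feature
        cfg = QCConfig(n_pcs=2)
        model = fit_block_model(X, list("abcde"), cfg)
        assert model.dropped == [("e", 7.0)]
        on_const = project_sample(np.array([0, 0, 0, 0, 7.0]), model)
        off_const = project_sample(np.array([0, 0, 0, 0, 7.1]), model)
        assert off_const.spe > on_const.spe
        assert off_const.spe_reject

    def test_sign_convention_makes_refits_identical(self):
        rng = np.random.default_rng(9)
        X, _ = _random_model(rng)
        cfg = QCConfig()
        m1 = fit_block_model(X, [f"f{i}" for i in range(X.shape[1])], cfg)
        m2 = fit_block_model(X.copy(), [f"f{i}" for i in range(X.shape[1])], cfg)
        np.testing.assert_array_equal(m1.loadings, m2.loadings)
        assert all(
            m1.loadings[np.argmax(np.abs(m1.loadings[:, j])), j] > 0
            for j in range(m1.loadings.shape[1])
        )

    def test_serialisation_round_trip_projects_identically(self, tmp_path):
        rng = np.random.default_rng(10)
        _, model = _random_model(rng)
        path = tmp_path / "model.json"
        model.save(path)
        back = NOCModel.load(path)
        x = rng.normal(size=model.loadings.shape[0]) * model.sds + model.means
        a, b = project_sample(x, model), project_sample(x, back)
        assert a.t2 == pytest.approx(b.t2) and a.spe == pytest.approx(b.spe)


class TestControlLimits:
    def test_t2_limit_approaches_chi_square_for_large_n(self):
        alpha = 0.05 / 6
        lim = t2_limit_f(n=10**6, k=3, alpha=alpha)
        assert lim == pytest.approx(stats.chi2.ppf(1 - alpha, 3), rel=1e-3)

    def test_limits_scale_sensibly_with_alpha(self):
        rng = np.random.default_rng(11)
        X, strict = _random_model(rng, alpha=0.001)
        cfg = QCConfig()
        loose = fit_block_model(X, [f"f{i}" for i in range(X.shape[1])], cfg,
                                alpha_corrected=0.05)
        assert strict.t2_limit > loose.t2_limit
        assert strict.spe_limit > loose.spe_limit


class TestBuildNocAndEvaluate:
    def _history(self, n_pass, n_fail=0, n_mspc_flagged=0, n_incomplete=0):
        rng = np.random.default_rng(0)
        h = HistoryStore()
        ids = [f"is{i}" for i in range(8)]
        t = T0 - timedelta(days=30)
        counter = 0
        for group, (qc, mspc, detected_n) in {
            "pass": (True, False, 8), "fail": (False, False, 8),
            "mspc": (True, True, 8), "incomplete": (True, False, 7),
        }.items():
            n = {"pass": n_pass, "fail": n_fail,
                 "mspc": n_mspc_flagged, "incomplete": n_incomplete}[group]
            for _ in range(n):
                counter += 1
                for j, cid in enumerate(ids):
                    if j >= detected_n:
                        continue
                    h.add_record(
                        run_id=f"{group}{counter}", at=t + timedelta(hours=counter),
                        sample_type="sample", compound_id=cid,
                        height=1e5 * rng.lognormal(0, 0.1),
                        apex_rt=300.0 + 30 * j + rng.normal(0, 1),
                        mass_error=rng.normal(0, 0.2),
                        qc_pass=qc, n_detected=detected_n, mspc_flag=mspc,
                    )
        return h, ids

    def test_only_complete_passing_unflagged_runs_enter_noc(self, cfg):
        h, ids = self._history(n_pass=30, n_fail=5, n_mspc_flagged=4, n_incomplete=3)
        noc = build_noc(h, T0, cfg, ids)
        for block in ("height", "retention_time", "mass_error"):
            matrix, names = noc[block]
            assert matrix.shape[0] == 30
        assert noc["height"][0].shape[1] == 28
        assert noc["mass_error"][0].shape[1] == 8

    def test_too_small_noc_returns_none(self, cfg):
        h, ids = self._history(n_pass=10)
        noc = build_noc(h, T0, cfg, ids)
        assert all(v is None for v in noc.values())

    def test_and_rule_requires_both_statistics(self):
        h, ids = self._history(n_pass=40)
        cfg_and = QCConfig()
        noc = build_noc(h, T0, cfg_and, ids)
        models = {
            b: fit_block_model(m, names, cfg_and, block=b)
            for b, (m, names) in ((b, v) for b, v in noc.items() if v)
        }
        # a run with one standard's mass error shifted far: SPE fires, T2 may not
        ms, _ = _measurements([1e5] * 8, errs=[0.0] * 7 + [50.0])
        for m, cid in zip(ms, ids):
            m.compound_id = cid
        res_and = evaluate_mspc(ms, models, cfg_and, ids)
        cfg_or = QCConfig(mspc_rule="or")
        res_or = evaluate_mspc(ms, models, cfg_or, ids)
        blk = res_and.blocks["mass_error"]
        assert blk.spe_reject
        if not blk.t2_reject:
            assert "mass_error" not in res_and.flagged_blocks
        assert "mass_error" in res_or.flagged_blocks

    def test_shifted_mass_bias_flags_mass_error_block_only(self):
        h, ids = self._history(n_pass=60)
        cfg = QCConfig()
        noc = build_noc(h, T0, cfg, ids)
        models = {b: fit_block_model(m, names, cfg, block=b)
                  for b, (m, names) in ((b, v) for b, v in noc.items() if v)}
        rng = np.random.default_rng(3)
        ms, _ = _measurements(
            [1e5 * rng.lognormal(0, 0.1) for _ in range(8)],
            rts=[300.0 + 30 * j + rng.normal(0, 1) for j in range(8)],
            errs=list(rng.normal(1.3, 0.3, 8)),  # +1.3 ppm everywhere, far below 10
        )
        for m, cid in zip(ms, ids):
            m.compound_id = cid
        res = evaluate_mspc(ms, models, cfg, ids)
        blk = res.blocks["mass_error"]
        assert blk.t2_reject and blk.spe_reject
        assert res.flagged_blocks == ["mass_error"]

    def test_missing_block_models_are_skipped(self, cfg):
        ms, ids = _measurements([1e5] * 8)
        res = evaluate_mspc(ms, {}, cfg, ids)
        assert res.blocks == {} and not res.out_of_control
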