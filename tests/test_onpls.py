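import itertools
import logging

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from onplskit import (
    ModelSpec,
    MultiBlockDataset,
    NoVariationError,
    SimSpec,
    extract_consensus_component,
    extract_orthogonal_candidate,
    fit_o2pls,
    fit_onpls,
    genotype_cv,
    project_block,
    simulate_multiomics,
    variance_decomposition,
)
from onplskit.onpls import fit_frames
from conftest import make_block


def _centered(rng, m, n):
    X = rng.normal(size=(m, n))
    return X - X.mean(axis=0)


def _dataset(blocks, design):
    return MultiBlockDataset(design=design, blocks=blocks)


class TestConsensusExtraction:
    def test_two_blocks_match_svd_of_cross_covariance(self):
        rng = np.random.default_rng(42)
        X1, X2 = _centered(rng, 9, 5), _centered(rng, 9, 4)
        comps, traj, converged = extract_consensus_component(
            {"a": X1, "b": X2}, tol=1e-12, max_iter=5000)
        assert converged
        U, _s, Vt = np.linalg.svd(X1.T @ X2)
        for est, ref in ((comps["a"]["w"], U[:, 0]), (comps["b"]["w"], Vt[0])):
            if est @ ref < 0:
                ref = -ref
            assert np.abs(est - ref).max() < 1e-8

    def test_noiseless_rank_one_shared_signal(self):
        rng = np.random.default_rng(0)
        t0 = rng.normal(size=9)
        vs = [rng.normal(size=n) for n in (6, 5, 4)]
        vs = [v / np.linalg.norm(v) for v in vs]
        X = {f"b{i}": np.outer(t0, v) for i, v in enumerate(vs)}
        comps, traj, _ = extract_consensus_component(X, tol=1e-12)
        for i, v in enumerate(vs):
            w = comps[f"b{i}"]["w"]
            if w @ v < 0:
                v = -v
            assert np.abs(w - v).max() < 1e-9
            corr = np.corrcoef(comps[f"b{i}"]["t"], t0)[0, 1]
            assert abs(abs(corr) - 1) < 1e-12

    def test_noise_block_does_not_disturb_shared_pair(self):
        rng = np.random.default_rng(1)
        t0 = rng.normal(size=9)
        t0 -= t0.mean()
        v1, v2 = rng.normal(size=3), rng.normal(size=3)
        v1, v2 = v1 / np.linalg.norm(v1), v2 / np.linalg.norm(v2)
        # block 3: noise orthogonalized against t0 so it shares nothing
        N3 = rng.normal(size=(9, 3)) * 0.1
        N3 -= np.outer(t0, t0 @ N3) / (t0 @ t0)
        X = {"b1": np.outer(t0, v1), "b2": np.outer(t0, v2), "b3": N3}
        comps, traj, _ = extract_consensus_component(X, tol=1e-12)
        for name, v in (("b1", v1), ("b2", v2)):
            w = comps[name]["w"]
            if w @ v < 0:
                v = -v
            assert np.abs(w - v).max() < 1e-6
        # objective dominated by the (b1, b2) pair
        J_12 = comps["b1"]["t"] @ comps["b2"]["t"]
        assert traj[-1] == pytest.approx(J_12, rel=1e-2)

    def test_objective_nondecreasing(self):
        rng = np.random.default_rng(7)
        X = {n: _centered(rng, 9, k) for n, k in (("a", 8), ("b", 6), ("c", 5))}
        _, traj, _ = extract_consensus_component(X)
        assert np.all(np.diff(traj) >= -1e-9 * max(abs(t) for t in traj))

    def test_zero_block_raises(self):
        rng = np.random.default_rng(3)
        X = {"a": np.zeros((9, 4)), "b": _centered(rng, 9, 3)}
        with pytest.raises(NoVariationError):
            extract_consensus_component(X)


class TestOrthogonalCandidate:
    def test_loading_parallel_to_weight_gives_none(self):
        rng = np.random.default_rng(0)
        X = _centered(rng, 9, 5)
        w = np.zeros(5)
        w[0] = 1.0
        assert extract_orthogonal_candidate(X, w, 3.0 * w) is None

    def test_recovers_constructed_orthogonal_direction(self):
        rng = np.random.default_rng(4)
        t0, u = rng.normal(size=9), rng.normal(size=9)
        w = rng.normal(size=6)
        w /= np.linalg.norm(w)
        q = rng.normal(size=6)
        q -= (w @ q) * w
        q /= np.linalg.norm(q)
        X = np.outer(t0, w) + 3.0 * np.outer(u, q)
        p = X.T @ (X @ w) / ((X @ w) @ (X @ w))
        cand = extract_orthogonal_candidate(X, w, p, ortho_var_ratio=0.05)
        assert cand is not None
        wo = cand["w"]
        if wo @ q < 0:
            q = -q
        assert np.abs(wo - q).max() < 1e-8

    def test_below_variance_threshold_gives_none(self):
        rng = np.random.default_rng(5)
        t0, u = rng.normal(size=9), rng.normal(size=9)
        w = np.zeros(4)
        w[0] = 1.0
        q = np.zeros(4)
        q[1] = 1.0
        X = np.outer(t0, w) + 1e-3 * np.outer(u, q)
        p = X.T @ (X @ w) / ((X @ w) @ (X @ w))
        assert extract_orthogonal_candidate(X, w, p, ortho_var_ratio=0.05) is None


class TestFitOnpls:
    def test_noiseless_r2_matches_generator(self, noiseless_sim, default_model_spec):
        raw, _scaled, truth = noiseless_sim
        model = fit_onpls(raw, default_model_spec)
        for name in model.block_names:
            row = model.r2.row(name)
            fr = truth.variance_fractions[name]
            assert row["global"] == pytest.approx(fr["global"], abs=1e-6)
            assert row["unique"] == pytest.approx(fr["unique"], abs=1e-6)
            assert row["residual"] < 1e-8

    def test_additivity_of_variance(self, noisy_sim, default_model_spec):
        raw, scaled, _ = noisy_sim
        model = fit_onpls(scaled, default_model_spec)
        for name in model.block_names:
            sq = model.input_sq_norms[name]
            parts = sum(c.variance for c in model.components[name])
            resid = float(np.sum(model.residuals[name] ** 2))
            assert abs(parts + resid - sq) / sq < 1e-8
            assert model.r2.parts_sum(name) == pytest.approx(1.0, abs=1e-10)

    def test_block_order_symmetry(self, noisy_sim, default_model_spec):
        raw, scaled, _ = noisy_sim
        reference = None
        for perm in (list(scaled.blocks), list(reversed(scaled.blocks))):
            model = fit_onpls(
                MultiBlockDataset(design=scaled.design, blocks=perm),
                default_model_spec)
            r2 = model.r2.as_frame()
            scores = model.consensus_global_scores()
            if reference is None:
                reference = (r2, scores)
            else:
                assert np.abs(r2.to_numpy() - reference[0].to_numpy()).max() < 1e-8
                angles = scipy.linalg.subspace_angles(scores, reference[1])
                assert angles.max() < 1e-8

    def test_rank_bound_validated_before_fit(self, noisy_sim):
        raw, scaled, _ = noisy_sim
        with pytest.raises(ValueError, match="rank bound"):
            fit_onpls(scaled, ModelSpec(n_global=8, n_unique=3))

    def test_missing_values_rejected(self, design9):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(9, 4))
        vals[0, 0] = np.nan
        b1 = make_block(vals, sample_ids=list(design9.sample_ids),
                        name="a", state="centered")
        b2 = make_block(rng.normal(size=(9, 3)),
                        sample_ids=list(design9.sample_ids), name="b",
                        state="centered")
        with pytest.raises(ValueError, match="MISSING"):
            fit_onpls(MultiBlockDataset(design=design9, blocks=[b1, b2]))


class TestO2pls:
    def _two_block_dataset(self, design, rng):
        blocks = [
            make_block(_centered(rng, 9, 6), sample_ids=list(design.sample_ids),
                       name="a", state="centered"),
            make_block(_centered(rng, 9, 5), sample_ids=list(design.sample_ids),
                       name="b", state="centered"),
        ]
        return MultiBlockDataset(design=design, blocks=blocks)

    def test_delegates_to_fit_onpls(self, design9):
        ds = self._two_block_dataset(design9, np.random.default_rng(10))
        spec = ModelSpec(n_global=1, n_unique=1)
        m1 = fit_o2pls(ds, spec)
        m2 = fit_onpls(ds, spec)
        assert m1.r2.as_frame().equals(m2.r2.as_frame())
        assert (m1.consensus_global_scores() == m2.consensus_global_scores()).all()

    def test_requires_exactly_two_blocks(self, noisy_sim):
        _, scaled, _ = noisy_sim
        with pytest.raises(ValueError, match="exactly 2"):
            fit_o2pls(scaled)

    def test_joint_weights_match_svd_with_filtering_off(self, design9):
        rng = np.random.default_rng(11)
        ds = self._two_block_dataset(design9, rng)
        spec = ModelSpec(n_global=1, n_unique=0, filter_orthogonal=False,
                         tol=1e-12, max_iter=5000)
        model = fit_o2pls(ds, spec)
        X1, X2 = ds.blocks[0].values, ds.blocks[1].values
        U, _s, Vt = np.linalg.svd(X1.T @ X2)
        for name, ref in (("a", U[:, 0]), ("b", Vt[0])):
            w = model.block_components(name, "global")[0].w
            if w @ ref < 0:
                ref = -ref
            assert np.abs(w - ref).max() < 1e-8

    def test_zero_cross_covariance_warns(self, design9, caplog):
        rng = np.random.default_rng(12)
        X1 = _centered(rng, 9, 4)
        # make block b's columns orthogonal to block a's column space
        Q, _ = np.linalg.qr(X1)
        X2 = _centered(rng, 9, 3)
        X2 -= Q @ (Q.T @ X2)
        ds = MultiBlockDataset(design=design9, blocks=[
            make_block(X1, sample_ids=list(design9.sample_ids), name="a",
                       state="centered"),
            make_block(X2, sample_ids=list(design9.sample_ids), name="b",
                       state="centered"),
        ])
        with caplog.at_level(logging.WARNING, logger="onplskit"):
            fit_o2pls(ds, ModelSpec(n_global=1, n_unique=0,
                                    filter_orthogonal=False, max_iter=50))
        assert any("joint variation" in r.message or "converge" in r.message
                   for r in caplog.records)


class TestModelSummaries:
    def test_variance_decomposition_matches_direct_norms(self, noisy_sim,
                                                         default_model_spec):
        raw, scaled, _ = noisy_sim
        model = fit_onpls(scaled, default_model_spec)
        r2 = variance_decomposition(model)
        for name in model.block_names:
            sq = model.input_sq_norms[name]
            direct = sum(
                float(c.t @ c.t) * float(c.p @ c.p)
                for c in model.components[name] if c.kind == "global"
            ) / sq
            assert r2.row(name)["global"] == pytest.approx(direct, rel=1e-12)

    def test_rank_one_global_only_r2_is_one(self, design9):
        rng = np.random.default_rng(13)
        t0 = rng.normal(size=9)
        blocks = []
        for i, n in enumerate((5, 4)):
            v = rng.normal(size=n)
            blocks.append(make_block(np.outer(t0, v),
                                     sample_ids=list(design9.sample_ids),
                                     name=f"b{i}", state="centered"))
        ds = MultiBlockDataset(design=design9, blocks=blocks)
        model = fit_onpls(ds, ModelSpec(n_global=1, n_unique=0))
        for name in model.block_names:
            assert model.r2.row(name)["global"] == pytest.approx(1.0, abs=1e-10)

    def test_projection_reproduces_training_scores(self, noisy_sim,
                                                   default_model_spec):
        raw, scaled, _ = noisy_sim
        model = fit_onpls(scaled, default_model_spec)
        for name in model.block_names:
            scores = project_block(model, name, scaled.block(name).data)
            assert np.abs(scores - model.global_scores(name)).max() < 1e-8
        zero = project_block(
            model, "proteins",
            np.zeros((1, len(model.variable_ids["proteins"]))))
        assert np.abs(zero).max() == 0.0

    def test_projection_recovers_held_out_sample(self, default_model_spec):
        raw, _scaled, truth = simulate_multiomics(
            SimSpec(seed=21, noise_sd=0.1))
        model = fit_frames({b.name: b.data for b in raw.blocks},
                           raw.design.sample_ids, default_model_spec)
        # held-out rows built from the true first global loading at known
        # score values, plus fresh noise at the training level
        rng = np.random.default_rng(99)
        t_new = np.linspace(-3, 3, 7)
        p1 = truth.loadings["transcripts"][("global", 0)]
        x_new = np.outer(t_new, p1) + rng.normal(0, 0.1, (7, len(p1)))
        proj = project_block(model, "transcripts", x_new)
        corr = np.corrcoef(proj[:, 0], t_new)[0, 1]
        assert abs(corr) > 0.99

    def test_genotype_cv(self, design9):
        rng = np.random.default_rng(14)
        # genotype-constant score pattern: within-genotype sd is exactly 0
        t0 = np.repeat([0.0, 5.0, 10.0], 3)
        blocks = [
            make_block(np.outer(t0, rng.normal(size=n)),
                       sample_ids=list(design9.sample_ids), name=f"b{i}",
                       state="centered")
            for i, n in enumerate((6, 5))
        ]
        ds = MultiBlockDataset(design=design9, blocks=blocks)
        model = fit_onpls(ds, ModelSpec(n_global=1, n_unique=0))
        cvs = genotype_cv(model, design9)
        assert set(cvs) == {"WT", "AS-SOD9", "AS-SOD24"}
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in cvs.values())

    def test_genotype_cv_formula_on_generator_scores(self, noisy_sim,
                                                     default_model_spec):
        raw, _scaled, _ = noisy_sim
        model = fit_onpls(raw, default_model_spec)
        cvs = genotype_cv(model, raw.design)
        score = model.consensus_global_scores()[:, 0]
        rng_ = score.max() - score.min()
        idx = {s: i for i, s in enumerate(model.sample_ids)}
        for g in raw.design.genotypes:
            vals = np.array([score[idx[s]] for s in raw.design.samples_of(g)])
            assert cvs[g] == pytest.approx(100 * vals.std(ddof=1) / rng_)

    def test_determinism(self, default_model_spec):
        runs = []
        for _ in range(2):
            raw, scaled, _ = simulate_multiomics(SimSpec(seed=5))
            model = fit_onpls(scaled, default_model_spec)
            runs.append((model.r2.as_frame(), model.consensus_global_scores()))
        assert runs[0][0].equals(runs[1][0])
        assert (runs[0][1] == runs[1][1]).all()
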