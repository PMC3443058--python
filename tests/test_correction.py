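"""Mean-centering, ComBat, DWD and XPN correction methods.

ComBat is cross-checked against the reference implementation
(Bioconductor sva::ComBat via Rscript); DWD against a brute-force
direction search on a tiny instance; XPN against its K=1/L=1 closed form.
"""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from crossnorm.correction import combat, dwd_correct, mean_center, xpn
from crossnorm.diffexp import ClassLabels
from crossnorm.evaluation import foldchange_concordance

from conftest import make_matrix


class TestMeanCenter:
    def test_hand_example(self):
        m = make_matrix([[1.0, 3.0, 5.0, 7.0]], samples=["a1", "a2", "b1", "b2"])
        batches = pd.Series(["P1", "P1", "P2", "P2"], index=m.columns)
        out = mean_center(m, batches)
        assert np.allclose(out.to_numpy(), [[-1, 1, -1, 1]])

    def test_batch_means_zero_to_machine_precision(self, rng):
        m = make_matrix(rng.normal(8, 2, (30, 10)))
        batches = pd.Series(["A"] * 4 + ["B"] * 6, index=m.columns)
        out = mean_center(m, batches)
        for b in ("A", "B"):
            cols = batches.index[batches == b]
            assert np.abs(out[cols].mean(axis=1)).max() < 1e-12

    def test_already_centered_unchanged(self):
        m = make_matrix([[-1.0, 1.0, -2.0, 2.0]], samples=list("abcd"))
        batches = pd.Series(["P1", "P1", "P2", "P2"], index=m.columns)
        out = mean_center(m, batches)
        assert np.allclose(out.to_numpy(), m.to_numpy())

    def test_single_batch_centers_row(self, rng):
        m = make_matrix(rng.normal(5, 1, (10, 6)))
        batches = pd.Series(["P1"] * 6, index=m.columns)
        out = mean_center(m, batches)
        assert np.abs(out.mean(axis=1)).max() < 1e-12

    def test_unlabeled_sample_error(self):
        m = make_matrix([[1.0, 2.0]])
        batches = pd.Series(["P1"], index=[m.columns[0]])
        with pytest.raises(ValueError, match="without batch label"):
            mean_center(m, batches)


class TestCombat:
    def simulate(self, rng, G=2000, n1=10, n2=10, shift_mean=2.0, shift_sd=0.1):
        base = rng.normal(8, 2, (G, 1))
        shift = rng.normal(shift_mean, shift_sd, (G, 1))
        b1 = base + rng.normal(0, 0.5, (G, n1))
        b2 = base + shift + rng.normal(0, 0.5, (G, n2))
        m = make_matrix(
            np.hstack([b1, b2]),
            samples=[f"a{j}" for j in range(n1)] + [f"b{j}" for j in range(n2)],
        )
        batches = pd.Series(["P1"] * n1 + ["P2"] * n2, index=m.columns)
        return m, batches, shift.ravel()

    def test_matches_sva_combat(self, rng, tmp_path):
        m, batches, _ = self.simulate(rng, G=150, n1=6, n2=6)
        ours, _ = combat(m, batches)
        m.to_csv(tmp_path / "in.tsv", sep="\t")
        (tmp_path / "batch.txt").write_text("\n".join(batches) + "\n")
        script = textwrap.dedent(f"""
            suppressMessages(library(sva))
            x <- as.matrix(read.delim("{tmp_path}/in.tsv", row.names = 1,
                                      check.names = FALSE))
            batch <- scan("{tmp_path}/batch.txt", what = character(), quiet = TRUE)
            out <- ComBat(dat = x, batch = batch, mod = NULL,
                          par.prior = TRUE, prior.plots = FALSE)
            write.table(out, "{tmp_path}/out.tsv", sep = "\\t", quote = FALSE,
                        col.names = NA)
        """)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t", index_col=0)
        assert np.abs(ours.to_numpy() - ref.to_numpy()).max() < 1e-4

    def test_no_batch_effect_nearly_unchanged(self, rng):
        G = 400
        base = rng.normal(8, 2, (G, 1))
        X = base + rng.normal(0, 0.5, (G, 16))
        m = make_matrix(X)
        batches = pd.Series(["P1"] * 8 + ["P2"] * 8, index=m.columns)
        out, _ = combat(m, batches)
        diff_before = np.abs(
            X[:, :8].mean(axis=1) - X[:, 8:].mean(axis=1)
        ).mean()
        o = out.to_numpy()
        diff_after = np.abs(o[:, :8].mean(axis=1) - o[:, 8:].mean(axis=1)).mean()
        assert diff_after <= diff_before
        assert np.abs(o - X).max() < 1.0  # shrinkage adjustment stays modest

    def test_known_shift_removed(self, rng):
        # batch 2 is an exact copy of batch 1 plus a per-gene N(2, 0.1^2) shift
        G = 2000
        base = np.random.default_rng(rng.integers(2**31)).normal(8, 2, (G, 1))
        noise = rng.normal(0, 0.5, (G, 10))
        shift = rng.normal(2.0, 0.1, (G, 1))
        b1 = base + noise
        b2 = b1 + shift
        m = make_matrix(
            np.hstack([b1, b2]),
            samples=[f"a{j}" for j in range(10)] + [f"b{j}" for j in range(10)],
        )
        batches = pd.Series(["P1"] * 10 + ["P2"] * 10, index=m.columns)
        out, _ = combat(m, batches)
        o = out.to_numpy()
        pooled_diff = np.abs(o[:, :10].mean(axis=1) - o[:, 10:].mean(axis=1)).mean()
        assert pooled_diff < 0.1

    def test_gamma_star_tracks_true_shifts(self, rng):
        m, batches, shift = self.simulate(rng, shift_mean=0.0, shift_sd=1.0)
        _, model = combat(m, batches)
        # gamma* is on the standardized scale; the P2-P1 contrast recovers
        # the per-gene shift direction
        contrast = (
            model.gamma_star["P2"] - model.gamma_star["P1"]
        ).to_numpy() * model.sigma
        r = np.corrcoef(contrast, shift)[0, 1]
        assert r > 0.95

    def test_posterior_scales_positive(self, rng):
        m, batches, _ = self.simulate(rng, G=200, n1=5, n2=5)
        _, model = combat(m, batches)
        assert (model.delta2_star.to_numpy() > 0).all()
        assert all(model.converged.values())

    def test_single_batch_error(self, rng):
        m = make_matrix(rng.normal(0, 1, (30, 4)))
        with pytest.raises(ValueError, match="two batches"):
            combat(m, pd.Series(["P1"] * 4, index=m.columns))

    def test_small_batch_error(self, rng):
        m = make_matrix(rng.normal(0, 1, (30, 4)))
        with pytest.raises(ValueError, match="fewer than 2"):
            combat(m, pd.Series(["P1", "P1", "P1", "P2"], index=m.columns))

    def test_too_few_genes_error(self, rng):
        m = make_matrix(rng.normal(0, 1, (10, 8)))
        batches = pd.Series(["P1"] * 4 + ["P2"] * 4, index=m.columns)
        with pytest.raises(ValueError, match="25 genes"):
            combat(m, batches)


def _dwd_loss(w, beta, X, y, C):
    margins = y * (w @ X + beta)
    thr = 1.0 / np.sqrt(C)
    loss = np.where(margins >= thr, 1.0 / np.maximum(margins, 1e-300),
                    2.0 * np.sqrt(C) - C * margins)
    return loss.sum()


class TestDwd:
    def test_identical_batches_unchanged(self, rng):
        X = rng.normal(8, 1, (20, 6))
        m = make_matrix(np.hstack([X, X]),
                        samples=[f"a{j}" for j in range(6)] + [f"b{j}" for j in range(6)])
        batches = pd.Series(["P1"] * 6 + ["P2"] * 6, index=m.columns)
        out, _ = dwd_correct(m, batches)
        assert np.abs(out.to_numpy() - m.to_numpy()).max() < 1e-8

    def test_direction_recovers_separating_axis(self, rng):
        G, n = 30, 8
        noise = rng.normal(0, 0.01, (G, 2 * n))
        X = noise.copy()
        X[0, :n] += 5.0  # batches differ only along gene 0
        m = make_matrix(X)
        batches = pd.Series(["P1"] * n + ["P2"] * n, index=m.columns)
        _, direction = dwd_correct(m, batches)
        assert abs(direction.w.iloc[0]) > 0.999

    def test_batch_projections_equal_after(self, two_batch_matrix):
        m, batches, _ = two_batch_matrix
        out, direction = dwd_correct(m, batches)
        after = list(direction.batch_proj_after.values())
        assert abs(after[0] - after[1]) < 1e-6
        w = direction.w.to_numpy()
        proj = w @ out.to_numpy()
        p1 = proj[:6].mean()
        p2 = proj[6:].mean()
        assert abs(p1 - p2) < 1e-6

    def test_direction_is_unit_norm(self, two_batch_matrix):
        m, batches, _ = two_batch_matrix
        _, direction = dwd_correct(m, batches)
        assert abs(np.linalg.norm(direction.w.to_numpy()) - 1.0) < 1e-8

    def test_solver_beats_brute_force_grid(self, rng):
        # 3 genes x 6 samples: exhaustive direction search on the sphere
        X = np.array(
            [
                [1.0, 1.5, 0.5, -1.0, -1.2, -0.8],
                [0.2, -0.3, 0.1, 0.4, -0.2, 0.0],
                [0.0, 0.3, -0.2, 0.1, 0.2, -0.4],
            ]
        )
        m = make_matrix(X)
        batches = pd.Series(["P1"] * 3 + ["P2"] * 3, index=m.columns)
        C = 10.0
        _, direction = dwd_correct(m, batches, penalty=C)
        y = np.array([1.0] * 3 + [-1.0] * 3)

        from scipy.optimize import minimize_scalar

        best = np.inf
        for theta in np.linspace(0, np.pi, 60):
            for phi in np.linspace(0, 2 * np.pi, 120, endpoint=False):
                w = np.array(
                    [
                        np.sin(theta) * np.cos(phi),
                        np.sin(theta) * np.sin(phi),
                        np.cos(theta),
                    ]
                )
                res = minimize_scalar(
                    lambda b: _dwd_loss(w, b, X, y, C), bounds=(-10, 10),
                    method="bounded",
                )
                best = min(best, res.fun)
        assert direction.objective <= best + 1e-3

    def test_confounded_classes_lose_separation(self, rng):
        # class fully confounded with batch: the DWD shift removes genuine
        # between-class signal together with the batch bias
        G = 50
        class_effect = rng.normal(0, 1.0, (G, 1))
        b1 = rng.normal(0, 0.3, (G, 8))  # batch 1 = class 1
        b2 = class_effect + rng.normal(0, 0.3, (G, 8))  # batch 2 = class 2
        m = make_matrix(np.hstack([b1, b2]))
        batches = pd.Series(["P1"] * 8 + ["P2"] * 8, index=m.columns)
        out, _ = dwd_correct(m, batches)
        o = out.to_numpy()
        sep_before = np.linalg.norm(
            m.to_numpy()[:, 8:].mean(axis=1) - m.to_numpy()[:, :8].mean(axis=1)
        )
        sep_after = np.linalg.norm(o[:, 8:].mean(axis=1) - o[:, :8].mean(axis=1))
        assert sep_after < 0.5 * sep_before

    def test_three_batches_rejected(self, rng):
        m = make_matrix(rng.normal(0, 1, (10, 6)))
        batches = pd.Series(["A", "A", "B", "B", "C", "C"], index=m.columns)
        with pytest.raises(ValueError, match="exactly 2"):
            dwd_correct(m, batches)

    def test_small_batch_rejected(self, rng):
        m = make_matrix(rng.normal(0, 1, (10, 3)))
        batches = pd.Series(["A", "A", "B"], index=m.columns)
        with pytest.raises(ValueError, match="fewer than 2"):
            dwd_correct(m, batches)


class TestXpn:
    def test_identical_platforms_unchanged(self, rng):
        X = rng.normal(8, 2, (60, 8))
        a = make_matrix(X, samples=[f"a{j}" for j in range(8)])
        b = make_matrix(X, samples=[f"b{j}" for j in range(8)])
        out, _ = xpn(a, b, K=4, L=2, reps=2, seed=0)
        assert np.abs(out[a.columns].to_numpy() - X).max() < 1e-6
        assert np.abs(out[b.columns].to_numpy() - X).max() < 1e-6

    def test_k1_l1_matches_closed_form(self, rng):
        n1, n2 = 8, 6
        A = rng.normal(5, 1, (40, n1))
        B = rng.normal(7, 2, (40, n2))
        a = make_matrix(A, samples=[f"a{j}" for j in range(n1)])
        b = make_matrix(B, samples=[f"b{j}" for j in range(n2)])
        out, _ = xpn(a, b, K=1, L=1, reps=1, seed=0)
        # closed form: pooled weighted mean and pooled (weighted linear
        # average) scale applied to each platform's standardized residual
        m1, m2 = A.mean(1), B.mean(1)
        s1, s2 = A.std(1), B.std(1)
        mw = (n1 * m1 + n2 * m2) / (n1 + n2)
        sw = (n1 * s1 + n2 * s2) / (n1 + n2)
        oa = mw[:, None] + sw[:, None] * (A - m1[:, None]) / s1[:, None]
        ob = mw[:, None] + sw[:, None] * (B - m2[:, None]) / s2[:, None]
        assert np.abs(out[a.columns].to_numpy() - oa).max() < 1e-10
        assert np.abs(out[b.columns].to_numpy() - ob).max() < 1e-10

    def test_per_gene_offset_removed(self, rng):
        G = 120
        base = rng.normal(8, 2, (G, 1))
        X = base + rng.normal(0, 1, (G, 20))
        offset = rng.normal(0, 1.5, (G, 1))
        a = make_matrix(X[:, :10], samples=[f"a{j}" for j in range(10)])
        b = make_matrix(X[:, 10:] + offset, samples=[f"b{j}" for j in range(10)])
        gap_before = np.abs(
            a.to_numpy().mean(1) - b.to_numpy().mean(1)
        ).mean()
        out, _ = xpn(a, b, K=5, L=2, reps=3, seed=0)
        gap_after = np.abs(
            out[a.columns].to_numpy().mean(1) - out[b.columns].to_numpy().mean(1)
        ).mean()
        assert gap_after < 0.1
        assert gap_after < 0.1 * gap_before

    def test_offset_preserves_foldchange_concordance(self, rng):
        # two-class design measured on both platforms; platform 2 adds a
        # per-gene constant offset.  After XPN the class fold changes of
        # the two platforms must agree nearly perfectly.
        G, n = 300, 8
        base = rng.normal(8, 2, (G, 1))
        effect = np.zeros((G, 1))
        effect[: G // 4] = rng.normal(0, 1.5, (G // 4, 1))
        cls = np.array([1] * (n // 2) + [2] * (n // 2))
        signal = base + effect * (cls == 2)
        Xa = signal + rng.normal(0, 0.3, (G, n))
        Xb = signal + rng.normal(0, 0.3, (G, n)) + rng.normal(0, 1.5, (G, 1))
        a = make_matrix(Xa, samples=[f"a{j}" for j in range(n)])
        b = make_matrix(Xb, samples=[f"b{j}" for j in range(n)])
        out, _ = xpn(a, b, K=8, L=2, reps=5, seed=0)
        labels = ClassLabels(
            pd.Series(
                np.concatenate([cls, cls]), index=list(a.columns) + list(b.columns)
            )
        )
        _, r = foldchange_concordance(out[a.columns], out[b.columns], labels)
        assert r >= 0.99

    def test_flat_cluster_profiles_stay_bounded(self, rng):
        # platforms drawn from one distribution: harmonization must not
        # inflate values even when gene clusters carry no block structure
        base = rng.normal(8, 2, (120, 1))
        X = base + rng.normal(0, 1, (120, 20))
        a = make_matrix(X[:, :10], samples=[f"a{j}" for j in range(10)])
        b = make_matrix(X[:, 10:], samples=[f"b{j}" for j in range(10)])
        out, model = xpn(a, b, K=5, L=2, reps=3, seed=0)
        assert np.abs(out.to_numpy() - X).max() < 3.0
        assert np.abs(model.b_consensus).max() < 5.0

    def test_k_exceeding_genes_rejected(self, rng):
        a = make_matrix(rng.normal(0, 1, (10, 6)))
        b = make_matrix(rng.normal(0, 1, (10, 6)), samples=[f"b{j}" for j in range(6)])
        with pytest.raises(ValueError, match="K="):
            xpn(a, b, K=11, L=2)

    def test_l_exceeding_samples_rejected(self, rng):
        a = make_matrix(rng.normal(0, 1, (30, 4)))
        b = make_matrix(rng.normal(0, 1, (30, 4)), samples=[f"b{j}" for j in range(4)])
        with pytest.raises(ValueError, match="L="):
            xpn(a, b, K=2, L=5)

    def test_unaligned_gene_spaces_rejected(self, rng):
        a = make_matrix(rng.normal(0, 1, (10, 4)))
        b = make_matrix(rng.normal(0, 1, (10, 4)),
                        genes=[f"H{i}" for i in range(10)],
                        samples=[f"b{j}" for j in range(4)])
        with pytest.raises(ValueError, match="aligned"):
            xpn(a, b, K=2, L=2)

    def test_zero_variance_gene_warns(self, rng):
        X = rng.normal(8, 1, (40, 12))
        X[0] = 5.0  # constant gene on both platforms
        a = make_matrix(X[:, :6], samples=[f"a{j}" for j in range(6)])
        b = make_matrix(X[:, 6:], samples=[f"b{j}" for j in range(6)])
        with pytest.warns(UserWarning, match="zero-variance"):
            xpn(a, b, K=2, L=2, reps=1, seed=0)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(8, 2, (50, 16))
        a = make_matrix(X[:, :8], samples=[f"a{j}" for j in range(8)])
        b = make_matrix(X[:, 8:], samples=[f"b{j}" for j in range(8)])
        out1, _ = xpn(a, b, K=4, L=2, reps=3, seed=7)
        out2, _ = xpn(a, b, K=4, L=2, reps=3, seed=7)
        pd.testing.assert_frame_equal(out1, out2)
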