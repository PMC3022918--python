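import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asmip.preprocess import log_transform
from asmip.scoring import m_score, median_polish, r_score, tissue_pair_scores
from asmip.synthetic_data import (
    REFERENCE_TISSUE,
    SimConfig,
    render_sequencing,
    simulate_truth,
)

from conftest import make_theta
from oracles import median_polish_oracle


class TestMedianPolish:
    def test_exact_additive_one_sweep(self):
        a = np.array([1.0, 4.0, -2.0])
        b = np.array([0.5, -1.0, 3.0, 2.0])
        fit = median_polish(a[:, None] + b[None, :])
        assert np.allclose(fit.residuals.to_numpy(), 0.0)
        assert fit.n_iterations == 1
        assert fit.converged

    def test_degenerate_1x1(self):
        fit = median_polish(np.array([[7.5]]))
        assert fit.overall == 7.5
        assert fit.residuals.iloc[0, 0] == 0.0

    def test_against_oracle_3x3(self):
        m = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 100.0]]
        fit = median_polish(np.array(m), tol=1e-9, max_iter=500)
        oracle = np.array(median_polish_oracle(m, tol=1e-9, max_iter=500), dtype=float)
        assert np.abs(fit.residuals.to_numpy() - oracle).max() < 1e-9

    def test_reconstruction_invariant(self, rng):
        x = rng.normal(size=(7, 5))
        x[rng.random(size=x.shape) < 0.15] = np.nan
        if np.isnan(x).all(axis=1).any() or np.isnan(x).all(axis=0).any():
            pytest.skip("degenerate draw")
        fit = median_polish(x, tol=1e-9, max_iter=200)
        recon = (
            fit.overall
            + fit.row_effects.to_numpy()[:, None]
            + fit.col_effects.to_numpy()[None, :]
            + fit.residuals.to_numpy()
        )
        obs = np.isfinite(x)
        assert np.abs(recon[obs] - x[obs]).max() < 1e-9
        assert np.isnan(fit.residuals.to_numpy()[~obs]).all()

    def test_residual_medians_near_zero_at_convergence(self, rng):
        x = rng.normal(size=(6, 6))
        fit = median_polish(x, tol=1e-9, max_iter=500)
        z = fit.residuals.to_numpy()
        # columns are swept last, so their medians vanish exactly; rows
        # retain only a small remainder at the SAR fixed point
        assert np.abs(np.nanmedian(z, axis=0)).max() < 1e-12
        assert np.abs(np.nanmedian(z, axis=1)).max() < 0.05 * np.nanstd(z)

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            median_polish(np.empty((0, 0)))

    def test_all_missing_row_raises(self):
        x = np.array([[1.0, 2.0], [np.nan, np.nan]])
        with pytest.raises(ValueError, match="missing"):
            median_polish(x)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_random(self, seed):
        rng = np.random.default_rng(seed)
        nr = int(rng.integers(2, 7))
        nc = int(rng.integers(2, 7))
        x = rng.normal(scale=3.0, size=(nr, nc))
        mask = rng.random(size=x.shape) < 0.2
        # keep every row and column observed
        mask[np.arange(nr), rng.integers(0, nc, nr)] = False
        mask[rng.integers(0, nr, nc), np.arange(nc)] = False
        x[mask] = np.nan
        fit = median_polish(x, tol=1e-9, max_iter=1000)
        oracle = np.array(
            median_polish_oracle(
                [[None if np.isnan(v) else v for v in row] for row in x],
                tol=1e-9,
                max_iter=1000,
            ),
            dtype=float,
        )
        obs = np.isfinite(x)
        assert np.abs(fit.residuals.to_numpy()[obs] - oracle[obs]).max() < 1e-6


def _two_tissue_annot():
    return pd.DataFrame(
        [("G1", "c1", "constitutive"), ("G1", "c2", "constitutive"), ("G1", "a1", "alternative")],
        columns=["gene_id", "junction_id", "status"],
    )


def _fixture_theta():
    """theta_ref = 0 so d equals theta; one tag."""
    d = {
        ("c1", "A"): 0.2, ("c1", "B"): -0.1,
        ("c2", "A"): 0.0, ("c2", "B"): 0.3,
        ("a1", "A"): 2.0, ("a1", "B"): -1.0,
    }
    rows = [("G1", j, 1, t, v) for (j, t), v in d.items()]
    rows += [("G1", j, 1, REFERENCE_TISSUE, 0.0) for j in ("c1", "c2", "a1")]
    return make_theta(rows)


class TestRScore:
    def test_hand_worked_fixture(self):
        # frozen from an independent spreadsheet-style evaluation of the
        # d -> f -> fbar -> R chain (constitutive mean, MAD x 1.4826 scale)
        scores, inter = r_score(_fixture_theta(), _two_tissue_annot())
        assert inter.s_g["G1"] == pytest.approx(0.22239033277584033, abs=1e-12)
        expected = {
            ("c1", "A"): 0.4496598334640544,
            ("c1", "B"): -0.8993196669281088,
            ("c2", "A"): -0.4496598334640544,
            ("c2", "B"): 0.8993196669281088,
            ("a1", "A"): 8.543536835817033,
            ("a1", "B"): -4.946258168104599,
        }
        assert len(scores) == 6
        for (j, t), v in expected.items():
            got = scores[(scores["junction_id"] == j) & (scores["tissue_id"] == t)]["value"].iloc[0]
            assert got == pytest.approx(v, abs=1e-12)

    def test_pure_expression_shift_gives_zero(self):
        # theta_tissue = theta_ref + c for every junction: no splicing signal
        rows = []
        for j, p in (("c1", 1.0), ("c2", 2.0), ("a1", -0.5)):
            rows.append(("G1", j, 1, REFERENCE_TISSUE, p))
            rows.append(("G1", j, 1, "A", p + 0.5))
            rows.append(("G1", j, 1, "B", p + 1.25))
        scores, _ = r_score(make_theta(rows), _two_tissue_annot())
        assert len(scores) == 6
        assert (scores["value"] == 0.0).all()

    def test_normalization_identity(self):
        # a junction whose fbar equals s_g scores exactly 1
        scores, inter = r_score(_fixture_theta(), _two_tissue_annot())
        s = inter.s_g["G1"]
        fbar = inter.fbar.set_index(["junction_id", "tissue_id"])["fbar"]
        for (j, t), f in fbar.items():
            got = scores[(scores["junction_id"] == j) & (scores["tissue_id"] == t)]["value"].iloc[0]
            assert got == pytest.approx(f / s)

    def test_f_equals_d_minus_dbar(self):
        _, inter = r_score(_fixture_theta(), _two_tissue_annot())
        merged = inter.f.merge(
            inter.d, on=["gene_id", "junction_id", "tag", "tissue_id"]
        ).merge(inter.dbar_c, on=["gene_id", "tag", "tissue_id"])
        assert np.allclose(merged["f"], merged["d"] - merged["dbar_c"])

    def test_too_few_constitutive_skipped(self, caplog):
        theta = _fixture_theta()
        annot = _two_tissue_annot()
        annot.loc[annot["junction_id"] == "c2", "status"] = "alternative"
        scores, _ = r_score(theta, annot)
        assert len(scores) == 0

    def test_tag_averaging_uses_available_tags(self):
        rows = [
            ("G1", "c1", 1, "A", 0.4), ("G1", "c1", 1, REFERENCE_TISSUE, 0.0),
            ("G1", "c1", 2, "A", 0.6), ("G1", "c1", 2, REFERENCE_TISSUE, 0.0),
            ("G1", "c2", 1, "A", -0.4), ("G1", "c2", 1, REFERENCE_TISSUE, 0.0),
            # c2 tag 2 missing entirely
            ("G1", "a1", 1, "A", 3.0), ("G1", "a1", 1, REFERENCE_TISSUE, 0.0),
        ]
        scores, _ = r_score(make_theta(rows), _two_tissue_annot())
        n_tags = scores.set_index("junction_id")["n_tags_used"]
        assert n_tags["c1"] == 2
        assert n_tags["c2"] == 1

    def test_huber_scale_option(self):
        scores, _ = r_score(_fixture_theta(), _two_tissue_annot(), scale="huber")
        assert len(scores) == 6
        assert np.isfinite(scores["value"]).all()


class TestMScore:
    def test_degenerate_additive_reported_undefined(self, caplog):
        rows = []
        for j, p in (("1-2", 1.0), ("2-3", -0.5), ("3-4", 2.0)):
            for t, b in (("A", 0.2), ("B", 1.0), ("C", -0.3)):
                rows.append(("G1", j, 1, t, p + b))
        scores, inter = m_score(make_theta(rows))
        assert len(scores) == 0  # zero scale -> undefined, not NaN/inf
        assert inter.sstar_g["G1"] == 0.0

    def test_single_perturbed_cell_residual(self):
        delta = 2.0
        rows = []
        for ji in range(10):
            for t, b in (("A", 0.2), ("B", 1.0), ("C", -0.3), ("D", 0.9), ("E", -1.4)):
                v = float(ji) + b + (delta if (ji == 0 and t == "A") else 0.0)
                rows.append(("G1", f"{ji + 1}-{ji + 2}", 1, t, v))
        _, inter = m_score(make_theta(rows))
        fstar = inter.fstar.set_index(["junction_id", "tissue_id"])["fstar"]
        assert abs(fstar[("1-2", "A")] - delta) < 0.1 * delta
        others = fstar.drop(index=("1-2", "A"))
        assert others.abs().max() < 0.1 * delta

    def test_additive_shift_invariance(self):
        cfg = SimConfig(n_genes=3, seed=23)
        truth = simulate_truth(cfg)
        theta = log_transform(render_sequencing(truth, cfg))
        base, _ = m_score(theta)

        shifted = theta.copy()
        mask = (
            (shifted["gene_id"] == "G001")
            & (shifted["junction_id"] == "1-2")
            & (shifted["tag"] == 1)
        )
        shifted.loc[mask, "theta"] += 4.321
        row_shift, _ = m_score(shifted)
        pd.testing.assert_series_equal(base["value"], row_shift["value"], atol=1e-9, rtol=0)

        shifted = theta.copy()
        mask = (shifted["gene_id"] == "G002") & (shifted["tissue_id"] == "T3")
        shifted.loc[mask, "theta"] += -2.718
        col_shift, _ = m_score(shifted)
        pd.testing.assert_series_equal(base["value"], col_shift["value"], atol=1e-9, rtol=0)

    def test_small_gene_skipped(self):
        rows = [("G1", "1-2", 1, "A", 1.0), ("G1", "1-2", 1, "B", 2.0)]
        scores, _ = m_score(make_theta(rows))
        assert len(scores) == 0


@pytest.fixture(scope="module")
def theta():
    cfg = SimConfig(n_genes=4, seed=29)
    truth = simulate_truth(cfg)
    return log_transform(render_sequencing(truth, cfg)), truth.annotation


class TestProbeEffectInvariance:
    """The assay's central normalization claim, for both scores."""

    def test_r_score_probe_shift(self, theta):
        table, annot = theta
        base, _ = r_score(table, annot)
        shifted = table.copy()
        mask = (
            (shifted["gene_id"] == "G001")
            & (shifted["junction_id"] == "2-3")
            & (shifted["tag"] == 2)
        )
        assert mask.any()
        shifted.loc[mask, "theta"] += 7.7
        out, _ = r_score(shifted, annot)
        pd.testing.assert_series_equal(base["value"], out["value"], atol=1e-9, rtol=0)

    def test_r_score_tissue_shift(self, theta):
        table, annot = theta
        base, _ = r_score(table, annot)
        for tissue in ("T2", REFERENCE_TISSUE):
            shifted = table.copy()
            mask = (shifted["gene_id"] == "G002") & (shifted["tissue_id"] == tissue)
            shifted.loc[mask, "theta"] += 1.618
            out, _ = r_score(shifted, annot)
            pd.testing.assert_series_equal(base["value"], out["value"], atol=1e-9, rtol=0)


class TestTissuePairScores:
    def _scores(self, va, vb):
        return pd.DataFrame(
            {
                "gene_id": ["G1", "G1"],
                "junction_id": ["1-2", "1-2"],
                "tissue_id": ["A", "B"],
                "score_type": ["M", "M"],
                "value": [va, vb],
                "n_tags_used": [2, 2],
                "platform": ["seq", "seq"],
            }
        )

    def test_identity(self):
        out = tissue_pair_scores(self._scores(1.5, 1.5), {"G1": ("A", "B")})
        assert out["value"].iloc[0] == 0.0

    def test_arithmetic(self):
        out = tissue_pair_scores(self._scores(2.0, -1.0), {"G1": ("A", "B")})
        assert out["value"].iloc[0] == 3.0

    def test_missing_tissue_skipped(self):
        out = tissue_pair_scores(self._scores(2.0, -1.0), {"G1": ("A", "C")})
        assert len(out) == 0

    def test_pair_auc_on_simulated_splicing(self):
        # delta = 3 x noise_sd: alternative junctions must outrank
        # constitutive ones in the designated pair
        from asmip.evaluate import choose_tissue_pairs, concordance_auc

        cfg = SimConfig(
            n_genes=12, junctions_per_gene=(8, 12), noise_sd=0.5,
            delta_magnitude=1.5, seed=37,
        )
        truth = simulate_truth(cfg)
        theta = log_transform(render_sequencing(truth, cfg))
        scores, _ = m_score(theta)
        pairs, labels = choose_tissue_pairs(truth)
        pair_scores = tissue_pair_scores(scores, pairs)
        merged = pair_scores.merge(labels, on=["gene_id", "junction_id"])
        auc = concordance_auc(merged["value"], merged["label"])
        assert auc > 0.9
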