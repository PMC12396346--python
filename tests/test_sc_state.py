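import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from gliaquant import sc_state as sc
from gliaquant import synth

from conftest import make_matrix


def matrix_with_detected(detected_counts, n_genes, samples, platforms):
    """One cell per entry of detected_counts, each with that many nonzero genes."""
    nc = len(detected_counts)
    vals = np.zeros((n_genes, nc))
    for j, d in enumerate(detected_counts):
        vals[:d, j] = 1.0
    return make_matrix(vals, samples=samples, platforms=platforms)


class TestFilterCells:
    def test_smartseq2_boundary_inclusive(self):
        m = matrix_with_detected(
            [2500, 2000, 1500], 3000, ["S"] * 3, {"S": "smartseq2"}
        )
        out = sc.filter_cells(m)
        assert list(out.cell_ids) == ["C0", "C1"]

    def test_umi_boundary_inclusive(self):
        m = matrix_with_detected([1000, 999], 1200, ["S"] * 2, {"S": "umi"})
        out = sc.filter_cells(m)
        assert list(out.cell_ids) == ["C0"]

    def test_identity_when_all_pass(self):
        m = matrix_with_detected([1500, 1200], 1600, ["S"] * 2, {"S": "umi"})
        out = sc.filter_cells(m)
        assert out.n_cells == 2
        np.testing.assert_array_equal(out.values, m.values)

    def test_mixed_platforms(self):
        m = matrix_with_detected(
            [1500, 1500], 3000, ["A", "B"], {"A": "smartseq2", "B": "umi"}
        )
        out = sc.filter_cells(m)
        assert list(out.cell_ids) == ["C1"]  # smartseq2 cell fails 2000 cutoff

    def test_all_filtered_error(self):
        m = matrix_with_detected([10, 20], 3000, ["S"] * 2, {"S": "umi"})
        with pytest.raises(ValueError, match="all cells filtered"):
            sc.filter_cells(m)

    def test_lognorm_rejected(self):
        m = matrix_with_detected([1500], 1600, ["S"], {"S": "umi"})
        m.unit = "lognorm"
        with pytest.raises(ValueError, match="pre-log"):
            sc.filter_cells(m)

    def test_retained_counts_match_naive(self, rng):
        vals = (rng.random((3000, 40)) < 0.4) * rng.integers(1, 5, (3000, 40))
        m = make_matrix(vals, samples=["S"] * 40, platforms={"S": "umi"})
        out = sc.filter_cells(m)
        naive = sum((vals[:, j] > 0).sum() >= 1000 for j in range(40))
        assert out.n_cells == naive


class TestFilterGenes:
    def test_forced_ordering(self):
        m = make_matrix([[5.0], [1.0], [3.0]])
        out = sc.filter_genes(m, k=2)
        assert list(out.gene_ids) == ["G0", "G2"]

    def test_k_at_least_n_is_identity(self):
        m = make_matrix([[5.0], [1.0], [3.0]])
        assert sc.filter_genes(m, k=3) is m
        assert sc.filter_genes(m, k=10) is m

    def test_exactly_k_survive(self, rng):
        vals = rng.random((10_000, 5))
        m = make_matrix(vals)
        out = sc.filter_genes(m, k=7000)
        assert out.n_genes == 7000
        # survivors are exactly the naive top-7000 by mean
        means = vals.mean(axis=1)
        thresh = np.sort(means)[::-1][6999]
        assert set(out.gene_ids) == {
            g for g, mu in zip(m.gene_ids, means) if mu >= thresh
        }

    def test_tie_break_lexicographic(self):
        m = make_matrix(
            [[2.0], [2.0], [5.0]], gene_ids=["B_gene", "A_gene", "Z_gene"]
        )
        out = sc.filter_genes(m, k=2)
        assert set(out.gene_ids) == {"Z_gene", "A_gene"}

    def test_k_validation(self):
        m = make_matrix([[1.0]])
        with pytest.raises(ValueError):
            sc.filter_genes(m, k=0)


class TestNormalizeLog:
    def test_cpm_spot_values(self):
        m = make_matrix([[10.0], [0.0]], unit="cpm")
        out = sc.normalize_log(m)
        assert out.values[0, 0] == pytest.approx(1.0)  # log2(2)
        assert out.values[1, 0] == 0.0
        assert out.unit == "lognorm"

    def test_counts_two_gene_cell(self):
        m = make_matrix([[90.0], [10.0]], unit="counts")
        out = sc.normalize_log(m)
        assert out.values[0, 0] == pytest.approx(math.log2(90001), rel=1e-12)
        assert out.values[1, 0] == pytest.approx(math.log2(10001), rel=1e-12)

    def test_monotone_and_zero_maps_to_zero(self, rng):
        v = np.sort(rng.random(50) * 1e5)
        m = make_matrix(v[:, None], unit="tpm")
        out = sc.normalize_log(m).values[:, 0]
        assert out[0] >= 0 and np.all(np.diff(out) >= 0)
        zero = make_matrix(np.vstack([[0.0], [5.0]]), unit="tpm")
        assert sc.normalize_log(zero).values[0, 0] == 0.0

    def test_zero_total_cell_error(self):
        m = make_matrix([[0.0, 1.0], [0.0, 1.0]], unit="counts")
        with pytest.raises(ValueError, match="C0"):
            sc.normalize_log(m)

    def test_lognorm_rejected(self, random_lognorm):
        with pytest.raises(ValueError):
            sc.normalize_log(random_lognorm)


class TestCenterWithinSample:
    def test_single_sample_row(self):
        m = make_matrix([[1.0, 2.0, 3.0]], unit="lognorm")
        out = sc.center_within_sample(m)
        np.testing.assert_allclose(out.values, [[-1.0, 0.0, 1.0]])
        assert out.centered

    def test_samples_centered_independently(self):
        m = make_matrix(
            [[1.0, 3.0, 10.0, 20.0]],
            samples=["A", "A", "B", "B"],
            platforms={"A": "umi", "B": "umi"},
            unit="lognorm",
        )
        out = sc.center_within_sample(m)
        np.testing.assert_allclose(out.values, [[-1.0, 1.0, -5.0, 5.0]])

    def test_random_matrix_means_below_tol(self, random_lognorm):
        out = sc.center_within_sample(random_lognorm)
        for s in out.samples:
            cols = out.sample_of_cell == s
            assert np.abs(out.values[:, cols].mean(axis=1)).max() < 1e-9

    def test_idempotent(self, random_lognorm):
        once = sc.center_within_sample(random_lognorm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            twice = sc.center_within_sample(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_single_cell_sample_warns(self):
        m = make_matrix(
            [[1.0, 2.0]], samples=["A", "B"],
            platforms={"A": "umi", "B": "umi"}, unit="lognorm",
        )
        with pytest.warns(UserWarning, match="single cell"):
            out = sc.center_within_sample(m)
        np.testing.assert_allclose(out.values, [[0.0, 0.0]])


class TestSignatureScore:
    def test_single_gene_no_ctrl_equals_centered_expression(self, random_lognorm):
        score = sc.signature_score(random_lognorm, ["G3"], n_ctrl=0)
        expected = random_lognorm.values[3] - random_lognorm.values[3].mean()
        np.testing.assert_allclose(score.to_numpy(), expected, atol=1e-12)

    def test_all_genes_no_ctrl_equals_mean_centered(self, random_lognorm):
        score = sc.signature_score(
            random_lognorm, list(random_lognorm.gene_ids), n_ctrl=0
        )
        centered = random_lognorm.values - random_lognorm.values.mean(
            axis=1, keepdims=True
        )
        np.testing.assert_allclose(score.to_numpy(), centered.mean(axis=0), atol=1e-12)

    def test_empty_intersection_error(self, random_lognorm):
        with pytest.raises(ValueError, match="NOPE"):
            sc.signature_score(random_lognorm, ["NOPE"])

    def test_controls_shift_score_scale(self, random_lognorm):
        with_ctrl = sc.signature_score(random_lognorm, ["G1", "G2"],
                                       n_bins=5, n_ctrl=5, seed=1)
        assert np.isfinite(with_ctrl.to_numpy()).all()

    def test_seeded_determinism(self, random_lognorm):
        a = sc.signature_score(random_lognorm, ["G1", "G2"], n_bins=5, n_ctrl=5, seed=9)
        b = sc.signature_score(random_lognorm, ["G1", "G2"], n_bins=5, n_ctrl=5, seed=9)
        pd.testing.assert_series_equal(a, b)

    def test_opc_discrimination_auroc(self):
        cfg = synth.ScSimConfig(
            n_cells=300, n_genes=2000, n_samples=3,
            n_signature_genes_per_state=50, state_effect=1.0,
            noise_dispersion=0.1, seed=7,
        )
        m, true_state, sigs = synth.gen_expression(cfg)
        logm = sc.normalize_log(m)
        score = sc.signature_score(logm, sigs["OPC"], seed=0)
        auroc = roc_auc_score(true_state == "OPC", score.to_numpy())
        assert auroc >= 0.9


@pytest.fixture(scope="module")
def sim():
    cfg = synth.ScSimConfig(
        n_cells=150, n_genes=600, n_samples=3,
        n_signature_genes_per_state=30, state_effect=1.0, seed=11,
    )
    m, true_state, sigs = synth.gen_expression(cfg)
    return sc.normalize_log(m), true_state, sigs


class TestStateScores:

    def test_requires_state_keys(self, sim):
        logm, _, sigs = sim
        with pytest.raises(ValueError, match="AC"):
            sc.state_scores(logm, {"OPC": sigs["OPC"], "OC": sigs["OC"]})

    def test_own_state_score_is_max(self, sim):
        logm, true_state, sigs = sim
        table = sc.state_scores(logm, sigs, n_ctrl=50, seed=0)
        for st, col in [("OPC", "opc_score"), ("OC", "oc_score"), ("AC", "ac_score")]:
            means = table.loc[true_state == st,
                              ["opc_score", "oc_score", "ac_score"]].mean()
            assert means.idxmax() == col

    def test_permuting_cells_permutes_scores(self, sim):
        logm, _, sigs = sim
        table = sc.state_scores(logm, sigs, n_ctrl=20, seed=0)
        perm = np.random.default_rng(1).permutation(logm.n_cells)
        table_p = sc.state_scores(logm.subset_cells(perm), sigs, n_ctrl=20, seed=0)
        np.testing.assert_allclose(
            table_p["opc_score"].to_numpy(),
            table["opc_score"].to_numpy()[perm],
            atol=1e-12,
        )

    def test_duplicated_sample_identical_scores(self, random_lognorm):
        m = random_lognorm
        dup = make_matrix(
            np.hstack([m.values, m.values]),
            samples=list(m.sample_of_cell) + [s + "_dup" for s in m.sample_of_cell],
            platforms={**m.platform_of_sample,
                       **{s + "_dup": p for s, p in m.platform_of_sample.items()}},
            unit="lognorm",
            cell_ids=[f"C{j}" for j in range(m.n_cells)]
            + [f"D{j}" for j in range(m.n_cells)],
        )
        sigs = {"OPC": ["G0", "G1"], "OC": ["G2", "G3"], "AC": ["G4", "G5"]}
        table = sc.state_scores(dup, sigs, n_bins=5, n_ctrl=5, seed=3)
        np.testing.assert_allclose(
            table["opc_score"].to_numpy()[: m.n_cells],
            table["opc_score"].to_numpy()[m.n_cells :],
            atol=1e-12,
        )


def brute_force_stemness_lineage(opc, oc, ac):
    """Independent direct transcription of the printed formulas."""
    dominant = max(oc, ac)
    stemness = opc - dominant
    if oc < 0 and ac < 0:
        return stemness, None  # jittered
    lineage = dominant * (-1 if ac > oc else 1)
    return stemness, lineage


class TestStemnessLineage:
    def _table(self, triples):
        return pd.DataFrame(triples, columns=["opc_score", "oc_score", "ac_score"])

    @pytest.mark.parametrize(
        "triple,stem,lin",
        [
            ((2.0, 1.0, 0.5), 1.0, 1.0),
            ((0.5, 1.0, 1.5), -1.0, -1.5),
            ((1.0, 1.0, 1.0), 0.0, 1.0),  # tie -> OC sign (positive)
        ],
    )
    def test_formula_cases(self, triple, stem, lin):
        out = sc.stemness_lineage(self._table([triple]))
        assert out["stemness"].iloc[0] == pytest.approx(stem, abs=1e-12)
        assert out["lineage"].iloc[0] == pytest.approx(lin, abs=1e-12)
        assert not out["jittered"].iloc[0]

    def test_jitter_case(self):
        out = sc.stemness_lineage(self._table([(1.0, -0.2, -0.3)]), jitter_eps=0.05)
        assert out["stemness"].iloc[0] == pytest.approx(1.2, abs=1e-12)
        assert abs(out["lineage"].iloc[0]) <= 0.05
        assert out["jittered"].iloc[0]

    def test_matches_brute_force_on_random_triples(self, rng):
        triples = rng.normal(0, 2, size=(1000, 3))
        out = sc.stemness_lineage(self._table(triples), jitter_eps=0.05, seed=0)
        for i, (opc, oc, ac) in enumerate(triples):
            stem, lin = brute_force_stemness_lineage(opc, oc, ac)
            assert abs(out["stemness"].iloc[i] - stem) <= 1e-12
            if lin is None:
                assert out["jittered"].iloc[i]
                assert abs(out["lineage"].iloc[i]) <= 0.05
            else:
                assert not out["jittered"].iloc[i]
                assert abs(out["lineage"].iloc[i] - lin) <= 1e-12

    @given(
        st.tuples(
            st.floats(-5, 5, allow_nan=False),
            st.floats(-5, 5, allow_nan=False),
            st.floats(-5, 5, allow_nan=False),
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_property_matches_brute_force(self, triple):
        out = sc.stemness_lineage(
            pd.DataFrame([triple], columns=["opc_score", "oc_score", "ac_score"])
        )
        stem, lin = brute_force_stemness_lineage(*triple)
        assert out["stemness"].iloc[0] == pytest.approx(stem, abs=1e-12)
        if lin is not None:
            assert out["lineage"].iloc[0] == pytest.approx(lin, abs=1e-12)

    def test_seeded_jitter_deterministic(self):
        t = self._table([(0.0, -1.0, -1.0)] * 5)
        a = sc.stemness_lineage(t, seed=4)
        b = sc.stemness_lineage(t, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_column_error(self):
        with pytest.raises(ValueError, match="ac_score"):
            sc.stemness_lineage(pd.DataFrame({"opc_score": [1], "oc_score": [1]}))


class TestHighlightCells:
    def test_strict_threshold(self):
        m = make_matrix([[1.2, 1.0, 0.4]], unit="lognorm")
        m = sc.center_within_sample(m)
        m.values[0] = [1.2, 1.0, 0.4]  # force known centered values
        flags = sc.highlight_cells(m, "G0", threshold=1.0)
        assert list(flags) == [True, False, False]

    def test_all_negative_no_flags(self):
        m = make_matrix([[0.5, 0.1, 0.9]], unit="lognorm")
        m = sc.center_within_sample(m)
        m.values[0] = [-0.5, -0.1, -0.9]
        assert not sc.highlight_cells(m, "G0").any()

    def test_threshold_zero_on_symmetric_data(self, rng):
        vals = np.log2(rng.gamma(2, 50, size=(5, 400)) / 10 + 1)
        m = make_matrix(vals, unit="lognorm")
        m = sc.center_within_sample(m)
        frac = sc.highlight_cells(m, "G0", threshold=0.0).mean()
        assert 0.3 < frac < 0.7  # roughly half for a near-symmetric distribution

    def test_requires_centered(self, random_lognorm):
        with pytest.raises(ValueError, match="centered"):
            sc.highlight_cells(random_lognorm, "G0")

    def test_missing_gene(self, random_lognorm):
        m = sc.center_within_sample(random_lognorm)
        with pytest.raises(KeyError):
            sc.highlight_cells(m, "NOPE")


class TestPseudoBulk:
    def test_cpm_toy(self):
        m = make_matrix([[10.0, 30.0]], unit="cpm")
        pb = sc.pseudo_bulk(m)
        assert pb.loc["S0", "G0"] == pytest.approx(math.log2(3.0), rel=1e-12)

    def test_non_malignant_ignored(self):
        m = make_matrix(
            [[10.0, 30.0, 999.0]],
            malignant=np.array([True, True, False]),
            unit="cpm",
        )
        pb = sc.pseudo_bulk(m)
        assert pb.loc["S0", "G0"] == pytest.approx(math.log2(3.0), rel=1e-12)

    def test_matches_groupby_oracle(self, rng):
        vals = rng.random((20, 30)) * 100
        samples = [f"S{j % 3}" for j in range(30)]
        mal = rng.random(30) < 0.7
        m = make_matrix(vals, samples=samples,
                        platforms={f"S{i}": "umi" for i in range(3)},
                        malignant=mal, unit="tpm")
        pb = sc.pseudo_bulk(m)
        for s in pb.index:
            cols = (np.array(samples) == s) & mal
            oracle = np.log2(vals[:, cols].mean(axis=1) / 10 + 1)
            np.testing.assert_allclose(pb.loc[s].to_numpy(), oracle, atol=1e-12)

    def test_sample_without_malignant_dropped(self):
        m = make_matrix(
            [[1.0, 2.0]], samples=["A", "B"],
            platforms={"A": "umi", "B": "umi"},
            malignant=np.array([True, False]), unit="cpm",
        )
        with pytest.warns(UserWarning, match="no malignant"):
            pb = sc.pseudo_bulk(m)
        assert list(pb.index) == ["A"]

    def test_no_malignant_error(self):
        m = make_matrix([[1.0]], malignant=np.array([False]), unit="cpm")
        with pytest.raises(ValueError, match="no malignant"):
            sc.pseudo_bulk(m)


def pearson_oracle(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return float(
        ((x - x.mean()) * (y - y.mean())).sum()
        / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    )


class TestCorrelateWithinSamples:
    def test_gene_identical_to_score(self, random_lognorm):
        m = random_lognorm
        score = pd.Series(m.values[0], index=m.cell_ids)
        rep = sc.correlate_within_samples(m, score, ["G0"])
        assert rep.loc["G0", "mean_r"] == pytest.approx(1.0, abs=1e-12)

    def test_r_within_bounds_and_matches_oracle(self, random_lognorm):
        m = random_lognorm
        rng = np.random.default_rng(5)
        score = pd.Series(rng.normal(size=m.n_cells), index=m.cell_ids)
        rep = sc.correlate_within_samples(m, score, list(m.gene_ids[:5]))
        assert (rep["mean_r"].abs() <= 1).all()
        # oracle: mean of per-sample textbook Pearson
        for g in m.gene_ids[:5]:
            row = m.values[list(m.gene_ids).index(g)]
            rs = []
            for s in pd.unique(m.sample_of_cell):
                colsel = m.sample_of_cell == s
                rs.append(pearson_oracle(row[colsel], score.to_numpy()[colsel]))
            assert rep.loc[g, "mean_r"] == pytest.approx(np.mean(rs), abs=1e-12)

    def test_null_effect_mean_r_near_zero(self):
        cfg = synth.ScSimConfig(
            n_cells=240, n_genes=400, n_samples=4,
            n_signature_genes_per_state=20, state_effect=1.0,
            coupled_gene_state=None, seed=2,
        )
        m, true_state, sigs = synth.gen_expression(cfg)
        logm = sc.normalize_log(m)
        table = sc.state_scores(logm, sigs, n_ctrl=30, seed=0)
        centered = sc.center_within_sample(logm)
        # a filler gene is independent of state
        rep = sc.correlate_within_samples(
            centered, table["opc_score"], ["FILLER00000"]
        )
        rs = []
        for s in pd.unique(m.sample_of_cell):
            colsel = m.sample_of_cell == s
            row = centered.values[centered.gene_index("FILLER00000")]
            rs.append(pearson_oracle(row[colsel],
                                     table["opc_score"].to_numpy()[colsel]))
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(rep.loc["FILLER00000", "mean_r"]) < 3 * max(se, 0.05)

    def test_zero_variance_sample_skipped(self):
        vals = np.array([[1.0, 1.0, 1.0, 1.0, 2.0, 3.0, 1.0, 5.0]])
        m = make_matrix(vals, samples=["A"] * 4 + ["B"] * 4,
                        platforms={"A": "umi", "B": "umi"}, unit="lognorm")
        score = pd.Series(np.arange(8.0), index=m.cell_ids)
        with pytest.warns(UserWarning, match="zero variance"):
            rep = sc.correlate_within_samples(m, score, ["G0"])
        assert rep.loc["G0", "n_units"] == 1

    def test_all_skipped_missing(self):
        m = make_matrix(np.ones((1, 6)), samples=["A"] * 6,
                        platforms={"A": "umi"}, unit="lognorm")
        score = pd.Series(np.arange(6.0), index=m.cell_ids)
        with pytest.warns(UserWarning):
            rep = sc.correlate_within_samples(m, score, ["G0"])
        assert np.isnan(rep.loc["G0", "mean_r"])


class TestCorrelateAcrossSamples:
    def _pb(self, rng, n_samples=8, n_genes=4):
        pb = pd.DataFrame(
            rng.random((n_samples, n_genes)),
            index=[f"S{i}" for i in range(n_samples)],
            columns=[f"G{i}" for i in range(n_genes)],
        )
        scores = pd.Series(rng.normal(size=n_samples), index=pb.index)
        study = pd.Series("st1", index=pb.index)
        return pb, scores, study

    def test_linear_function_gives_r_one(self, rng):
        pb, scores, study = self._pb(rng)
        pb["G0"] = 2.0 * scores + 3.0
        rep = sc.correlate_across_samples(pb, scores, study, genes=["G0"])
        assert rep.loc["G0", "mean_r"] == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip(self, rng):
        pb, scores, study = self._pb(rng)
        rep = sc.correlate_across_samples(pb, scores, study, genes=["G1"])
        pb2 = pb.copy()
        pb2["G1"] = -pb2["G1"]
        rep2 = sc.correlate_across_samples(pb2, scores, study, genes=["G1"])
        assert rep2.loc["G1", "mean_r"] == pytest.approx(-rep.loc["G1", "mean_r"],
                                                         abs=1e-12)

    def test_matches_pearson_oracle(self, rng):
        pb, scores, study = self._pb(rng)
        study.iloc[4:] = "st2"
        rep = sc.correlate_across_samples(pb, scores, study)
        for g in pb.columns:
            rs = [
                pearson_oracle(pb.loc[study == st_, g], scores[study == st_])
                for st_ in ("st1", "st2")
            ]
            assert rep.loc[g, "mean_r"] == pytest.approx(np.mean(rs), abs=1e-12)

    def test_small_study_skipped(self, rng):
        pb, scores, study = self._pb(rng, n_samples=5)
        study.iloc[3:] = "tiny"
        with pytest.warns(UserWarning, match="tiny"):
            rep = sc.correlate_across_samples(pb, scores, study, genes=["G0"])
        assert rep.loc["G0", "n_units"] == 1


def bh_oracle(p):
    """Hand-rolled Benjamini-Hochberg step-up."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestFdrAdjust:
    def test_single_p(self):
        q, flags = sc.fdr_adjust([0.01])
        assert q[0] == pytest.approx(0.01, abs=1e-15)
        assert flags[0]

    def test_hand_bh_example(self):
        q, _ = sc.fdr_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-15)

    def test_all_ones(self):
        q, flags = sc.fdr_adjust([1.0, 1.0, 1.0])
        np.testing.assert_array_equal(q, 1.0)
        assert not flags.any()

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            sc.fdr_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            sc.fdr_adjust([-0.1])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle_and_invariants(self, pvals):
        q, flags = sc.fdr_adjust(pvals)
        np.testing.assert_allclose(q, bh_oracle(pvals), atol=1e-12)
        assert np.all(q >= np.asarray(pvals) - 1e-12)  # q >= p
        # step-up monotonicity: sorted by p, q is non-decreasing
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestPipelineOrderInvariance:
    def test_consistent_relabeling_permutes_outputs(self):
        cfg = synth.ScSimConfig(
            n_cells=90, n_genes=300, n_samples=3,
            n_signature_genes_per_state=20, seed=6,
        )
        m, _, sigs = synth.gen_expression(cfg)
        perm = np.random.default_rng(2).permutation(m.n_cells)
        mp = m.subset_cells(perm)

        t1 = sc.stemness_lineage(
            sc.state_scores(sc.normalize_log(m), sigs, n_ctrl=10, seed=0), seed=0
        )
        t2 = sc.stemness_lineage(
            sc.state_scores(sc.normalize_log(mp), sigs, n_ctrl=10, seed=0), seed=0
        )
        np.testing.assert_allclose(
            t2["stemness"].to_numpy(), t1["stemness"].to_numpy()[perm], atol=1e-12
        )
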