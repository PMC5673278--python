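import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import thymeth as tm
from thymeth.classifier import (
    CascadeConfig,
    _confusion,
    apply_fixed_signature,
    load_reference_panel,
    loocv,
    prognostic_filter,
    score_samples,
    select_candidates,
    stratify,
    train_dlda,
)
from thymeth.datatypes import SignatureModel

from conftest import make_metadata


def _signature(nt_range=(-8.0, -2.0), threshold=0.0):
    return SignatureModel(
        probe_ids=("cg1",),
        weights=np.array([10.0]),
        mean_gp=np.array([0.2]),
        mean_pp=np.array([0.6]),
        pooled_var=np.array([0.04]),
        decision_threshold=threshold,
        nt_score_range=nt_range,
    )


def _group_beta(group_values: dict, n_per_group: int, probe_ids, jitter=0.0, seed=0):
    """Constant-per-group beta values (probes x samples) plus optional noise."""
    rng = np.random.default_rng(seed)
    cols, names, meta = [], [], {}
    histo = {"NT": ("NT", "NA"), "BTL": ("FA", "NA"), "PDTC_ATC": ("ATC", "NA"),
             "GP": ("PTC", "GP"), "PP": ("PTC", "PP")}
    for g, vals in group_values.items():
        for i in range(n_per_group):
            sid = f"{g}_{i}"
            names.append(sid)
            meta[sid] = histo[g]
            cols.append(np.asarray(vals) + rng.normal(0, jitter, len(vals)))
    X = np.clip(np.column_stack(cols), 0, 1)
    return tm.BetaMatrix.from_arrays(X, probe_ids, names), make_metadata(meta)


class TestSelectCandidates:
    def test_region_gate_and_any_promoter_rule(self):
        ann = tm.ProbeAnnotation(
            pd.DataFrame(
                {
                    "chrom": "1",
                    "pos": 1,
                    "genes": [("A",), ("A", "B"), ("A",)],
                    "gene_regions": [("Body",), ("Body", "TSS200"), ("5UTR",)],
                    "island_relation": "island",
                    "cross_reactive": False,
                    "snp_maf_gt_5pct": False,
                    "sex_chromosome": False,
                },
                index=pd.Index(["cgBody", "cgMixed", "cgUTR"], name="IlmnID"),
            )
        )
        diff = pd.DataFrame(
            {"direction": ["hyper", "hypo", "hyper"]},
            index=["cgBody", "cgMixed", "cgUTR"],
        )
        assert select_candidates(diff, ann) == ["cgMixed", "cgUTR"]

    def test_matches_brute_force_on_cohort(self, small_cohort):
        diff = tm.call_differential(
            tm.ContrastSpec("PDTC_ATC", "NT"), small_cohort.beta, small_cohort.metadata
        )
        got = select_candidates(diff, small_cohort.annotation)
        promoter = small_cohort.annotation.is_promoter()
        brute = [
            p
            for p in diff.index
            if diff.loc[p, "direction"] != "none" and promoter.loc[p]
        ]
        assert got == brute


class TestPrognosticFilter:
    PROBES = ["keep", "pan_tumor", "discordant", "weak"]

    def _cohort(self):
        # beta means per probe for [NT, BTL, PDTC_ATC, GP, PP]
        layout = {
            "NT":       [0.30, 0.30, 0.30, 0.30],
            "BTL":      [0.32, 0.31, 0.30, 0.30],
            "PDTC_ATC": [0.60, 0.60, 0.60, 0.60],
            "GP":       [0.31, 0.61, 0.30, 0.30],
            "PP":       [0.43, 0.73, 0.18, 0.35],
        }
        return _group_beta(layout, 4, self.PROBES)

    def test_gates_applied(self):
        beta, meta = self._cohort()
        kept = prognostic_filter(self.PROBES, beta, meta)
        # keep: PP-GP=+0.12 concordant with PDTC shift, GP ~ NT ~ BTL
        # pan_tumor: PP-GP=+0.12 but GP-NT=+0.31 (not PP-exclusive)
        # discordant: PP-GP=-0.12 vs PDTC-NT=+0.30 (sign mismatch)
        # weak: |PP-GP|=0.05 <= 0.1
        assert kept == ["keep"]

    def test_empty_required_group_rejected(self):
        beta, meta = self._cohort()
        no_pp = tm.SampleMetadata(
            meta.table[meta.table["outcome"] != "PP"].copy()
        )
        with pytest.raises(ValueError, match="WDTC_PP"):
            prognostic_filter(self.PROBES, beta, no_pp)


class TestTrainDLDA:
    def test_weight_signs_track_class_mean_difference(self, fitted_results):
        s = fitted_results.signature
        assert (np.sign(s.weights) == np.sign(s.mean_pp - s.mean_gp)).all()

    def test_identical_class_means_flagged_degenerate(self):
        # symmetric values: class means equal on both probes, nonzero variance
        X = np.array([[0.3, 0.5, 0.5, 0.3], [0.2, 0.6, 0.6, 0.2]])
        beta = tm.BetaMatrix.from_arrays(X, ["cg1", "cg2"], ["g1", "g2", "p1", "p2"])
        labels = pd.Series(["GP", "GP", "PP", "PP"], index=["g1", "g2", "p1", "p2"])
        model = train_dlda(beta, labels)
        assert model.degenerate
        np.testing.assert_allclose(model.weights, 0.0)
        assert (score_samples(model, beta)["score"] == 0).all()

    def test_all_zero_variance_rejected(self):
        X = np.full((2, 4), 0.5)
        beta = tm.BetaMatrix.from_arrays(X, ["cg1", "cg2"], ["g1", "g2", "p1", "p2"])
        labels = pd.Series(["GP", "GP", "PP", "PP"], index=["g1", "g2", "p1", "p2"])
        with pytest.raises(ValueError, match="zero within-class variance"):
            train_dlda(beta, labels)

    def test_matches_diagonal_gaussian_likelihood_oracle(self):
        """DLDA class calls equal the brute-force two-class diagonal-Gaussian
        likelihood classifier (equal priors) on well-separated data."""
        rng = np.random.default_rng(17)
        p, n = 5, 200
        mu_g, mu_p = rng.uniform(0.2, 0.4, p), rng.uniform(0.5, 0.8, p)
        sd = rng.uniform(0.03, 0.1, p)
        train_g = np.clip(mu_g[:, None] + rng.normal(0, sd[:, None], (p, 30)), 0, 1)
        train_p = np.clip(mu_p[:, None] + rng.normal(0, sd[:, None], (p, 30)), 0, 1)
        probes = [f"cg{i}" for i in range(p)]
        ids = [f"g{i}" for i in range(30)] + [f"p{i}" for i in range(30)]
        beta = tm.BetaMatrix.from_arrays(np.hstack([train_g, train_p]), probes, ids)
        labels = pd.Series(["GP"] * 30 + ["PP"] * 30, index=ids)
        model = train_dlda(beta, labels)

        Xe = np.clip(
            np.where(rng.random(n) < 0.5, 0, 1)[None, :] * (mu_p - mu_g)[:, None]
            + mu_g[:, None]
            + rng.normal(0, sd[:, None] * 2, (p, n)),
            0, 1,
        )
        eval_beta = tm.BetaMatrix.from_arrays(Xe, probes, [f"e{i}" for i in range(n)])
        dlda_call = score_samples(model, eval_beta)["score"] > 0
        # oracle: evaluate both diagonal-Gaussian log-likelihoods explicitly
        ll_g = -0.5 * np.sum((Xe - model.mean_gp[:, None]) ** 2 / model.pooled_var[:, None], axis=0)
        ll_p = -0.5 * np.sum((Xe - model.mean_pp[:, None]) ** 2 / model.pooled_var[:, None], axis=0)
        assert (dlda_call.to_numpy() == (ll_p > ll_g)).all()


class TestScoreAndStratify:
    def test_gp_mean_scores_negative_midpoint_zero(self, fitted_results):
        s = fitted_results.signature
        X = np.column_stack([s.mean_gp, s.midpoints])
        beta = tm.BetaMatrix.from_arrays(X, list(s.probe_ids), ["gp_mean", "mid"])
        scores = score_samples(s, beta)["score"]
        expected_gp = -0.5 * np.sum(s.weights * (s.mean_pp - s.mean_gp))
        np.testing.assert_allclose(scores["gp_mean"], expected_gp)
        assert scores["gp_mean"] < 0
        np.testing.assert_allclose(scores["mid"], 0.0, atol=1e-12)

    def test_linearity_against_finite_differences(self, fitted_results):
        s = fitted_results.signature
        rng = np.random.default_rng(2)
        x = np.clip(s.midpoints + rng.normal(0, 0.05, len(s.probe_ids)), 0, 1)
        base = score_samples(
            s, tm.BetaMatrix.from_arrays(x[:, None], list(s.probe_ids), ["a"])
        )["score"]["a"]
        j, eps = 3, 1e-4
        x2 = x.copy()
        x2[j] += eps
        bumped = score_samples(
            s, tm.BetaMatrix.from_arrays(x2[:, None], list(s.probe_ids), ["a"])
        )["score"]["a"]
        np.testing.assert_allclose(bumped - base, s.weights[j] * eps, rtol=1e-6)

    def test_missing_probe_named_in_error(self, fitted_results):
        s = fitted_results.signature
        beta = tm.BetaMatrix.from_arrays(
            np.full((1, 1), 0.5), [s.probe_ids[0]], ["a"]
        )
        with pytest.raises(KeyError, match=s.probe_ids[1]):
            score_samples(s, beta)

    def test_tier_rule_table_and_tie_break(self):
        model = _signature(nt_range=(-8.0, -2.0), threshold=0.0)
        calls = pd.DataFrame({"score": [-5.0, -1.0, 3.0, 0.0, -2.0]},
                             index=list("abcde"))
        tiers = stratify(model, calls)["tier"].tolist()
        # score at the threshold (0.0) and at the NT maximum (-2.0) go down
        assert tiers == ["low", "intermediate", "high", "intermediate", "low"]

    def test_missing_nt_range_rejected(self):
        model = _signature(nt_range=None)
        with pytest.raises(ValueError, match="NT score range"):
            stratify(model, pd.DataFrame({"score": [0.0]}))

    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_tiers_partition_any_score_vector(self, scores):
        model = _signature()
        calls = pd.DataFrame({"score": scores})
        tiers = stratify(model, calls)["tier"]
        assert tiers.isin(["low", "intermediate", "high"]).all()
        assert len(tiers) == len(scores)

    def test_scale_coherence_of_stratification(self):
        model = _signature()
        c = 7.3
        scaled = SignatureModel(
            probe_ids=model.probe_ids,
            weights=model.weights * c,
            mean_gp=model.mean_gp,
            mean_pp=model.mean_pp,
            pooled_var=model.pooled_var,
            decision_threshold=model.decision_threshold * c,
            nt_score_range=(model.nt_score_range[0] * c, model.nt_score_range[1] * c),
        )
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, (1, 30))
        beta = tm.BetaMatrix.from_arrays(X, ["cg1"], [f"s{i}" for i in range(30)])
        t1 = stratify(model, score_samples(model, beta))["tier"]
        t2 = stratify(scaled, score_samples(scaled, beta))["tier"]
        assert (t1 == t2).all()


class TestLOOCV:
    def test_perfectly_separated_classes(self):
        layout = {"GP": [0.2, 0.8], "PP": [0.8, 0.2], "NT": [0.2, 0.8]}
        beta, meta = _group_beta(layout, 10, ["cgA", "cgB"], jitter=0.02, seed=5)
        res = loocv(beta, meta, mode="fixed_probes", probes=["cgA", "cgB"])
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert not res.flagged

    def test_deterministic(self, small_cohort, fitted_results):
        a = fitted_results.loocv("fixed_probes")
        b = fitted_results.loocv("fixed_probes")
        pd.testing.assert_frame_equal(a.calls, b.calls)

    def test_permuted_labels_give_chance_performance(self):
        """With outcome labels shuffled, held-out sensitivity + specificity
        averages to ~1.0 (chance level) over 100 seeded permutations."""
        rng = np.random.default_rng(31)
        n_gp, n_pp, p = 20, 8, 8
        probes = [f"cg{i}" for i in range(p)]
        totals = []
        for _ in range(100):
            X = np.clip(rng.normal(0.5, 0.1, (p, n_gp + n_pp)), 0, 1)
            outcomes = rng.permutation(["GP"] * n_gp + ["PP"] * n_pp)
            meta = make_metadata(
                {f"s{i}": ("PTC", o) for i, o in enumerate(outcomes)}
            )
            beta = tm.BetaMatrix.from_arrays(X, probes, [f"s{i}" for i in range(n_gp + n_pp)])
            res = loocv(beta, meta, mode="fixed_probes", probes=probes)
            totals.append(res.sensitivity + res.specificity)
        assert abs(np.mean(totals) - 1.0) < 0.15

    def test_confusion_arithmetic(self):
        true_pp = np.array([True] * 8 + [False] * 48)
        pred_pp = np.array([True] * 5 + [False] * 3 + [True] * 4 + [False] * 44)
        sens, spec = _confusion(true_pp, pred_pp)
        assert sens == pytest.approx(5 / 8)          # 0.625
        assert spec == pytest.approx(44 / 48)        # 0.9167

    def test_untrainable_fold_flagged_not_fatal(self):
        rng = np.random.default_rng(6)
        ids = [f"g{i}" for i in range(6)] + ["pp0", "pp1"]
        vals = np.clip(
            np.array([[0.2] * 6 + [0.8] * 2]) + rng.normal(0, 0.02, (1, 8)), 0, 1
        )
        beta = tm.BetaMatrix.from_arrays(vals, ["cgA"], ids)
        meta = make_metadata({s: ("PTC", "PP" if s.startswith("pp") else "GP") for s in ids})
        res = loocv(beta, meta, mode="fixed_probes", probes=["cgA"])
        # holding out either of the 2 PP samples leaves a 1-sample class
        assert set(res.flagged) == {"pp0", "pp1"}
        assert (res.calls["true"] == "GP").all()

    def test_fixed_probes_not_more_pessimistic_than_full_cascade(self):
        """Selection inside the loop can only hurt (or match) held-out
        performance on average, never help it."""
        fixed_tot, full_tot = [], []
        for seed in range(120, 140):
            c = tm.simulate_cohort(tm.SimulationConfig(n_probes=4000, seed=seed))
            beta, _ = tm.filter_probes(c.beta, c.annotation, c.qc)
            ann = c.annotation.subset(beta.probe_ids)
            model = tm.PrognosticDLDA.from_cohort(beta, ann, c.metadata)
            res = model.fit()
            full = res.loocv("full_cascade")
            fixed = res.loocv("fixed_probes")
            full_tot.append(full.sensitivity + full.specificity)
            fixed_tot.append(fixed.sensitivity + fixed.specificity)
        assert np.mean(fixed_tot) >= np.mean(full_tot) - 1e-9


class TestApplyFixedSignature:
    def test_training_data_reproduces_resubstitution(self, small_cohort, fitted_results):
        sens_r, spec_r = fitted_results.resubstitution()
        labels = fitted_results.labels
        meta = tm.SampleMetadata(small_cohort.metadata.table.loc[labels.index].copy())
        _, sens, spec = apply_fixed_signature(
            fitted_results.signature, small_cohort.beta, meta
        )
        assert sens == sens_r and spec == spec_r

    def test_matched_external_cohort_generalizes(self, fitted_results):
        """A fresh cohort from the training distribution scores within 0.1
        of the training sensitivity/specificity."""
        s = fitted_results.signature
        rng = np.random.default_rng(23)
        n_gp, n_pp = 150, 50
        sd = np.sqrt(s.pooled_var)
        Xg = np.clip(s.mean_gp[:, None] + rng.normal(0, sd[:, None], (len(sd), n_gp)), 0, 1)
        Xp = np.clip(s.mean_pp[:, None] + rng.normal(0, sd[:, None], (len(sd), n_pp)), 0, 1)
        ids = [f"g{i}" for i in range(n_gp)] + [f"p{i}" for i in range(n_pp)]
        beta = tm.BetaMatrix.from_arrays(np.hstack([Xg, Xp]), list(s.probe_ids), ids)
        meta = make_metadata(
            {sid: ("PTC", "GP" if sid.startswith("g") else "PP") for sid in ids}
        )
        _, sens, spec = apply_fixed_signature(s, beta, meta)
        sens_r, spec_r = fitted_results.resubstitution()
        assert abs(sens - sens_r) <= 0.1 and abs(spec - spec_r) <= 0.1

    def test_inverted_external_cohort_not_reoriented(self, fitted_results):
        s = fitted_results.signature
        rng = np.random.default_rng(9)
        n = 40
        sd = np.sqrt(s.pooled_var)
        # swap the class means: PP samples drawn around the GP profile
        Xp = np.clip(s.mean_gp[:, None] + rng.normal(0, sd[:, None], (len(sd), n)), 0, 1)
        Xg = np.clip(s.mean_pp[:, None] + rng.normal(0, sd[:, None], (len(sd), n)), 0, 1)
        ids = [f"p{i}" for i in range(n)] + [f"g{i}" for i in range(n)]
        beta = tm.BetaMatrix.from_arrays(np.hstack([Xp, Xg]), list(s.probe_ids), ids)
        meta = make_metadata(
            {sid: ("PTC", "PP" if sid.startswith("p") else "GP") for sid in ids}
        )
        _, sens, _ = apply_fixed_signature(s, beta, meta)
        assert sens < 0.5


class TestReferencePanel:
    def test_panel_loads_with_expected_structure(self):
        panel = load_reference_panel()
        assert len(panel) == 21
        assert {"probe_id", "delta_pdtc_atc_vs_nt", "delta_pp_vs_gp", "dlda_score"} <= set(
            panel.columns
        )
        assert panel["probe_id"].is_unique
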