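"""Stratified folds, per-probe cross-validation, voting ensembles."""

import numpy as np
import pandas as pd
import pytest

import mesomark as mm
from mesomark import classify as clf
from mesomark.containers import NormalizedMatrix, ValidationError
from mesomark.lda import fit_lda
from test_lda import auc_pair_oracle


def sheet_of(strata):
    ids = [f"s{i}" for i in range(len(strata))]
    return pd.DataFrame(
        {"group": strata, "tissue_type": strata},
        index=pd.Index(ids, name="sample_id"),
    )


class TestStratifiedFolds:
    def test_even_split_of_single_stratum(self):
        folds = clf.stratified_folds(sheet_of(["a"] * 10), k=5, seed=0)
        assert folds.folds.value_counts().tolist() == [2] * 5

    def test_per_stratum_counts_differ_at_most_one(self):
        strata = ["w"] * 27 + ["x"] * 10 + ["y"] * 23 + ["z"] * 8
        folds = clf.stratified_folds(sheet_of(strata), k=5, seed=1)
        sheet = sheet_of(strata)
        for s in "wxyz":
            per_fold = folds.folds[sheet["tissue_type"] == s].value_counts()
            counts = [int(per_fold.get(f, 0)) for f in range(5)]
            assert max(counts) - min(counts) <= 1

    def test_deterministic_under_seed(self):
        sheet = sheet_of(["a"] * 7 + ["b"] * 9)
        f1 = clf.stratified_folds(sheet, k=5, seed=3)
        f2 = clf.stratified_folds(sheet, k=5, seed=3)
        pd.testing.assert_series_equal(f1.folds, f2.folds)
        f3 = clf.stratified_folds(sheet, k=5, seed=4)
        assert not f1.folds.equals(f3.folds)


def norm_matrix(values: pd.DataFrame, strata=None) -> NormalizedMatrix:
    sheet = sheet_of(strata or ["a"] * len(values))
    sheet.index = values.index
    annot = pd.DataFrame(
        {"role": "target", "cpg_id": list(values.columns), "tile_index": 0},
        index=pd.Index(values.columns, name="probe_id"),
    )
    return NormalizedMatrix(
        values=values, reference_totals=pd.Series(1.0, index=values.index),
        sample_sheet=sheet, probe_annotation=annot,
    )


class TestCvAUC:
    def test_perfect_separation_every_fold(self):
        idx = pd.Index([f"s{i}" for i in range(20)], name="sample_id")
        x = pd.Series(np.r_[np.linspace(0, 0.1, 10), np.linspace(0.9, 1.0, 10)], index=idx)
        y = pd.Series([0] * 10 + [1] * 10, index=idx)
        folds = clf.stratified_folds(sheet_of(["a"] * 20), k=5, seed=0)
        folds.folds.index = idx
        per_fold, cv, oof = clf.cv_auc(x, y, folds)
        assert per_fold == [1.0] * 5 and cv == 1.0

    def test_uninformative_probe_near_half(self):
        rng = np.random.default_rng(0)
        idx = pd.Index([f"s{i}" for i in range(200)], name="sample_id")
        x = pd.Series(rng.uniform(0, 1, 200), index=idx)
        y = pd.Series(rng.integers(0, 2, 200), index=idx)
        folds = clf.stratified_folds(sheet_of(["a"] * 200), k=5, seed=0)
        folds.folds.index = idx
        _, cv, _ = clf.cv_auc(x, y, folds)
        assert abs(cv - 0.5) < 0.15

    def test_toy_two_fold_matches_hand_oracle(self):
        """8 points, fixed 2 folds: fold AUCs equal pair-counting by hand."""
        idx = pd.Index([f"s{i}" for i in range(8)], name="sample_id")
        x = pd.Series([0.1, 0.9, 0.4, 0.55, 0.3, 0.8, 0.6, 0.2], index=idx)
        y = pd.Series([0, 1, 0, 1, 0, 1, 1, 0], index=idx)
        folds = clf.FoldAssignment(
            folds=pd.Series([0, 0, 0, 0, 1, 1, 1, 1], index=idx), k=2, seed=0
        )
        per_fold, cv, oof = clf.cv_auc(x, y, folds)
        expected = []
        for f in (0, 1):
            tr, te = folds.folds != f, folds.folds == f
            model = fit_lda(x[tr].to_numpy(), y[tr].to_numpy())
            scores = model.posterior(x[te].to_numpy())
            expected.append(auc_pair_oracle(y[te].to_numpy(), scores))
        assert per_fold == pytest.approx(expected)
        assert cv == pytest.approx(np.mean(expected))


class TestSelectSmMIPs:
    def _reports(self, cvaucs):
        return [
            clf.SmMIPModelReport(p, [cv], cv, 0.5) for p, cv in cvaucs.items()
        ]

    def test_best_tile_kept(self):
        reports = self._reports({"cg0_t0": 0.85, "cg0_t1": 0.92})
        cpgs = pd.Series({"cg0_t0": "cg0", "cg0_t1": "cg0"})
        assert clf.select_smmips(reports, cpgs) == ["cg0_t1"]

    def test_low_cvauc_dropped_before_tiling(self):
        reports = self._reports({"cg0_t0": 0.79, "cg0_t1": 0.81})
        cpgs = pd.Series({"cg0_t0": "cg0", "cg0_t1": "cg0"})
        assert clf.select_smmips(reports, cpgs) == ["cg0_t1"]
        dropped = next(r for r in reports if r.probe_id == "cg0_t0")
        assert dropped.drop_reason == "cv_auc"

    def test_tile_ties_broken_by_undigested_totals_then_id(self):
        reports = self._reports({"cg0_t0": 0.9, "cg0_t1": 0.9})
        cpgs = pd.Series({"cg0_t0": "cg0", "cg0_t1": "cg0"})
        totals = pd.Series({"cg0_t0": 100, "cg0_t1": 900})
        assert clf.select_smmips(reports, cpgs, undigested_totals=totals) == ["cg0_t1"]
        assert clf.select_smmips(self._reports({"cg0_t0": 0.9, "cg0_t1": 0.9}), cpgs) == [
            "cg0_t0"
        ]


def exhaustive_cutoff_oracle(votes, y, n_models):
    """Independent scan over C: recompute accuracy/balanced accuracy per C
    from raw predictions and apply the documented tie rules."""
    rows = []
    for c in range(1, n_models + 1):
        pred = (votes >= c).astype(int)
        acc = (pred == y).mean()
        sens = ((pred == 1) & (y == 1)).sum() / max((y == 1).sum(), 1)
        spec = ((pred == 0) & (y == 0)).sum() / max((y == 0).sum(), 1)
        rows.append((acc, (sens + spec) / 2, -c, c))
    return max(rows)[3]


class TestEnsemble:
    def _fit(self, n=40, informative=3, noise=2, seed=0, k=5):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
        y = pd.Series([0] * (n // 2) + [1] * (n // 2), index=idx)
        cols = {}
        for j in range(informative):
            cols[f"p{j}"] = np.where(y, rng.normal(0.7, 0.08, n), rng.normal(0.2, 0.08, n))
        for j in range(noise):
            cols[f"q{j}"] = rng.uniform(0, 1, n)
        X = pd.DataFrame(cols, index=idx).clip(0, 1)
        matrix = norm_matrix(X)
        folds = clf.stratified_folds(matrix.sample_sheet, k=k, seed=seed)
        model = clf.build_ensemble(matrix, y, folds, list(X.columns), "pos", "neg")
        return model, X, y

    def test_perfect_models_tie_break_to_smallest_cutoff(self):
        idx = pd.Index([f"s{i}" for i in range(12)], name="sample_id")
        y = pd.Series([0] * 6 + [1] * 6, index=idx)
        X = pd.DataFrame(
            {f"p{j}": np.r_[np.linspace(0.0, 0.1, 6), np.linspace(0.9, 1.0, 6)] for j in range(3)},
            index=idx,
        )
        matrix = norm_matrix(X)
        folds = clf.stratified_folds(matrix.sample_sheet, k=3, seed=0)
        model = clf.build_ensemble(matrix, y, folds, ["p0", "p1", "p2"], "pos")
        # all C in 1..3 give accuracy 1 and tie on balanced accuracy
        assert model.cutoff == 1 and model.oof_cutoff == 1
        assert model.cv_auc == 1.0

    def test_cutoff_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(30):
            M, n = 5, 8
            votes = rng.integers(0, M + 1, n)
            y = rng.integers(0, 2, n)
            got = clf._choose_agreement_cutoff(votes, y, M)
            assert got == exhaustive_cutoff_oracle(votes, y, M)

    def test_accuracy_at_chosen_cutoff_is_maximal(self):
        model, X, y = self._fit(seed=3)
        votes = model.votes(X).to_numpy()
        acc_at = lambda c: ((votes >= c).astype(int) == y.to_numpy()).mean()
        best = max(acc_at(c) for c in range(1, model.n_models + 1))
        assert acc_at(model.cutoff) == pytest.approx(best)

    def test_votes_monotone_in_values_for_hypermethylated_design(self):
        model, X, y = self._fit(seed=4)
        keep = [p for p in model.probe_ids if model.models[p].mu1 > model.models[p].mu0]
        base = model.votes(X)
        bumped = X.copy()
        bumped[keep] = np.clip(bumped[keep] + 0.05, 0, 1)
        shifted = clf.EnsembleModel(
            probe_ids=keep, models={p: model.models[p] for p in keep},
            cutoff=1, positive_class="pos", negative_class="neg",
        )
        assert (shifted.votes(bumped) >= shifted.votes(X)).all()

    def test_fold_roc_auc_equals_rank_oracle_on_votes(self):
        model, X, y = self._fit(seed=5)
        oof = model.oof_votes
        folds = clf.stratified_folds(sheet_of(["a"] * len(X)), k=5, seed=5)
        folds.folds.index = X.index
        aucs = []
        for f in range(5):
            te = folds.held_out(f)
            if y[te].nunique() < 2:
                continue
            aucs.append(auc_pair_oracle(y[te].to_numpy(), oof[te].to_numpy()))
        assert model.cv_auc == pytest.approx(np.mean(aucs))

    def test_mean_roc_reaches_corner_when_perfect(self):
        idx = pd.Index([f"s{i}" for i in range(20)], name="sample_id")
        y = pd.Series([0] * 10 + [1] * 10, index=idx)
        X = pd.DataFrame(
            {"p0": np.r_[np.linspace(0, 0.05, 10), np.linspace(0.95, 1, 10)]}, index=idx
        )
        matrix = norm_matrix(X)
        folds = clf.stratified_folds(matrix.sample_sheet, k=5, seed=0)
        model = clf.build_ensemble(matrix, y, folds, ["p0"], "pos")
        rocs, mean_roc, cv = clf.ensemble_roc(model)
        assert cv == 1.0
        at_zero = mean_roc.loc[mean_roc["fpr"] == 0.0, "tpr"]
        assert (at_zero == 1.0).any()

    def test_constant_votes_give_diagonal_roc(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        votes = np.full(6, 2)
        roc = clf._roc_points(votes, y, 3)
        assert np.allclose(roc["tpr"], roc["fpr"])
        assert auc_pair_oracle(y, votes) == 0.5

    def test_empty_retention_rejected(self):
        model, X, y = self._fit(seed=6)
        matrix = norm_matrix(X)
        folds = clf.stratified_folds(matrix.sample_sheet, k=5, seed=6)
        with pytest.raises(ValidationError):
            clf.build_ensemble(matrix, y, folds, [], "pos")


class TestTwoStep:
    def _models(self):
        idx = pd.Index([f"s{i}" for i in range(12)], name="sample_id")
        y = pd.Series([0] * 6 + [1] * 6, index=idx)
        spread = np.tile(np.linspace(-0.02, 0.02, 6), 2)
        X = pd.DataFrame(
            {"pA": y * 0.8 + 0.1 + spread, "pB": y * 0.8 + 0.1 + spread},
            index=idx, dtype=float,
        )
        matrix = norm_matrix(X)
        folds = clf.stratified_folds(matrix.sample_sheet, k=3, seed=0)
        a = clf.build_ensemble(matrix, y, folds, ["pA"], "tumoral")
        b = clf.build_ensemble(matrix, y, folds, ["pB"], "mesothelioma")
        return a, b

    def test_short_circuit_below_model_a(self):
        a, b = self._models()
        values = pd.DataFrame({"pA": [0.1], "pB": [np.nan]},
                              index=pd.Index(["x"], name="sample_id"))
        # Model B would fail on NaN-only probes, but is never consulted
        labels = mm.two_step_classify(values, a, b)
        assert labels["x"] == clf.NONTUMORAL

    def test_positive_cascade(self):
        a, b = self._models()
        values = pd.DataFrame({"pA": [0.9, 0.9], "pB": [0.9, 0.1]},
                              index=pd.Index(["pm", "met"], name="sample_id"))
        labels = mm.two_step_classify(values, a, b)
        assert labels["pm"] == clf.MESOTHELIOMA
        assert labels["met"] == clf.METASTASIS

    def test_missing_probe_errors(self):
        a, b = self._models()
        values = pd.DataFrame({"pB": [0.9]}, index=pd.Index(["x"], name="sample_id"))
        with pytest.raises(ValidationError, match="pA"):
            mm.two_step_classify(values, a, b)

    def test_end_to_end_synthetic_cohort(self, processed):
        normalized, _, _, _ = processed
        sheet = normalized.sample_sheet
        cfg = mm.PipelineConfig(seed=5)

        def train(pos, neg):
            keep = sheet["group"].isin(pos + neg)
            y = sheet.loc[keep, "group"].isin(pos).astype(int)
            sub = NormalizedMatrix(
                values=normalized.values.loc[y.index],
                reference_totals=normalized.reference_totals.loc[y.index],
                sample_sheet=sheet.loc[y.index],
                probe_annotation=normalized.probe_annotation,
            )
            folds = clf.stratified_folds(sheet.loc[y.index], k=5, seed=5)
            reports = clf.evaluate_probes(sub, y, folds)
            retained = clf.select_smmips(reports, normalized.probe_annotation["cpg_id"])
            return clf.build_ensemble(sub, y, folds, retained, "+".join(pos))

        a = train(["pm", "metastasis"], ["pleura", "pleuritis"])
        b = train(["pm"], ["metastasis"])
        labels = mm.two_step_classify(normalized.values, a, b)
        truth = sheet["group"].map(
            {"pm": clf.MESOTHELIOMA, "metastasis": clf.METASTASIS,
             "pleura": clf.NONTUMORAL, "pleuritis": clf.NONTUMORAL}
        )
        assert int((labels != truth).sum()) <= 1
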