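"""Per-probe LDA models, cross-validation and the voting ensemble.

The two-step scheme trains one binary voting ensemble per question:
Model A separates tumoral from nontumoral tissue, Model B separates
pleural mesothelioma from pleural metastasis among the tumoral calls.
Each ensemble is a set of univariate LDA models (one per retained probe)
whose binary votes are summed; a sample is called positive when at least
C models agree. C is the integer agreement cutoff that maximizes accuracy.

Evaluation is out-of-fold throughout: within each cross-validation fold the
single-probe models and their posterior cutoffs are refit on the training
folds only, and votes are recorded for the held-out samples. The deployable
model is then refit on all samples with cutoffs re-derived on the full data;
both the out-of-fold and the full-data cutoffs are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix, ValidationError
from .lda import UnivariateLDAModel, choose_cutoff, fit_lda
from .metrics import ConfusionMetrics, auc_score, confusion_metrics

log = logging.getLogger(__name__)

K_FOLDS = 5
CV_MIN = 0.8

NONTUMORAL = "nontumoral"
MESOTHELIOMA = "mesothelioma"
METASTASIS = "metastasis"


@dataclass
class FoldAssignment:
    """Fold index per sample, stratified by tissue type."""

    folds: pd.Series
    k: int
    seed: int

    def held_out(self, fold: int) -> pd.Index:
        return self.folds.index[self.folds == fold]

    def training(self, fold: int) -> pd.Index:
        return self.folds.index[self.folds != fold]


def stratified_folds(sample_sheet: pd.DataFrame, k: int = K_FOLDS, seed: int = 0,
                     stratify_by: str = "tissue_type") -> FoldAssignment:
    """Assign samples to k folds so that each tissue type is spread across
    folds as evenly as integer division allows (per-stratum fold counts
    differ by at most 1). Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    strata = sample_sheet[stratify_by]
    if strata.isna().any():
        raise ValidationError("samples without stratification key")
    smallest = strata.value_counts().min()
    if k > smallest:
        log.warning("k=%d exceeds smallest stratum size %d", k, smallest)
    assignment = pd.Series(-1, index=sample_sheet.index, dtype=int, name="fold")
    offset = 0
    for stratum in sorted(strata.unique()):
        members = list(sample_sheet.index[strata == stratum])
        rng.shuffle(members)
        for i, s in enumerate(members):
            assignment[s] = (i + offset) % k
        offset += len(members)  # stagger strata so small strata rotate folds
    return FoldAssignment(folds=assignment, k=k, seed=seed)


@dataclass
class SmMIPModelReport:
    """Cross-validation outcome for one probe's univariate model."""

    probe_id: str
    fold_aucs: list[float]
    cv_auc: float | None
    cutoff: float | None
    retained: bool = False
    drop_reason: str | None = None


def cv_auc(values: pd.Series, labels: pd.Series, folds: FoldAssignment,
           positive_class: str = "1") -> tuple[list[float], float | None, np.ndarray]:
    """Out-of-fold AUC of a univariate LDA on one probe.

    Per fold: fit on the training folds, score held-out samples by posterior,
    AUC by the rank statistic with ties counted 0.5. The cvAUC is the
    unweighted mean over folds containing both classes. Also returns the
    pooled out-of-fold posteriors (NaN where a fold could not be fit).

    Returns (per-fold AUCs, cvAUC or None, out-of-fold posterior array).
    """
    y = np.asarray(labels).astype(int)
    oof = np.full(len(values), np.nan)
    fold_aucs: list[float] = []
    fold_arr = folds.folds.reindex(values.index).to_numpy()
    x = values.to_numpy(dtype=float)
    for f in range(folds.k):
        test = fold_arr == f
        train = ~test
        if not test.any():
            continue
        y_tr, y_te = y[train], y[test]
        if len(np.unique(y_te)) < 2:
            continue  # AUC undefined on a single-class fold
        try:
            model = fit_lda(x[train], y_tr, positive_class=positive_class)
        except ValidationError:
            continue
        scores = model.posterior(x[test])
        oof[test] = scores
        fold_aucs.append(auc_score(y_te, scores))
    cv = float(np.mean(fold_aucs)) if fold_aucs else None
    return fold_aucs, cv, oof


def evaluate_probes(matrix: NormalizedMatrix, labels: pd.Series, folds: FoldAssignment,
                    positive_class: str = "1") -> list[SmMIPModelReport]:
    """Cross-validate every target probe's univariate model.

    The per-probe cutoff recorded here is chosen on the pooled out-of-fold
    posteriors (it is re-derived inside each fold during ensemble training).
    """
    y = labels.reindex(matrix.values.index)
    reports = []
    for probe in matrix.probe_ids:
        fold_aucs, cv, oof = cv_auc(matrix.values[probe], y, folds, positive_class)
        if cv is None:
            reports.append(SmMIPModelReport(probe, [], None, None, False, "cv_undefined"))
            continue
        have = ~np.isnan(oof)
        cutoff = choose_cutoff(oof[have], y.to_numpy()[have])
        reports.append(SmMIPModelReport(probe, fold_aucs, cv, cutoff))
    return reports


def select_smmips(
    reports: list[SmMIPModelReport],
    probe_cpgs: pd.Series,
    cv_min: float = CV_MIN,
    undigested_totals: pd.Series | None = None,
) -> list[str]:
    """Retain discriminating probes, one per CpG target.

    Probes with cvAUC below ``cv_min`` are dropped first; among the
    remaining tiles of each CpG the probe with the highest cvAUC is kept
    (ties: higher cumulative undigested counts, then lexicographic probe id).
    Drop reasons are recorded on the reports in place.
    """
    by_id = {r.probe_id: r for r in reports}
    eligible = []
    for r in reports:
        if r.cv_auc is None:
            continue
        if r.cv_auc < cv_min:
            r.retained, r.drop_reason = False, "cv_auc"
        else:
            eligible.append(r)
    totals = undigested_totals if undigested_totals is not None else pd.Series(dtype=float)
    kept: list[str] = []
    groups: dict[str, list[SmMIPModelReport]] = {}
    for r in eligible:
        groups.setdefault(str(probe_cpgs.get(r.probe_id, r.probe_id)), []).append(r)
    for cpg in sorted(groups):
        tiles = groups[cpg]
        tiles.sort(key=lambda r: (-r.cv_auc, -float(totals.get(r.probe_id, 0)), r.probe_id))
        best, rest = tiles[0], tiles[1:]
        best.retained = True
        kept.append(best.probe_id)
        for r in rest:
            r.retained, r.drop_reason = False, "tile"
    if not kept:
        log.warning("no probes retained by select_smmips")
    return sorted(kept)


@dataclass
class EnsembleModel:
    """Voting ensemble of univariate LDA models with an agreement cutoff.

    ``models``/``cutoff`` are the deployable full-data fit; ``oof_*`` fields
    document the out-of-fold evaluation that produced the reported
    performance (cutoff chosen on pooled out-of-fold votes, confusion matrix
    of pooled out-of-fold predictions at that cutoff).
    """

    probe_ids: list[str]
    models: dict[str, UnivariateLDAModel]
    cutoff: int
    positive_class: str
    negative_class: str
    oof_votes: pd.Series | None = None
    oof_cutoff: int | None = None
    oof_confusion: ConfusionMetrics | None = None
    fold_rocs: list[pd.DataFrame] = field(default_factory=list)
    mean_roc: pd.DataFrame | None = None
    cv_auc: float | None = None

    @property
    def n_models(self) -> int:
        return len(self.probe_ids)

    def votes(self, values: pd.DataFrame) -> pd.Series:
        """Number of single-probe models voting positive per sample."""
        missing = [p for p in self.probe_ids if p not in values.columns]
        if missing:
            raise ValidationError(f"missing probe values: {missing[:5]}")
        v = np.zeros(len(values), dtype=int)
        for p in self.probe_ids:
            v += self.models[p].predict(values[p].to_numpy()).astype(int)
        return pd.Series(v, index=values.index, name="votes")

    def predict(self, values: pd.DataFrame) -> pd.Series:
        return self.votes(values) >= self.cutoff


def _choose_agreement_cutoff(votes: np.ndarray, y: np.ndarray, n_models: int) -> int:
    """argmax over C in 1..M of accuracy of (votes >= C); ties broken by
    higher balanced accuracy, then smaller C."""
    best = None
    for c in range(1, n_models + 1):
        pred = (votes >= c).astype(int)
        acc = float((pred == y).mean())
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        sens = tp / max(int((y == 1).sum()), 1)
        spec = tn / max(int((y == 0).sum()), 1)
        bal = (sens + spec) / 2
        key = (acc, bal, -c)
        if best is None or key > best[0]:
            best = (key, c)
    return best[1]


def _roc_points(votes: np.ndarray, y: np.ndarray, n_models: int) -> pd.DataFrame:
    """ROC over all integer vote thresholds 0..M+1 (TPR/FPR per threshold)."""
    pts = []
    pos = max(int((y == 1).sum()), 1)
    neg = max(int((y == 0).sum()), 1)
    for c in range(0, n_models + 2):
        pred = votes >= c
        pts.append({
            "threshold": c,
            "tpr": float((pred & (y == 1)).sum()) / pos,
            "fpr": float((pred & (y == 0)).sum()) / neg,
        })
    return pd.DataFrame(pts)


def build_ensemble(
    matrix: NormalizedMatrix,
    labels: pd.Series,
    folds: FoldAssignment,
    retained_probes: list[str],
    positive_class: str,
    negative_class: str = "other",
) -> EnsembleModel:
    """Combine retained single-probe models into a voting ensemble.

    Out-of-fold protocol: per fold, every single-probe LDA and its posterior
    cutoff are refit on the training folds and votes recorded on the held-out
    samples. The agreement cutoff C maximizing accuracy is chosen on the
    pooled out-of-fold votes, and the pooled confusion matrix at that C is
    reported. The deployable model refits every probe and both cutoff levels
    on the full data.
    """
    if not retained_probes:
        raise ValidationError("cannot build an ensemble without retained probes")
    X = matrix.values.loc[:, retained_probes]
    y = labels.reindex(X.index).to_numpy()
    y = np.asarray(y).astype(int)
    M = len(retained_probes)

    oof_votes = np.full(len(X), -1, dtype=int)
    fold_arr = folds.folds.reindex(X.index).to_numpy()
    for f in range(folds.k):
        test = fold_arr == f
        train = ~test
        if not test.any():
            continue
        votes_f = np.zeros(int(test.sum()), dtype=int)
        for p in retained_probes:
            x = X[p].to_numpy(dtype=float)
            model = fit_lda(x[train], y[train], positive_class=positive_class)
            model.cutoff = choose_cutoff(model.posterior(x[train]), y[train])
            votes_f += model.predict(x[test]).astype(int)
        oof_votes[test] = votes_f
    have = oof_votes >= 0
    if not have.any():
        raise ValidationError("no out-of-fold votes could be computed")
    oof_cutoff = _choose_agreement_cutoff(oof_votes[have], y[have], M)
    pred = (oof_votes[have] >= oof_cutoff).astype(int)
    yh = y[have]
    oof_conf = confusion_metrics(
        tp=int(((pred == 1) & (yh == 1)).sum()),
        tn=int(((pred == 0) & (yh == 0)).sum()),
        fp=int(((pred == 1) & (yh == 0)).sum()),
        fn=int(((pred == 0) & (yh == 1)).sum()),
    )

    fold_rocs, fold_aucs = [], []
    for f in range(folds.k):
        test = (fold_arr == f) & have
        if not test.any() or len(np.unique(y[test])) < 2:
            if test.any():
                log.warning("fold %d has a single class; skipped in ROC", f)
            continue
        fold_rocs.append(_roc_points(oof_votes[test], y[test], M))
        fold_aucs.append(auc_score(y[test], oof_votes[test]))
    mean_roc = _vertical_average(fold_rocs) if fold_rocs else None
    ens_cv = float(np.mean(fold_aucs)) if fold_aucs else None

    models: dict[str, UnivariateLDAModel] = {}
    full_votes = np.zeros(len(X), dtype=int)
    for p in retained_probes:
        x = X[p].to_numpy(dtype=float)
        model = fit_lda(x, y, positive_class=positive_class)
        model.cutoff = choose_cutoff(model.posterior(x), y)
        models[p] = model
        full_votes += model.predict(x).astype(int)
    full_cutoff = _choose_agreement_cutoff(full_votes, y, M)

    return EnsembleModel(
        probe_ids=list(retained_probes),
        models=models,
        cutoff=full_cutoff,
        positive_class=positive_class,
        negative_class=negative_class,
        oof_votes=pd.Series(np.where(have, oof_votes, np.nan), index=X.index, name="oof_votes"),
        oof_cutoff=oof_cutoff,
        oof_confusion=oof_conf,
        fold_rocs=fold_rocs,
        mean_roc=mean_roc,
        cv_auc=ens_cv,
    )


def _vertical_average(fold_rocs: list[pd.DataFrame], grid_size: int = 101) -> pd.DataFrame:
    """Mean ROC by vertical averaging of the fold curves on an FPR grid."""
    grid = np.linspace(0.0, 1.0, grid_size)
    tprs = []
    for roc in fold_rocs:
        pts = roc.sort_values(["fpr", "tpr"])
        fpr = np.concatenate([[0.0], pts["fpr"].to_numpy(), [1.0]])
        tpr = np.concatenate([[0.0], pts["tpr"].to_numpy(), [1.0]])
        order = np.argsort(fpr, kind="stable")
        tprs.append(np.interp(grid, fpr[order], tpr[order]))
    return pd.DataFrame({"fpr": grid, "tpr": np.mean(tprs, axis=0)})


def ensemble_roc(model: EnsembleModel) -> tuple[list[pd.DataFrame], pd.DataFrame | None, float | None]:
    """Per-fold ROC curves, the vertically averaged mean curve and the
    ensemble cvAUC (mean of fold AUCs on vote counts)."""
    return model.fold_rocs, model.mean_roc, model.cv_auc


def two_step_classify(
    values: pd.DataFrame,
    model_a: EnsembleModel,
    model_b: EnsembleModel,
) -> pd.Series:
    """Apply the two-step scheme to normalized counts.

    Model A below its agreement cutoff ends the cascade at ``nontumoral``;
    tumoral calls go to Model B, whose positive class is mesothelioma and
    whose negatives are called ``metastasis``.
    """
    tumoral = model_a.predict(values)
    out = pd.Series(NONTUMORAL, index=values.index, name="label", dtype=object)
    if tumoral.any():  # Model B is only consulted for tumoral calls
        is_pm = model_b.predict(values.loc[tumoral])
        out[tumoral] = np.where(is_pm, MESOTHELIOMA, METASTASIS)
    return out
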