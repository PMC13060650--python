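"""Differential-methylation candidate selection and in-silico validation.

Candidate CpGs must be hypermethylated in the tumor group against every
control group (adjusted p <= 0.05 and positive delta in each comparison),
show low and stable methylation in each control group (mean <= 0.3,
SD <= 0.1), and sit inside a recognition site of the configured MSREs.
Survivors are ranked by the smallest tumor-minus-control methylation
difference and truncated to the top k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import BetaMatrix, CpGContext, ValidationError
from .enzymes import DEFAULT_ENZYMES, EnzymeSet, msre_site_overlap
from .lda import fit_lda
from .metrics import auc_score

log = logging.getLogger(__name__)

P_MAX = 0.05
CONTROL_MEAN_MAX = 0.3
CONTROL_SD_MAX = 0.1
TOP_K = 1000


def differential_methylation(beta: BetaMatrix, group_a: str, group_b: str) -> pd.DataFrame:
    """Per-CpG Welch t-test of ``group_a`` vs ``group_b`` beta values.

    Returns a DataFrame indexed by CpG id with columns ``statistic``,
    ``p_value``, ``p_adjusted`` (Benjamini-Hochberg across all CpGs of this
    comparison) and ``delta`` = mean(a) - mean(b).

    CpGs where both groups are constant get p = 1 when the constants are
    equal and p = 0 (with a warning in the log) otherwise.
    """
    a = beta.group_samples(group_a).to_numpy(dtype=float)
    b = beta.group_samples(group_b).to_numpy(dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValidationError("each compared group needs >= 2 samples")
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    delta = mean_a - mean_b

    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=False)
        t, p = np.array(res.statistic), np.array(res.pvalue)

    # exact constancy, not var==0: float summation noise must not leak through
    both_const = (a == a[:1]).all(axis=0) & (b == b[:1]).all(axis=0)
    equal_const = both_const & (mean_a == mean_b)
    unequal_const = both_const & (mean_a != mean_b)
    t[equal_const], p[equal_const] = 0.0, 1.0
    if unequal_const.any():
        log.warning("%d CpGs constant within groups but unequal; p set to 0",
                    int(unequal_const.sum()))
        t[unequal_const] = np.where(delta[unequal_const] > 0, np.inf, -np.inf)
        p[unequal_const] = 0.0

    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"statistic": t, "p_value": p, "p_adjusted": p_adj, "delta": delta},
        index=pd.Index(beta.cpg_ids, name="cpg_id"),
    )


@dataclass
class DMCRecord:
    """Per-CpG evidence across both tumor-vs-control comparisons."""

    cpg_id: str
    tumor_mean: float
    control_means: dict[str, float]
    control_sds: dict[str, float]
    p_adjusted: dict[str, float]
    p_value: dict[str, float]
    deltas: dict[str, float]
    msre_overlap: bool
    ranking_score: float = field(init=False)
    passes: dict[str, bool] = field(default_factory=dict)
    rank: int | None = None

    def __post_init__(self) -> None:
        self.ranking_score = min(self.deltas.values())


def select_candidates(
    beta: BetaMatrix,
    tumor_group: str,
    control_groups: list[str],
    contexts: dict[str, CpGContext],
    enzymes: EnzymeSet = DEFAULT_ENZYMES,
    p_max: float = P_MAX,
    control_mean_max: float = CONTROL_MEAN_MAX,
    control_sd_max: float = CONTROL_SD_MAX,
    top_k: int = TOP_K,
) -> list[DMCRecord]:
    """Rank candidate biomarker CpGs.

    A CpG is retained iff, in every tumor-vs-control comparison, adjusted
    p <= ``p_max`` with delta > 0; every control group's mean and SD are at
    most ``control_mean_max`` / ``control_sd_max``; and an MSRE recognition
    site overlaps the CpG. Survivors are sorted by ranking score (the minimum
    delta over control groups) descending, ties broken by CpG id, and
    truncated to ``top_k``.
    """
    if len(control_groups) < 1:
        raise ValidationError("at least one control group is required")
    comparisons = {g: differential_methylation(beta, tumor_group, g) for g in control_groups}
    tumor = beta.group_samples(tumor_group)
    tumor_means = tumor.mean(axis=0)
    ctrl_stats = {
        g: (beta.group_samples(g).mean(axis=0), beta.group_samples(g).std(axis=0, ddof=1))
        for g in control_groups
    }

    records: list[DMCRecord] = []
    for cpg in beta.cpg_ids:
        ctx = contexts.get(cpg)
        overlap = bool(ctx is not None and msre_site_overlap(ctx, enzymes))
        rec = DMCRecord(
            cpg_id=cpg,
            tumor_mean=float(tumor_means[cpg]),
            control_means={g: float(ctrl_stats[g][0][cpg]) for g in control_groups},
            control_sds={g: float(ctrl_stats[g][1][cpg]) for g in control_groups},
            p_adjusted={g: float(comparisons[g].loc[cpg, "p_adjusted"]) for g in control_groups},
            p_value={g: float(comparisons[g].loc[cpg, "p_value"]) for g in control_groups},
            deltas={g: float(comparisons[g].loc[cpg, "delta"]) for g in control_groups},
            msre_overlap=overlap,
        )
        rec.passes = {
            "significant": all(rec.p_adjusted[g] <= p_max for g in control_groups),
            "hypermethylated": all(rec.deltas[g] > 0 for g in control_groups),
            "control_mean": all(rec.control_means[g] <= control_mean_max for g in control_groups),
            "control_sd": all(rec.control_sds[g] <= control_sd_max for g in control_groups),
            "msre": overlap,
        }
        records.append(rec)

    kept = [r for r in records if all(r.passes.values())]
    kept.sort(key=lambda r: (-r.ranking_score, r.cpg_id))
    kept = kept[:top_k]
    for i, r in enumerate(kept):
        r.rank = i + 1
    if not kept:
        log.warning("no CpGs survived candidate selection")
    return kept


def records_to_frame(records: list[DMCRecord]) -> pd.DataFrame:
    """Flatten DMC records into a tidy table (one row per CpG)."""
    rows = []
    for r in records:
        row: dict = {"cpg_id": r.cpg_id, "tumor_mean": r.tumor_mean,
                     "ranking_score": r.ranking_score, "msre_overlap": r.msre_overlap,
                     "rank": r.rank}
        for g in r.control_means:
            row[f"mean_{g}"] = r.control_means[g]
            row[f"sd_{g}"] = r.control_sds[g]
            row[f"p_adj_{g}"] = r.p_adjusted[g]
            row[f"delta_{g}"] = r.deltas[g]
        for name, ok in r.passes.items():
            row[f"pass_{name}"] = ok
        rows.append(row)
    return pd.DataFrame(rows)


def insilico_validate(
    train: BetaMatrix,
    test: BetaMatrix,
    candidates: list[str],
    tumor_group: str,
) -> tuple[pd.DataFrame, dict]:
    """Per-CpG transferability check of candidate biomarkers.

    For every candidate present in both cohorts, a univariate LDA is fit on
    the training betas (tumor vs rest) and its posterior scores the test
    cohort; the AUC against the test labels measures how well the site
    separates tumor from control in independent data. Candidates missing from
    the test matrix are skipped and logged.

    Returns (per-CpG AUC table, summary with mean/median/min/max/n).
    """
    y_train = (train.groups == tumor_group).astype(int).to_numpy()
    y_test = (test.groups == tumor_group).astype(int).to_numpy()
    if y_train.sum() in (0, len(y_train)) or y_test.sum() in (0, len(y_test)):
        raise ValidationError("both cohorts need tumor and non-tumor samples")
    aucs, skipped = {}, []
    for cpg in candidates:
        if cpg not in train.betas.columns or cpg not in test.betas.columns:
            skipped.append(cpg)
            continue
        model = fit_lda(train.betas[cpg].to_numpy(), y_train, positive_class=tumor_group)
        scores = model.posterior(test.betas[cpg].to_numpy())
        aucs[cpg] = auc_score(y_test, scores)
    if skipped:
        log.info("skipped %d candidates absent from one cohort", len(skipped))
    table = pd.Series(aucs, name="auc").rename_axis("cpg_id").to_frame()
    vals = table["auc"].to_numpy()
    summary = {
        "n": int(len(vals)),
        "n_skipped": len(skipped),
        "mean": float(vals.mean()) if len(vals) else float("nan"),
        "median": float(np.median(vals)) if len(vals) else float("nan"),
        "min": float(vals.min()) if len(vals) else float("nan"),
        "max": float(vals.max()) if len(vals) else float("nan"),
    }
    return table, summary
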