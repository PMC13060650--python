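"""QC and normalization of MSRE/smMIP count matrices.

Pipeline order is fixed: spike-in digestion QC and sample exclusion, then the
probe-efficiency filter on undigested aliquots, then human-reference
normalization of the digested target counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .containers import DIGESTED, CountMatrix, NormalizedMatrix, ValidationError

log = logging.getLogger(__name__)

QC_THRESHOLD_PERCENT = 5.0
CUMULATIVE_MIN = 1000


class QCUndefinedError(ValidationError):
    """Raised when a sample's digestion QC cannot be computed."""


@dataclass
class DigestQCReport:
    """Per-sample percentage of undigested fragments and pass flags.

    ``percent_undigested`` is on the 0-100 scale and may exceed 100 (no cap);
    ``passed`` is percent <= threshold (exclusion is strictly greater-than).
    """

    percent_undigested: pd.Series
    threshold: float

    @property
    def passed(self) -> pd.Series:
        return self.percent_undigested <= self.threshold

    @property
    def failed_samples(self) -> list[str]:
        return list(self.percent_undigested.index[~self.passed])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "percent_undigested": self.percent_undigested,
                "passed": self.passed,
                "threshold": self.threshold,
            }
        )


def percent_undigested(matrix: CountMatrix, sample_id: str) -> float:
    """Spike-in estimate of incomplete digestion for one sample.

    100 x (mean count over lambda cut-site probes) / (mean count over lambda
    reference probes). The ratio of within-sample means is robust to the cut
    and reference probe sets having different sizes.
    """
    cut = matrix.probes_with_role("lambda_cut")
    ref = matrix.probes_with_role("lambda_ref")
    if not cut or not ref:
        raise QCUndefinedError("lambda cut-site and reference probes are both required")
    ref_mean = float(matrix.counts.loc[sample_id, ref].mean())
    if ref_mean == 0:
        raise QCUndefinedError(f"sample {sample_id!r}: lambda reference mean is 0")
    cut_mean = float(matrix.counts.loc[sample_id, cut].mean())
    return 100.0 * cut_mean / ref_mean


def digestion_qc(matrix: CountMatrix, threshold: float = QC_THRESHOLD_PERCENT) -> DigestQCReport:
    """Compute percent undigested for every digested sample."""
    samples = matrix.digested_samples
    if not samples:
        raise QCUndefinedError("no digested samples present")
    pct = pd.Series({s: percent_undigested(matrix, s) for s in samples}, name="percent_undigested")
    return DigestQCReport(percent_undigested=pct, threshold=threshold)


def exclude_failed_samples(
    matrix: CountMatrix,
    qc: DigestQCReport,
    threshold: float | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop digested samples whose percent undigested is strictly above the
    threshold; undigested aliquots are exempt (they exist only for the
    probe-efficiency filter). Returns the filtered matrix and an exclusion log.
    """
    thr = qc.threshold if threshold is None else threshold
    digested = matrix.digested_samples
    missing = set(digested) - set(qc.percent_undigested.index)
    if missing:
        raise QCUndefinedError(f"QC missing for digested samples: {sorted(missing)[:5]}")
    pct = qc.percent_undigested
    excluded = [s for s in digested if pct[s] > thr]
    exclusion_log = pd.DataFrame(
        {"sample_id": excluded, "percent_undigested": [pct[s] for s in excluded]}
    )
    for _, row in exclusion_log.iterrows():
        log.info(
            "excluding sample %s: %.2f%% undigested (> %.2f%%)",
            row["sample_id"], row["percent_undigested"], thr,
        )
    keep = [s for s in matrix.counts.index if s not in set(excluded)]
    return matrix.subset_samples(keep), exclusion_log


def efficiency_filter(
    matrix: CountMatrix,
    cumulative_min: int = CUMULATIVE_MIN,
    bypass: bool = False,
) -> list[str]:
    """Target probes whose raw counts summed over all undigested aliquots
    reach ``cumulative_min`` (>= rule). Undigested aliquots carry the full,
    digestion-independent capture signal, so a low cumulative count marks an
    inefficient probe rather than an unmethylated target.

    With ``bypass=True`` and no undigested aliquots, all target probes pass.
    """
    targets = matrix.target_probes
    undig = matrix.undigested_samples
    if not undig:
        if bypass:
            log.warning("no undigested aliquots; efficiency filter bypassed")
            return list(targets)
        raise ValidationError(
            "efficiency filter requires undigested aliquots (or an explicit bypass)"
        )
    totals = matrix.counts.loc[undig, targets].sum(axis=0)
    retained = list(totals.index[totals >= cumulative_min])
    log.info("efficiency filter retained %d / %d target probes", len(retained), len(targets))
    return retained


def undigested_totals(matrix: CountMatrix) -> pd.Series:
    """Cumulative raw counts per target probe across undigested aliquots
    (used as a tie-break when choosing among tiled probes)."""
    undig = matrix.undigested_samples
    targets = matrix.target_probes
    if not undig:
        return pd.Series(0, index=pd.Index(targets))
    return matrix.counts.loc[undig, targets].sum(axis=0)


def normalize_counts(matrix: CountMatrix, target_probes=None) -> NormalizedMatrix:
    """Divide each target-probe count of a digested sample by that sample's
    pooled human-reference total (both reference classes together).

    Scale-invariant: multiplying all of a sample's counts by c > 0 leaves its
    normalized row unchanged. Reference and lambda probes never appear in the
    output.
    """
    refs = matrix.human_ref_probes
    if not refs:
        raise ValidationError("no human reference probes present")
    targets = list(target_probes) if target_probes is not None else matrix.target_probes
    non_target = set(targets) - set(matrix.target_probes)
    if non_target:
        raise ValidationError(f"non-target probes requested: {sorted(non_target)[:5]}")
    digested = matrix.digested_samples
    if not digested:
        raise ValidationError("no digested samples to normalize")
    ref_totals = matrix.counts.loc[digested, refs].sum(axis=1).astype(float)
    zero = ref_totals.index[ref_totals == 0].tolist()
    if zero:
        raise ValidationError(f"zero reference total for samples: {zero}")
    values = matrix.counts.loc[digested, targets].astype(float).div(ref_totals, axis=0)
    return NormalizedMatrix(
        values=values,
        reference_totals=ref_totals,
        sample_sheet=matrix.sample_sheet.loc[digested],
        probe_annotation=matrix.probe_annotation.loc[targets],
    )


def qc_normalize(
    matrix: CountMatrix,
    qc_threshold: float = QC_THRESHOLD_PERCENT,
    cumulative_min: int = CUMULATIVE_MIN,
    bypass_efficiency: bool = False,
) -> tuple[NormalizedMatrix, DigestQCReport, pd.DataFrame, list[str]]:
    """Full processing chain: digestion QC -> sample exclusion -> probe
    efficiency filter -> reference normalization.

    Returns (normalized matrix, QC report, exclusion log, retained probes).
    """
    qc = digestion_qc(matrix, threshold=qc_threshold)
    filtered, exclusion_log = exclude_failed_samples(matrix, qc)
    retained = efficiency_filter(filtered, cumulative_min=cumulative_min, bypass=bypass_efficiency)
    normalized = normalize_counts(filtered, target_probes=retained)
    return normalized, qc, exclusion_log, retained
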