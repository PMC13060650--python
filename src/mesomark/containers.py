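"""In-memory containers shared across the pipeline stages.

All tabular payloads are pandas objects; the dataclasses bundle them with the
annotations (sample sheets, probe roles, CpG contexts) that the individual
stages need, and validate the invariants the downstream code relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: probe roles of an MSRE/smMIP count matrix
PROBE_ROLES = ("target", "human_ref_nocpg", "human_ref_nomsre", "lambda_cut", "lambda_ref")
HUMAN_REF_ROLES = ("human_ref_nocpg", "human_ref_nomsre")

DIGESTED = "digested"
UNDIGESTED = "undigested"


class ValidationError(ValueError):
    """Raised when an input container violates a documented invariant."""


@dataclass
class BetaMatrix:
    """Methylation fractions (beta values), samples x CpG sites.

    Parameters
    ----------
    betas : DataFrame
        Rows = samples, columns = CpG ids, values in [0, 1].
    groups : Series
        Group label per sample (index aligned with ``betas.index``), e.g.
        ``tumor`` / ``pleura`` / ``blood``.
    """

    betas: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.betas.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.betas.index)
        if self.groups.isna().any():
            missing = self.groups[self.groups.isna()].index.tolist()
            raise ValidationError(f"samples without group label: {missing}")
        vals = self.betas.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValidationError("beta matrix contains missing values")
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValidationError("beta values must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.betas.index)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.betas.columns)

    def group_samples(self, group: str) -> pd.DataFrame:
        """Beta sub-matrix of all samples carrying ``group``."""
        keep = self.groups[self.groups == group].index
        if keep.empty:
            raise ValidationError(f"no samples in group {group!r}")
        return self.betas.loc[keep]


@dataclass
class CpGContext:
    """A CpG site with its local sequence context.

    ``position`` is the 0-based coordinate of the C of the CpG on the '+'
    strand; ``offset`` locates that same C inside ``sequence``.
    """

    cpg_id: str
    contig: str
    position: int
    sequence: str
    offset: int
    strand: str = "+"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGTN"):
            raise ValidationError(f"{self.cpg_id}: context has non-ACGTN characters")
        if self.sequence[self.offset : self.offset + 2] != "CG":
            raise ValidationError(f"{self.cpg_id}: no CG at offset {self.offset}")


@dataclass
class TargetPanel:
    """CpG contexts plus the probe tiling that covers them.

    ``probes`` columns: probe_id, cpg_id, tile_index (0-based within a CpG).
    """

    contexts: dict[str, CpGContext]
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        unknown = set(self.probes["cpg_id"]) - set(self.contexts)
        if unknown:
            raise ValidationError(f"probes target unknown CpGs: {sorted(unknown)[:5]}")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def probes_for(self, cpg_id: str) -> list[str]:
        return self.probes.loc[self.probes["cpg_id"] == cpg_id, "probe_id"].tolist()


@dataclass
class CountMatrix:
    """Raw smMIP read counts with probe and sample annotations.

    counts : DataFrame, samples x probes, nonnegative integers.
    probe_annotation : DataFrame indexed by probe_id with columns
        role (one of :data:`PROBE_ROLES`), cpg_id, tile_index.
    sample_sheet : DataFrame indexed by sample_id with columns
        group, tissue_type, aliquot (``digested`` | ``undigested``).
    """

    counts: pd.DataFrame
    probe_annotation: pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.probe_annotation.index):
            self.probe_annotation = self.probe_annotation.reindex(self.counts.columns)
        if self.probe_annotation["role"].isna().any():
            raise ValidationError("probes without role annotation")
        bad_roles = set(self.probe_annotation["role"]) - set(PROBE_ROLES)
        if bad_roles:
            raise ValidationError(f"unknown probe roles: {sorted(bad_roles)}")
        if not self.counts.index.equals(self.sample_sheet.index):
            self.sample_sheet = self.sample_sheet.reindex(self.counts.index)
        if self.sample_sheet["aliquot"].isna().any():
            raise ValidationError("samples missing from sample sheet")
        bad_aliquot = set(self.sample_sheet["aliquot"]) - {DIGESTED, UNDIGESTED}
        if bad_aliquot:
            raise ValidationError(f"unknown aliquot flags: {sorted(bad_aliquot)}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # non-integer counts indicate already-normalized input
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError(
                    "counts are not integers; refusing what looks like normalized input"
                )
            self.counts = self.counts.round().astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            raise ValidationError("negative counts")
        is_target = self.probe_annotation["role"] == "target"
        if self.probe_annotation.loc[is_target, "cpg_id"].isna().any():
            raise ValidationError("target probes must map to a CpG id")

    def probes_with_role(self, *roles: str) -> list[str]:
        mask = self.probe_annotation["role"].isin(roles)
        return list(self.probe_annotation.index[mask])

    @property
    def target_probes(self) -> list[str]:
        return self.probes_with_role("target")

    @property
    def human_ref_probes(self) -> list[str]:
        return self.probes_with_role(*HUMAN_REF_ROLES)

    def samples_with_aliquot(self, aliquot: str) -> list[str]:
        mask = self.sample_sheet["aliquot"] == aliquot
        return list(self.sample_sheet.index[mask])

    @property
    def digested_samples(self) -> list[str]:
        return self.samples_with_aliquot(DIGESTED)

    @property
    def undigested_samples(self) -> list[str]:
        return self.samples_with_aliquot(UNDIGESTED)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[list(sample_ids)],
            probe_annotation=self.probe_annotation.copy(),
            sample_sheet=self.sample_sheet.loc[list(sample_ids)],
        )

    def subset_probes(self, probe_ids) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[:, list(probe_ids)],
            probe_annotation=self.probe_annotation.loc[list(probe_ids)],
            sample_sheet=self.sample_sheet.copy(),
        )


@dataclass
class NormalizedMatrix:
    """Reference-normalized target-probe counts (digested samples only).

    ``values[s, p] = raw count / reference_total[s]`` where the reference
    total pools all human reference probes of sample ``s``.
    """

    values: pd.DataFrame
    reference_totals: pd.Series
    sample_sheet: pd.DataFrame
    probe_annotation: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("normalized values must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)
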