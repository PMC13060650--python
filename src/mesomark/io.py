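"""Readers and writers for the pipeline's tabular and JSON artifacts.

All tables are TSV with a header row; missing values are encoded as ``NA``.
Raw count files must contain integers — floats are rejected to catch
accidentally re-submitted normalized output. CpG context files are BED-like
(0-based half-open coordinates). Trained ensembles serialize to a versioned
JSON layout.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import EnsembleModel
from .containers import BetaMatrix, CountMatrix, CpGContext, NormalizedMatrix, ValidationError
from .lda import UnivariateLDAModel

MODEL_SCHEMA_VERSION = 1
NA = "NA"


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False, **kw)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"{path}: malformed TSV ({exc})") from exc


def write_beta_matrix(beta: BetaMatrix, beta_path, sheet_path) -> None:
    # CpG rows x sample columns on disk
    beta.betas.T.rename_axis("cpg_id").to_csv(beta_path, sep="\t")
    sheet = pd.DataFrame({"sample_id": beta.sample_ids, "group": beta.groups.to_numpy()})
    sheet.to_csv(sheet_path, sep="\t", index=False)


def read_beta_matrix(beta_path, sheet_path) -> BetaMatrix:
    mat = _read_tsv(beta_path, index_col=0).T
    mat.index.name = "sample_id"
    mat.columns.name = None
    sheet = _read_tsv(sheet_path).set_index("sample_id")
    if "group" not in sheet.columns:
        raise ValidationError(f"{sheet_path}: sample sheet needs a 'group' column")
    return BetaMatrix(betas=mat, groups=sheet["group"].reindex(mat.index))


def write_contexts(contexts: dict[str, CpGContext], path) -> None:
    rows = [
        {
            "contig": c.contig, "start": c.position, "end": c.position + 2,
            "cpg_id": c.cpg_id, "sequence": c.sequence, "offset": c.offset,
        }
        for c in contexts.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_contexts(path) -> dict[str, CpGContext]:
    df = _read_tsv(path)
    out = {}
    for _, r in df.iterrows():
        out[str(r["cpg_id"])] = CpGContext(
            cpg_id=str(r["cpg_id"]), contig=str(r["contig"]), position=int(r["start"]),
            sequence=str(r["sequence"]), offset=int(r["offset"]),
        )
    return out


def write_count_matrix(matrix: CountMatrix, counts_path, annot_path, sheet_path) -> None:
    matrix.counts.T.rename_axis("probe_id").to_csv(counts_path, sep="\t")
    matrix.probe_annotation.rename_axis("probe_id").to_csv(
        annot_path, sep="\t", na_rep=NA
    )
    matrix.sample_sheet.rename_axis("sample_id").to_csv(sheet_path, sep="\t", na_rep=NA)


def read_count_matrix(counts_path, annot_path, sheet_path) -> CountMatrix:
    wide = _read_tsv(counts_path, index_col=0)
    arr = wide.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError(f"{counts_path}: non-numeric counts")
    if not np.allclose(arr, np.round(arr), atol=0, rtol=0):
        raise ValidationError(
            f"{counts_path}: counts must be integers (normalized input rejected)"
        )
    counts = wide.T.astype(np.int64)
    counts.index.name = "sample_id"
    counts.columns.name = None
    annot = _read_tsv(annot_path).set_index("probe_id")
    sheet = _read_tsv(sheet_path).set_index("sample_id")
    return CountMatrix(counts=counts, probe_annotation=annot, sample_sheet=sheet)


def read_counts_long(path, annot_path, sheet_path) -> CountMatrix:
    """Long-format alternative: columns sample_id, probe_id, count."""
    df = _read_tsv(path)
    need = {"sample_id", "probe_id", "count"}
    if not need <= set(df.columns):
        raise ValidationError(f"{path}: long count file needs columns {sorted(need)}")
    wide = df.pivot_table(index="sample_id", columns="probe_id", values="count",
                          aggfunc="sum", fill_value=0)
    wide = wide.reindex(index=pd.unique(df["sample_id"]),
                        columns=pd.unique(df["probe_id"]))
    wide.columns.name = None
    wide.index.name = "sample_id"
    annot = _read_tsv(annot_path).set_index("probe_id")
    sheet = _read_tsv(sheet_path).set_index("sample_id")
    return CountMatrix(counts=wide.astype(np.int64), probe_annotation=annot.reindex(wide.columns),
                       sample_sheet=sheet.reindex(wide.index))


def write_normalized(matrix: NormalizedMatrix, path) -> None:
    out = matrix.values.copy()
    out.insert(0, "reference_total", matrix.reference_totals)
    out.rename_axis("sample_id").to_csv(path, sep="\t")


def read_normalized(path, sheet_path) -> NormalizedMatrix:
    df = _read_tsv(path, index_col=0)
    ref = df.pop("reference_total")
    sheet = _read_tsv(sheet_path).set_index("sample_id")
    return NormalizedMatrix(values=df, reference_totals=ref,
                            sample_sheet=sheet.reindex(df.index))


def model_to_dict(model: EnsembleModel, seed: int | None = None,
                  config_hash: str | None = None) -> dict:
    return {
        "schema_version": MODEL_SCHEMA_VERSION,
        "positive_class": model.positive_class,
        "negative_class": model.negative_class,
        "agreement_cutoff": model.cutoff,
        "oof_agreement_cutoff": model.oof_cutoff,
        "cv_auc": model.cv_auc,
        "seed": seed,
        "config_hash": config_hash,
        "probes": {p: model.models[p].to_dict() for p in model.probe_ids},
    }


def write_model(model: EnsembleModel, path, seed: int | None = None,
                config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model, seed, config_hash), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model(path) -> EnsembleModel:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValidationError(f"{path}: unsupported model schema {d.get('schema_version')!r}")
    probes = sorted(d["probes"])
    return EnsembleModel(
        probe_ids=probes,
        models={p: UnivariateLDAModel.from_dict(d["probes"][p]) for p in probes},
        cutoff=int(d["agreement_cutoff"]),
        positive_class=d["positive_class"],
        negative_class=d["negative_class"],
        oof_cutoff=d.get("oof_agreement_cutoff"),
        cv_auc=d.get("cv_auc"),
    )


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config_hash: str, seed: int, artifacts: list[str | Path],
                   exclusions: list[dict] | None = None, version: str = "0.1.0") -> None:
    """Run manifest: config hash, seed, version and per-artifact checksums.

    Deterministic (no timestamps), so identical reruns are byte-identical.
    """
    manifest = {
        "config_hash": config_hash,
        "seed": seed,
        "version": version,
        "artifacts": {Path(p).name: file_sha256(p) for p in sorted(map(str, artifacts))},
        "exclusions": exclusions or [],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
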