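"""Pipeline configuration: a flat key-value text format with typed defaults.

Defaults are the analysis' canonical thresholds: adjusted p <= 0.05,
control mean <= 0.3 and SD <= 0.1, top 1000 candidates, 5% undigested
exclusion, 1000 cumulative undigested counts per probe, fivefold
cross-validation and a cvAUC retention floor of 0.8.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields

from .containers import ValidationError
from .enzymes import DEFAULT_ENZYMES, EnzymeSet


@dataclass
class PipelineConfig:
    p_max: float = 0.05
    control_mean_max: float = 0.3
    control_sd_max: float = 0.1
    top_k: int = 1000
    qc_threshold_percent: float = 5.0
    cumulative_min: int = 1000
    k_folds: int = 5
    cv_min: float = 0.8
    dims: int = 2
    seed: int = 0
    tumor_group: str = "pm"
    control_groups: tuple[str, ...] = ("pleura", "blood")
    # group labels feeding each binary model
    model_a_positive: tuple[str, ...] = ("pm", "metastasis")
    model_a_negative: tuple[str, ...] = ("pleura", "pleuritis")
    model_b_positive: tuple[str, ...] = ("pm",)
    model_b_negative: tuple[str, ...] = ("metastasis",)
    enzymes: EnzymeSet = field(default_factory=lambda: DEFAULT_ENZYMES)

    def __post_init__(self) -> None:
        checks = [
            (0 < self.p_max <= 1, "p_max must be in (0, 1]"),
            (0 <= self.control_mean_max <= 1, "control_mean_max must be in [0, 1]"),
            (0 <= self.control_sd_max <= 1, "control_sd_max must be in [0, 1]"),
            (self.top_k >= 1, "top_k must be >= 1"),
            (self.qc_threshold_percent >= 0, "qc_threshold_percent must be >= 0"),
            (self.cumulative_min >= 0, "cumulative_min must be >= 0"),
            (self.k_folds >= 2, "k_folds must be >= 2"),
            (0 <= self.cv_min <= 1, "cv_min must be in [0, 1]"),
            (self.dims >= 1, "dims must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(msg)

    def to_flat(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "enzymes":
                out[f.name] = ",".join(f"{e.name}:{e.recognition}" for e in v)
            elif isinstance(v, tuple):
                out[f.name] = ",".join(v)
            else:
                out[f.name] = str(v)
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.to_flat(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


_TUPLE_KEYS = {"control_groups", "model_a_positive", "model_a_negative",
               "model_b_positive", "model_b_negative"}


def parse_config(text: str) -> PipelineConfig:
    """Parse ``key = value`` lines (``#`` comments allowed). Unknown keys are
    rejected to catch typos."""
    known = {f.name: f for f in fields(PipelineConfig)}
    kwargs: dict = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        if key not in known:
            raise ValidationError(f"line {lineno}: unknown configuration key {key!r}")
        if key == "enzymes":
            pairs = [item.split(":", 1) for item in val.split(",") if item.strip()]
            kwargs[key] = EnzymeSet.from_pairs([(n.strip(), s.strip()) for n, s in pairs])
        elif key in _TUPLE_KEYS:
            kwargs[key] = tuple(v.strip() for v in val.split(",") if v.strip())
        elif key in ("top_k", "cumulative_min", "k_folds", "dims", "seed"):
            kwargs[key] = int(val)
        elif key == "tumor_group":
            kwargs[key] = val
        else:
            kwargs[key] = float(val)
    return PipelineConfig(**kwargs)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return parse_config(fh.read())
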