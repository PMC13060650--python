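"""Synthetic cohorts with the statistical structure the pipeline assumes.

Two generators cover the two data modalities:

* array-style beta-value cohorts: most CpGs sit at a low control methylation
  level in every group, while a chosen subset is hypermethylated in the tumor
  group by a fixed effect size (``tumor_delta``). Noise is Beta-distributed,
  reparameterized by (mean, sd), which keeps values bounded in [0, 1] and
  heteroskedastic like real array betas.

* MSRE/smMIP count matrices: a target probe's expected count in a digested
  sample is library factor x capture efficiency x (m + (1-m)(1-d)), where m
  is the methylation fraction of the target and d the digestion efficiency —
  methylated (uncut) fragments survive digestion, unmethylated ones survive
  only when digestion fails. Undigested aliquots and probes without
  CpG/MSRE content carry the full, methylation-independent signal; lambda
  spike-in cut sites (unmethylated by construction) survive at rate (1-d).
  Counts are negative binomial with library sizes lognormal across samples
  and capture efficiencies log-uniform across human probes; lambda control
  probes use unit capture efficiency, mirroring a spike-in set designed for
  uniform capture.

Both generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    DIGESTED,
    UNDIGESTED,
    BetaMatrix,
    CountMatrix,
    CpGContext,
    TargetPanel,
    ValidationError,
)
from .enzymes import DEFAULT_ENZYMES, EnzymeSet, expand_iupac, find_site_hits


@dataclass
class SyntheticCohortConfig:
    """Parameters of a beta-value discovery cohort."""

    n_per_group: int = 30
    n_cpg: int = 5000
    n_informative: int = 50
    control_beta_mean: float = 0.15
    control_beta_sd: float = 0.05
    tumor_delta: float = 0.4
    noise_model: str = "beta"  # "beta" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_cpg:
            raise ValidationError("n_informative must not exceed n_cpg")
        if not 0 <= self.control_beta_mean <= 1 or not 0 <= self.tumor_delta <= 1:
            raise ValidationError("means and deltas must lie in [0, 1]")
        if self.control_beta_mean + self.tumor_delta > 1:
            raise ValidationError("control_beta_mean + tumor_delta exceeds 1")
        if self.noise_model not in ("beta", "none"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")


@dataclass
class SyntheticAssayConfig:
    """Parameters of an MSRE/smMIP count experiment.

    Control-probe counts default to the panel layout of the assay: 12 lambda
    cut-site and 10 lambda reference probes, 300 human reference probes
    without CpG sites and 300 without MSRE sites.
    """

    n_target_smmips: int = 100
    n_human_ref_nocpg: int = 300
    n_human_ref_nomsre: int = 300
    n_lambda_cut: int = 12
    n_lambda_ref: int = 10
    digestion_efficiency: float = 0.99
    library_size_mean: float = 2_000_000.0
    library_size_cv: float = 0.3
    dispersion: float = 0.1
    capture_efficiency_range: tuple[float, float] = (0.5, 2.0)
    tiling_plan: tuple[int, int, int] = (270, 463, 11)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_target_smmips", "n_human_ref_nocpg", "n_human_ref_nomsre",
                     "n_lambda_cut", "n_lambda_ref"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if not 0 <= self.digestion_efficiency <= 1:
            raise ValidationError("digestion_efficiency must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be nonnegative")
        lo, hi = self.capture_efficiency_range
        if not 0 <= lo <= hi:
            raise ValidationError("invalid capture_efficiency_range")


@dataclass
class TruthRecord:
    """Ground truth for one CpG or probe, for parameter-recovery tests."""

    feature_id: str
    is_informative: bool
    true_fraction: dict[str, float] = field(default_factory=dict)


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Shape parameters of a Beta distribution with the given mean and sd.

    The sd is shrunk if it is infeasible for the mean (sd^2 < m(1-m) must
    hold for a proper Beta).
    """
    m = min(max(mean, 1e-6), 1 - 1e-6)
    max_sd = np.sqrt(m * (1 - m))
    s = min(sd, 0.95 * max_sd)
    nu = m * (1 - m) / (s * s) - 1
    return m * nu, (1 - m) * nu


def generate_beta_matrix(
    config: SyntheticCohortConfig,
    group_labels: list[str] | None = None,
    tumor_group: str = "tumor",
) -> tuple[BetaMatrix, list[TruthRecord]]:
    """Simulate a beta-value cohort with injected hypermethylated sites.

    Every group has ``n_per_group`` samples. All CpGs are centered at
    ``control_beta_mean`` except the first ``n_informative`` sites, whose
    tumor-group mean is shifted up by ``tumor_delta``. Informative site ids
    are recorded in the returned truth records.
    """
    groups = list(group_labels) if group_labels else [tumor_group, "pleura", "blood"]
    if tumor_group not in groups or len(groups) < 2:
        raise ValidationError("need >= 2 groups including the tumor group")
    rng = np.random.default_rng(config.seed)
    cpg_ids = [f"cg{i:06d}" for i in range(config.n_cpg)]
    informative = set(cpg_ids[: config.n_informative])

    sample_ids, sample_groups, rows = [], [], []
    for g in groups:
        for j in range(config.n_per_group):
            sample_ids.append(f"{g}_{j:03d}")
            sample_groups.append(g)
    means = np.full(config.n_cpg, config.control_beta_mean)
    tumor_means = means.copy()
    tumor_means[: config.n_informative] += config.tumor_delta

    for g_label in sample_groups:
        mu = tumor_means if g_label == tumor_group else means
        if config.noise_model == "none":
            row = mu.copy()
        else:
            a, b = zip(*(_beta_params(m, config.control_beta_sd) for m in mu))
            row = rng.beta(np.array(a), np.array(b))
        rows.append(np.clip(row, 0.0, 1.0))

    betas = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"), columns=cpg_ids)
    beta = BetaMatrix(betas=betas, groups=pd.Series(sample_groups, index=betas.index, name="group"))
    truth = [
        TruthRecord(
            feature_id=c,
            is_informative=c in informative,
            true_fraction={
                g: float(tumor_means[i] if g == tumor_group else means[i]) for g in groups
            },
        )
        for i, c in enumerate(cpg_ids)
    ]
    return beta, truth


def _random_context(rng: np.random.Generator, window: int = 41) -> tuple[str, int]:
    """Random ACGT window with a CG planted at its center."""
    off = window // 2
    seq = rng.choice(list("ACGT"), size=window)
    seq[off], seq[off + 1] = "C", "G"
    return "".join(seq), off


def _implant_site(seq: str, off: int, enzymes: EnzymeSet, rng: np.random.Generator) -> str:
    """Overwrite part of the window with a concrete enzyme recognition site
    whose CG aligns with the context CpG."""
    enz = enzymes.enzymes[rng.integers(len(enzymes.enzymes))]
    concrete = sorted(expand_iupac(enz.recognition))
    site = concrete[rng.integers(len(concrete))]
    cg_positions = [i for i in range(len(site) - 1) if site[i : i + 2] == "CG"]
    cg_at = cg_positions[rng.integers(len(cg_positions))]
    start = off - cg_at
    if start < 0 or start + len(site) > len(seq):
        raise ValidationError("context window too small for recognition site")
    return seq[:start] + site + seq[start + len(site) :]


def _scrub_sites(seq: str, off: int, enzymes: EnzymeSet, rng: np.random.Generator) -> str:
    """Rebuild the window from A/T plus the central CG until no enzyme site
    overlaps the CpG (used for deliberately non-assayable contexts)."""
    for _ in range(100):
        chars = rng.choice(list("AT"), size=len(seq))
        chars[off], chars[off + 1] = "C", "G"
        cand = "".join(chars)
        if not any(s < off + 2 and e > off for _, s, e in find_site_hits(cand, enzymes)):
            return cand
    raise ValidationError("could not construct an MSRE-free context")


def generate_target_panel(
    n_targets: int,
    enzyme_set: EnzymeSet = DEFAULT_ENZYMES,
    tiling_plan: tuple[int, int, int] = (270, 463, 11),
    seed: int = 0,
    cpg_ids: list[str] | None = None,
    msre_fraction: float = 1.0,
) -> TargetPanel:
    """Contexts plus probe tiling for ``n_targets`` CpG sites.

    Each context contains a recognition site of a randomly chosen enzyme
    overlapping the CpG, except for a ``1 - msre_fraction`` share built to
    contain none (to exercise the MSRE filter). Tiling multiplicities (1, 2
    or 3 probes per CpG) follow the proportions of ``tiling_plan``.
    """
    rng = np.random.default_rng(seed)
    ids = cpg_ids if cpg_ids is not None else [f"cg{i:06d}" for i in range(n_targets)]
    if len(ids) != n_targets:
        raise ValidationError("cpg_ids length must equal n_targets")
    plan = np.asarray(tiling_plan, dtype=float)
    if plan.sum() <= 0:
        raise ValidationError("tiling plan must have positive mass")
    # integer apportionment of multiplicities by largest remainder
    raw = plan / plan.sum() * n_targets
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: n_targets - counts.sum()]:
        counts[i] += 1
    multiplicities = np.repeat([1, 2, 3], counts)

    contexts: dict[str, CpGContext] = {}
    probe_rows = []
    for i, cpg in enumerate(ids):
        seq, off = _random_context(rng)
        if rng.random() < msre_fraction:
            seq = _implant_site(seq, off, enzyme_set, rng)
        else:
            seq = _scrub_sites(seq, off, enzyme_set, rng)
        contexts[cpg] = CpGContext(
            cpg_id=cpg, contig="chrS", position=1000 * i + off, sequence=seq, offset=off
        )
        for tile in range(multiplicities[i]):
            probe_rows.append({"probe_id": f"{cpg}_t{tile}", "cpg_id": cpg, "tile_index": tile})
    return TargetPanel(contexts=contexts, probes=pd.DataFrame(probe_rows))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2; the dispersion->0
    limit returns rounded expectations exactly (deterministic)."""
    mu = np.clip(mu, 0.0, None)
    if dispersion == 0:
        return np.round(mu).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + mu)
    out = np.zeros_like(mu, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def generate_count_matrix(
    assay_config: SyntheticAssayConfig,
    methylation_fractions: pd.DataFrame,
    aliquot_flags: pd.Series,
    sample_sheet: pd.DataFrame | None = None,
    digestion_efficiency: pd.Series | None = None,
    target_probe_cpgs: pd.Series | None = None,
) -> CountMatrix:
    """Simulate raw smMIP counts for a set of samples.

    Parameters
    ----------
    methylation_fractions : DataFrame
        samples x target probes, the methylated fraction m of each target in
        each sample.
    aliquot_flags : Series
        ``digested`` / ``undigested`` per sample.
    digestion_efficiency : Series, optional
        Per-sample digestion efficiency; defaults to the config value for
        every sample.
    target_probe_cpgs : Series, optional
        CpG id per target probe (for tiling annotation); defaults to one CpG
        per probe.
    """
    frac = methylation_fractions
    if ((frac.to_numpy() < 0) | (frac.to_numpy() > 1)).any():
        raise ValidationError("methylation fractions must lie in [0, 1]")
    if not frac.index.equals(aliquot_flags.index):
        aliquot_flags = aliquot_flags.reindex(frac.index)
        if aliquot_flags.isna().any():
            raise ValidationError("aliquot flags missing for some samples")
    if frac.shape[1] != assay_config.n_target_smmips:
        raise ValidationError(
            f"fractions have {frac.shape[1]} target probes, "
            f"config expects {assay_config.n_target_smmips}"
        )
    cfg = assay_config
    rng = np.random.default_rng(cfg.seed)

    roles = (
        [("target", p) for p in frac.columns]
        + [("human_ref_nocpg", f"href_nocpg_{i:03d}") for i in range(cfg.n_human_ref_nocpg)]
        + [("human_ref_nomsre", f"href_nomsre_{i:03d}") for i in range(cfg.n_human_ref_nomsre)]
        + [("lambda_cut", f"lambda_cut_{i:02d}") for i in range(cfg.n_lambda_cut)]
        + [("lambda_ref", f"lambda_ref_{i:02d}") for i in range(cfg.n_lambda_ref)]
    )
    probe_ids = [p for _, p in roles]
    role_arr = np.array([r for r, _ in roles])
    n_probes = len(probe_ids)

    lo, hi = cfg.capture_efficiency_range
    if lo == hi:
        capture = np.full(n_probes, float(lo))
    else:
        capture = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_probes))
    capture[np.isin(role_arr, ["lambda_cut", "lambda_ref"])] = 1.0  # designed-uniform spike-ins

    base = cfg.library_size_mean / n_probes
    cv = cfg.library_size_cv
    sigma2 = np.log1p(cv * cv)
    lib = np.exp(rng.normal(-sigma2 / 2, np.sqrt(sigma2), size=len(frac.index)))

    if digestion_efficiency is None:
        d_eff = pd.Series(cfg.digestion_efficiency, index=frac.index)
    else:
        d_eff = digestion_efficiency.reindex(frac.index)
        if d_eff.isna().any():
            raise ValidationError("digestion efficiency missing for some samples")

    is_target = role_arr == "target"
    is_lambda_cut = role_arr == "lambda_cut"
    counts = np.zeros((len(frac.index), n_probes), dtype=np.int64)
    for si, s in enumerate(frac.index):
        d = float(d_eff[s]) if aliquot_flags[s] == DIGESTED else 0.0
        surviving = np.ones(n_probes)
        m = frac.loc[s].to_numpy(dtype=float)
        surviving[is_target] = m + (1 - m) * (1 - d)
        surviving[is_lambda_cut] = 1 - d  # spike-in lambda DNA is unmethylated
        mu = lib[si] * base * capture * surviving
        counts[si] = _nb_draw(rng, mu, cfg.dispersion)

    if target_probe_cpgs is None:
        target_probe_cpgs = pd.Series(list(frac.columns), index=frac.columns)
    annot = pd.DataFrame(index=pd.Index(probe_ids, name="probe_id"))
    annot["role"] = role_arr
    annot["cpg_id"] = pd.NA
    annot.loc[frac.columns, "cpg_id"] = target_probe_cpgs.reindex(frac.columns).to_numpy()
    annot["tile_index"] = pd.NA
    annot.loc[frac.columns, "tile_index"] = (
        annot.loc[frac.columns].groupby("cpg_id").cumcount().to_numpy()
    )

    if sample_sheet is None:
        sample_sheet = pd.DataFrame(
            {"group": "unknown", "tissue_type": "unknown"}, index=frac.index
        )
    sheet = sample_sheet.copy()
    sheet["aliquot"] = aliquot_flags
    return CountMatrix(
        counts=pd.DataFrame(counts, index=frac.index, columns=probe_ids),
        probe_annotation=annot,
        sample_sheet=sheet,
    )


@dataclass
class TwoStepCohort:
    """A simulated assay cohort for the two-step classifier, with truth."""

    matrix: CountMatrix
    truth: list[TruthRecord]
    panel: TargetPanel


def generate_two_step_cohort(
    n_per_group: int = 20,
    n_targets: int = 60,
    n_informative_a: int = 20,
    n_informative_b: int = 10,
    methylated_level: float = 0.85,
    background_level: float = 0.08,
    n_undigested: int = 3,
    assay_config: SyntheticAssayConfig | None = None,
    seed: int = 0,
) -> TwoStepCohort:
    """Cohort of four tissue groups (pm, metastasis, pleura, pleuritis) with
    two informative target blocks: the first is methylated in all tumoral
    samples (drives the tumoral-vs-nontumoral model), the second only in PM
    (drives the PM-vs-metastasis model). Remaining targets are background.
    Adds ``n_undigested`` pooled undigested aliquots for the probe-efficiency
    filter.
    """
    if n_informative_a + n_informative_b > n_targets:
        raise ValidationError("informative blocks exceed the target count")
    rng = np.random.default_rng(seed)
    groups = ["pm", "metastasis", "pleura", "pleuritis"]
    tumoral = {"pm", "metastasis"}
    panel = generate_target_panel(
        n_targets, tiling_plan=(1, 0, 0), seed=int(rng.integers(2**31))
    )
    probe_ids = panel.probes["probe_id"].tolist()

    sample_ids, sample_groups = [], []
    for g in groups:
        for j in range(n_per_group):
            sample_ids.append(f"{g}_{j:03d}")
            sample_groups.append(g)
    for j in range(n_undigested):
        sample_ids.append(f"undig_{j:03d}")
        sample_groups.append("pool")

    frac = np.full((len(sample_ids), len(probe_ids)), background_level)
    jitter = rng.normal(0, 0.02, size=frac.shape)
    for si, g in enumerate(sample_groups):
        if g in tumoral:
            frac[si, :n_informative_a] = methylated_level
        if g == "pm":
            frac[si, n_informative_a : n_informative_a + n_informative_b] = methylated_level
    frac = np.clip(frac + jitter, 0.0, 1.0)
    frac_df = pd.DataFrame(frac, index=pd.Index(sample_ids, name="sample_id"), columns=probe_ids)

    aliquot = pd.Series(
        [UNDIGESTED if g == "pool" else DIGESTED for g in sample_groups], index=frac_df.index
    )
    sheet = pd.DataFrame(
        {"group": sample_groups, "tissue_type": sample_groups}, index=frac_df.index
    )
    cfg = assay_config or SyntheticAssayConfig(
        n_target_smmips=len(probe_ids), seed=int(rng.integers(2**31))
    )
    matrix = generate_count_matrix(
        cfg, frac_df, aliquot, sample_sheet=sheet,
        target_probe_cpgs=panel.probes.set_index("probe_id")["cpg_id"],
    )
    truth = []
    for pi, p in enumerate(probe_ids):
        in_a = pi < n_informative_a
        in_b = n_informative_a <= pi < n_informative_a + n_informative_b
        per_group = {
            g: methylated_level
            if (in_a and g in tumoral) or (in_b and g == "pm")
            else background_level
            for g in groups
        }
        truth.append(
            TruthRecord(feature_id=p, is_informative=in_a or in_b, true_fraction=per_group)
        )
    return TwoStepCohort(matrix=matrix, truth=truth, panel=panel)
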