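"""Synthetic cohort generator.

Patient cohorts carrying the statistical structure the downstream classifiers
assume — group-structured SBS96 spectra, tandem-duplication span profiles,
quantitative promoter methylation (complete > 98% vs partial 35–83%),
methylation-coupled BRCA1 expression, immune deconvolution scores with an
M1 effect on nonBRCA response, binary pCR outcomes, exponential survival
with group hazard ratios, and exponentially growing PDX tumor-volume series —
so that every pipeline stage is testable without controlled-access patient
data.

Group sizes and outcome frequencies default to the printed cohort
compositions (42-sample TNBC trial cohort: 9 BRCAmut / 11 BRCA1meth /
22 nonBRCA; PDX cohort response rates 10/11, 10/16, 5/16). A single integer
seed drives one deterministic sub-stream per table, so adding a table never
perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .brca_state import BRCA1_METH, BRCA_MUT, NON_BRCA, STATES
from .hrd import SBS96_CHANNELS, ReferenceSignatures, synthetic_signature_matrix
from .predictor import LM22_CELL_TYPES

# fixed per-table stream codes: a table's stream is default_rng([seed, code])
_STREAMS = {
    "groups": 11, "mutations": 12, "methylation": 13, "spectra": 14,
    "svs": 15, "expression": 16, "immune": 17, "outcomes": 18,
    "survival": 19, "pdx": 20,
}


def _table_rng(seed: int, table: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[table]])


@dataclass
class TdSpanMode:
    """One log-normal mode of the tandem-duplication span distribution."""

    median_bp: float
    sigma_log10: float
    count: int

    def __post_init__(self) -> None:
        if self.median_bp <= 0:
            raise ValueError("span modes must be strictly positive")


@dataclass
class GrowthConfig:
    """PDX growth-simulation parameters.

    Slopes are natural-log volume per day; ``noise_cv`` is the lognormal
    coefficient of variation of each measurement.
    """

    baseline_slope: float = 0.08
    responder_reduction: float = 0.09
    nonresponder_reduction: float = 0.01
    noise_cv: float = 0.1
    baseline_volume: float = 180.0
    days: tuple[float, ...] = (0, 3, 7, 10, 14, 17, 21, 24, 28)
    n_animals: int = 3

    def __post_init__(self) -> None:
        if self.baseline_volume <= 0:
            raise ValueError("baseline volume must be positive")
        if len(self.days) < 3:
            raise ValueError("need at least 3 timepoints")


@dataclass
class SurvivalConfig:
    """Exponential survival with per-group hazard ratios and uniform censoring."""

    baseline_median_days: float = 1100.0
    hazard_ratio_per_group: dict = field(
        default_factory=lambda: {BRCA_MUT: 0.5, BRCA1_METH: 0.9, NON_BRCA: 1.0}
    )
    censor_window_days: float = 3000.0


@dataclass
class CohortConfig:
    """Full parameterisation of one synthetic cohort. Seed-deterministic."""

    n_per_group: dict = field(
        default_factory=lambda: {BRCA_MUT: 9, BRCA1_METH: 11, NON_BRCA: 22}
    )
    pcr_prob_per_group: dict = field(
        default_factory=lambda: {BRCA_MUT: 8 / 9, BRCA1_METH: 3 / 11, NON_BRCA: 0.30}
    )
    #: nonBRCA pCR probability is M1-dependent when these are set
    nonbrca_pcr_prob_m1_high: float = 0.75
    nonbrca_pcr_prob_m1_low: float = 0.10
    pdx_response_prob_per_group: dict = field(
        default_factory=lambda: {BRCA_MUT: 10 / 11, BRCA1_METH: 10 / 16, NON_BRCA: 5 / 16}
    )
    meth_complete_range: tuple[float, float] = (98.2, 100.0)
    meth_partial_range: tuple[float, float] = (35.4, 82.8)
    meth_complete_fraction: float = 11 / 16
    meth_expr_correlation: float = -0.82
    sbs3_fraction_per_group: dict = field(
        default_factory=lambda: {BRCA_MUT: 0.45, BRCA1_METH: 0.45, NON_BRCA: 0.02}
    )
    n_mutations_per_sample: int = 3000
    td_span_profile_per_group: dict = field(
        default_factory=lambda: {
            BRCA_MUT: [TdSpanMode(11_000, 0.18, 80)],
            BRCA1_METH: [TdSpanMode(11_000, 0.18, 80)],
            NON_BRCA: [TdSpanMode(600_000, 0.35, 10)],
        }
    )
    n_background_svs: int = 12
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    n_expression_genes: int = 200
    m1_score_mean: float = 0.05
    m1_score_sd: float = 0.02
    signatures: ReferenceSignatures | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            list(self.pcr_prob_per_group.values())
            + list(self.pdx_response_prob_per_group.values())
            + [self.nonbrca_pcr_prob_m1_high, self.nonbrca_pcr_prob_m1_low,
               self.meth_complete_fraction]
        )
        for p in probs:
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        for g, f in self.sbs3_fraction_per_group.items():
            if not 0 <= f <= 1:
                raise ValueError(f"SBS3 fraction for {g} outside [0, 1]")
        for rng_ in (self.meth_complete_range, self.meth_partial_range):
            if not 0 <= rng_[0] <= rng_[1] <= 100:
                raise ValueError("methylation ranges must be ordered within [0, 100]")
        if not -1 <= self.meth_expr_correlation <= 0:
            raise ValueError("meth_expr_correlation must lie in [-1, 0]")
        for g, modes in self.td_span_profile_per_group.items():
            self.td_span_profile_per_group[g] = [
                m if isinstance(m, TdSpanMode) else TdSpanMode(*m) for m in modes
            ]
        if self.n_mutations_per_sample <= 0:
            raise ValueError("n_mutations_per_sample must be positive")

    @property
    def reference_signatures(self) -> ReferenceSignatures:
        return self.signatures if self.signatures is not None else synthetic_signature_matrix()


@dataclass
class CohortTables:
    """All per-sample tables of one synthetic cohort, cross-referenced by id."""

    samples: pd.DataFrame
    mutations: pd.DataFrame
    methylation: pd.DataFrame
    spectra: pd.DataFrame  # samples x 96 channels
    svs: pd.DataFrame
    expression: pd.DataFrame  # genes x samples
    meth_expression: pd.DataFrame  # sample_id, meth_percent, brca1_log2_expression
    immune: pd.DataFrame  # samples x 22 cell types
    outcomes: pd.DataFrame
    pdx_volumes: pd.DataFrame


def _signature_mixture(config: CohortConfig, group: str) -> np.ndarray:
    """Per-group 96-channel emission probabilities: sbs3_fraction of the flat
    HRD signature plus a fixed clock/APOBEC background."""
    sigs = config.reference_signatures
    if group not in config.sbs3_fraction_per_group:
        raise KeyError(f"no configured SBS3 fraction for group {group!r}")
    f = config.sbs3_fraction_per_group[group]
    background = (
        0.35 * sigs.column("SBS1")
        + 0.20 * sigs.column("SBS2")
        + 0.35 * sigs.column("SBS5")
        + 0.10 * sigs.column("SBS13")
    )
    return f * sigs.column("SBS3") + (1 - f) * background


def generate_spectrum(
    group: str, n_mutations: int, rng: np.random.Generator, config: CohortConfig | None = None
) -> np.ndarray:
    """Multinomial SBS96 draw from the group's configured signature mixture."""
    config = config or CohortConfig()
    if n_mutations <= 0:
        raise ValueError("n_mutations must be positive")
    return rng.multinomial(n_mutations, _signature_mixture(config, group)).astype(float)


def generate_sv_set(
    group: str,
    rng: np.random.Generator,
    config: CohortConfig | None = None,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Structural-variant table for one genome: TDs drawn from the group's
    log-normal span mixture plus a non-TD rearrangement background."""
    config = config or CohortConfig()
    if group not in config.td_span_profile_per_group:
        raise KeyError(f"no configured TD span profile for group {group!r}")
    rows = []
    for mode in config.td_span_profile_per_group[group]:
        spans = 10 ** rng.normal(np.log10(mode.median_bp), mode.sigma_log10, mode.count)
        for span in spans:
            chrom = f"chr{rng.integers(1, 23)}"
            pos1 = int(rng.integers(1_000_000, 200_000_000))
            rows.append((sample_id, chrom, pos1, chrom, pos1 + max(1, int(span)), "TD"))
    for _ in range(config.n_background_svs):
        kind = rng.choice(["DEL", "INV", "TRA"])
        chrom = f"chr{rng.integers(1, 23)}"
        pos1 = int(rng.integers(1_000_000, 200_000_000))
        if kind == "TRA":
            chrom2 = f"chr{rng.integers(1, 23)}"
            while chrom2 == chrom:
                chrom2 = f"chr{rng.integers(1, 23)}"
            rows.append((sample_id, chrom, pos1, chrom2, int(rng.integers(1_000_000, 200_000_000)), "TRA"))
        else:
            rows.append((sample_id, chrom, pos1, chrom, pos1 + int(rng.integers(5_000, 2_000_000)), kind))
    return pd.DataFrame(rows, columns=["sample_id", "chrom1", "pos1", "chrom2", "pos2", "sv_type"])


@dataclass
class PdxModelSpec:
    model_id: str
    control_slope: float
    treatment_reduction: float
    growth: GrowthConfig = field(default_factory=GrowthConfig)

    def __post_init__(self) -> None:
        if self.growth.baseline_volume <= 0:
            raise ValueError("baseline volume must be positive")


def generate_pdx_trajectories(spec: PdxModelSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Exponential-growth volume series for one PDX model, two arms.

    ln(volume) grows at ``control_slope`` (control arm) or ``control_slope -
    treatment_reduction`` (treated arm) with iid lognormal measurement noise.
    """
    g = spec.growth
    sigma = np.sqrt(np.log(1 + g.noise_cv**2)) if g.noise_cv > 0 else 0.0
    rows = []
    for arm, slope in (("control", spec.control_slope),
                       ("treated", spec.control_slope - spec.treatment_reduction)):
        for a in range(g.n_animals):
            animal = f"{spec.model_id}-{arm}-{a}"
            for day in g.days:
                noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
                vol = g.baseline_volume * np.exp(slope * day + noise)
                rows.append((spec.model_id, arm, animal, float(day), float(vol)))
    return pd.DataFrame(rows, columns=["model_id", "arm", "animal_id", "day", "volume_mm3"])


def _generate_methylation(config: CohortConfig, sample_ids, rng) -> pd.DataFrame:
    rows = []
    for sid in sample_ids:
        complete = rng.random() < config.meth_complete_fraction
        lo, hi = config.meth_complete_range if complete else config.meth_partial_range
        rows.append(
            (sid, float(rng.uniform(lo, hi)), None, "complete" if complete else "partial")
        )
    return pd.DataFrame(rows, columns=["sample_id", "raw_percent", "cellularity", "msp_call"])


def _coupled_expression(config: CohortConfig, meth_percent: np.ndarray, rng) -> np.ndarray:
    """BRCA1 log2 expression coupled to methylation.

    Signal is log2(1 - 0.99 * meth/100) (multiplicative silencing on the log
    scale); Gaussian noise is scaled so the signal:total variance ratio
    matches the target Pearson correlation magnitude.
    """
    r = abs(config.meth_expr_correlation)
    signal = np.log2(1.0 - 0.99 * meth_percent / 100.0)
    baseline = 6.0  # arbitrary log2 abundance origin
    if r >= 1.0 or np.std(signal) == 0:
        return baseline + signal
    noise_sd = np.std(signal) * np.sqrt(1.0 / r**2 - 1.0)
    return baseline + signal + rng.normal(0.0, noise_sd, len(signal))


def generate_cohort(config: CohortConfig | None = None) -> CohortTables:
    """Generate one full synthetic cohort (all tables, fixed-seed deterministic)."""
    config = config or CohortConfig()
    for g in config.n_per_group:
        if g not in STATES:
            raise ValueError(f"unknown group {g!r}")

    sample_ids, groups = [], []
    for g in STATES:
        for i in range(config.n_per_group.get(g, 0)):
            sample_ids.append(f"{g}-{i:04d}")
            groups.append(g)
    samples = pd.DataFrame({"sample_id": sample_ids, "group": groups})

    rng = _table_rng(config.seed, "mutations")
    mut_rows = []
    for sid, g in zip(sample_ids, groups):
        if g == BRCA_MUT:
            gene = "BRCA1" if rng.random() < 8 / 11 else "BRCA2"
            origin = "germline" if rng.random() < 0.6 else "somatic"
            mut_rows.append((sid, gene, True, origin))
    mutations = pd.DataFrame(mut_rows, columns=["sample_id", "gene", "pathogenic", "origin"])

    meth_ids = [s for s, g in zip(sample_ids, groups) if g == BRCA1_METH]
    methylation = _generate_methylation(config, meth_ids, _table_rng(config.seed, "methylation"))

    rng = _table_rng(config.seed, "spectra")
    spectra = pd.DataFrame(
        [generate_spectrum(g, config.n_mutations_per_sample, rng, config) for g in groups],
        index=sample_ids,
        columns=list(SBS96_CHANNELS),
    )

    rng = _table_rng(config.seed, "svs")
    svs = pd.concat(
        [generate_sv_set(g, rng, config, sample_id=sid) for sid, g in zip(sample_ids, groups)],
        ignore_index=True,
    )

    rng = _table_rng(config.seed, "expression")
    expression = pd.DataFrame(
        rng.lognormal(3.0, 1.0, (config.n_expression_genes, len(sample_ids))),
        index=[f"GENE{i:04d}" for i in range(config.n_expression_genes)],
        columns=sample_ids,
    )
    meth_pct = np.zeros(len(sample_ids))
    meth_map = dict(zip(methylation["sample_id"], methylation["raw_percent"]))
    for i, sid in enumerate(sample_ids):
        meth_pct[i] = meth_map.get(sid, 0.0)
    if meth_ids:
        idx = [i for i, sid in enumerate(sample_ids) if sid in meth_map]
        brca1_log2 = np.full(len(sample_ids), 6.0) + rng.normal(0, 0.3, len(sample_ids))
        brca1_log2[idx] = _coupled_expression(config, meth_pct[idx], rng)
    else:
        brca1_log2 = np.full(len(sample_ids), 6.0) + rng.normal(0, 0.3, len(sample_ids))
    expression.loc["BRCA1"] = 2.0**brca1_log2
    meth_expression = pd.DataFrame(
        {"sample_id": sample_ids, "meth_percent": meth_pct, "brca1_log2_expression": brca1_log2}
    )

    rng = _table_rng(config.seed, "immune")
    immune = pd.DataFrame(
        np.abs(rng.normal(config.m1_score_mean, config.m1_score_sd,
                          (len(sample_ids), len(LM22_CELL_TYPES)))),
        index=sample_ids,
        columns=list(LM22_CELL_TYPES),
    )

    rng = _table_rng(config.seed, "outcomes")
    m1 = immune["Macrophages M1"]
    nonbrca_median = float(np.median(m1[[g == NON_BRCA for g in groups]])) if NON_BRCA in groups else 0.0
    pcr = []
    for sid, g in zip(sample_ids, groups):
        if g == NON_BRCA:
            p = (config.nonbrca_pcr_prob_m1_high if m1[sid] > nonbrca_median
                 else config.nonbrca_pcr_prob_m1_low)
        else:
            p = config.pcr_prob_per_group[g]
        pcr.append(bool(rng.random() < p))

    rng = _table_rng(config.seed, "survival")
    surv = config.survival
    base_rate = np.log(2) / surv.baseline_median_days
    times, events, debulk = [], [], []
    for sid, g in zip(sample_ids, groups):
        rate = base_rate * surv.hazard_ratio_per_group.get(g, 1.0)
        t = rng.exponential(1.0 / rate)
        c = rng.uniform(0, surv.censor_window_days)
        times.append(float(min(t, c)))
        events.append(bool(t <= c))
        debulk.append("optimal" if rng.random() < 0.6 else "suboptimal")
    outcomes = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "pcr": pcr,
            "survival_time": times,
            "event": events,
            "debulking": debulk,
        }
    )

    rng = _table_rng(config.seed, "pdx")
    g_cfg = config.growth
    pdx_frames = []
    for sid, g in zip(sample_ids, groups):
        responder = rng.random() < config.pdx_response_prob_per_group[g]
        spec = PdxModelSpec(
            model_id=sid,
            control_slope=g_cfg.baseline_slope,
            treatment_reduction=(
                g_cfg.responder_reduction if responder else g_cfg.nonresponder_reduction
            ),
            growth=g_cfg,
        )
        pdx_frames.append(generate_pdx_trajectories(spec, rng))
    pdx_volumes = (
        pd.concat(pdx_frames, ignore_index=True)
        if pdx_frames
        else pd.DataFrame(columns=["model_id", "arm", "animal_id", "day", "volume_mm3"])
    )

    return CohortTables(
        samples=samples,
        mutations=mutations,
        methylation=methylation,
        spectra=spectra,
        svs=svs,
        expression=expression,
        meth_expression=meth_expression,
        immune=immune,
        outcomes=outcomes,
        pdx_volumes=pdx_volumes,
    )


def generate_outcome_cohort(config: CohortConfig) -> pd.DataFrame:
    """Lightweight cohort: only group labels, M1 scores and pCR outcomes.

    Used for repeated-cohort evaluation studies where the genomic tables are
    not needed; shares the immune/outcome streams with :func:`generate_cohort`
    so the two agree for a given seed.
    """
    sample_ids, groups = [], []
    for g in STATES:
        for i in range(config.n_per_group.get(g, 0)):
            sample_ids.append(f"{g}-{i:04d}")
            groups.append(g)
    rng = _table_rng(config.seed, "immune")
    m1 = pd.Series(
        np.abs(rng.normal(config.m1_score_mean, config.m1_score_sd,
                          (len(sample_ids), len(LM22_CELL_TYPES))))[:, LM22_CELL_TYPES.index("Macrophages M1")],
        index=sample_ids,
    )
    rng = _table_rng(config.seed, "outcomes")
    nonbrca_mask = np.array([g == NON_BRCA for g in groups])
    nonbrca_median = float(np.median(m1[nonbrca_mask])) if nonbrca_mask.any() else 0.0
    pcr = []
    for sid, g in zip(sample_ids, groups):
        if g == NON_BRCA:
            p = (config.nonbrca_pcr_prob_m1_high if m1[sid] > nonbrca_median
                 else config.nonbrca_pcr_prob_m1_low)
        else:
            p = config.pcr_prob_per_group[g]
        pcr.append(bool(rng.random() < p))
    return pd.DataFrame(
        {"sample_id": sample_ids, "group": groups, "m1_score": m1.to_numpy(), "pcr": pcr}
    )
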