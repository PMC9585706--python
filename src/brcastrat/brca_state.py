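"""BRCA-state assignment: BRCAmut / BRCA1meth / nonBRCA.

Tumors are partitioned into three mutually exclusive states: carriers of a
pathogenic BRCA1 or BRCA2 mutation (``BRCAmut``), tumors silencing BRCA1
through promoter hypermethylation (``BRCA1meth``), and tumors proficient for
both genes with no methylation call (``nonBRCA``). A pathogenic mutation takes
precedence over methylation. BRCA2 promoter methylation is never assessed
(epigenetic BRCA2 silencing is vanishingly rare).

Quantitative promoter methylation (MS-ddPCR percentages) is corrected for
neoplastic cellularity where available (``raw / cellularity``, capped at 100)
and dichotomised at a cohort-dependent threshold: 70% where cellularity was
assessed (ovarian cohorts), 60% where it was not (TNBC, absorbing ~10% normal
contamination). Array-based calls average the beta-values of the four minimal
promoter probes and call methylation above 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

BRCA_MUT = "BRCAmut"
BRCA1_METH = "BRCA1meth"
NON_BRCA = "nonBRCA"
STATES = (BRCA_MUT, BRCA1_METH, NON_BRCA)

#: Illumina array probes spanning the BRCA1 minimal promoter.
DEFAULT_BETA_PROBES = ("cg19531713", "cg19088651", "cg08993267", "cg04658354")


@dataclass
class MutationRecord:
    sample_id: str
    gene: str  # BRCA1 | BRCA2
    pathogenic: bool
    origin: str = "unknown"  # germline | somatic | unknown

    def __post_init__(self) -> None:
        if self.gene not in ("BRCA1", "BRCA2"):
            raise ValueError(f"gene must be BRCA1 or BRCA2, got {self.gene!r}")


@dataclass
class MethylationRecord:
    """One quantitative (MS-ddPCR) promoter methylation measurement."""

    sample_id: str
    raw_percent: float
    cellularity: float | None = None
    msp_call: str | None = None  # none | partial | complete

    def __post_init__(self) -> None:
        if not 0 <= self.raw_percent <= 100:
            raise ValueError("raw_percent must lie in [0, 100]")
        if self.cellularity is not None and not 0 < self.cellularity <= 1:
            raise ValueError("cellularity must lie in (0, 1]")

    @property
    def corrected_percent(self) -> float:
        return correct_methylation(self.raw_percent, self.cellularity)


@dataclass
class MethylationConfig:
    """Methylation dichotomisation thresholds.

    ``high_threshold_percent`` defaults to 70 (cellularity-corrected ovarian
    convention); use 60 for TNBC cohorts without cellularity assessment.
    """

    high_threshold_percent: float = 70.0
    beta_probe_ids: tuple[str, ...] = DEFAULT_BETA_PROBES
    beta_threshold: float = 0.4

    def __post_init__(self) -> None:
        if not 0 < self.high_threshold_percent <= 100:
            raise ValueError("high_threshold_percent must lie in (0, 100]")
        if not 0 < self.beta_threshold < 1:
            raise ValueError("beta_threshold must lie in (0, 1)")

    @classmethod
    def for_cohort(cls, cohort_type: str) -> "MethylationConfig":
        if cohort_type.lower() in ("ovca", "ovarian"):
            return cls(high_threshold_percent=70.0)
        if cohort_type.lower() in ("tnbc", "pdx"):
            return cls(high_threshold_percent=60.0)
        raise ValueError(f"unknown cohort type {cohort_type!r}")


@dataclass
class BrcaState:
    sample_id: str
    state: str  # BRCAmut | BRCA1meth | nonBRCA
    meth_level: str = "none"  # high | low | none
    basis: str = ""

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.meth_level not in ("high", "low", "none"):
            raise ValueError(f"unknown methylation level {self.meth_level!r}")


def correct_methylation(raw_percent: float, cellularity: float | None) -> float:
    """Rescale a methylation percentage to the neoplastic fraction.

    ``corrected = min(100, raw / cellularity)``; with no cellularity estimate
    the raw value passes through unchanged.
    """
    if not 0 <= raw_percent <= 100:
        raise ValueError("raw_percent must lie in [0, 100]")
    if cellularity is None:
        return float(raw_percent)
    if cellularity <= 0 or cellularity > 1:
        raise ValueError("cellularity must lie in (0, 1]")
    return float(min(100.0, raw_percent / cellularity))


def classify_methylation_level(
    corrected_percent: float, config: MethylationConfig | None = None
) -> str:
    """Dichotomise a corrected methylation percentage: high iff >= threshold."""
    config = config or MethylationConfig()
    if not 0 <= corrected_percent <= 100:
        raise ValueError("corrected_percent must lie in [0, 100]")
    return "high" if corrected_percent >= config.high_threshold_percent else "low"


def classify_beta_methylation(
    beta_values: dict[str, float], config: MethylationConfig | None = None
) -> bool:
    """Array-based methylation call: mean beta over the promoter probes > 0.4.

    Only the configured probes participate; at least one must be present.
    """
    config = config or MethylationConfig()
    present = [beta_values[p] for p in config.beta_probe_ids if p in beta_values]
    if not present:
        raise ValueError("none of the configured promoter probes are present")
    return float(np.mean(present)) > config.beta_threshold


def assign_brca_state(
    mutations: list[MutationRecord],
    methylation: MethylationRecord | None,
    config: MethylationConfig | None = None,
    sample_id: str | None = None,
) -> BrcaState:
    """Assign one sample's BRCA state from its mutation and methylation records.

    Pathogenic BRCA1/2 mutations take precedence; otherwise a methylation
    record yields BRCA1meth with a high/low level; otherwise nonBRCA.
    """
    config = config or MethylationConfig()
    pathogenic = [m for m in mutations if m.pathogenic]
    if sample_id is None:
        if pathogenic:
            sample_id = pathogenic[0].sample_id
        elif methylation is not None:
            sample_id = methylation.sample_id
        else:
            raise ValueError("sample_id required when no records are supplied")
    if pathogenic:
        genes = sorted({m.gene for m in pathogenic})
        return BrcaState(
            sample_id=sample_id,
            state=BRCA_MUT,
            meth_level="none",
            basis=f"pathogenic {'/'.join(genes)} mutation",
        )
    if methylation is not None:
        corrected = methylation.corrected_percent
        level = classify_methylation_level(corrected, config)
        return BrcaState(
            sample_id=sample_id,
            state=BRCA1_METH,
            meth_level=level,
            basis=f"promoter methylation {corrected:.1f}% ({level})",
        )
    return BrcaState(sample_id=sample_id, state=NON_BRCA, meth_level="none", basis="no BRCA alteration")


class BrcaStateClassifier(BaseEstimator):
    """Cohort-level BRCA-state assignment as an sklearn-style estimator.

    Parameters
    ----------
    high_threshold_percent : float, default 70
        Complete-methylation cutoff (70 ovarian / 60 TNBC convention).
    beta_threshold : float, default 0.4
        Array beta-value cutoff for the promoter probes.
    """

    def __init__(self, high_threshold_percent: float = 70.0, beta_threshold: float = 0.4):
        self.high_threshold_percent = high_threshold_percent
        self.beta_threshold = beta_threshold

    def fit(self, X=None, y=None):
        self.config_ = MethylationConfig(
            high_threshold_percent=self.high_threshold_percent,
            beta_threshold=self.beta_threshold,
        )
        return self

    def predict(
        self, mutations: pd.DataFrame, methylation: pd.DataFrame, sample_ids=None
    ) -> pd.DataFrame:
        """Assign states for a cohort.

        ``mutations``: columns sample_id, gene, pathogenic[, origin].
        ``methylation``: columns sample_id, raw_percent[, cellularity, msp_call];
        at most one row per sample (duplicates raise).
        ``sample_ids``: optional full roster; samples absent from both tables
        become nonBRCA.
        """
        if not hasattr(self, "config_"):
            self.fit()
        dup = methylation["sample_id"].duplicated()
        if dup.any():
            raise ValueError(
                "conflicting duplicate methylation records for "
                f"{sorted(methylation.loc[dup, 'sample_id'].unique())}"
            )
        if sample_ids is None:
            sample_ids = sorted(
                set(mutations["sample_id"]) | set(methylation["sample_id"])
            )
        mut_by_sample = {
            sid: [
                MutationRecord(
                    sample_id=sid,
                    gene=row.gene,
                    pathogenic=bool(row.pathogenic),
                    origin=getattr(row, "origin", "unknown"),
                )
                for row in grp.itertuples()
            ]
            for sid, grp in mutations.groupby("sample_id")
        }
        meth_by_sample = {}
        for row in methylation.itertuples():
            cellularity = getattr(row, "cellularity", None)
            if cellularity is not None and pd.isna(cellularity):
                cellularity = None
            meth_by_sample[row.sample_id] = MethylationRecord(
                sample_id=row.sample_id,
                raw_percent=float(row.raw_percent),
                cellularity=cellularity,
            )
        states = [
            assign_brca_state(
                mut_by_sample.get(sid, []),
                meth_by_sample.get(sid),
                self.config_,
                sample_id=sid,
            )
            for sid in sample_ids
        ]
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in states],
                "state": [s.state for s in states],
                "meth_level": [s.meth_level for s in states],
                "basis": [s.basis for s in states],
            }
        )
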