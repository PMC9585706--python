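"""Orchestration: run every classifier over a cohort and evaluate the
stratifications.

The report joins, per sample, the BRCA state, the sequence-based HRD call,
the TDP call and the decision-tree prediction, and compares the predictive
accuracy of three stratifications against the pCR outcome: BRCA status alone
(BRCAmut predicts response), HRD status alone (HRD-high predicts response)
and the combined BRCA + M1 criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .brca_state import BRCA_MUT, BrcaStateClassifier, MethylationConfig
from .hrd import HrdConfig, SignatureRefitter
from .predictor import (
    NON_RESPONDER,
    RESPONDER,
    ResponseTreeClassifier,
    evaluate_predictions,
)
from .simulate import CohortConfig, CohortTables, generate_cohort
from .tdp import TdpClassifier

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cohort_type: str = "tnbc"  # tnbc | ovca | pdx
    methylation: MethylationConfig | None = None
    hrd: HrdConfig = field(default_factory=HrdConfig)
    seed: int = 0
    cohort: CohortConfig | None = None

    def __post_init__(self) -> None:
        if self.methylation is None:
            self.methylation = MethylationConfig.for_cohort(self.cohort_type)


def run_pipeline(config: PipelineConfig | None = None, tables: CohortTables | None = None) -> dict:
    """Run the full stratification over a cohort (generated if not supplied).

    Returns a dict with ``per_sample`` (one row per sample joining all calls)
    and ``evaluation`` (accuracy of brca-only / hrd-only / combined
    stratifications against pCR).
    """
    config = config or PipelineConfig()
    if tables is None:
        cohort_cfg = config.cohort or CohortConfig(seed=config.seed)
        tables = generate_cohort(cohort_cfg)

    states = (
        BrcaStateClassifier(high_threshold_percent=config.methylation.high_threshold_percent)
        .fit()
        .predict(
            tables.mutations,
            tables.methylation,
            sample_ids=list(tables.samples["sample_id"]),
        )
    )

    refitter = SignatureRefitter().fit()
    contributions = refitter.transform(tables.spectra.to_numpy())
    hrd_status = [
        "high" if c > config.hrd.sbs3_threshold else "low"
        for c in contributions["SBS3"]
    ]
    hrd = pd.DataFrame(
        {
            "sample_id": tables.spectra.index,
            "sbs3_contribution": contributions["SBS3"].to_numpy(),
            "hrd_status": hrd_status,
        }
    )

    tdp = TdpClassifier().fit().predict(tables.svs)

    per_sample = (
        tables.samples.merge(states, on="sample_id")
        .merge(hrd, on="sample_id", how="left")
        .merge(tdp[["sample_id", "tdp_status", "group_label"]], on="sample_id", how="left")
    )

    if tables.immune is not None and not tables.immune.empty:
        m1 = tables.immune["Macrophages M1"].reindex(per_sample["sample_id"])
        tree_input = pd.DataFrame(
            {
                "sample_id": per_sample["sample_id"].to_numpy(),
                "state": per_sample["state"].to_numpy(),
                "m1_score": m1.to_numpy(),
            }
        )
        tree = ResponseTreeClassifier().fit(tree_input)
        preds = tree.predict_detailed(tree_input)
        per_sample["predicted"] = [p.predicted for p in preds]
        per_sample["branch"] = [p.branch for p in preds]
    else:
        logger.warning("no immune table: nonBRCA predictions are unpredictable")
        per_sample["predicted"] = [
            RESPONDER if s == BRCA_MUT else ("non-responder" if s == "BRCA1meth" else "unpredictable")
            for s in per_sample["state"]
        ]
        per_sample["branch"] = "no_m1_score"

    evaluation = {}
    if tables.outcomes is not None and "pcr" in tables.outcomes.columns:
        outcomes = tables.outcomes.set_index("sample_id")["pcr"]
        idx = per_sample.set_index("sample_id")
        combined = evaluate_predictions(idx["predicted"], outcomes)
        brca_only = evaluate_predictions(
            idx["state"].map(lambda s: RESPONDER if s == BRCA_MUT else NON_RESPONDER),
            outcomes,
        )
        hrd_only = evaluate_predictions(
            idx["hrd_status"].map(lambda s: RESPONDER if s == "high" else NON_RESPONDER),
            outcomes,
        )
        evaluation = {
            "combined": combined,
            "brca_only": brca_only,
            "hrd_only": hrd_only,
        }

    return {"per_sample": per_sample, "evaluation": evaluation}
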