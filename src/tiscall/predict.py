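"""Apply a trained model to new transcripts: the scan-and-score workflow."""

from __future__ import annotations

from typing import Callable, Mapping

import pandas as pd

from .conservation import OrthologPair
from .features import EfficiencyTable, FeatureConfig, build_feature_matrix
from .model import TrainedModel, confidence_class
from .transcripts import Transcript, enumerate_candidates

__all__ = ["predict_candidates"]


def predict_candidates(
    transcript: Transcript,
    model: TrainedModel,
    efficiency_table: EfficiencyTable,
    *,
    pair: OrthologPair | None = None,
    threshold: float | None = None,
    mfe_engine: Callable[[str], float] | None = None,
    config: FeatureConfig = FeatureConfig(),
    with_features: bool = False,
) -> pd.DataFrame:
    """Enumerate all eligible start candidates and predict their confidences.

    Returns one row per candidate (sorted by position) with codon, frame, ORF
    length, clamped initiation confidence and qualitative confidence class;
    ``with_features`` appends all feature columns.  An ineligible transcript
    yields an empty, schema-complete frame.
    """
    t = model.threshold if threshold is None else threshold
    candidates = enumerate_candidates(transcript, window=config.flank)
    base_cols = ["transcript_id", "position", "codon", "frame",
                 "orf_length_nt", "confidence", "confidence_class"]
    if not candidates:
        return pd.DataFrame(columns=base_cols)

    X, meta = build_feature_matrix(
        candidates, {transcript.id: transcript},
        {transcript.id: pair} if pair is not None else None,
        efficiency_table, pwm_model=model.pwm,
        mfe_engine=mfe_engine, config=config,
    )
    conf = model.predict_confidence(X)
    out = pd.DataFrame(
        {
            "transcript_id": [c.transcript_id for c in candidates],
            "position": [c.position for c in candidates],
            "codon": [c.codon for c in candidates],
            "frame": [c.frame for c in candidates],
            "orf_length_nt": [c.orf_length_nt for c in candidates],
            "confidence": conf,
            "confidence_class": [confidence_class(v, t) for v in conf],
        }
    )
    if with_features:
        out = pd.concat([out, X.reset_index(drop=True)], axis=1)
    return out.sort_values("position").reset_index(drop=True)
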