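"""In-silico SNP analysis of start-site flanking contexts.

Every non-codon position of the context window (by default 15 nt upstream and
10 nt downstream of the codon, 25 positions) is substituted by the three
alternative nucleotides, features are recomputed from the mutated sequence, and
the trained model is re-applied.  The default window therefore yields 75
variant contexts per candidate; the change against the unmutated sequence is
reported as IC_difference = IC_mutation - IC_wildtype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import OrthologPair, align_orthologs
from .features import (
    ContextWindow,
    EfficiencyTable,
    FeatureConfig,
    extract_features,
)
from .model import TrainedModel
from .transcripts import StartCandidate, Transcript, orf_length_at

log = logging.getLogger(__name__)

NT_ORDER = "ACGU"


@dataclass
class MutationMatrix:
    """Predicted confidences for all single-nucleotide context variants.

    ``confidence`` is a 4 x P frame (rows A/C/G/U, columns Kozak positions);
    wildtype cells carry the wildtype confidence so their IC difference is
    exactly zero.  Codon positions are absent by construction.
    """

    transcript_id: str
    position: int
    codon: str
    wildtype_confidence: float
    wildtype_nt: dict[int, str]
    confidence: pd.DataFrame
    threshold: float

    @property
    def ic_difference(self) -> pd.DataFrame:
        return self.confidence - self.wildtype_confidence

    @property
    def above_threshold(self) -> pd.DataFrame:
        return self.confidence >= self.threshold

    @property
    def n_variants(self) -> int:
        """Number of non-wildtype cells (mutable positions x 3)."""
        return sum(
            1
            for pos in self.confidence.columns
            for nt in self.confidence.index
            if nt != self.wildtype_nt[pos]
        )


def _mutate(transcript: Transcript, index: int, nt: str) -> Transcript:
    seq = transcript.sequence
    return Transcript(
        transcript.id, seq[:index] + nt + seq[index + 1 :], transcript.cds_start
    )


def _refresh_candidate(
    candidate: StartCandidate, transcript: Transcript, flank: int
) -> StartCandidate:
    """Re-derive windows and ORF length of a candidate on a mutated sequence.

    A downstream substitution may create or destroy stop codons; if the last
    in-frame stop is lost the ORF length falls back to the in-frame distance to
    the transcript end.
    """
    i = candidate.index
    seq = transcript.sequence
    orf_len = orf_length_at(seq, i)
    if orf_len is None:
        orf_len = ((len(seq) - i) // 3) * 3
        log.warning(
            "mutation removed the downstream in-frame stop of %s:%d; "
            "open ORF length %d used",
            candidate.transcript_id, candidate.position, orf_len,
        )
    return replace(
        candidate,
        upstream_window=seq[i - flank : i],
        downstream_window=seq[i + 3 : i + 3 + flank],
        orf_length_nt=orf_len,
    )


def snp_scan(
    candidate: StartCandidate,
    transcript: Transcript,
    model: TrainedModel,
    efficiency_table: EfficiencyTable,
    *,
    pair: OrthologPair | None = None,
    window: ContextWindow | None = None,
    freeze_conservation: bool = False,
    mfe_engine: Callable[[str], float] | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> MutationMatrix:
    """Mutate every non-codon context position and re-predict the confidence.

    ``window`` defaults to the model's PWM window (or the standard 15/10
    context).  All affected features are recomputed from the mutated sequence;
    with ``freeze_conservation`` the wildtype ortholog alignment is reused
    instead of realigning against the mutated primary.
    """
    if window is None:
        window = model.pwm.window if model.pwm is not None else ContextWindow()

    def predict_one(cand, tx, tx_pair):
        feats = extract_features(
            cand, tx, tx_pair, model.pwm, efficiency_table,
            mfe_engine=mfe_engine, config=config,
        )
        return float(model.predict_confidence(feats)[0])

    wt_conf = predict_one(candidate, transcript, pair)

    positions = list(window.mutable_positions)
    wildtype_nt: dict[int, str] = {}
    grid = pd.DataFrame(
        np.nan, index=list(NT_ORDER), columns=positions, dtype=float
    )
    for pos in positions:
        idx = transcript.index_of(candidate.position) + (
            pos if pos < 0 else pos - 1
        )
        if not 0 <= idx < len(transcript.sequence):
            raise ValueError(
                f"context position {pos} of {candidate.transcript_id}:"
                f"{candidate.position} lies outside the transcript"
            )
        wt = transcript.sequence[idx]
        wildtype_nt[pos] = wt
        grid.loc[wt, pos] = wt_conf
        for nt in NT_ORDER:
            if nt == wt:
                continue
            mut_tx = _mutate(transcript, idx, nt)
            mut_cand = _refresh_candidate(candidate, mut_tx, config.flank)
            if pair is None:
                mut_pair = None
            elif freeze_conservation:
                mut_pair = pair
            else:
                mut_pair = align_orthologs(mut_tx, pair.ortholog)
            grid.loc[nt, pos] = predict_one(mut_cand, mut_tx, mut_pair)

    return MutationMatrix(
        transcript_id=candidate.transcript_id,
        position=candidate.position,
        codon=candidate.codon,
        wildtype_confidence=wt_conf,
        wildtype_nt=wildtype_nt,
        confidence=grid,
        threshold=model.threshold,
    )


def summarize_scan(matrices: Sequence[MutationMatrix]) -> pd.DataFrame:
    """Per-(position, nucleotide) quartiles of IC difference across candidates.

    Wildtype cells (IC difference identically zero) are excluded from each
    cell's sample; the output has one row per (position, nt) with the median,
    lower and upper quartiles, and the number of contributing candidates —
    ready for a per-position boxplot.
    """
    if not matrices:
        raise ValueError("need at least one mutation matrix")
    samples: dict[tuple[int, str], list[float]] = {}
    for m in matrices:
        diff = m.ic_difference
        for pos in diff.columns:
            for nt in diff.index:
                if nt == m.wildtype_nt[pos]:
                    continue
                samples.setdefault((pos, nt), []).append(float(diff.loc[nt, pos]))
    rows = []
    for (pos, nt), vals in sorted(samples.items()):
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {"position": pos, "nt": nt, "median": med,
             "q1": q1, "q3": q3, "n": len(vals)}
        )
    return pd.DataFrame(rows)
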