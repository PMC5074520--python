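"""The 1,252-slot feature space computed for every candidate start site.

Slots split into three groups:

* 3 position-weight-matrix scores (positive, negative, log-ratio matrices built
  from true/false training contexts over a 15 nt upstream + codon + 10 nt
  downstream window),
* 20 biologically motivated features (5' UTR length/conservation/composition,
  codon and amino-acid conservation, discretized Kozak context, flanking-context
  translation efficiency, four folding-energy and four GC windows, ORF length,
  and the in-frame indicator),
* 1,229 k-mer features over the +-99 nt flanks: 792 position-specific
  single-nucleotide indicators, 320 codon counts, 100 amino-acid counts, 5 stop
  counts (each over five regions: complete / upstream / downstream /
  in-frame-upstream / in-frame-downstream) and 12 mononucleotide counts
  (complete / upstream / downstream).

All positions use Kozak numbering relative to the candidate codon (first codon
nucleotide = +1, no position 0): the upstream flank covers -99..-1 and the
downstream flank +4..+102; the codon itself is excluded from both flanks.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import CODON_TO_AA, OrthologPair, start_conservation, utr_conservation
from .folding import nussinov_mfe
from .transcripts import StartCandidate, Transcript

log = logging.getLogger(__name__)

NT_ORDER = "ACGU"
NT_INDEX = {nt: k for k, nt in enumerate(NT_ORDER)}

CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(NT_ORDER, repeat=3)
)

#: one-letter -> three-letter residue names, used in k-mer slot names
AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
AA_ORDER: tuple[str, ...] = tuple(sorted(AA3.values()))
#: RNA codon -> three-letter residue, or None for stop codons
CODON_TO_AA3 = {
    codon: (AA3[aa] if aa != "*" else None) for codon, aa in CODON_TO_AA.items()
}

KMER_REGIONS = ("complete", "up", "down", "inframe_up", "inframe_down")
MONO_REGIONS = ("complete", "up", "down")

PWM_FEATURES = ("pwm_positive", "pwm_negative", "pwm_ratio")

BIO_FEATURES = (
    "utr_length",
    "utr_conservation",
    "codon_conserved",
    "aa_conserved",
    "kozak_context",
    "context_efficiency",
    "mfe_p14", "mfe_p20", "mfe_m10_p50", "mfe_m50_p50",
    "gc_p14", "gc_p20", "gc_m10_p50", "gc_m50_p50",
    "orf_length",
    "utr_frac_A", "utr_frac_C", "utr_frac_G", "utr_frac_U",
    "in_frame",
)

#: folding / GC windows as inclusive Kozak coordinate ranges
ENERGY_WINDOWS: dict[str, tuple[int, int]] = {
    "p14": (14, 73),
    "p20": (20, 79),
    "m10_p50": (-10, 50),
    "m50_p50": (-50, 50),
}


@dataclass(frozen=True)
class ContextWindow:
    """Flanking context around the codon: ``up`` nt 5' and ``down`` nt 3'.

    The default (15, 10) spans Kozak positions -15..-1, the codon, and +4..+13,
    giving 25 mutable (non-codon) positions.  ``ContextWindow(15, 7)`` restores
    a literal -15..+10 reading with 22 mutable positions.
    """

    up: int = 15
    down: int = 10

    @property
    def length(self) -> int:
        return self.up + 3 + self.down

    @property
    def mutable_positions(self) -> tuple[int, ...]:
        return tuple(range(-self.up, 0)) + tuple(range(4, 4 + self.down))


def flank_positions(flank: int = 99) -> tuple[int, ...]:
    """Kozak coordinates of the non-codon flank positions (-flank..-1, +4..)."""
    return tuple(range(-flank, 0)) + tuple(range(4, 4 + flank))


def feature_names(flank: int = 99) -> list[str]:
    """The ordered registry of feature slot names for a given flank width."""
    names: list[str] = list(PWM_FEATURES) + list(BIO_FEATURES)
    for pos in flank_positions(flank):
        for nt in NT_ORDER:
            names.append(f"kmer:pos:{pos}:{nt}")
    for region in KMER_REGIONS:
        for codon in CODONS:
            names.append(f"kmer:{region}:{codon}")
    for region in KMER_REGIONS:
        for aa in AA_ORDER:
            names.append(f"kmer:{region}:{aa}")
    for region in KMER_REGIONS:
        names.append(f"kmer:{region}:stop")
    for region in MONO_REGIONS:
        for nt in NT_ORDER:
            names.append(f"kmer:{region}:{nt}")
    return names


def feature_families(flank: int = 99) -> dict[str, list[str]]:
    """Registry names grouped by family (pwm / bio / k-mer sub-families)."""
    names = feature_names(flank)
    n_pos = 2 * flank * 4
    i = len(PWM_FEATURES) + len(BIO_FEATURES)
    fam = {
        "pwm": names[: len(PWM_FEATURES)],
        "bio": names[len(PWM_FEATURES) : i],
        "kmer_position": names[i : i + n_pos],
    }
    i += n_pos
    fam["kmer_codon"] = names[i : i + 64 * 5]; i += 64 * 5
    fam["kmer_aa"] = names[i : i + 20 * 5]; i += 20 * 5
    fam["kmer_stop"] = names[i : i + 5]; i += 5
    fam["kmer_mono"] = names[i : i + 12]; i += 12
    assert i == len(names)
    return fam


REGISTRY: tuple[str, ...] = tuple(feature_names(99))
assert len(REGISTRY) == 1252, len(REGISTRY)
assert len(REGISTRY) == 3 + 20 + (792 + 320 + 100 + 5 + 12)


# ---------------------------------------------------------------------------
# position weight matrices
# ---------------------------------------------------------------------------

@dataclass
class PWMModel:
    """Positive / negative / ratio PWMs over the context window.

    ``pfm_pos`` / ``pfm_neg`` are 4 x L frequency matrices (rows in ACGU
    order, columns summing to 1), ``bg`` the background nucleotide frequency of
    the training 5' UTRs.  ``pwm_pos(nt, i) = ln(pfm_pos(nt, i) / bg_nt)`` and
    ``pwm_ratio = ln(pfm_pos / pfm_neg)``.
    """

    window: ContextWindow
    pfm_pos: np.ndarray
    pfm_neg: np.ndarray
    bg: np.ndarray
    pseudocount: float
    pwm_pos: np.ndarray = field(init=False)
    pwm_neg: np.ndarray = field(init=False)
    pwm_ratio: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.pwm_pos = np.log(self.pfm_pos / self.bg[:, None])
        self.pwm_neg = np.log(self.pfm_neg / self.bg[:, None])
        self.pwm_ratio = np.log(self.pfm_pos / self.pfm_neg)

    def score(self, context: str, which: str = "pos") -> float:
        matrix = {"pos": self.pwm_pos, "neg": self.pwm_neg, "ratio": self.pwm_ratio}[which]
        return pwm_score(context, matrix)

    def to_dict(self) -> dict:
        return {
            "window": {"up": self.window.up, "down": self.window.down},
            "pfm_pos": self.pfm_pos.tolist(),
            "pfm_neg": self.pfm_neg.tolist(),
            "bg": self.bg.tolist(),
            "pseudocount": self.pseudocount,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PWMModel":
        return cls(
            window=ContextWindow(d["window"]["up"], d["window"]["down"]),
            pfm_pos=np.asarray(d["pfm_pos"]),
            pfm_neg=np.asarray(d["pfm_neg"]),
            bg=np.asarray(d["bg"]),
            pseudocount=d["pseudocount"],
        )


def _pfm(contexts: Sequence[str], length: int, pseudocount: float) -> np.ndarray:
    counts = np.full((4, length), pseudocount, dtype=float)
    for ctx in contexts:
        if len(ctx) != length:
            raise ValueError(
                f"context length {len(ctx)} != window length {length}"
            )
        for i, nt in enumerate(ctx):
            counts[NT_INDEX[nt], i] += 1.0
    return counts / (len(contexts) + 4.0 * pseudocount)


def build_pwm_model(
    true_contexts: Sequence[str],
    false_contexts: Sequence[str],
    training_utrs: Iterable[str],
    *,
    pseudocount: float = 0.5,
    window: ContextWindow = ContextWindow(),
) -> PWMModel:
    """Build the three PWMs from labelled training contexts.

    The background is the pooled nucleotide frequency of the training-set
    5' UTRs; a zero background frequency for any nucleotide is an error (the
    log-scaling would be undefined).
    """
    if not true_contexts or not false_contexts:
        raise ValueError("need at least one context per class")
    length = window.length
    bg_counts = np.zeros(4)
    for utr in training_utrs:
        for nt in utr:
            bg_counts[NT_INDEX[nt]] += 1
    if bg_counts.sum() == 0 or (bg_counts == 0).any():
        raise ValueError(
            "background frequency is zero for at least one nucleotide"
        )
    bg = bg_counts / bg_counts.sum()
    return PWMModel(
        window=window,
        pfm_pos=_pfm(true_contexts, length, pseudocount),
        pfm_neg=_pfm(false_contexts, length, pseudocount),
        bg=bg,
        pseudocount=pseudocount,
    )


def pwm_score(context: str, matrix: np.ndarray) -> float:
    """Sum of matrix entries along the context (one column per position)."""
    if len(context) != matrix.shape[1]:
        raise ValueError(
            f"context length {len(context)} != matrix width {matrix.shape[1]}"
        )
    return float(sum(matrix[NT_INDEX[nt], i] for i, nt in enumerate(context)))


def context_string(
    transcript: Transcript, index: int, window: ContextWindow = ContextWindow()
) -> str:
    """The context window (up + codon + down) around a codon-start index."""
    start, end = index - window.up, index + 3 + window.down
    if start < 0 or end > len(transcript.sequence):
        raise ValueError(
            f"context window [{start}, {end}) outside transcript {transcript.id!r}"
        )
    return transcript.sequence[start:end]


# ---------------------------------------------------------------------------
# flanking-context features
# ---------------------------------------------------------------------------

def kozak_class(nt_m3: str, nt_p4: str) -> int:
    """Discretized Kozak context from the -3 and +4 nucleotides.

    4 = strong (purine at -3 and G at +4), 3 = intermediate (purine at -3, no
    G at +4), 2 = weak (no purine at -3, G at +4), 1 = no Kozak context.
    """
    purine = nt_m3 in "AG"
    g4 = nt_p4 == "G"
    if purine and g4:
        return 4
    if purine:
        return 3
    if g4:
        return 2
    return 1


class EfficiencyTable:
    """11-nt flanking-context translation-efficiency lookup (-6..+5, AUG fixed)."""

    def __init__(self, values: Mapping[str, float]):
        self.values = dict(values)
        if not self.values:
            raise ValueError("empty efficiency table")
        self.mean = float(np.mean(list(self.values.values())))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EfficiencyTable":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["context", "efficiency"], dtype={"context": str})
        if len(df) and not _is_number(df.iloc[0]["efficiency"]):
            df = df.iloc[1:].reset_index(drop=True)
        return cls(dict(zip(df["context"], df["efficiency"].astype(float))))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("context\tefficiency\n")
            for ctx in sorted(self.values):
                fh.write(f"{ctx}\t{self.values[ctx]:.4f}\n")

    def lookup(self, context: str) -> float:
        """Value for an 11-nt context; unknown contexts fall back to the mean."""
        try:
            return float(self.values[context])
        except KeyError:
            log.warning(
                "context %r missing from efficiency table; using mean %.3f",
                context, self.mean,
            )
            return self.mean


def context_efficiency(
    transcript: Transcript, index: int, table: EfficiencyTable
) -> float:
    """Translation efficiency of the -6..+5 context with AUG substituted.

    Near-cognate codons are looked up as if they were AUG, on the assumption
    that alternative starts respond to flanking context like AUG does.
    """
    seq = transcript.sequence
    ctx = seq[index - 6 : index] + "AUG" + seq[index + 3 : index + 5]
    return table.lookup(ctx)


# ---------------------------------------------------------------------------
# window features (folding energy + GC)
# ---------------------------------------------------------------------------

def _kozak_to_index(index: int, pos: int) -> int:
    return index + pos if pos < 0 else index + pos - 1


def window_features(
    transcript: Transcript,
    index: int,
    *,
    mfe_engine: Callable[[str], float] | None = None,
) -> tuple[dict[str, float], set[str]]:
    """Folding energy and GC content of the four standard windows.

    Windows are resolved in Kozak coordinates relative to the codon start
    (60 nt from +14, 60 nt from +20, -10..+50, -50..+50) and truncated at
    transcript bounds; truncated window names are returned alongside.  An empty
    window yields 0 for both features.
    """
    engine = mfe_engine or nussinov_mfe
    seq = transcript.sequence
    values: dict[str, float] = {}
    truncated: set[str] = set()
    for name, (p_start, p_end) in ENERGY_WINDOWS.items():
        lo = _kozak_to_index(index, p_start)
        hi = _kozak_to_index(index, p_end) + 1
        if lo < 0 or hi > len(seq):
            truncated.add(name)
        window = seq[max(lo, 0) : min(hi, len(seq))]
        if not window:
            values[f"mfe_{name}"] = 0.0
            values[f"gc_{name}"] = 0.0
            continue
        values[f"mfe_{name}"] = float(engine(window))
        values[f"gc_{name}"] = (window.count("G") + window.count("C")) / len(window)
    return values, truncated


def utr_stats(transcript: Transcript) -> tuple[int, float, float, float, float]:
    """(length, frac_A, frac_C, frac_G, frac_U) of the whole 5' UTR."""
    utr = transcript.utr5
    if not utr:
        raise ValueError(f"transcript {transcript.id!r} has an empty 5' UTR")
    n = len(utr)
    return (n, utr.count("A") / n, utr.count("C") / n,
            utr.count("G") / n, utr.count("U") / n)


# ---------------------------------------------------------------------------
# k-mer features
# ---------------------------------------------------------------------------

def _triplet_counts(s: str, start: int, step: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(start, len(s) - 2, step):
        t = s[i : i + 3]
        counts[t] = counts.get(t, 0) + 1
    return counts


def kmer_features(
    upstream: str, codon: str, downstream: str, *, flank: int = 99
) -> dict[str, int]:
    """All k-mer slots for one candidate (flanks must match ``flank``).

    Region triplet counts overlap (stride 1) except the two in-frame families,
    which step by 3 in the candidate's frame.  The complete region is the
    concatenation upstream + codon + downstream, so codon-spanning triplets are
    counted there but in neither flank alone.
    """
    if len(upstream) != flank or len(downstream) != flank:
        raise ValueError(
            f"flank lengths ({len(upstream)}, {len(downstream)}) != {flank}"
        )
    out: dict[str, int] = {}
    for pos, nt_seen in zip(
        flank_positions(flank), itertools.chain(upstream, downstream)
    ):
        for nt in NT_ORDER:
            out[f"kmer:pos:{pos}:{nt}"] = int(nt == nt_seen)

    complete = upstream + codon + downstream
    region_counts = {
        "complete": _triplet_counts(complete, 0, 1),
        "up": _triplet_counts(upstream, 0, 1),
        "down": _triplet_counts(downstream, 0, 1),
        # in-frame upstream codons end flush against the candidate codon
        "inframe_up": _triplet_counts(upstream, len(upstream) % 3, 3),
        # downstream flank starts at the codon immediately after the candidate
        "inframe_down": _triplet_counts(downstream, 0, 3),
    }
    for region in KMER_REGIONS:
        counts = region_counts[region]
        aa_counts = dict.fromkeys(AA_ORDER, 0)
        stop = 0
        for triplet in CODONS:
            c = counts.get(triplet, 0)
            out[f"kmer:{region}:{triplet}"] = c
            aa = CODON_TO_AA3[triplet]
            if aa is None:
                stop += c
            else:
                aa_counts[aa] += c
        for aa in AA_ORDER:
            out[f"kmer:{region}:{aa}"] = aa_counts[aa]
        out[f"kmer:{region}:stop"] = stop

    mono_regions = {"complete": complete, "up": upstream, "down": downstream}
    for region in MONO_REGIONS:
        s = mono_regions[region]
        for nt in NT_ORDER:
            out[f"kmer:{region}:{nt}"] = s.count(nt)
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureConfig:
    """Widths of the flanking windows used throughout feature extraction."""

    flank: int = 99
    context: ContextWindow = ContextWindow()


def extract_features(
    candidate: StartCandidate,
    transcript: Transcript,
    pair: OrthologPair | None,
    pwm_model: PWMModel | None,
    efficiency_table: EfficiencyTable,
    *,
    mfe_engine: Callable[[str], float] | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """The full named feature vector for one candidate.

    PWM slots are NaN when no ``pwm_model`` is supplied (pure-extraction mode;
    they are filled once training-fold PWMs exist).  Missing-ortholog
    conservation defaults to zero.
    """
    out: dict[str, float] = {}
    if pwm_model is not None:
        ctx = context_string(transcript, candidate.index, pwm_model.window)
        out["pwm_positive"] = pwm_model.score(ctx, "pos")
        out["pwm_negative"] = pwm_model.score(ctx, "neg")
        out["pwm_ratio"] = pwm_model.score(ctx, "ratio")
    else:
        out["pwm_positive"] = out["pwm_negative"] = out["pwm_ratio"] = math.nan

    utr_len, fa, fc, fg, fu = utr_stats(transcript)
    codon_cons, aa_cons = start_conservation(candidate, pair)
    seq = transcript.sequence
    i = candidate.index
    out["utr_length"] = float(utr_len)
    out["utr_conservation"] = utr_conservation(pair)
    out["codon_conserved"] = float(codon_cons)
    out["aa_conserved"] = float(aa_cons)
    out["kozak_context"] = float(kozak_class(seq[i - 3], seq[i + 3]))
    out["context_efficiency"] = context_efficiency(transcript, i, efficiency_table)
    win_values, _trunc = window_features(transcript, i, mfe_engine=mfe_engine)
    out.update(win_values)
    out["orf_length"] = float(candidate.orf_length_nt)
    out["utr_frac_A"], out["utr_frac_C"] = fa, fc
    out["utr_frac_G"], out["utr_frac_U"] = fg, fu
    out["in_frame"] = float(candidate.in_frame)

    out.update(
        kmer_features(
            candidate.upstream_window, candidate.codon,
            candidate.downstream_window, flank=config.flank,
        )
    )
    expected = feature_names(config.flank)
    assert len(out) == len(expected)
    return {name: float(out[name]) for name in expected}


def build_feature_matrix(
    candidates: Sequence[StartCandidate],
    transcripts: Mapping[str, Transcript],
    pairs: Mapping[str, OrthologPair | None] | None,
    efficiency_table: EfficiencyTable,
    *,
    pwm_model: PWMModel | None = None,
    mfe_engine: Callable[[str], float] | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature matrix plus per-candidate metadata for many candidates.

    Returns ``(X, meta)``: ``X`` is indexed by (transcript_id, position) with
    one named column per registry slot; ``meta`` carries codon, frame, label
    and the PWM context string needed to (re)build fold-specific PWMs.
    """
    rows, meta_rows, keys = [], [], []
    for cand in candidates:
        tx = transcripts[cand.transcript_id]
        pair = pairs.get(cand.transcript_id) if pairs else None
        rows.append(
            extract_features(
                cand, tx, pair, pwm_model, efficiency_table,
                mfe_engine=mfe_engine, config=config,
            )
        )
        meta_rows.append(
            {
                "codon": cand.codon,
                "frame": cand.frame,
                "label": cand.label,
                "context": context_string(tx, cand.index, config.context),
            }
        )
        keys.append((cand.transcript_id, cand.position))
    index = pd.MultiIndex.from_tuples(keys, names=["transcript_id", "position"])
    X = pd.DataFrame(rows, index=index, columns=feature_names(config.flank))
    meta = pd.DataFrame(meta_rows, index=index)
    return X, meta


def apply_pwm(
    X: pd.DataFrame, contexts: pd.Series, pwm_model: PWMModel
) -> pd.DataFrame:
    """Return a copy of ``X`` with the three PWM columns scored from contexts."""
    out = X.copy()
    for which, col in (("pos", "pwm_positive"), ("neg", "pwm_negative"),
                       ("ratio", "pwm_ratio")):
        out[col] = [pwm_model.score(ctx, which) for ctx in contexts.loc[X.index]]
    return out


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False
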