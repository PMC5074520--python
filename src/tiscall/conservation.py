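"""Human-ortholog conservation features for candidate start sites.

Three features are derived from a pair of orthologous transcripts: whether the
candidate codon is identical in the aligned ortholog (codon conservation),
whether the two codons encode the same residue (amino-acid conservation), and
the fraction of identically aligned nucleotides in the 5' UTR (5' UTR
conservation).  The primary 5'UTR+CDS is translated in all three frames and
each frame is globally aligned against the ortholog's frames; the protein
alignment is then mapped back onto gap-free codon pairs, which gives the
ortholog codon aligned to any codon-start coordinate of the primary sequence.

The ortholog is explicit input (a FASTA plus a pairing table); no homology
search is performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .transcripts import StartCandidate, Transcript

log = logging.getLogger(__name__)

_STANDARD_RNA = CodonTable.unambiguous_rna_by_id[1]
#: Standard genetic code over RNA triplets; stops map to '*'.
CODON_TO_AA: dict[str, str] = dict(_STANDARD_RNA.forward_table)
for _stop in _STANDARD_RNA.stop_codons:
    CODON_TO_AA[_stop] = "*"


def translate_frame(sequence: str, frame: int) -> str:
    """Translate an RNA string in the given frame; stops stay in-line as '*'."""
    return "".join(
        CODON_TO_AA[sequence[i : i + 3]]
        for i in range(frame, len(sequence) - 2, 3)
    )


@dataclass
class FrameAlignment:
    """Best ortholog-frame alignment for one primary reading frame."""

    primary_frame: int
    ortholog_frame: int
    score: float
    #: primary codon-start index -> aligned (gap-free) ortholog codon
    codon_map: dict[int, str]


@dataclass
class OrthologPair:
    """A primary transcript aligned against its ortholog."""

    primary: Transcript
    ortholog: Transcript
    frames: dict[int, FrameAlignment]
    utr_matches: int

    @property
    def utr_conservation(self) -> float:
        """Identically aligned nt divided by the primary 5' UTR length."""
        return utr_conservation(self)


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def align_orthologs(
    primary: Transcript,
    ortholog: Transcript | None,
    *,
    frame_pairing: str = "best",
) -> OrthologPair | None:
    """Align a transcript against its ortholog; None ortholog -> None sentinel.

    ``frame_pairing`` is "best" (each primary frame paired with the
    highest-scoring ortholog frame) or "matched" (frame f against frame f).
    Frames shorter than one codon are skipped.
    """
    if ortholog is None:
        return None
    if frame_pairing not in ("best", "matched"):
        raise ValueError(f"unknown frame_pairing {frame_pairing!r}")

    paligner = _protein_aligner()
    frames: dict[int, FrameAlignment] = {}
    for pf in range(3):
        pprot = translate_frame(primary.sequence, pf)
        if not pprot:
            continue
        of_range = range(3) if frame_pairing == "best" else (pf,)
        best: tuple[float, int, object] | None = None
        for of in of_range:
            oprot = translate_frame(ortholog.sequence, of)
            if not oprot:
                continue
            aln = paligner.align(pprot, oprot)[0]
            if best is None or aln.score > best[0]:
                best = (aln.score, of, aln)
        if best is None:
            continue
        score, of, aln = best
        codon_map: dict[int, str] = {}
        for (ps, pe), (os_, _oe) in zip(*aln.aligned):
            for k in range(pe - ps):
                pidx = pf + 3 * (ps + k)
                oidx = of + 3 * (os_ + k)
                codon_map[pidx] = ortholog.sequence[oidx : oidx + 3]
        frames[pf] = FrameAlignment(pf, of, score, codon_map)

    naligner = _nucleotide_aligner()
    matches = 0
    if primary.utr5 and ortholog.utr5:
        aln = naligner.align(primary.utr5, ortholog.utr5)[0]
        for (ps, pe), (os_, _oe) in zip(*aln.aligned):
            for k in range(pe - ps):
                if primary.utr5[ps + k] == ortholog.utr5[os_ + k]:
                    matches += 1
    return OrthologPair(primary, ortholog, frames, matches)


def start_conservation(
    candidate: StartCandidate, pair: OrthologPair | None
) -> tuple[int, int]:
    """(codon_conserved, aa_conserved) for one candidate; missing data -> (0, 0).

    The codon is conserved iff the aligned ortholog codon is identical; the
    amino acid is conserved iff both codons translate to the same residue under
    the standard code (near-cognates translated literally, e.g. CUG -> Leu).
    Unalignable or gapped positions score (0, 0).
    """
    if pair is None:
        return (0, 0)
    frame = candidate.index % 3
    fa = pair.frames.get(frame)
    if fa is None:
        return (0, 0)
    ort_codon = fa.codon_map.get(candidate.index)
    if ort_codon is None or len(ort_codon) < 3:
        return (0, 0)
    codon_conserved = int(ort_codon == candidate.codon)
    aa_conserved = int(CODON_TO_AA[ort_codon] == CODON_TO_AA[candidate.codon])
    return (codon_conserved, aa_conserved)


def utr_conservation(pair: OrthologPair | None) -> float:
    """Fraction of identically aligned 5' UTR nucleotides; missing pair -> 0.

    The denominator is the primary 5' UTR length; gap columns contribute to the
    denominator only.
    """
    if pair is None:
        return 0.0
    if not pair.primary.utr5:
        raise ValueError("primary transcript has an empty 5' UTR")
    return pair.utr_matches / len(pair.primary.utr5)


def read_pairing_table(path: str | Path) -> pd.DataFrame:
    """Pairing TSV ``primary_id<TAB>ortholog_id``."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["primary_id", "ortholog_id"], dtype=str,
    )
    if len(df) and df.iloc[0]["primary_id"] == "primary_id":
        df = df.iloc[1:].reset_index(drop=True)
    return df


def build_pairs(
    primaries: Mapping[str, Transcript],
    orthologs: Mapping[str, Transcript],
    pairing: pd.DataFrame,
    *,
    frame_pairing: str = "best",
) -> dict[str, OrthologPair | None]:
    """Align every listed pair; primaries without a listed ortholog map to None."""
    pair_of = {
        str(r.primary_id): str(r.ortholog_id) for r in pairing.itertuples()
    }
    out: dict[str, OrthologPair | None] = {}
    for tid, tx in primaries.items():
        oid = pair_of.get(tid)
        ort = orthologs.get(oid) if oid is not None else None
        if oid is not None and ort is None:
            log.warning("ortholog %r for %r not found; treated as missing", oid, tid)
        out[tid] = align_orthologs(tx, ort, frame_pairing=frame_pairing)
    return out
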