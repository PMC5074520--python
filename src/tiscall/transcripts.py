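"""Annotated transcripts, start-site candidate enumeration, and training labels.

A transcript is an mRNA sequence with an annotated CDS start that partitions it
into a 5' UTR prefix and a CDS suffix.  Candidate translation initiation sites
(TIS) are all AUG and near-cognate triplets in the 5' UTR that (i) have a
downstream in-frame stop codon and (ii) carry full flanking windows (99 nt by
default) on both sides, as required by the position-specific feature set.

Positions follow Kozak numbering: the first nucleotide of the annotated CDS is
+1, the nucleotide immediately 5' of it is -1, and there is no position 0.  A
candidate's position is the offset of its codon's first nucleotide, so all
enumerated candidates sit at positions <= -3 (the codon lies fully inside the
5' UTR).
"""

from __future__ import annotations

import csv
import gzip
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: AUG plus the nine triplets differing from it by exactly one nucleotide.
NEAR_COGNATE_CODONS: tuple[str, ...] = (
    "AUG", "CUG", "UUG", "GUG", "AAG", "ACG", "AGG", "AUA", "AUC", "AUU",
)
START_CODON_SET = frozenset(NEAR_COGNATE_CODONS)
STOP_CODONS = frozenset(("UAA", "UAG", "UGA"))

TRUE_START = "TRUE_START"
FALSE_START = "FALSE_START"
EXCLUDED = "EXCLUDED"

_CDS_START_RE = re.compile(r"cds_start=(\d+)")


class TranscriptError(ValueError):
    """Raised for malformed transcript records or annotations."""


@dataclass(frozen=True)
class Transcript:
    """An mRNA sequence with a 1-based annotated CDS start."""

    id: str
    sequence: str
    cds_start: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise TranscriptError(
                f"transcript {self.id!r}: invalid characters {sorted(bad)}"
            )
        if not 1 <= self.cds_start <= len(seq):
            raise TranscriptError(
                f"transcript {self.id!r}: cds_start={self.cds_start} outside "
                f"sequence of length {len(seq)}"
            )

    @property
    def utr5(self) -> str:
        return self.sequence[: self.cds_start - 1]

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start - 1 :]

    def index_of(self, position: int) -> int:
        """0-based sequence index of a Kozak position (no position 0)."""
        if position == 0:
            raise ValueError("Kozak numbering has no position 0")
        utr_len = self.cds_start - 1
        return utr_len + position if position < 0 else utr_len + position - 1

    def position_of(self, index: int) -> int:
        """Kozak position of a 0-based sequence index."""
        if not 0 <= index < len(self.sequence):
            raise ValueError(f"index {index} outside transcript {self.id!r}")
        utr_len = self.cds_start - 1
        return index - utr_len if index < utr_len else index - utr_len + 1


@dataclass(frozen=True)
class StartCandidate:
    """One putative TIS: a near-cognate codon in the 5' UTR with full flanks."""

    transcript_id: str
    position: int           # Kozak offset of the codon's first nt (<= -3)
    codon: str
    index: int              # 0-based offset of the codon's first nt
    in_frame: bool          # in frame with the main ORF
    upstream_window: str
    downstream_window: str
    orf_length_nt: int      # codon through first downstream in-frame stop
    label: str = EXCLUDED

    @property
    def frame(self) -> str:
        return "in_frame" if self.in_frame else "out_of_frame"


def _read_annotation(path: str | Path) -> dict[str, int]:
    """Sidecar TSV ``transcript_id<TAB>cds_start`` (1-based); header optional."""
    mapping: dict[str, int] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise TranscriptError(f"annotation row too short: {row!r}")
            try:
                mapping[row[0]] = int(row[1])
            except ValueError:
                # tolerate a single header line
                if row[0] in mapping or mapping:
                    raise TranscriptError(f"bad cds_start in annotation: {row!r}")
    return mapping


def parse_transcripts(
    fasta_path: str | Path,
    annotation: str | Path | Mapping[str, int] | None = None,
) -> list[Transcript]:
    """Read transcripts from FASTA (plain or gzip) with CDS-start annotation.

    ``cds_start`` comes from a ``cds_start=<int>`` header tag or from a sidecar
    TSV / mapping; the sidecar wins on conflict.  DNA input is converted T->U.
    Records without any annotation are skipped with a logged warning.
    """
    if annotation is None:
        sidecar: Mapping[str, int] = {}
    elif isinstance(annotation, Mapping):
        sidecar = annotation
    else:
        sidecar = _read_annotation(annotation)

    fasta_path = Path(fasta_path)
    opener = gzip.open if fasta_path.suffix == ".gz" else open
    transcripts: list[Transcript] = []
    skipped = 0
    with opener(fasta_path, "rt") as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if len(record.seq) == 0:
                raise TranscriptError(f"empty FASTA record {record.id!r}")
            cds_start = sidecar.get(record.id)
            if cds_start is None:
                m = _CDS_START_RE.search(record.description)
                if m:
                    cds_start = int(m.group(1))
            if cds_start is None:
                skipped += 1
                log.warning("record %r has no cds_start annotation; skipped", record.id)
                continue
            transcripts.append(Transcript(record.id, str(record.seq), cds_start))
    if skipped:
        log.warning("skipped %d record(s) without cds_start", skipped)
    return transcripts


def orf_length_at(
    sequence: str, index: int, *, search_limit: int | None = None
) -> int | None:
    """Length in nt of the ORF starting at ``index`` through its first in-frame
    stop (inclusive), or None if no stop exists before ``search_limit``."""
    limit = len(sequence) if search_limit is None else search_limit
    for j in range(index + 3, limit - 2, 3):
        if sequence[j : j + 3] in STOP_CODONS:
            return j + 3 - index
    return None


def enumerate_candidates(
    transcript: Transcript,
    *,
    window: int = 99,
    stop_before_cds_end: bool = False,
) -> list[StartCandidate]:
    """Scan the 5' UTR for all eligible AUG / near-cognate start candidates.

    A candidate is emitted iff the triplet is in the 10-codon alphabet, a stop
    codon exists downstream in the candidate's frame (anywhere in the
    transcript, or before the main ORF's own stop when ``stop_before_cds_end``
    is set), and ``window`` nt of sequence flank the codon on both sides.
    Candidates are returned sorted by position ascending and left unlabeled.
    """
    seq = transcript.sequence
    utr_len = transcript.cds_start - 1
    limit: int | None = None
    if stop_before_cds_end:
        main = orf_length_at(seq, utr_len)
        limit = utr_len + main if main is not None else None
    out: list[StartCandidate] = []
    for i in range(utr_len - 2):
        codon = seq[i : i + 3]
        if codon not in START_CODON_SET:
            continue
        if i < window or len(seq) - (i + 3) < window:
            continue
        orf_len = orf_length_at(seq, i, search_limit=limit)
        if orf_len is None:
            continue
        position = i - utr_len
        out.append(
            StartCandidate(
                transcript_id=transcript.id,
                position=position,
                codon=codon,
                index=i,
                in_frame=(position % 3 == 0),
                upstream_window=seq[i - window : i],
                downstream_window=seq[i + 3 : i + 3 + window],
                orf_length_nt=orf_len,
            )
        )
    return out


def enumerate_all(
    transcripts: Iterable[Transcript],
    *,
    window: int = 99,
    stop_before_cds_end: bool = False,
) -> list[StartCandidate]:
    """Enumerate candidates for many transcripts, sorted by (id, position)."""
    out: list[StartCandidate] = []
    for tx in sorted(transcripts, key=lambda t: t.id):
        out.extend(
            enumerate_candidates(
                tx, window=window, stop_before_cds_end=stop_before_cds_end
            )
        )
    return out


def read_reported_table(path: str | Path) -> pd.DataFrame:
    """Reported-TIS TSV ``transcript_id<TAB>position<TAB>codon``."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["transcript_id", "position", "codon"],
        dtype={"transcript_id": str, "codon": str},
    )
    # tolerate a header line
    if len(df) and not str(df.iloc[0]["position"]).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    df["position"] = df["position"].astype(int)
    df["codon"] = df["codon"].str.upper().str.replace("T", "U")
    return df


def label_candidates(
    candidates: Sequence[StartCandidate],
    reported: pd.DataFrame,
    *,
    min_upstream: int = 99,
) -> list[StartCandidate]:
    """Assign TRUE_START / FALSE_START / EXCLUDED labels from a reported table.

    A candidate matching a reported (transcript_id, position) row is a
    TRUE_START (codon mismatches are logged).  Unmatched candidates are
    FALSE_STARTs iff their codon starts at least ``min_upstream`` nt downstream
    of the transcript's 5' end and strictly upstream of the transcript's most
    downstream reported start; everything else — including every candidate of a
    transcript absent from the table — is EXCLUDED.
    """
    key_to_codon = {
        (str(r.transcript_id), int(r.position)): str(r.codon)
        for r in reported.itertuples()
    }
    anchor: dict[str, int] = {}
    for tid, pos in key_to_codon:
        anchor[tid] = max(anchor.get(tid, pos), pos)

    matched: set[tuple[str, int]] = set()
    labeled: list[StartCandidate] = []
    for cand in candidates:
        key = (cand.transcript_id, cand.position)
        if key in key_to_codon:
            matched.add(key)
            if key_to_codon[key] != cand.codon:
                log.warning(
                    "reported codon %s at %s:%d disagrees with sequence codon %s",
                    key_to_codon[key], cand.transcript_id, cand.position, cand.codon,
                )
            labeled.append(replace(cand, label=TRUE_START))
        elif (
            cand.transcript_id in anchor
            and cand.position < anchor[cand.transcript_id]
            and cand.index >= min_upstream
        ):
            labeled.append(replace(cand, label=FALSE_START))
        else:
            labeled.append(replace(cand, label=EXCLUDED))

    missing = set(key_to_codon) - matched
    if missing:
        log.warning(
            "%d reported start(s) had no matching enumerated candidate: %s",
            len(missing), sorted(missing)[:10],
        )
    return labeled


def candidates_to_frame(candidates: Sequence[StartCandidate]) -> pd.DataFrame:
    """Tabular view of candidates (id, position, codon, frame, ORF length, label)."""
    return pd.DataFrame(
        {
            "transcript_id": [c.transcript_id for c in candidates],
            "position": [c.position for c in candidates],
            "codon": [c.codon for c in candidates],
            "frame": [c.frame for c in candidates],
            "orf_length_nt": [c.orf_length_nt for c in candidates],
            "label": [c.label for c in candidates],
        }
    )


def candidates_to_bed(candidates: Sequence[StartCandidate]) -> pd.DataFrame:
    """BED-like 0-based half-open codon intervals in transcript coordinates."""
    return pd.DataFrame(
        {
            "chrom": [c.transcript_id for c in candidates],
            "start": [c.index for c in candidates],
            "end": [c.index + 3 for c in candidates],
            "name": [f"{c.codon}@{c.position}" for c in candidates],
            "score": 0,
            "strand": "+",
        }
    )
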