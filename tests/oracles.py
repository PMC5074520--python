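"""Independent brute-force reference implementations used only by the tests.

Each oracle recomputes a quantity by direct enumeration or naive counting,
sharing no code path with the package implementation it checks.
"""

from functools import lru_cache
from itertools import combinations

import numpy as np

NT = "ACGU"
START_CODONS = {"AUG", "CUG", "UUG", "GUG", "AAG", "ACG", "AGG", "AUA", "AUC", "AUU"}
STOPS = {"UAA", "UAG", "UGA"}

_PAIR_E = {"GC": -3.0, "CG": -3.0, "AU": -2.0, "UA": -2.0, "GU": -1.0, "UG": -1.0}


def brute_mfe(seq: str) -> float:
    """Minimum pairing energy by explicit enumeration of all non-crossing
    structures (pairs at least 4 apart, GC -3 / AU -2 / GU -1)."""

    @lru_cache(maxsize=None)
    def best(positions: tuple) -> float:
        if len(positions) < 2:
            return 0.0
        i, rest = positions[0], positions[1:]
        out = best(rest)  # i unpaired
        for k in rest:
            if k - i <= 3:
                continue
            e = _PAIR_E.get(seq[i] + seq[k])
            if e is None:
                continue
            inside = tuple(p for p in rest if p < k)
            outside = tuple(p for p in rest if p > k)
            out = min(out, e + best(inside) + best(outside))
        return out

    return best(tuple(range(len(seq))))


def brute_pfm(contexts, pseudocount: float) -> np.ndarray:
    """Column frequencies with a per-cell pseudocount, counted one by one."""
    length = len(contexts[0])
    m = np.zeros((4, length))
    for ctx in contexts:
        for i, c in enumerate(ctx):
            m[NT.index(c), i] += 1
    return (m + pseudocount) / (len(contexts) + 4 * pseudocount)


def brute_pwm_score(context: str, matrix: np.ndarray) -> float:
    total = 0.0
    for i, c in enumerate(context):
        total += matrix[NT.index(c), i]
    return total


def midranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_ranksum_p(a, b) -> float:
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    pooled = list(a) + list(b)
    ranks = midranks(pooled)
    n1 = len(a)
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    us = [
        sum(ranks[i] for i in comb) - n1 * (n1 + 1) / 2
        for comb in combinations(range(len(pooled)), n1)
    ]
    lo = sum(u <= u_obs for u in us) / len(us)
    hi = sum(u >= u_obs for u in us) / len(us)
    return min(1.0, 2 * min(lo, hi))


def brute_confusion(confidences, labels, t):
    tp = fp = tn = fn = 0
    for c, y in zip(confidences, labels):
        pred = c >= t
        if pred and y:
            tp += 1
        elif pred and not y:
            fp += 1
        elif not pred and y:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def brute_auc(confidences, labels) -> float:
    pos = [c for c, y in zip(confidences, labels) if y]
    neg = [c for c, y in zip(confidences, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def naive_enumerate(sequence: str, cds_start: int, window: int = 99):
    """Independent candidate scan: (position, codon, in_frame, orf_length)."""
    utr_len = cds_start - 1
    out = []
    for i in range(utr_len - 2):
        codon = sequence[i : i + 3]
        if codon not in START_CODONS:
            continue
        if i < window or len(sequence) - i - 3 < window:
            continue
        orf = None
        j = i + 3
        while j + 3 <= len(sequence):
            if sequence[j : j + 3] in STOPS:
                orf = j + 3 - i
                break
            j += 3
        if orf is None:
            continue
        pos = i - utr_len
        out.append((pos, codon, abs(pos) % 3 == 0, orf))
    return out


def naive_kmers(upstream: str, codon: str, downstream: str) -> dict:
    """Sliding-window recount of every k-mer slot, indexed the same way."""
    from Bio.Seq import Seq

    flank = len(upstream)
    out = {}
    for q, nt_seen in enumerate(upstream):
        pos = q - flank
        for nt in NT:
            out[f"kmer:pos:{pos}:{nt}"] = 1 if nt == nt_seen else 0
    for q, nt_seen in enumerate(downstream):
        pos = 4 + q
        for nt in NT:
            out[f"kmer:pos:{pos}:{nt}"] = 1 if nt == nt_seen else 0

    complete = upstream + codon + downstream
    regions = {
        "complete": [complete[i : i + 3] for i in range(len(complete) - 2)],
        "up": [upstream[i : i + 3] for i in range(len(upstream) - 2)],
        "down": [downstream[i : i + 3] for i in range(len(downstream) - 2)],
        "inframe_up": [
            upstream[i : i + 3]
            for i in range(len(upstream) % 3, len(upstream) - 2, 3)
        ],
        "inframe_down": [
            downstream[i : i + 3] for i in range(0, len(downstream) - 2, 3)
        ],
    }
    aa3 = {
        "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
        "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
        "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
        "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    }
    triplets = ["".join((a, b, c)) for a in NT for b in NT for c in NT]
    for region, found in regions.items():
        for t in triplets:
            out[f"kmer:{region}:{t}"] = found.count(t)
        for name, letter in aa3.items():
            out[f"kmer:{region}:{name}"] = sum(
                1 for t in found if str(Seq(t).translate()) == letter
            )
        out[f"kmer:{region}:stop"] = sum(1 for t in found if t in STOPS)
    for region, s in (("complete", complete), ("up", upstream), ("down", downstream)):
        for nt in NT:
            out[f"kmer:{region}:{nt}"] = sum(1 for c in s if c == nt)
    return out
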