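"""Pluggable RNA secondary-structure energy engines.

The built-in engine is a simplified maximum-weight non-crossing base-pairing
model (Nussinov-style dynamic programme) with pair energies GC = -3, AU = -2,
GU = -1 kcal/mol and a minimum hairpin loop of 3 unpaired nucleotides.  It is
deliberately NOT a Turner nearest-neighbour model and its energies do not match
RNAfold; it provides a fast, dependency-free stability proxy.  Any callable
``engine(rna_string) -> float`` (kcal/mol, <= 0) can be supplied instead; an
adapter for an external RNAfold binary is included.
"""

from __future__ import annotations

import shutil
import subprocess

import numpy as np

MIN_LOOP = 3

_NT_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}

#: pair energies indexed by (code_i, code_j); 0.0 means "cannot pair"
_PAIR_ENERGY = np.zeros((4, 4))
for _a, _b, _e in (("G", "C", -3.0), ("A", "U", -2.0), ("G", "U", -1.0)):
    _PAIR_ENERGY[_NT_CODE[_a], _NT_CODE[_b]] = _e
    _PAIR_ENERGY[_NT_CODE[_b], _NT_CODE[_a]] = _e


def _mfe_dp(codes, pair_energy, min_loop):
    n = codes.shape[0]
    E = np.zeros((n, n))
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = E[i + 1, j]
            if E[i, j - 1] < best:
                best = E[i, j - 1]
            e = pair_energy[codes[i], codes[j]]
            if e < 0.0:
                cand = (E[i + 1, j - 1] if j - 1 >= i + 1 else 0.0) + e
                if cand < best:
                    best = cand
            for k in range(i + 1, j):
                cand = E[i, k] + E[k + 1, j]
                if cand < best:
                    best = cand
            E[i, j] = best
    return E[0, n - 1]


try:  # optional JIT: the pure-Python DP is the reference semantics
    from numba import njit

    _mfe_dp_jit = njit(cache=False)(_mfe_dp)
except ImportError:  # pragma: no cover - numba present in normal installs
    _mfe_dp_jit = None


def nussinov_mfe(sequence: str) -> float:
    """Minimum energy (kcal/mol, <= 0) under the built-in pairing model."""
    if len(sequence) < MIN_LOOP + 2:
        return 0.0
    codes = np.array([_NT_CODE[c] for c in sequence], dtype=np.int64)
    fn = _mfe_dp_jit if _mfe_dp_jit is not None else _mfe_dp
    return float(fn(codes, _PAIR_ENERGY, MIN_LOOP))


def rnafold_mfe(sequence: str, *, binary: str = "RNAfold") -> float:
    """Plug-in adapter calling an external Turner-model RNAfold binary."""
    if shutil.which(binary) is None:
        raise RuntimeError(f"{binary} not found on PATH")
    proc = subprocess.run(
        [binary, "--noPS"], input=sequence + "\n",
        capture_output=True, text=True, check=True,
    )
    last = proc.stdout.strip().splitlines()[-1]
    return float(last.rsplit("(", 1)[1].rstrip(")").strip())
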