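"""Small shared helpers: base encoding, seed derivation, interval checks."""

from __future__ import annotations

import hashlib

import numpy as np

BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}

# byte-value -> 0..3 for ACGT, 4 for N, 255 otherwise
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_ENC[ord("N")] = 4
_ENC[ord("n")] = 4

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode_bases(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_bases(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def derive_seed(seed: int, tag: str) -> int:
    """Stable per-stage substream seed below 2**31."""
    h = hashlib.sha256(f"{int(seed)}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def check_sorted_intervals(intervals) -> bool:
    """True if half-open intervals are sorted, non-empty and non-overlapping."""
    prev_end = -1
    for start, end in intervals:
        if end <= start or start < prev_end:
            return False
        prev_end = end
    return True


def phred_from_error(error_rate: float, cap: int = 60) -> int:
    """Phred-scale an error probability, capping the no-error limit."""
    if error_rate <= 0:
        return cap
    return min(cap, int(round(-10.0 * np.log10(error_rate))))


def error_from_phred(q: int | float) -> float:
    return 10.0 ** (-float(q) / 10.0)
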