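"""Small DNA-string helpers shared across modules."""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")

# byte code per base; N = 4 is scored neutrally by the aligner
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware via Biopython)."""
    return str(Seq(seq).reverse_complement())


def check_dna(seq: str, name: str = "sequence", allow_n: bool = True) -> str:
    """Validate and upper-case a DNA string; raise ValueError otherwise."""
    if not seq:
        raise ValueError(f"{name} is empty")
    up = seq.upper()
    alphabet = DNA_ALPHABET if allow_n else DNA_ALPHABET - {"N"}
    bad = set(up) - alphabet
    if bad:
        raise ValueError(f"{name} contains non-DNA characters: {sorted(bad)}")
    return up


def encode(seq: str) -> np.ndarray:
    """Encode ACGTN to uint8 codes 0..4."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside ACGTN")
    return arr


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    xa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    xb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    return int((xa != xb).sum())
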