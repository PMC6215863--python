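"""Compositional profiles: k-mer usage and codon usage.

A genome carries a characteristic oligonucleotide "signature": the
frequencies of its 4^k k-mers (256 tetranucleotides at k=4) and of the 64
codons in its coding genes are stable genome-wide but differ between
lineages, which is what makes laterally transferred regions stand out.

K-mer profiles are optionally "reverse-complement extended": the sequence
and its reverse complement are counted as two independent sequences, which
makes the profile exactly strand-symmetric without introducing artifactual
junction k-mers.  Windows containing any non-ACGT character are skipped
entirely.  Codons are read in frame 0 within each CDS independently (never
across gene boundaries); a trailing partial codon is dropped with a warning.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
import pandas as pd

_BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i


def encode_dna(seq: str) -> np.ndarray:
    """Map a DNA string to int codes A=0,C=1,G=2,T=3; anything else -> -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@lru_cache(maxsize=None)
def kmer_categories(k: int) -> tuple[str, ...]:
    """All 4^k k-mers in lexicographic order (index == base-4 code)."""
    return tuple("".join(t) for t in itertools.product(_BASES, repeat=k))


CODONS: tuple[str, ...] = kmer_categories(3)
STOP_CODONS = ("TAA", "TAG", "TGA")


@lru_cache(maxsize=None)
def revcomp_code_permutation(k: int) -> np.ndarray:
    """Permutation p with p[code(w)] == code(reverse_complement(w))."""
    codes = np.arange(4**k, dtype=np.int64)
    out = np.zeros_like(codes)
    for j in range(k):
        digit = (codes >> (2 * j)) & 3  # j-th base from the right
        out += (3 - digit) << (2 * (k - 1 - j))
    return out


def _window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 codes of all valid (ambiguity-free) k-windows."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    valid = codes >= 0
    c = np.where(valid, codes, 0)
    w = c[: len(c) - k + 1].copy()
    ok = valid[: len(c) - k + 1].copy()
    for j in range(1, k):
        w = w * 4 + c[j : len(c) - k + 1 + j]
        ok &= valid[j : len(c) - k + 1 + j]
    return w[ok]


def count_kmers(seq: str | np.ndarray, k: int, revcomp_extend: bool = True) -> np.ndarray:
    """Raw k-mer counts (length 4^k) for one sequence."""
    codes = encode_dna(seq) if isinstance(seq, str) else seq
    w = _window_codes(codes, k)
    counts = np.bincount(w, minlength=4**k).astype(np.int64)
    if revcomp_extend:
        counts = counts + counts[revcomp_code_permutation(k)]
    return counts


@dataclass
class CompositionProfile:
    """Normalized frequency vector over a fixed k-mer or codon alphabet."""

    alphabet_kind: Literal["kmer", "codon"]
    k: int | None
    counts: np.ndarray
    source_id: str = ""
    source_kind: Literal["region", "genome"] = "region"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expected = 64 if self.alphabet_kind == "codon" else 4 ** int(self.k)
        if self.counts.shape != (expected,):
            raise ValueError(
                f"{self.alphabet_kind} profile needs {expected} categories, "
                f"got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def categories(self) -> tuple[str, ...]:
        return CODONS if self.alphabet_kind == "codon" else kmer_categories(self.k)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        tot = self.counts.sum()
        if tot == 0:
            raise ValueError("profile has zero total count")
        return self.counts / tot

    def same_alphabet(self, other: "CompositionProfile") -> bool:
        return self.alphabet_kind == other.alphabet_kind and self.k == other.k

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(self.categories),
                "count": self.counts,
                "frequency": self.frequencies,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def kmer_profile(
    seq: str,
    k: int,
    revcomp_extend: bool = True,
    source_id: str = "",
    source_kind: Literal["region", "genome"] = "region",
) -> CompositionProfile:
    """K-mer usage profile of one sequence (2 <= k <= 8).

    With ``revcomp_extend`` the sequence and its reverse complement are
    counted as two independent sequences, making the profile strand
    symmetric.  Raises if no ambiguity-free window exists.
    """
    if not 2 <= k <= 8:
        raise ValueError(f"k must be in 2..8, got {k}")
    counts = count_kmers(seq, k, revcomp_extend=revcomp_extend)
    if counts.sum() == 0:
        raise ValueError(f"sequence too short/ambiguous for k={k}")
    return CompositionProfile("kmer", k, counts, source_id, source_kind)


def codon_profile(
    cds_list: Sequence[str],
    source_id: str = "",
    source_kind: Literal["region", "genome"] = "region",
) -> CompositionProfile:
    """Codon usage over a collection of CDS, each read in frame 0.

    Codons never span CDS boundaries; trailing partial codons are dropped
    with a warning; codons containing ambiguity codes are skipped.
    """
    if len(cds_list) == 0:
        raise ValueError("empty CDS list")
    counts = np.zeros(64, dtype=np.int64)
    for idx, cds in enumerate(cds_list):
        if len(cds) < 3:
            raise ValueError(f"CDS #{idx} shorter than one codon")
        if len(cds) % 3:
            warnings.warn(
                f"CDS #{idx}: length {len(cds)} not a multiple of 3; "
                "trailing partial codon dropped",
                stacklevel=2,
            )
        codes = encode_dna(cds)
        n = (len(codes) // 3) * 3
        trip = codes[:n].reshape(-1, 3)
        ok = (trip >= 0).all(axis=1)
        vals = trip[ok] @ np.array([16, 4, 1])
        counts += np.bincount(vals, minlength=64)
    if counts.sum() == 0:
        raise ValueError("no unambiguous codons found")
    return CompositionProfile("codon", None, counts, source_id, source_kind)
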