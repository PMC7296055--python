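"""k-mer counting and rho-normalized oligonucleotide relative abundances.

The genomic-signature statistic used throughout is the *rho* statistic: the
observed k-mer frequency divided by the product of the mononucleotide
frequencies of its letters,

    rho(w) = f(w) / (f(w_1) f(w_2) ... f(w_k)),

which factors GC content out of the signature. Frequencies are computed on
overlapping windows of a single strand (optionally both strands summed);
windows containing any non-ACGT letter are skipped, and the frequency
denominator is the number of windows actually counted, so f sums to one.

A sequence window in which some base never occurs cannot be rho-normalized;
its vector is flagged invalid instead of carrying infinities, and invalid
segments are dropped from composition matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, List

import numpy as np

from .records import SegmentSet

__all__ = [
    "ALPHABET",
    "KmerVector",
    "CompositionMatrix",
    "EmptyCompositionError",
    "count_kmers",
    "mononucleotide_frequencies",
    "rho_vector",
    "composition_matrix",
    "kmer_strings",
]

ALPHABET = "ACGT"

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


class EmptyCompositionError(ValueError):
    """A composition matrix would contain zero valid segment rows."""


def encode(sequence: str) -> np.ndarray:
    """Map a nucleotide string to int codes A,C,G,T -> 0..3; others -> -1."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def kmer_strings(k: int) -> List[str]:
    """All 4^k k-mers in lexicographic order over ACGT."""
    return ["".join(p) for p in product(ALPHABET, repeat=k)]


def _digits(k: int) -> np.ndarray:
    # (4^k, k) matrix: base code of each position of each lexicographic k-mer
    idx = np.arange(4**k)
    return (idx[:, None] // 4 ** np.arange(k - 1, -1, -1)) % 4


def _revcomp_perm(k: int) -> np.ndarray:
    # index permutation sending each k-mer code to its reverse complement
    d = _digits(k)
    rc = (3 - d)[:, ::-1]
    return (rc * 4 ** np.arange(k - 1, -1, -1)).sum(axis=1)


def _window_codes(codes: np.ndarray, k: int):
    """k-mer code and validity mask for every overlapping window."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    kcode = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        valid &= c >= 0
        kcode = kcode * 4 + np.where(c >= 0, c, 0)
    return kcode, valid


def kmer_count_vector(codes: np.ndarray, k: int) -> np.ndarray:
    """Counts of all 4^k k-mers (lexicographic) in an encoded sequence."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    kcode, valid = _window_codes(codes, k)
    return np.bincount(kcode[valid], minlength=4**k)


def count_kmers(sequence: str, k: int) -> Dict[str, int]:
    """Count overlapping k-mers on the given strand, step 1.

    Windows containing any non-ACGT letter are skipped and excluded from the
    total. Returns a full map over all 4^k k-mers (zeros included).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(sequence):
        raise ValueError(f"k={k} exceeds sequence length {len(sequence)}")
    counts = kmer_count_vector(encode(sequence), k)
    return dict(zip(kmer_strings(k), counts.tolist()))


def mononucleotide_frequencies(sequence: str) -> np.ndarray:
    """Frequencies of A, C, G, T among unambiguous bases only."""
    codes = encode(sequence)
    counts = np.bincount(codes[codes >= 0], minlength=4)
    total = counts.sum()
    if total == 0:
        raise ValueError("no unambiguous base: mononucleotide frequencies undefined")
    return counts / total


@dataclass(frozen=True)
class KmerVector:
    """rho-normalized k-mer abundance vector of one sequence window."""

    k: int
    values: np.ndarray
    valid: bool
    n_kmers_counted: int

    def __post_init__(self) -> None:
        if len(self.values) != 4**self.k:
            raise ValueError("values length must be 4^k")


@dataclass(frozen=True)
class CompositionMatrix:
    """n valid segments x 4^k rho values for one replicon at one k."""

    source_id: str
    k: int
    rows: np.ndarray  # (n, 4^k)
    n_invalid_segments: int = 0

    @property
    def n(self) -> int:
        return self.rows.shape[0]

    @property
    def p(self) -> int:
        return 4**self.k

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.rows, columns=kmer_strings(self.k))
        df.insert(0, "segment", np.arange(self.n))
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, source_id: str = "") -> "CompositionMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        cols = [c for c in df.columns if c != "segment"]
        k = int(round(np.log(len(cols)) / np.log(4)))
        if 4**k != len(cols):
            raise ValueError(f"{path}: column count {len(cols)} is not a power of 4")
        return cls(source_id=source_id, k=k, rows=df[cols].to_numpy(float))


def _rho_from_counts(kmer_counts: np.ndarray, mono_counts: np.ndarray, k: int):
    """rho values from raw counts; returns (values, valid, n_counted)."""
    total = int(kmer_counts.sum())
    mono_total = mono_counts.sum()
    if total == 0 or mono_total == 0:
        return np.full(4**k, np.nan), False, total
    f = kmer_counts / total
    mono_f = mono_counts / mono_total
    denom = mono_f[_digits(k)].prod(axis=1)
    # entries whose letters never occur are undefined (0/0), not infinite;
    # any absent base invalidates the vector as a whole
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom > 0, f / np.where(denom > 0, denom, 1.0), np.nan)
    return values, bool((mono_counts > 0).all()), total


def rho_vector(sequence: str, k: int, strand: str = "given") -> KmerVector:
    """rho-normalized k-mer abundance vector of a whole sequence.

    With ``strand="both"`` the k-mer counts of the reverse complement are
    added before normalization (mononucleotide counts symmetrized likewise).
    The vector is flagged invalid when any base is absent from the sequence
    or no unambiguous window exists.
    """
    if k not in (2, 3, 4):
        raise ValueError(f"k must be in {{2, 3, 4}}, got {k}")
    codes = encode(sequence)
    counts = kmer_count_vector(codes, k)
    mono = np.bincount(codes[codes >= 0], minlength=4)
    counts, mono = _apply_strand(counts, mono, k, strand)
    values, valid, n_counted = _rho_from_counts(counts, mono, k)
    return KmerVector(k=k, values=values, valid=valid, n_kmers_counted=n_counted)


def _apply_strand(counts: np.ndarray, mono: np.ndarray, k: int, strand: str):
    if strand == "given":
        return counts, mono
    if strand == "both":
        return counts + counts[_revcomp_perm(k)], mono + mono[::-1]
    raise ValueError(f"strand must be 'given' or 'both', got {strand!r}")


def composition_matrix(
    segments: SegmentSet, k: int, strand: str = "given"
) -> CompositionMatrix:
    """One rho vector per valid segment, rows in segment order.

    Segments whose vector is invalid (a base absent, or no countable
    window) are dropped and tallied in ``n_invalid_segments``. Raises
    :class:`EmptyCompositionError` when no valid segment remains.
    """
    if k not in (2, 3, 4):
        raise ValueError(f"k must be in {{2, 3, 4}}, got {k}")
    n_seg = len(segments)
    if n_seg == 0:
        raise EmptyCompositionError(
            f"{segments.source_id}: no segments to compose (sequence shorter "
            f"than one {segments.window_bp} bp window)"
        )
    w = segments.window_bp
    p = 4**k
    codes = encode(segments.reassemble())

    # k-mer windows, globally, then restricted to windows inside one segment
    kcode, valid = _window_codes(codes, k)
    starts = np.arange(len(kcode))
    inside = starts // w == (starts + k - 1) // w
    ok = valid & inside
    seg_of = starts[ok] // w
    kmat = np.bincount(seg_of * p + kcode[ok], minlength=n_seg * p).reshape(n_seg, p)

    base_ok = codes >= 0
    seg_of_base = np.arange(len(codes))[base_ok] // w
    mmat = np.bincount(
        seg_of_base * 4 + codes[base_ok], minlength=n_seg * 4
    ).reshape(n_seg, 4)

    if strand == "both":
        kmat = kmat + kmat[:, _revcomp_perm(k)]
        mmat = mmat + mmat[:, ::-1]
    elif strand != "given":
        raise ValueError(f"strand must be 'given' or 'both', got {strand!r}")

    totals = kmat.sum(axis=1)
    row_valid = (totals > 0) & (mmat > 0).all(axis=1)
    if not row_valid.any():
        raise EmptyCompositionError(
            f"{segments.source_id}: zero valid segments at k={k}"
        )
    kmat = kmat[row_valid]
    mmat = mmat[row_valid]
    f = kmat / kmat.sum(axis=1, keepdims=True)
    mono_f = mmat / mmat.sum(axis=1, keepdims=True)
    digits = _digits(k)
    denom = np.ones((row_valid.sum(), p))
    for j in range(k):
        denom *= mono_f[:, digits[:, j]]
    return CompositionMatrix(
        source_id=segments.source_id,
        k=k,
        rows=f / denom,
        n_invalid_segments=int(n_seg - row_valid.sum()),
    )
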