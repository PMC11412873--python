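"""K-mer spectrum construction and ploidy/heterozygosity diagnostics.

A k-mer frequency spectrum of a diploid (or dikaryotic) genome shows two
peaks: homozygous k-mers shared by both haplotypes sit at the full depth
``c`` while k-mers overlapping a heterozygous site are haplotype-specific
and sit near ``c/2``.  This module counts canonical k-mers (lexicographic
minimum of a k-mer and its reverse complement, so counts are
strand-independent), detects spectrum peaks, classifies the spectrum as
unimodal/bimodal/ambiguous, and inverts the heterozygous k-mer fraction into
a simple per-base heterozygosity estimate.

The heterozygosity inversion uses the spanning model: a k-mer overlaps no
heterozygous site with probability ``(1 - h)^k``, and each heterozygous site
contributes two allele-specific k-mer sets (one per haplotype), so the
fraction ``f`` of distinct k-mers attributed to the half-depth peak is
inverted as ``h = 1 - (1 - f/2)^(1/k)``.  This is a deliberately simple
GenomeScope-like surrogate, validated against this package's own simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._encode import encode
from .errors import DegenerateInputError
from .io_formats import SequenceRecord

DEFAULT_K = 31

#: A pair of peaks is called haploid/diploid when the deeper peak's depth is
#: within this factor window of twice the shallower peak's depth.
PEAK_RATIO_WINDOW = (1.6, 2.4)


@dataclass
class KmerHistogram:
    """Spectrum of canonical k-mer multiplicities (or simulated depths)."""

    k: int
    bins: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k % 2 == 0:
            raise ValueError("k must be odd")
        if any(m < 1 for m in self.bins):
            raise ValueError("multiplicities must be positive")

    @property
    def n_distinct(self) -> int:
        return sum(self.bins.values())


@dataclass
class PloidyReport:
    peaks: list[tuple[int, float]]
    modality: str  # unimodal | bimodal | ambiguous
    het_estimate: float | None
    het_kmer_fraction: float


def _canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical integer codes of all valid k-mer windows of a coded sequence.

    Windows containing an ambiguity code (255) are skipped.  Returns an
    int64 array: each value is min(forward, reverse-complement) packed 2 bits
    per base, so k <= 31 fits without overflow.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    bad = (codes >= 4).astype(np.int64)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0

    c = codes.astype(np.int64)
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    safe = np.where(c >= 4, 0, c)  # placeholder; invalid windows masked out
    for j in range(k):
        fwd = fwd * 4 + safe[j : j + n]
    for j in range(k - 1, -1, -1):
        rev = rev * 4 + (3 - safe[j : j + n])
    return np.minimum(fwd, rev)[valid]


def count_canonical_kmers(
    seqs: Iterable[SequenceRecord | str], k: int = DEFAULT_K
) -> dict[str, int]:
    """Count every length-k window under its canonical form.

    k must be odd (a palindromic k-mer would make the canonical form
    ambiguous) and between 3 and 63; windows containing ambiguity codes are
    skipped.
    """
    _check_k(k)
    codes = _pooled_canonical_codes(seqs, k)
    if codes.size == 0:
        return {}
    values, counts = np.unique(codes, return_counts=True)
    if codes.dtype == object:  # string fallback for k > 31
        return {str(v): int(c) for v, c in zip(values, counts)}
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    out: dict[str, int] = {}
    shifts = np.arange(k - 1, -1, -1, dtype=np.int64) * 2
    for v, c in zip(values.tolist(), counts.tolist()):
        letters = lut[(v >> shifts) & 3]
        out[letters.tobytes().decode("ascii")] = int(c)
    return out


def _check_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError("k must be odd (canonical form is ambiguous for palindromes)")
    if not 3 <= k <= 63:
        raise ValueError("k must be between 3 and 63")


def _canonical_strings(seq: str, k: int) -> list[str]:
    """Canonical k-mer strings of one sequence (fallback path for k > 31,
    where 2-bit packing would overflow int64)."""
    from ._encode import reverse_complement

    out = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if set(window) - set("ACGT"):
            continue
        out.append(min(window, reverse_complement(window)))
    return out


def _pooled_canonical_codes(
    seqs: Iterable[SequenceRecord | str], k: int
) -> np.ndarray:
    parts = []
    for s in seqs:
        seq = s.seq if isinstance(s, SequenceRecord) else s
        if k <= 31:
            parts.append(_canonical_codes(encode(seq), k))
        else:
            parts.append(np.array(_canonical_strings(seq, k), dtype=object))
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(parts)


def build_histogram(
    counts: Mapping[str, int] | Sequence[int] | np.ndarray, k: int = DEFAULT_K
) -> KmerHistogram:
    """Bin k-mer multiplicities (or simulated depths) into a spectrum.

    ``bins[m]`` is the number of distinct k-mers observed with multiplicity
    or depth ``m``.
    """
    if isinstance(counts, Mapping):
        values = np.fromiter(counts.values(), dtype=np.int64)
    else:
        values = np.asarray(counts, dtype=np.int64)
    if values.size == 0:
        raise DegenerateInputError("no k-mer counts to histogram")
    mult, n = np.unique(values, return_counts=True)
    return KmerHistogram(k=k, bins={int(m): int(c) for m, c in zip(mult, n) if m >= 1})


def _dense_spectrum(hist: KmerHistogram) -> tuple[np.ndarray, np.ndarray]:
    depths = np.arange(1, max(hist.bins) + 1)
    heights = np.zeros(depths.size, dtype=float)
    for m, c in hist.bins.items():
        heights[m - 1] = c
    return depths, heights


def detect_peaks(
    hist: KmerHistogram,
    smoothing_halfwidth: int = 2,
    min_height_fraction: float = 0.02,
) -> list[tuple[int, float]]:
    """Locate spectrum peaks after smoothing and noise-region truncation.

    The spectrum is smoothed with a moving average of the given halfwidth.
    The low-depth error/noise region is excluded by truncating everything
    below the minimum of the smoothed curve between depth 1 and the global
    maximum (the first valley; nothing is removed when the curve rises
    monotonically to its maximum).  Strict local maxima of the remaining
    smoothed curve are kept if they reach ``min_height_fraction`` of the
    tallest peak (suppressing sampling-noise bumps in the sparse tail) and
    returned sorted by depth; peaks closer than 25% of their mean depth are
    merged, keeping the taller.
    """
    depths, heights = _dense_spectrum(hist)
    w = 2 * smoothing_halfwidth + 1
    kernel = np.ones(w) / w
    smooth = np.convolve(heights, kernel, mode="same")

    top = int(np.argmax(smooth))
    cut = int(np.argmin(smooth[: top + 1]))  # first valley before the mode
    d = depths[cut:]
    y = smooth[cut:]
    floor = min_height_fraction * float(np.max(smooth))

    peaks: list[tuple[int, float]] = []
    for i in range(1, len(y) - 1):
        if y[i] > y[i - 1] and y[i] > y[i + 1] and y[i] >= floor:
            peaks.append((int(d[i]), float(y[i])))

    merged: list[tuple[int, float]] = []
    for depth, height in peaks:
        if merged:
            prev_d, prev_h = merged[-1]
            if depth - prev_d < 0.25 * (depth + prev_d) / 2:
                if height > prev_h:
                    merged[-1] = (depth, height)
                continue
        merged.append((depth, height))
    return merged


def classify_and_estimate(
    hist: KmerHistogram,
    peaks: Sequence[tuple[int, float]] | None = None,
    k: int | None = None,
) -> PloidyReport:
    """Classify the spectrum and estimate per-base heterozygosity.

    Bimodal requires two peaks whose depth ratio lies in
    ``PEAK_RATIO_WINDOW`` (the deeper peak near twice the shallower); the
    shallower is then the heterozygous (haplotype-unique) peak.  Histogram
    bins are attributed to the nearest peak, the heterozygous fraction ``f``
    is computed over the two attributed masses, and heterozygosity is
    ``1 - (1 - f/2)^(1/k)``.
    """
    k = k if k is not None else hist.k
    if peaks is None:
        peaks = detect_peaks(hist)
    peaks = sorted(peaks, key=lambda p: p[0])

    if len(peaks) == 0:
        return PloidyReport([], "ambiguous", None, 0.0)
    if len(peaks) == 1:
        return PloidyReport(list(peaks), "unimodal", None, 0.0)

    # Consider the two tallest peaks as the candidate haploid/diploid pair.
    tallest = sorted(peaks, key=lambda p: p[1], reverse=True)[:2]
    low, high = sorted(tallest, key=lambda p: p[0])
    ratio = high[0] / low[0]
    lo, hi = PEAK_RATIO_WINDOW
    if not lo <= ratio <= hi:
        return PloidyReport(list(peaks), "ambiguous", None, 0.0)

    het_mass = 0
    hom_mass = 0
    for depth, count in hist.bins.items():
        if abs(depth - low[0]) <= abs(depth - high[0]):
            het_mass += count
        else:
            hom_mass += count
    total = het_mass + hom_mass
    f = het_mass / total if total else 0.0
    het = 1.0 - (1.0 - f / 2.0) ** (1.0 / k)
    return PloidyReport(list(peaks), "bimodal", het, f)


def analyze_spectrum(hist: KmerHistogram) -> PloidyReport:
    """Convenience wrapper: peak detection followed by classification."""
    return classify_and_estimate(hist, detect_peaks(hist), hist.k)


def read_histogram(path, k: int = DEFAULT_K) -> KmerHistogram:
    """Read a two-column TSV (depth, count) into a histogram."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    bins = {int(d): int(c) for d, c in zip(df.iloc[:, 0], df.iloc[:, 1])}
    return KmerHistogram(k=k, bins=bins)


def write_histogram(hist: KmerHistogram, path) -> None:
    with open(path, "w") as handle:
        handle.write("depth\tcount\n")
        for depth in sorted(hist.bins):
            handle.write(f"{depth}\t{hist.bins[depth]}\n")
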