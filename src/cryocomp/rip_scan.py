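"""Sliding-window scan for repeat-induced point mutation (RIP).

RIP is a fungal genome-defense process that introduces C->T transition
mutations in duplicated sequence, preferentially at CpA dinucleotides (TpG on
the reverse strand).  The mutation depletes the substrate dinucleotides
CpA/TpG and creates TpA, so RIP-affected sequence is recognized from three
dinucleotide-ratio indices computed in sliding windows:

* product index  = TpA / ApT          (elevated by RIP)
* substrate index = (CpA + TpG) / (ApC + GpT)   (depleted by RIP)
* composite index = product - substrate          (positive under RIP)

A window is RIP-positive only when all three indices indicate RIP (product >
1.15, substrate < 0.75, composite > 0 under the stringent defaults, all
strict).  Runs of consecutive positive windows are merged into regions;
regions longer than 4000 bp (strict) are large RIP-affected regions (LRARs).
The genome-wide RIP percentage is the union of positive-window bases divided
by assembly length.

Zero-denominator windows are declared non-RIP (a conservative convention);
contigs shorter than one window are analyzed as a single whole-contig window
flagged ``short``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._encode import encode
from .errors import DegenerateInputError
from .io_formats import SequenceRecord

#: order of the six RIP-relevant dinucleotides in count tuples
DINUCLEOTIDES = ("TpA", "ApT", "CpA", "TpG", "ApC", "GpT")

# 2-bit pair codes (first*4 + second) for the six dinucleotides
_PAIR_CODES = {"TpA": 12, "ApT": 3, "CpA": 4, "TpG": 14, "ApC": 1, "GpT": 11}


@dataclass(frozen=True)
class RipConfig:
    """Window geometry and thresholds for the RIP scan (stringent defaults)."""

    window: int = 1000
    step: int = 500
    product_min: float = 1.15
    substrate_max: float = 0.75
    composite_min: float = 0.0
    lrar_min_len: int = 4000

    def __post_init__(self) -> None:
        if self.step > self.window:
            raise ValueError("step must not exceed window")
        if self.window < 2 or self.step < 1:
            raise ValueError("window and step must be positive (window >= 2)")


@dataclass
class RipWindow:
    contig: str
    start: int
    end: int
    counts: tuple[int, int, int, int, int, int]  # order: DINUCLEOTIDES
    product: float
    substrate: float
    composite: float
    gc: float
    rip_positive: bool
    short: bool = False


@dataclass
class Lrar:
    contig: str
    start: int
    end: int
    mean_composite: float
    n_windows: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RipSummary:
    genome_rip_percent: float
    total_rip_bp: int
    genome_bp: int
    lrars: list[Lrar] = field(default_factory=list)
    lrar_mean_composite: float | None = None


def dinucleotide_counts(seq: str) -> dict[str, int]:
    """Count the six RIP-relevant overlapping forward-strand dinucleotides.

    Pairs containing an ambiguity code are skipped; a sequence shorter than
    two bases is a degenerate input.
    """
    if len(seq) < 2:
        raise DegenerateInputError("sequence shorter than one dinucleotide")
    codes = encode(seq)
    return _counts_from_codes(codes)


def _counts_from_codes(codes: np.ndarray) -> dict[str, int]:
    first, second = codes[:-1], codes[1:]
    valid = (first < 4) & (second < 4)
    pair = first.astype(np.int16) * 4 + second
    out = {}
    for name, code in _PAIR_CODES.items():
        out[name] = int(np.count_nonzero(valid & (pair == code)))
    return out


def rip_indices(counts: dict[str, int]) -> tuple[float, float, float, bool]:
    """Product, substrate and composite indices from dinucleotide counts.

    Returns ``(product, substrate, composite, defined)``; ``defined`` is
    False when either denominator is zero, in which case the affected index
    is reported as 0 and the window must be treated as RIP-negative.
    """
    defined = True
    if counts["ApT"] > 0:
        product = counts["TpA"] / counts["ApT"]
    else:
        product, defined = 0.0, False
    denom = counts["ApC"] + counts["GpT"]
    if denom > 0:
        substrate = (counts["CpA"] + counts["TpG"]) / denom
    else:
        substrate, defined = 0.0, False
    composite = product - substrate if defined else 0.0
    return product, substrate, composite, defined


def window_positive(
    product: float,
    substrate: float,
    composite: float,
    defined: bool,
    config: RipConfig = RipConfig(),
) -> bool:
    """RIP-positive call: all three indices must pass strictly, and a window
    with a zero denominator in either index is never positive."""
    return (
        defined
        and product > config.product_min
        and substrate < config.substrate_max
        and composite > config.composite_min
    )


def _window_starts(contig_len: int, window: int, step: int) -> list[int]:
    return list(range(0, contig_len - window + 1, step))


def scan_windows(
    assembly: Iterable[SequenceRecord], config: RipConfig = RipConfig()
) -> list[RipWindow]:
    """Scan every contig with sliding windows and score each window.

    Full windows start at 0, step, 2*step, ... while ``start + window`` fits;
    contigs shorter than one window yield a single whole-contig window
    flagged ``short``.  A window is RIP-positive iff all three indices pass
    their thresholds strictly and both denominators are nonzero.
    """
    windows: list[RipWindow] = []
    for rec in assembly:
        codes = encode(rec.seq)
        n = len(codes)
        if n < config.window:
            spans = [(0, n)]
            short = True
        else:
            spans = [(s, s + config.window) for s in _window_starts(n, config.window, config.step)]
            short = False

        # prefix sums per pair type over pair positions 0..n-2
        first, second = codes[:-1], codes[1:]
        valid = (first < 4) & (second < 4)
        pair = first.astype(np.int16) * 4 + second
        prefix = {}
        for name, code in _PAIR_CODES.items():
            ind = (valid & (pair == code)).astype(np.int64)
            prefix[name] = np.concatenate(([0], np.cumsum(ind)))
        gc_ind = ((codes == 1) | (codes == 2)).astype(np.int64)
        base_ind = (codes < 4).astype(np.int64)
        gc_prefix = np.concatenate(([0], np.cumsum(gc_ind)))
        base_prefix = np.concatenate(([0], np.cumsum(base_ind)))

        for start, end in spans:
            counts = tuple(
                int(prefix[name][end - 1] - prefix[name][start])
                for name in DINUCLEOTIDES
            )
            cdict = dict(zip(DINUCLEOTIDES, counts))
            product, substrate, composite, defined = rip_indices(cdict)
            nbases = base_prefix[end] - base_prefix[start]
            gc = float((gc_prefix[end] - gc_prefix[start]) / nbases) if nbases else 0.0
            positive = window_positive(product, substrate, composite, defined, config)
            windows.append(
                RipWindow(
                    contig=rec.id,
                    start=start,
                    end=end,
                    counts=counts,
                    product=product,
                    substrate=substrate,
                    composite=composite,
                    gc=gc,
                    rip_positive=positive,
                    short=short,
                )
            )
    return windows


def call_rip_regions(
    windows: Sequence[RipWindow], config: RipConfig = RipConfig()
) -> tuple[list[tuple[str, int, int, float]], list[Lrar]]:
    """Merge runs of consecutive RIP-positive windows into regions and LRARs.

    On each contig, maximal runs of positive windows (consecutive in scan
    order) are merged into one region [first.start, last.end); overlapping
    windows merge by union.  Regions strictly longer than ``lrar_min_len``
    become LRARs; the region score is the unweighted mean composite index of
    its member windows.
    """
    prev: tuple[str, int] | None = None
    for w in windows:
        key = (w.contig, w.start)
        if prev is not None and w.contig == prev[0] and w.start < prev[1]:
            raise ValueError("windows must be sorted by (contig, start)")
        if prev is not None and w.contig != prev[0]:
            pass
        prev = key

    regions: list[tuple[str, int, int, float]] = []
    lrars: list[Lrar] = []
    run: list[RipWindow] = []

    def _flush() -> None:
        if not run:
            return
        contig = run[0].contig
        start, end = run[0].start, run[-1].end
        mean_comp = float(np.mean([w.composite for w in run]))
        regions.append((contig, start, end, mean_comp))
        if end - start > config.lrar_min_len:
            lrars.append(Lrar(contig, start, end, mean_comp, len(run)))
        run.clear()

    last_contig = None
    for w in windows:
        if w.contig != last_contig:
            _flush()
            last_contig = w.contig
        if w.rip_positive:
            run.append(w)
        else:
            _flush()
    _flush()
    return regions, lrars


def summarize_rip(
    assembly: Iterable[SequenceRecord],
    regions: Sequence[tuple[str, int, int, float]],
    lrars: Sequence[Lrar],
) -> RipSummary:
    """Genome-wide RIP percentage from the union of RIP-positive regions."""
    genome_bp = sum(len(rec.seq) for rec in assembly)
    total_rip_bp = sum(end - start for _, start, end, _ in regions)
    percent = 100.0 * total_rip_bp / genome_bp if genome_bp else 0.0
    mean_comp = (
        float(np.mean([l.mean_composite for l in lrars])) if lrars else None
    )
    return RipSummary(
        genome_rip_percent=percent,
        total_rip_bp=total_rip_bp,
        genome_bp=genome_bp,
        lrars=list(lrars),
        lrar_mean_composite=mean_comp,
    )


def scan_assembly(
    assembly: Sequence[SequenceRecord], config: RipConfig = RipConfig()
) -> tuple[list[RipWindow], list[tuple[str, int, int, float]], list[Lrar], RipSummary]:
    """Full pipeline: scan, call regions/LRARs, summarize."""
    windows = scan_windows(assembly, config)
    regions, lrars = call_rip_regions(windows, config)
    summary = summarize_rip(assembly, regions, lrars)
    return windows, regions, lrars, summary


def windows_to_frame(windows: Sequence[RipWindow]) -> pd.DataFrame:
    rows = []
    for w in windows:
        row = {
            "contig": w.contig,
            "start": w.start,
            "end": w.end,
            **dict(zip(DINUCLEOTIDES, w.counts)),
            "product": w.product,
            "substrate": w.substrate,
            "composite": w.composite,
            "gc": w.gc,
            "rip_positive": w.rip_positive,
            "short": w.short,
        }
        rows.append(row)
    return pd.DataFrame(rows)
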