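"""Nucleotide composition metrics and group comparisons.

Computes GC content of whole genomes and individual contigs, GC of coding
sequences, and GC3 (the fraction of G or C at third codon positions, pooled
over all codons of all CDS rather than averaged per gene).  Ambiguity codes
(including N) are excluded from both numerator and denominator of every GC
calculation, so gap-rich assemblies are not biased downward.

Group comparisons of any per-species metric (genome size, GC, GC3, ...) use
one-way ANOVA followed by Tukey's HSD, via scipy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError
from .io_formats import SequenceRecord


@dataclass
class CompositionReport:
    species_id: str
    genome_gc: float
    contig_gc: list[tuple[str, int, float]]
    cds_gc: float | None = None
    gc3: float | None = None
    n_cds: int = 0
    n_partial_codons_trimmed: int = 0


@dataclass
class GroupComparison:
    metric: str
    group_means: dict[str, float]
    F: float
    df_between: int
    df_within: int
    p: float
    tukey: pd.DataFrame | None = None


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T); ambiguity codes excluded from both sides."""
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    total = gc + at
    if total == 0:
        raise DegenerateInputError("sequence contains no unambiguous base")
    return gc / total


def per_contig_gc(
    assembly: Sequence[SequenceRecord], bin_width: float = 2.0
) -> tuple[list[tuple[str, int, float]], list[tuple[float, float]]]:
    """Per-contig GC plus a binned histogram of contig GC percentages.

    Returns ``(rows, histogram)`` where rows are (contig_id, length, gc) and
    the histogram gives (bin_left_percent, fraction_of_contigs) for bins of
    ``bin_width`` percentage points over [0, 100]; the top bin is closed.
    """
    if not assembly:
        raise DegenerateInputError("empty assembly")
    rows = [(rec.id, len(rec.seq), gc_content(rec.seq)) for rec in assembly]

    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    percents = [gc * 100.0 for _, _, gc in rows]
    counts, _ = np.histogram(percents, bins=edges)  # np.histogram closes top bin
    fractions = counts / len(rows)
    histogram = [
        (float(edges[i]), float(fractions[i])) for i in range(len(fractions))
    ]
    return rows, histogram


def genome_gc(assembly: Sequence[SequenceRecord]) -> float:
    """Pooled GC over the whole assembly (equals the length-weighted contig mean)."""
    gc = at = 0
    for rec in assembly:
        gc += rec.seq.count("G") + rec.seq.count("C")
        at += rec.seq.count("A") + rec.seq.count("T")
    if gc + at == 0:
        raise DegenerateInputError("assembly contains no unambiguous base")
    return gc / (gc + at)


def cds_gc_and_gc3(
    cds_set: Iterable[SequenceRecord], per_gene: bool = False
) -> tuple[float, float, int]:
    """GC of coding sequence and GC3, pooled over all codons of all CDS.

    Trailing partial codons are trimmed (with a warning) and counted;
    records shorter than one codon are skipped with a warning.  With
    ``per_gene=True``, GC and GC3 are averaged over genes instead of pooled.
    Stop codons are not excluded.
    """
    n_trimmed = 0
    pooled_gc = pooled_total = 0
    pooled_gc3 = pooled_third = 0
    gene_gc: list[float] = []
    gene_gc3: list[float] = []

    for rec in cds_set:
        seq = rec.seq
        extra = len(seq) % 3
        if extra:
            if len(seq) < 3:
                warnings.warn(f"CDS {rec.id!r} shorter than one codon; skipped")
                continue
            warnings.warn(f"CDS {rec.id!r}: trimming {extra}-base partial codon")
            seq = seq[:-extra]
            n_trimmed += 1
        third = seq[2::3]
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        gc3 = third.count("G") + third.count("C")
        at3 = third.count("A") + third.count("T")
        pooled_gc += gc
        pooled_total += gc + at
        pooled_gc3 += gc3
        pooled_third += gc3 + at3
        if per_gene and gc + at > 0 and gc3 + at3 > 0:
            gene_gc.append(gc / (gc + at))
            gene_gc3.append(gc3 / (gc3 + at3))

    if pooled_total == 0 or pooled_third == 0:
        raise DegenerateInputError("no usable coding sequence")
    if per_gene:
        return float(np.mean(gene_gc)), float(np.mean(gene_gc3)), n_trimmed
    return pooled_gc / pooled_total, pooled_gc3 / pooled_third, n_trimmed


def composition_report(
    species_id: str,
    assembly: Sequence[SequenceRecord],
    cds_set: Sequence[SequenceRecord] | None = None,
) -> CompositionReport:
    """Full composition report for one species."""
    rows, _ = per_contig_gc(assembly)
    report = CompositionReport(
        species_id=species_id,
        genome_gc=genome_gc(assembly),
        contig_gc=rows,
    )
    if cds_set:
        cds_gc, gc3, n_trim = cds_gc_and_gc3(cds_set)
        report.cds_gc = cds_gc
        report.gc3 = gc3
        report.n_cds = len(cds_set)
        report.n_partial_codons_trimmed = n_trim
    return report


def _validate_groups(values: Mapping[str, Sequence[float]]) -> None:
    if len(values) < 2:
        raise ValueError("need at least two groups")
    for g, v in values.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than two values")


def anova_oneway(
    values: Mapping[str, Sequence[float]], metric: str = "metric"
) -> GroupComparison:
    """Classical one-way ANOVA across groups of per-species values.

    Degenerate cases: identical group means with zero within-group variance
    give F=0, p=1; separated means with zero within-group variance give
    F=inf, p=0.
    """
    _validate_groups(values)
    groups = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    k = len(groups)
    n_total = sum(len(v) for v in groups.values())
    df_between, df_within = k - 1, n_total - k
    means = {g: float(np.mean(v)) for g, v in groups.items()}

    grand = np.mean(np.concatenate(list(groups.values())))
    ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
    ss_within = sum(np.sum((v - np.mean(v)) ** 2) for v in groups.values())

    if ss_within == 0:
        if ss_between == 0:
            F, p = 0.0, 1.0
        else:
            F, p = float("inf"), 0.0
    else:
        F, p = stats.f_oneway(*groups.values())
        F, p = float(F), float(p)
    return GroupComparison(
        metric=metric,
        group_means=means,
        F=F,
        df_between=df_between,
        df_within=df_within,
        p=p,
    )


def tukey_hsd(
    values: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """All-pairs Tukey HSD via the studentized-range distribution.

    Returns one row per unordered pair with the mean difference (a - b), the
    adjusted p-value, and a significance flag at ``alpha``.
    """
    _validate_groups(values)
    labels = list(values.keys())
    arrays = [np.asarray(values[g], dtype=float) for g in labels]
    result = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            diff = float(np.mean(arrays[i]) - np.mean(arrays[j]))
            p = float(result.pvalue[i, j])
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": diff,
                    "adjusted_p": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def compare_groups(
    metric_values: Mapping[str, float],
    groups: Mapping[str, str],
    metric: str = "metric",
    alpha: float = 0.05,
) -> GroupComparison:
    """ANOVA + Tukey of one per-species metric across lifestyle groups."""
    by_group: dict[str, list[float]] = {}
    for species, value in metric_values.items():
        by_group.setdefault(groups[species], []).append(float(value))
    comparison = anova_oneway(by_group, metric=metric)
    comparison.tukey = tukey_hsd(by_group, alpha=alpha)
    return comparison
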