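"""Generators for synthetic inputs with the statistical structure the
pipeline assumes, so every analysis stage is testable without downloads.

Four generators are provided, each a pure function of its arguments and a
seed:

* gene-count matrices with two species groups and planted multiplicative
  expansions/contractions, drawn from a negative binomial (counts of gene
  family members are overdispersed relative to Poisson);
* random genomes with controlled GC, optionally containing planted repeat
  regions subjected to RIP-style C->T mutation in the CpA (forward) / TpG
  (reverse-strand CpA) context, the canonical Neurospora preference;
* coding sequences with controlled third-codon GC (GC3) — composition
  fixtures, not genes: no stop-codon avoidance;
* diploid k-mer depth spectra at a stated per-base heterozygosity, simulated
  at the k-mer level (haplotype pair -> canonical k-mer multiplicities ->
  Poisson depths), with no read-level error model.

The planted truth of every generator is recorded in a ``SyntheticTruth`` so
recovery can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._encode import decode, encode
from .errors import DegenerateInputError
from .io_formats import GeneCountMatrix, SequenceRecord
from .kmer_ploidy import KmerHistogram, _canonical_codes, _check_k


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator, the recovery target of tests."""

    seed: int
    planted_expanded: set[str] = field(default_factory=set)
    planted_contracted: set[str] = field(default_factory=set)
    effect_multiplier: float = 1.0
    rip_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    rip_rate: float = 0.0
    het_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.planted_expanded & self.planted_contracted:
            raise ValueError("an orthogroup cannot be both expanded and contracted")


def simulate_count_matrix(
    n_orthogroups: int,
    group_sizes: Mapping[str, int],
    baseline_mean: float = 3.0,
    dispersion: float = 2.0,
    n_expanded: int = 0,
    n_contracted: int = 0,
    effect_multiplier: float = 4.0,
    focal_group: str | None = None,
    seed: int = 0,
) -> tuple[GeneCountMatrix, SyntheticTruth]:
    """Negative-binomial gene-count matrix with planted group shifts.

    Counts are i.i.d. NB with the stated mean and dispersion theta
    (variance = mu + mu^2/theta).  For planted-expanded orthogroups the
    focal-group mean is multiplied by ``effect_multiplier`` before sampling;
    for planted-contracted it is divided by it.  The focal group defaults to
    the first key of ``group_sizes``.
    """
    if n_expanded + n_contracted > n_orthogroups:
        raise ValueError("more planted orthogroups than orthogroups")
    if (n_expanded or n_contracted) and effect_multiplier <= 1:
        raise ValueError("effect_multiplier must exceed 1")
    if baseline_mean <= 0 or dispersion <= 0:
        raise ValueError("baseline_mean and dispersion must be positive")
    group_names = list(group_sizes)
    if focal_group is None:
        focal_group = group_names[0]
    if group_sizes.get(focal_group, 0) < 2:
        raise ValueError("focal group needs >= 2 species")
    if sum(v for g, v in group_sizes.items() if g != focal_group) < 2:
        raise ValueError("background needs >= 2 species")

    rng = np.random.default_rng(seed)
    species: list[str] = []
    groups: dict[str, str] = {}
    for g in group_names:
        for i in range(group_sizes[g]):
            name = f"{g}_{i + 1:02d}"
            species.append(name)
            groups[name] = g
    og_ids = [f"OG{i:07d}" for i in range(n_orthogroups)]

    planted = rng.choice(n_orthogroups, size=n_expanded + n_contracted, replace=False)
    expanded_idx = planted[:n_expanded]
    contracted_idx = planted[n_expanded:]

    mu = np.full((n_orthogroups, len(species)), baseline_mean, dtype=float)
    focal_cols = np.array([groups[s] == focal_group for s in species])
    mu[np.ix_(expanded_idx, np.flatnonzero(focal_cols))] *= effect_multiplier
    mu[np.ix_(contracted_idx, np.flatnonzero(focal_cols))] /= effect_multiplier

    # NB(mean mu, dispersion theta): numpy's (n, p) with n=theta, p=theta/(theta+mu)
    p = dispersion / (dispersion + mu)
    counts = rng.negative_binomial(dispersion, p)

    matrix = GeneCountMatrix(
        pd.DataFrame(counts, index=og_ids, columns=species), groups
    )
    truth = SyntheticTruth(
        seed=seed,
        planted_expanded={og_ids[i] for i in expanded_idx},
        planted_contracted={og_ids[i] for i in contracted_idx},
        effect_multiplier=effect_multiplier,
    )
    return matrix, truth


def simulate_genome(
    length: int, gc: float = 0.5, seed: int = 0, contig_id: str = "synth_contig"
) -> SequenceRecord:
    """Random genome with i.i.d. bases: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
    return SequenceRecord(id=contig_id, seq=decode(codes))


def rip_mutate(seq: str, rate: float, seed: int = 0) -> str:
    """Apply RIP-style C->T mutation at CpA/TpG contexts of the original sequence.

    A single left-to-right pass over the ORIGINAL sequence: the C of each
    forward-strand CpA is replaced by T with probability ``rate``, and the G
    of each forward-strand TpG (the reverse-strand CpA) is replaced by A with
    the same probability.  Contexts created by mutations are never
    re-evaluated, so the operation is order-independent and reproducible.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    codes = encode(seq)
    if (codes >= 4).any():
        raise ValueError("rip_mutate requires a pure ACGT sequence")
    rng = np.random.default_rng(seed)
    out = codes.copy()
    first, second = codes[:-1], codes[1:]
    ca = np.flatnonzero((first == 1) & (second == 0))  # C at i, A at i+1
    tg = np.flatnonzero((first == 3) & (second == 2))  # T at i, G at i+1
    if ca.size:
        hit = rng.random(ca.size) < rate
        out[ca[hit]] = 3  # C -> T
    if tg.size:
        hit = rng.random(tg.size) < rate
        out[tg[hit] + 1] = 0  # G -> A
    return decode(out)


def simulate_ripped_genome(
    length: int,
    gc: float = 0.55,
    n_regions: int = 2,
    region_length: int = 8000,
    rate: float = 0.9,
    seed: int = 0,
    contig_id: str = "synth_contig",
) -> tuple[SequenceRecord, SyntheticTruth]:
    """Random genome with non-overlapping planted regions mutated by RIP.

    Region starts are drawn uniformly among all non-overlapping placements
    (sorted uniform draws over the free space); the planted intervals are
    recorded in the returned truth.
    """
    if n_regions * region_length > length // 2:
        raise ValueError("planted regions must cover at most half the genome")
    background = simulate_genome(length, gc=gc, seed=seed, contig_id=contig_id)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    intervals: list[tuple[str, int, int]] = []
    seq = background.seq
    if n_regions > 0:
        free = length - n_regions * region_length
        offsets = np.sort(rng.integers(0, free + 1, size=n_regions))
        chars = list(seq)
        for i, off in enumerate(offsets):
            start = int(off + i * region_length)
            end = start + region_length
            mutated = rip_mutate(seq[start:end], rate, seed=int(rng.integers(2**31)))
            chars[start:end] = mutated
            intervals.append((contig_id, start, end))
        seq = "".join(chars)

    record = SequenceRecord(id=contig_id, seq=seq)
    truth = SyntheticTruth(seed=seed, rip_intervals=intervals, rip_rate=rate)
    return record, truth


def simulate_cds(
    n: int, n_codons: int, gc3_target: float = 0.5, seed: int = 0
) -> list[SequenceRecord]:
    """Composition fixtures: CDS with controlled third-codon GC.

    Third-position bases are G or C with total probability ``gc3_target``
    (split evenly), A or T otherwise; first and second positions are uniform.
    No stop-codon avoidance — these are composition fixtures, not genes.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if not 0.0 <= gc3_target <= 1.0:
        raise ValueError("gc3_target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    p3 = np.array(
        [(1 - gc3_target) / 2, gc3_target / 2, gc3_target / 2, (1 - gc3_target) / 2]
    )
    for i in range(n):
        codes = np.empty(3 * n_codons, dtype=np.uint8)
        codes[0::3] = rng.integers(0, 4, size=n_codons)
        codes[1::3] = rng.integers(0, 4, size=n_codons)
        codes[2::3] = rng.choice(4, size=n_codons, p=p3)
        records.append(SequenceRecord(id=f"cds_{i + 1:05d}", seq=decode(codes)))
    return records


def simulate_diploid_kmers(
    genome_length: int, het_rate: float, k: int = 21, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate a haplotype pair and count canonical k-mer multiplicities.

    Returns ``(hap_a, hap_b, het_sites, multiplicities)``: the two haplotype
    code arrays, the planted substitution positions, and the multiplicity of
    every distinct canonical k-mer over both haplotypes (1 for
    haplotype-unique, 2 for shared, higher for genomic repeats).
    """
    _check_k(k)
    if not 0.0 <= het_rate < 0.1:
        raise ValueError("het_rate must be in [0, 0.1) (model breaks above)")
    rng = np.random.default_rng(seed)
    hap_a = rng.integers(0, 4, size=genome_length).astype(np.uint8)
    hap_b = hap_a.copy()
    het_sites = np.flatnonzero(rng.random(genome_length) < het_rate)
    if het_sites.size:
        shift = rng.integers(1, 4, size=het_sites.size).astype(np.uint8)
        hap_b[het_sites] = (hap_b[het_sites] + shift) % 4
    if k <= 31:
        codes = np.concatenate([_canonical_codes(hap_a, k), _canonical_codes(hap_b, k)])
    else:  # string path: 2-bit packing overflows int64 beyond k=31
        from .kmer_ploidy import _canonical_strings

        codes = np.array(
            _canonical_strings(decode(hap_a), k) + _canonical_strings(decode(hap_b), k),
            dtype=object,
        )
    _, multiplicity = np.unique(codes, return_counts=True)
    return hap_a, hap_b, het_sites, multiplicity


def simulate_diploid_spectrum(
    genome_length: int,
    het_rate: float,
    coverage: float = 40.0,
    k: int = 21,
    seed: int = 0,
) -> tuple[KmerHistogram, SyntheticTruth]:
    """Canonical k-mer depth spectrum of a simulated diploid genome.

    Haplotype A is a random genome; haplotype B carries i.i.d. substitutions
    at ``het_rate`` (to a uniformly chosen different base).  Canonical k-mers
    are counted over both haplotypes; a distinct k-mer of multiplicity m
    (1 for haplotype-unique, 2 for shared) receives an observed depth drawn
    from Poisson(m * coverage / 2).  Depth-0 k-mers are dropped.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    _, _, _, multiplicity = simulate_diploid_kmers(genome_length, het_rate, k, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    depths = rng.poisson(multiplicity * coverage / 2.0)
    depths = depths[depths > 0]
    if depths.size == 0:
        raise DegenerateInputError("all simulated k-mer depths were zero")
    mult, counts = np.unique(depths, return_counts=True)
    hist = KmerHistogram(k=k, bins={int(m): int(c) for m, c in zip(mult, counts)})
    truth = SyntheticTruth(seed=seed, het_rate=het_rate)
    return hist, truth
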