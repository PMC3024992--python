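"""Per-individual genotyping, locus-number estimation and replicate
concordance.

An individual's genotype is the set of accepted alleles with at least
``min_reads`` reads in its amplicon.  Because a true recombinant allele can
co-occur with both of its evolutionary parents in some individuals, any
called allele that *could* be a single-crossover chimera of two more
abundant called alleles is discarded for the conservative count; the
conservative per-individual maximum, divided by the diploid copy number,
bounds the number of loci from below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .variant_filter import ChimeraWitness, explainable_as_chimera

__all__ = [
    "Genotype",
    "ConcordanceReport",
    "call_alleles",
    "conservative_count",
    "min_locus_count",
    "replicate_concordance",
]

PLOIDY = 2  # diploid: each locus contributes at most two distinct alleles


@dataclass
class Genotype:
    individual: str
    replicate: int
    alleles: list[tuple[str, int]]  # (allele sequence/id, read count)
    per_cluster: dict[str, int] = field(default_factory=dict)
    conservative_alleles: Optional[list[str]] = None
    witnesses: list[ChimeraWitness] = field(default_factory=list)

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def conservative_count(self) -> int:
        if self.conservative_alleles is None:
            return self.n_alleles
        return len(self.conservative_alleles)


@dataclass
class ConcordanceReport:
    """Mean numbers of replicate-shared and single-replicate alleles per
    individual, overall and per cluster category."""

    n_individuals: int
    shared_mean: dict[str, float]
    single_replicate_mean: dict[str, float]


def call_alleles(
    amplicon_counts: Mapping[str, int],
    allele_set: Iterable[str],
    min_reads: int = 2,
    *,
    individual: str = "",
    replicate: int = 1,
    clusters: Optional[Mapping[str, str]] = None,
) -> Genotype:
    """Alleles of the accepted set with >= min_reads reads in the amplicon,
    sorted by descending read count (ties by sequence)."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    accepted = set(allele_set)
    called = sorted(
        ((a, c) for a, c in amplicon_counts.items() if a in accepted and c >= min_reads),
        key=lambda ac: (-ac[1], ac[0]),
    )
    per_cluster: dict[str, int] = {}
    if clusters is not None:
        for a, _ in called:
            lab = clusters.get(a, "unclassified")
            per_cluster[lab] = per_cluster.get(lab, 0) + 1
    return Genotype(
        individual=individual,
        replicate=replicate,
        alleles=called,
        per_cluster=per_cluster,
    )


def conservative_count(
    genotype: Genotype, amplicon_counts: Mapping[str, int]
) -> int:
    """Allele count after discarding every called allele explainable as a
    single crossover of two strictly more abundant *called* alleles in the
    same amplicon.

    Single pass over alleles in descending abundance; a discarded allele
    stays in the parent pool, so verdicts do not depend on the order in
    which chimera-like alleles are removed.  Updates the genotype in place
    (``conservative_alleles``, ``witnesses``) and returns the count.
    """
    called = {a: amplicon_counts.get(a, 0) for a, _ in genotype.alleles}
    kept: list[str] = []
    witnesses: list[ChimeraWitness] = []
    for allele, _count in genotype.alleles:  # already sorted descending
        w = explainable_as_chimera(allele, called)
        if w is None:
            kept.append(allele)
        else:
            witnesses.append(w)
    genotype.conservative_alleles = kept
    genotype.witnesses = witnesses
    return len(kept)


def min_locus_count(max_alleles: int, ploidy: int = PLOIDY) -> int:
    """Minimum number of loci consistent with a per-individual maximum
    allele count: ceil(max / ploidy)."""
    if max_alleles < 0:
        raise ValueError("allele count cannot be negative")
    return math.ceil(max_alleles / ploidy)


def replicate_concordance(
    replicate_counts_by_individual: Mapping[str, Sequence[Mapping[str, int]]],
    allele_set: Iterable[str],
    *,
    clusters: Optional[Mapping[str, str]] = None,
    min_reads_evidence: int = 2,
) -> ConcordanceReport:
    """Replicate concordance of allele detection.

    For each individual with >= 2 replicate amplicons: an allele is *shared*
    when it has >= 1 read in every replicate, and *single-replicate* when it
    has >= ``min_reads_evidence`` reads in exactly one replicate and zero
    reads in all others.  Means are reported per category ("all" plus each
    cluster label when ``clusters`` is given).
    """
    accepted = sorted(set(allele_set))
    replicated = {
        ind: reps
        for ind, reps in replicate_counts_by_individual.items()
        if len(reps) >= 2
    }
    if not replicated:
        import warnings

        warnings.warn("no individuals with >= 2 replicates; empty report")
        return ConcordanceReport(0, {}, {})
    categories = ["all"]
    if clusters is not None:
        categories += sorted(set(clusters.values()))
    shared_sums = {c: 0 for c in categories}
    single_sums = {c: 0 for c in categories}
    for ind, reps in replicated.items():
        for allele in accepted:
            counts = [r.get(allele, 0) for r in reps]
            cats = ["all"]
            if clusters is not None:
                cats.append(clusters.get(allele, "unclassified"))
            if all(c >= 1 for c in counts):
                for cat in cats:
                    if cat in shared_sums:
                        shared_sums[cat] += 1
            elif (
                sum(c >= min_reads_evidence for c in counts) == 1
                and sum(c > 0 for c in counts) == 1
            ):
                for cat in cats:
                    if cat in single_sums:
                        single_sums[cat] += 1
    n = len(replicated)
    return ConcordanceReport(
        n_individuals=n,
        shared_mean={c: shared_sums[c] / n for c in categories},
        single_replicate_mean={c: single_sums[c] / n for c in categories},
    )
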