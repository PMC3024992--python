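"""Cluster assignment, reading-frame assessment and allele phylogenetics.

Putative alleles of the amplified MHC class IIB exon-2 fragment fall into
sequence clusters with different functional status:

* **cluster I** — low-divergence pseudogenes marked by a diagnostic C/T at
  the first window position and a 1–2 bp frameshift deletion;
* **group II.A** — pseudogenes within cluster II bearing a 9-bp plus a 1-bp
  deletion (net 10 bp, a frameshift);
* **expressed cluster II** — divergent alleles with a diagnostic G, intact
  reading frame and no internal stop codons, cross-checkable against
  cDNA-derived sequences.

Relationships among alleles are summarised by a neighbour-joining tree of
Tamura–Nei (TN93) distances with column-bootstrap support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Seq import Seq

__all__ = [
    "CodingAssessment",
    "ClusterLabel",
    "CLUSTER_I",
    "GROUP_IIA",
    "EXPRESSED_II",
    "UNCLASSIFIED",
    "assess_coding",
    "assign_cluster",
    "consensus_reference",
    "match_cdna",
    "tamura_nei_distance",
    "neighbor_joining",
    "bootstrap_support",
]

CLUSTER_I = "cluster_I"
GROUP_IIA = "group_IIA"
EXPRESSED_II = "expressed_II"
UNCLASSIFIED = "unclassified"

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class IndelEvent:
    """An insertion (+length) or deletion (-length) relative to the
    reference, at a reference coordinate."""

    position: int
    length: int  # >0 insertion, <0 deletion


@dataclass
class CodingAssessment:
    frame_offset: int
    indels: list[IndelEvent]
    frameshift: bool
    internal_stops: list[int]  # codon indices in the variant's own frame

    @property
    def net_indel(self) -> int:
        return sum(e.length for e in self.indels)


@dataclass
class ClusterLabel:
    label: str
    diagnostic_base: str
    assessment: Optional[CodingAssessment] = None


def _aligner() -> Align.PairwiseAligner:
    # affine scores chosen to keep small indels as single contiguous gaps
    a = Align.PairwiseAligner(
        mode="global",
        match_score=2,
        mismatch_score=-1,
        open_gap_score=-6,
        extend_gap_score=-0.5,
    )
    return a


def assess_coding(
    variant: str, reference: str, frame_offset: int = 0
) -> CodingAssessment:
    """Align the variant to a functional reference and assess its reading
    frame.

    Indels are taken from a global pairwise alignment.  A frameshift is a
    prefix of indel events whose net length is not a multiple of 3 (a later
    compensating indel does not restore the intervening frame).  The variant
    is translated in its own frame up to the first frame loss; internal stop
    codons found in that region are reported.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    variant = variant.upper()
    reference = reference.upper()
    aln = _aligner().align(reference, variant)[0]
    ref_blocks, var_blocks = aln.aligned
    indels: list[IndelEvent] = []
    shift_start: Optional[int] = None  # variant coordinate of first frameshift
    net = 0
    for i in range(len(ref_blocks)):
        if i > 0:
            ref_gap = ref_blocks[i][0] - ref_blocks[i - 1][1]
            var_gap = var_blocks[i][0] - var_blocks[i - 1][1]
            if var_gap:  # insertion in variant
                indels.append(IndelEvent(int(ref_blocks[i][0]), int(var_gap)))
                net += var_gap
            if ref_gap:  # deletion from reference
                indels.append(IndelEvent(int(ref_blocks[i - 1][1]), -int(ref_gap)))
                net -= ref_gap
            if net % 3 != 0 and shift_start is None:
                shift_start = int(var_blocks[i][0])
    # unaligned leading/trailing variant sequence counts as indels too
    frameshift = shift_start is not None
    scan_to = shift_start if frameshift else len(variant)
    coding = variant[frame_offset:scan_to]
    coding = coding[: len(coding) - len(coding) % 3]
    stops = []
    if coding:
        protein = str(Seq(coding).translate())
        stops = [i for i, aa in enumerate(protein[:-1]) if aa == "*"]
        if protein and protein[-1] == "*" and scan_to < len(variant):
            stops.append(len(protein) - 1)
    return CodingAssessment(
        frame_offset=frame_offset,
        indels=indels,
        frameshift=frameshift,
        internal_stops=stops,
    )


def _has_iia_signature(assessment: CodingAssessment) -> bool:
    lens = sorted(-e.length for e in assessment.indels if e.length < 0)
    return 9 in lens and 1 in lens


def assign_cluster(
    variant: str,
    assessment: CodingAssessment,
    *,
    diagnostic_position: int = 0,
    cluster_i_bases: frozenset = frozenset("CT"),
    cluster_ii_bases: frozenset = frozenset("G"),
) -> ClusterLabel:
    """Deterministic, total cluster assignment.

    The base at the diagnostic window position separates cluster I (C/T)
    from cluster II (G).  Within cluster II, the 9-bp + 1-bp deletion
    signature marks group II.A; an intact frame with no internal stops marks
    an expressed allele; anything else is unclassified.
    """
    base = variant[diagnostic_position].upper()
    if base in cluster_i_bases:
        return ClusterLabel(CLUSTER_I, base, assessment)
    if base not in cluster_ii_bases:
        return ClusterLabel(UNCLASSIFIED, base, assessment)
    if _has_iia_signature(assessment):
        return ClusterLabel(GROUP_IIA, base, assessment)
    if not assessment.frameshift and not assessment.internal_stops:
        return ClusterLabel(EXPRESSED_II, base, assessment)
    return ClusterLabel(UNCLASSIFIED, base, assessment)


def consensus_reference(sequences: Iterable[str]) -> str:
    """Majority-rule consensus (ties broken alphabetically) of equal-length
    sequences — the data-driven surrogate for a known functional reference."""
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise ValueError("no sequences for consensus")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("consensus requires equal-length sequences")
    from collections import Counter

    out = []
    for i in range(L):
        counts = Counter(s[i] for s in seqs)
        out.append(min(counts, key=lambda b: (-counts[b], b)))
    return "".join(out)


@dataclass
class CdnaReport:
    confirmed: list[str]
    cdna_only: list[str]
    unconfirmed_alleles: list[str]


def match_cdna(
    alleles: Iterable[str],
    cdna_counts: Mapping[str, int],
    min_clones: int = 2,
) -> CdnaReport:
    """Exact-match cross-check of putative alleles against cDNA-derived
    sequences; cDNA variants supported by fewer than ``min_clones`` clones
    are ignored."""
    alleles = {a.upper() for a in alleles}
    supported = {s.upper() for s, c in cdna_counts.items() if c >= min_clones}
    if supported and alleles:
        la = {len(a) for a in alleles}
        lc = {len(c) for c in supported}
        if la != lc:
            raise ValueError(
                f"cDNA window {sorted(lc)} does not match allele window {sorted(la)}"
            )
    return CdnaReport(
        confirmed=sorted(alleles & supported),
        cdna_only=sorted(supported - alleles),
        unconfirmed_alleles=sorted(alleles - supported),
    )


def tamura_nei_distance(seq1: str, seq2: str) -> float:
    """Tamura–Nei (TN93) distance between two aligned sequences.

    Sites with a gap or ambiguity in either sequence are excluded (pairwise
    deletion).  Base frequencies are estimated from the two sequences
    jointly; transitions are split into purine (A<->G, proportion P1) and
    pyrimidine (C<->T, proportion P2), Q is the transversion proportion.
    Returns ``math.inf`` when any logarithm argument is non-positive
    (saturation).
    """
    s1 = seq1.upper()
    s2 = seq2.upper()
    if len(s1) != len(s2):
        raise ValueError("sequences must be aligned to equal length")
    pairs = [
        (a, b) for a, b in zip(s1, s2) if a in "ACGT" and b in "ACGT"
    ]
    if not pairs:
        raise ValueError("no comparable (ungapped, unambiguous) sites")
    n = len(pairs)
    from collections import Counter

    freq = Counter()
    p1 = p2 = q = 0
    for a, b in pairs:
        freq[a] += 1
        freq[b] += 1
        if a != b:
            pur = (a in PURINES) + (b in PURINES)
            if pur == 2:
                p1 += 1
            elif pur == 0:
                p2 += 1
            else:
                q += 1
    if p1 + p2 + q == 0:
        return 0.0
    g = {b: freq[b] / (2 * n) for b in "ACGT"}
    gr = g["A"] + g["G"]
    gy = g["C"] + g["T"]
    P1, P2, Q = p1 / n, p2 / n, q / n
    if gr == 0.0 or gy == 0.0:
        return math.inf
    # each class term vanishes (in the limit) when its frequency product is
    # zero and no differences of that class were seen; with differences the
    # distance is undefined and reported as saturated
    k1 = 2 * g["A"] * g["G"] / gr
    k2 = 2 * g["C"] * g["T"] / gy
    if (k1 == 0.0 and P1 > 0) or (k2 == 0.0 and P2 > 0):
        return math.inf
    d = 0.0
    w3 = 1 - Q / (2 * gr * gy)
    if w3 <= 0:
        return math.inf
    if k1 > 0:
        w1 = 1 - P1 / k1 - Q / (2 * gr)
        if w1 <= 0:
            return math.inf
        d -= k1 * math.log(w1)
    if k2 > 0:
        w2 = 1 - P2 / k2 - Q / (2 * gy)
        if w2 <= 0:
            return math.inf
        d -= k2 * math.log(w2)
    k3 = 2 * (gr * gy - g["A"] * g["G"] * gy / gr - g["C"] * g["T"] * gr / gy)
    d -= k3 * math.log(w3)
    return max(d, 0.0)


def distance_matrix(sequences: Mapping[str, str]) -> "np.ndarray":
    """Symmetric TN93 distance matrix over a name -> sequence mapping;
    returns (labels, matrix)."""
    labels = list(sequences)
    m = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            d = tamura_nei_distance(sequences[a], sequences[labels[j]])
            m[i, j] = m[j, i] = d
    return labels, m


def neighbor_joining(matrix, labels: Sequence[str]):
    """Canonical neighbour joining (Q-matrix agglomeration) of a symmetric
    distance matrix; returns an unrooted ``skbio.TreeNode``.

    Serialise with ``str(tree)`` (newick).
    """
    import skbio
    from skbio.tree import nj

    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(m).any() or np.isinf(m).any():
        raise ValueError("distance matrix contains NaN/inf entries")
    if (m < 0).any():
        raise ValueError("distance matrix contains negative entries")
    if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
        raise ValueError("matrix must be symmetric with zero diagonal")
    dm = skbio.DistanceMatrix(m, ids=list(labels))
    return nj(dm)


def _bipartitions(tree, labels: frozenset) -> set[frozenset]:
    """Non-trivial splits of an (arbitrarily rooted) tree, each represented
    by the lexicographically smaller side."""
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = labels - side
        if 1 < len(side) < len(labels) - 1:
            splits.add(min(side, other, key=sorted))
    return splits


def bootstrap_support(
    sequences: Mapping[str, str],
    n_replicates: int = 1000,
    seed: int = 0,
) -> tuple[object, dict[frozenset, float]]:
    """NJ tree of the full data plus column-bootstrap split support.

    Alignment columns are resampled with replacement; each replicate's TN93
    matrix is re-estimated and its NJ tree's splits recorded.  Support for
    each split of the full-data tree is the fraction of replicates
    containing it.
    """
    labels = list(sequences)
    L = len(next(iter(sequences.values())))
    arr = {k: np.frombuffer(v.encode(), dtype="S1") for k, v in sequences.items()}
    _, m = distance_matrix(sequences)
    tree = neighbor_joining(m, labels)
    names = frozenset(labels)
    target = _bipartitions(tree, names)
    hits = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        boot = {k: v[cols].tobytes().decode() for k, v in arr.items()}
        _, bm = distance_matrix(boot)
        if np.isinf(bm).any():
            continue
        bt = neighbor_joining(bm, labels)
        for s in _bipartitions(bt, names):
            if s in hits:
                hits[s] += 1
    support = {s: hits[s] / n_replicates for s in target}
    return tree, support
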