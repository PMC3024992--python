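"""Nei–Gojobori dN/dS estimation and the Z-test of positive selection.

Historical positive selection on antigen-presenting codons leaves an excess
of nonsynonymous over synonymous substitutions (dN > dS) at antigen-binding
sites (ABS), while the rest of the molecule evolves under purifying or
neutral dynamics.  This module implements the classical Nei–Gojobori (1986)
counting method with equal weighting of minimal mutational pathways,
Jukes–Cantor multiple-hit correction, codon-bootstrap standard errors and
the normal-deviate Z-test, partitioned over a user-supplied ABS mask.

ABS positions are configuration, not code: which alignment codons contact
the antigen depends on how the amplified fragment maps onto the class II
beta-chain structure, so the mask ships as an editable text file of codon
indices (see :func:`load_abs_mask`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "RateEstimate",
    "ZResult",
    "ng_site_counts",
    "pathway_differences",
    "pairwise_ng",
    "jukes_cantor",
    "mean_rates",
    "z_test",
    "load_abs_mask",
]

_TABLE = standard_dna_table
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = frozenset(_TABLE.forward_table)
BASES = "ACGT"


def _aa(codon: str) -> Optional[str]:
    return _TABLE.forward_table.get(codon)


def ng_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Each position contributes 1 site, split as (synonymous one-step
    changes)/(non-stop one-step changes); mutations to stop codons are
    excluded from both numerator and denominator, so s + n = 3.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    if codon not in SENSE_CODONS:
        raise ValueError(f"not an unambiguous sense codon: {codon!r}")
    aa = _aa(codon)
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            if _aa(mutant) == aa:
                syn += 1
        s += syn / valid
    return s, 3.0 - s


def pathway_differences(codon1: str, codon2: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous difference counts between two sense
    codons, averaged with equal weight over all minimal mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked, all pathways are used (the conventional fallback).
    """
    c1, c2 = codon1.upper(), codon2.upper()
    for c in (c1, c2):
        if c not in SENSE_CODONS:
            raise ValueError(f"not an unambiguous sense codon: {c!r}")
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diffs):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        pathways.append((blocked, steps))
    usable = [steps for blocked, steps in pathways if not blocked]
    if not usable:
        usable = [steps for _, steps in pathways]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if a in STOP_CODONS or b in STOP_CODONS:
                nd += 1  # only reachable in the all-blocked fallback
            elif _aa(a) == _aa(b):
                sd += 1
            else:
                nd += 1
    k = len(usable)
    return sd / k, nd / k


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3);
    ``math.inf`` at saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion cannot be negative")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _comparable(codon: str) -> bool:
    return codon in SENSE_CODONS


@dataclass(frozen=True)
class NGPair:
    """Nei–Gojobori comparison of one sequence pair."""

    Nd: float
    Sd: float
    n_sites: float  # averaged over the two sequences
    s_sites: float
    pN: float
    pS: float
    dN: float  # Jukes–Cantor corrected (inf at saturation)
    dS: float


def _codons(seq: str) -> list[str]:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def pairwise_ng(seq1: str, seq2: str, jc_correction: bool = True) -> NGPair:
    """Nei–Gojobori comparison of two aligned coding sequences.

    Codon pairs where either member contains a gap, an ambiguity or a stop
    are excluded pairwise; site counts are averaged between the two
    sequences; differences are averaged over minimal mutational pathways.
    """
    cod1, cod2 = _codons(seq1), _codons(seq2)
    if len(cod1) != len(cod2):
        raise ValueError("sequences differ in codon count")
    Nd = Sd = n1 = s1 = n2 = s2 = 0.0
    for a, b in zip(cod1, cod2):
        if not (_comparable(a) and _comparable(b)):
            continue
        sa, na = ng_site_counts(a)
        sb, nb = ng_site_counts(b)
        s1 += sa
        n1 += na
        s2 += sb
        n2 += nb
        ds, dn = pathway_differences(a, b)
        Sd += ds
        Nd += dn
    n_sites = (n1 + n2) / 2.0
    s_sites = (s1 + s2) / 2.0
    pN = Nd / n_sites if n_sites else 0.0
    pS = Sd / s_sites if s_sites else 0.0
    dN = jukes_cantor(pN) if jc_correction else pN
    dS = jukes_cantor(pS) if jc_correction else pS
    return NGPair(Nd=Nd, Sd=Sd, n_sites=n_sites, s_sites=s_sites,
                  pN=pN, pS=pS, dN=dN, dS=dS)


@dataclass(frozen=True)
class RateEstimate:
    dN: float
    dS: float
    SE_dN: float
    SE_dS: float
    n_sequences: int
    n_codons: int
    partition: str


@dataclass(frozen=True)
class ZResult:
    z: float
    p: float
    degenerate: bool = False


def _pair_site_arrays(sequences: Sequence[str]):
    """Per-pair, per-codon contribution arrays for fast codon bootstrap:
    (ND, SD, NS, SS, CMP), each shaped (n_pairs, n_codons)."""
    cods = [_codons(s) for s in sequences]
    n_cod = len(cods[0])
    if any(len(c) != n_cod for c in cods):
        raise ValueError("sequences differ in codon count")
    pairs = list(itertools.combinations(range(len(sequences)), 2))
    ND = np.zeros((len(pairs), n_cod))
    SD = np.zeros_like(ND)
    NS = np.zeros_like(ND)
    SS = np.zeros_like(ND)
    CMP = np.zeros_like(ND, dtype=bool)
    site_cache: dict[str, tuple[float, float]] = {}
    diff_cache: dict[tuple[str, str], tuple[float, float]] = {}
    for p, (i, j) in enumerate(pairs):
        for c in range(n_cod):
            a, b = cods[i][c], cods[j][c]
            if not (_comparable(a) and _comparable(b)):
                continue
            CMP[p, c] = True
            for cod in (a, b):
                if cod not in site_cache:
                    site_cache[cod] = ng_site_counts(cod)
            key = (a, b) if a <= b else (b, a)
            if key not in diff_cache:
                diff_cache[key] = pathway_differences(*key)
            sa, na = site_cache[a]
            sb, nb = site_cache[b]
            ds, dn = diff_cache[key]
            NS[p, c] = (na + nb) / 2.0
            SS[p, c] = (sa + sb) / 2.0
            ND[p, c] = dn
            SD[p, c] = ds
    return ND, SD, NS, SS, CMP


def _rates_from_arrays(ND, SD, NS, SS, idx):
    """Mean over pairs of JC-corrected pN and pS on codon subset ``idx``.

    ``idx`` may be 1-D (one estimate) or 2-D ``(reps, k)`` (vectorised
    bootstrap); indices may repeat.  Returns scalars or arrays of length
    ``reps``.
    """
    nd = ND[:, idx].sum(axis=-1)  # (pairs,) or (pairs, reps)
    sd = SD[:, idx].sum(axis=-1)
    ns = NS[:, idx].sum(axis=-1)
    ss = SS[:, idx].sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pn = np.where(ns > 0, nd / np.maximum(ns, 1e-300), 0.0)
        ps = np.where(ss > 0, sd / np.maximum(ss, 1e-300), 0.0)
        dn = np.where(pn < 0.75, -0.75 * np.log1p(-4 * np.minimum(pn, 0.7499) / 3), np.inf)
        ds = np.where(ps < 0.75, -0.75 * np.log1p(-4 * np.minimum(ps, 0.7499) / 3), np.inf)
    dn_mean = dn.mean(axis=0)
    ds_mean = ds.mean(axis=0)
    if dn_mean.ndim == 0:
        return float(dn_mean), float(ds_mean)
    return dn_mean, ds_mean


def mean_rates(
    sequences: Sequence[str],
    abs_mask: Optional[Sequence[bool]] = None,
    partition: str = "all",
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> RateEstimate:
    """Mean pairwise dN and dS over a codon partition, with codon-bootstrap
    standard errors.

    ``abs_mask`` marks ABS codons (True) and must be given for the "ABS"
    and "nonABS" partitions.  Bootstrap resamples codon columns *within* the
    partition (seeded, bit-reproducible).
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    ND, SD, NS, SS, _ = _pair_site_arrays(sequences)
    n_cod = ND.shape[1]
    if partition == "all":
        idx = np.arange(n_cod)
    else:
        if abs_mask is None:
            raise ValueError(f"partition {partition!r} requires an ABS mask")
        mask = np.asarray(abs_mask, dtype=bool)
        if mask.size != n_cod:
            raise ValueError("mask length does not match codon count")
        idx = np.flatnonzero(mask if partition == "ABS" else ~mask)
    if idx.size == 0:
        raise ValueError(f"partition {partition!r} contains no codons")
    dN, dS = _rates_from_arrays(ND, SD, NS, SS, idx)
    rng = np.random.default_rng(seed)
    samples = rng.choice(idx, size=(bootstrap_reps, idx.size), replace=True)
    boots_n, boots_s = _rates_from_arrays(ND, SD, NS, SS, samples)
    finite_n = boots_n[np.isfinite(boots_n)]
    finite_s = boots_s[np.isfinite(boots_s)]
    se_n = float(np.std(finite_n, ddof=1)) if finite_n.size > 1 else 0.0
    se_s = float(np.std(finite_s, ddof=1)) if finite_s.size > 1 else 0.0
    return RateEstimate(
        dN=dN, dS=dS, SE_dN=se_n, SE_dS=se_s,
        n_sequences=len(sequences), n_codons=int(idx.size), partition=partition,
    )


def z_test(est: RateEstimate, alternative: str = "positive") -> ZResult:
    """Z-test of selection: Z = (dN - dS) / sqrt(SE_dN^2 + SE_dS^2).

    ``alternative="positive"`` is the one-tailed test of dN > dS;
    ``"two-sided"`` tests dN != dS.
    """
    if alternative not in ("positive", "two-sided"):
        raise ValueError("alternative must be 'positive' or 'two-sided'")
    denom = math.hypot(est.SE_dN, est.SE_dS)
    diff = est.dN - est.dS
    if denom == 0.0:
        if diff == 0.0:
            return ZResult(z=0.0, p=1.0)
        return ZResult(z=math.copysign(math.inf, diff), p=math.nan, degenerate=True)
    z = diff / denom
    if alternative == "positive":
        p = float(stats.norm.sf(z))
    else:
        p = float(2 * stats.norm.sf(abs(z)))
    return ZResult(z=z, p=p)


def load_abs_mask(path, n_codons: int) -> np.ndarray:
    """Read an ABS configuration file: one 1-based codon index per line
    (``#`` comments allowed); returns a boolean mask of length n_codons."""
    mask = np.zeros(n_codons, dtype=bool)
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            i = int(line)
            if not 1 <= i <= n_codons:
                raise ValueError(f"ABS codon index {i} outside 1..{n_codons}")
            mask[i - 1] = True
    return mask
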