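"""Discriminating true alleles from PCR and sequencing artifacts.

The filter operates on a variant x amplicon read-count matrix and applies,
in order:

1. the replication criterion — a variant must occur in at least
   ``min_pcrs`` independent PCRs with at least ``min_copies`` reads in each
   (the "2-PCRs-3-copies-in-each" rule), which removes virtually all
   sequencing-error variants because the probability of the same error
   recurring three times is negligible;
2. PCR-chimera classification — a chimera formed by template switching
   during PCR must co-occur, in the amplicon where it arose, with both of
   its parents at higher abundance, whereas a true recombinant allele need
   not; candidates are sorted by their maximum per-amplicon frequency
   (MPAF) and each low-MPAF variant is tested, in the few amplicons where
   it is most abundant, for explainability as a single crossover of two
   more abundant variants;
3. threshold derivation — the smallest allele MPAF above the largest
   chimera MPAF; above it chimeras were never observed, so it can be
   transferred to sequence classes where direct classification is
   unreliable by scaling with the classes' relative read proportions;
4. homopolymer-indel flagging for the dominant pyrosequencing error mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FilterConfig",
    "VariantTable",
    "VariantRecord",
    "ChimeraWitness",
    "apply_replication_criterion",
    "explainable_as_chimera",
    "compute_mpaf",
    "classify_by_mpaf",
    "derive_threshold",
    "scale_threshold",
    "flag_homopolymer_indel",
    "spot_check_sample",
]

STATUS_CANDIDATE = "candidate"
STATUS_ALLELE = "putative allele"
STATUS_CHIMERA = "PCR chimera"
STATUS_ARTIFACT = "sequencing artifact"


class AlignmentError(ValueError):
    """Sequences of unequal length where an ungapped comparison is required."""


@dataclass(frozen=True)
class FilterConfig:
    min_pcrs: int = 2
    min_copies: int = 3
    n_check_amplicons: int = 3
    grey_zone_upper: float = 0.015
    homopolymer_min_len: int = 3

    def __post_init__(self):
        if min(self.min_pcrs, self.min_copies, self.n_check_amplicons,
               self.homopolymer_min_len) < 1:
            raise ValueError("all FilterConfig counts must be positive")
        if not 0.0 < self.grey_zone_upper < 1.0:
            raise ValueError("grey_zone_upper must lie in (0, 1)")


@dataclass(frozen=True)
class ChimeraWitness:
    """A reproducible explanation: variant = parent_a[:breakpoint] + parent_b[breakpoint:]."""

    amplicon: object
    parent_a: str
    parent_b: str
    breakpoint: int

    def reconstruct(self) -> str:
        return self.parent_a[: self.breakpoint] + self.parent_b[self.breakpoint :]


@dataclass
class VariantRecord:
    sequence: str
    mpaf: float
    status: str = STATUS_CANDIDATE
    cluster: Optional[str] = None
    witnesses: list[ChimeraWitness] = field(default_factory=list)


class VariantTable:
    """Unique variant sequences x amplicons with read counts.

    Wraps a pandas DataFrame (index = variant sequence, columns = amplicon
    id) plus per-amplicon total read counts.  Totals may exceed column sums
    when low-count reads (e.g. singletons) were collapsed before tabulation;
    frequencies are always computed against the totals.
    """

    def __init__(self, counts: pd.DataFrame, totals: Optional[pd.Series] = None):
        if counts.empty:
            raise ValueError("empty variant table")
        lengths = {len(s) for s in counts.index}
        if len(lengths) != 1:
            raise AlignmentError(
                f"variants have unequal lengths {sorted(lengths)}; align or pad first"
            )
        counts = counts.astype(int)
        if (counts.values < 0).any():
            raise ValueError("negative read counts")
        if totals is None:
            totals = counts.sum(axis=0)
        totals = totals.astype(int).reindex(counts.columns)
        if (counts.sum(axis=0) > totals).any():
            raise ValueError("column sums exceed amplicon totals")
        if (totals <= 0).any():
            bad = list(totals.index[totals <= 0])
            raise ValueError(f"non-positive amplicon totals: {bad}")
        if (counts.sum(axis=1) == 0).any():
            raise ValueError("variant with zero reads everywhere")
        self.counts = counts
        self.totals = totals

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_demux(cls, demux, min_count: int = 1) -> "VariantTable":
        """Tabulate a DemuxResult.  Totals = all assigned reads per amplicon,
        so frequencies stay correct when ``min_count`` collapses rare reads."""
        from collections import Counter

        cols = {}
        totals = {}
        for amp, reads in demux.assigned.items():
            if not reads:
                continue
            key = f"{amp[0]}.{amp[1]}" if isinstance(amp, tuple) else str(amp)
            cols[key] = Counter(seq for _, seq in reads)
            totals[key] = len(reads)
        counts = pd.DataFrame(cols).fillna(0).astype(int)
        counts = counts[counts.max(axis=1) >= min_count]
        counts = counts.sort_index()
        return cls(counts, pd.Series(totals))

    @classmethod
    def from_tsv(cls, path) -> "VariantTable":
        """Variant-count matrix as tab-separated text: variants as rows
        (first column the sequence), amplicons as columns; an optional row
        named ``__total__`` carries amplicon totals."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        totals = None
        if "__total__" in df.index:
            totals = df.loc["__total__"]
            df = df.drop(index="__total__")
        return cls(df, totals)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.loc["__total__"] = self.totals
        out.to_csv(path, sep="\t")

    # -- accessors ---------------------------------------------------------

    @property
    def variants(self) -> list[str]:
        return list(self.counts.index)

    @property
    def amplicons(self) -> list:
        return list(self.counts.columns)

    def amplicon_counts(self, amplicon) -> dict[str, int]:
        col = self.counts[amplicon]
        return {seq: int(c) for seq, c in col.items() if c > 0}

    def frequencies(self) -> pd.DataFrame:
        return self.counts.div(self.totals, axis=1)


# ---------------------------------------------------------------------------


def apply_replication_criterion(table: VariantTable, cfg: FilterConfig) -> list[str]:
    """Variants present in >= min_pcrs amplicons with >= min_copies reads in
    each such amplicon.  Returned in table order."""
    ok = (table.counts >= cfg.min_copies).sum(axis=1) >= cfg.min_pcrs
    return list(table.counts.index[ok])


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def explainable_as_chimera(
    variant: str,
    amplicon_counts: Mapping[str, int],
    amplicon: object = None,
) -> Optional[ChimeraWitness]:
    """Can ``variant`` be written as a single crossover of two strictly more
    abundant variants of the same amplicon?

    Parents A, B must each have strictly more reads in the amplicon than the
    variant; a breakpoint k in [1, L-1] must satisfy
    ``variant == A[:k] + B[k:]`` with the result differing from both
    parents.  Returns the first witness in a deterministic order (parents by
    descending count, then sequence; smallest breakpoint), or ``None``.

    Implementation note: for a candidate ordered pair (A, B) the valid
    breakpoints are exactly the k with ``k <= common_prefix(variant, A)``
    and ``L - k <= common_suffix(variant, B)``, which avoids scanning all
    breakpoints explicitly.
    """
    L = len(variant)
    own = amplicon_counts.get(variant, 0)
    parents = sorted(
        (
            (seq, c)
            for seq, c in amplicon_counts.items()
            if c > own and seq != variant
        ),
        key=lambda sc: (-sc[1], sc[0]),
    )
    for a, _ca in parents:
        if len(a) != L:
            raise AlignmentError("parent/variant length mismatch")
        p = _common_prefix_len(variant, a)
        if p == 0:
            continue
        for b, _cb in parents:
            if b == a:
                continue
            s = _common_suffix_len(variant, b)
            lo = max(1, L - s)
            hi = min(L - 1, p)
            for k in range(lo, hi + 1):
                rec = a[:k] + b[k:]
                if rec == variant and rec != a and rec != b:
                    return ChimeraWitness(amplicon, a, b, k)
    return None


def compute_mpaf(variant: str, table: VariantTable) -> float:
    """Maximum per-amplicon frequency: the variant's highest read fraction
    across amplicons (denominator = the amplicon's total read count)."""
    if variant not in table.counts.index:
        return 0.0
    freqs = table.counts.loc[variant] / table.totals
    return float(freqs.max())


def _check_amplicons(variant: str, table: VariantTable, n: int) -> list:
    """The n amplicons where the variant has most reads (ties broken by
    frequency, then amplicon id, for determinism); fewer if the variant
    occupies fewer amplicons."""
    row = table.counts.loc[variant]
    freqs = row / table.totals
    occupied = [amp for amp in table.amplicons if row[amp] > 0]
    occupied.sort(key=lambda amp: (-row[amp], -freqs[amp], str(amp)))
    return occupied[:n]


def classify_by_mpaf(
    candidates: Sequence[str],
    table: VariantTable,
    cfg: FilterConfig = FilterConfig(),
    *,
    full_scan: bool = False,
) -> dict[str, VariantRecord]:
    """MPAF-sorted chimera classification.

    Candidates are processed in ascending MPAF order.  Every variant with
    MPAF below ``grey_zone_upper`` (all variants when ``full_scan``) is
    examined in the ``n_check_amplicons`` amplicons where it is most
    abundant; if it is explainable as a chimera of more abundant variants in
    *all* of them it is labelled a PCR chimera, otherwise a putative allele.
    Variants above the grey zone are putative alleles (spot-checking is
    available separately via :func:`spot_check_sample`).  Already-classified
    chimeras stay in the parent pool: the procedure is a single pass.
    """
    records: dict[str, VariantRecord] = {}
    order = sorted(candidates, key=lambda v: (compute_mpaf(v, table), v))
    for variant in order:
        mpaf = compute_mpaf(variant, table)
        rec = VariantRecord(sequence=variant, mpaf=mpaf)
        if full_scan or mpaf < cfg.grey_zone_upper:
            amps = _check_amplicons(variant, table, cfg.n_check_amplicons)
            witnesses = []
            for amp in amps:
                w = explainable_as_chimera(
                    variant, table.amplicon_counts(amp), amplicon=amp
                )
                if w is None:
                    witnesses = []
                    break
                witnesses.append(w)
            if witnesses:
                rec.status = STATUS_CHIMERA
                rec.witnesses = witnesses
            else:
                rec.status = STATUS_ALLELE
        else:
            rec.status = STATUS_ALLELE
        records[variant] = rec
    return records


def derive_threshold(records: Mapping[str, VariantRecord]) -> float:
    """Smallest putative-allele MPAF strictly above the largest chimera MPAF
    (the frequency above which no chimera was observed).  With no chimeras,
    the smallest allele MPAF."""
    if not records:
        raise ValueError("empty classification")
    allele_mpafs = sorted(
        r.mpaf for r in records.values() if r.status == STATUS_ALLELE
    )
    chimera_mpafs = [r.mpaf for r in records.values() if r.status == STATUS_CHIMERA]
    if not allele_mpafs:
        raise ValueError("no putative alleles; threshold undefined")
    if not chimera_mpafs:
        return allele_mpafs[0]
    top_chimera = max(chimera_mpafs)
    for m in allele_mpafs:
        if m > top_chimera:
            return m
    raise ValueError("no allele MPAF above the largest chimera MPAF")


def scale_threshold(
    base_threshold: float,
    base_read_proportion: float,
    target_read_proportion: float,
) -> float:
    """Transfer an MPAF threshold between sequence classes by their relative
    mean read proportions (assumes the PCR-recombination rate is the same
    for all classes, so expected chimera frequency scales with class
    abundance)."""
    if not 0.0 < base_read_proportion <= 1.0:
        raise ValueError("base_read_proportion must lie in (0, 1]")
    if not 0.0 < target_read_proportion <= 1.0:
        raise ValueError("target_read_proportion must lie in (0, 1]")
    return base_threshold * target_read_proportion / base_read_proportion


def _runs(seq: str):
    """(start, length, base) for each maximal homopolymer run."""
    out = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        out.append((i, j - i, seq[i]))
        i = j
    return out


def flag_homopolymer_indel(
    variant: str,
    more_abundant: Iterable[str],
    cfg: FilterConfig = FilterConfig(),
) -> bool:
    """Is the variant a single 1-bp indel, inside a homopolymer run of the
    more abundant sequence, away from that sequence — with no other
    differences?  This is the characteristic pyrosequencing error mode."""
    for parent in more_abundant:
        if abs(len(parent) - len(variant)) != 1:
            continue
        longer, shorter = (
            (parent, variant) if len(parent) > len(variant) else (variant, parent)
        )
        p = _common_prefix_len(longer, shorter)
        s = _common_suffix_len(longer, shorter)
        if p + s < len(shorter):
            continue  # more than one difference
        # indel position in the longer sequence lies in [len-s-1 .. p];
        # canonicalise to the leftmost placement
        pos = min(p, len(longer) - s - 1)
        base = longer[pos]
        # run length around pos in the *parent* sequence
        ref = parent
        # map pos into parent coordinates (identical up to the indel)
        ref_pos = min(pos, len(ref) - 1)
        if ref[ref_pos] != base:
            ref_pos = max(0, ref_pos - 1)
        if ref[ref_pos] != base:
            continue
        i = ref_pos
        while i > 0 and ref[i - 1] == base:
            i -= 1
        j = ref_pos
        while j + 1 < len(ref) and ref[j + 1] == base:
            j += 1
        if j - i + 1 >= cfg.homopolymer_min_len:
            return True
    return False


def spot_check_sample(
    records: Mapping[str, VariantRecord],
    n: int,
    seed: int,
    mpaf_above: float = 0.015,
) -> list[str]:
    """Seeded random sample of variants above the grey zone, for manual
    chimera spot checks."""
    pool = sorted(v for v, r in records.items() if r.mpaf > mpaf_above)
    rng = np.random.default_rng(seed)
    if len(pool) <= n:
        return pool
    return sorted(rng.choice(pool, size=n, replace=False))
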