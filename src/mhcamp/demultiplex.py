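"""Tag-based demultiplexing of fusion-primer amplicon reads.

Reads produced by tagged fusion-primer amplicon sequencing have the layout

    adapter + tag (k bp) + forward primer + target sequence

The tag identifies the amplicon (one individual x one PCR replicate).  This
module locates the degenerate forward primer in each read, reads the tag
immediately 5' of it, assigns the read to an amplicon and truncates the
target to a fixed-length analysis window.  Reads carrying tags that were
never used in the experiment provide a direct upper bound on the rate at
which reads are misassigned between amplicons: a tag-synthesis or
sequencing error that turns a used tag into an unused one is observed,
whereas one that turns it into another used tag silently misassigns the
read, and the two channels have comparable probability when the unused
fraction of tag space is large.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

__all__ = [
    "TagSheet",
    "Read",
    "DemuxResult",
    "MisassignmentEstimate",
    "CoverageSummary",
    "locate_primer",
    "demultiplex",
    "estimate_misassignment",
    "coverage_summary",
]

#: IUPAC code -> set of concrete bases it stands for
IUPAC_SETS: Mapping[str, frozenset] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}


class ConfigurationError(ValueError):
    """Invalid primer, tag sheet or window configuration."""


@dataclass(frozen=True)
class Read:
    """One sequencing read (quality is ignored)."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")


@dataclass
class TagSheet:
    """The tag universe and the tag -> (individual, replicate) assignment.

    Parameters
    ----------
    tag_length
        Length of the tag in bases (the tag space has ``4**tag_length``
        members).
    assignment
        Mapping from each *used* tag to an ``(individual, replicate)`` pair.
    """

    tag_length: int
    assignment: dict[str, tuple[str, int]]

    def __post_init__(self):
        if self.tag_length <= 0:
            raise ConfigurationError("tag_length must be positive")
        if not self.assignment:
            raise ConfigurationError("tag sheet is empty")
        for tag in self.assignment:
            if len(tag) != self.tag_length or set(tag) - set("ACGT"):
                raise ConfigurationError(f"bad tag {tag!r}")
        amps = list(self.assignment.values())
        if len(set(amps)) != len(amps):
            raise ConfigurationError("two tags map to the same amplicon")

    @property
    def used_tags(self) -> frozenset:
        return frozenset(self.assignment)

    @property
    def tag_space_size(self) -> int:
        return 4**self.tag_length

    def unused_tag_fraction(self) -> float:
        """Fraction of the tag space not used in the experiment."""
        return (self.tag_space_size - len(self.assignment)) / self.tag_space_size

    def min_pairwise_distance(self) -> int:
        """Smallest Hamming distance between any two used tags (reported,
        not enforced; well-designed tag sets keep it >= 3)."""
        tags = sorted(self.assignment)
        if len(tags) < 2:
            return self.tag_length
        return min(
            sum(a != b for a, b in zip(t1, t2))
            for i, t1 in enumerate(tags)
            for t2 in tags[i + 1 :]
        )

    @classmethod
    def from_tsv(cls, path) -> "TagSheet":
        """Read a tab-separated sheet with columns tag, individual, replicate."""
        assignment: dict[str, tuple[str, int]] = {}
        tag_len = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                tag, individual, replicate = line.split("\t")[:3]
                if tag.lower() == "tag":  # header
                    continue
                assignment[tag.upper()] = (individual, int(replicate))
                tag_len = len(tag)
        if tag_len is None:
            raise ConfigurationError(f"no tags found in {path}")
        return cls(tag_length=tag_len, assignment=assignment)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("tag\tindividual\treplicate\n")
            for tag, (ind, rep) in sorted(self.assignment.items()):
                fh.write(f"{tag}\t{ind}\t{rep}\n")


@dataclass
class DemuxResult:
    """Outcome of demultiplexing one read set.

    ``assigned`` maps amplicon id ``(individual, replicate)`` to the list of
    ``(read id, retained window sequence)`` pairs.  ``unassigned`` holds
    ``(read id, reason)`` pairs with reason one of ``no_primer``,
    ``incomplete_tag``, ``unused_tag``, ``short_window``.  Conservation
    holds: every input read appears exactly once across the two.
    """

    assigned: dict[tuple[str, int], list[tuple[str, str]]]
    unassigned: list[tuple[str, str]]
    total_reads: int
    complete_tag_reads: int
    unused_tag_reads: int
    window: int

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())

    def coverages(self) -> dict[tuple[str, int], int]:
        return {amp: len(reads) for amp, reads in self.assigned.items()}


@dataclass(frozen=True)
class MisassignmentEstimate:
    unused_tag_fraction_of_tag_space: float
    misassignment_rate_upper_bound: float
    expected_misassigned_reads_per_amplicon: float


@dataclass(frozen=True)
class CoverageSummary:
    mean: float
    sd: float
    min: int
    max: int
    n_amplicons: int
    unique_variants: int
    singletons: int
    singleton_fraction: float


def _iupac_set(code: str) -> frozenset:
    try:
        return IUPAC_SETS[code]
    except KeyError:
        raise ConfigurationError(f"non-IUPAC character {code!r} in primer") from None


def locate_primer(
    read: str, primer: str, max_mismatches: int = 0
) -> Optional[int]:
    """Leftmost position where ``primer`` matches ``read``.

    Every primer position is expanded to its IUPAC base set; a read base
    matches when it is a member of that set.  Up to ``max_mismatches``
    non-matching positions are tolerated (default 0, i.e. exact under
    degeneracy).  Returns ``None`` when no window matches.
    """
    if not primer:
        raise ConfigurationError("primer is empty")
    sets = [_iupac_set(c) for c in primer.upper()]
    m = len(sets)
    read = read.upper()
    for start in range(len(read) - m + 1):
        mismatches = 0
        for j, allowed in enumerate(sets):
            if read[start + j] not in allowed:
                mismatches += 1
                if mismatches > max_mismatches:
                    break
        else:
            return start
    return None


def demultiplex(
    reads: Iterable[Read],
    tag_sheet: TagSheet,
    primer: str,
    window: int = 188,
    *,
    max_mismatches: int = 0,
    drop_short: bool = True,
    scan_revcomp: bool = True,
    drop_ambiguous: bool = False,
) -> DemuxResult:
    """Assign tagged reads to amplicons and truncate to the analysis window.

    For each read the forward primer is located (optionally also on the
    reverse complement); the ``tag_length`` bases immediately 5' of the
    primer are the tag.  Reads whose tag is in the sheet are assigned to
    that amplicon and their retained sequence is the first ``window`` bases
    after the primer.  Reads whose retained sequence is shorter than the
    window are dropped by default (the procedure analyses fixed-length
    segments).  Reads with tags outside the used set are tallied: they are
    the observable channel of tag misassignment.
    """
    if window <= 0:
        raise ConfigurationError("window must be positive")
    k = tag_sheet.tag_length
    assigned: dict[tuple[str, int], list[tuple[str, str]]] = {
        amp: [] for amp in tag_sheet.assignment.values()
    }
    unassigned: list[tuple[str, str]] = []
    total = complete = unused = 0
    for read in reads:
        total += 1
        seq = read.sequence.upper()
        pos = locate_primer(seq, primer, max_mismatches)
        if pos is None and scan_revcomp:
            rc = reverse_complement(seq)
            pos = locate_primer(rc, primer, max_mismatches)
            if pos is not None:
                seq = rc
        if pos is None:
            unassigned.append((read.id, "no_primer"))
            continue
        if pos < k:
            unassigned.append((read.id, "incomplete_tag"))
            continue
        retained = seq[pos + len(primer) : pos + len(primer) + window]
        if drop_short and len(retained) < window:
            unassigned.append((read.id, "short_window"))
            continue
        complete += 1
        tag = seq[pos - k : pos]
        amp = tag_sheet.assignment.get(tag)
        if amp is None:
            unused += 1
            unassigned.append((read.id, "unused_tag"))
            continue
        if drop_ambiguous and set(retained) - set("ACGT"):
            unassigned.append((read.id, "ambiguous_window"))
            continue
        assigned[amp].append((read.id, retained))
    return DemuxResult(
        assigned=assigned,
        unassigned=unassigned,
        total_reads=total,
        complete_tag_reads=complete,
        unused_tag_reads=unused,
        window=window,
    )


def estimate_misassignment(
    demux: DemuxResult, tag_sheet: TagSheet, mean_coverage: Optional[float] = None
) -> MisassignmentEstimate:
    """Upper bound on the read-to-amplicon misassignment rate.

    Because the unused fraction of tag space is near 1, the rate at which
    corrupted tags land on *used* tags (true misassignment) is at most about
    the observed rate at which they land on unused ones; the unused-tag read
    fraction is therefore an upper bound on the misassignment rate.
    """
    if demux.complete_tag_reads == 0:
        raise ZeroDivisionError("no reads with complete tags; rate undefined")
    rate = demux.unused_tag_reads / demux.complete_tag_reads
    if mean_coverage is None:
        covs = list(demux.coverages().values())
        mean_coverage = float(np.mean(covs)) if covs else 0.0
    return MisassignmentEstimate(
        unused_tag_fraction_of_tag_space=tag_sheet.unused_tag_fraction(),
        misassignment_rate_upper_bound=rate,
        expected_misassigned_reads_per_amplicon=rate * mean_coverage,
    )


def coverage_summary(demux: DemuxResult) -> CoverageSummary:
    """Per-amplicon coverage statistics and dataset-wide variant counts.

    A singleton is a unique retained sequence represented by exactly one
    read in the whole dataset; the singleton fraction is computed over all
    assigned reads.
    """
    covs = np.array(sorted(demux.coverages().values()), dtype=int)
    if covs.size == 0:
        raise ValueError("no amplicons in demultiplexing result")
    from collections import Counter

    seq_counts = Counter(
        seq for reads in demux.assigned.values() for _, seq in reads
    )
    n_reads = sum(seq_counts.values())
    singletons = sum(1 for c in seq_counts.values() if c == 1)
    return CoverageSummary(
        mean=float(covs.mean()),
        sd=float(covs.std(ddof=1)) if covs.size > 1 else 0.0,
        min=int(covs.min()),
        max=int(covs.max()),
        n_amplicons=int(covs.size),
        unique_variants=len(seq_counts),
        singletons=singletons,
        singleton_fraction=singletons / n_reads if n_reads else 0.0,
    )
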