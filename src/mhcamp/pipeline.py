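"""End-to-end read-to-genotype convenience pipeline.

Chains demultiplexing, variant tabulation, the replication and chimera
filters, cluster assignment, per-class MPAF thresholds and per-amplicon
genotyping.  Each stage remains available individually; this wrapper fixes
the glue for the common case and for the examples and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from Bio.Seq import Seq

from . import classify as _classify
from . import genotype as _genotype
from . import variant_filter as vf
from .demultiplex import DemuxResult, Read, TagSheet, demultiplex

__all__ = ["PipelineResult", "infer_reference", "run_pipeline"]


@dataclass
class PipelineResult:
    demux: DemuxResult
    table: vf.VariantTable
    candidates: list[str]
    records: dict[str, vf.VariantRecord]
    clusters: dict[str, str]  # variant sequence -> cluster label
    threshold: Optional[float]  # expressed-allele MPAF threshold
    scaled_thresholds: dict[str, float]
    alleles: list[str]  # accepted putative alleles (all clusters)
    genotypes: dict[tuple[str, int], _genotype.Genotype]

    def alleles_in(self, cluster: str) -> list[str]:
        return [a for a in self.alleles if self.clusters.get(a) == cluster]


def infer_reference(sequences: Iterable[str], frame_offset: int = 0) -> str:
    """Majority-rule consensus of sequences whose direct translation has no
    internal stop codon — the data-driven surrogate for a known functional
    reference."""
    intact = []
    for seq in sequences:
        coding = seq[frame_offset:]
        coding = coding[: len(coding) - len(coding) % 3]
        protein = str(Seq(coding).translate())
        if "*" not in protein[:-1]:
            intact.append(seq)
    if not intact:
        raise ValueError("no intact-frame sequences to build a reference from")
    return _classify.consensus_reference(intact)


def run_pipeline(
    reads: Iterable[Read],
    tag_sheet: TagSheet,
    primer: str,
    window: int = 188,
    cfg: vf.FilterConfig = vf.FilterConfig(),
    *,
    reference: Optional[str] = None,
    frame_offset: int = 0,
    read_proportions: Optional[Mapping[str, float]] = None,
    min_reads_genotype: int = 2,
) -> PipelineResult:
    """Run the full procedure.

    1. demultiplex and truncate to the window;
    2. tabulate variants, apply the replication criterion;
    3. MPAF-sorted chimera classification, homopolymer-indel flagging;
    4. cluster assignment against ``reference`` (inferred from intact-frame
       candidates when not given);
    5. expressed-allele MPAF threshold; scaled thresholds for the
       pseudogene clusters when ``read_proportions`` maps cluster label ->
       mean per-amplicon read proportion (expressed proportion required);
       pseudogene variants below their scaled threshold are dropped from
       the accepted allele list (conservative);
    6. per-amplicon genotypes over the accepted alleles.
    """
    demux = demultiplex(reads, tag_sheet, primer, window)
    table = vf.VariantTable.from_demux(demux)
    candidates = vf.apply_replication_criterion(table, cfg)
    records = vf.classify_by_mpaf(candidates, table, cfg)

    # homopolymer-indel artifacts among putative alleles
    by_abundance = sorted(
        candidates, key=lambda s: -int(table.counts.loc[s].sum())
    )
    totals = {s: int(table.counts.loc[s].sum()) for s in candidates}
    for seq in candidates:
        rec = records[seq]
        if rec.status != vf.STATUS_ALLELE:
            continue
        more_abundant = [s for s in by_abundance if totals[s] > totals[seq]]
        if vf.flag_homopolymer_indel(seq, more_abundant, cfg):
            rec.status = vf.STATUS_ARTIFACT

    if reference is None:
        reference = infer_reference(candidates, frame_offset)
    clusters: dict[str, str] = {}
    for seq in candidates:
        assessment = _classify.assess_coding(seq, reference, frame_offset)
        label = _classify.assign_cluster(seq, assessment)
        clusters[seq] = label.label
        records[seq].cluster = label.label

    expressed = [
        s
        for s, r in records.items()
        if r.status == vf.STATUS_ALLELE and clusters[s] == _classify.EXPRESSED_II
    ]
    threshold = None
    scaled: dict[str, float] = {}
    expressed_records = {s: records[s] for s in records
                         if clusters[s] == _classify.EXPRESSED_II}
    try:
        threshold = vf.derive_threshold(expressed_records)
    except ValueError:
        threshold = None
    if threshold is not None and read_proportions:
        base = read_proportions.get(_classify.EXPRESSED_II)
        if base:
            for cluster, prop in read_proportions.items():
                if cluster != _classify.EXPRESSED_II:
                    scaled[cluster] = vf.scale_threshold(threshold, base, prop)

    alleles = []
    for seq, rec in records.items():
        if rec.status != vf.STATUS_ALLELE:
            continue
        cluster = clusters[seq]
        bar = scaled.get(cluster)
        if bar is not None and rec.mpaf < bar:
            continue
        alleles.append(seq)

    genotypes: dict[tuple[str, int], _genotype.Genotype] = {}
    for amp in table.amplicons:
        individual, _, replicate = amp.rpartition(".")
        counts = table.amplicon_counts(amp)
        g = _genotype.call_alleles(
            counts,
            alleles,
            min_reads=min_reads_genotype,
            individual=individual,
            replicate=int(replicate),
            clusters=clusters,
        )
        _genotype.conservative_count(g, counts)
        genotypes[(individual, int(replicate))] = g

    return PipelineResult(
        demux=demux,
        table=table,
        candidates=candidates,
        records=records,
        clusters=clusters,
        threshold=threshold,
        scaled_thresholds=scaled,
        alleles=alleles,
        genotypes=genotypes,
    )
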