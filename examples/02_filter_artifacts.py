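"""Separate true alleles from PCR chimeras and sequencing artifacts.

Applies the 2-PCRs-3-copies replication criterion to a simulated variant
table, classifies low-frequency candidates by the MPAF-sorted chimera
search, derives the frequency threshold above which no chimera occurred,
and scales it to the pseudogene clusters by their read proportions.
"""

from collections import Counter

from mhcamp.demultiplex import demultiplex
from mhcamp.simulate import PRIMER_IUPAC, SimConfig, simulate_run
from mhcamp.variant_filter import (
    FilterConfig,
    VariantTable,
    apply_replication_criterion,
    classify_by_mpaf,
    derive_threshold,
    scale_threshold,
)

cfg = SimConfig(seed=3, n_individuals=32, replicate_fraction=0.25,
                coverage_mean=500, coverage_sd=100)
run = simulate_run(cfg)
demux = demultiplex(run.reads, run.tag_sheet, PRIMER_IUPAC, cfg.window)
table = VariantTable.from_demux(demux)
print(f"{len(table.variants)} unique variants in {len(table.amplicons)} amplicons")

fcfg = FilterConfig()  # 2 PCRs x 3 copies, grey zone < 1.5% MPAF
candidates = apply_replication_criterion(table, fcfg)
records = classify_by_mpaf(candidates, table, fcfg)
statuses = Counter(r.status for r in records.values())
print(f"{len(candidates)} candidates pass replication; statuses: {dict(statuses)}")

threshold = derive_threshold(records)
print(f"derived MPAF threshold: {100 * threshold:.2f}% "
      "(smallest allele MPAF above the largest chimera MPAF)")
for name, prop in [("cluster I", 0.718), ("group II.A", 0.118)]:
    scaled = scale_threshold(threshold, 0.164, prop)
    print(f"  scaled threshold for {name} (read proportion {prop}): "
          f"{100 * scaled:.2f}%")
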