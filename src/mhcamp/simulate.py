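"""Synthetic tagged-amplicon reads with full ground truth.

The generator emulates a fusion-primer amplicon run over a multigene MHC
class IIB family: diploid multilocus genotypes drawn from allele pools with
cluster structure (a low-divergence pseudogene cluster carrying a 1–2 bp
frameshift deletion and a diagnostic C/T first base; a second pseudogene
group with 9-bp + 1-bp deletions; divergent expressed alleles with intact
reading frames), per-amplicon coverage variation, per-allele amplification
skew, i.i.d. PCR substitution errors, single-crossover PCR chimeras,
homopolymer indels and tag corruption.  Every emitted read carries
provenance, so each pipeline stage can be scored against truth.

Templates are stored with downstream slack beyond the analysis window:
a deletion (biological or sequencing) pulls downstream template sequence
into the window, exactly as in real reads that extend past the analysed
fragment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml
from Bio.Seq import Seq

from .demultiplex import Read, TagSheet

__all__ = [
    "SimConfig",
    "Allele",
    "ReadOrigin",
    "SimTruth",
    "SimResult",
    "PRIMER_IUPAC",
    "PRIMER_CONCRETE",
    "generate_allele_pools",
    "generate_tags",
    "simulate_run",
    "evaluate_against_truth",
    "EvalMetrics",
]

#: degenerate forward primer used for demultiplexing (IUPAC codes H, Y, V)
PRIMER_IUPAC = "GAGTGTCHYTTCVTTAACGGCAC"
#: the concrete primer realisation incorporated into simulated reads
PRIMER_CONCRETE = "GAGTGTCACTTCGTTAACGGCAC"

EXPRESSED = "expressed_II"
CLUSTER_I = "cluster_I"
GROUP_IIA = "group_IIA"

BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimConfig:
    """Study conditions for one synthetic run.

    Defaults reproduce the conditions of the motivating experiment at desk
    scale: 188-bp analysis window, 6-bp tags, per-amplicon coverage
    541 +- 166 reads, 9 expressed / 10 cluster-I / 5 group-II.A diploid
    loci, per-base PCR substitution rate 1e-3, 5% chimeric reads, and
    cluster amplification weights that put roughly 16% / 72% / 12% of reads
    on expressed / cluster I / II.A templates.
    """

    seed: int = 0
    window: int = 188
    slack: int = 15  # extra template downstream of the window
    tag_length: int = 6
    n_individuals: int = 20
    replicate_fraction: float = 0.25
    expressed_loci: int = 9
    cluster1_loci: int = 10
    iia_loci: int = 5
    expressed_pool: int = 40
    cluster1_pool: int = 25
    iia_pool: int = 9
    expressed_divergence: float = 0.10
    coverage_mean: float = 541.0
    coverage_sd: float = 166.0
    coverage_min: int = 50
    skew_sigma: float = 0.5
    cluster_weights: dict = field(
        default_factory=lambda: {EXPRESSED: 1.0, CLUSTER_I: 3.9, GROUP_IIA: 1.3}
    )
    substitution_rate: float = 1e-3
    chimera_fraction: float = 0.05
    chimera_reads_per_event: float = 4.0
    homopolymer_indel_rate: float = 1e-4
    homopolymer_min_len: int = 3
    # per-base tag corruption; 1-(1-r)^6 ~ 0.33% of reads carry a
    # corrupted (almost always unused) tag, the level seen in real runs
    tag_corruption_rate: float = 5.5e-4

    def __post_init__(self):
        for name in ("replicate_fraction", "expressed_divergence",
                     "substitution_rate", "chimera_fraction",
                     "homopolymer_indel_rate", "tag_corruption_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if min(self.expressed_loci, self.cluster1_loci, self.iia_loci) < 0:
            raise ValueError("locus counts cannot be negative")
        if self.window <= 0 or self.tag_length <= 0:
            raise ValueError("window and tag_length must be positive")
        if self.slack < 12:
            raise ValueError("slack must cover the largest deletion (>= 12)")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


@dataclass(frozen=True)
class Allele:
    id: str
    cluster: str
    extended: str  # window + slack template, deletions already applied

    def window_seq(self, window: int) -> str:
        return self.extended[:window]


@dataclass(frozen=True)
class ReadOrigin:
    amplicon: tuple[str, int]
    templates: tuple[str, ...]  # one allele id, or two for a chimera
    breakpoint: Optional[int]
    n_substitutions: int
    n_homopolymer_indels: int
    tag_intended: str
    tag_emitted: str

    @property
    def is_chimera(self) -> bool:
        return len(self.templates) == 2


@dataclass
class SimTruth:
    window: int
    alleles: dict[str, Allele]  # id -> allele
    genotypes: dict[str, dict[str, int]]  # individual -> allele id -> copies
    amplicons: list[tuple[str, int]]
    provenance: dict[str, ReadOrigin]
    tag_sheet: TagSheet

    def allele_cluster(self, allele_id: str) -> str:
        return self.alleles[allele_id].cluster

    def window_seqs(self, cluster: Optional[str] = None) -> dict[str, str]:
        """allele id -> analysis-window sequence (optionally one cluster)."""
        return {
            a.id: a.window_seq(self.window)
            for a in self.alleles.values()
            if cluster is None or a.cluster == cluster
        }

    def seq_to_allele(self) -> dict[str, str]:
        return {a.window_seq(self.window): a.id for a in self.alleles.values()}

    def chimera_window_seq(self, origin: ReadOrigin) -> str:
        a, b = (self.alleles[t] for t in origin.templates)
        k = origin.breakpoint
        return (a.extended[:k] + b.extended[k:])[: self.window]

    def true_genotype_seqs(self, individual: str) -> set[str]:
        return {
            self.alleles[aid].window_seq(self.window)
            for aid in self.genotypes[individual]
        }


@dataclass
class SimResult:
    reads: list[Read]
    tag_sheet: TagSheet
    truth: SimTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# allele pools


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """Random sequence of sense codons (frame 0), first base G."""
    sense = sorted(set("".join(p) for p in itertools.product(BASES, repeat=3)) - _STOPS)
    g_start = [c for c in sense if c[0] == "G"]
    n_codons = length // 3 + 1
    codons = [g_start[rng.integers(len(g_start))]]
    for _ in range(n_codons - 1):
        codons.append(sense[rng.integers(len(sense))])
    return "".join(codons)[:length]


def _mutate(rng, seq: str, rate: float, protect: frozenset = frozenset()) -> str:
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        if i in protect:
            continue
        alt = [b for b in BASES if b != out[i]]
        out[i] = alt[rng.integers(3)]
    return "".join(out)


def _fix_stops(ancestor: str, seq: str, limit: int) -> str:
    """Revert any in-frame stop codon within the first ``limit`` bases to
    the ancestral codon (frame 0)."""
    out = list(seq)
    for i in range(0, limit - 2, 3):
        if "".join(out[i : i + 3]) in _STOPS:
            out[i : i + 3] = ancestor[i : i + 3]
    return "".join(out)


def _substitute_one(rng, seq: str, forbid: frozenset = frozenset({0})) -> str:
    i = int(rng.integers(1, len(seq)))
    while i in forbid:
        i = int(rng.integers(1, len(seq)))
    alt = [b for b in BASES if b != seq[i]]
    return seq[:i] + alt[rng.integers(3)] + seq[i + 1 :]


def generate_allele_pools(cfg: SimConfig, rng: Optional[np.random.Generator] = None
                          ) -> dict[str, list[Allele]]:
    """Allele pools with the three-cluster structure.

    * expressed: intact reading frame over the window, no internal stops,
      diagnostic G at position 0, target mean pairwise divergence
      ``expressed_divergence`` (independent mutation at half that rate from
      a common ancestor);
    * cluster I: diagnostic C/T at position 0, a shared 1–2 bp deletion
      mid-window, pairwise Hamming distance <= 2 (each allele at most one
      substitution from the cluster ancestor);
    * group II.A: diagnostic G, a 9-bp and a 1-bp deletion (net 10,
      a frameshift), pairwise distance <= 2.

    All window sequences are distinct across pools.  A zero divergence
    target with a pool of more than one expressed allele is degenerate and
    rejected.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.expressed_divergence == 0.0 and cfg.expressed_pool > 1:
        raise ValueError(
            "expressed divergence 0 with pool > 1 yields identical alleles"
        )
    ext_len = cfg.window + cfg.slack
    ancestor = _random_orf(rng, ext_len)
    seen: set[str] = set()
    pools: dict[str, list[Allele]] = {EXPRESSED: [], CLUSTER_I: [], GROUP_IIA: []}

    def add(cluster: str, prefix: str, i: int, ext: str) -> bool:
        w = ext[: cfg.window]
        if w in seen:
            return False
        seen.add(w)
        pools[cluster].append(Allele(id=f"{prefix}{i:03d}", cluster=cluster, extended=ext))
        return True

    rate = cfg.expressed_divergence / 2.0
    for i in range(cfg.expressed_pool):
        for _attempt in range(200):
            ext = _mutate(rng, ancestor, rate, protect=frozenset({0}))
            ext = _fix_stops(ancestor, ext, cfg.window)
            if add(EXPRESSED, "E", i, ext):
                break
        else:
            raise RuntimeError("could not generate a distinct expressed allele")

    # cluster I ancestor: diverged, C/T at position 0, 1-2 bp deletion
    c1_anc = _mutate(rng, ancestor, 0.08, protect=frozenset({0}))
    c1_anc = ("C" if rng.random() < 0.5 else "T") + c1_anc[1:]
    del_len = int(rng.integers(1, 3))
    del_pos = cfg.window // 2
    c1_anc = c1_anc[:del_pos] + c1_anc[del_pos + del_len :]
    for i in range(cfg.cluster1_pool):
        for _attempt in range(200):
            ext = c1_anc if i == 0 else _substitute_one(rng, c1_anc)
            if add(CLUSTER_I, "P1-", i, ext):
                break
        else:
            raise RuntimeError("could not generate a distinct cluster I allele")

    # group II.A ancestor: G at position 0, 9-bp + 1-bp deletions
    iia_anc = _mutate(rng, ancestor, 0.05, protect=frozenset({0}))
    p9 = cfg.window // 3
    p1 = 2 * cfg.window // 3
    iia_anc = iia_anc[:p9] + iia_anc[p9 + 9 :]
    p1 -= 9
    iia_anc = iia_anc[:p1] + iia_anc[p1 + 1 :]
    for i in range(cfg.iia_pool):
        for _attempt in range(200):
            ext = iia_anc if i == 0 else _substitute_one(rng, iia_anc)
            if add(GROUP_IIA, "P2-", i, ext):
                break
        else:
            raise RuntimeError("could not generate a distinct group II.A allele")
    return pools


def generate_tags(
    n: int, tag_length: int, rng: np.random.Generator, min_distance: int = 3
) -> list[str]:
    """Random distinct tags with pairwise Hamming distance >= min_distance."""
    tags: list[str] = []
    for _attempt in range(200_000):
        if len(tags) == n:
            break
        cand = "".join(BASES[b] for b in rng.integers(0, 4, size=tag_length))
        if all(sum(a != b for a, b in zip(cand, t)) >= min_distance for t in tags):
            tags.append(cand)
    if len(tags) < n:
        raise RuntimeError(f"could not place {n} tags at distance {min_distance}")
    return tags


# ---------------------------------------------------------------------------
# read generation


def _homopolymer_runs(seq: str, min_len: int):
    out = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            out.append((i, j - i, seq[i]))
        i = j
    return out


def _apply_errors(rng, cfg: SimConfig, ext: str) -> tuple[str, int, int]:
    """PCR/sequencing substitutions then homopolymer indels; returns
    (sequence, n_substitutions, n_indels)."""
    n_sub = 0
    if cfg.substitution_rate > 0:
        hits = np.flatnonzero(rng.random(len(ext)) < cfg.substitution_rate)
        if hits.size:
            out = list(ext)
            for i in hits:
                alt = [b for b in BASES if b != out[i]]
                out[i] = alt[rng.integers(3)]
            ext = "".join(out)
            n_sub = int(hits.size)
    n_indel = 0
    if cfg.homopolymer_indel_rate > 0:
        # right-to-left so earlier run coordinates stay valid
        for start, length, base in reversed(
            _homopolymer_runs(ext[: cfg.window + 2], cfg.homopolymer_min_len)
        ):
            p = cfg.homopolymer_indel_rate * (length - 2)
            if rng.random() < p:
                if rng.random() < 0.5:
                    ext = ext[:start] + base + ext[start:]  # insertion
                else:
                    ext = ext[: start + 1] + ext[start + 2 :]  # 1-bp deletion
                n_indel += 1
    return ext, n_sub, n_indel


def _corrupt_tag(rng, tag: str, rate: float) -> str:
    if rate <= 0:
        return tag
    hits = np.flatnonzero(rng.random(len(tag)) < rate)
    if not hits.size:
        return tag
    out = list(tag)
    for i in hits:
        alt = [b for b in BASES if b != out[i]]
        out[i] = alt[rng.integers(3)]
    return "".join(out)


def simulate_run(cfg: SimConfig) -> SimResult:
    """Generate one tagged amplicon run with ground truth.

    The configuration seed fixes the entire output stream: the same config
    yields byte-identical reads and truth.
    """
    rng = np.random.default_rng(cfg.seed)
    pools = generate_allele_pools(cfg, rng)
    loci = {
        EXPRESSED: cfg.expressed_loci,
        CLUSTER_I: cfg.cluster1_loci,
        GROUP_IIA: cfg.iia_loci,
    }
    if sum(loci.values()) == 0 and cfg.coverage_mean > 0:
        raise ValueError("zero loci with nonzero coverage")
    alleles = {a.id: a for pool in pools.values() for a in pool}

    genotypes: dict[str, dict[str, int]] = {}
    individuals = [f"ind{i:03d}" for i in range(cfg.n_individuals)]
    for ind in individuals:
        geno: dict[str, int] = {}
        for cluster, n_loci in loci.items():
            pool = pools[cluster]
            for _locus in range(n_loci):
                for hap in rng.integers(0, len(pool), size=2):
                    aid = pool[int(hap)].id
                    geno[aid] = geno.get(aid, 0) + 1
        genotypes[ind] = geno

    n_replicated = int(round(cfg.replicate_fraction * cfg.n_individuals))
    amplicons: list[tuple[str, int]] = []
    for i, ind in enumerate(individuals):
        amplicons.append((ind, 1))
        if i < n_replicated:
            amplicons.append((ind, 2))

    tags = generate_tags(len(amplicons), cfg.tag_length, rng)
    tag_sheet = TagSheet(
        tag_length=cfg.tag_length,
        assignment={t: amp for t, amp in zip(tags, amplicons)},
    )
    tag_of = {amp: t for t, amp in tag_sheet.assignment.items()}

    reads: list[Read] = []
    provenance: dict[str, ReadOrigin] = {}
    for a_idx, amp in enumerate(amplicons):
        ind = amp[0]
        geno = genotypes[ind]
        ids = sorted(geno)
        weights = np.array(
            [
                geno[aid]
                * cfg.cluster_weights[alleles[aid].cluster]
                * rng.lognormal(0.0, cfg.skew_sigma)
                for aid in ids
            ]
        )
        weights /= weights.sum()
        coverage = max(cfg.coverage_min,
                       int(round(rng.normal(cfg.coverage_mean, cfg.coverage_sd))))
        n_chim = int(rng.binomial(coverage, cfg.chimera_fraction))
        tag = tag_of[amp]
        choices = rng.choice(len(ids), size=coverage - n_chim, p=weights)
        specs: list[tuple[tuple[str, ...], Optional[int], str]] = []
        for c in choices:
            specs.append(((ids[int(c)],), None, alleles[ids[int(c)]].extended))
        # chimeric molecules form in early PCR cycles and are then amplified:
        # a few (pair, breakpoint) events per amplicon each yield several
        # identical reads, so recurrent identical chimeras arise as they do
        # in real amplicon data
        if n_chim:
            n_events = max(1, int(np.ceil(n_chim / cfg.chimera_reads_per_event)))
            events: list[tuple[tuple[str, ...], Optional[int], str]] = []
            for _ in range(n_events):
                for _attempt in range(50):
                    i, j = rng.choice(len(ids), size=2, p=weights)
                    if ids[int(i)] == ids[int(j)]:
                        continue
                    a, b = alleles[ids[int(i)]], alleles[ids[int(j)]]
                    k = int(rng.integers(1, cfg.window))
                    ext = a.extended[:k] + b.extended[k:]
                    w = ext[: cfg.window]
                    if w != a.window_seq(cfg.window) and w != b.window_seq(cfg.window):
                        events.append(((a.id, b.id), k, ext))
                        break
                else:
                    # degenerate genotype (e.g. one allele): template read
                    aid = ids[int(rng.choice(len(ids), p=weights))]
                    events.append(((aid,), None, alleles[aid].extended))
            for e in rng.integers(0, len(events), size=n_chim):
                specs.append(events[int(e)])
        for r_idx, (templates, breakpoint, ext) in enumerate(specs):
            seq, n_sub, n_indel = _apply_errors(rng, cfg, ext)
            emitted_tag = _corrupt_tag(rng, tag, cfg.tag_corruption_rate)
            rid = f"amp{a_idx:03d}_r{r_idx:05d}"
            reads.append(Read(id=rid, sequence=emitted_tag + PRIMER_CONCRETE + seq))
            provenance[rid] = ReadOrigin(
                amplicon=amp,
                templates=templates,
                breakpoint=breakpoint,
                n_substitutions=n_sub,
                n_homopolymer_indels=n_indel,
                tag_intended=tag,
                tag_emitted=emitted_tag,
            )

    truth = SimTruth(
        window=cfg.window,
        alleles=alleles,
        genotypes=genotypes,
        amplicons=amplicons,
        provenance=provenance,
        tag_sheet=tag_sheet,
    )
    return SimResult(reads=reads, tag_sheet=tag_sheet, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# scoring


@dataclass
class EvalMetrics:
    allele_recall: dict[str, float]  # per cluster + "all", over detectable alleles
    allele_precision: float
    chimera_sensitivity: float
    chimera_false_discovery: float
    genotype_accuracy: Optional[float]
    detectable: dict[str, int]
    recovered: dict[str, int]


def detectable_alleles(truth: SimTruth, table, min_pcrs: int = 2,
                       min_copies: int = 3) -> set[str]:
    """True alleles whose window sequence meets the replication criterion in
    the observed count table (the detectability bar for recall)."""
    out = set()
    for aid, seq in truth.window_seqs().items():
        if seq in table.counts.index:
            row = table.counts.loc[seq]
            if int((row >= min_copies).sum()) >= min_pcrs:
                out.add(aid)
    return out


def evaluate_against_truth(
    records: Mapping[str, "object"],
    truth: SimTruth,
    table,
    *,
    min_pcrs: int = 2,
    min_copies: int = 3,
    called_genotypes: Optional[Mapping[str, set]] = None,
) -> EvalMetrics:
    """Score pipeline output against simulator truth.

    ``records`` is the classification mapping (sequence -> VariantRecord).
    Recall is computed per cluster over *detectable* alleles (replication
    criterion met in the observed table).  Reads are identified by final
    sequence: a planted chimera whose sequence coincides with a true allele
    counts as that allele.
    """
    from .variant_filter import STATUS_ALLELE, STATUS_CHIMERA

    seq2allele = truth.seq_to_allele()
    detectable = detectable_alleles(truth, table, min_pcrs, min_copies)
    accepted_seqs = {s for s, r in records.items() if r.status == STATUS_ALLELE}
    chimera_seqs = {s for s, r in records.items() if r.status == STATUS_CHIMERA}
    recovered = {
        seq2allele[s] for s in accepted_seqs if s in seq2allele
    } & detectable

    clusters = [EXPRESSED, CLUSTER_I, GROUP_IIA]
    det_by = {c: {a for a in detectable if truth.allele_cluster(a) == c}
              for c in clusters}
    rec_by = {c: {a for a in recovered if truth.allele_cluster(a) == c}
              for c in clusters}
    recall = {
        c: (len(rec_by[c]) / len(det_by[c])) if det_by[c] else float("nan")
        for c in clusters
    }
    recall["all"] = (len(recovered) / len(detectable)) if detectable else float("nan")

    precision = (
        sum(1 for s in accepted_seqs if s in seq2allele) / len(accepted_seqs)
        if accepted_seqs
        else float("nan")
    )

    # planted chimeras that became candidate variants distinct from any true allele
    planted = {
        truth.chimera_window_seq(o)
        for o in truth.provenance.values()
        if o.is_chimera
    } - set(seq2allele)
    planted_candidates = planted & set(records)
    sens = (
        len(planted_candidates & chimera_seqs) / len(planted_candidates)
        if planted_candidates
        else float("nan")
    )
    fdr = (
        sum(1 for s in chimera_seqs if s in seq2allele) / len(chimera_seqs)
        if chimera_seqs
        else 0.0
    )

    geno_acc = None
    if called_genotypes is not None:
        accs = []
        for ind, called in called_genotypes.items():
            true_seqs = truth.true_genotype_seqs(ind)
            union = called | true_seqs
            accs.append(len(called & true_seqs) / len(union) if union else 1.0)
        geno_acc = float(np.mean(accs)) if accs else None

    return EvalMetrics(
        allele_recall=recall,
        allele_precision=precision,
        chimera_sensitivity=sens,
        chimera_false_discovery=fdr,
        genotype_accuracy=geno_acc,
        detectable={c: len(det_by[c]) for c in clusters} | {"all": len(detectable)},
        recovered={c: len(rec_by[c]) for c in clusters} | {"all": len(recovered)},
    )
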