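"""Synthetic parent/parent/hybrid transcriptome data with known truth.

Generates (i) random transcripts, a fraction carrying one embedded perfect
SSR placed with generous flanks, (ii) biallelic SNP sites whose trio
zygosity states follow configurable proportions over the eight classes
(direct mode) or arise from Mendelian inheritance (parents drawn, hybrid
takes one allele from each), and (iii) uniform-coverage error-bearing reads
per variety with constant Phred qualities, plus a truth alignment stream
(all-match CIGAR at the true origin). Every stage of the analysis can then
be scored against exact truth.

All randomness flows from ``SimConfig.seed``; each stage derives its own
child generator, so identical configs give byte-identical outputs and the
read stream can be regenerated repeatedly.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .io import AlignmentRecord, TranscriptSet, VARIETY_DELIM, \
    write_fasta, write_table, read_table
from .ssr import DEFAULT_MIN_REPS, SSRLocus, canonical_motif, is_primitive
from .zygosity import CLASS_PATTERNS, DEFAULT_TRIO, HT, classify_trio

_BASES = np.array(list("ACGT"))
_MIN_FLANK = 60           # bases kept free on either side of an embedded SSR
_MAX_EXTRA_REPS = 6       # reiterations drawn in [threshold, threshold+6]

#: trio zygosity class proportions observed in the mango Neelam x Dashehari
#: -> Amrapali study (22,306 filtered SNPs); the simulator's default regime
MANGO_TRIO_CLASS_COUNTS = (6831, 4158, 2049, 1354, 2061, 1154, 1270, 3429)
MANGO_TRIO_PROPORTIONS = tuple(c / sum(MANGO_TRIO_CLASS_COUNTS) for c in MANGO_TRIO_CLASS_COUNTS)


@dataclass
class SimConfig:
    n_transcripts: int = 80
    length_range: tuple[int, int] = (400, 1500)
    ssr_per_transcript_prob: float = 0.5
    snp_sites_total: int = 400
    class_proportions: tuple[float, ...] = MANGO_TRIO_PROPORTIONS
    mode: str = "direct"                      # "direct" or "mendelian"
    coverage_per_variety: float = 30.0
    read_len: int = 50
    error_rate: float = 0.001                 # coherent with Q30 qualities
    base_quality: int = 30
    varieties: tuple[str, str, str] = DEFAULT_TRIO
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid length_range")
        if self.mode not in ("direct", "mendelian"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.class_proportions) != 8 or any(p < 0 for p in self.class_proportions):
            raise ValueError("class_proportions must be 8 non-negative values")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if min(self.n_transcripts, self.snp_sites_total, self.read_len) < 0:
            raise ValueError("sizes must be non-negative")
        if self.read_len > lo:
            raise ValueError("read_len exceeds shortest transcript")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if min(self.coverage_per_variety, self.base_quality) < 0:
            raise ValueError("coverage and quality must be non-negative")
        if len(set(self.varieties)) != 3:
            raise ValueError("varieties must be 3 distinct labels")
        max_tract = 6 * (max(DEFAULT_MIN_REPS.values()) + _MAX_EXTRA_REPS)
        if self.ssr_per_transcript_prob > 0 and lo < 2 * _MIN_FLANK + max_tract:
            raise ValueError(
                f"shortest transcript ({lo} bp) cannot host an SSR with "
                f"{_MIN_FLANK} bp flanks; raise length_range or set "
                f"ssr_per_transcript_prob=0")

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2 ** 31), stage])


@dataclass
class TruthSite:
    """One simulated biallelic site with known genotypes and class."""

    transcript_id: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str
    genotypes: dict[str, tuple[str, str]]  # variety -> unordered allele pair
    trio_class: int


def zygosity_of(genotype: tuple[str, str]) -> str:
    return "HM" if genotype[0] == genotype[1] else HT


def truth_class(site: TruthSite, varieties: Sequence[str]) -> int:
    """Class implied by the genotypes at infinite depth."""
    zyg = tuple(zygosity_of(site.genotypes[v]) for v in varieties)
    cls = classify_trio(*zyg)
    assert cls is not None
    return cls


def simulate_reference(config: SimConfig) -> tuple[TranscriptSet, list[SSRLocus]]:
    """Random transcripts, optionally one embedded perfect SSR each."""
    rng = config._rng(1)
    records: dict[str, str] = {}
    truth: list[SSRLocus] = []
    for i in range(config.n_transcripts):
        tid = f"TR{i + 1:05d}"
        L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = _BASES[rng.integers(0, 4, L)]
        if rng.random() < config.ssr_per_transcript_prob:
            unit = int(rng.integers(2, 7))
            motif = _random_primitive_motif(rng, unit)
            min_rep = DEFAULT_MIN_REPS[unit]
            reps = int(rng.integers(min_rep, min_rep + _MAX_EXTRA_REPS + 1))
            tract = motif * reps
            start0 = int(rng.integers(_MIN_FLANK, L - _MIN_FLANK - len(tract) + 1))
            seq[start0:start0 + len(tract)] = list(tract)
            truth.append(SSRLocus(
                transcript_id=tid,
                start=start0 + 1,
                end=start0 + len(tract),
                motif=motif,
                canonical_motif=canonical_motif(motif),
                unit_size=unit,
                repeat_count=reps,
                ssr_type="I" if len(tract) >= 20 else "II",
            ))
        records[tid] = "".join(seq)
    return TranscriptSet(records), truth


def _random_primitive_motif(rng: np.random.Generator, unit: int) -> str:
    while True:
        motif = "".join(_BASES[rng.integers(0, 4, unit)])
        if is_primitive(motif):
            return motif


def simulate_trio_genotypes(config: SimConfig, reference: TranscriptSet
                            ) -> list[TruthSite]:
    """Place SNP sites on a read-length-spaced grid and draw trio genotypes.

    Direct mode draws each site's class from the configured proportions and
    assigns genotypes consistent with the class pattern (HT = ref/alt; HM
    drawn ref-ref or alt-alt, with class 1 forcing contrasting parents and
    class 6 restricted to patterns in which both alleles occur in the trio,
    so every site is a detectable biallelic variant). Mendelian mode draws
    parental allele pairs at frequency 1/2 and gives the hybrid one allele
    from each parent, recording the implied class.
    """
    rng = config._rng(2)
    rl = config.read_len
    slots: list[tuple[str, int]] = []
    for tid, seq in reference.items():
        slots.extend((tid, p) for p in range(rl, len(seq) - rl + 2, rl))
    if config.snp_sites_total > len(slots):
        raise ValueError(
            f"cannot place {config.snp_sites_total} sites: only {len(slots)} "
            f"positions satisfy the read-length spacing")
    chosen = rng.choice(len(slots), size=config.snp_sites_total, replace=False)
    chosen.sort()
    sites: list[TruthSite] = []
    for k in chosen:
        tid, pos = slots[int(k)]
        ref = reference[tid][pos - 1]
        if ref not in "ACGT":  # N reference base: not a usable site
            continue
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        if config.mode == "direct":
            cls = int(rng.choice(8, p=config.class_proportions)) + 1
            genos = _direct_genotypes(rng, cls, ref, alt)
        else:
            genos, cls = _mendelian_genotypes(rng, ref, alt)
        sites.append(TruthSite(
            transcript_id=tid, pos=pos, ref_base=ref, alt_base=alt,
            genotypes=dict(zip(config.varieties, genos)), trio_class=cls,
        ))
    return sites


def _direct_genotypes(rng, cls: int, ref: str, alt: str
                      ) -> tuple[tuple[str, str], ...]:
    het = (ref, alt) if rng.random() < 0.5 else (alt, ref)
    if cls == 1:  # contrasting homozygous parents, heterozygous hybrid
        parents = [(ref, ref), (alt, alt)]
        if rng.random() < 0.5:
            parents.reverse()
        return parents[0], parents[1], het
    if cls == 6:  # all homozygous, both alleles present within the trio
        while True:
            picks = rng.random(3) < 0.5
            if 0 < picks.sum() < 3:
                break
        return tuple((alt, alt) if p else (ref, ref) for p in picks)
    pattern = CLASS_PATTERNS[cls]
    genos = []
    for z in pattern:
        if z == HT:
            genos.append((ref, alt) if rng.random() < 0.5 else (alt, ref))
        else:
            genos.append((alt, alt) if rng.random() < 0.5 else (ref, ref))
    return tuple(genos)


def _mendelian_genotypes(rng, ref: str, alt: str):
    while True:
        p1 = tuple(str(a) for a in rng.choice([ref, alt], 2))
        p2 = tuple(str(a) for a in rng.choice([ref, alt], 2))
        hyb = (str(rng.choice(p1)), str(rng.choice(p2)))
        if alt in p1 + p2 + hyb:
            break
    genos = (p1, p2, hyb)
    cls = classify_trio(*(zygosity_of(g) for g in genos))
    return genos, cls


def simulate_reads(config: SimConfig, reference: TranscriptSet,
                   truth: Sequence[TruthSite]) -> Iterator[AlignmentRecord]:
    """Stream truth alignments (reads with their true origin, all-M CIGAR).

    Per variety and transcript, round(coverage * L / read_len) reads start
    uniformly; read i copies haplotype i % 2 (SNP alleles substituted), then
    suffers per-base substitution errors at ``error_rate``; qualities are
    constant at ``base_quality``. Read ids end in ``|VARIETY``.
    """
    rng = config._rng(3)
    rl = config.read_len
    qual = [config.base_quality] * rl
    # per (variety, transcript): sorted site positions and phased haplotypes
    site_map: dict[tuple[str, str], tuple[list[int], list[tuple[str, str]]]] = {}
    for s in truth:
        for v, geno in s.genotypes.items():
            pos_list, hap_list = site_map.setdefault((v, s.transcript_id), ([], []))
            pos_list.append(s.pos - 1)
            phased = geno if rng.random() < 0.5 else (geno[1], geno[0])
            hap_list.append(phased)
    for variety in config.varieties:
        for tid, seq in reference.items():
            L = len(seq)
            n_reads = int(round(config.coverage_per_variety * L / rl))
            if n_reads <= 0:
                continue
            positions, haps = site_map.get((variety, tid), ([], []))
            starts = rng.integers(0, L - rl + 1, size=n_reads)
            n_errs = (rng.binomial(rl, config.error_rate, size=n_reads)
                      if config.error_rate > 0 else np.zeros(n_reads, np.int64))
            for i in range(n_reads):
                start0 = int(starts[i])
                bases = list(seq[start0:start0 + rl])
                j = bisect_left(positions, start0)
                if j < len(positions) and positions[j] < start0 + rl:
                    bases[positions[j] - start0] = haps[j][i % 2]
                k = int(n_errs[i])
                if k:
                    for off in rng.choice(rl, size=k, replace=False):
                        wrong = [b for b in "ACGT" if b != bases[off]]
                        bases[int(off)] = str(rng.choice(wrong))
                yield AlignmentRecord(
                    read_id=f"{tid}.{i}{VARIETY_DELIM}{variety}",
                    transcript_id=tid,
                    pos=start0 + 1,
                    cigar=[(rl, "M")],
                    sequence="".join(bases),
                    qualities=qual,
                )


TRUTH_SITE_COLUMNS = ["transcript_id", "pos", "ref", "alt",
                      "genotype_1", "genotype_2", "genotype_3", "trio_class"]


def write_truth(truth: Sequence[TruthSite], path,
                varieties: Sequence[str] = DEFAULT_TRIO) -> None:
    """Truth sites as TSV (genotypes as e.g. ``A/G`` in trio order)."""
    rows = []
    for s in truth:
        row = {"transcript_id": s.transcript_id, "pos": s.pos,
               "ref": s.ref_base, "alt": s.alt_base,
               "trio_class": s.trio_class}
        for i, v in enumerate(varieties, 1):
            row[f"genotype_{i}"] = "/".join(s.genotypes[v])
        rows.append(row)
    write_table(rows, path, columns=TRUTH_SITE_COLUMNS)


def read_truth(path, varieties: Sequence[str] = DEFAULT_TRIO) -> list[TruthSite]:
    sites = []
    for row in read_table(path):
        genos = {v: tuple(row[f"genotype_{i}"].split("/"))
                 for i, v in enumerate(varieties, 1)}
        sites.append(TruthSite(row["transcript_id"], int(row["pos"]), row["ref"],
                               row["alt"], genos, int(row["trio_class"])))
    return sites


def write_truth_ssrs(loci: Sequence[SSRLocus], path) -> None:
    rows = [{
        "transcript_id": l.transcript_id, "start": l.start, "end": l.end,
        "motif": l.motif, "canonical_motif": l.canonical_motif,
        "repeat_count": l.repeat_count, "total_len": l.total_len_bp,
        "type": l.ssr_type,
    } for l in loci]
    write_table(rows, path, columns=["transcript_id", "start", "end", "motif",
                                     "canonical_motif", "repeat_count",
                                     "total_len", "type"])


def simulate_to_dir(config: SimConfig, outdir) -> dict[str, Path]:
    """Run the full simulator and write ref.fasta, per-variety FASTQ, the
    truth SAM and the truth tables. Returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference, truth_ssrs = simulate_reference(config)
    truth_sites = simulate_trio_genotypes(config, reference)
    paths = {"reference": outdir / "ref.fasta",
             "truth_sam": outdir / "truth.sam",
             "truth_sites": outdir / "truth_sites.tsv",
             "truth_ssrs": outdir / "truth_ssrs.tsv"}
    write_fasta(reference, paths["reference"])
    write_truth(truth_sites, paths["truth_sites"], config.varieties)
    write_truth_ssrs(truth_ssrs, paths["truth_ssrs"])
    fastq_handles = {}
    try:
        for v in config.varieties:
            p = outdir / f"{v.lower()}.fastq"
            paths[f"fastq_{v}"] = p
            fastq_handles[v] = open(p, "w")
        with open(paths["truth_sam"], "w") as sam:
            sam.write("@HD\tVN:1.6\tSO:unsorted\n")
            for tid, seq in reference.items():
                sam.write(f"@SQ\tSN:{tid}\tLN:{len(seq)}\n")
            for a in simulate_reads(config, reference, truth_sites):
                qual = "".join(chr(q + 33) for q in a.qualities)
                cigar = "".join(f"{n}{op}" for n, op in a.cigar)
                sam.write(f"{a.read_id}\t0\t{a.transcript_id}\t{a.pos}\t60\t"
                          f"{cigar}\t*\t0\t0\t{a.sequence}\t{qual}\n")
                variety = a.read_id.rsplit(VARIETY_DELIM, 1)[1]
                fastq_handles[variety].write(
                    f"@{a.read_id}\n{a.sequence}\n+\n{qual}\n")
    finally:
        for fh in fastq_handles.values():
            fh.close()
    return paths
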