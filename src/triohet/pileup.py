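"""Variety-tagged pileup construction and stringent biallelic SNP calling.

Reads from each variety carry the variety name at the end of the read id
(``read_id|VARIETY``). Pileups tally, per transcript position and per
variety, how many reads show each base and the summed Phred quality, by
walking each alignment's CIGAR (M/=/X place read bases on the reference,
I/S consume read only, D reference only; N bases are ignored and counted).

SNP sites are emitted under three hard filters: pooled depth across
varieties >= 10 reads, mean base quality over all piled bases >= 25, and an
allele counts as supported only when at least one variety shows it on >= 2
reads. A site must have exactly two supported alleles, at least one of them
differing from the reference base; sub-threshold alleles are treated as
sequencing noise. Indels never generate candidate alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .io import AlignmentRecord, ReadRecord, TranscriptSet, VARIETY_DELIM

log = logging.getLogger("triohet")

BASES = "ACGT"
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i
_BASE_CODE[ord("N")] = 4
_BASE_CODE[ord("n")] = 4


@dataclass(frozen=True)
class SNPFilters:
    """The three stringency filters plus the biallelic cap."""

    min_total_depth: int = 10
    min_avg_basequal: float = 25.0
    min_allele_reads_per_variety: int = 2
    max_alleles: int = 2

    def __post_init__(self):
        if min(self.min_total_depth, self.min_allele_reads_per_variety) < 1:
            raise ValueError("depth/support thresholds must be >= 1")
        if self.min_avg_basequal < 1:
            raise ValueError("min_avg_basequal must be >= 1")
        if self.max_alleles != 2:
            raise ValueError("only biallelic calling is supported")


def tag_reads(reads: Iterable[ReadRecord], variety_label: str
              ) -> Iterator[ReadRecord]:
    """Append ``|VARIETY`` to each read id (the tag a pooled alignment keeps)."""
    if not variety_label or any(ch.isspace() for ch in variety_label) \
            or VARIETY_DELIM in variety_label:
        raise ValueError(f"invalid variety label: {variety_label!r}")
    for r in reads:
        if VARIETY_DELIM in r.read_id:
            raise ValueError(f"read {r.read_id!r} is already tagged")
        yield replace(r, read_id=f"{r.read_id}{VARIETY_DELIM}{variety_label}")


def untag_read_id(read_id: str) -> tuple[str, str | None]:
    if VARIETY_DELIM in read_id:
        base, tag = read_id.rsplit(VARIETY_DELIM, 1)
        return base, tag
    return read_id, None


@dataclass
class PileupColumn:
    """Per-position, per-variety base -> (depth, quality_sum) tallies."""

    transcript_id: str
    pos: int  # 1-based
    ref_base: str
    tallies: dict[str, dict[str, tuple[int, int]]]

    def pooled_depth(self) -> int:
        return sum(d for per in self.tallies.values() for d, _ in per.values())


class Pileup:
    """Per-transcript, per-variety base-count and quality-sum matrices."""

    def __init__(self, reference: TranscriptSet, varieties: Sequence[str] | None = None):
        self.reference = reference
        self.varieties: list[str] = list(varieties) if varieties else []
        self._fixed_varieties = varieties is not None
        # (transcript_id, variety) -> (counts[L,4] int32, qualsums[L,4] int64)
        self._mats: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        self.n_bases_skipped_n = 0
        self.n_unmapped_skipped = 0

    def _mat(self, tid: str, variety: str) -> tuple[np.ndarray, np.ndarray]:
        key = (tid, variety)
        mats = self._mats.get(key)
        if mats is None:
            if variety not in self.varieties:
                if self._fixed_varieties:
                    raise ValueError(f"unexpected variety tag {variety!r}")
                self.varieties.append(variety)
            L = len(self.reference[tid])
            mats = (np.zeros((L, 4), np.int32), np.zeros((L, 4), np.int64))
            self._mats[key] = mats
        return mats

    def add_alignment(self, aln: AlignmentRecord) -> None:
        if aln.is_unmapped:
            self.n_unmapped_skipped += 1
            return
        if aln.transcript_id not in self.reference:
            raise ValueError(f"alignment references unknown transcript "
                             f"{aln.transcript_id!r}")
        _, variety = untag_read_id(aln.read_id)
        if variety is None:
            raise ValueError(f"read {aln.read_id!r} carries no variety tag")
        counts, quals = self._mat(aln.transcript_id, variety)
        L = counts.shape[0]
        codes = _BASE_CODE[np.frombuffer(aln.sequence.encode(), np.uint8)]
        q = np.asarray(aln.qualities, dtype=np.int64)
        qpos = 0
        rpos = aln.pos - 1  # 0-based
        for n, op in aln.cigar:
            if op in "M=X":
                if rpos + n > L:
                    raise ValueError(
                        f"alignment {aln.read_id!r} overruns transcript "
                        f"{aln.transcript_id!r}")
                seg = codes[qpos:qpos + n]
                ok = seg < 4
                if not ok.all():
                    self.n_bases_skipped_n += int((~ok).sum())
                    idx = np.nonzero(ok)[0]
                    np.add.at(counts, (rpos + idx, seg[idx]), 1)
                    np.add.at(quals, (rpos + idx, seg[idx]), q[qpos + idx])
                else:
                    pos_idx = np.arange(rpos, rpos + n)
                    np.add.at(counts, (pos_idx, seg), 1)
                    np.add.at(quals, (pos_idx, seg), q[qpos:qpos + n])
                qpos += n
                rpos += n
            elif op in "IS":
                qpos += n
            elif op == "D":
                rpos += n
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")

    def transcript_arrays(self, tid: str) -> tuple[np.ndarray, np.ndarray]:
        """Stacked (V, L, 4) count and quality-sum arrays for one transcript
        in ``self.varieties`` order (zeros where a variety has no coverage)."""
        L = len(self.reference[tid])
        V = len(self.varieties)
        counts = np.zeros((V, L, 4), np.int64)
        quals = np.zeros((V, L, 4), np.int64)
        for vi, v in enumerate(self.varieties):
            mats = self._mats.get((tid, v))
            if mats is not None:
                counts[vi] = mats[0]
                quals[vi] = mats[1]
        return counts, quals

    def covered_transcripts(self) -> list[str]:
        tids = {tid for tid, _ in self._mats}
        return [t for t in self.reference if t in tids]

    def columns(self) -> Iterator[PileupColumn]:
        """Yield columns with any coverage, in reference order."""
        for tid in self.covered_transcripts():
            counts, quals = self.transcript_arrays(tid)
            depth = counts.sum(axis=(0, 2))
            seq = self.reference[tid]
            for p in np.nonzero(depth)[0]:
                tallies: dict[str, dict[str, tuple[int, int]]] = {}
                for vi, v in enumerate(self.varieties):
                    per = {BASES[b]: (int(counts[vi, p, b]), int(quals[vi, p, b]))
                           for b in range(4) if counts[vi, p, b] > 0}
                    if per:
                        tallies[v] = per
                yield PileupColumn(tid, int(p) + 1, seq[p], tallies)


def build_pileup(alignments: Iterable[AlignmentRecord], reference: TranscriptSet,
                 varieties: Sequence[str] | None = None) -> Pileup:
    """Accumulate variety-tagged alignments into a Pileup."""
    pile = Pileup(reference, varieties)
    for aln in alignments:
        pile.add_alignment(aln)
    return pile


@dataclass
class SNPSite:
    """A filtered biallelic site with per-variety depths for the two alleles.

    ``ref_base`` is the reference base as found (possibly unsupported or N);
    ``ref_allele``/``alt_allele`` are the two supported alleles, with the
    reference base on the ref side whenever it is itself supported, else the
    lexicographically smaller supported allele.
    """

    transcript_id: str
    pos: int
    ref_base: str
    ref_allele: str
    alt_allele: str
    allele_depths: dict[str, tuple[int, int]]  # variety -> (ref-side, alt-side)
    avg_basequal: float
    total_depth: int


def call_snps(pileups: Pileup, filters: SNPFilters | None = None,
              stats: dict | None = None) -> list[SNPSite]:
    """Emit biallelic SNP sites passing all filters.

    ``stats``, when given, collects the filtering funnel: candidate variant
    positions (>= 2 distinct bases observed) and per-reason drop counts.
    """
    f = filters or SNPFilters()
    if stats is None:
        stats = {}
    for k in ("candidate_positions", "dropped_low_depth", "dropped_low_avg_qual",
              "dropped_support", "dropped_multiallelic", "emitted"):
        stats.setdefault(k, 0)
    t = f.min_allele_reads_per_variety
    sites: list[SNPSite] = []
    for tid in pileups.covered_transcripts():
        counts, quals = pileups.transcript_arrays(tid)
        pooled = counts.sum(axis=0)                      # (L, 4)
        depth = pooled.sum(axis=1)                       # (L,)
        qual_total = quals.sum(axis=(0, 2))              # (L,)
        supported = (counts >= t).any(axis=0)            # (L, 4) bool
        n_sup = supported.sum(axis=1)
        candidates = np.nonzero((pooled > 0).sum(axis=1) >= 2)[0]
        stats["candidate_positions"] += len(candidates)
        seq = pileups.reference[tid]
        for p in candidates:
            if depth[p] < f.min_total_depth:
                stats["dropped_low_depth"] += 1
                continue
            avg_q = qual_total[p] / depth[p]
            if avg_q < f.min_avg_basequal:
                stats["dropped_low_avg_qual"] += 1
                continue
            ns = int(n_sup[p])
            if ns < 2:
                stats["dropped_support"] += 1
                continue
            if ns > f.max_alleles:
                stats["dropped_multiallelic"] += 1
                continue
            a, b = (int(x) for x in np.nonzero(supported[p])[0])
            ref_base = seq[p]
            ref_code = BASES.index(ref_base) if ref_base in BASES else None
            if ref_code == a:
                ref_c, alt_c = a, b
            elif ref_code == b:
                ref_c, alt_c = b, a
            else:
                ref_c, alt_c = a, b  # lexicographic: codes follow ACGT order
            depths = {
                v: (int(counts[vi, p, ref_c]), int(counts[vi, p, alt_c]))
                for vi, v in enumerate(pileups.varieties)
            }
            sites.append(SNPSite(
                transcript_id=tid,
                pos=int(p) + 1,
                ref_base=ref_base,
                ref_allele=BASES[ref_c],
                alt_allele=BASES[alt_c],
                allele_depths=depths,
                avg_basequal=float(avg_q),
                total_depth=int(depth[p]),
            ))
            stats["emitted"] += 1
    log.info("call_snps: %s", stats)
    return sites


def write_vcf(sites: Sequence[SNPSite], varieties: Sequence[str], path) -> None:
    """Minimal VCF-style sidecar: one record per site, AD per variety."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=triohet\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Pooled depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=2,Type=Integer,'
                 'Description="Ref,alt allele read depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(varieties) + "\n")
        for s in sites:
            ads = "\t".join(
                f"{s.allele_depths.get(v, (0, 0))[0]},{s.allele_depths.get(v, (0, 0))[1]}"
                for v in varieties)
            fh.write(f"{s.transcript_id}\t{s.pos}\t.\t{s.ref_allele}\t{s.alt_allele}"
                     f"\t.\tPASS\tDP={s.total_depth}\tAD\t{ads}\n")
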