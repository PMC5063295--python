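"""SSR-flanking primer pair enumeration under hard marker-design constraints.

Hard constraints (defaults follow common EST-SSR marker practice): primer
length 20-25 nt, product 100-250 bp strictly containing the SSR tract, GC
40-60%, and a 3' clamp rule of at most one consecutive identical G or C at
the 3' terminus of either primer. Among feasible pairs the returned one
minimises a score that prioritises proximity of both melting temperatures to
the annealing target (65 degC by default) and inter-primer Tm balance, with
GC deviation from the optimum as a tie-breaker at one-tenth weight.

Tm uses the long-oligo approximation Tm = 81.5 + 0.41*GC% - 675/N, standard
for 20-25-mers; it depends on length and GC only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .ssr import SSRLocus, reverse_complement

_ACGT = frozenset("ACGT")
_MIN_TM_LEN = 14


@dataclass(frozen=True)
class PrimerConstraints:
    len_min: int = 20
    len_max: int = 25
    product_min: int = 100
    product_max: int = 250
    tm_target: float = 65.0
    gc_min: float = 40.0
    gc_max: float = 60.0
    gc_opt: float = 50.0

    def __post_init__(self):
        if self.len_min > self.len_max:
            raise ValueError("len_min > len_max")
        if self.product_min > self.product_max:
            raise ValueError("product_min > product_max")
        if not self.gc_min <= self.gc_opt <= self.gc_max:
            raise ValueError("gc_opt must lie within [gc_min, gc_max]")


@dataclass
class PrimerPair:
    marker_id: str
    transcript_id: str
    forward_seq: str
    reverse_seq: str
    forward_start: int  # 1-based template position of the forward 5' end
    reverse_end: int    # 1-based template position of the reverse 5' end
    product_size_bp: int
    gc_forward: float
    gc_reverse: float
    tm_forward: float
    tm_reverse: float
    score: float


def gc_content(seq: str) -> float:
    """GC percentage of an A/C/G/T sequence."""
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - _ACGT:
        raise ValueError(f"sequence contains non-ACGT characters: {seq!r}")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def melting_temp(seq: str) -> float:
    """Long-oligo Tm approximation: 81.5 + 0.41*GC% - 675/length (degC)."""
    if len(seq) < _MIN_TM_LEN:
        raise ValueError(f"Tm formula requires length >= {_MIN_TM_LEN}")
    return 81.5 + 0.41 * gc_content(seq) - 675.0 / len(seq)


def passes_clamp(seq: str) -> bool:
    """3' clamp rule: the run of identical G's or C's ending at the 3'
    terminal base must not exceed one (a non-G/C terminus passes)."""
    if not seq:
        return True
    last = seq[-1]
    if last not in "GC":
        return True
    run = 1
    for ch in reversed(seq[:-1]):
        if ch == last:
            run += 1
        else:
            break
    return run <= 1


def design_primers(sequence: str, ssr: SSRLocus,
                   constraints: PrimerConstraints | None = None
                   ) -> PrimerPair | None:
    """Best feasible primer pair around one SSR locus, or None.

    The forward primer lies entirely upstream of the repeat (3' end at least
    one base before ssr.start), the reverse primer entirely downstream; the
    product strictly contains the tract. Deterministic: score ties break on
    smaller forward_start, then smaller product, then shorter primers.
    """
    c = constraints or PrimerConstraints()
    sequence = sequence.upper()
    n = len(sequence)
    if not (1 <= ssr.start <= ssr.end <= n):
        raise ValueError(
            f"SSR span {ssr.start}-{ssr.end} outside sequence of length {n}")

    # candidate forward primers: template slice [s, s+lf-1], 3' end <= ssr.start-1
    fwd: list[tuple[int, int, str, float, float]] = []  # (start, len, seq, gc, tm)
    lo = max(1, ssr.end + 1 - c.product_max + 1)  # product upper bound coarse cut
    for s in range(lo, ssr.start):
        for lf in range(c.len_min, c.len_max + 1):
            end = s + lf - 1
            if end > ssr.start - 1:
                break
            cand = sequence[s - 1:end]
            if not _primer_ok(cand, c):
                continue
            fwd.append((s, lf, cand, gc_content(cand), melting_temp(cand)))

    rev: list[tuple[int, int, str, float, float]] = []  # (end, len, seq, gc, tm)
    hi = min(n, ssr.start - 1 + c.product_max)
    for e in range(ssr.end + 1, hi + 1):
        for lr in range(c.len_min, c.len_max + 1):
            rs = e - lr + 1
            if rs < ssr.end + 1:
                break
            cand = reverse_complement(sequence[rs - 1:e])
            if not _primer_ok(cand, c):
                continue
            rev.append((e, lr, cand, gc_content(cand), melting_temp(cand)))

    best = None
    best_key = None
    for s, lf, fseq, fgc, ftm in fwd:
        for e, lr, rseq, rgc, rtm in rev:
            product = e - s + 1
            if product < c.product_min:
                continue
            if product > c.product_max:
                break  # rev sorted by end ascending
            score = (abs(ftm - c.tm_target) + abs(rtm - c.tm_target)
                     + abs(ftm - rtm)
                     + (abs(fgc - c.gc_opt) + abs(rgc - c.gc_opt)) / 10.0)
            key = (score, s, product, lf, lr)
            if best_key is None or key < best_key:
                best_key = key
                best = PrimerPair(
                    marker_id="",
                    transcript_id=ssr.transcript_id,
                    forward_seq=fseq,
                    reverse_seq=rseq,
                    forward_start=s,
                    reverse_end=e,
                    product_size_bp=product,
                    gc_forward=fgc,
                    gc_reverse=rgc,
                    tm_forward=ftm,
                    tm_reverse=rtm,
                    score=score,
                )
    return best


def _primer_ok(seq: str, c: PrimerConstraints) -> bool:
    if set(seq) - _ACGT:  # N or other ambiguity in the window
        return False
    gc = gc_content(seq)
    return c.gc_min <= gc <= c.gc_max and passes_clamp(seq)


def design_all(transcripts, loci: Sequence[SSRLocus],
               constraints: PrimerConstraints | None = None,
               marker_prefix: str = "MSSR") -> list[PrimerPair]:
    """Design primers for every locus; successful designs are numbered
    ``MSSR1, MSSR2, ...`` in transcript order then locus order."""
    c = constraints or PrimerConstraints()
    by_tid: dict[str, list[SSRLocus]] = {}
    for loc in loci:
        by_tid.setdefault(loc.transcript_id, []).append(loc)
    pairs: list[PrimerPair] = []
    serial = 0
    for tid in transcripts:
        for loc in sorted(by_tid.get(tid, []), key=lambda l: l.start):
            pair = design_primers(transcripts[tid], loc, c)
            if pair is not None:
                serial += 1
                pair.marker_id = f"{marker_prefix}{serial}"
                pairs.append(pair)
    return pairs
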