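"""Perfect-microsatellite (SSR) mining in transcript sequences.

Detects maximal perfect tandem repeats of 2-6 bp primitive motifs, pools
motifs into canonical classes (closed under cyclic rotation and reverse
complementation, e.g. AG/GA/CT/TC -> AG), marks compound loci, applies the
marker-development exclusions (mononucleotide, compound, total length
< 10 bp) and types the survivors: Type I when the repeat tract is >= 20 bp
(the length class preferred for polymorphic markers), Type II otherwise.

Default reiteration thresholds are the MISA-style criteria used for genic-SSR
surveys: >= 6 repeats for dinucleotides, >= 5 for tri- through
hexanucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_MIN_REPS: dict[int, int] = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

UNIT_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass(frozen=True)
class SSRCriteria:
    """Detection and filtering thresholds for SSR mining."""

    min_reps_by_unit: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPS)
    )
    min_total_len_bp: int = 10
    type1_min_len_bp: int = 20
    compound_max_gap_bp: int = 100
    unit_sizes: frozenset[int] = frozenset({2, 3, 4, 5, 6})

    def __post_init__(self):
        if not self.unit_sizes <= {1, 2, 3, 4, 5, 6}:
            raise ValueError("unit_sizes must be within 1..6")
        for u in self.unit_sizes:
            if self.min_reps_by_unit.get(u, 0) < 1:
                raise ValueError(f"missing/invalid min reiterations for unit size {u}")
        if min(self.min_total_len_bp, self.type1_min_len_bp,
               self.compound_max_gap_bp) < 1:
            raise ValueError("all length thresholds must be >= 1")


@dataclass
class SSRLocus:
    """One maximal perfect tandem repeat; coordinates 1-based inclusive."""

    transcript_id: str
    start: int
    end: int
    motif: str
    canonical_motif: str
    unit_size: int
    repeat_count: int
    ssr_type: str = ""  # "I" or "II", set by filter_loci
    compound: bool = False

    @property
    def total_len_bp(self) -> int:
        return self.end - self.start + 1


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True iff the motif is not a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Class representative: the lexicographically smallest cyclic rotation
    of the motif or of its reverse complement.

    Pools e.g. CT/TC/AG/GA into AG, matching the AG/CT style of reporting.
    """
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 1-6, got {motif!r}")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif must be over A/C/G/T, got {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    candidates = []
    for m in (motif, reverse_complement(motif)):
        candidates.extend(m[i:] + m[:i] for i in range(len(m)))
    return min(candidates)


def find_ssrs(transcript_id: str, sequence: str, criteria: SSRCriteria | None = None
              ) -> list[SSRLocus]:
    """All maximal perfect tandem repeats meeting the reiteration thresholds.

    A run is maximal when it cannot be extended by one more unit-phase base on
    either side; only whole units count (a partial trailing unit extends
    neither the span nor repeat_count). Each stretch is reported once, under
    its primitive unit and leftmost phase. Runs are broken at N. When maximal
    runs of distinct motifs overlap, the longer (ties: leftmost, then smaller
    unit) wins.
    """
    criteria = criteria or SSRCriteria()
    sequence = sequence.upper()
    loci: list[SSRLocus] = []
    offset = 0
    for segment in sequence.split("N"):
        if segment:
            loci.extend(_scan_segment(transcript_id, segment, offset, criteria))
        offset += len(segment) + 1
    loci.sort(key=lambda l: (l.start, -(l.total_len_bp), l.unit_size))
    return _resolve_overlaps(loci)


def _scan_segment(tid: str, seg: str, offset: int, criteria: SSRCriteria
                  ) -> Iterable[SSRLocus]:
    n = len(seg)
    for u in sorted(criteria.unit_sizes):
        if u < 1:
            continue
        min_rep = criteria.min_reps_by_unit[u]
        min_run = u * min_rep
        i = 0
        while i + min_run <= n:
            # leftmost phase only: a run extendable one base left is a dup
            if i > 0 and seg[i - 1] == seg[i + u - 1]:
                i += 1
                continue
            motif = seg[i:i + u]
            if not is_primitive(motif):
                i += 1
                continue
            j = i + u
            while j < n and seg[j] == seg[j - u]:
                j += 1
            reps = (j - i) // u
            if reps >= min_rep:
                start = offset + i + 1  # 1-based
                yield SSRLocus(
                    transcript_id=tid,
                    start=start,
                    end=start + reps * u - 1,
                    motif=motif,
                    canonical_motif=canonical_motif(motif),
                    unit_size=u,
                    repeat_count=reps,
                )
                i = j - u + 1  # next same-size run can start inside the tail
            else:
                i += 1


def _resolve_overlaps(loci: list[SSRLocus]) -> list[SSRLocus]:
    # input sorted by (start, -length, unit); on overlap the longer run wins,
    # ties go to the leftmost start, then the smaller (primitive) unit
    kept: list[SSRLocus] = []
    for loc in loci:
        discard = False
        while kept and loc.start <= kept[-1].end:
            if loc.total_len_bp > kept[-1].total_len_bp:
                kept.pop()  # strictly longer newcomer displaces; recheck back
            else:
                discard = True
                break
        if not discard:
            kept.append(loc)
    return kept


def mark_compound(loci: Sequence[SSRLocus], compound_max_gap_bp: int = 100
                  ) -> list[SSRLocus]:
    """Flag loci (one transcript, sorted by start) whose spans lie within
    ``compound_max_gap_bp`` of a neighbour; flags propagate along chains."""
    starts = [l.start for l in loci]
    if starts != sorted(starts):
        raise ValueError("loci must be sorted by start")
    out = [replace(l) for l in loci]
    for a, b in zip(out, out[1:]):
        gap = b.start - a.end - 1
        if gap <= compound_max_gap_bp:
            a.compound = True
            b.compound = True
    return out


def filter_loci(loci: Iterable[SSRLocus], criteria: SSRCriteria | None = None
                ) -> list[SSRLocus]:
    """Apply the marker-development exclusions and assign SSR types.

    Drops mononucleotide runs, compound loci and tracts shorter than
    ``min_total_len_bp``; annotates the rest Type I (>= type1_min_len_bp)
    or Type II.
    """
    criteria = criteria or SSRCriteria()
    retained = []
    for loc in loci:
        if loc.unit_size == 1 or loc.compound:
            continue
        if loc.total_len_bp < criteria.min_total_len_bp:
            continue
        loc = replace(loc)
        loc.ssr_type = "I" if loc.total_len_bp >= criteria.type1_min_len_bp else "II"
        retained.append(loc)
    return retained


def category_percentages(counts: Mapping[int, int]) -> pd.DataFrame:
    """Per-unit-size counts and percentages of the total (e.g. tri: 774 of
    1,481 -> 52.26%)."""
    total = sum(counts.values())
    rows = []
    for u in sorted(counts):
        c = counts[u]
        rows.append({
            "unit_size": u,
            "category": UNIT_NAMES.get(u, str(u)),
            "count": c,
            "pct": 100.0 * c / total if total else 0.0,
        })
    return pd.DataFrame(rows, columns=["unit_size", "category", "count", "pct"])


@dataclass
class SSRSummary:
    total_loci: int
    categories: pd.DataFrame           # unit_size, category, count, pct
    n_unigenes: int
    unigenes_with_ssr: int
    pct_unigenes_with_ssr: float
    unigenes_single_locus: int
    unigenes_multi_locus: int
    motif_table: pd.DataFrame          # canonical_motif, repeat_count, count


def ssr_summary(loci: Sequence[SSRLocus], n_unigenes: int) -> SSRSummary:
    """Frequency summaries over retained loci: counts/percentages by unit-size
    category, unigene occupancy, and the canonical-motif x repeat-count
    frequency table."""
    if n_unigenes <= 0:
        raise ValueError("n_unigenes must be positive")
    counts: dict[int, int] = {}
    per_unigene: dict[str, int] = {}
    motif_counts: dict[tuple[str, int], int] = {}
    for loc in loci:
        counts[loc.unit_size] = counts.get(loc.unit_size, 0) + 1
        per_unigene[loc.transcript_id] = per_unigene.get(loc.transcript_id, 0) + 1
        key = (loc.canonical_motif, loc.repeat_count)
        motif_counts[key] = motif_counts.get(key, 0) + 1
    with_ssr = len(per_unigene)
    motif_rows = [
        {"canonical_motif": m, "repeat_count": r, "count": c}
        for (m, r), c in sorted(motif_counts.items())
    ]
    return SSRSummary(
        total_loci=len(loci),
        categories=category_percentages(counts),
        n_unigenes=n_unigenes,
        unigenes_with_ssr=with_ssr,
        pct_unigenes_with_ssr=100.0 * with_ssr / n_unigenes,
        unigenes_single_locus=sum(1 for v in per_unigene.values() if v == 1),
        unigenes_multi_locus=sum(1 for v in per_unigene.values() if v >= 2),
        motif_table=pd.DataFrame(
            motif_rows, columns=["canonical_motif", "repeat_count", "count"]
        ),
    )


def mine_transcripts(transcripts, criteria: SSRCriteria | None = None
                     ) -> list[SSRLocus]:
    """Scan every transcript, mark compound loci, and apply the filters."""
    criteria = criteria or SSRCriteria()
    out: list[SSRLocus] = []
    for tid, seq in transcripts.items():
        loci = find_ssrs(tid, seq, criteria)
        loci = mark_compound(loci, criteria.compound_max_gap_bp)
        out.extend(filter_loci(loci, criteria))
    return out
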