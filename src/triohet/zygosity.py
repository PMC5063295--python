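"""Per-variety zygosity calls and eight-class trio classification.

At a biallelic site a variety is heterozygous (HT) when both alleles reach
the read-support threshold, homozygous (HM) when exactly one does, and
NOCALL otherwise. The ordered (parent1, parent2, hybrid) HM/HT triple maps
onto eight classes:

    1 (HM,HM,HT)  novel heterozygosity in the hybrid
    2 (HT,HM,HT)  maintained from parent 1
    3 (HM,HT,HT)  maintained from parent 2
    4 (HT,HT,HT)  maintained from both
    5 (HT,HT,HM)  lost from both
    6 (HM,HM,HM)  homozygous throughout
    7 (HM,HT,HM)  lost from parent 2
    8 (HT,HM,HM)  lost from parent 1

Sites with any NOCALL are excluded from the table (only sites informative in
all three genotypes are classified). Hybrid heterozygosity splits into
novel (class 1), maintained (2+3+4) and lost (5+7+8).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .pileup import SNPSite

HM = "HM"
HT = "HT"
NOCALL = "NOCALL"

#: class number -> ordered (parent1, parent2, hybrid) zygosity pattern
CLASS_PATTERNS: dict[int, tuple[str, str, str]] = {
    1: (HM, HM, HT),
    2: (HT, HM, HT),
    3: (HM, HT, HT),
    4: (HT, HT, HT),
    5: (HT, HT, HM),
    6: (HM, HM, HM),
    7: (HM, HT, HM),
    8: (HT, HM, HM),
}
CLASS_BY_PATTERN = {pat: cls for cls, pat in CLASS_PATTERNS.items()}

DEFAULT_TRIO = ("NEELAM", "DASHEHARI", "AMRAPALI")


def call_zygosity(ref_depth: int, alt_depth: int, min_allele_reads: int = 2) -> str:
    """HT iff both alleles reach support; HM iff exactly one; else NOCALL."""
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("negative allele depth")
    supported = (ref_depth >= min_allele_reads) + (alt_depth >= min_allele_reads)
    return (NOCALL, HM, HT)[supported]


def classify_trio(z_parent1: str, z_parent2: str, z_hybrid: str) -> int | None:
    """Class number for an ordered zygosity triple; None if any call is NOCALL."""
    return CLASS_BY_PATTERN.get((z_parent1, z_parent2, z_hybrid))


@dataclass
class ClassifiedSite:
    transcript_id: str
    pos: int
    zygosity: tuple[str, str, str]
    trio_class: int


def classify_sites(sites: Iterable[SNPSite], order: Sequence[str] = DEFAULT_TRIO,
                   min_allele_reads: int = 2,
                   stats: dict | None = None) -> list[ClassifiedSite]:
    """Call zygosity per variety (in trio order, hybrid last) and classify.

    Sites with a NOCALL in any variety are excluded; the count lands in
    ``stats["excluded_nocall"]`` when a stats dict is supplied.
    """
    if len(set(order)) != 3:
        raise ValueError("trio order must name exactly 3 distinct varieties")
    if stats is None:
        stats = {}
    stats.setdefault("excluded_nocall", 0)
    out: list[ClassifiedSite] = []
    for s in sites:
        zyg = tuple(
            call_zygosity(*s.allele_depths.get(v, (0, 0)), min_allele_reads)
            for v in order
        )
        cls = classify_trio(*zyg)
        if cls is None:
            stats["excluded_nocall"] += 1
            continue
        out.append(ClassifiedSite(s.transcript_id, s.pos, zyg, cls))
    return out


@dataclass
class TrioSummary:
    labels: tuple[str, str, str]
    class_counts: tuple[int, ...]          # c1..c8
    total: int
    ht_counts: dict[str, int]
    ht_pct: dict[str, float]
    novel_het: int
    maintained_het: int
    lost_het: int
    snps_per_transcript_mean: float | None = None
    snps_per_transcript_min: int | None = None
    snps_per_transcript_max: int | None = None
    n_transcripts: int | None = None
    snps_per_transcript_hist: dict[int, int] = field(default_factory=dict)


def summarize_counts(class_counts: Sequence[int],
                     labels: Sequence[str] = DEFAULT_TRIO,
                     n_transcripts: int | None = None) -> TrioSummary:
    """Derive every summary quantity from the eight class counts alone.

    Per-variety HT counts come from the class patterns (e.g. parent1 is HT in
    classes 2, 4, 5, 8); percentages are 100*HT/total; hybrid heterozygosity
    splits into novel (c1), maintained (c2+c3+c4) and lost (c5+c7+c8).
    """
    counts = tuple(int(c) for c in class_counts)
    if len(counts) != 8 or any(c < 0 for c in counts):
        raise ValueError("expected 8 non-negative class counts")
    labels = tuple(labels)
    total = sum(counts)
    ht_counts = {
        lab: sum(counts[cls - 1] for cls, pat in CLASS_PATTERNS.items()
                 if pat[i] == HT)
        for i, lab in enumerate(labels)
    }
    ht_pct = {lab: (100.0 * c / total if total else 0.0)
              for lab, c in ht_counts.items()}
    summary = TrioSummary(
        labels=labels,
        class_counts=counts,
        total=total,
        ht_counts=ht_counts,
        ht_pct=ht_pct,
        novel_het=counts[0],
        maintained_het=counts[1] + counts[2] + counts[3],
        lost_het=counts[4] + counts[6] + counts[7],
        n_transcripts=n_transcripts,
    )
    if n_transcripts:
        summary.snps_per_transcript_mean = total / n_transcripts
    return summary


def summarize_trio(classified_sites: Sequence[ClassifiedSite],
                   labels: Sequence[str] = DEFAULT_TRIO) -> TrioSummary:
    """Full summary over classified sites, including the SNPs-per-transcript
    distribution across transcripts bearing at least one classified site."""
    counts = [0] * 8
    per_transcript: Counter[str] = Counter()
    for s in classified_sites:
        counts[s.trio_class - 1] += 1
        per_transcript[s.transcript_id] += 1
    summary = summarize_counts(counts, labels, n_transcripts=len(per_transcript) or None)
    if per_transcript:
        vals = per_transcript.values()
        summary.snps_per_transcript_min = min(vals)
        summary.snps_per_transcript_max = max(vals)
        summary.snps_per_transcript_hist = dict(sorted(Counter(vals).items()))
    return summary


def heterozygosity_report(summary: TrioSummary) -> list[dict]:
    """Eight class rows plus a totals row, then derived-metric rows."""
    p1, p2, hyb = summary.labels
    rows: list[dict] = []
    for cls in range(1, 9):
        pat = CLASS_PATTERNS[cls]
        rows.append({
            "class": str(cls),
            p1: pat[0], p2: pat[1], hyb: pat[2],
            "n_snps": str(summary.class_counts[cls - 1]),
        })
    rows.append({
        "class": "Total",
        p1: f"{summary.ht_counts[p1]} HT",
        p2: f"{summary.ht_counts[p2]} HT",
        hyb: f"{summary.ht_counts[hyb]} HT",
        "n_snps": str(summary.total),
    })
    for name, val in (
        (f"HT% {p1}", f"{summary.ht_pct[p1]:.2f}"),
        (f"HT% {p2}", f"{summary.ht_pct[p2]:.2f}"),
        (f"HT% {hyb}", f"{summary.ht_pct[hyb]:.2f}"),
        ("novel_het", str(summary.novel_het)),
        ("maintained_het", str(summary.maintained_het)),
        ("lost_het", str(summary.lost_het)),
    ):
        rows.append({"class": name, p1: "", p2: "", hyb: "", "n_snps": val})
    if summary.snps_per_transcript_mean is not None:
        rows.append({"class": "mean_snps_per_transcript", p1: "", p2: "", hyb: "",
                     "n_snps": f"{summary.snps_per_transcript_mean:.1f}"})
    return rows


def mean_sites_per_transcript(n_sites: int, n_transcripts: int) -> float:
    """Average SNPs per transcript for a (site count, transcript count) pair."""
    if n_transcripts <= 0:
        raise ValueError("n_transcripts must be positive")
    return n_sites / n_transcripts
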