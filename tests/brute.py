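"""Brute-force oracles, kept deliberately naive and independent of the
implementation's scanning strategy."""

from triohet.ssr import SSRCriteria


def _primitive(motif: str) -> bool:
    for d in range(1, len(motif)):
        if len(motif) % d == 0 and motif == motif[:d] * (len(motif) // d):
            return False
    return True


def brute_find_ssrs(seq: str, criteria: SSRCriteria | None = None
                    ) -> list[tuple[int, int, str, int]]:
    """Enumerate every (unit size, start), extend perfect repeats unit by
    unit via slice equality, keep maximal primitive runs meeting thresholds,
    then apply the longest-wins/leftmost/smallest-unit overlap rule.

    Returns (start, end, motif, repeat_count) with 1-based inclusive spans.
    """
    criteria = criteria or SSRCriteria()
    seq = seq.upper()
    n = len(seq)
    runs: list[tuple[int, int, str, int]] = []
    for u in sorted(criteria.unit_sizes):
        min_rep = criteria.min_reps_by_unit[u]
        for i in range(n - u + 1):
            motif = seq[i:i + u]
            if "N" in motif or not _primitive(motif):
                continue
            reps = 1
            while seq[i + reps * u:i + (reps + 1) * u] == motif:
                reps += 1
            if reps < min_rep:
                continue
            # maximal on the left: one more phase base would extend the run
            if i >= 1 and seq[i - 1] == motif[-1]:
                continue
            runs.append((i + 1, i + reps * u, motif, reps))
    runs.sort(key=lambda r: (r[0], -(r[1] - r[0] + 1), len(r[2])))
    kept: list[tuple[int, int, str, int]] = []
    for run in runs:
        discard = False
        while kept and run[0] <= kept[-1][1]:
            if (run[1] - run[0]) > (kept[-1][1] - kept[-1][0]):
                kept.pop()
            else:
                discard = True
                break
        if not discard:
            kept.append(run)
    return kept
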