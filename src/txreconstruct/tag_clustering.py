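"""TSS / PAS cluster calling from tag-end profiles.

Nonzero positions on one strand are merged when separated by at most
``max_gap`` bp; merged clusters below ``min_tag_count`` pooled tags are
dropped as positional noise.  The summit is the position of maximal count
(leftmost on '+', rightmost on '-' at ties) and is the anchor used later
for long-read extension.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

from .core import TAG_MAX_GAP, TAG_MIN_COUNT, GenomicInterval, TagCluster, TagProfile


def call_tag_clusters(
    profile: TagProfile,
    kind: str,
    max_gap: int = TAG_MAX_GAP,
    min_tag_count: int = TAG_MIN_COUNT,
    min_sample_fraction: float = 0.0,
    replicate_profiles: Optional[Sequence[TagProfile]] = None,
) -> List[TagCluster]:
    """Merge tag positions into clusters and filter by pooled score.

    ``min_sample_fraction`` (off by default) additionally requires a cluster
    to hold at least one tag in that fraction of the per-replicate profiles.
    """
    if kind not in ("TSS", "PAS"):
        raise ValueError(f"kind must be 'TSS' or 'PAS', got {kind!r}")
    clusters: List[TagCluster] = []
    raw: List[Tuple[str, str, int, int, int, int]] = []
    for (chrom, strand) in sorted(profile):
        counts = profile[(chrom, strand)]
        positions = sorted(counts)
        run: List[int] = []
        for pos in positions:
            if run and pos - run[-1] > max_gap:
                raw.append(_finish(chrom, strand, run, counts))
                run = []
            run.append(pos)
        if run:
            raw.append(_finish(chrom, strand, run, counts))

    for chrom, strand, start, end, summit, score in raw:
        if score < min_tag_count:
            continue
        if min_sample_fraction > 0 and replicate_profiles:
            n_with = sum(
                1
                for rep in replicate_profiles
                if any(
                    start <= p < end
                    for p in rep.get((chrom, strand), {})
                )
            )
            if n_with < min_sample_fraction * len(replicate_profiles):
                continue
        clusters.append(
            TagCluster(
                id="",
                interval=GenomicInterval(chrom, start, end, strand),
                summit=summit,
                score=score,
                kind=kind,
            )
        )
    if not clusters:
        raise ValueError(
            f"no {kind} clusters survive filtering; relax min_tag_count "
            f"(currently {min_tag_count})"
        )
    clusters.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.strand))
    for i, c in enumerate(clusters, start=1):
        c.id = f"{kind}_{i:05d}"
    return clusters


def _finish(chrom: str, strand: str, run: List[int], counts: Dict[int, int]):
    start, end = run[0], run[-1] + 1
    best = max(counts[p] for p in run)
    candidates = [p for p in run if counts[p] == best]
    summit = min(candidates) if strand == "+" else max(candidates)
    score = sum(counts[p] for p in run)
    return chrom, strand, start, end, summit, score


def summarize_clusters(clusters: Sequence[TagCluster]) -> Dict[str, dict]:
    """Per-kind counts and score quantiles for the run report."""
    out: Dict[str, dict] = {"TSS": _empty(), "PAS": _empty()}
    by_kind: Dict[str, List[int]] = {"TSS": [], "PAS": []}
    for c in clusters:
        by_kind[c.kind].append(c.score)
    for kind, scores in by_kind.items():
        if not scores:
            continue
        scores.sort()
        n = len(scores)
        out[kind] = {
            "count": n,
            "score_min": scores[0],
            "score_median": scores[n // 2],
            "score_max": scores[-1],
        }
    return out


def _empty() -> dict:
    return {"count": 0, "score_min": 0, "score_median": 0, "score_max": 0}
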