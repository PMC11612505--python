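"""Discordant-pair clustering into imprecise candidate CNVs, and merging.

Same-kind discordant pairs whose anchors lie within max_IS of each other
(single linkage on both anchors) form a cluster; clusters with enough
support emit an imprecise candidate. When a discordant candidate matches a
split-module candidate under the imprecise comparison parameters, the
precise split coordinates are retained.
"""

from __future__ import annotations

from typing import Sequence

from .compare import IMPRECISE, cnv_match
from .core import GenomeInterval, LibraryStats
from .evidence import DiscordantPair
from .split_caller import CandidateCNV

MIN_DISC_SUPPORT = 3


def _single_linkage(pairs: list[DiscordantPair], max_dist: int) -> list[list[DiscordantPair]]:
    pairs = sorted(pairs, key=lambda p: (p.left_anchor, p.right_anchor))
    clusters: list[list[DiscordantPair]] = []
    for p in pairs:
        merged = False
        for cl in clusters:
            if any(
                abs(p.left_anchor - q.left_anchor) <= max_dist
                and abs(p.right_anchor - q.right_anchor) <= max_dist
                for q in cl
            ):
                cl.append(p)
                merged = True
                break
        if merged:
            continue
        clusters.append([p])
    # single linkage can bridge clusters added separately; merge transitively
    changed = True
    while changed:
        changed = False
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                if any(
                    abs(p.left_anchor - q.left_anchor) <= max_dist
                    and abs(p.right_anchor - q.right_anchor) <= max_dist
                    for p in clusters[a]
                    for q in clusters[b]
                ):
                    clusters[a].extend(clusters[b])
                    del clusters[b]
                    changed = True
                    break
            if changed:
                break
    return clusters


def cluster_discordant(
    pairs: Sequence[DiscordantPair],
    stats: LibraryStats,
    min_support: int = MIN_DISC_SUPPORT,
) -> list[CandidateCNV]:
    """Cluster discordant pairs into imprecise candidates.

    Deletion interval: [max forward-read end, min reverse-read start).
    Duplication interval: [min upstream-read start, max downstream-read end).
    """
    max_is = int(round(stats.max_is))
    ci = max(0, max_is - stats.read_len)
    out: list[CandidateCNV] = []
    for kind in ("DEL", "DUP"):
        for chrom in sorted({p.chrom for p in pairs if p.kind == kind}):
            sub = [p for p in pairs if p.kind == kind and p.chrom == chrom]
            for cl in _single_linkage(sub, max_is):
                if len(cl) < min_support:
                    continue
                if kind == "DEL":
                    start = max(p.left_anchor for p in cl)
                    end = min(p.right_anchor for p in cl)
                else:
                    start = min(p.left_anchor for p in cl)
                    end = max(p.right_anchor for p in cl)
                if end <= start:
                    continue
                out.append(
                    CandidateCNV(
                        svtype=kind,
                        interval=GenomeInterval(chrom, start, end),
                        precise=False,
                        source="DISCORDANT",
                        support_disc=len(cl),
                        ci=ci,
                    )
                )
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return out


def merge_candidates(
    split_calls: Sequence[CandidateCNV], discordant_calls: Sequence[CandidateCNV]
) -> list[CandidateCNV]:
    """Drop discordant candidates explained by a precise split candidate."""
    kept = list(split_calls)
    for disc in discordant_calls:
        explained = False
        for sp in split_calls:
            if cnv_match(sp, disc, IMPRECISE):
                sp.support_disc = max(sp.support_disc, disc.support_disc)
                explained = True
        if not explained:
            kept.append(disc)
    kept.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return kept
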