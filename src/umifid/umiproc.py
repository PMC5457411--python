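"""UMI extraction and the coverage / parent-child filters.

Reads are grouped by the exact sequence of their leading UMI bases.  Two
filters then remove artifact groups: tags read fewer than five times are
dropped (too little coverage for consensus error correction), and
low-coverage "satellite" tags that sit within Hamming distance 1 (coverage
ratio < 1:20) or distance 2 (ratio < 1:200) of a high-coverage parent tag
are treated as UMI sequence errors and removed.  Ratio comparisons are
strict and are evaluated against the original, pre-removal coverages; a
child with several candidate parents is tested against the
highest-coverage one.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

logger = logging.getLogger(__name__)

__all__ = [
    "UmiGroup",
    "extract_umis",
    "filter_low_coverage",
    "collapse_parent_child",
    "group_manifest",
]

_ALPHABET = "ACGT"


@dataclass
class UmiGroup:
    """All reads sharing one UMI tag; ``coverage`` is the read count."""

    umi: str
    reads: list = field(default_factory=list)  # (sequence, quality) pairs

    @property
    def coverage(self) -> int:
        return len(self.reads)


def extract_umis(reads: Iterable, umi_length: int = 14) -> dict:
    """Group reads by their first ``umi_length`` bases.

    ``reads`` yields ``(name, sequence, quality)`` triples (extra fields
    are ignored).  Reads shorter than ``umi_length + 1`` are skipped and
    counted.  Returns ``{umi: UmiGroup}``.
    """
    if umi_length < 1:
        raise ValueError("umi_length must be >= 1")
    groups: dict = {}
    skipped = 0
    for rec in reads:
        seq, qual = rec[1], rec[2]
        if len(seq) < umi_length + 1:
            skipped += 1
            continue
        umi = seq[:umi_length]
        group = groups.get(umi)
        if group is None:
            group = groups[umi] = UmiGroup(umi)
        group.reads.append((seq[umi_length:], qual[umi_length:]))
    if skipped:
        logger.info("extract_umis: skipped %d reads shorter than UMI+1", skipped)
    return groups


def filter_low_coverage(groups: dict, min_reads: int = 5) -> dict:
    """Drop UMI groups read fewer than ``min_reads`` times."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    kept = {u: g for u, g in groups.items() if g.coverage >= min_reads}
    logger.info(
        "filter_low_coverage: removed %d of %d UMI groups (coverage < %d)",
        len(groups) - len(kept), len(groups), min_reads,
    )
    return kept


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _neighbor_coverages(umis: list, coverage: dict) -> dict:
    """Max parent coverage at Hamming distance 1 and 2 for every tag.

    Tags within distance <= 2 must match exactly on at least one of three
    near-equal substring parts (pigeonhole), so candidate parents are found
    by hashing the parts instead of enumerating the mutation neighborhood.
    Only equal-length tags are compared.
    """
    best: dict = {u: [0, 0] for u in umis}
    by_len = defaultdict(list)
    for u in umis:
        by_len[len(u)].append(u)
    for length, members in by_len.items():
        third = max(1, length // 3)
        cuts = [(0, third), (third, 2 * third), (2 * third, length)]
        buckets = defaultdict(list)
        for u in members:
            for pi, (a, b) in enumerate(cuts):
                buckets[(pi, u[a:b])].append(u)
        for u in members:
            seen = set()
            for pi, (a, b) in enumerate(cuts):
                for other in buckets[(pi, u[a:b])]:
                    if other == u or other in seen:
                        continue
                    seen.add(other)
                    d = _hamming(u, other)
                    if d in (1, 2):
                        slot = best[u][d - 1]
                        cov = coverage[other]
                        if cov > slot:
                            best[u][d - 1] = cov
    return best


def classify_parent_child(groups: dict) -> dict:
    """Map each removable satellite UMI to the rule that removes it.

    A group is removable if some tag at Hamming distance 1 has more than
    20x its coverage, or some tag at distance 2 has more than 200x its
    coverage (strict inequality: child/parent < 1/20 resp. < 1/200).  Both
    rules use the original coverages, so removal decisions do not cascade.
    """
    coverage = {u: g.coverage for u, g in groups.items()}
    neighbors = _neighbor_coverages(list(groups), coverage)
    removed = {}
    for umi, cov in coverage.items():
        parent1, parent2 = neighbors[umi]
        if parent1 and cov / parent1 < 1.0 / 20.0:
            removed[umi] = "parent_child_d1"
        elif parent2 and cov / parent2 < 1.0 / 200.0:
            removed[umi] = "parent_child_d2"
    return removed


def collapse_parent_child(groups: dict) -> dict:
    """Remove satellite UMIs sitting near a much higher-coverage parent."""
    removed = classify_parent_child(groups)
    logger.info(
        "collapse_parent_child: removed %d of %d UMI groups", len(removed), len(groups)
    )
    return {u: g for u, g in groups.items() if u not in removed}


def group_manifest(all_groups: dict, retained: dict, removal_reasons: dict | None = None) -> list:
    """Rows (umi, coverage, retained_flag, removal_reason) for the group TSV."""
    reasons = removal_reasons or {}
    rows = []
    for umi in sorted(all_groups):
        kept = umi in retained
        reason = "" if kept else reasons.get(umi, "low_coverage")
        rows.append((umi, all_groups[umi].coverage, int(kept), reason))
    return rows
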