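"""Majority-consensus assembly per UMI and substitution calling.

Every retained UMI group is collapsed to one consensus sequence: at each
template position the base with the plurality of read support is emitted,
with ties broken first by summed Phred quality and then in favor of the
reference base (biasing ties toward no-call).  Consensus sequences are
compared to the reference by position — templates are fixed-length and
indel-free in this assay, so no gapped alignment is needed — and every
mismatching base contributes to an :class:`ErrorCall`.

Because the dilution bottleneck guarantees that all reads of a UMI descend
from a single first-PCR molecule, second-PCR and sequencing errors are
subdominant within a read group and are removed by the consensus, while
first-PCR and linear-amplification errors are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .umiproc import UmiGroup

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusSequence",
    "ErrorCall",
    "assemble_consensus",
    "call_errors",
    "VARIANT_COLUMNS",
]

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_LOOKUP = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LOOKUP[_b] = _i

#: Column order of the variant interchange table.
VARIANT_COLUMNS = ["sample", "position", "ref", "alt", "umi_count", "coverage", "frequency"]


@dataclass
class ConsensusSequence:
    """Per-UMI consensus with per-position majority support."""

    umi: str
    sequence: str
    per_position_majority_fraction: np.ndarray
    low_coverage_positions: int = 0


class ErrorCall(NamedTuple):
    """One substitution aggregated over consensus sequences."""

    sample: str
    position: int  # 1-based
    ref: str
    alt: str
    umi_count: int
    coverage: int
    frequency: float


def assemble_consensus(
    group: UmiGroup,
    reference: str,
    min_reads: int = 1,
) -> ConsensusSequence:
    """Plurality consensus of one UMI group against the reference length.

    Positions covered by fewer than ``min_reads`` reads (short reads) are
    emitted as the reference base and counted in
    ``low_coverage_positions``.
    """
    L = len(reference)
    ref_codes = _CODE_LOOKUP[np.frombuffer(reference.encode(), dtype=np.uint8)]
    counts = np.zeros((L, 4), dtype=np.int64)
    qual_sums = np.zeros((L, 4), dtype=np.int64)
    depth = np.zeros(L, dtype=np.int64)
    for seq, qual in group.reads:
        n = min(len(seq), L)
        codes = _CODE_LOOKUP[np.frombuffer(seq[:n].encode(), dtype=np.uint8)]
        quals = np.frombuffer(qual[:n].encode(), dtype=np.uint8).astype(np.int64) - 33
        valid = codes < 4
        idx = np.flatnonzero(valid)
        np.add.at(counts, (idx, codes[idx]), 1)
        np.add.at(qual_sums, (idx, codes[idx]), quals[idx])
        depth[:n] += valid
    # plurality, then summed quality, then reference; encoded as a single
    # sortable score so ties resolve without per-position python logic
    max_qual = max(int(qual_sums.max()), 1)
    score = (
        counts.astype(np.float64) * (max_qual + 2.0)
        + qual_sums
        + 0.5 * (np.arange(4) == ref_codes[:, None])
    )
    best = np.argmax(score, axis=1)
    covered = depth >= max(min_reads, 1)
    consensus_codes = np.where(covered, best, ref_codes)
    with np.errstate(invalid="ignore", divide="ignore"):
        support = counts[np.arange(L), consensus_codes] / np.maximum(depth, 1)
    support[~covered] = 0.0
    n_low = int((~covered).sum())
    seq = _BASE_CODES[consensus_codes].tobytes().decode()
    return ConsensusSequence(group.umi, seq, support, n_low)


def call_errors(
    consensuses: Iterable[ConsensusSequence],
    reference: str,
    sample: str,
) -> pd.DataFrame:
    """Count substitutions of consensus sequences against the reference.

    Returns the variant interchange table (:data:`VARIANT_COLUMNS`): one
    row per observed (position, ref, alt) with the number of consensus
    sequences carrying it (``umi_count``), the number of consensus
    sequences covering the position (``coverage``) and their ratio.  Only
    substitutions are considered; the result is independent of read and
    UMI iteration order.
    """
    L = len(reference)
    ref_arr = np.frombuffer(reference.encode(), dtype=np.uint8)
    counts = np.zeros((L, 4), dtype=np.int64)
    n_cons = 0
    for cons in consensuses:
        if len(cons.sequence) != L:
            raise ValueError(
                f"consensus length {len(cons.sequence)} != reference length {L}"
            )
        n_cons += 1
        arr = np.frombuffer(cons.sequence.encode(), dtype=np.uint8)
        diff = np.flatnonzero(arr != ref_arr)
        np.add.at(counts, (diff, _CODE_LOOKUP[arr[diff]]), 1)
    rows = []
    pos_idx, alt_idx = np.nonzero(counts)
    for p, a in zip(pos_idx, alt_idx):
        umi_count = int(counts[p, a])
        rows.append(
            ErrorCall(
                sample=sample,
                position=int(p) + 1,
                ref=chr(ref_arr[p]),
                alt=chr(_BASE_CODES[a]),
                umi_count=umi_count,
                coverage=n_cons,
                frequency=umi_count / n_cons,
            )
        )
    frame = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return frame.sort_values(["position", "alt"], kind="stable").reset_index(drop=True)
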