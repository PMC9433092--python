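"""Anchor-fixed parsing of reporter reads.

A valid read is left_anchor + target region + PAM window + right_anchor.
Anchors are matched by Hamming distance only (no gaps inside anchors: they
are short and fixed, and indels are expected strictly between them). The
target region is everything strictly between the left anchor and the PAM
window; the PAM window is the ``pam_len`` bases ending where the right
anchor begins, and is accepted only when the short protospacer-suffix
anchor (e.g. CTG) sits immediately 5' of it, matched exactly. Failures are
statuses, never exceptions, and statuses partition the input.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .design import AmpliconDesign, revcomp
from .fastqio import iter_fastq

PARSE_STATUSES = (
    "ok",
    "no_left_anchor",
    "no_right_anchor",
    "no_pam_anchor",
    "region_out_of_bounds",
)

# slack on the target-region length when no explicit bounds are given;
# matches the simulator's default maximum indel size
DEFAULT_LENGTH_SLACK = 12


@dataclass(frozen=True)
class ParserParams:
    max_mismatch: int = 1
    try_revcomp: bool = True
    min_len: Optional[int] = None
    max_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")

    def length_bounds(self, design: AmpliconDesign) -> tuple[int, int]:
        ref = len(design.protospacer)
        lo = self.min_len if self.min_len is not None else ref - DEFAULT_LENGTH_SLACK
        hi = self.max_len if self.max_len is not None else ref + DEFAULT_LENGTH_SLACK
        return max(lo, 0), hi


@dataclass(frozen=True)
class ParsedRead:
    read_id: str
    status: str
    orientation: str = "forward"
    target_region: Optional[str] = None
    pam: Optional[str] = None


def find_anchor(
    read: str, anchor: str, k: int, from_index: int = 0
) -> Optional[int]:
    """Leftmost index >= from_index of a window within Hamming distance k of
    ``anchor``; None when absent."""
    if len(anchor) == 0:
        raise ValueError("anchor must be nonempty")
    if from_index < 0:
        from_index = 0
    if len(read) - from_index < len(anchor):
        return None
    r = np.frombuffer(read.encode("ascii"), dtype=np.uint8)
    a = np.frombuffer(anchor.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(r, len(a))[from_index:]
    mismatches = (windows != a).sum(axis=1)
    hits = np.flatnonzero(mismatches <= k)
    if hits.size == 0:
        return None
    return from_index + int(hits[0])


def _hamming_le(a: str, b: str, k: int) -> bool:
    return sum(x != y for x, y in zip(a, b)) <= k


def _parse_oriented(
    read_id: str, seq: str, design: AmpliconDesign, params: ParserParams, orientation: str
) -> ParsedRead:
    k = params.max_mismatch
    lpos = find_anchor(seq, design.left_anchor, k)
    if lpos is None:
        return ParsedRead(read_id, "no_left_anchor", orientation)
    left_end = lpos + len(design.left_anchor)
    rpos = find_anchor(seq, design.right_anchor, k, from_index=left_end)
    if rpos is None:
        return ParsedRead(read_id, "no_right_anchor", orientation)
    pam_start = rpos - design.pam_len
    pla = design.pam_left_anchor
    anchor_start = pam_start - len(pla)
    if anchor_start < 0 or not seq[anchor_start:pam_start] == pla:
        # the short PAM anchor is matched exactly (k=0): 3 nt tolerates no noise
        return ParsedRead(read_id, "no_pam_anchor", orientation)
    pam = seq[pam_start:rpos]
    prefix = design.pam_fixed_prefix
    if prefix and not _hamming_le(pam[: len(prefix)], prefix, k):
        return ParsedRead(read_id, "no_pam_anchor", orientation)
    target = seq[left_end:pam_start]
    lo, hi = params.length_bounds(design)
    if pam_start < left_end or not lo <= len(target) <= hi:
        return ParsedRead(read_id, "region_out_of_bounds", orientation)
    return ParsedRead(read_id, "ok", orientation, target_region=target, pam=pam)


def parse_read(
    read: str,
    design: AmpliconDesign,
    params: ParserParams = ParserParams(),
    read_id: str = "read",
) -> ParsedRead:
    """Parse one read; falls back to the reverse complement when the forward
    orientation fails and ``try_revcomp`` is set. On double failure the
    forward status is reported."""
    forward = _parse_oriented(read_id, read, design, params, "forward")
    if forward.status == "ok" or not params.try_revcomp:
        return forward
    reverse = _parse_oriented(read_id, revcomp(read), design, params, "revcomp")
    return reverse if reverse.status == "ok" else forward


def parse_stream(
    fastq: str | Path,
    design: AmpliconDesign,
    params: ParserParams = ParserParams(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Parse a FASTQ file into a table of :class:`ParsedRead` rows plus
    status counts. The counts always partition the input read count."""
    rows = []
    stats = Counter({status: 0 for status in PARSE_STATUSES})
    for rec in iter_fastq(fastq):
        parsed = parse_read(rec.seq, design, params, read_id=rec.id)
        stats[parsed.status] += 1
        rows.append(
            {
                "read_id": parsed.read_id,
                "status": parsed.status,
                "orientation": parsed.orientation,
                "target_region": parsed.target_region,
                "pam": parsed.pam,
            }
        )
    table = pd.DataFrame(
        rows, columns=["read_id", "status", "orientation", "target_region", "pam"]
    )
    return table, dict(stats)
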