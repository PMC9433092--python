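"""Edit calling on target regions and indel-efficiency quantification.

Edits are called from optimal global affine-gap alignments (Needleman-
Wunsch/Gotoh, via Bio.Align.PairwiseAligner). A gap of length L scores
``gap_open + (L-1) * gap_extend``. Frame classification follows the GFP
reporter logic: the unedited insert (protospacer + PAM window) shifts GFP
out of frame by ``frame_offset`` nucleotides (mod 3), so a read is in-frame
exactly when it carries gaps and (frame_offset + net_delta) mod 3 == 0.
A net_delta of 0 with gaps (balanced indels) stays frameshift for the
default construct because frame_offset is 2.

Substitution-only differences are never counted as edits: sequencing error
is indistinguishable from substitution editing, and the nuclease produces
indels.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from Bio import Align

from .design import AmpliconDesign, EndogenousAmplicon, revcomp
from .fastqio import FastqRecord

_DNA_RE = re.compile(r"^[ACGT]+$")

EDIT_STATUSES = ("unedited", "inframe", "frameshift", "substitution_only")


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring; defaults are fixed for reproducibility."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -1

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = self.match
        aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        return aligner


@dataclass(frozen=True)
class GlobalAlignment:
    score: float
    cigar: str
    net_delta: int
    n_insertions: int
    n_deletions: int
    n_substitutions: int
    n_matches: int
    n_columns: int
    # (op, ref_start, ref_end, query_start, query_end) per segment
    segments: tuple


@dataclass(frozen=True)
class EditCall:
    status: str
    net_delta: int
    n_insertions: int
    n_deletions: int
    n_substitutions: int
    cigar: str


def _walk_alignment(alignment, ref: str, query: str):
    """Yield (op, ref_start, ref_end, query_start, query_end) segments,
    op in {M, I, D} with I/D relative to the query."""
    coords = alignment.coordinates
    for col in range(coords.shape[1] - 1):
        t0, t1 = int(coords[0, col]), int(coords[0, col + 1])
        q0, q1 = int(coords[1, col]), int(coords[1, col + 1])
        if t1 > t0 and q1 > q0:
            yield ("M", t0, t1, q0, q1)
        elif t1 > t0:
            yield ("D", t0, t1, q0, q0)
        elif q1 > q0:
            yield ("I", t0, t0, q0, q1)


def align_global(
    query: str, reference: str, params: AlignParams = AlignParams()
) -> GlobalAlignment:
    """Optimal global affine-gap alignment of query against reference."""
    for name, seq in (("query", query), ("reference", reference)):
        if not seq:
            raise ValueError(f"{name} must be nonempty")
        if not _DNA_RE.match(seq):
            raise ValueError(f"{name} contains non-ACGT characters")
    aligner = params.make_aligner()
    alignment = aligner.align(reference, query)[0]
    segments = tuple(_walk_alignment(alignment, reference, query))
    cigar_parts = []
    n_ins = n_del = n_sub = n_match = n_cols = 0
    for op, t0, t1, q0, q1 in segments:
        length = max(t1 - t0, q1 - q0)
        n_cols += length
        cigar_parts.append(f"{length}{op}")
        if op == "M":
            mismatches = sum(a != b for a, b in zip(reference[t0:t1], query[q0:q1]))
            n_sub += mismatches
            n_match += length - mismatches
        elif op == "I":
            n_ins += 1
        else:
            n_del += 1
    return GlobalAlignment(
        score=float(alignment.score),
        cigar="".join(cigar_parts),
        net_delta=len(query) - len(reference),
        n_insertions=n_ins,
        n_deletions=n_del,
        n_substitutions=n_sub,
        n_matches=n_match,
        n_columns=n_cols,
        segments=segments,
    )


def classify_edit(
    target_region: str,
    design: AmpliconDesign,
    params: AlignParams = AlignParams(),
) -> EditCall:
    """Classify a parsed target region against the reference protospacer."""
    if not target_region:
        raise ValueError("empty target region")
    ref = design.protospacer
    if target_region == ref:
        return EditCall("unedited", 0, 0, 0, 0, f"{len(ref)}M")
    aln = align_global(target_region, ref, params)
    if aln.n_insertions == 0 and aln.n_deletions == 0:
        status = "substitution_only"
    elif (design.frame_offset + aln.net_delta) % 3 == 0:
        status = "inframe"
    else:
        status = "frameshift"
    return EditCall(
        status,
        aln.net_delta,
        aln.n_insertions,
        aln.n_deletions,
        aln.n_substitutions,
        aln.cigar,
    )


def classify_table(
    parsed: pd.DataFrame,
    design: AmpliconDesign,
    params: AlignParams = AlignParams(),
) -> pd.DataFrame:
    """Classify every status-ok parsed read; returns one row per ok read.

    Distinct target regions are aligned once and the calls broadcast, so
    the cost scales with allele diversity, not read count.
    """
    ok = parsed[parsed["status"] == "ok"]
    calls: dict[str, EditCall] = {
        region: classify_edit(region, design, params)
        for region in ok["target_region"].unique()
    }
    rows = [
        {
            "read_id": read_id,
            "status": calls[region].status,
            "net_delta": calls[region].net_delta,
            "n_insertions": calls[region].n_insertions,
            "n_deletions": calls[region].n_deletions,
            "n_substitutions": calls[region].n_substitutions,
            "cigar": calls[region].cigar,
        }
        for read_id, region in zip(ok["read_id"], ok["target_region"])
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "status",
            "net_delta",
            "n_insertions",
            "n_deletions",
            "n_substitutions",
            "cigar",
        ],
    )


@dataclass(frozen=True)
class IndelEfficiencyResult:
    """``efficiency`` is None (undefined) when no read aligns — distinct
    from a measured 0.0."""

    efficiency: Optional[float]
    n_edited: int
    n_aligned: int
    n_input: int
    allele_table: pd.DataFrame


def _gap_in_window(segments, cut: int, w: int) -> bool:
    lo, hi = cut - w, cut + w
    for op, t0, t1, q0, q1 in segments:
        if op == "D" and t0 <= hi and t1 - 1 >= lo:
            return True
        if op == "I" and lo <= t0 <= hi:
            return True
    return False


def indel_efficiency(
    reads: Iterable[FastqRecord | str],
    amplicon: EndogenousAmplicon,
    params: AlignParams = AlignParams(),
    min_identity: float = 0.75,
) -> IndelEfficiencyResult:
    """Fraction of aligned reads with >= 1 gap event overlapping the
    cut-site window [cut-w, cut+w].

    Reads are oriented by alignment score (forward vs reverse complement)
    and must reach ``min_identity`` (matches / alignment columns) to count
    as aligned. The allele table lists distinct edited alleles with CIGAR,
    net length change, count and frequency among aligned reads.
    """
    ref = amplicon.sequence
    seq_counts: Counter[str] = Counter(
        rec.seq if isinstance(rec, FastqRecord) else rec for rec in reads
    )
    n_input = sum(seq_counts.values())
    aligner = params.make_aligner()
    n_aligned = n_edited = 0
    allele_rows = []
    for seq, count in seq_counts.items():
        if not _DNA_RE.match(seq):
            continue
        rc = revcomp(seq)
        oriented = seq if aligner.score(ref, seq) >= aligner.score(ref, rc) else rc
        aln = align_global(oriented, ref, params)
        if aln.n_columns == 0 or aln.n_matches / aln.n_columns < min_identity:
            continue
        n_aligned += count
        if _gap_in_window(aln.segments, amplicon.cut_index, amplicon.window_halfwidth):
            n_edited += count
            allele_rows.append(
                {
                    "allele": oriented,
                    "cigar": aln.cigar,
                    "net_delta": aln.net_delta,
                    "count": count,
                }
            )
    allele_table = pd.DataFrame(
        allele_rows, columns=["allele", "cigar", "net_delta", "count"]
    )
    if len(allele_table):
        allele_table = allele_table.sort_values(
            ["count", "allele"], ascending=[False, True]
        ).reset_index(drop=True)
        allele_table["frequency"] = allele_table["count"] / n_aligned
    else:
        allele_table["frequency"] = pd.Series(dtype=float)
    efficiency = n_edited / n_aligned if n_aligned > 0 else None
    return IndelEfficiencyResult(efficiency, n_edited, n_aligned, n_input, allele_table)
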