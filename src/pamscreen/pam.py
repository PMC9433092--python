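"""PAM profiles, sequence-logo information content, consensus calls and
PAM wheels.

The PAMs of in-frame-edited reads are tabulated into a position x base
count matrix. Per-position information content follows the sequence-logo
convention for DNA: IC_j = 2 - H_j - e(n), with H_j the Shannon entropy of
the base frequencies in bits and e(n) = 3 / (2 ln2 n) the small-sample
correction for a 4-letter alphabet; letter heights are f[j][b] * IC_j.

A degenerate consensus is called per position: below an information
threshold the position is N; otherwise the IUPAC symbol covering every
base whose frequency reaches the inclusion threshold. The PAM wheel is the
hierarchical (sunburst) view: a prefix-count tree over the PAMs read in a
chosen position order, exported as JSON rather than drawn.

PAM positions in all exports are 1-based from the protospacer-proximal
side.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .iupac import DNA_BASES, symbol_for_bases

_BASE_INDEX = {b: i for i, b in enumerate(DNA_BASES)}


@dataclass(frozen=True)
class PAMProfile:
    """Position x base counts over a set of equal-length PAMs."""

    counts: np.ndarray  # shape (pam_len, 4), base order ACGT
    n: int

    @property
    def pam_len(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        if self.n == 0:
            raise ValueError("frequencies undefined for an empty profile")
        return self.counts / self.n

    def frequency(self, position: int, base: str) -> float:
        """Base frequency at a 1-based PAM position."""
        if not 1 <= position <= self.pam_len:
            raise ValueError(f"position {position} outside 1..{self.pam_len}")
        return float(self.frequencies[position - 1, _BASE_INDEX[base]])


@dataclass(frozen=True)
class ConsensusParams:
    ic_threshold: float = 0.3
    include_threshold: float = 0.15
    apply_correction: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.include_threshold < 1.0:
            raise ValueError("include_threshold must be in (0, 1)")
        if self.ic_threshold < 0.0:
            raise ValueError("ic_threshold must be >= 0")


def collect_pams(
    parsed: pd.DataFrame,
    calls: pd.DataFrame,
    which: str = "inframe_only",
    min_count: int = 1,
) -> list[str]:
    """PAMs of edited reads, joined from the parse and edit-call tables.

    ``inframe_only`` (default) keeps reads whose edit restores the GFP
    frame; ``any_indel`` also keeps frameshift reads. PAM variants observed
    fewer than ``min_count`` times are dropped.
    """
    if which not in ("inframe_only", "any_indel"):
        raise ValueError(f"unknown selection: {which!r}")
    ok = parsed[parsed["status"] == "ok"]
    if set(ok["read_id"]) != set(calls["read_id"]):
        raise ValueError("parse and edit-call tables do not join 1:1 on read_id")
    merged = ok.merge(calls, on="read_id", suffixes=("_parse", "_call"))
    wanted = ("inframe",) if which == "inframe_only" else ("inframe", "frameshift")
    pams = list(merged.loc[merged["status_call"].isin(wanted), "pam"])
    if min_count > 1:
        counts = Counter(pams)
        pams = [p for p in pams if counts[p] >= min_count]
    return pams


def profile(pams: Sequence[str]) -> PAMProfile:
    """Tabulate PAMs into a position x base count matrix."""
    if not pams:
        return PAMProfile(counts=np.zeros((0, 4), dtype=int), n=0)
    pam_len = len(pams[0])
    counts = np.zeros((pam_len, 4), dtype=int)
    for pam in pams:
        if len(pam) != pam_len:
            raise ValueError("PAMs of unequal length")
        for j, base in enumerate(pam):
            counts[j, _BASE_INDEX[base]] += 1
    return PAMProfile(counts=counts, n=len(pams))


def small_sample_correction(n: int) -> float:
    """e(n) = 3 / (2 ln2 n) for a 4-letter alphabet."""
    return 3.0 / (2.0 * math.log(2.0) * n)


def information_content(
    prof: PAMProfile, params: ConsensusParams = ConsensusParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position information content (bits, clamped to [0, 2]) and the
    logo letter heights f[j][b] * IC_j."""
    if prof.n == 0:
        raise ValueError("information content undefined for an empty profile")
    f = prof.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    entropy = -plogp.sum(axis=1)
    e_n = small_sample_correction(prof.n) if params.apply_correction else 0.0
    ic = np.clip(2.0 - entropy - e_n, 0.0, 2.0)
    heights = f * ic[:, None]
    return ic, heights


def call_consensus(
    prof: PAMProfile, params: ConsensusParams = ConsensusParams()
) -> str:
    """Degenerate IUPAC consensus, one symbol per PAM position.

    Positions with IC below ``ic_threshold`` are N; otherwise the symbol
    covers {b : f[j][b] >= include_threshold}, falling back to the single
    most frequent base if no base reaches the threshold.
    """
    if prof.n == 0:
        raise ValueError("consensus undefined for an empty profile")
    ic, _ = information_content(prof, params)
    f = prof.frequencies
    symbols = []
    for j in range(prof.pam_len):
        if ic[j] < params.ic_threshold:
            symbols.append("N")
            continue
        bases = {DNA_BASES[b] for b in range(4) if f[j, b] >= params.include_threshold}
        if not bases:
            bases = {DNA_BASES[int(np.argmax(f[j]))]}
        symbols.append(symbol_for_bases(bases))
    return "".join(symbols)


def trim_trailing_n(consensus: str) -> str:
    """Reporting form of a consensus: trailing N positions carry no
    constraint and are dropped (N4CCNN -> N4CC); an all-N call is kept."""
    trimmed = consensus.rstrip("N")
    return consensus if trimmed == "" else trimmed


def pam_coverage_stats(pams: Sequence[str]) -> tuple[int, Optional[float]]:
    """(number of unique PAM variants, median per-variant observation
    count); median is None for an empty list."""
    if not pams:
        return 0, None
    counts = Counter(pams)
    return len(counts), float(np.median(list(counts.values())))


@dataclass
class PAMWheelNode:
    """Node of the prefix-count tree behind a PAM wheel (sunburst) chart."""

    base: str  # "root" or A/C/G/T
    depth: int
    count: int
    children: list["PAMWheelNode"] = field(default_factory=list)

    def child(self, base: str) -> Optional["PAMWheelNode"]:
        for c in self.children:
            if c.base == base:
                return c
        return None

    def to_dict(self, total: Optional[int] = None) -> dict:
        total = total if total is not None else max(self.count, 1)
        return {
            "base": self.base,
            "depth": self.depth,
            "count": self.count,
            "fraction": self.count / total,
            "children": [c.to_dict(total) for c in self.children],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PAMWheelNode":
        return cls(
            base=d["base"],
            depth=d["depth"],
            count=d["count"],
            children=[cls.from_dict(c) for c in d.get("children", [])],
        )


def build_wheel(
    pams: Sequence[str], position_order: Optional[Sequence[int]] = None
) -> PAMWheelNode:
    """Prefix-count tree over the PAMs read in ``position_order`` (1-based
    permutation of the PAM positions; default protospacer-proximal first).

    The angular fraction of a wheel sector is node.count / root.count.
    """
    pam_len = len(pams[0]) if pams else 0
    if position_order is None:
        position_order = list(range(1, pam_len + 1))
    if sorted(position_order) != list(range(1, pam_len + 1)):
        raise ValueError(
            f"position_order must be a permutation of 1..{pam_len}, "
            f"got {list(position_order)}"
        )
    root = PAMWheelNode(base="root", depth=0, count=0)
    for pam in pams:
        if len(pam) != pam_len:
            raise ValueError("PAMs of unequal length")
        root.count += 1
        node = root
        for depth, pos in enumerate(position_order, start=1):
            base = pam[pos - 1]
            nxt = node.child(base)
            if nxt is None:
                nxt = PAMWheelNode(base=base, depth=depth, count=0)
                node.children.append(nxt)
                node.children.sort(key=lambda c: c.base)
            nxt.count += 1
            node = nxt
    return root


def compare_profiles(foreground: PAMProfile, background: PAMProfile) -> np.ndarray:
    """Per-position, per-base log2 enrichment of foreground over background
    frequencies, each pseudocounted by 0.5/n of its own profile."""
    if foreground.pam_len != background.pam_len:
        raise ValueError("profiles have different PAM lengths")
    eps_fg = 0.5 / foreground.n
    eps_bg = 0.5 / background.n
    return np.log2(
        (foreground.frequencies + eps_fg) / (background.frequencies + eps_bg)
    )


def export_logo_matrix(
    prof: PAMProfile,
    params: ConsensusParams = ConsensusParams(),
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Long-form logo table (position, base, frequency, height_bits);
    heights at a position sum to its information content."""
    if prof.n == 0:
        raise ValueError("cannot export an empty profile")
    _, heights = information_content(prof, params)
    f = prof.frequencies
    rows = [
        {
            "position": j + 1,
            "base": base,
            "frequency": f[j, b],
            "height_bits": heights[j, b],
        }
        for j in range(prof.pam_len)
        for b, base in enumerate(DNA_BASES)
    ]
    table = pd.DataFrame(rows)
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return table


def export_wheel(root: PAMWheelNode, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(root.to_dict(), fh, indent=1)


def load_wheel(path: str | Path) -> PAMWheelNode:
    with open(path) as fh:
        return PAMWheelNode.from_dict(json.load(fh))
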