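"""Synthetic reads for the PAM screen and endogenous-amplicon editing.

The screen generator emulates the sorted-cell GFP-activation assay: each
cell/read carries the fixed reporter construct with a uniformly randomized
PAM window; editing happens with a PAM-dependent probability; an edited
molecule carries a single indel near the blunt cut site; GFP sorting keeps
exactly the reads whose net indel length restores the GFP reading frame
((frame_offset + delta) mod 3 == 0 with delta != 0), plus an optional
impurity fraction. Per-base substitution sequencing error is applied last,
so all downstream tolerance to noise is exercised.

Every output is a pure function of the inputs and the seed in
:class:`SimConfig`; equal seeds give byte-identical FASTQ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .design import AmpliconDesign, EndogenousAmplicon
from .fastqio import FastqRecord
from .iupac import DNA_BASES, IUPAC_CODES, pam_matches

TRUTH_COLUMNS = ["read_id", "pam", "edited", "net_delta", "frame_restored"]


@dataclass(frozen=True)
class PAMActivityModel:
    """Editing probability as a function of the PAM.

    ``consensus`` kind: probability ``p_match`` when the PAM matches the
    degenerate consensus, ``p_mismatch`` otherwise. ``positional`` kind:
    the product over positions of a per-position, per-base weight matrix
    (shape pam_len x 4, base order ACGT).
    """

    kind: str = "consensus"
    consensus: Optional[str] = None
    p_match: float = 0.8
    p_mismatch: float = 0.01
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in ("consensus", "positional"):
            raise ValueError(f"unknown activity model kind: {self.kind!r}")
        for p in (self.p_match, self.p_mismatch):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.kind == "consensus":
            if not self.consensus:
                raise ValueError("consensus kind requires a consensus string")
            if any(sym not in IUPAC_CODES for sym in self.consensus):
                raise ValueError(f"invalid IUPAC consensus: {self.consensus!r}")
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.ndim != 2 or w.shape[1] != 4:
                raise ValueError("weights must have shape (pam_len, 4)")
            if (w < 0).any() or (w > 1).any():
                raise ValueError("weights must lie in [0, 1]")
            object.__setattr__(self, "weights", w)

    def validate_for(self, design: AmpliconDesign) -> None:
        if self.kind == "consensus" and len(self.consensus) != design.pam_len:
            raise ValueError(
                f"consensus length {len(self.consensus)} != pam_len {design.pam_len}"
            )
        if self.kind == "positional" and self.weights.shape[0] != design.pam_len:
            raise ValueError("weights row count != pam_len")

    def editing_probability(self, pam: str) -> float:
        if self.kind == "consensus":
            return self.p_match if pam_matches(self.consensus, pam) else self.p_mismatch
        idx = [DNA_BASES.index(b) for b in pam]
        return float(np.prod(self.weights[np.arange(len(pam)), idx]))


@dataclass(frozen=True)
class IndelModel:
    """Single-indel outcome model for an edited molecule.

    Lengths are geometric (support 1..max_indel, clamped at max_indel); the
    indel start is jittered uniformly within ``position_jitter`` of the cut
    site. With ``allow_anchor_damage`` False, deletions are clipped at the
    randomized PAM start so the flanking anchors stay parseable.
    """

    p_insertion: float = 0.3
    del_len_geom_p: float = 0.3
    ins_len_geom_p: float = 0.7
    max_indel: int = 12
    position_jitter: int = 2
    allow_anchor_damage: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_insertion <= 1.0:
            raise ValueError("p_insertion must be in [0, 1]")
        for p in (self.del_len_geom_p, self.ins_len_geom_p):
            if not 0.0 < p <= 1.0:
                raise ValueError("geometric parameters must be in (0, 1]")
        if self.max_indel < 1:
            raise ValueError("max_indel must be >= 1")
        if self.position_jitter < 0:
            raise ValueError("position_jitter must be >= 0")


@dataclass(frozen=True)
class ErrorModel:
    sub_rate: float = 0.001
    quality_char: str = "I"

    def __post_init__(self) -> None:
        if not 0.0 <= self.sub_rate <= 1.0:
            raise ValueError("sub_rate must be in [0, 1]")
        if len(self.quality_char) != 1 or not (33 <= ord(self.quality_char) <= 126):
            raise ValueError("quality_char must be a single printable Phred+33 symbol")


@dataclass(frozen=True)
class SimConfig:
    n_reads: int = 10_000
    seed: int = 0
    sort_mode: str = "unsorted"
    sort_impurity: float = 0.0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.sort_mode not in ("gfp_sorted", "unsorted"):
            raise ValueError(f"unknown sort_mode: {self.sort_mode!r}")
        if not 0.0 <= self.sort_impurity <= 1.0:
            raise ValueError("sort_impurity must be in [0, 1]")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(DNA_BASES[i] for i in rng.integers(0, 4, size=length))


def _apply_errors(rng: np.random.Generator, seq: str, sub_rate: float) -> str:
    if sub_rate <= 0.0:
        return seq
    mask = rng.random(len(seq)) < sub_rate
    if not mask.any():
        return seq
    chars = list(seq)
    for i in np.flatnonzero(mask):
        # substitute with one of the three other bases, uniformly
        current = DNA_BASES.index(chars[i])
        chars[i] = DNA_BASES[(current + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(chars)


def _apply_screen_indel(
    rng: np.random.Generator,
    design: AmpliconDesign,
    pam: str,
    indels: IndelModel,
) -> tuple[str, int]:
    """Apply one indel near the cut site; returns (edited core, net delta).

    The core is protospacer+PAM; insertions land inside the protospacer,
    deletions may run 3' at most up to the randomized PAM start (or through
    the PAM window when anchor damage is allowed).
    """
    proto = design.protospacer
    cut = design.cut_index
    jitter = int(rng.integers(-indels.position_jitter, indels.position_jitter + 1))
    if rng.random() < indels.p_insertion:
        length = min(int(rng.geometric(indels.ins_len_geom_p)), indels.max_indel)
        pos = int(np.clip(cut + jitter, 0, len(proto)))
        insert = random_dna(rng, length)
        return proto[:pos] + insert + proto[pos:] + pam, length
    length = min(int(rng.geometric(indels.del_len_geom_p)), indels.max_indel)
    start = int(np.clip(cut + jitter, 0, len(proto) - 1))
    combined = proto + pam
    if indels.allow_anchor_damage:
        max_end = len(combined)
    else:
        max_end = len(proto) + len(design.pam_fixed_prefix)
    end = min(start + length, max_end)
    return combined[:start] + combined[end:], -(end - start)


def simulate_screen(
    design: AmpliconDesign,
    activity: PAMActivityModel,
    indels: IndelModel,
    errors: ErrorModel,
    cfg: SimConfig,
) -> tuple[list[FastqRecord], pd.DataFrame]:
    """Simulate the randomized-PAM reporter screen.

    Returns the emitted reads and a truth table (emitted reads only) with
    the planted PAM, edit state, net length change and frame restoration.
    """
    activity.validate_for(design)
    rng = np.random.default_rng(cfg.seed)
    records: list[FastqRecord] = []
    truth_rows = []
    for i in range(cfg.n_reads):
        pam = design.pam_fixed_prefix + random_dna(rng, design.n_random)
        edited = rng.random() < activity.editing_probability(pam)
        if edited:
            core, delta = _apply_screen_indel(rng, design, pam, indels)
        else:
            core, delta = design.protospacer + pam, 0
        frame_restored = delta != 0 and (design.frame_offset + delta) % 3 == 0
        seq = _apply_errors(
            rng, design.left_anchor + core + design.right_anchor, errors.sub_rate
        )
        if cfg.sort_mode == "gfp_sorted" and not frame_restored:
            if cfg.sort_impurity == 0.0 or rng.random() >= cfg.sort_impurity:
                continue
        records.append(
            FastqRecord(
                id=f"sim_{i:06d}", seq=seq, qual=errors.quality_char * len(seq)
            )
        )
        truth_rows.append((f"sim_{i:06d}", pam, edited, delta, frame_restored))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return records, truth


def simulate_endogenous(
    amplicon: EndogenousAmplicon,
    true_efficiency: float,
    indels: IndelModel,
    errors: ErrorModel,
    cfg: SimConfig,
) -> tuple[list[FastqRecord], pd.DataFrame]:
    """Simulate amplicon reads from a genomic target edited at a known rate."""
    if not 0.0 <= true_efficiency <= 1.0:
        raise ValueError("true_efficiency must be in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    ref = amplicon.sequence
    cut = amplicon.cut_index
    records: list[FastqRecord] = []
    truth_rows = []
    for i in range(cfg.n_reads):
        edited = rng.random() < true_efficiency
        delta = 0
        seq = ref
        if edited:
            jitter = int(
                rng.integers(-indels.position_jitter, indels.position_jitter + 1)
            )
            if rng.random() < indels.p_insertion:
                length = min(
                    int(rng.geometric(indels.ins_len_geom_p)), indels.max_indel
                )
                pos = int(np.clip(cut + jitter, 1, len(ref) - 1))
                seq = ref[:pos] + random_dna(rng, length) + ref[pos:]
                delta = length
            else:
                length = min(
                    int(rng.geometric(indels.del_len_geom_p)), indels.max_indel
                )
                start = int(np.clip(cut + jitter, 1, len(ref) - 2))
                end = min(start + length, len(ref) - 1)
                seq = ref[:start] + ref[end:]
                delta = -(end - start)
        seq = _apply_errors(rng, seq, errors.sub_rate)
        records.append(
            FastqRecord(
                id=f"amp_{i:06d}", seq=seq, qual=errors.quality_char * len(seq)
            )
        )
        truth_rows.append((f"amp_{i:06d}", "", edited, delta, False))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return records, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
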