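"""Amplicon layouts for the PAM screen and endogenous targets.

The reporter construct of the GFP-activation screen is

    [left anchor] [24-nt protospacer] [pam_len randomized bases] [right anchor]

inserted between an ATG start codon and the GFP coding sequence so that the
unedited insert puts GFP out of frame. ``AmpliconDesign`` records the fixed
sequences and the geometry that read parsing, edit classification and
simulation all share. ``EndogenousAmplicon`` describes a genomic target
amplified for indel-efficiency quantification.

All internal coordinates are 0-based half-open; PAM positions exposed to
users are 1-based from the protospacer-proximal side.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from pathlib import Path

import yaml

_DNA_RE = re.compile(r"^[ACGT]+$")

DEFAULT_LEFT_ANCHOR = "AAGCCTTGTTTGCCACCATG"
DEFAULT_PROTOSPACER = "GAGAGTAGAGGCGGCCACGACCTG"
DEFAULT_RIGHT_ANCHOR = "GTGAGCAAGGGCGAGGAGCT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(value: str, field: str, allow_empty: bool = False) -> None:
    if value == "" and allow_empty:
        return
    if not _DNA_RE.match(value):
        raise ValueError(f"{field} must be uppercase A/C/G/T, got {value!r}")


@dataclass(frozen=True)
class AmpliconDesign:
    """Layout of the randomized-PAM reporter amplicon.

    Parameters
    ----------
    left_anchor, right_anchor:
        Fixed 20-bp flanks used to locate the variable region in a read.
    protospacer:
        The 24-nt target sequence; its edit state decides GFP frame.
    pam_len:
        Width of the PAM window 3' of the protospacer (8 by default; 11 for
        shifted libraries that extend the readable PAM).
    pam_left_anchor:
        Suffix of the protospacer required immediately 5' of the PAM window
        when extracting PAMs (default "CTG").
    pam_fixed_prefix:
        Construct-fixed bases occupying the PAM-proximal positions of an
        extended window (empty for the standard 8-bp design).
    cut_offset:
        Blunt-cut position counted from the protospacer 3' end toward 5'
        (3 => cut site between positions -4 and -3 of the protospacer).
    """

    left_anchor: str = DEFAULT_LEFT_ANCHOR
    protospacer: str = DEFAULT_PROTOSPACER
    pam_len: int = 8
    pam_left_anchor: str = "CTG"
    right_anchor: str = DEFAULT_RIGHT_ANCHOR
    pam_fixed_prefix: str = ""
    cut_offset: int = 3

    def __post_init__(self) -> None:
        for field in ("left_anchor", "protospacer", "pam_left_anchor", "right_anchor"):
            _check_dna(getattr(self, field), field)
        _check_dna(self.pam_fixed_prefix, "pam_fixed_prefix", allow_empty=True)
        if self.pam_len < 1:
            raise ValueError("pam_len must be >= 1")
        if not self.protospacer.endswith(self.pam_left_anchor):
            raise ValueError("pam_left_anchor must be a suffix of the protospacer")
        if self.pam_len - len(self.pam_fixed_prefix) < 1:
            raise ValueError("at least one PAM position must be randomized")
        if not 0 <= self.cut_offset <= len(self.protospacer):
            raise ValueError("cut_offset outside the protospacer")

    @property
    def frame_offset(self) -> int:
        """(len(protospacer) + pam_len) mod 3; 0 would leave GFP in frame."""
        return (len(self.protospacer) + self.pam_len) % 3

    @property
    def cut_index(self) -> int:
        """0-based cut position within the protospacer/target region."""
        return len(self.protospacer) - self.cut_offset

    @property
    def n_random(self) -> int:
        """Number of randomized PAM positions."""
        return self.pam_len - len(self.pam_fixed_prefix)

    def reference_read(self, pam: str) -> str:
        """The unedited read sequence carrying the given PAM window."""
        if len(pam) != self.pam_len:
            raise ValueError(f"PAM must have length {self.pam_len}")
        _check_dna(pam, "pam")
        return self.left_anchor + self.protospacer + pam + self.right_anchor

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frame_offset"] = self.frame_offset
        return d


_DESIGN_FIELDS = {f.name for f in dataclasses.fields(AmpliconDesign)}


def load_design(config_path: str | Path) -> AmpliconDesign:
    """Load an :class:`AmpliconDesign` from a YAML key-value config.

    Missing keys fall back to the defaults. ``frame_offset`` in the file is
    checked against the recomputed value, never trusted.
    """
    raw = _load_yaml_mapping(config_path)
    declared_frame = raw.pop("frame_offset", None)
    unknown = set(raw) - _DESIGN_FIELDS
    if unknown:
        raise ValueError(f"unknown design fields: {sorted(unknown)}")
    design = AmpliconDesign(**raw)
    if declared_frame is not None and int(declared_frame) != design.frame_offset:
        raise ValueError(
            f"frame_offset {declared_frame} inconsistent with "
            f"(|protospacer|+pam_len) mod 3 = {design.frame_offset}"
        )
    return design


def write_design(design: AmpliconDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design.to_dict(), fh, sort_keys=True)


@dataclass(frozen=True)
class EndogenousAmplicon:
    """A genomic amplicon with an expected blunt-cut site.

    ``window_halfwidth`` (w) defines the cut-site window [cut-w, cut+w] used
    for indel counting; gap events entirely outside it are ignored.
    """

    name: str
    sequence: str
    cut_index: int
    window_halfwidth: int = 5

    def __post_init__(self) -> None:
        _check_dna(self.sequence, "sequence")
        if not 0 <= self.cut_index < len(self.sequence):
            raise ValueError("cut_index outside the amplicon")
        if self.window_halfwidth < 0:
            raise ValueError("window_halfwidth must be >= 0")
        if (
            self.cut_index - self.window_halfwidth < 0
            or self.cut_index + self.window_halfwidth >= len(self.sequence)
        ):
            raise ValueError("cut-site window extends outside the amplicon")


def load_amplicon(config_path: str | Path) -> EndogenousAmplicon:
    raw = _load_yaml_mapping(config_path)
    allowed = {f.name for f in dataclasses.fields(EndogenousAmplicon)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown amplicon fields: {sorted(unknown)}")
    return EndogenousAmplicon(**raw)


def _load_yaml_mapping(path: str | Path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a key-value mapping")
    return raw
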