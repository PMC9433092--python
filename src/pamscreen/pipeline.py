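"""End-to-end workflows: simulate, PAM screen analysis, indel
quantification.

``run_screen`` chains parsing -> edit calling -> PAM collection ->
profile/logo/consensus/wheel and writes its exports plus a JSON run report
whose counts reconcile exactly with the stage outputs (parse statuses
partition the input; edit statuses partition the ok parses; the PAM count
equals the selected edit class). ``run_indel`` quantifies editing at an
endogenous amplicon. All randomness enters through the simulation seed
only; reports are reproducible apart from the isolated timestamp field.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .design import AmpliconDesign, EndogenousAmplicon
from .editing import AlignParams, classify_table, indel_efficiency
from .fastqio import read_fastq, write_fastq
from .pam import (
    ConsensusParams,
    build_wheel,
    call_consensus,
    collect_pams,
    export_logo_matrix,
    export_wheel,
    pam_coverage_stats,
    profile,
    trim_trailing_n,
)
from .parsing import ParserParams, parse_stream
from .simulate import (
    ErrorModel,
    IndelModel,
    PAMActivityModel,
    SimConfig,
    simulate_endogenous,
    simulate_screen,
    write_truth,
)


@dataclass
class RunReport:
    command: str
    input_read_count: int = 0
    parse_stats: dict = field(default_factory=dict)
    edit_status_counts: dict = field(default_factory=dict)
    n_pams: int = 0
    consensus: Optional[str] = None
    consensus_full: Optional[str] = None
    coverage: dict = field(default_factory=dict)
    efficiency: Optional[float] = None
    n_edited: Optional[int] = None
    n_aligned: Optional[int] = None
    outputs: dict = field(default_factory=dict)
    seed: Optional[int] = None
    parameters: dict = field(default_factory=dict)
    timestamp: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")


def run_screen(
    fastq: str | Path,
    design: AmpliconDesign,
    outdir: str | Path,
    parser_params: ParserParams = ParserParams(),
    align_params: AlignParams = AlignParams(),
    consensus_params: ConsensusParams = ConsensusParams(),
    which: str = "inframe_only",
    min_count: int = 1,
) -> RunReport:
    """Analyze a (typically GFP-sorted) reporter FASTQ into PAM calls."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        command="screen",
        parameters={
            "parser": dataclasses.asdict(parser_params),
            "align": dataclasses.asdict(align_params),
            "consensus": dataclasses.asdict(consensus_params),
            "which": which,
            "min_count": min_count,
        },
        timestamp=_now(),
    )
    parsed, stats = parse_stream(fastq, design, parser_params)
    report.input_read_count = len(parsed)
    report.parse_stats = stats
    calls = classify_table(parsed, design, align_params)
    report.edit_status_counts = calls["status"].value_counts().to_dict()
    pams = collect_pams(parsed, calls, which=which, min_count=min_count)
    report.n_pams = len(pams)
    n_unique, median_cov = pam_coverage_stats(pams)
    report.coverage = {"n_unique": n_unique, "median_coverage": median_cov}
    pam_path = outdir / "pams.txt"
    pam_path.write_text("".join(p + "\n" for p in pams))
    report.outputs["pams"] = str(pam_path)
    if pams:
        prof = profile(pams)
        full = call_consensus(prof, consensus_params)
        report.consensus_full = full
        report.consensus = trim_trailing_n(full)
        logo_path = outdir / "logo.tsv"
        export_logo_matrix(prof, consensus_params, logo_path)
        report.outputs["logo"] = str(logo_path)
        wheel_path = outdir / "wheel.json"
        export_wheel(build_wheel(pams), wheel_path)
        report.outputs["wheel"] = str(wheel_path)
    report_path = outdir / "report.json"
    report.write(report_path)
    report.outputs["report"] = str(report_path)
    return report


def run_indel(
    fastq: str | Path,
    amplicon: EndogenousAmplicon,
    outdir: str | Path,
    align_params: AlignParams = AlignParams(),
    min_identity: float = 0.75,
) -> RunReport:
    """Quantify indel efficiency at an endogenous amplicon.

    ``report.efficiency`` is None when no read aligns (undefined, distinct
    from 0.0); callers treating this as fatal should check ``n_aligned``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = indel_efficiency(
        read_fastq(fastq), amplicon, align_params, min_identity=min_identity
    )
    report = RunReport(
        command="indel",
        input_read_count=result.n_input,
        efficiency=result.efficiency,
        n_edited=result.n_edited,
        n_aligned=result.n_aligned,
        parameters={
            "align": dataclasses.asdict(align_params),
            "min_identity": min_identity,
            "amplicon": amplicon.name,
            "cut_index": amplicon.cut_index,
            "window_halfwidth": amplicon.window_halfwidth,
        },
        timestamp=_now(),
    )
    allele_path = outdir / "alleles.tsv"
    result.allele_table.to_csv(allele_path, sep="\t", index=False)
    report.outputs["alleles"] = str(allele_path)
    report_path = outdir / "report.json"
    report.write(report_path)
    report.outputs["report"] = str(report_path)
    return report


def run_simulate(
    design: AmpliconDesign,
    outdir: str | Path,
    activity: Optional[PAMActivityModel] = None,
    indels: IndelModel = IndelModel(),
    errors: ErrorModel = ErrorModel(),
    cfg: SimConfig = SimConfig(),
    amplicon: Optional[EndogenousAmplicon] = None,
    true_efficiency: Optional[float] = None,
) -> RunReport:
    """Write simulated reads plus their truth table.

    With an ``activity`` model this simulates the reporter screen; with an
    ``amplicon`` and ``true_efficiency`` it simulates endogenous editing.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if (activity is None) == (amplicon is None):
        raise ValueError("provide exactly one of activity or amplicon")
    if activity is not None:
        records, truth = simulate_screen(design, activity, indels, errors, cfg)
    else:
        if true_efficiency is None:
            raise ValueError("endogenous simulation requires true_efficiency")
        records, truth = simulate_endogenous(
            amplicon, true_efficiency, indels, errors, cfg
        )
    fastq_path = outdir / "reads.fastq"
    truth_path = outdir / "truth.tsv"
    write_fastq(records, fastq_path)
    write_truth(truth, truth_path)
    report = RunReport(
        command="simulate",
        input_read_count=len(records),
        seed=cfg.seed,
        parameters={
            "n_reads": cfg.n_reads,
            "sort_mode": cfg.sort_mode,
            "sort_impurity": cfg.sort_impurity,
        },
        outputs={"fastq": str(fastq_path), "truth": str(truth_path)},
        timestamp=_now(),
    )
    report_path = outdir / "report.json"
    report.write(report_path)
    report.outputs["report"] = str(report_path)
    return report
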