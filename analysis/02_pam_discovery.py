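#!/usr/bin/env python
"""Run the PAM-discovery pipeline on the simulated sorted libraries.

For each library from 01_simulate_screens.py: parse the reads against the
reporter design, keep in-frame edits, and derive the PAM profile, sequence
logo, PAM wheel, coverage statistics and degenerate consensus call. Exports
land in results/pam/<library>/; the recovered consensus is compared to the
planted ground truth.
"""

import sys
from pathlib import Path

from pamscreen import AmpliconDesign, profile, run_screen

LIBRARIES = {
    "dinucleotide_n4cc": "NNNNCC",
    "single_base_n4c": "NNNNC",
}


def main() -> None:
    simdir = Path("scratch/sim")
    if not simdir.exists():
        sys.exit("no simulated libraries found; run analysis/01_simulate_screens.py first")
    design = AmpliconDesign()
    for name, expected in LIBRARIES.items():
        outdir = Path("results/pam") / name
        report = run_screen(simdir / f"{name}.fastq", design, outdir)
        pams = (outdir / "pams.txt").read_text().splitlines()
        prof = profile(pams)
        verdict = "recovered" if report.consensus == expected else "MISSED"
        print(f"{name}:")
        print(f"  reads={report.input_read_count} ok-parsed={report.parse_stats['ok']}")
        print(
            f"  in-frame PAMs={report.n_pams} "
            f"unique={report.coverage['n_unique']} "
            f"median coverage={report.coverage['median_coverage']}"
        )
        print(
            f"  consensus={report.consensus} (expected {expected}: {verdict}); "
            f"f[5][C]={prof.frequency(5, 'C'):.3f}"
        )
        print(f"  exports in {outdir}/")


if __name__ == "__main__":
    main()
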