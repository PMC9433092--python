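"""Packaged metadata for the 29 type II-C Cas9 orthologs under study.

The table carries, for each ortholog, its UniProt accession, host organism,
working name (e.g. Nsp2Cas9), protein length in residues and percent amino
acid identity to the Nme1Cas9 reference. Identity values are metadata only;
the package never recomputes them.

``verify_lengths`` cross-checks the tabulated lengths against a
user-supplied protein FASTA (e.g. fetched from UniProt); sequences that are
not present are flagged ``absent`` rather than failed, so the check degrades
gracefully offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO

EXPECTED_RECORD_COUNT = 29


@dataclass(frozen=True)
class OrthologRecord:
    accession: str
    host: str
    name: str
    length_aa: int
    identity_pct: float

    def __post_init__(self) -> None:
        if self.length_aa <= 0:
            raise ValueError("length_aa must be positive")
        if not 0 <= self.identity_pct <= 100:
            raise ValueError("identity_pct must be a percentage")


class OrthologTable:
    """Lookup-friendly wrapper around the packaged ortholog table."""

    def __init__(self, records: list[OrthologRecord]):
        self.records = list(records)
        self._by_accession = {r.accession: r for r in self.records}
        self._by_name = {r.name: r for r in self.records}
        if len(self._by_accession) != len(self.records):
            raise ValueError("duplicated accession in ortholog table")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_accession(self, accession: str) -> OrthologRecord:
        try:
            return self._by_accession[accession]
        except KeyError:
            raise KeyError(f"unknown accession: {accession}") from None

    def by_name(self, name: str) -> OrthologRecord:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown Cas9 name: {name}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def load_ortholog_table(path: str | Path | None = None) -> OrthologTable:
    """Load the ortholog table (packaged TSV unless ``path`` is given)."""
    if path is None:
        source = resources.files("pamscreen").joinpath("data/nme1_orthologs.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"accession", "host", "name", "length_aa", "identity_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ortholog table missing columns: {sorted(missing)}")
    if df["accession"].isna().any():
        raise ValueError("ortholog table has a missing accession")
    records = [
        OrthologRecord(
            accession=row.accession,
            host=row.host,
            name=row.name,
            length_aa=int(row.length_aa),
            identity_pct=float(row.identity_pct),
        )
        for row in df.itertuples()
    ]
    table = OrthologTable(records)
    if path is None and len(table) != EXPECTED_RECORD_COUNT:
        raise ValueError(
            f"packaged table has {len(table)} records, expected {EXPECTED_RECORD_COUNT}"
        )
    return table


def _fasta_lengths(fasta: str | Path) -> dict[str, int]:
    """Map accessions to residue counts; UniProt-style ``db|ACC|name`` ids
    are resolved to the bare accession."""
    lengths: dict[str, int] = {}
    with open(fasta) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            keys = {rec.id}
            if "|" in rec.id:
                keys.update(part for part in rec.id.split("|") if part)
            for key in keys:
                lengths[key] = len(rec.seq)
    return lengths


def verify_lengths(records, fasta: str | Path) -> pd.DataFrame:
    """Compare tabulated protein lengths to sequences in a FASTA file.

    Returns a frame with columns ``accession``, ``expected_length``,
    ``observed_length`` and ``match`` ('match', 'mismatch' or 'absent').
    """
    fasta = Path(fasta)
    if not fasta.exists():
        raise FileNotFoundError(fasta)
    observed = _fasta_lengths(fasta)
    rows = []
    for rec in records:
        obs = observed.get(rec.accession)
        if obs is None:
            status = "absent"
        elif obs == rec.length_aa:
            status = "match"
        else:
            status = "mismatch"
        rows.append(
            {
                "accession": rec.accession,
                "expected_length": rec.length_aa,
                "observed_length": obs if obs is not None else pd.NA,
                "match": status,
            }
        )
    return pd.DataFrame(rows)
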