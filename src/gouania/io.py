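"""Readers, writers and packaged fixtures.

FASTA goes through Biopython. Species metadata for sequences can either be
embedded in the record ID as ``accession|species`` or supplied as a separate
two-column mapping file (GenBank description lines for older accessions
predate the current species names, so a sidecar map is the robust route).
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .barcoding import VALID_ALPHABET, Alignment, DistanceMatrix, SequenceRecord
from .key_engine import KeyDefinition, load_key
from .morphometrics import CHARACTERS, SL_ROW, SpeciesRangeTable, SpecimenMeasurements

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_species_map",
    "read_measurements",
    "write_measurements",
    "write_distance_matrix",
    "load_table1_fixture",
    "load_default_key",
    "FixtureError",
]

#: SHA-256 of the packaged range-table fixture; guards against silent edits.
_TABLE1_SHA256 = "e3d44b102de92fcbae62fa3bd71452cbde82d2a91dace0d76be8728d17e69d9f"


class FixtureError(RuntimeError):
    """A packaged fixture failed its integrity check."""


def read_fasta(path: str | Path) -> Alignment:
    """Read aligned (or equal-length) barcodes from FASTA.

    IDs of the form ``accession|species`` carry their species label inline.
    Validates non-emptiness, ID uniqueness and the {A,C,G,T,N,-} alphabet;
    the equal-length requirement is enforced by the Alignment container.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        illegal = set(seq) - VALID_ALPHABET
        if illegal:
            raise ValueError(
                f"{path}: record {rec.id!r} contains illegal characters {sorted(illegal)}"
            )
        # species labels may contain spaces ("G. pigra"), so parse the full
        # header line rather than the whitespace-delimited id
        header = rec.description or rec.id
        if "|" in header:
            accession, species = header.split("|", 1)
            records.append(SequenceRecord(accession.strip(), seq, species.strip()))
        else:
            records.append(SequenceRecord(rec.id, seq, None))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return Alignment(records)


def write_fasta(alignment: Alignment, path: str | Path,
                embed_species: bool = False) -> None:
    bio = [
        BioSeqRecord(
            Seq(r.sequence),
            id=f"{r.id}|{r.species}" if embed_species and r.species else r.id,
            description="",
        )
        for r in alignment.records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_species_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: record ID -> species."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "species"], dtype=str)
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{path}: duplicate IDs in species map: {dupes}")
    return dict(zip(df["id"], df["species"]))


def read_measurements(path: str | Path) -> list[SpecimenMeasurements]:
    """Specimen measurement table: TSV with columns specimen_id,
    species_label, sl_mm, then character columns in mm (blank = missing)."""
    df = pd.read_csv(path, sep="\t")
    required = {"specimen_id", "sl_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    unknown = set(df.columns) - required - {"species_label"} - set(CHARACTERS)
    if unknown:
        raise ValueError(f"{path}: unknown character columns {sorted(unknown)}")
    out = []
    for _, row in df.iterrows():
        measurements = {
            c: float(row[c])
            for c in CHARACTERS
            if c in df.columns and pd.notna(row[c])
        }
        species = row.get("species_label")
        out.append(
            SpecimenMeasurements(
                specimen_id=str(row["specimen_id"]),
                sl_mm=float(row["sl_mm"]),
                species_label=None if pd.isna(species) else str(species),
                measurements=measurements,
            )
        )
    return out


def write_measurements(specimens: list[SpecimenMeasurements], path: str | Path) -> None:
    chars = [c for c in CHARACTERS if any(c in s.measurements for s in specimens)]
    rows = []
    for s in specimens:
        row = {"specimen_id": s.specimen_id, "species_label": s.species_label,
               "sl_mm": s.sl_mm}
        row.update({c: s.measurements.get(c) for c in chars})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_distance_matrix(matrix: DistanceMatrix, path: str | Path,
                          percent: bool = False) -> None:
    """Square TSV; values in substitutions/site, or x100 when percent=True."""
    df = matrix.to_frame()
    if percent:
        df = df * 100.0
        df.index.name = "percent"
    else:
        df.index.name = "subst_per_site"
    df.to_csv(path, sep="\t")


def _fixture_text(name: str) -> str:
    return resources.files("gouania.data").joinpath(name).read_text()


def load_table1_fixture(verify: bool = True) -> SpeciesRangeTable:
    """The packaged species range table (5 species x 25 %SL characters + SL).

    verify=True checks the fixture file against its recorded SHA-256 so a
    corrupted or edited copy fails loudly rather than skewing diagnoses.
    """
    text = _fixture_text("table1_ranges.tsv")
    if verify:
        digest = hashlib.sha256(text.encode()).hexdigest()
        if digest != _TABLE1_SHA256:
            raise FixtureError(
                f"range-table fixture checksum mismatch: {digest} != {_TABLE1_SHA256}"
            )
    rows: dict[str, dict[str, tuple[float, float, float]]] = {}
    sl_rows: dict[str, tuple[float, float, float]] = {}
    for line in text.splitlines()[1:]:
        species, character, holo, lo, hi = line.split("\t")
        triple = (float(holo), float(lo), float(hi))
        if character == SL_ROW:
            sl_rows[species] = triple
        else:
            rows.setdefault(species, {})[character] = triple
    return SpeciesRangeTable(rows, sl_rows)


def load_default_key() -> KeyDefinition:
    """The packaged identification key for the five species."""
    with resources.as_file(
        resources.files("gouania.data").joinpath("key_gouania.yaml")
    ) as p:
        return load_key(p)


def load_species_profiles() -> dict:
    """Categorical key-character states and vertebral ranges per species."""
    return yaml.safe_load(_fixture_text("species_profiles.yaml"))
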