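"""Reading, cleaning and writing DNA-barcode datasets.

Barcode reference libraries are distributed as FASTA files whose headers carry
a record accession and the specimen's species name in the BOLD export style
``ACCESSION-Genus species``.  This module parses those headers, normalises
sequences to the uppercase A/C/G/T alphabet, applies the standard cleaning
rules (drop records with ambiguous sites, drop records shorter than the
barcode's standard length, optionally truncate to a common length) and writes
assignment tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FastaParseError, HeaderError

ALPHABET = frozenset("ACGT")

# status codes for assignment tables
STATUS_CORRECT = "correct"
STATUS_WRONG = "wrong"
STATUS_EXCLUDED = "excluded_singleton"
STATUS_UNLABELED = "unlabeled"


@dataclass(frozen=True)
class BarcodeRecord:
    """One barcode sequence with its accession and (optional) species label.

    ``species`` is ``None`` for records whose header carries no label; such
    records can be classified but not used for training or evaluation.
    """

    accession: str
    species: str | None
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_labeled(self) -> bool:
        return self.species is not None


@dataclass
class Dataset:
    """An ordered collection of barcode records.

    ``species_table`` maps each species name to the indices of its records,
    in record order; unlabeled records appear in no bucket.
    """

    records: list[BarcodeRecord] = field(default_factory=list)

    @property
    def species_table(self) -> dict[str, list[int]]:
        table: dict[str, list[int]] = {}
        for i, rec in enumerate(self.records):
            if rec.species is not None:
                table.setdefault(rec.species, []).append(i)
        return table

    @property
    def species(self) -> list[str]:
        return list(self.species_table)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, indices: Iterable[int]) -> "Dataset":
        return Dataset([self.records[i] for i in indices])


def parse_header(header: str) -> tuple[str, str]:
    """Split a BOLD-style FASTA header into (accession, species).

    The species name is everything after the *first* ``-`` (species names may
    contain spaces; accessions in BOLD exports contain no internal hyphen).
    Raises :class:`HeaderError` when no ``-`` is present.
    """
    if "-" not in header:
        raise HeaderError(
            f"header {header!r} has no '-' separating accession from species"
        )
    accession, species = header.split("-", 1)
    accession, species = accession.strip(), species.strip()
    if not accession or not species:
        raise HeaderError(f"header {header!r} has an empty accession or species")
    return accession, species


def read_fasta(path: str | Path, require_labels: bool = False) -> Dataset:
    """Read a FASTA file into a :class:`Dataset`.

    Sequences are uppercased; entry order is preserved.  Headers that do not
    parse as ``ACCESSION-species`` yield unlabeled records (the whole header
    becomes the accession) unless ``require_labels`` is set, in which case
    they raise :class:`HeaderError`.
    """
    path = Path(path)
    records: list[BarcodeRecord] = []
    with open(path) as handle:
        # reject sequence data before the first header with a line number,
        # which SeqIO would silently skip
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path.name}:{lineno}: sequence data before first '>' header"
                )
            break
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description.strip()
        seq = str(entry.seq).upper()
        if not seq:
            raise FastaParseError(f"{path.name}: entry {header!r} has an empty sequence")
        try:
            accession, species = parse_header(header)
        except HeaderError:
            if require_labels:
                raise
            accession, species = header, None
        records.append(BarcodeRecord(accession, species, seq))
    return Dataset(records)


def write_fasta(ds: Dataset, path: str | Path) -> None:
    """Write a dataset back to FASTA with ``ACCESSION-species`` headers."""
    entries = []
    for rec in ds:
        header = rec.accession if rec.species is None else f"{rec.accession}-{rec.species}"
        entries.append(SeqRecord(Seq(rec.sequence), id=header, description=""))
    SeqIO.write(entries, str(path), "fasta")


@dataclass
class CleaningReport:
    """Counts of records removed by each cleaning rule."""

    n_input: int = 0
    n_output: int = 0
    removed_ambiguous: int = 0
    removed_short: int = 0
    removed_long: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def clean_dataset(
    ds: Dataset,
    min_length: int = 0,
    max_length: int | None = None,
    trim_to: int | None = None,
    drop_ambiguous: bool = True,
) -> tuple[Dataset, CleaningReport]:
    """Apply barcode cleaning rules and report removals.

    Rules, in order per record: drop records containing any symbol outside
    A/C/G/T (IUPAC ambiguity codes such as N, and gap characters) when
    ``drop_ambiguous``; drop records shorter than ``min_length`` or longer
    than ``max_length``; finally truncate survivors to their first ``trim_to``
    bases when set (used to reduce a library to a common barcode length).
    """
    if min_length < 0:
        raise ValueError("min_length must be non-negative")
    if trim_to is not None and trim_to > min_length and min_length > 0:
        raise ValueError("trim_to must be <= min_length when both are set")
    report = CleaningReport(n_input=len(ds))
    kept: list[BarcodeRecord] = []
    for rec in ds:
        if drop_ambiguous and (set(rec.sequence) - ALPHABET):
            report.removed_ambiguous += 1
            continue
        if len(rec) < min_length:
            report.removed_short += 1
            continue
        if max_length is not None and len(rec) > max_length:
            report.removed_long += 1
            continue
        if trim_to is not None and len(rec) > trim_to:
            rec = BarcodeRecord(rec.accession, rec.species, rec.sequence[:trim_to])
        kept.append(rec)
    report.n_output = len(kept)
    return Dataset(kept), report


def write_assignments(
    rows: Sequence[tuple[str, str | None, str, str]], path: str | Path
) -> None:
    """Write per-query assignments as a TSV table with a header line.

    Each row is ``(query_accession, true_species, predicted_species, status)``
    with status one of correct / wrong / excluded_singleton / unlabeled.
    """
    with open(path, "w") as fh:
        fh.write("query_accession\ttrue_species\tpredicted_species\tstatus\n")
        for accession, true_sp, pred_sp, status in rows:
            fh.write(f"{accession}\t{true_sp or ''}\t{pred_sp}\t{status}\n")


def read_assignments(path: str | Path) -> list[tuple[str, str | None, str, str]]:
    """Read a TSV written by :func:`write_assignments`."""
    rows = []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            accession, true_sp, pred_sp, status = line.rstrip("\n").split("\t")
            rows.append((accession, true_sp or None, pred_sp, status))
    return rows
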