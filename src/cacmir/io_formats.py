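"""Readers and writers: FASTA, tabular reports, and the packaged reference tables.

Sequences are normalised to the DNA alphabet internally (U -> T) with the
original RNA alphabet flagged, so downstream stages can reason over a single
alphabet while round trips preserve what the user supplied.  Coordinates are
0-based half-open everywhere in this package.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import (
    FastaFormatError,
    FastaRecordError,
    FixtureError,
    SequenceError,
)

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA-alphabet sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence, stored in DNA form.

    ``is_rna`` flags that the source used U; writers restore the original
    alphabet.  ``description`` keeps any header text after the first
    whitespace.
    """

    id: str
    sequence: str
    description: str = ""
    is_rna: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaRecordError("sequence record id must be non-empty")
        seq = self.sequence.upper()
        if "U" in seq:
            self.is_rna = True
            seq = seq.replace("U", "T")
        bad = set(seq) - ALPHABET
        if bad:
            raise SequenceError(
                f"record {self.id!r}: characters outside A/C/G/T/U/N: {sorted(bad)}"
            )
        if not seq:
            raise FastaRecordError(f"record {self.id!r} has an empty sequence body")
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def output_sequence(self) -> str:
        """Sequence in the alphabet of the input (U restored if RNA)."""
        return self.sequence.replace("T", "U") if self.is_rna else self.sequence


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (wrapped or unwrapped) multi-record FASTA file.

    The id is everything up to the first whitespace (``|`` preserved intact);
    the remainder of the header line is kept as the description.
    """
    path = Path(path)
    _validate_fasta_shape(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FastaRecordError(f"record {rec.id!r} has an empty sequence body")
        records.append(
            SequenceRecord(id=rec.id, sequence=str(rec.seq), description=rec.description[len(rec.id):].strip())
        )
    return records


def _validate_fasta_shape(path: Path) -> None:
    """Light structural pre-scan so format errors can name the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaFormatError(
                    f"{path}:{lineno}: expected a '>' header before sequence data"
                )
            if stripped == ">":
                raise FastaFormatError(f"{path}:{lineno}: empty FASTA header")
            return  # first record header looks sane; Biopython handles the rest


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records, restoring each record's original alphabet."""
    bio = [
        _BioSeqRecord(Seq(r.output_sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Packaged reference tables (transcribed from the printed study tables)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureTable1Row:
    """One putative-miRNA record of the printed summary table.

    ``mature_seq_raw`` is the printed string including alignment gap
    characters "-"; ``mature_seq`` is gap-stripped.  MSL as printed equals
    the gap-inclusive alignment length, and is validated against it.
    ``mfe_dg`` is the folding-score column that Eq.-style MFEI arithmetic
    uses; ``mfe_kcal`` is the separately reported kcal/mol value.
    """

    est_id: str
    mirna_name: str
    homolog_name: str
    mature_seq_raw: str
    msl: int
    psl: int
    mfe_dg: float
    mfe_kcal: float
    gc_percent: float
    mfei: float

    @property
    def mature_seq(self) -> str:
        return self.mature_seq_raw.replace("-", "")


@dataclass(frozen=True)
class FixtureTable2Row:
    """One printed miRNA -> target-gene association (duplicates preserved)."""

    mirna_name: str
    mirna_acc: str
    gene_symbol: str


def _fixture_bytes(name: str) -> bytes:
    return resources.files("cacmir.data").joinpath(name).read_bytes()


def load_fixture_tables() -> tuple[list[FixtureTable1Row], list[FixtureTable2Row]]:
    """Load the packaged putative-miRNA and target-gene tables.

    Both files are verified against a manifest (row counts and SHA-256)
    recorded at transcription time; any mismatch raises ``FixtureError``.
    """
    manifest = json.loads(_fixture_bytes("fixtures_manifest.json"))

    t1_rows: list[FixtureTable1Row] = []
    raw1 = _fixture_bytes("table1_putative_mirnas.tsv")
    _check_fixture("table1_putative_mirnas.tsv", raw1, manifest)
    lines = raw1.decode().rstrip("\n").split("\n")
    for line in lines[1:]:
        (est_id, name, homolog, mature_raw, msl, psl, dg, kcal, gc, mfei) = line.split("\t")
        row = FixtureTable1Row(
            est_id=est_id,
            mirna_name=name,
            homolog_name=homolog,
            mature_seq_raw=mature_raw,
            msl=int(msl),
            psl=int(psl),
            mfe_dg=float(dg),
            mfe_kcal=float(kcal),
            gc_percent=float(gc),
            mfei=float(mfei),
        )
        if row.msl != len(row.mature_seq_raw) or not 18 <= row.msl <= 24:
            raise FixtureError(f"{row.mirna_name}: MSL inconsistent with printed sequence")
        if row.mfe_dg >= 0 or not 0 < row.gc_percent < 100:
            raise FixtureError(f"{row.mirna_name}: out-of-range numeric column")
        t1_rows.append(row)

    raw2 = _fixture_bytes("table2_targets.tsv")
    _check_fixture("table2_targets.tsv", raw2, manifest)
    t2_rows = [
        FixtureTable2Row(*line.split("\t"))
        for line in raw2.decode().rstrip("\n").split("\n")[1:]
    ]
    return t1_rows, t2_rows


def _check_fixture(name: str, raw: bytes, manifest: Mapping) -> None:
    entry = manifest[name]
    n_rows = raw.decode().rstrip("\n").count("\n")  # excludes header
    if n_rows != entry["rows"]:
        raise FixtureError(f"{name}: expected {entry['rows']} rows, found {n_rows}")
    digest = hashlib.sha256(raw).hexdigest()
    if digest != entry["sha256"]:
        raise FixtureError(f"{name}: checksum mismatch (fixture corrupted)")


# ---------------------------------------------------------------------------
# Result reports
# ---------------------------------------------------------------------------


def _fmt_value(v) -> str:
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        return format(v, ".6g")
    return str(v)


def _round6(v):
    if isinstance(v, float):
        return float(format(v, ".6g"))
    if isinstance(v, dict):
        return {k: _round6(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_round6(x) for x in v]
    return v


def write_report(
    results: Sequence[Mapping] | Mapping,
    path: str | Path,
    format: str = "tsv",
    columns: Sequence[str] | None = None,
) -> None:
    """Write results as TSV (list of flat mappings) or JSON.

    Column/key order is deterministic (``columns`` if given, else the first
    record's insertion order); floats are rendered with 6 significant digits
    (``%.6g``).  An empty result set yields a header-only TSV.
    """
    path = Path(path)
    if format == "tsv":
        rows = list(results)
        with open(path, "w") as fh:
            if not rows and columns is None:
                fh.write("\n")
                return
            cols = list(columns) if columns is not None else list(rows[0].keys())
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write("\t".join(_fmt_value(row[c]) for c in cols) + "\n")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(_round6(results), fh, indent=1, sort_keys=False)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
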