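"""Sequence and metadata input/output.

All sequences are held internally as uppercase RNA (``U``); DNA input is
converted on read and can be converted back on write.  IUPAC ambiguity codes
are preserved but treated as unpairable by the folding engine.  Every
coordinate exposed to users is 1-based inclusive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: IUPAC nucleotide one-letter codes (RNA canonical form).
IUPAC_RNA = set("ACGUNRYSWKMBDHV")
#: Unambiguous RNA bases.
RNA_BASES = set("ACGU")
#: Alignment gap characters accepted in aligned input.
GAP_CHARS = {"-"}

HABITATS = {
    "freshwater",
    "soil",
    "marine",
    "endosymbiont-sponge",
    "endosymbiont-other",
    "unknown",
}
REGIONS = {"Europe", "Asia", "North America", "South America", "unknown"}


class SeqIOError(ValueError):
    """Raised on malformed sequence or metadata input."""


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class SeqRecord:
    """An identified nucleotide sequence with optional strain metadata."""

    id: str
    sequence: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = to_rna(self.sequence)
        if not self.sequence:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - IUPAC_RNA - GAP_CHARS
        if bad:
            raise SeqIOError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def as_dna(self) -> str:
        return to_dna(self.sequence)


def read_fasta(path, rna: bool = True) -> list[SeqRecord]:
    """Read a (multi-)FASTA file into :class:`SeqRecord` objects.

    Order is preserved; duplicate ids and empty files are errors.  ``rna``
    is accepted for symmetry but the internal representation is always RNA.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, str(rec.seq)))
    if not records:
        raise SeqIOError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path, dna: bool = False) -> None:
    """Write records as FASTA (RNA by default, DNA with ``dna=True``)."""
    bio = [
        _BioSeqRecord(
            Seq(r.as_dna() if dna else r.sequence), id=r.id, description=""
        )
        for r in records
    ]
    _BioSeqIO.write(bio, str(path), "fasta-2line")


# -- Vienna dot-bracket -----------------------------------------------------

def parse_dotbracket(db: str) -> frozenset[tuple[int, int]]:
    """Parse a dot-bracket string into a set of 0-based (i, j) pairs.

    Unbalanced strings raise :class:`SeqIOError` naming the first offending
    0-based offset.
    """
    stack: list[int] = []
    pairs = set()
    for k, ch in enumerate(db):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            if not stack:
                raise SeqIOError(f"unbalanced ')' at offset {k}")
            pairs.add((stack.pop(), k))
        elif ch != ".":
            raise SeqIOError(f"invalid dot-bracket character {ch!r} at offset {k}")
    if stack:
        raise SeqIOError(f"unbalanced '(' at offset {stack[0]}")
    return frozenset(pairs)


def read_vienna(path) -> list:
    """Read 2-line Vienna records (``>id``, sequence, dot-bracket).

    Returns a list of :class:`its2delim.fold.SecondaryStructure`.
    """
    from .fold import SecondaryStructure  # deferred: fold imports seqio

    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise SeqIOError(f"no Vienna records found in {path}")
    out = []
    i = 0
    seen: set[str] = set()
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise SeqIOError(f"expected '>' header at line {i + 1} of {path}")
        rid = lines[i][1:].split()[0]
        if rid in seen:
            raise SeqIOError(f"duplicate Vienna id {rid!r} in {path}")
        seen.add(rid)
        try:
            seq, db = lines[i + 1], lines[i + 2]
        except IndexError:
            raise SeqIOError(f"truncated Vienna record {rid!r}") from None
        if len(seq) != len(db):
            raise SeqIOError(
                f"record {rid!r}: sequence and structure lengths differ"
            )
        pairs = parse_dotbracket(db)
        out.append(SecondaryStructure(SeqRecord(rid, seq), pairs))
        i += 3
    return out


def write_vienna(structures: Iterable, path) -> None:
    with open(path, "w") as fh:
        for s in structures:
            fh.write(f">{s.record.id}\n{s.record.sequence}\n{s.dotbracket()}\n")


# -- metadata ---------------------------------------------------------------

_HABITAT_ALIASES = {
    "sponge": "endosymbiont-sponge",
    "endosymbiont": "endosymbiont-other",
    "fresh water": "freshwater",
}


@dataclass
class MetadataTable:
    """Per-sequence metadata (habitat, region, haplotype label).

    Backed by a DataFrame indexed by sequence id with normalized category
    labels; anything unrecognized or missing becomes ``"unknown"``.
    """

    frame: pd.DataFrame

    @classmethod
    def from_rows(cls, rows: Mapping[str, Mapping[str, str]]) -> "MetadataTable":
        df = pd.DataFrame.from_dict(dict(rows), orient="index")
        df.index.name = "id"
        return cls(_normalize(df))

    def get(self, rid: str) -> dict:
        if rid not in self.frame.index:
            return {"habitat": "unknown", "region": "unknown"}
        return self.frame.loc[rid].to_dict()

    def habitat(self, rid: str) -> str:
        return self.get(rid).get("habitat", "unknown")

    def region(self, rid: str) -> str:
        return self.get(rid).get("region", "unknown")

    @property
    def ids(self) -> list[str]:
        return list(self.frame.index)

    def check_ids(self, records: Iterable[SeqRecord]) -> None:
        known = {r.id for r in records}
        orphans = [i for i in self.ids if i not in known]
        if orphans:
            raise SeqIOError(f"metadata ids without sequence records: {orphans}")


def _norm_label(value, allowed: set[str], aliases: Mapping[str, str] = {}) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return "unknown"
    v = str(value).strip()
    if not v:
        return "unknown"
    v = aliases.get(v.lower(), v)
    for a in allowed:
        if v.lower() == a.lower():
            return a
    return "unknown"


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "habitat" not in df.columns:
        df["habitat"] = "unknown"
    if "region" not in df.columns:
        df["region"] = "unknown"
    df["habitat"] = df["habitat"].map(
        lambda v: _norm_label(v, HABITATS, _HABITAT_ALIASES)
    )
    df["region"] = df["region"].map(lambda v: _norm_label(v, REGIONS))
    return df


def read_metadata(path) -> MetadataTable:
    """Read a TSV metadata table (columns: id, habitat, region, ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in df.columns:
        raise SeqIOError(f"metadata file {path} lacks an 'id' column")
    if df["id"].duplicated().any():
        dups = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise SeqIOError(f"duplicate metadata ids: {dups}")
    df = df.set_index("id")
    return MetadataTable(_normalize(df))


def write_metadata(table: MetadataTable, path) -> None:
    table.frame.to_csv(path, sep="\t")
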