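"""ITS-2 conserved-region barcoding and CBC/HCBC classification.

The conserved region comprises the 16 basal pairs of the 5.8S/LSU stem, the
5 basal pairs of Helix I, the 11 basal rungs of Helix II (including the
pyrimidine/pyrimidine mismatch) and all pairs of Helix III.  Each rung is
written as a one-digit code::

    1 = A-U   2 = U-A   3 = G-C   4 = C-G   5 = G.U   6 = U.G
    7 = mismatch        8 = deletion/insertion or single bases

Two barcodes are compared segment-by-segment; a column where both partner
bases change while pairing is retained is a compensatory base change (CBC),
a column where exactly one partner changes is a hemi-CBC (HCBC).  Taxa
separated by at least one CBC in the conserved region are treated as
distinct species candidates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .fold import SecondaryStructure
from .seqio import RNA_BASES

GAP = "-"

CODE_OF_PAIR = {
    ("A", "U"): "1",
    ("U", "A"): "2",
    ("G", "C"): "3",
    ("C", "G"): "4",
    ("G", "U"): "5",
    ("U", "G"): "6",
}
PAIR_OF_CODE = {v: k for k, v in CODE_OF_PAIR.items()}

SEGMENTS = ("STEM", "HELIX_I", "HELIX_II", "HELIX_III")
#: rung quotas for the fixed-length segments (Helix III takes all rungs).
QUOTAS = {"STEM": 16, "HELIX_I": 5, "HELIX_II": 11}

_SEGMENT_OF_HELIX = {"STEM": "STEM", "I": "HELIX_I", "II": "HELIX_II", "III": "HELIX_III"}

CLASSES = ("identical", "CBC", "HCBC", "indel", "mismatch-shift", "unpaired-change")


def encode_pair(b5: str | None, b3: str | None) -> str:
    """Translate one rung (5' base, 3' base) into the 1-8 number code."""
    if b5 in (None, GAP) or b3 in (None, GAP):
        return "8"
    b5, b3 = b5.upper(), b3.upper()
    for b in (b5, b3):
        if b not in RNA_BASES:
            raise ValueError(
                f"ambiguity code {b!r} cannot be encoded; resolve it first"
            )
    return CODE_OF_PAIR.get((b5, b3), "7")


def decode(code: str) -> tuple[str, str]:
    """Inverse of :func:`encode_pair` on the six canonical pair codes."""
    try:
        return PAIR_OF_CODE[code]
    except KeyError:
        raise ValueError(f"code {code!r} does not name a canonical pair") from None


@dataclass(frozen=True)
class BarcodePosition:
    segment: str
    index: int  # 1-based within the segment, basal -> apical
    b5: str  # GAP for missing rungs
    b3: str
    code: str


@dataclass
class Its2Barcode:
    """The number-code barcode of one ITS-2 structure."""

    id: str
    positions: list[BarcodePosition]
    partial: bool = False

    @property
    def codes(self) -> str:
        return "".join(p.code for p in self.positions)

    def segment(self, name: str) -> list[BarcodePosition]:
        return [p for p in self.positions if p.segment == name]

    @property
    def segment_lengths(self) -> dict[str, int]:
        c = Counter(p.segment for p in self.positions)
        return {s: c.get(s, 0) for s in SEGMENTS}

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": self.id,
                    "segment": p.segment,
                    "position": p.index,
                    "base5": p.b5,
                    "base3": p.b3,
                    "code": p.code,
                }
                for p in self.positions
            ]
        )


def extract_barcode(structure: SecondaryStructure) -> Its2Barcode:
    """Extract the conserved-region barcode from a decomposed structure.

    Helices shorter than their quota are padded with code-8 positions and
    the barcode is flagged partial.
    """
    if not structure.helices:
        raise ValueError("structure must be helix-decomposed first")
    seq = structure.record.sequence
    positions: list[BarcodePosition] = []
    partial = False
    for helix_label, segment in _SEGMENT_OF_HELIX.items():
        try:
            helix = structure.helix(helix_label)
            rungs = helix.rungs
        except KeyError:
            rungs = []
        quota = QUOTAS.get(segment, len(rungs))
        for idx in range(quota):
            if idx < len(rungs):
                r = rungs[idx]
                b5, b3 = seq[r.i], seq[r.j]
                # a coded (constraint-tolerated) mismatch is always 7
                code = encode_pair(b5, b3) if r.paired else "7"
            else:
                b5 = b3 = GAP
                code = "8"
                partial = True
            positions.append(BarcodePosition(segment, idx + 1, b5, b3, code))
    return Its2Barcode(structure.record.id, positions, partial=partial)


# -- alignment --------------------------------------------------------------

@dataclass(frozen=True)
class AlignedColumn:
    segment: str
    a: BarcodePosition | None
    b: BarcodePosition | None


@dataclass
class AlignedBarcodes:
    id_a: str
    id_b: str
    columns: list[AlignedColumn]


def _nw_codes(a: list[BarcodePosition], b: list[BarcodePosition]):
    """Global alignment of two code strings (match 1, mismatch 0, gap -1).

    Ties are broken so that gaps fall as late (apically) as possible.
    """
    m, n = len(a), len(b)
    # suffix-optimal scores: S[i][j] = best score aligning a[i:] with b[j:]
    S = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        S[i][n] = -(m - i)
    for j in range(n + 1):
        S[m][j] = -(n - j)
    for i in range(m - 1, -1, -1):
        for j in range(n - 1, -1, -1):
            diag = S[i + 1][j + 1] + (1 if a[i].code == b[j].code else 0)
            S[i][j] = max(diag, S[i + 1][j] - 1, S[i][j + 1] - 1)
    cols: list[tuple[BarcodePosition | None, BarcodePosition | None]] = []
    i = j = 0
    while i < m or j < n:
        # diagonal first: a gap is taken only when strictly required, and
        # the forward walk defers it as far apically as possible
        if (
            i < m
            and j < n
            and S[i][j] == S[i + 1][j + 1] + (1 if a[i].code == b[j].code else 0)
        ):
            cols.append((a[i], b[j]))
            i += 1
            j += 1
        elif i < m and S[i][j] == S[i + 1][j] - 1:
            cols.append((a[i], None))
            i += 1
        else:
            cols.append((None, b[j]))
            j += 1
    return cols


def align_barcodes(a: Its2Barcode, b: Its2Barcode) -> AlignedBarcodes:
    """Segment-wise global alignment of two barcodes (STEM vs STEM, ...)."""
    columns: list[AlignedColumn] = []
    for segment in SEGMENTS:
        for pa, pb in _nw_codes(a.segment(segment), b.segment(segment)):
            columns.append(AlignedColumn(segment, pa, pb))
    return AlignedBarcodes(a.id, b.id, columns)


# -- classification ---------------------------------------------------------

@dataclass(frozen=True)
class ColumnChange:
    segment: str
    position: int  # 1-based position within the segment (of side A, else B)
    code_a: str
    code_b: str
    bases_a: tuple[str, str]
    bases_b: tuple[str, str]
    klass: str


@dataclass
class ChangeReport:
    """Per-column classification of the differences between two barcodes."""

    id_a: str
    id_b: str
    columns: list[ColumnChange]

    @property
    def totals(self) -> dict[str, int]:
        c = Counter(col.klass for col in self.columns)
        return {k: c.get(k, 0) for k in CLASSES}

    @property
    def n_cbc(self) -> int:
        return self.totals["CBC"]

    @property
    def n_hcbc(self) -> int:
        return self.totals["HCBC"]

    @property
    def n_indel(self) -> int:
        return self.totals["indel"]

    def changes(self) -> list[ColumnChange]:
        return [c for c in self.columns if c.klass != "identical"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id_a": self.id_a,
                    "id_b": self.id_b,
                    "segment": c.segment,
                    "position": c.position,
                    "code_a": c.code_a,
                    "code_b": c.code_b,
                    "bases_a": "".join(c.bases_a),
                    "bases_b": "".join(c.bases_b),
                    "class": c.klass,
                }
                for c in self.columns
            ]
        )


def _classify_column(code_a, ba, code_b, bb) -> str:
    if code_a == "8" and code_b == "8":
        return "identical" if ba == bb else "unpaired-change"
    if (code_a == "8") != (code_b == "8"):
        return "indel"
    if code_a == "7" and code_b == "7":
        return "identical" if ba == bb else "unpaired-change"
    if (code_a == "7") != (code_b == "7"):
        return "mismatch-shift"
    # both canonical 1..6
    if code_a == code_b:
        return "identical"
    diffs = (ba[0] != bb[0]) + (ba[1] != bb[1])
    return "CBC" if diffs == 2 else "HCBC"


def classify_changes(aligned: AlignedBarcodes) -> ChangeReport:
    """Classify every aligned column as identical/CBC/HCBC/indel/etc.

    Symmetric in its inputs: swapping A and B swaps the per-column codes but
    leaves every class total unchanged.
    """
    out: list[ColumnChange] = []
    for col in aligned.columns:
        pa, pb = col.a, col.b
        code_a = pa.code if pa else "8"
        code_b = pb.code if pb else "8"
        ba = (pa.b5, pa.b3) if pa else (GAP, GAP)
        bb = (pb.b5, pb.b3) if pb else (GAP, GAP)
        klass = _classify_column(code_a, ba, code_b, bb)
        pos = pa.index if pa else (pb.index if pb else 0)
        out.append(
            ColumnChange(col.segment, pos, code_a, code_b, ba, bb, klass)
        )
    return ChangeReport(aligned.id_a, aligned.id_b, out)


def compare_barcodes(a: Its2Barcode, b: Its2Barcode) -> ChangeReport:
    return classify_changes(align_barcodes(a, b))


# -- multi-taxon tallies and species delimitation ---------------------------

def _pad_to_anchor(bc: Its2Barcode, anchor: Its2Barcode) -> list[BarcodePosition | None]:
    """Project a barcode onto the anchor's columns (anchor-gap columns dropped)."""
    cols = []
    for col in align_barcodes(anchor, bc).columns:
        if col.a is not None:  # keep anchor coordinates
            cols.append(col.b)
    return cols


def union_and_sum_tallies(barcodes: list[Its2Barcode]) -> dict[str, dict[str, int]]:
    """Tally CBC/HCBC/indel columns across all pairwise comparisons.

    ``union`` counts a changed column once however many species pairs it
    separates (columns are put on the coordinates of the longest barcode);
    ``sum`` adds the pairwise totals.
    """
    if len(barcodes) < 2:
        return {"union": dict.fromkeys(("CBC", "HCBC", "indel"), 0),
                "sum": dict.fromkeys(("CBC", "HCBC", "indel"), 0)}
    anchor = max(barcodes, key=len)
    projected = {bc.id: _pad_to_anchor(bc, anchor) for bc in barcodes}
    union: dict[str, set[int]] = {"CBC": set(), "HCBC": set(), "indel": set()}
    total: Counter = Counter()
    ids = [bc.id for bc in barcodes]
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            pa, pb = projected[ids[x]], projected[ids[y]]
            for k in range(len(pa)):
                code_a = pa[k].code if pa[k] else "8"
                code_b = pb[k].code if pb[k] else "8"
                ba = (pa[k].b5, pa[k].b3) if pa[k] else (GAP, GAP)
                bb = (pb[k].b5, pb[k].b3) if pb[k] else (GAP, GAP)
                klass = _classify_column(code_a, ba, code_b, bb)
                if klass in union:
                    union[klass].add(k)
                    total[klass] += 1
    return {
        "union": {k: len(v) for k, v in union.items()},
        "sum": {k: total.get(k, 0) for k in ("CBC", "HCBC", "indel")},
    }


@dataclass
class DelimitResult:
    """Candidate species partition plus the supporting pairwise evidence."""

    components: list[list[str]]
    reports: dict[tuple[str, str], ChangeReport]

    @property
    def n_species(self) -> int:
        return len(self.components)

    def rationale(self) -> pd.DataFrame:
        rows = []
        comp_of = {}
        for k, comp in enumerate(self.components):
            for rid in comp:
                comp_of[rid] = k + 1
        for (ida, idb), rep in sorted(self.reports.items()):
            rows.append(
                {
                    "id_a": ida,
                    "id_b": idb,
                    "component_a": comp_of[ida],
                    "component_b": comp_of[idb],
                    "CBC": rep.n_cbc,
                    "HCBC": rep.n_hcbc,
                    "indel": rep.n_indel,
                    "same_species": rep.n_cbc == 0,
                }
            )
        return pd.DataFrame(rows)


def delimit_species(barcodes: list[Its2Barcode]) -> DelimitResult:
    """Partition taxa into candidate species: linked iff zero CBCs."""
    if not barcodes:
        return DelimitResult([], {})
    g = nx.Graph()
    g.add_nodes_from(bc.id for bc in barcodes)
    reports: dict[tuple[str, str], ChangeReport] = {}
    for x in range(len(barcodes)):
        for y in range(x + 1, len(barcodes)):
            a, b = barcodes[x], barcodes[y]
            rep = compare_barcodes(a, b)
            reports[(a.id, b.id)] = rep
            if rep.n_cbc == 0:
                g.add_edge(a.id, b.id)
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: c[0])
    return DelimitResult(components, reports)
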