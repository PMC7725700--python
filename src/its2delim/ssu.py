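"""SSU rDNA utilities: reference coordinate mapping, group I intron
detection and excision, V4/V9 variable-region extraction, variable-site
counting, and V9 secondary-structure haplotype comparison.

Intron insertion sites are named by the homologous position in the SSU
numbering reference (E. coli-style coordinates): the reported anchor is the
reference coordinate of the last exon base 5' of the insertion, the
convention behind names like "position 1512".  All coordinates are 1-based
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from . import barcode as _barcode
from .fold import FoldParams, SecondaryStructure, fold_sequence
from .seqio import RNA_BASES, SeqRecord
from .synth import V4_WINDOW, V9_WINDOW, default_reference

#: default 1-based reference windows for the variable regions
DEFAULT_WINDOWS = {"V4": V4_WINDOW, "V9": V9_WINDOW}

MIN_INTRON_LEN = 100
IDENTITY_WARN = 0.5


class SsuError(ValueError):
    """Raised on unusable SSU input (unalignable windows, ragged alignments)."""


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -8
    # near-free extension so multi-hundred-nt introns align as single gaps
    # even close to the sequence ends
    aligner.extend_gap_score = -0.05
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


@dataclass
class CoordinateMap:
    """Pairwise query<->reference coordinate map (1-based on both sides)."""

    query_id: str
    reference_id: str
    #: aligned (query_pos, ref_pos) columns, both 1-based, monotone
    query_to_ref: dict[int, int]
    ref_to_query: dict[int, int]
    #: unaligned query blocks: (ref anchor, query start, query end)
    insertions: list[tuple[int, int, int]]
    identity: float
    low_identity: bool = False

    def ref_pos(self, query_pos: int) -> int | None:
        return self.query_to_ref.get(query_pos)

    def query_pos(self, ref_pos: int) -> int | None:
        return self.ref_to_query.get(ref_pos)


def map_to_reference(query: SeqRecord, reference: SeqRecord | None = None) -> CoordinateMap:
    """Semi-global (ends-free) affine-gap alignment of query against the
    numbering reference; deterministic (first optimal alignment)."""
    reference = reference or default_reference()
    aln = _make_aligner().align(reference.sequence, query.sequence)[0]
    t_blocks, q_blocks = aln.aligned
    q2r: dict[int, int] = {}
    r2q: dict[int, int] = {}
    insertions: list[tuple[int, int, int]] = []
    matches = 0
    aligned_cols = 0
    prev_t_end = None
    prev_q_end = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if qs > prev_q_end:
            anchor = prev_t_end if prev_t_end is not None else 0
            insertions.append((anchor, prev_q_end + 1, qs))
        for k in range(te - ts):
            rp, qp = ts + k + 1, qs + k + 1
            q2r[qp] = rp
            r2q[rp] = qp
            if reference.sequence[ts + k] == query.sequence[qs + k]:
                matches += 1
            aligned_cols += 1
        prev_t_end = te
        prev_q_end = qe
    if prev_q_end < len(query.sequence):
        insertions.append(
            (prev_t_end or 0, prev_q_end + 1, len(query.sequence))
        )
    identity = matches / aligned_cols if aligned_cols else 0.0
    return CoordinateMap(
        query.id,
        reference.id,
        q2r,
        r2q,
        insertions,
        identity,
        low_identity=identity < IDENTITY_WARN,
    )


@dataclass(frozen=True)
class IntronCall:
    """A putative group I intron insertion in a query SSU sequence."""

    query_start: int  # 1-based inclusive
    query_end: int
    length: int
    #: reference coordinate of the exon base immediately 5' of the insertion
    ecoli_position: int
    klass: str = "putative group I"


def detect_introns(
    query: SeqRecord,
    reference: SeqRecord | None = None,
    min_intron_len: int = MIN_INTRON_LEN,
    cmap: CoordinateMap | None = None,
) -> list[IntronCall]:
    """Report every unaligned query block of at least ``min_intron_len`` nt
    with its reference anchor."""
    cmap = cmap or map_to_reference(query, reference)
    calls = []
    for anchor, qs, qe in cmap.insertions:
        length = qe - qs + 1
        if length >= min_intron_len:
            calls.append(IntronCall(qs, qe, length, anchor))
    return calls


def excise_introns(query: SeqRecord, calls: list[IntronCall]) -> SeqRecord:
    """Concatenate the exon sequence (query minus the called introns)."""
    spans = sorted((c.query_start, c.query_end) for c in calls)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise SsuError(f"overlapping intron calls at {s1}-{e1} and {s2}-{e2}")
    seq = query.sequence
    parts = []
    prev = 0
    for s, e in spans:
        parts.append(seq[prev : s - 1])
        prev = e
    parts.append(seq[prev:])
    return SeqRecord(query.id, "".join(parts), dict(query.metadata))


def extract_region(
    query: SeqRecord,
    reference: SeqRecord | None = None,
    region: str = "V9",
    windows: dict[str, tuple[int, int]] | None = None,
    cmap: CoordinateMap | None = None,
) -> tuple[SeqRecord, tuple[int, int]]:
    """Extract the query segment aligned to a variable-region window.

    The query should be intron-excised first.  Returns the segment (with
    any query insertions inside the window included) and its 1-based query
    coordinates.
    """
    windows = windows or DEFAULT_WINDOWS
    if region not in windows:
        raise SsuError(f"unknown region {region!r}; have {sorted(windows)}")
    lo, hi = windows[region]
    cmap = cmap or map_to_reference(query, reference)
    q_lo = next(
        (q for r in range(lo, hi + 1) if (q := cmap.query_pos(r)) is not None), None
    )
    q_hi = next(
        (q for r in range(hi, lo - 1, -1) if (q := cmap.query_pos(r)) is not None),
        None,
    )
    if q_lo is None or q_hi is None or q_hi < q_lo:
        raise SsuError(f"window {region} {lo}-{hi} unalignable for {query.id}")
    seg = query.sequence[q_lo - 1 : q_hi]
    return SeqRecord(f"{query.id}_{region}", seg, dict(query.metadata)), (q_lo, q_hi)


def count_variable_sites(seqs: list[str | SeqRecord]) -> tuple[int, int, float]:
    """Count variable columns of an alignment (gaps and ambiguity ignored).

    A column is variable iff it holds >= 2 distinct unambiguous bases.
    Returns (variable, total, fraction).
    """
    rows = [s.sequence if isinstance(s, SeqRecord) else s.upper().replace("T", "U") for s in seqs]
    if not rows:
        raise SsuError("empty alignment")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise SsuError("ragged alignment: sequences differ in length")
    variable = 0
    for k in range(length):
        seen = {r[k] for r in rows} & RNA_BASES
        if len(seen) >= 2:
            variable += 1
    return variable, length, variable / length if length else 0.0


# -- V9 haplotypes ----------------------------------------------------------

@dataclass
class V9Haplotype:
    """A V9 subsequence with its folded helix and (optional) label."""

    record: SeqRecord
    structure: SecondaryStructure
    label: str | None = None


def fold_v9(record: SeqRecord, params: FoldParams | None = None) -> V9Haplotype:
    return V9Haplotype(record, fold_sequence(record, params))


def _helix_rungs(structure: SecondaryStructure):
    """All rungs of the structure's helices in 5' order, basal->apical,
    with 1x1 interruptions kept as coded mismatches."""
    from .fold import _chain_from, _nesting_children

    if not structure.pairs:
        return []
    roots, children = _nesting_children(sorted(structure.pairs))
    rungs = []
    stack = list(reversed(roots))
    while stack:
        start = stack.pop()
        chain, kids = _chain_from(start, children, bulge_tol=3)
        rungs.extend(chain)
        stack.extend(reversed(sorted(kids)))
    return rungs


def compare_v9(a: V9Haplotype, b: V9Haplotype) -> _barcode.ChangeReport:
    """Compare the paired positions of two folded V9 helices.

    Rungs are encoded with the 1-8 number code and classified exactly as
    the ITS-2 barcode comparison; both haplotypes must be folded with the
    same engine and parameters.
    """
    rungs_a = _helix_rungs(a.structure)
    rungs_b = _helix_rungs(b.structure)
    if not rungs_a or not rungs_b:
        raise SsuError("structures share no helix to compare")

    def positions(hap, rungs):
        seq = hap.record.sequence
        out = []
        for k, r in enumerate(rungs):
            b5, b3 = seq[r.i], seq[r.j]
            code = _barcode.encode_pair(b5, b3) if r.paired else "7"
            out.append(_barcode.BarcodePosition("V9", k + 1, b5, b3, code))
        return out

    bc_a = _barcode.Its2Barcode(a.record.id, positions(a, rungs_a))
    bc_b = _barcode.Its2Barcode(b.record.id, positions(b, rungs_b))
    cols = [
        _barcode.AlignedColumn("V9", pa, pb)
        for pa, pb in _barcode._nw_codes(bc_a.positions, bc_b.positions)
    ]
    return _barcode.classify_changes(
        _barcode.AlignedBarcodes(bc_a.id, bc_b.id, cols)
    )


def assign_v9_haplotypes(
    records: list[SeqRecord], params: FoldParams | None = None
) -> dict[str, str]:
    """Assign V9 haplotype labels: identical subsequences share a label.

    Primary labels 1, 2, ... go to distinct paired-position profiles by
    decreasing frequency then first-seen order; sequence variants within a
    profile that differ only at unpaired positions get lowercase suffixes
    (1a, 1b, ...), a suffix-free label when the profile has one variant.
    """
    by_seq: dict[str, list[str]] = {}
    order: list[str] = []
    for r in records:
        if r.sequence not in by_seq:
            order.append(r.sequence)
        by_seq.setdefault(r.sequence, []).append(r.id)
    profiles: dict[str, str] = {}
    for seq in order:
        hap = fold_v9(SeqRecord("_q", seq), params)
        rungs = _helix_rungs(hap.structure)
        profiles[seq] = "|".join(f"{seq[r.i]}{seq[r.j]}" for r in rungs)
    prof_counts: dict[str, int] = {}
    prof_order: list[str] = []
    for seq in order:
        p = profiles[seq]
        if p not in prof_counts:
            prof_order.append(p)
            prof_counts[p] = 0
        prof_counts[p] += len(by_seq[seq])
    ranked = sorted(prof_order, key=lambda p: (-prof_counts[p], prof_order.index(p)))
    label_of_profile = {p: str(k + 1) for k, p in enumerate(ranked)}
    out: dict[str, str] = {}
    for p in ranked:
        variants = [s for s in order if profiles[s] == p]
        variants.sort(key=lambda s: (-len(by_seq[s]), order.index(s)))
        for v_idx, seq in enumerate(variants):
            label = label_of_profile[p]
            if len(variants) > 1:
                label += "abcdefghijklmnopqrstuvwxyz"[v_idx]
            for rid in by_seq[seq]:
                out[rid] = label
    return out
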