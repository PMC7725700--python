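"""Constrained ITS-2 secondary-structure prediction.

The ITS-2 cassette (3' tail of the 5.8S rRNA, the spacer itself, and the 5'
head of the LSU rRNA) is folded under the three constraints classically used
for green-algal ITS-2 models:

1. the last ``stem_len`` 5.8S bases must bind the first ``stem_len`` LSU
   bases (the 5.8S/LSU stem closing the multiloop);
2. Helix II must carry a pyrimidine/pyrimidine mismatch after the 5th-7th
   base pair (the first RNA processing site);
3. the GGU motif must sit on the 5' strand of Helix III (the second
   processing site).

Scoring is a weighted Nussinov dynamic program (G-C=3, A-U=2, G-U=1, +1 per
stacked adjacent pair, minimum hairpin loop 3) rather than a full
thermodynamic model; externally computed dot-bracket structures (mfold,
RNAfold) can be fed in through :func:`its2delim.seqio.read_vienna` so the
downstream barcode stages are engine-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .seqio import RNA_BASES, SeqRecord

CANONICAL_PAIRS = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}
PYRIMIDINES = {"C", "U"}

_NEG = np.int64(-(10 ** 9))


class ConstraintUnsatisfiable(ValueError):
    """No structure satisfies a folding constraint; names the first failure."""

    def __init__(self, constraint: str, message: str = ""):
        self.constraint = constraint
        super().__init__(f"{constraint}: {message}" if message else constraint)


class StructureShapeError(ValueError):
    """Structure does not have the expected stem + multiloop shape."""


@dataclass(frozen=True)
class FoldParams:
    """Pairing weights and geometry of the folding score."""

    gc_weight: int = 3
    au_weight: int = 2
    gu_weight: int = 1
    stacking_bonus: int = 1
    min_loop: int = 3

    def pair_weight(self, a: str, b: str) -> int:
        if (a, b) in (("G", "C"), ("C", "G")):
            return self.gc_weight
        if (a, b) in (("A", "U"), ("U", "A")):
            return self.au_weight
        if (a, b) in (("G", "U"), ("U", "G")):
            return self.gu_weight
        return 0


@dataclass(frozen=True)
class FoldingConstraints:
    """The three hard ITS-2 folding constraints (see module docstring)."""

    stem_len: int = 25
    helix2_mismatch_window: tuple[int, int] = (5, 7)
    helix3_motif: str = "GGU"
    #: the motif must start within the first this-many nt of the Helix III
    #: 5' strand.
    motif_max_offset: int = 6

    def __post_init__(self):
        if self.stem_len < 1:
            raise ValueError("stem_len must be >= 1")
        lo, hi = self.helix2_mismatch_window
        if lo > hi or lo < 1:
            raise ValueError("invalid helix2_mismatch_window")
        if set(self.helix3_motif) - RNA_BASES:
            raise ValueError("helix3_motif must be over {A,C,G,U}")


@dataclass(frozen=True)
class Rung:
    """One position of a helix ladder: a base pair or a tolerated mismatch.

    ``i``/``j`` are 0-based sequence indices of the 5' and 3' partner.
    """

    i: int
    j: int
    paired: bool = True


@dataclass
class Helix:
    """A helix as an ordered ladder of rungs, basal (multiloop-proximal) first."""

    label: str  # STEM, I, II, III, IV
    rungs: list[Rung]

    @property
    def coded_mismatch_positions(self) -> list[int]:
        """1-based rung indices holding a tolerated (coded) mismatch."""
        return [k + 1 for k, r in enumerate(self.rungs) if not r.paired]

    def strand5(self, seq: str) -> str:
        return "".join(seq[r.i] for r in self.rungs)

    def n_pairs(self) -> int:
        return sum(1 for r in self.rungs if r.paired)


@dataclass
class SecondaryStructure:
    """A sequence plus a nested base-pair set, optionally helix-decomposed."""

    record: SeqRecord
    pairs: frozenset[tuple[int, int]]
    helices: list[Helix] = field(default_factory=list)
    #: cassette bookkeeping (None for plain sequences)
    five8s_len: int | None = None
    lsu_len: int | None = None
    score: int | None = None

    def __post_init__(self):
        self.pairs = frozenset(tuple(p) for p in self.pairs)
        n = len(self.record.sequence)
        used: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise ValueError(f"pair ({i},{j}) out of range")
            if i in used or j in used:
                raise ValueError(f"base in more than one pair near ({i},{j})")
            used.update((i, j))
        ps = sorted(self.pairs)
        for a in range(len(ps)):
            for b in range(a + 1, len(ps)):
                i1, j1 = ps[a]
                i2, j2 = ps[b]
                if i1 < i2 < j1 < j2:
                    raise ValueError(
                        f"crossing pairs ({i1},{j1}) and ({i2},{j2})"
                    )

    def dotbracket(self) -> str:
        db = ["."] * len(self.record.sequence)
        for i, j in self.pairs:
            db[i], db[j] = "(", ")"
        return "".join(db)

    def helix(self, label: str) -> Helix:
        for h in self.helices:
            if h.label == label:
                return h
        raise KeyError(f"no helix labelled {label!r}")


@dataclass(frozen=True)
class Violation:
    constraint: str
    message: str


def _pair_ok(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


# -- weighted Nussinov ------------------------------------------------------

def _dp_matrices(seq: str, params: FoldParams):
    """Fill W (best score on [i,j]) and V (best given i pairs j)."""
    n = len(seq)
    bonus = params.stacking_bonus
    pw = np.full((n, n), _NEG, dtype=np.int64)
    for i in range(n):
        for j in range(i + params.min_loop + 1, n):
            if _pair_ok(seq[i], seq[j]):
                pw[i, j] = params.pair_weight(seq[i], seq[j])
    V = np.full((n, n), _NEG, dtype=np.int64)
    W = np.zeros((n, n), dtype=np.int64)
    for s in range(1, n):
        i = np.arange(0, n - s)
        j = i + s
        if s >= params.min_loop + 1:
            inner = np.maximum(W[i + 1, j - 1], V[i + 1, j - 1] + bonus)
            v = pw[i, j] + inner
            V[i, j] = np.where(pw[i, j] > _NEG // 2, v, _NEG)
        cand = np.maximum(W[i + 1, j], W[i, j - 1])
        cand = np.maximum(cand, V[i, j])  # k == i
        for t in range(1, s + 1):  # i pairs nothing up to k-1; k = i + t
            cand = np.maximum(cand, W[i, i + t - 1] + V[i + t, j])
        W[i, j] = cand
    return W, V


def _traceback(seq: str, W, V, params: FoldParams) -> set[tuple[int, int]]:
    """Deterministic traceback: the leftmost base pairs first, with its
    nearest score-optimal partner."""
    bonus = params.stacking_bonus
    min_loop = params.min_loop
    pairs: set[tuple[int, int]] = set()

    stack: list[tuple[int, int, bool]] = [(0, len(seq) - 1, False)]
    while stack:
        i, j, enclosed = stack.pop()
        while i < j:
            target = W[i, j]
            if enclosed:
                target = max(target, V[i, j] + bonus)
            chosen = None
            for k in range(i + min_loop + 1, j + 1):
                if V[i, k] <= _NEG // 2:
                    continue
                val = V[i, k] + (W[k + 1, j] if k < j else 0)
                if enclosed and k == j:
                    val += bonus
                if val == target:
                    chosen = k
                    break
            if chosen is None:
                i += 1
                enclosed = False
                continue
            pairs.add((i, chosen))
            if chosen < j:
                stack.append((chosen + 1, j, False))
            # descend into the paired interval
            i, j, enclosed = i + 1, chosen - 1, True
    return pairs


def fold_sequence(record: SeqRecord, params: FoldParams | None = None) -> SecondaryStructure:
    """Unconstrained maximum-score fold of an arbitrary RNA sequence."""
    params = params or FoldParams()
    seq = record.sequence
    if len(seq) < params.min_loop + 2:
        return SecondaryStructure(record, frozenset(), score=0)
    W, V = _dp_matrices(seq, params)
    pairs = _traceback(seq, W, V, params)
    return SecondaryStructure(record, frozenset(pairs), score=int(W[0, len(seq) - 1]))


def structure_score(structure: SecondaryStructure, params: FoldParams | None = None) -> int:
    """Score an explicit structure under the same model as the folder."""
    params = params or FoldParams()
    seq = structure.record.sequence
    total = 0
    pairs = set(structure.pairs)
    for i, j in pairs:
        total += params.pair_weight(seq[i], seq[j])
        if (i + 1, j - 1) in pairs:
            total += params.stacking_bonus
    return total


# -- helix decomposition ----------------------------------------------------

def _nesting_children(pairs: list[tuple[int, int]]):
    """Map each pair to its directly nested child pairs."""
    order = sorted(pairs)
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in order}
    roots: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = []
    for p in order:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        if stack:
            children[stack[-1]].append(p)
        else:
            roots.append(p)
        stack.append(p)
    return roots, children


def _chain_from(start, children, bulge_tol: int) -> tuple[list[Rung], list]:
    """Follow single-child links from ``start`` into one helix ladder.

    A 1x1 interruption is recorded as a coded-mismatch rung; larger
    interruptions up to ``bulge_tol`` per side are bridged silently.  Returns
    the ladder and the child pairs where the ladder ends (a branch point or
    the helix tip).
    """
    rungs = [Rung(*start)]
    cur = start
    while True:
        kids = children[cur]
        if len(kids) != 1:
            return rungs, kids
        (ni, nj) = kids[0]
        gap5 = ni - cur[0] - 1
        gap3 = cur[1] - nj - 1
        if gap5 > bulge_tol or gap3 > bulge_tol:
            return rungs, kids
        if gap5 == 1 and gap3 == 1:
            rungs.append(Rung(cur[0] + 1, cur[1] - 1, paired=False))
        rungs.append(Rung(ni, nj))
        cur = (ni, nj)


_MULTILOOP_LABELS = ["I", "II", "III", "IV"]


def decompose_helices(
    structure: SecondaryStructure, bulge_tol: int = 3
) -> SecondaryStructure:
    """Label the 5.8S/LSU stem and the multiloop helices I..IV.

    The STEM is the helix containing the outermost pair; the helices emerging
    from the multiloop it closes are labelled I, II, III (IV) in 5'->3' order
    of their 5' starts.  Helices are merged across interruptions of at most
    ``bulge_tol`` unpaired bases per side; 1x1 interruptions are kept in the
    ladder as coded mismatches.  STEM rungs are reported basal
    (multiloop-proximal) first.
    """
    if not structure.pairs:
        raise StructureShapeError("no pairs to decompose")
    roots, children = _nesting_children(sorted(structure.pairs))
    if len(roots) != 1:
        raise StructureShapeError(
            f"expected a single closing stem, found {len(roots)} outermost helices"
        )
    stem_rungs, stem_end_children = _chain_from(roots[0], children, bulge_tol)
    if len(stem_end_children) < 2:
        raise StructureShapeError(
            f"multiloop with {len(stem_end_children)} helices; need >= 2"
        )
    if len(stem_end_children) > len(_MULTILOOP_LABELS):
        raise StructureShapeError(
            f"{len(stem_end_children)} multiloop helices; at most 4 supported"
        )
    helices = [Helix("STEM", list(reversed(stem_rungs)))]
    for label, child in zip(
        _MULTILOOP_LABELS, sorted(stem_end_children, key=lambda p: p[0])
    ):
        rungs, _ = _chain_from(child, children, bulge_tol)
        helices.append(Helix(label, rungs))
    out = replace(structure)
    out.helices = helices
    return out


# -- constraint validation --------------------------------------------------

def validate_constraints(
    structure: SecondaryStructure, constraints: FoldingConstraints | None = None
) -> list[Violation]:
    """Check the three ITS-2 constraints on a decomposed structure.

    Returns an empty list iff all constraints hold; a pure check, never
    raises for a merely non-compliant structure.
    """
    constraints = constraints or FoldingConstraints()
    out: list[Violation] = []
    seq = structure.record.sequence
    if not structure.helices:
        structure = decompose_helices(structure)
    try:
        stem = structure.helix("STEM")
    except KeyError:  # pragma: no cover - decompose always labels STEM
        return [Violation("stem_len", "no stem helix")]

    # (a) stem: stem_len rungs (pairs or recorded mismatches) bridging the
    # 5.8S tail and LSU head.
    if structure.five8s_len is not None and structure.lsu_len is not None:
        n = len(seq)
        f = structure.five8s_len
        want = {
            (f - 1 - k, n - structure.lsu_len + k)
            for k in range(constraints.stem_len)
        }
        have = {(r.i, r.j) for r in stem.rungs}
        missing = sorted(want - have)
        if missing:
            out.append(
                Violation(
                    "stem_len",
                    f"{len(missing)} of {constraints.stem_len} stem positions "
                    f"unbound (first at 5.8S index {missing[0][0] + 1})",
                )
            )
    elif len(stem.rungs) < constraints.stem_len:
        out.append(
            Violation(
                "stem_len",
                f"stem has {len(stem.rungs)} rungs; {constraints.stem_len} required",
            )
        )

    # (b)/(c) Helix II pyrimidine/pyrimidine mismatch within the window.
    lo, hi = constraints.helix2_mismatch_window
    try:
        h2 = structure.helix("II")
    except KeyError:
        out.append(Violation("helix2_mismatch_window", "no Helix II"))
    else:
        found = False
        n_pairs_before = 0
        for r in h2.rungs:
            if r.paired:
                n_pairs_before += 1
                continue
            pyr = seq[r.i] in PYRIMIDINES and seq[r.j] in PYRIMIDINES
            if pyr and lo <= n_pairs_before <= hi:
                found = True
                break
        if not found:
            out.append(
                Violation(
                    "helix2_mismatch_window",
                    f"no pyrimidine/pyrimidine mismatch after pairs {lo}-{hi} "
                    "of Helix II",
                )
            )

    # (d) GGU motif near the 5' start of Helix III.
    try:
        h3 = structure.helix("III")
    except KeyError:
        out.append(Violation("helix3_motif", "no Helix III"))
    else:
        strand = h3.strand5(seq)
        idx = strand.find(constraints.helix3_motif)
        if idx < 0 or idx >= constraints.motif_max_offset:
            out.append(
                Violation(
                    "helix3_motif",
                    f"{constraints.helix3_motif} not within the first "
                    f"{constraints.motif_max_offset} nt of the Helix III 5' strand",
                )
            )
    return out


# -- constrained cassette folding -------------------------------------------

def fold_its2(
    cassette: SeqRecord,
    five8s_len: int = 25,
    lsu_len: int = 25,
    constraints: FoldingConstraints | None = None,
    params: FoldParams | None = None,
    bulge_tol: int = 3,
) -> SecondaryStructure:
    """Fold a 5.8S-tail + ITS-2 + LSU-head cassette under the constraints.

    The stem is enforced as a hard mask: position ``five8s_len - 1 - k``
    pairs ``L - lsu_len + k`` whenever Watson-Crick/wobble-compatible;
    incompatible positions stay as recorded stem-internal mismatches.  The
    spacer interior is folded to maximum score, decomposed, and validated;
    any violated constraint raises :class:`ConstraintUnsatisfiable`.
    """
    constraints = constraints or FoldingConstraints()
    structure = fold_cassette(
        cassette, five8s_len, lsu_len, constraints.stem_len, params
    )
    try:
        structure = decompose_helices(structure, bulge_tol=bulge_tol)
    except StructureShapeError as exc:
        raise ConstraintUnsatisfiable("multiloop_helices", str(exc)) from exc
    if len(structure.helices) < 4:  # STEM + >= 3
        raise ConstraintUnsatisfiable(
            "multiloop_helices",
            f"only {len(structure.helices) - 1} multiloop helices; 3 required",
        )
    violations = validate_constraints(structure, constraints)
    if violations:
        first = violations[0]
        raise ConstraintUnsatisfiable(first.constraint, first.message)
    return structure


def fold_cassette(
    cassette: SeqRecord,
    five8s_len: int = 25,
    lsu_len: int = 25,
    stem_len: int = 25,
    params: FoldParams | None = None,
) -> SecondaryStructure:
    """Stem-masked maximum-score fold of a cassette, without helix
    decomposition or constraint validation."""
    params = params or FoldParams()
    seq = cassette.sequence
    n = len(seq)
    k = stem_len
    if five8s_len < k or lsu_len < k:
        raise ValueError("flanks shorter than stem_len")
    min_its2 = 2 * (params.min_loop + 2)
    if n < five8s_len + lsu_len + min_its2:
        raise ValueError(
            f"cassette of {n} nt too short for {five8s_len}+{lsu_len} flanks "
            "plus a minimal ITS-2"
        )
    stem_pairs = set()
    for t in range(k):
        i, j = five8s_len - 1 - t, n - lsu_len + t
        if _pair_ok(seq[i], seq[j]):
            stem_pairs.add((i, j))
    lo, hi = five8s_len, n - lsu_len  # ITS-2 proper: [lo, hi)
    inner = SeqRecord("_inner", seq[lo:hi])
    inner_struct = fold_sequence(inner, params)
    pairs = stem_pairs | {(i + lo, j + lo) for i, j in inner_struct.pairs}
    structure = SecondaryStructure(
        cassette,
        frozenset(pairs),
        five8s_len=five8s_len,
        lsu_len=lsu_len,
        score=structure_score(
            SecondaryStructure(cassette, frozenset(pairs)), params
        ),
    )
    return structure
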