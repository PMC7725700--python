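"""Synthetic-data generators with known ground truth.

Every input the pipeline assumes can be generated here with a planted
truth object, so each stage is testable offline:

* ITS-2 cassettes (5.8S tail + three-helix multiloop + LSU head) satisfying
  the three folding constraints, with plantable CBC/HCBC/indel changes at
  chosen barcode positions;
* SSU-like sequences derived from the shipped reference with plantable
  group I intron insertions at chosen reference-mapped anchors;
* haplotype samples realizing a known mutation-step tree with habitat and
  region labels.

All generators are pure functions of (seed, parameters).  Design choices:
loops and spacers are poly-A and variable-region flanks are A/C-only, so
the planted helices are the unique score-optimal structures under the
folding model; basal and apical rungs of planted helices are G-C to anchor
them; mismatch sites are always pyrimidine/pyrimidine.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import barcode as _barcode
from .fold import Helix, Rung, SecondaryStructure
from .seqio import SeqRecord

PAIR_TYPES = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
WC_PAIRS = PAIR_TYPES[:4]
_GC = [("G", "C"), ("C", "G")]
_PYR = ["C", "U"]

REFERENCE_SEED = 7
REFERENCE_LEN = 1542
#: 1-based inclusive variable-region windows in reference coordinates.
V4_WINDOW = (576, 682)
V9_WINDOW = (1380, 1510)
_V4_HAIRPIN = (30, 12)  # (offset into window, rungs)
_V9_HAIRPIN = (40, 14)
_LOOP = "AAAA"


class SynthError(ValueError):
    """Raised for infeasible generator parameters."""


# -- ITS-2 cassettes --------------------------------------------------------

@dataclass
class RungSpec:
    b5: str
    b3: str
    kind: str = "pair"  # or "mismatch"


@dataclass
class CassetteTemplate:
    """Symbolic layout of a cassette; materialized into sequence + pairs."""

    stem: list[RungSpec]  # rung 0 = multiloop-proximal
    helices: list[list[RungSpec]]  # I, II, III; basal rung first
    spacers: list[str]  # around/between the multiloop helices (len = #helices+1)
    loops: list[str]  # hairpin loop per helix
    five8s_extra: str = ""
    lsu_extra: str = ""


@dataclass
class Its2Truth:
    """Planted truth for one synthetic cassette."""

    record: SeqRecord
    structure: SecondaryStructure  # helices populated
    template: CassetteTemplate
    five8s_len: int
    lsu_len: int
    barcode: _barcode.Its2Barcode
    planted_changes: list[tuple[str, int, str]] = field(default_factory=list)


def _materialize(template: CassetteTemplate, rid: str) -> tuple[SeqRecord, SecondaryStructure, int, int]:
    stem_len = len(template.stem)
    five8s_len = stem_len + len(template.five8s_extra)
    lsu_len = stem_len + len(template.lsu_extra)
    parts: list[str] = [template.five8s_extra]
    parts.append("".join(template.stem[k].b5 for k in reversed(range(stem_len))))
    pos = five8s_len
    helix_objs: list[Helix] = []
    interior: list[str] = []

    def emit(s: str) -> None:
        nonlocal pos
        interior.append(s)
        pos += len(s)

    for h, rungs in enumerate(template.helices):
        emit(template.spacers[h])
        m = len(rungs)
        s5 = pos
        emit("".join(r.b5 for r in rungs))
        emit(template.loops[h])
        t = pos
        emit("".join(rungs[m - 1 - q].b3 for q in range(m)))
        helix_objs.append(
            Helix(
                ["I", "II", "III", "IV"][h],
                [
                    Rung(s5 + q, t + (m - 1 - q), paired=(rungs[q].kind == "pair"))
                    for q in range(m)
                ],
            )
        )
    emit(template.spacers[len(template.helices)])
    parts.append("".join(interior))
    parts.append("".join(r.b3 for r in template.stem))
    parts.append(template.lsu_extra)
    seq = "".join(parts)
    n = len(seq)
    pairs = set()
    stem_rungs = []
    for k, r in enumerate(template.stem):
        i, j = five8s_len - 1 - k, n - lsu_len + k
        stem_rungs.append(Rung(i, j, paired=(r.kind == "pair")))
        if r.kind == "pair":
            pairs.add((i, j))
    for h in helix_objs:
        for r in h.rungs:
            if r.paired:
                pairs.add((r.i, r.j))
    record = SeqRecord(rid, seq)
    structure = SecondaryStructure(
        record,
        frozenset(pairs),
        helices=[Helix("STEM", stem_rungs)] + helix_objs,
        five8s_len=five8s_len,
        lsu_len=lsu_len,
    )
    return record, structure, five8s_len, lsu_len


def _truth_from_template(
    template: CassetteTemplate, rid: str, planted=None
) -> tuple[SeqRecord, Its2Truth]:
    record, structure, f, l = _materialize(template, rid)
    bc = _barcode.extract_barcode(structure)
    truth = Its2Truth(record, structure, template, f, l, bc, list(planted or []))
    return record, truth


def gen_its2_cassette(
    seed: int,
    stem_len: int = 25,
    helix_lens: tuple[int, int, int] = (5, 11, 8),
    mismatch_pos: int = 6,
    motif_offset: int = 0,
    loop_len: int = 4,
    spacer_len: int = 3,
    rid: str | None = None,
) -> tuple[SeqRecord, Its2Truth]:
    """Generate a constraint-compliant ITS-2 cassette with planted structure.

    ``helix_lens`` are rung counts for Helices I-III (Helix II includes the
    pyrimidine/pyrimidine mismatch rung); ``mismatch_pos`` is the number of
    Helix II base pairs basal of that mismatch; ``motif_offset`` shifts the
    GGU motif along the Helix III 5' strand.
    """
    h1, h2, h3 = helix_lens
    if h1 < 5 or h2 < 11 or h3 < 4:
        raise SynthError("helix_lens below barcode quotas (>=5, >=11, >=4)")
    if not (1 <= mismatch_pos <= h2 - 2):
        raise SynthError(f"mismatch_pos {mismatch_pos} outside Helix II interior")
    if not (0 <= motif_offset <= h3 - 3):
        raise SynthError("motif_offset leaves no room for GGU in Helix III")
    if loop_len < 3:
        raise SynthError("hairpin loops must be >= 3 nt")
    for attempt in range(_MAX_DRAWS):
        rec, truth = _draw_cassette(
            np.random.default_rng([seed, attempt]),
            stem_len, (h1, h2, h3), mismatch_pos, motif_offset,
            loop_len, spacer_len,
            rid or f"synthetic_its2_seed{seed}",
        )
        if _folds_to_truth(rec, truth):
            return rec, truth
    raise SynthError(  # pragma: no cover - draws virtually always succeed
        f"no recoverable cassette found for seed {seed} after {_MAX_DRAWS} draws"
    )


_MAX_DRAWS = 25


def _folds_to_truth(rec: SeqRecord, truth: "Its2Truth") -> bool:
    """True iff the stem-masked folder recovers exactly the planted pairs
    (constraint compliance is the caller's concern, so deliberately
    non-compliant cassettes still generate)."""
    from .fold import fold_cassette

    stem_len = len(truth.template.stem)
    folded = fold_cassette(rec, truth.five8s_len, truth.lsu_len, stem_len)
    return set(folded.pairs) == set(truth.structure.pairs)


def _draw_cassette(
    rng, stem_len, helix_lens, mismatch_pos, motif_offset, loop_len, spacer_len, rid
) -> tuple[SeqRecord, "Its2Truth"]:
    h1, h2, h3 = helix_lens

    def draw_pair():
        return PAIR_TYPES[rng.integers(len(PAIR_TYPES))]

    def draw_wc():
        # multiloop helices are planted from Watson-Crick pairs only, so the
        # planted ladder is the strict score optimum; wobble (code 5/6)
        # rungs enter through planted HCBCs
        return WC_PAIRS[rng.integers(len(WC_PAIRS))]

    def draw_gc():
        return _GC[rng.integers(2)]

    stem = [RungSpec(*draw_pair()) for _ in range(stem_len)]
    helices: list[list[RungSpec]] = []
    for h, m in enumerate((h1, h2, h3)):
        rungs = [RungSpec(*draw_wc()) for _ in range(m)]
        rungs[0] = RungSpec(*draw_gc())
        rungs[-1] = RungSpec(*draw_gc())
        helices.append(rungs)
    # Helix II: coded mismatch after `mismatch_pos` pairs
    helices[1][mismatch_pos] = RungSpec(
        _PYR[rng.integers(2)], _PYR[rng.integers(2)], kind="mismatch"
    )
    # Helix III: GGU on the 5' strand (strong partners)
    for off, (b5, b3) in zip(
        range(motif_offset, motif_offset + 3), [("G", "C"), ("G", "C"), ("U", "A")]
    ):
        helices[2][off] = RungSpec(b5, b3)
    template = CassetteTemplate(
        stem=stem,
        helices=helices,
        spacers=["A" * spacer_len] * 4,
        loops=["A" * loop_len] * 3,
    )
    return _truth_from_template(template, rid)


def plant_changes(
    truth: Its2Truth,
    changes: list[tuple[str, int, str]],
    seed: int,
    rid: str | None = None,
) -> tuple[SeqRecord, Its2Truth]:
    """Plant CBC/HCBC/indel changes at chosen barcode rungs.

    ``changes`` entries are ``(segment, rung_position_1based, class)`` with
    segment in {STEM, I, II, III} and class in {CBC, HCBC, indel}.  The
    mutated cassette's true barcode differs from the original exactly per
    the list.

    The truth structure is authoritative; replacement pairs are re-drawn a
    few times so that, whenever possible, the mutant cassette also folds
    back to its planted structure.
    """
    has_subs = any(c[2] in ("CBC", "HCBC") for c in changes)
    first = None
    for attempt in range(_MAX_DRAWS if has_subs else 1):
        rec, new_truth = _draw_plant(
            np.random.default_rng([seed, attempt]), truth, changes, rid
        )
        if first is None:
            first = (rec, new_truth)
        if _folds_to_truth(rec, new_truth):
            return rec, new_truth
    return first


def _draw_plant(rng, truth, changes, rid):
    template = copy.deepcopy(truth.template)
    seg_map = {
        "STEM": template.stem,
        "I": template.helices[0],
        "II": template.helices[1],
        "III": template.helices[2],
        "HELIX_I": template.helices[0],
        "HELIX_II": template.helices[1],
        "HELIX_III": template.helices[2],
    }
    subs = [c for c in changes if c[2] in ("CBC", "HCBC")]
    dels = [c for c in changes if c[2] == "indel"]
    bad = [c for c in changes if c[2] not in ("CBC", "HCBC", "indel")]
    if bad:
        raise SynthError(f"unknown change class in {bad[0]}")
    for segment, pos, klass in subs:
        rungs = seg_map.get(segment)
        if rungs is None:
            raise SynthError(f"unknown segment {segment!r}")
        if not (1 <= pos <= len(rungs)):
            raise SynthError(f"position {pos} outside segment {segment}")
        r = rungs[pos - 1]
        if r.kind != "pair":
            raise SynthError(
                f"{segment} rung {pos} is a mismatch; no valid replacement pair"
            )
        if klass == "CBC":
            cands = [p for p in PAIR_TYPES if p[0] != r.b5 and p[1] != r.b3]
        else:
            cands = [p for p in PAIR_TYPES if (p[0] != r.b5) != (p[1] != r.b3)]
        if not cands:
            raise SynthError(f"no {klass} replacement for {r.b5}-{r.b3}")
        b5, b3 = cands[rng.integers(len(cands))]
        rungs[pos - 1] = RungSpec(b5, b3)
    for segment, pos, klass in sorted(dels, key=lambda c: -c[1]):
        if segment == "STEM":
            raise SynthError("cannot plant an indel in the forced stem")
        rungs = seg_map.get(segment)
        if rungs is None:
            raise SynthError(f"unknown segment {segment!r}")
        if not (1 <= pos <= len(rungs)):
            raise SynthError(f"position {pos} outside segment {segment}")
        del rungs[pos - 1]
    rid = rid or f"{truth.record.id}_mut"
    rec, new_truth = _truth_from_template(template, rid, planted=changes)
    return rec, new_truth


def plant_loop_changes(
    truth: Its2Truth, n_changes: int, seed: int, rid: str | None = None
) -> tuple[SeqRecord, Its2Truth]:
    """Mutate unpaired loop/spacer bases only (variable-region changes).

    The conserved-region barcode is untouched, emulating conspecific strains
    that differ by a few bases outside the barcode.
    """
    rng = np.random.default_rng(seed)
    template = copy.deepcopy(truth.template)
    slots = [("loop", k, p) for k, s in enumerate(template.loops) for p in range(len(s))]
    slots += [
        ("spacer", k, p) for k, s in enumerate(template.spacers) for p in range(len(s))
    ]
    if n_changes > len(slots):
        raise SynthError("more loop changes requested than loop bases")
    picks = rng.choice(len(slots), size=n_changes, replace=False)
    for s in picks:
        kind, k, p = slots[int(s)]
        target = template.loops if kind == "loop" else template.spacers
        old = target[k]
        # A -> C keeps the region unpairable with the poly-A context
        newb = "C" if old[p] != "C" else "A"
        target[k] = old[:p] + newb + old[p + 1:]
    rid = rid or f"{truth.record.id}_var"
    return _truth_from_template(template, rid, planted=truth.planted_changes)


def gen_species_panel(seed: int) -> dict:
    """Three species-level cassettes plus a conspecific variant.

    Emulates the three-species situation the ITS-2/CBC approach is used
    for: species A, a variant of A differing only at two unpaired
    (variable-region) bases, and species B and C each separated from A by
    2 CBCs and 4 HCBCs at distinct conserved-region positions — so the
    union over all pairwise comparisons holds 4 CBCs and 8 HCBCs.  HCBCs
    are planted in the (constraint-forced) stem and CBCs in helix
    interiors; draws are rejected until every cassette folds back to its
    planted structure, so the full fold -> barcode -> delimit pipeline
    recovers the planted truth exactly.
    """
    # legal CBC rungs: helix interiors away from the G-C anchor rungs, the
    # Helix II mismatch (rung 7) and the Helix III GGU motif (rungs 1-3)
    helix_pool = (
        [("I", p) for p in (2, 3, 4)]
        + [("II", p) for p in (2, 3, 4, 5, 6, 8, 9, 10)]
        + [("III", p) for p in (4, 5, 6, 7)]
    )
    for attempt in range(_MAX_DRAWS):
        rng = np.random.default_rng([seed, attempt, 17])
        base_seed = int(rng.integers(2 ** 31 - 1))
        rec_a, truth_a = gen_its2_cassette(seed=base_seed, rid="speciesA")
        cbc_picks = [helix_pool[int(k)] for k in rng.choice(len(helix_pool), 4, replace=False)]
        stem_picks = [int(p) for p in rng.choice(np.arange(1, 17), 8, replace=False)]
        spec_b = [(s, p, "CBC") for s, p in cbc_picks[:2]]
        spec_b += [("STEM", p, "HCBC") for p in stem_picks[:4]]
        spec_c = [(s, p, "CBC") for s, p in cbc_picks[2:]]
        spec_c += [("STEM", p, "HCBC") for p in stem_picks[4:]]
        rec_a2, truth_a2 = plant_loop_changes(
            truth_a, 2, seed=base_seed + 1, rid="speciesA_var"
        )
        rec_b, truth_b = plant_changes(truth_a, spec_b, seed=base_seed + 2, rid="speciesB")
        rec_c, truth_c = plant_changes(truth_a, spec_c, seed=base_seed + 3, rid="speciesC")
        panel = {
            "records": [rec_a, rec_a2, rec_b, rec_c],
            "truths": [truth_a, truth_a2, truth_b, truth_c],
            "specs": {"speciesB": spec_b, "speciesC": spec_c},
        }
        if all(_folds_to_truth(r, t) for r, t in zip(panel["records"], panel["truths"])):
            return panel
    raise SynthError("no species panel draw folds to its truth")  # pragma: no cover


# -- SSU sequences with introns ---------------------------------------------

def _rand_bases(rng, n: int, alphabet: str = "ACGU") -> str:
    return "".join(alphabet[int(k)] for k in rng.integers(len(alphabet), size=n))


def make_reference(seed: int = REFERENCE_SEED) -> tuple[SeqRecord, dict]:
    """Construct the shipped synthetic SSU reference (a stand-in for the
    E. coli 16S numbering reference, which is not redistributed here).

    The V4 and V9 windows carry designed hairpins over A/C-only flanks so
    the variable-region folding stages have a unique optimal structure.
    Returns the record and an info dict with window coordinates and the
    0-based hairpin rung coordinates.
    """
    from .fold import fold_sequence

    for attempt in range(_MAX_DRAWS):
        rng = np.random.default_rng([seed, attempt])
        seq = list(_rand_bases(rng, REFERENCE_LEN))
        info: dict = {"windows": {"V4": V4_WINDOW, "V9": V9_WINDOW}, "hairpins": {}}
        ok = True
        for region, window, (off, n_rungs) in (
            ("V4", V4_WINDOW, _V4_HAIRPIN),
            ("V9", V9_WINDOW, _V9_HAIRPIN),
        ):
            lo, hi = window[0] - 1, window[1]  # 0-based half-open
            for k in range(lo, hi):
                seq[k] = "A"
            start = lo + off
            rungs = []
            # all-G-C rungs over inert poly-A flanks: the planted hairpin is
            # the strict score optimum, and stays so after single CBC/HCBC
            # edits (any steal by a flank base costs at least one stack)
            pair_choices = [_GC[int(rng.integers(2))] for _ in range(n_rungs)]
            for q, (b5, b3) in enumerate(pair_choices):
                i = start + q
                j = start + 2 * n_rungs + len(_LOOP) - 1 - q
                seq[i], seq[j] = b5, b3
                rungs.append((i, j))
            for q, ch in enumerate(_LOOP):
                seq[start + n_rungs + q] = ch
            info["hairpins"][region] = rungs
            window_seq = "".join(seq[lo:hi])
            folded = fold_sequence(SeqRecord("_w", window_seq))
            planted = {(i - lo, j - lo) for i, j in rungs}
            if set(folded.pairs) != planted:
                ok = False
                break
        if ok:
            return SeqRecord("SSU_REF_SYNTHETIC", "".join(seq)), info
    raise SynthError(  # pragma: no cover
        "no reference draw with recoverable hairpins"
    )


def default_reference() -> SeqRecord:
    """Load the packaged synthetic SSU reference."""
    from . import seqio

    with resources.as_file(
        resources.files("its2delim.data") / "ssu_reference_synthetic.fasta"
    ) as path:
        return seqio.read_fasta(path)[0]


@dataclass
class SsuTruth:
    """Planted truth for one synthetic SSU sequence."""

    exon: SeqRecord
    #: (reference anchor, query start, query end, length); 1-based inclusive
    introns: list[tuple[int, int, int, int]]


def gen_ssu(
    seed: int,
    reference: SeqRecord | None = None,
    sub_rate: float = 0.0,
    introns: list[tuple[int, int]] | None = None,
    rid: str | None = None,
) -> tuple[SeqRecord, SsuTruth]:
    """Derive an SSU-like sequence from the reference and insert introns.

    ``introns`` is a list of (anchor, length): the anchor is the 1-based
    reference coordinate of the last exon base 5' of the insertion.  Intron
    ends are chosen to mismatch the flanking exon bases, so the insertion
    cannot slide in an optimal alignment.
    """
    reference = reference or default_reference()
    introns = sorted(introns or [])
    rng = np.random.default_rng(seed)
    ref = reference.sequence
    anchors = [a for a, _ in introns]
    if len(set(anchors)) != len(anchors):
        raise SynthError("overlapping introns: duplicate anchors")
    for a, length in introns:
        if not (1 <= a <= len(ref) - 1):
            raise SynthError(f"anchor {a} outside the reference")
        if length < 1:
            raise SynthError("intron length must be >= 1")
    exon = list(ref)
    if sub_rate > 0:
        # exon bases flanking an insertion junction are kept unmutated so
        # the optimal alignment cannot slide the intron gap
        protected = {
            k
            for a, _ in introns
            for k in range(max(0, a - 4), min(len(exon), a + 4))
        }
        hits = [
            k
            for k in np.nonzero(rng.random(len(exon)) < sub_rate)[0]
            if int(k) not in protected
        ]
        for k in hits:
            others = [b for b in "ACGU" if b != exon[k]]
            exon[k] = others[int(rng.integers(3))]
    exon_s = "".join(exon)
    parts = []
    truth_introns = []
    prev = 0
    offset = 0
    for a, length in introns:
        parts.append(exon_s[prev:a])
        iseq = list(_rand_bases(rng, length))
        nxt = exon_s[a] if a < len(exon_s) else None  # base following the insertion
        if nxt is not None and iseq[0] == nxt:
            iseq[0] = "ACGU"[("ACGU".index(nxt) + 1) % 4]
        if iseq[-1] == exon_s[a - 1]:
            iseq[-1] = "ACGU"[("ACGU".index(exon_s[a - 1]) + 1) % 4]
        parts.append("".join(iseq))
        q_start = a + offset + 1
        truth_introns.append((a, q_start, q_start + length - 1, length))
        offset += length
        prev = a
    parts.append(exon_s[prev:])
    rid = rid or f"synthetic_ssu_seed{seed}"
    query = SeqRecord(rid, "".join(parts))
    return query, SsuTruth(SeqRecord(rid + "_exon", exon_s), truth_introns)


# -- V9 haplotype panel -----------------------------------------------------

def _apply_rung_change(seq: list[str], rung: tuple[int, int], klass: str, rng) -> None:
    b5, b3 = seq[rung[0]], seq[rung[1]]
    if klass == "CBC":
        cands = [p for p in PAIR_TYPES if p[0] != b5 and p[1] != b3]
    else:
        cands = [p for p in PAIR_TYPES if (p[0] != b5) != (p[1] != b3)]
    nb5, nb3 = cands[int(rng.integers(len(cands)))]
    seq[rung[0]], seq[rung[1]] = nb5, nb3


def gen_v9_panel(seed: int = 0) -> list[tuple[SeqRecord, str]]:
    """Five V9 haplotypes emulating the five-haplotype situation in the
    reference organisms: 1 vs 2 differ by exactly one HCBC in the V9 helix,
    3 vs 4 by exactly one CBC; 3 and 5 differ from 1 at unpaired sites.
    """
    from .fold import fold_sequence

    ref, info = make_reference()
    lo, hi = V9_WINDOW[0] - 1, V9_WINDOW[1]
    window = list(ref.sequence[lo:hi])
    rungs = [(i - lo, j - lo) for i, j in info["hairpins"]["V9"]]
    planted = set(rungs)
    # unpaired flank coordinates well away from the hairpin
    flank = [2, 5, 9, 12]

    for attempt in range(_MAX_DRAWS):
        rng = np.random.default_rng([seed, attempt])

        def variant(changes) -> list[str]:
            s = list(window)
            for kind, arg in changes:
                if kind in ("CBC", "HCBC"):
                    _apply_rung_change(s, rungs[arg], kind, rng)
                else:  # unpaired flank change (A->C stays unpairable)
                    s[arg] = "C" if s[arg] == "A" else "A"
            return s

        hap1 = variant([])
        hap2 = variant([("HCBC", 4)])
        hap3 = variant([("CBC", 2), ("flank", flank[0]), ("flank", flank[1])])
        hap4 = [c for c in hap3]
        _apply_rung_change(hap4, rungs[7], "CBC", rng)
        hap5 = variant([("HCBC", 9), ("flank", flank[2])])
        haps = [("1", hap1), ("2", hap2), ("3", hap3), ("4", hap4), ("5", hap5)]
        if all(
            set(fold_sequence(SeqRecord("_v", "".join(s))).pairs) == planted
            for _, s in haps
        ):
            return [
                (SeqRecord(f"V9_hap{label}", "".join(s)), label) for label, s in haps
            ]
    raise SynthError("no V9 panel draw with recoverable hairpins")  # pragma: no cover


# -- haplotype samples ------------------------------------------------------

DEFAULT_METADATA_PROBS = {
    "habitat": {
        "freshwater": 0.45,
        "soil": 0.2,
        "marine": 0.1,
        "endosymbiont-sponge": 0.2,
        "unknown": 0.05,
    },
    "region": {"Europe": 0.5, "Asia": 0.25, "North America": 0.25},
}


def gen_haplotype_sample(
    seed: int,
    n: int,
    length: int,
    step_graph=None,
    weights: dict | None = None,
    metadata_probs: dict | None = None,
):
    """Sample sequences realizing a known mutation-step tree.

    Each edge of ``step_graph`` (a tree) mutates one previously untouched
    position, so pairwise Hamming distances equal tree path lengths and the
    collapsed haplotype network equals the tree whenever the connection
    limit suffices.  Returns (records, MetadataTable, truth) where truth
    maps node -> (sequence, count).
    """
    import networkx as nx

    from .seqio import MetadataTable

    if step_graph is None:
        step_graph = nx.path_graph(3)
    step_graph = nx.relabel_nodes(step_graph, {v: str(v) for v in step_graph})
    if not nx.is_tree(step_graph):
        raise SynthError("step_graph must be a connected tree")
    n_nodes = step_graph.number_of_nodes()
    if step_graph.number_of_edges() > length:
        raise SynthError("more step-graph edges than sequence positions")
    if n < n_nodes:
        raise SynthError(f"need n >= {n_nodes} to observe every haplotype")
    rng = np.random.default_rng(seed)
    nodes = sorted(step_graph.nodes)
    root = nodes[0]
    free = list(rng.permutation(length))
    seqs = {root: list(_rand_bases(rng, length))}
    for parent, child in nx.bfs_edges(step_graph, root):
        pos = int(free.pop())
        s = list(seqs[parent])
        others = [b for b in "ACGU" if b != s[pos]]
        s[pos] = others[int(rng.integers(3))]
        seqs[child] = s
    w = np.array([(weights or {}).get(v, 1.0) for v in nodes], dtype=float)
    extra = rng.multinomial(n - n_nodes, w / w.sum())
    counts = {v: 1 + int(e) for v, e in zip(nodes, extra)}
    probs = metadata_probs or DEFAULT_METADATA_PROBS
    hab_labels = list(probs["habitat"])
    hab_p = np.array(list(probs["habitat"].values()), dtype=float)
    reg_labels = list(probs["region"])
    reg_p = np.array(list(probs["region"].values()), dtype=float)
    records = []
    meta_rows = {}
    k = 0
    for v in nodes:
        for _ in range(counts[v]):
            rid = f"s{k:03d}"
            records.append(SeqRecord(rid, "".join(seqs[v]), {"haplotype": v}))
            meta_rows[rid] = {
                "habitat": hab_labels[int(rng.choice(len(hab_labels), p=hab_p / hab_p.sum()))],
                "region": reg_labels[int(rng.choice(len(reg_labels), p=reg_p / reg_p.sum()))],
                "haplotype_label": v,
            }
            k += 1
    table = MetadataTable.from_rows(meta_rows)
    truth = {v: ("".join(seqs[v]), counts[v]) for v in nodes}
    return records, table, truth
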