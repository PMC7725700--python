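# Methods

`its2delim` reimplements, as one tested pipeline, the molecular toolkit
used to delimit coccoid green-algal species (e.g. *Choricystis* and
*Chlorella*-like sponge endosymbionts) from nuclear rDNA: constrained
ITS-2 secondary-structure prediction, conserved-region barcoding with
compensatory-base-change (CBC) analysis, SSU group I intron and
variable-region (V4/V9) utilities, and statistical-parsimony haplotype
networks. This note records the models, the tunable parameters, the
numerical choices, and what the synthetic-data generators do and do not
emulate.

## Constrained ITS-2 folding

The ITS-2 cassette is the 3' tail of the 5.8S rRNA, the spacer itself, and
the 5' head of the LSU rRNA. Three hard constraints define a biologically
meaningful fold for green algae:

1. **5.8S/LSU stem** — the last `stem_len` (default 25) 5.8S bases must
   bind the first `stem_len` LSU bases. Enforced as a hard mask: position
   `five8s_len − 1 − k` pairs `L − lsu_len + k` whenever the bases are
   Watson-Crick/wobble compatible; incompatible positions remain as
   recorded stem-internal mismatches rather than failures, because real
   stems contain occasional non-pairing rungs.
2. **Helix II processing site** — a pyrimidine/pyrimidine mismatch must sit
   after the 5th-7th base pair of Helix II (`helix2_mismatch_window`,
   default `5..7`, counted as the number of paired rungs basal of the
   mismatch).
3. **Helix III motif** — `GGU` must lie on the 5' strand of Helix III
   within the first `motif_max_offset` (default 6) nt.

**Scoring model.** Full Turner thermodynamics is out of scope; the folder
is a weighted Nussinov dynamic program: pair weights G-C = 3, A-U = 2,
G-U = 1, +1 for each stacked adjacent pair, minimum hairpin loop 3 nt,
IUPAC ambiguity codes unpairable. The spacer interior is folded to the
score optimum given the stem mask; the result is decomposed into helices
and the three constraints are then checked, raising
`ConstraintUnsatisfiable` (naming the first failed constraint) when
violated. We deliberately check constraints on the optimum rather than
searching suboptimal structures for a satisfying one: inputs whose optimal
fold is non-compliant are flagged instead of silently coerced, and
compliant inputs (including every generated cassette) fold to compliant
optima. Externally computed dot-bracket structures (mfold/RNAfold output
in Vienna format) can be supplied instead, so every downstream stage is
engine-agnostic.

**Determinism.** Co-optimal structures are resolved by a fixed traceback:
the leftmost base pairs first, with its nearest score-optimal partner.
Identical input and parameters always yield the identical structure.

**Helix decomposition.** Pairs are chained into helices across
interruptions of at most `bulge_tol` (default 3) unpaired bases per side;
1×1 interior loops are kept in the ladder as *coded mismatches* (they
become barcode code 7). The helix containing the outermost pair is the
STEM; helices emerging from the multiloop it closes are labelled I, II,
III (IV) in 5'→3' order. Rungs are reported basal (multiloop-proximal)
first — the alignment-stable end in the ITS-2 literature.

## Conserved-region barcode and CBC classification

The barcode takes the 16 basal stem rungs, 5 basal Helix I rungs, 11 basal
Helix II rungs (including the processing-site mismatch) and all Helix III
rungs, each written as a one-digit code (1 = A-U, 2 = U-A, 3 = G-C,
4 = C-G, 5 = G·U, 6 = U·G, 7 = mismatch, 8 = deletion/insertion or single
base). Helices shorter than their quota are padded with 8 and flagged
partial.

Barcodes are aligned segment-by-segment (STEM vs STEM, …) with a
Needleman-Wunsch alignment on code strings (match 1, mismatch 0, gap −1).
The traceback walks forward over a suffix-score matrix preferring the
diagonal, so a gap is introduced only when strictly required and sits as
late (apically) as possible — a gratuitous gap pair can otherwise tie with
two mismatch columns and corrupt the change classification.

Per aligned column: **CBC** if both codes are canonical (1-6) and *both*
partner bases differ; **HCBC** if exactly one partner differs; **indel**
if exactly one side is 8; **mismatch-shift** if exactly one side is 7;
**unpaired-change** when both sides are 7 (or both 8) with different
underlying bases — the enumerated classes leave that combination open, and
"bases changed, pairing status unchanged" is the closest description.
Classification therefore carries the underlying bases alongside the codes
(1 vs 2 is a CBC even though a single code digit changes).

Species delimitation links two taxa iff their conserved regions show zero
CBCs; connected components are the candidate species. Because "total
changes across three taxa" is ambiguous between a union and a sum of
pairwise counts, both tallies are reported; the union places all barcodes
on the coordinates of the longest one (columns inserted relative to that
anchor are dropped — acceptable at the ≤1-indel scale the tool targets).

**Known limitation.** When a substitution and an indel fall next to each
other inside one short segment, the optimal code alignment can
legitimately re-interpret the column combination (e.g. a gap column
absorbing a substituted rung inside a run of identical codes). Planted
change counts are therefore guaranteed recoverable only when indels are
not adjacent to substitutions within a segment; the test suite pins
exactly that contract.

## SSU utilities

**Coordinate mapping.** Query SSU sequences are aligned to a numbering
reference with Biopython's `PairwiseAligner` (global mode with free end
gaps; match 2, mismatch −1, gap open −8, extension −0.05). The
near-free extension lets multi-hundred-nt introns align as single gaps
even a few tens of nt from the sequence end, where a free end gap would
otherwise swallow the terminal exon. The first optimal alignment is taken;
Biopython's enumeration order makes that deterministic.

**Intron detection.** Every unaligned query block of at least
`min_intron_len` (default 100) nt is reported as a putative group I
intron; its anchor is the reference coordinate of the last exon base 5' of
the insertion, matching the classical naming convention ("position 1512").
Group I introns are hundreds of nt long; the 100-nt floor avoids calling
alignment noise. Excision concatenates the exon blocks and is the exact
inverse of planting.

**Numbering reference.** Positions are expressed in E. coli-style SSU
coordinates. The shipped reference
(`data/ssu_reference_synthetic.fasta`, 1542 nt) is a *synthetic*
stand-in constructed by `synth.make_reference`: the canonical E. coli
sequence is not redistributed with the package, and all shipped analyses
are synthetic end-to-end. Any real reference (e.g. GenBank J01695) can be
supplied via the `reference` config key and the same coordinates apply.
V4 and V9 windows default to 576-682 and 1380-1510 (1-based, inclusive)
and are configurable, since exact window bounds differ among authors.

**Variable sites.** A column of an equal-length alignment is variable iff
it holds ≥ 2 distinct unambiguous bases; gaps and ambiguity codes are
ignored. Published variable-site counts depend on the authors' manual,
structure-guided alignments, so exact reproduction of literature values is
not promised; the function is exercised on synthetic panels.

**V9 haplotypes.** V9 segments are folded with the same engine; the helix
rungs (including 1×1 coded mismatches) are encoded with the barcode
alphabet and classified exactly as ITS-2 barcodes. Haplotype labels 1, 2, …
go to distinct paired-position profiles by decreasing frequency then
first-seen order; variants within a profile differing only at unpaired
positions get lowercase suffixes (1a, 1b, …).

## Statistical-parsimony networks

Identical aligned sequences collapse into nodes carrying frequency and
habitat/region tallies. Agglomeration connects all pairs at one mutational
step, then pairs at 2, 3, … steps (inserting unobserved median nodes, one
per step) while they are still in different components, up to the
connection limit. Ties are processed higher-frequency-first, then by
lexicographic id; median chains change one differing site per step, always
taking the lexicographically smallest intermediate; existing nodes are
reused when an intermediate sequence already occurs. Every edge is exactly
one step; gaps count as a fifth character state by default (a single indel
is one step) or can be ignored per column.

**Connection limit.** The cited TCS literature does not restate its
formulas, so the package documents its own estimator of the same quantity:
sites accumulate substitutions as i.i.d. Poisson counts, substitutions
move between bases Jukes-Cantor fashion, and the per-site divergence is
the plug-in `d = j/m`. With `mu` solving `d = 3/4 (1 − exp(−4 mu/3))`,
`r1` the probability a visibly differing site changed exactly once and
`s0` the probability an identical-looking site never changed, the
parsimony probability of `j` observed differences over `m` sites is
`r1^j · s0^(m−j)`; the limit is the largest `j` keeping this at or above
`prob` (default 0.95, the conventional level), with a floor of one step.
The estimate is non-decreasing in `m`; at alignment scale (1780 bp) the
default limit is 13 steps. A `max_steps` override bypasses the estimator.
The test suite cross-checks the closed form against an independent
evaluation that sums the Poisson series with the exact per-event
Jukes-Cantor difference probability.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (seed, parameters) and every planted
truth is accepted by its analysis stage.

* **ITS-2 cassettes** (`gen_its2_cassette`): a stem of `stem_len` random
  pairs plus three multiloop helices (default rung counts 5/11/8 with the
  Helix II mismatch after 6 pairs and GGU at the Helix III start), poly-A
  loops (4 nt) and spacers (3 nt). Multiloop rungs are drawn from
  Watson-Crick pairs with G-C anchors at each helix end, so the planted
  ladder is the strict score optimum over the inert loops; wobble codes
  (5/6) enter through planted HCBCs. Each draw is verified by refolding
  and rejected (deterministically, ~1% of draws) if any alternative
  structure ties or beats the plant.
* **Planted changes** (`plant_changes`): CBC/HCBC/indel edits at chosen
  rungs; replacement pairs are re-drawn a bounded number of times so the
  mutant also refolds to its planted structure whenever possible. The
  truth structure, not the refold, is authoritative.
* **Species panels** (`gen_species_panel`): two species-level mutants each
  2 CBCs + 4 HCBCs from a common base (union 4 CBCs + 8 HCBCs), plus a
  conspecific variant differing at two unpaired bases; HCBCs go to the
  constraint-forced stem and CBCs to helix interiors, keeping every
  cassette fold-recoverable for any seed.
* **SSU sequences** (`gen_ssu`): the reference mutated i.i.d. per site at
  `sub_rate`, with random-sequence introns inserted after chosen anchors.
  Intron ends are chosen to mismatch the flanking exon bases and the four
  exon bases around each junction are kept unmutated, so the optimal
  alignment cannot slide an insertion — anchor recovery is exact up to
  `sub_rate` 0.05.
* **Haplotype samples** (`gen_haplotype_sample`): sequences realizing a
  mutation-step tree, one fresh position per edge, so pairwise Hamming
  distances equal tree path lengths; each haplotype is observed at least
  once and metadata labels are drawn from configurable habitat/region
  frequencies.
* **Variable-site panels**: strains derive from the reference at
  `sub_rate` 0.002 per site — a typical intra-genus SSU divergence — which
  puts multi-strain variable-site fractions in the low-percent range seen
  in real genus-level alignments.

What passing on this synthetic data shows: the algorithms recover planted
structure, changes, anchors and networks exactly under the stated models.
What it does not show: robustness to real thermodynamic folding (Turner
energies, pseudoknots, Helix IV), to alignment-ambiguous natural ITS-2
variation, to chimeric or low-identity SSU reads, or to recombination in
haplotype data. The i.i.d. substitution model has no rate heterogeneity
or indel process beyond what is planted.

## Degenerate inputs and edge behavior

Empty FASTA files, duplicate ids, unbalanced dot-brackets (position
reported), ragged alignments and unknown metadata labels raise typed
errors (CLI exit code 2); unsatisfiable folding constraints name the first
failed constraint (exit code 3). Sequences shorter than
`2·stem_len + minimal ITS-2` are rejected before folding. Structures with
fewer than two multiloop helices are a shape error; barcodes from
truncated helices are padded and flagged partial rather than rejected.
Problem sizes used by the shipped tests and the acceptance script
(cassettes ≈ 120 nt, SSU ≈ 1.5-2.6 knt, ≤ 200-sequence folding panels)
were chosen so the whole suite runs in well under a minute per module on a
single CPU.
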