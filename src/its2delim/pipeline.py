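"""End-to-end workflows: ITS-2/CBC species delimitation and SSU surveys.

``run_delimit`` takes ITS-2 cassettes (optionally with externally computed
dot-bracket structures), folds and validates them, extracts conserved-region
barcodes, classifies pairwise changes and partitions the taxa into
candidate species (zero CBCs = conspecific).

``run_survey`` takes SSU sequences plus metadata, excises group I introns,
extracts the V4/V9 variable regions, labels V9 haplotypes and exports a
statistical-parsimony network per region.

Outputs are plain TSV/FASTA/GML; re-running with an identical config and
inputs reproduces byte-identical files.  Every table starts with a header
comment recording the package version and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import __version__, barcode, fold, network, seqio, ssu

logger = logging.getLogger("its2delim")


class InputError(ValueError):
    """Bad or missing user input (exit code 2 territory)."""


@dataclass
class RunConfig:
    """Flat run configuration; every CLI flag overrides one key."""

    input: str = ""
    metadata: str = ""
    structures: str = ""  # optional Vienna file with precomputed structures
    outdir: str = "its2delim_out"
    engine: str = "internal"  # or "vienna-file"
    stem_len: int = 25
    five8s_len: int = 25
    lsu_len: int = 25
    mismatch_window: str = "5:7"
    motif: str = "GGU"
    bulge_tol: int = 3
    reference: str = ""  # FASTA path; empty = shipped synthetic reference
    v4_window: str = "576:682"
    v9_window: str = "1380:1510"
    min_intron_len: int = 100
    prob: float = 0.95
    max_steps: int = 0  # 0 = use the statistical connection limit
    gap_mode: str = "state"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cfg = cls()
        casts = {f.name: type(getattr(cfg, f.name)) for f in fields(cls)}
        for line_no, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise InputError(f"{path}:{line_no}: expected key = value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in casts:
                raise InputError(f"{path}:{line_no}: unknown config key {key!r}")
            setattr(cfg, key, casts[key](value))
        return cfg

    def window(self, region: str) -> tuple[int, int]:
        raw = self.v4_window if region == "V4" else self.v9_window
        lo, _, hi = raw.partition(":")
        return int(lo), int(hi)

    def constraints(self) -> fold.FoldingConstraints:
        lo, _, hi = self.mismatch_window.partition(":")
        return fold.FoldingConstraints(
            stem_len=self.stem_len,
            helix2_mismatch_window=(int(lo), int(hi)),
            helix3_motif=self.motif,
        )

    def reference_record(self) -> seqio.SeqRecord:
        if self.reference:
            return seqio.read_fasta(self.reference)[0]
        from .synth import default_reference

        return default_reference()


def _write_tsv(frame: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# its2delim {__version__} seed={seed}\n")
        frame.to_csv(fh, sep="\t", index=False)


@dataclass
class DelimitBundle:
    structures: list[fold.SecondaryStructure]
    barcodes: list[barcode.Its2Barcode]
    result: barcode.DelimitResult
    tallies: dict


def run_delimit(config: RunConfig) -> DelimitBundle:
    """Fold -> decompose -> barcode -> compare -> delimit, writing a report
    bundle (barcodes.tsv, changes.tsv, partition.tsv, summary.tsv)."""
    if not config.input:
        raise InputError("delimit workflow needs an input FASTA")
    records = seqio.read_fasta(config.input)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    constraints = config.constraints()
    provided = {}
    if config.engine == "vienna-file":
        if not config.structures:
            raise InputError("engine=vienna-file needs a structures path")
        provided = {s.record.id: s for s in seqio.read_vienna(config.structures)}
    structures = []
    for rec in records:
        if config.engine == "vienna-file":
            if rec.id not in provided:
                raise InputError(f"no Vienna structure for {rec.id!r}")
            s = provided[rec.id]
            s = fold.decompose_helices(s, bulge_tol=config.bulge_tol)
            s.five8s_len = config.five8s_len
            s.lsu_len = config.lsu_len
            for v in fold.validate_constraints(s, constraints):
                logger.warning("%s: constraint violation: %s: %s", rec.id, v.constraint, v.message)
        else:
            try:
                s = fold.fold_its2(
                    rec,
                    config.five8s_len,
                    config.lsu_len,
                    constraints,
                    bulge_tol=config.bulge_tol,
                )
            except fold.ConstraintUnsatisfiable as exc:
                raise fold.ConstraintUnsatisfiable(
                    exc.constraint, f"sequence {rec.id!r}: {exc}"
                ) from exc
        structures.append(s)
    barcodes = [barcode.extract_barcode(s) for s in structures]
    result = barcode.delimit_species(barcodes)
    tallies = barcode.union_and_sum_tallies(barcodes)

    _write_tsv(
        pd.concat([bc.to_frame() for bc in barcodes], ignore_index=True),
        outdir / "barcodes.tsv",
        config.seed,
    )
    if result.reports:
        _write_tsv(
            pd.concat(
                [rep.to_frame() for rep in result.reports.values()],
                ignore_index=True,
            ),
            outdir / "changes.tsv",
            config.seed,
        )
    part = pd.DataFrame(
        [
            {"id": rid, "species_component": k + 1}
            for k, comp in enumerate(result.components)
            for rid in comp
        ]
    )
    _write_tsv(part, outdir / "partition.tsv", config.seed)
    summary = pd.DataFrame(
        [
            {
                "n_taxa": len(barcodes),
                "n_species": result.n_species,
                "cbc_union": tallies["union"]["CBC"],
                "hcbc_union": tallies["union"]["HCBC"],
                "indel_union": tallies["union"]["indel"],
                "cbc_sum": tallies["sum"]["CBC"],
                "hcbc_sum": tallies["sum"]["HCBC"],
                "indel_sum": tallies["sum"]["indel"],
            }
        ]
    )
    _write_tsv(summary, outdir / "summary.tsv", config.seed)
    return DelimitBundle(structures, barcodes, result, tallies)


@dataclass
class SurveyBundle:
    intron_calls: dict[str, list[ssu.IntronCall]]
    excised: list[seqio.SeqRecord]
    regions: dict[str, list[seqio.SeqRecord]]
    v9_labels: dict[str, str]
    networks: dict[str, network.HaploNetwork]


def run_survey(config: RunConfig) -> SurveyBundle:
    """Introns -> excision -> V4/V9 extraction -> haplotypes -> networks."""
    if not config.input:
        raise InputError("survey workflow needs an input FASTA")
    records = seqio.read_fasta(config.input)
    metadata = (
        seqio.read_metadata(config.metadata)
        if config.metadata
        else seqio.MetadataTable.from_rows({})
    )
    reference = config.reference_record()
    windows = {"V4": config.window("V4"), "V9": config.window("V9")}
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    intron_rows = []
    intron_calls: dict[str, list[ssu.IntronCall]] = {}
    excised = []
    for rec in records:
        cmap = ssu.map_to_reference(rec, reference)
        if cmap.low_identity:
            logger.warning(
                "%s: identity to reference only %.1f%%", rec.id, 100 * cmap.identity
            )
        calls = ssu.detect_introns(rec, reference, config.min_intron_len, cmap=cmap)
        intron_calls[rec.id] = calls
        for c in calls:
            intron_rows.append(
                {
                    "id": rec.id,
                    "query_start": c.query_start,
                    "query_end": c.query_end,
                    "length": c.length,
                    "ecoli_position": c.ecoli_position,
                    "class": c.klass,
                }
            )
        excised.append(ssu.excise_introns(rec, calls))
    _write_tsv(pd.DataFrame(intron_rows), outdir / "introns.tsv", config.seed)
    seqio.write_fasta(excised, outdir / "excised.fasta")

    regions: dict[str, list[seqio.SeqRecord]] = {}
    for region in ("V4", "V9"):
        segs = []
        for rec in excised:
            seg, _ = ssu.extract_region(rec, reference, region, windows=windows)
            segs.append(seg)
        regions[region] = segs
        seqio.write_fasta(segs, outdir / f"{region}.fasta")

    v9_labels = ssu.assign_v9_haplotypes(regions["V9"])
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "id": rec.id,
                    "v9_id": seg.id,
                    "v9_haplotype": v9_labels[seg.id],
                    "habitat": metadata.habitat(rec.id),
                    "region": metadata.region(rec.id),
                }
                for rec, seg in zip(records, regions["V9"])
            ]
        ),
        outdir / "haplotypes.tsv",
        config.seed,
    )

    networks = {}
    limit = config.max_steps or None
    for region, segs in regions.items():
        lengths = {len(s.sequence) for s in segs}
        if len(lengths) != 1:
            logger.warning(
                "%s segments of unequal length; skipping the %s network",
                region,
                region,
            )
            continue
        renamed = [
            seqio.SeqRecord(rec.id, seg.sequence, dict(rec.metadata))
            for rec, seg in zip(records, segs)
        ]
        nodes = network.collapse_haplotypes(renamed, metadata)
        nw = network.build_network(nodes, limit=limit, prob=config.prob, gap_mode=config.gap_mode)
        networks[region] = nw
        network.export_gml(nw, outdir / f"network_{region}.gml")
        node_rows = [
            {
                "node": n,
                "freq": d["freq"],
                "inferred": int(d["inferred"]),
                "sequence": d["sequence"],
            }
            for n, d in sorted(nw.graph.nodes(data=True))
        ]
        edge_rows = [
            {"a": a, "b": b, "steps": d["steps"]}
            for a, b, d in sorted(nw.graph.edges(data=True))
        ]
        _write_tsv(pd.DataFrame(node_rows), outdir / f"network_{region}_nodes.tsv", config.seed)
        _write_tsv(pd.DataFrame(edge_rows), outdir / f"network_{region}_edges.tsv", config.seed)

    return SurveyBundle(intron_calls, excised, regions, v9_labels, networks)
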