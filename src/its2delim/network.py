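"""Statistical-parsimony (TCS-style) haplotype networks.

Identical aligned sequences collapse into haplotype nodes carrying their
frequency and habitat/region tallies.  Nodes are then connected
agglomeratively: all pairs one mutational step apart, then pairs two steps
apart (inserting unobserved intermediate "median" nodes), and so on up to a
connection limit.  The limit is the largest number of steps whose
probability of being strictly parsimonious (no superimposed substitutions)
still reaches the chosen level, classically 95%.

The parsimony probability is estimated under a finite-sites model: each of
the ``m`` sites accumulates substitutions as a Poisson count with a common
rate, substitutions move between the four bases Jukes-Cantor fashion, and
the per-pair divergence is the plug-in estimate ``j/m``.  Two haplotypes
``j`` observed differences apart are parsimoniously connected when every
differing site changed exactly once and every identical site never changed:

    P(j) = r1(mu)^j * s0(mu)^(m-j)

with ``mu`` the expected substitutions per site solving the Jukes-Cantor
relation ``j/m = 3/4 (1 - exp(-4 mu / 3))``, ``r1`` the probability a
visibly differing site changed exactly once, and ``s0`` the probability an
identical-looking site never changed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import Counter

import networkx as nx

from .seqio import GAP_CHARS, MetadataTable, SeqRecord


class NetworkError(ValueError):
    """Raised on unusable haplotype input (ragged alignments, bad options)."""


# -- haplotype collapsing ---------------------------------------------------

@dataclass
class HaploNode:
    """One network node: an observed haplotype or an inferred median."""

    id: str
    sequence: str
    freq: int
    members: list[str] = field(default_factory=list)
    habitat_tally: Counter = field(default_factory=Counter)
    region_tally: Counter = field(default_factory=Counter)
    inferred: bool = False


def collapse_haplotypes(
    records: list[SeqRecord], metadata: MetadataTable | None = None
) -> list[HaploNode]:
    """Collapse identical aligned sequences into frequency-tallied nodes.

    Nodes are labelled H1, H2, ... by decreasing frequency then first-seen
    order.
    """
    if not records:
        return []
    length = len(records[0].sequence)
    if any(len(r.sequence) != length for r in records):
        raise NetworkError("ragged input: aligned sequences must share a length")
    groups: dict[str, list[SeqRecord]] = {}
    order: list[str] = []
    for r in records:
        if r.sequence not in groups:
            order.append(r.sequence)
        groups.setdefault(r.sequence, []).append(r)
    ranked = sorted(order, key=lambda s: (-len(groups[s]), order.index(s)))
    nodes = []
    for k, seq in enumerate(ranked):
        members = [r.id for r in groups[seq]]
        hab: Counter = Counter()
        reg: Counter = Counter()
        if metadata is not None:
            for rid in members:
                hab[metadata.habitat(rid)] += 1
                reg[metadata.region(rid)] += 1
        nodes.append(
            HaploNode(f"H{k + 1}", seq, len(members), members, hab, reg)
        )
    return nodes


def hamming(a: str, b: str, gap_mode: str = "state") -> int:
    """Mutational steps between aligned sequences.

    ``gap_mode="state"`` treats a gap as a fifth character state (a single
    indel is one step); ``"ignore"`` skips columns where either sequence is
    gapped.
    """
    if len(a) != len(b):
        raise NetworkError("sequences must be aligned to equal length")
    if gap_mode == "state":
        return sum(x != y for x, y in zip(a, b))
    if gap_mode == "ignore":
        return sum(
            x != y
            for x, y in zip(a, b)
            if x not in GAP_CHARS and y not in GAP_CHARS
        )
    raise NetworkError(f"unknown gap_mode {gap_mode!r}")


# -- connection limit -------------------------------------------------------

def parsimony_probability(j: int, m: int) -> float:
    """Probability that ``j`` observed differences over ``m`` sites reflect
    exactly ``j`` substitutions (no superimposed changes)."""
    if j <= 0:
        return 1.0
    if m <= 0 or j > m:
        return 0.0
    d = j / m
    if d >= 0.75:
        return 0.0
    mu = -0.75 * math.log1p(-4.0 * d / 3.0)
    visible = 0.75 * (1.0 - math.exp(-4.0 * mu / 3.0))
    p0 = math.exp(-mu)
    r1 = min(1.0, mu * p0 / visible)
    s0 = min(1.0, p0 / (1.0 - visible))
    return (r1 ** j) * (s0 ** (m - j))


def connection_limit(seq_len: int, prob: float = 0.95) -> int:
    """Largest step count whose parsimony probability still reaches ``prob``.

    Always at least 1 (single-step connections are made regardless), which
    is also the limiting value as ``prob`` approaches 1.
    """
    if seq_len < 1:
        raise NetworkError("seq_len must be >= 1")
    j = 1
    while j + 1 <= seq_len and parsimony_probability(j + 1, seq_len) >= prob:
        j += 1
    return j


# -- network construction ---------------------------------------------------

@dataclass
class HaploNetwork:
    """Observed + inferred haplotype nodes with unit-step edges."""

    graph: nx.Graph
    limit: int

    @property
    def observed(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["inferred"]]

    @property
    def medians(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["inferred"]]

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def total_freq(self) -> int:
        return sum(d["freq"] for _, d in self.graph.nodes(data=True))


def _median_chain(seq_a: str, seq_b: str) -> list[str]:
    """Intermediate sequences from a to b, one site changed at a time.

    Among the equal-length candidate orders, each step takes the change
    producing the lexicographically smallest intermediate sequence.
    """
    chain = []
    cur = list(seq_a)
    sites = [k for k in range(len(seq_a)) if seq_a[k] != seq_b[k]]
    while len(sites) > 1:
        best = None
        best_site = None
        for k in sites:
            cand = cur.copy()
            cand[k] = seq_b[k]
            s = "".join(cand)
            if best is None or s < best:
                best, best_site = s, k
        chain.append(best)
        cur = list(best)
        sites.remove(best_site)
    return chain


def build_network(
    nodes: list[HaploNode],
    limit: int | None = None,
    prob: float = 0.95,
    gap_mode: str = "state",
) -> HaploNetwork:
    """TCS agglomeration over collapsed haplotypes.

    Distance-1 pairs are always joined; pairs at distance d = 2..limit are
    joined through d-1 inferred median nodes only when they still sit in
    different components (ties processed higher-frequency first, then by
    lexicographic id).  Unconnectable haplotypes remain separate
    components.  Deterministic and invariant to input order.
    """
    nodes = sorted(nodes, key=lambda n: (-n.freq, n.id))
    if nodes and limit is None:
        limit = connection_limit(len(nodes[0].sequence), prob)
    g = nx.Graph()
    for n in nodes:
        g.add_node(
            n.id,
            sequence=n.sequence,
            freq=n.freq,
            inferred=False,
            habitat_tally=dict(n.habitat_tally),
            region_tally=dict(n.region_tally),
        )
    by_seq = {n.sequence: n.id for n in nodes}
    dist = {}
    for x in range(len(nodes)):
        for y in range(x + 1, len(nodes)):
            dist[(nodes[x].id, nodes[y].id)] = hamming(
                nodes[x].sequence, nodes[y].sequence, gap_mode
            )
    median_count = 0
    for d in range(1, (limit or 0) + 1):
        at_d = [pair for pair, dd in dist.items() if dd == d]
        at_d.sort(
            key=lambda p: (
                -max(g.nodes[p[0]]["freq"], g.nodes[p[1]]["freq"]),
                -min(g.nodes[p[0]]["freq"], g.nodes[p[1]]["freq"]),
                p,
            )
        )
        for a, b in at_d:
            if d == 1:
                g.add_edge(a, b, steps=1)
                continue
            if nx.has_path(g, a, b):
                continue
            prev = a
            for seq in _median_chain(
                g.nodes[a]["sequence"], g.nodes[b]["sequence"]
            ):
                if seq in by_seq:
                    nid = by_seq[seq]
                else:
                    median_count += 1
                    nid = f"m{median_count}"
                    by_seq[seq] = nid
                    g.add_node(
                        nid,
                        sequence=seq,
                        freq=0,
                        inferred=True,
                        habitat_tally={},
                        region_tally={},
                    )
                if prev != nid and not g.has_edge(prev, nid):
                    g.add_edge(prev, nid, steps=1)
                prev = nid
            if prev != b and not g.has_edge(prev, b):
                g.add_edge(prev, b, steps=1)
    return HaploNetwork(g, limit or 0)


# -- GML export -------------------------------------------------------------

def export_gml(network: HaploNetwork, path) -> None:
    """Write the network as GML; tallies flatten to habitat_x/region_x keys."""
    g = nx.Graph()
    g.graph["limit"] = network.limit
    for n, d in network.graph.nodes(data=True):
        attrs = {
            "sequence": d["sequence"],
            "freq": d["freq"],
            "inferred": int(d["inferred"]),
        }
        for k, v in sorted(d.get("habitat_tally", {}).items()):
            attrs[f"habitat_{k.replace('-', '_').replace(' ', '_')}"] = v
        for k, v in sorted(d.get("region_tally", {}).items()):
            attrs[f"region_{k.replace('-', '_').replace(' ', '_')}"] = v
        g.add_node(n, **attrs)
    for a, b, d in network.graph.edges(data=True):
        g.add_edge(a, b, steps=d.get("steps", 1))
    nx.write_gml(g, str(path))


def import_gml(path) -> HaploNetwork:
    g = nx.read_gml(str(path))
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        hab = {
            k[len("habitat_"):].replace("_", "-"): v
            for k, v in d.items()
            if k.startswith("habitat_")
        }
        reg = {
            k[len("region_"):].replace("_", " "): v
            for k, v in d.items()
            if k.startswith("region_")
        }
        out.add_node(
            n,
            sequence=d["sequence"],
            freq=int(d["freq"]),
            inferred=bool(d["inferred"]),
            habitat_tally=hab,
            region_tally=reg,
        )
    for a, b, d in g.edges(data=True):
        out.add_edge(a, b, steps=int(d.get("steps", 1)))
    return HaploNetwork(out, int(g.graph.get("limit", 0)))
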