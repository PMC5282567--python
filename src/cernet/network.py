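"""Anticorrelation-constrained ceRNA network assembly.

Predicted regulator-target pairs are filtered so both endpoints are
differentially expressed with opposite directions (a repressor and its
target should move in contrast), assembled into the three pairwise
networks (miRNA-mRNA, miRNA-lncRNA, lncRNA-mRNA), and integrated into the
two tripartite views: a miRNA-centered network (miRNAs bridging >= 1 mRNA
target and >= 1 lncRNA partner) and lncRNA-centered triads
(lncRNA, miRNA, mRNA) sharing a miRNA.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .targets import InteractionPair

PAIRWISE_KINDS = {
    "mirna_mrna": ("mirna", "mrna"),
    "mirna_lncrna": ("mirna", "lncrna"),
    "lncrna_mrna": ("lncrna", "mrna"),
}
TRIPARTITE_KINDS = ("mirna_mrna_lncrna", "lncrna_mirna_mrna")


@dataclass(frozen=True)
class RegulatoryEdge:
    """A directed repression edge whose endpoints move in opposite directions."""

    regulator: str
    regulator_class: str
    regulator_direction: str
    target: str
    target_class: str
    target_direction: str
    evidence: str
    score: float

    def __post_init__(self) -> None:
        for d in (self.regulator_direction, self.target_direction):
            if d not in ("up", "down"):
                raise ValueError(f"edge direction must be up/down, got {d!r}")
        if self.regulator_direction == self.target_direction:
            raise ValueError(
                f"{self.regulator}->{self.target}: endpoints share direction "
                f"{self.regulator_direction!r}")


@dataclass
class CeRNANetwork:
    """A typed network of DE features with repression edges."""

    kind: str
    nodes: pd.DataFrame  # columns: id, node_class, direction, degree
    edges: tuple[RegulatoryEdge, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class TriadSummary:
    """Triads plus the venn partition of the shared node layer."""

    triads: list[tuple[str, str, str]]  # (lncRNA, miRNA, mRNA)
    venn: dict[str, int]
    degree_table: pd.DataFrame


def anticorrelation_filter(pairs: Sequence[InteractionPair],
                           de_tables: Mapping[str, pd.DataFrame],
                           gate: str = "de",
                           require_r: float | None = None,
                           expr: Mapping[str, ExpressionMatrix] | None = None,
                           ) -> list[RegulatoryEdge]:
    """Keep predicted pairs whose endpoints are DE with contrasting direction.

    ``gate`` selects the endpoint screen: ``"de"`` (|FC| > 2, q < 0.05 flags)
    or ``"candidate"`` (the stricter validation screen). When ``require_r``
    is set, the sample-level Pearson correlation between the two expression
    profiles must additionally be <= -require_r.
    """
    if gate not in ("de", "candidate"):
        raise ValueError(f"unknown gate {gate!r}")
    flag = "passes_de" if gate == "de" else "passes_candidate"
    lookup: dict[str, tuple[str, bool, str]] = {}
    for cls, table in de_tables.items():
        for row in table.itertuples(index=False):
            lookup[row.feature] = (cls, bool(getattr(row, flag)), row.direction)
    if require_r is not None and expr is None:
        raise ValueError("require_r needs expression matrices")
    edges = []
    for pair in pairs:
        for endpoint in (pair.source, pair.target):
            if endpoint not in lookup:
                raise KeyError(f"feature {endpoint!r} missing from DE tables")
        _, src_pass, src_dir = lookup[pair.source]
        _, tgt_pass, tgt_dir = lookup[pair.target]
        if not (src_pass and tgt_pass):
            continue
        if src_dir not in ("up", "down") or tgt_dir not in ("up", "down"):
            continue
        if src_dir == tgt_dir:
            continue
        if require_r is not None:
            r = _sample_correlation(pair, expr)
            if not (r <= -require_r):
                continue
        edges.append(RegulatoryEdge(pair.source, pair.source_class, src_dir,
                                    pair.target, pair.target_class, tgt_dir,
                                    pair.evidence, pair.score))
    return edges


def _sample_correlation(pair: InteractionPair,
                        expr: Mapping[str, ExpressionMatrix]) -> float:
    src = expr[pair.source_class].values.loc[pair.source]
    tgt = expr[pair.target_class].values.loc[pair.target]
    shared = src.index.intersection(tgt.index)
    x = src[shared].to_numpy(dtype=float)
    y = tgt[shared].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _nodes_from_edges(edges: Iterable[RegulatoryEdge]) -> pd.DataFrame:
    info: dict[str, tuple[str, str]] = {}
    degree: dict[str, int] = {}
    for e in edges:
        for node, cls, direction in ((e.regulator, e.regulator_class, e.regulator_direction),
                                     (e.target, e.target_class, e.target_direction)):
            prev = info.get(node)
            if prev is not None and prev != (cls, direction):
                raise ValueError(f"conflicting class/direction for node {node!r}")
            info[node] = (cls, direction)
            degree[node] = degree.get(node, 0) + 1
    ids = sorted(info)
    return pd.DataFrame({
        "id": ids,
        "node_class": [info[i][0] for i in ids],
        "direction": [info[i][1] for i in ids],
        "degree": [degree[i] for i in ids],
    })


def _dedupe(edges: Iterable[RegulatoryEdge]) -> tuple[RegulatoryEdge, ...]:
    seen = {}
    for e in edges:
        seen.setdefault((e.regulator, e.target, e.evidence), e)
    return tuple(sorted(seen.values(),
                        key=lambda e: (e.regulator, e.target, e.evidence)))


def build_pair_network(edges: Sequence[RegulatoryEdge], kind: str) -> CeRNANetwork:
    """Assemble one pairwise network; node order is lexicographic."""
    if kind not in PAIRWISE_KINDS:
        raise ValueError(f"unknown pairwise kind {kind!r}")
    allowed = set(PAIRWISE_KINDS[kind])
    for e in edges:
        if {e.regulator_class, e.target_class} - allowed:
            raise ValueError(
                f"edge {e.regulator}->{e.target} has classes outside {sorted(allowed)}")
    deduped = _dedupe(edges)
    return CeRNANetwork(kind, _nodes_from_edges(deduped), deduped)


def integrate_tripartite(mirna_mrna: CeRNANetwork, mirna_lncrna: CeRNANetwork,
                         lncrna_mrna: CeRNANetwork,
                         ) -> tuple[tuple[CeRNANetwork, TriadSummary],
                                    tuple[CeRNANetwork, TriadSummary]]:
    """Merge the pairwise networks into the two tripartite views.

    Returns ((miRNA-centered network, its summary),
             (lncRNA-centered network, its summary)).

    The miRNA-centered network keeps every miRNA with >= 1 mRNA target and
    >= 1 lncRNA partner, together with those edges. A triad (l, m, g)
    exists when the miRNA m hits both the lncRNA l and the mRNA g; the
    sign constraint forces l and g to share a direction opposite to m.
    The lncRNA-centered network carries all triad edges plus any direct
    lncRNA-mRNA edges within a triad's (l, g) pair.
    """
    _check_direction_consistency([mirna_mrna, mirna_lncrna, lncrna_mrna])
    mrna_targets: dict[str, list[RegulatoryEdge]] = {}
    for e in mirna_mrna.edges:
        mrna_targets.setdefault(e.regulator, []).append(e)
    lnc_partners: dict[str, list[RegulatoryEdge]] = {}
    for e in mirna_lncrna.edges:
        lnc_partners.setdefault(e.regulator, []).append(e)

    bridging = sorted(set(mrna_targets) & set(lnc_partners))
    mi_edges = [e for m in bridging for e in mrna_targets[m] + lnc_partners[m]]
    mirna_centered = CeRNANetwork("mirna_mrna_lncrna",
                                  _nodes_from_edges(_dedupe(mi_edges)),
                                  _dedupe(mi_edges))

    triads = sorted(
        (le.target, m, ge.target)
        for m in bridging
        for le in lnc_partners[m]
        for ge in mrna_targets[m]
    )
    triad_lnc_gene = {(l, g) for l, _, g in triads}
    lm_edges = [e for e in lncrna_mrna.edges
                if (e.regulator, e.target) in triad_lnc_gene]
    l_edges = _dedupe(mi_edges + lm_edges)
    lncrna_centered = CeRNANetwork("lncrna_mirna_mrna",
                                   _nodes_from_edges(l_edges), l_edges)

    # venn partitions over the shared node layer
    mrnas_by_mirna = {e.target for e in mirna_mrna.edges}
    mrnas_by_lnc = {e.target for e in lncrna_mrna.edges}
    mirnas_with_lnc = {e.regulator for e in mirna_lncrna.edges}
    mirnas_with_mrna = {e.regulator for e in mirna_mrna.edges}
    mi_summary = TriadSummary(
        triads=list(triads),
        venn=_venn(mrnas_by_mirna, mrnas_by_lnc,
                   "mrna_targets_of_mirnas", "mrna_partners_of_lncrnas"),
        degree_table=mirna_centered.nodes.copy(),
    )
    l_summary = TriadSummary(
        triads=list(triads),
        venn=_venn(mirnas_with_lnc, mirnas_with_mrna,
                   "mirnas_pairing_lncrnas", "mirnas_targeting_mrnas"),
        degree_table=lncrna_centered.nodes.copy(),
    )
    return (mirna_centered, mi_summary), (lncrna_centered, l_summary)


def _venn(a: set, b: set, name_a: str, name_b: str) -> dict[str, int]:
    return {
        f"{name_a}_only": len(a - b),
        "shared": len(a & b),
        f"{name_b}_only": len(b - a),
        "union": len(a | b),
    }


def _check_direction_consistency(networks: Sequence[CeRNANetwork]) -> None:
    seen: dict[str, tuple[str, str]] = {}
    for net in networks:
        for row in net.nodes.itertuples(index=False):
            prev = seen.get(row.id)
            cur = (row.node_class, row.direction)
            if prev is not None and prev != cur:
                raise ValueError(
                    f"node {row.id!r} has conflicting class/direction across inputs")
            seen[row.id] = cur


def brute_force_triads(mirna_mrna: CeRNANetwork, mirna_lncrna: CeRNANetwork,
                       ) -> list[tuple[str, str, str]]:
    """Reference triad enumeration by a triple loop over all (l, m, g).

    Kept as an independent check for the integration path; quadratic in the
    node counts, use on small instances only.
    """
    ml = {(e.regulator, e.target) for e in mirna_lncrna.edges}
    mm = {(e.regulator, e.target) for e in mirna_mrna.edges}
    lncs = sorted({l for _, l in ml})
    mirnas = sorted({m for m, _ in ml} | {m for m, _ in mm})
    genes = sorted({g for _, g in mm})
    out = []
    for l in lncs:
        for m in mirnas:
            for g in genes:
                if (m, l) in ml and (m, g) in mm:
                    out.append((l, m, g))
    return sorted(out)


def hub_nodes(network: CeRNANetwork, top_k: int = 10) -> pd.DataFrame:
    """Nodes ranked by descending degree, ties broken lexicographically."""
    ranked = network.nodes.sort_values(["degree", "id"],
                                       ascending=[False, True],
                                       kind="mergesort").reset_index(drop=True)
    return ranked.head(top_k) if top_k < len(ranked) else ranked


def to_networkx(network: CeRNANetwork) -> nx.DiGraph:
    g = nx.DiGraph(kind=network.kind)
    for row in network.nodes.itertuples(index=False):
        g.add_node(row.id, node_class=row.node_class, direction=row.direction,
                   degree=int(row.degree))
    for e in network.edges:
        g.add_edge(e.regulator, e.target, evidence=e.evidence, score=float(e.score))
    return g


def from_networkx(g: nx.DiGraph) -> CeRNANetwork:
    edges = []
    for u, v, data in sorted(g.edges(data=True)):
        edges.append(RegulatoryEdge(
            u, g.nodes[u]["node_class"], g.nodes[u]["direction"],
            v, g.nodes[v]["node_class"], g.nodes[v]["direction"],
            data["evidence"], float(data["score"])))
    kind = g.graph.get("kind", "mirna_mrna_lncrna")
    deduped = _dedupe(edges)
    return CeRNANetwork(kind, _nodes_from_edges(deduped), deduped)


def export_network(network: CeRNANetwork, fmt: str, path: str | Path) -> None:
    """Write GraphML (full attributes) or SIF ("represses" relation)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "graphml":
        nx.write_graphml(to_networkx(network), str(path))
    elif fmt == "sif":
        with open(path, "w", newline="\n") as handle:
            for e in network.edges:
                handle.write(f"{e.regulator}\trepresses\t{e.target}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_graphml(path: str | Path) -> CeRNANetwork:
    return from_networkx(nx.read_graphml(str(path)))


def triads_to_frame(summary: TriadSummary,
                    edges: Sequence[RegulatoryEdge]) -> pd.DataFrame:
    directions = {}
    for e in edges:
        directions[e.regulator] = e.regulator_direction
        directions[e.target] = e.target_direction
    rows = [(l, m, g, directions.get(l, ""), directions.get(m, ""), directions.get(g, ""))
            for l, m, g in summary.triads]
    return pd.DataFrame(rows, columns=["lncrna", "mirna", "mrna",
                                       "lncrna_direction", "mirna_direction",
                                       "mrna_direction"])
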