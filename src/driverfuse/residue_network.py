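"""Residue interaction networks and normalized betweenness profiles.

Protein structures are reduced to a graph whose nodes are residues and
whose edges carry an interaction strength

    I_ij = 100 * n_ij / sqrt(N_i * N_j)   (percent)

where ``n_ij`` counts heavy-atom pairs of residues i and j within the
contact cutoff (default 4.5 Å) and ``N_i`` is the total number of
heavy-atom contacts residue i makes in the structure.  An edge is kept
when I_ij exceeds the threshold ``i_min`` (default 4%); sequence-adjacent
residues are excluded by default so that backbone connectivity does not
dominate the network.

Betweenness of a residue is the sum over residue pairs of the fraction of
shortest paths passing through it, normalized per connected component by
(N-1)(N-2)/2.  Path counting uses exact Brandes accumulation; shortest
paths are unweighted by default, with an optional weighted mode using edge
length 1/I_ij.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResidueId:
    """Chain identifier plus residue number (insertion code appended)."""

    chain: str
    number: str  # e.g. "858" or "100A"

    def __str__(self) -> str:
        return f"{self.chain}:{self.number}"


def _parse_structure(path: str | Path):
    """Residues (id, name, heavy-atom coordinates) from a PDB file."""
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import is_aa

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"{path}: no models found (unparseable or empty PDB)") from None
    residues = []
    for chain in model:
        chain_res = []
        for res in chain:
            if res.id[0] != " " and not is_aa(res, standard=False):
                continue  # skip waters / non-polymer heteroatoms
            coords = []
            seen_names = set()
            for atom in res:
                if atom.element == "H":
                    continue
                if atom.name in seen_names:  # first altloc only
                    continue
                seen_names.add(atom.name)
                coords.append(atom.coord)
            if not coords:
                continue
            icode = res.id[2].strip()
            rid = ResidueId(chain.id, f"{res.id[1]}{icode}")
            chain_res.append((rid, res.get_resname(), np.asarray(coords, dtype=float)))
        if not chain_res:
            raise ValueError(f"chain {chain.id!r} in {path} has no residues with heavy atoms")
        residues.extend(chain_res)
    if len(residues) < 2:
        raise ValueError(f"{path}: need at least 2 residues to build a network")
    return residues


def build_graph(
    structure: str | Path,
    i_min: float = 4.0,
    contact_cutoff: float = 4.5,
    exclude_adjacent: bool = True,
) -> nx.Graph:
    """Residue interaction network from a PDB file.

    Node attributes: ``resname``; edge attribute ``weight`` is the
    interaction strength I_ij in percent (all retained edges satisfy
    I_ij > i_min).
    """
    residues = _parse_structure(structure)
    return graph_from_contacts(residues, i_min=i_min, contact_cutoff=contact_cutoff,
                               exclude_adjacent=exclude_adjacent)


def graph_from_contacts(
    residues: list[tuple[ResidueId, str, np.ndarray]],
    i_min: float = 4.0,
    contact_cutoff: float = 4.5,
    exclude_adjacent: bool = True,
) -> nx.Graph:
    """Network from pre-extracted residue heavy-atom coordinates."""
    coords = np.concatenate([c for _, _, c in residues])
    owner = np.concatenate([np.full(len(c), i) for i, (_, _, c) in enumerate(residues)])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=contact_cutoff, output_type="ndarray")

    n = len(residues)
    counts: dict[tuple[int, int], int] = {}
    for a, b in pairs:
        ra, rb = int(owner[a]), int(owner[b])
        if ra == rb:
            continue
        key = (min(ra, rb), max(ra, rb))
        counts[key] = counts.get(key, 0) + 1

    totals = np.zeros(n)
    for (ra, rb), c in counts.items():
        totals[ra] += c
        totals[rb] += c

    graph = nx.Graph()
    order = {}
    for i, (rid, resname, _) in enumerate(residues):
        graph.add_node(rid, resname=resname)
        order[rid] = i
    for (ra, rb), c in counts.items():
        if exclude_adjacent and _sequence_adjacent(residues[ra][0], residues[rb][0], ra, rb):
            continue
        strength = 100.0 * c / np.sqrt(totals[ra] * totals[rb])
        if strength > i_min:
            graph.add_edge(residues[ra][0], residues[rb][0], weight=float(strength))
    logger.info("residue network: %d nodes, %d edges (I_min %.1f%%)",
                graph.number_of_nodes(), graph.number_of_edges(), i_min)
    return graph


def _sequence_adjacent(a: ResidueId, b: ResidueId, ia: int, ib: int) -> bool:
    return a.chain == b.chain and abs(ia - ib) == 1


@dataclass
class BetweennessProfile:
    """Normalized betweenness per residue plus component bookkeeping."""

    values: pd.Series  # index: ResidueId
    component_sizes: dict[int, int]
    component_of: pd.Series
    weighted: bool = False

    def percentile(self, node) -> float:
        v = self.values
        return float(100.0 * (v <= v.loc[node]).sum() / len(v))


def _brandes(nodes, neighbors, weighted: bool) -> dict:
    """Exact betweenness accumulation (raw, unordered-pair counting)."""
    bet = {v: 0.0 for v in nodes}
    for s in nodes:
        sigma = {v: 0.0 for v in nodes}
        dist = {v: np.inf for v in nodes}
        preds = {v: [] for v in nodes}
        sigma[s], dist[s] = 1.0, 0.0
        stack = []
        if not weighted:
            queue = deque([s])
            while queue:
                v = queue.popleft()
                stack.append(v)
                for w, _ in neighbors(v):
                    if dist[w] == np.inf:
                        dist[w] = dist[v] + 1
                        queue.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
        else:
            seen = set()
            heap = [(0.0, id(s), s)]
            while heap:
                d, _, v = heapq.heappop(heap)
                if v in seen:
                    continue
                seen.add(v)
                stack.append(v)
                for w, length in neighbors(v):
                    nd = d + length
                    if nd < dist[w] - 1e-12:
                        dist[w] = nd
                        sigma[w] = sigma[v]
                        preds[w] = [v]
                        heapq.heappush(heap, (nd, id(w), w))
                    elif abs(nd - dist[w]) <= 1e-12 and v not in preds[w]:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
        delta = {v: 0.0 for v in nodes}
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1 + delta[w])
            if w is not s:
                bet[w] += delta[w]
    # each unordered pair was counted from both endpoints
    return {v: b / 2.0 for v, b in bet.items()}


def betweenness(graph: nx.Graph, weighted: bool = False) -> BetweennessProfile:
    """Per-residue normalized betweenness, component by component.

    Raw betweenness of node i sums g_jk(i)/g_jk over pairs j<k excluding i
    and is divided by (N-1)(N-2)/2 with N the size of i's connected
    component; components with N < 3 get 0 (degenerate normalizer, logged).
    In weighted mode shortest paths minimise the total edge length 1/I_ij.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    values = {}
    comp_of = {}
    comp_sizes = {}
    for ci, comp in enumerate(nx.connected_components(graph)):
        comp = list(comp)
        comp_sizes[ci] = len(comp)
        for v in comp:
            comp_of[v] = ci
        if len(comp) < 3:
            logger.info("component %d has %d node(s); betweenness defined as 0", ci, len(comp))
            for v in comp:
                values[v] = 0.0
            continue
        sub = graph.subgraph(comp)

        def neigh(v, sub=sub):
            return [(w, 1.0 / sub[v][w]["weight"] if weighted else 1.0) for w in sub[v]]

        raw = _brandes(comp, neigh, weighted)
        norm = (len(comp) - 1) * (len(comp) - 2) / 2.0
        for v in comp:
            values[v] = raw[v] / norm
    nodes = list(graph.nodes)
    return BetweennessProfile(
        values=pd.Series([values[v] for v in nodes], index=nodes),
        component_sizes=comp_sizes,
        component_of=pd.Series([comp_of[v] for v in nodes], index=nodes),
        weighted=weighted,
    )


def map_positions(profile: BetweennessProfile, positions: list) -> pd.DataFrame:
    """Annotate residue positions with centrality value and in-structure percentile.

    Positions may be ResidueId objects or "chain:number" strings.  Positions
    absent from the structure are returned with resolved=False rather than
    raising.
    """
    index_by_str = {str(node): node for node in profile.values.index}
    rows = []
    for pos in positions:
        key = str(pos)
        node = index_by_str.get(key)
        if node is None:
            rows.append({"position": key, "resolved": False, "betweenness": np.nan, "percentile": np.nan})
        else:
            rows.append({
                "position": key,
                "resolved": True,
                "betweenness": float(profile.values.loc[node]),
                "percentile": profile.percentile(node),
            })
    unresolved = [r["position"] for r in rows if not r["resolved"]]
    if unresolved:
        warnings.warn(f"unresolved positions: {unresolved}")
    return pd.DataFrame(rows, columns=["position", "resolved", "betweenness", "percentile"])


def write_profile(graph: nx.Graph, profile: BetweennessProfile, path: str | Path) -> None:
    """CSV dump: chain, residue number, residue type, betweenness, percentile."""
    rows = []
    for node in profile.values.index:
        rows.append({
            "chain": node.chain,
            "residue": node.number,
            "resname": graph.nodes[node].get("resname", ""),
            "betweenness": profile.values.loc[node],
            "percentile": profile.percentile(node),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
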