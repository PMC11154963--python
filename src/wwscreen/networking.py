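"""Molecular networking from MS2 spectra with a shift-aware spectral
similarity.

The modified cosine allows fragment pairs to match either directly or after
shifting by the precursor mass difference of the two spectra, which links a
parent pharmaceutical to its metabolites: fragments retaining the modified
moiety appear shifted by exactly the biotransformation mass delta, the rest
match directly.  Peak intensities are square-root compressed and each
spectrum's weight vector is normalized to unit length, so the similarity
lies in [0, 1] and equals 1 for identical spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .io_formats import Spectrum

DEFAULT_FRAG_TOL = 0.01  # Da
DEFAULT_MIN_SIMILARITY = 0.5
DEFAULT_MIN_MATCHED = 4
DEFAULT_MAX_LINKS = 10


@dataclass(frozen=True)
class NetworkEdge:
    node_a: str
    node_b: str
    similarity: float
    matched_fragments: int
    precursor_shift: float  # Da, precursor_a - precursor_b


def _weights(spectrum: Spectrum, intensity_power: float) -> np.ndarray:
    w = np.asarray(spectrum.intensity, dtype=float) ** intensity_power
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def _candidate_pairs(
    a: Spectrum, b: Spectrum, frag_tol: float
) -> list[tuple[int, int]]:
    shift = a.precursor_mz - b.precursor_mz
    mza = np.asarray(a.mz)
    mzb = np.asarray(b.mz)
    pairs = []
    for i, mi in enumerate(mza):
        for j, mj in enumerate(mzb):
            if abs(mi - mj) <= frag_tol or abs(mi - mj - shift) <= frag_tol:
                pairs.append((i, j))
    return pairs


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    frag_tol_da: float = DEFAULT_FRAG_TOL,
    intensity_power: float = 0.5,
    method: str = "exact",
) -> tuple[float, int]:
    """Shift-aware spectral similarity and matched-fragment count.

    Candidate pairs are fragment pairs whose m/z agree within ``frag_tol_da``
    either directly or after subtracting the precursor mass difference.  A
    one-to-one assignment of peaks maximizing the summed products of the
    normalized peak weights is chosen; the similarity is that sum and
    ``matched_fragments`` the number of pairs with positive weight in the
    assignment.

    ``method`` selects the assignment solver: ``"exact"`` (rectangular
    linear sum assignment, the default), ``"greedy"`` (descending pair score,
    each peak used once — the fast heuristic common in networking tools), or
    ``"brute"`` (full enumeration; only for tiny spectra, used as an
    independent reference in testing).
    """
    if not a.peaks or not b.peaks:
        raise ValueError("modified_cosine requires non-empty peak lists")
    wa = _weights(a, intensity_power)
    wb = _weights(b, intensity_power)
    pairs = _candidate_pairs(a, b, frag_tol_da)
    if not pairs:
        return 0.0, 0
    scores = {(i, j): wa[i] * wb[j] for i, j in pairs}

    if method == "exact":
        rows = sorted({i for i, _ in pairs})
        cols = sorted({j for _, j in pairs})
        cost = np.zeros((len(rows), len(cols)))
        rmap = {i: r for r, i in enumerate(rows)}
        cmap = {j: c for c, j in enumerate(cols)}
        for (i, j), s in scores.items():
            cost[rmap[i], cmap[j]] = max(cost[rmap[i], cmap[j]], s)
        ri, ci = linear_sum_assignment(cost, maximize=True)
        chosen = [
            (rows[r], cols[c])
            for r, c in zip(ri, ci)
            if (rows[r], cols[c]) in scores and scores[(rows[r], cols[c])] > 0
        ]
    elif method == "greedy":
        used_a: set[int] = set()
        used_b: set[int] = set()
        chosen = []
        for (i, j), s in sorted(
            scores.items(), key=lambda kv: (-kv[1], kv[0])
        ):
            if i in used_a or j in used_b or s <= 0:
                continue
            chosen.append((i, j))
            used_a.add(i)
            used_b.add(j)
    elif method == "brute":
        chosen = _brute_force_assignment(scores)
    else:
        raise ValueError(f"unknown assignment method {method!r}")

    similarity = float(sum(scores[p] for p in chosen))
    return min(similarity, 1.0), len(chosen)


def _brute_force_assignment(
    scores: dict[tuple[int, int], float]
) -> list[tuple[int, int]]:
    """Enumerate all one-to-one assignments; reference implementation."""
    rows = sorted({i for i, _ in scores})
    cols = sorted({j for _, j in scores})
    best: tuple[float, int, list] = (-1.0, 0, [])
    n = max(len(rows), len(cols))
    padded_cols = cols + [None] * (n - len(cols))
    for perm in permutations(padded_cols, len(rows)):
        chosen = [
            (i, j)
            for i, j in zip(rows, perm)
            if j is not None and (i, j) in scores and scores[(i, j)] > 0
        ]
        total = sum(scores[p] for p in chosen)
        key = (total, len(chosen))
        if key > (best[0], best[1]):
            best = (total, len(chosen), chosen)
    return best[2]


def build_network(
    spectra: list[Spectrum],
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    min_matched: int = DEFAULT_MIN_MATCHED,
    max_links_per_node: int = DEFAULT_MAX_LINKS,
    frag_tol_da: float = DEFAULT_FRAG_TOL,
) -> nx.Graph:
    """Build a molecular network over the given spectra.

    An edge is kept when similarity >= ``min_similarity`` AND matched
    fragments >= ``min_matched``; per node only the ``max_links_per_node``
    strongest edges are retained (an edge survives if it is in either
    endpoint's top-k).  Connected components of the result are the clusters.
    """
    if len(spectra) < 2:
        raise ValueError("networking requires at least two spectra")
    graph = nx.Graph()
    for sp in spectra:
        graph.add_node(sp.identifier, precursor_mz=sp.precursor_mz, rt=sp.rt)
    candidates: list[NetworkEdge] = []
    for idx_a in range(len(spectra)):
        for idx_b in range(idx_a + 1, len(spectra)):
            a, b = spectra[idx_a], spectra[idx_b]
            if not a.peaks or not b.peaks:
                continue
            sim, matched = modified_cosine(a, b, frag_tol_da)
            if sim >= min_similarity and matched >= min_matched:
                candidates.append(
                    NetworkEdge(
                        a.identifier, b.identifier, sim, matched,
                        a.precursor_mz - b.precursor_mz,
                    )
                )
    # symmetric top-k pruning
    per_node: dict[str, list[NetworkEdge]] = {}
    for e in candidates:
        per_node.setdefault(e.node_a, []).append(e)
        per_node.setdefault(e.node_b, []).append(e)
    keep = set()
    for node, edges in per_node.items():
        edges.sort(key=lambda e: (-e.similarity, e.node_a, e.node_b))
        keep.update(id(e) for e in edges[:max_links_per_node])
    for e in candidates:
        if id(e) in keep:
            graph.add_edge(
                e.node_a, e.node_b,
                similarity=e.similarity,
                matched_fragments=e.matched_fragments,
                precursor_shift=e.precursor_shift,
            )
    return graph


def clusters(graph: nx.Graph) -> list[set[str]]:
    """Connected components, largest first."""
    comps = [set(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)[0]))


def parent_link_fraction(
    graph: nx.Graph,
    confirmed_metabolites: list[str],
    parent_map: dict[str, str],
) -> float | None:
    """Fraction of confirmed metabolites directly linked (path length 1) to
    their parent or to a sibling metabolite of the same parent.

    ``parent_map`` maps every node name to its parent compound's node name
    (parents map to themselves).  Returns None for an empty confirmed set.
    """
    if not confirmed_metabolites:
        return None
    linked = 0
    for met in confirmed_metabolites:
        parent = parent_map.get(met)
        if met not in graph:
            continue
        for neighbor in graph.neighbors(met):
            if neighbor == parent or parent_map.get(neighbor) == parent:
                linked += 1
                break
    return linked / len(confirmed_metabolites)


def export_edges(graph: nx.Graph) -> list[dict]:
    """Edge list suitable for CSV/JSON export."""
    return [
        {
            "node_a": a,
            "node_b": b,
            "similarity": data["similarity"],
            "matched_fragments": data["matched_fragments"],
            "precursor_shift": data["precursor_shift"],
        }
        for a, b, data in sorted(graph.edges(data=True))
    ]
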