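"""Molecular networking with modified-cosine similarity.

The modified cosine pairs fragments either directly (equal m/z within a
tolerance) or shifted by the precursor m/z difference of the two spectra,
which is what lets a conjugate and its aglycone share "the same" fragments
despite the mass offset.  Peak weights are sqrt(intensity), L2-normalized
per spectrum; pairs are selected greedily by descending weight product with
each peak used at most once (ties broken by smaller |delta m/z|, then lower
m/z), so the score is deterministic and bounded in [0, 1].

Networks are built GNPS-style: all pairs are scored, edges below the cosine
or matched-fragment thresholds are dropped, an edge survives only if it
ranks within the top-K edges of BOTH endpoints, and components larger than
the cap are shrunk by iteratively removing their lowest-cosine edge.
Because that pruning preferentially discards conjugate:aglycone links in
dense networks, :func:`readd_delta_edges` restores any scored pair whose
absolute precursor difference matches a conjugation mass shift
(glucuronide 176.032, glucuronic acid 194.042, glucuronide-vs-sulfate
96.075; +/-0.003 Da); re-added edges are exempt from the top-K and
component-size limits and are tagged ``origin="readded"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import chem
from .spectra import Spectrum, SpectrumCollection

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkParams",
    "Edge",
    "MolecularNetwork",
    "LibraryMatch",
    "modified_cosine",
    "cluster_spectra",
    "build_network",
    "readd_delta_edges",
    "library_search",
    "propagate_suspect_annotations",
    "export_network",
    "DEFAULT_DELTA_TARGETS",
    "NETWORK_PRESETS",
]

#: Conjugation precursor deltas restored after pruning (Da).
DEFAULT_DELTA_TARGETS = (
    round(chem.GLUCURONIDE_NL, 3),
    round(chem.GLUCURONIC_ACID_NL, 3),
    round(chem.GLUCURONIDE_SULFATE_DELTA, 3),
)
DEFAULT_DELTA_TOL = 0.003

GLUCURONIDE_DELTAS = (chem.GLUCURONIDE_NL, chem.GLUCURONIC_ACID_NL)


@dataclass(frozen=True)
class NetworkParams:
    """Thresholds for building a molecular network."""

    frag_tol: float = 0.01
    cosine_min: float = 0.4
    min_matched: int = 3
    top_k: int = 10
    max_component: int = 100
    min_files: int = 2
    prec_tol: float = 0.01  # precursor tolerance for MS/MS clustering

    def __post_init__(self) -> None:
        if not (0 < self.cosine_min <= 1):
            raise ValueError("cosine_min must be in (0, 1]")
        for name in ("frag_tol", "min_matched", "top_k", "max_component", "min_files", "prec_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: Parameter presets: "standards" for clean library runs, "biological" for
#: multi-file biological sample networking.
NETWORK_PRESETS: dict[str, NetworkParams] = {
    "standards": NetworkParams(
        frag_tol=0.005, cosine_min=0.25, min_matched=3, top_k=5,
        max_component=25, min_files=1, prec_tol=0.002,
    ),
    "biological": NetworkParams(
        frag_tol=0.01, cosine_min=0.4, min_matched=3, top_k=10,
        max_component=100, min_files=2, prec_tol=0.01,
    ),
}


@dataclass(frozen=True)
class Edge:
    node_a: str
    node_b: str
    cosine: float
    n_matched: int
    delta_prec_mz: float  # signed, a - b
    origin: str = "scored"

    def key(self) -> tuple[str, str]:
        return (self.node_a, self.node_b) if self.node_a <= self.node_b else (self.node_b, self.node_a)


@dataclass
class MolecularNetwork:
    """Graph over spectra plus the full pre-pruning scored pair list."""

    graph: nx.Graph
    params: NetworkParams
    scored_pairs: list[Edge] = field(default_factory=list)

    def edges(self, origin: str | None = None) -> list[Edge]:
        out = []
        for a, b, data in self.graph.edges(data=True):
            e = Edge(a, b, data["cosine"], data["n_matched"], data["delta_prec_mz"], data["origin"])
            if origin is None or e.origin == origin:
                out.append(e)
        return out

    def spectrum(self, node_id: str) -> Spectrum:
        return self.graph.nodes[node_id]["spectrum"]


# ---------------------------------------------------------------------------
# Modified cosine
# ---------------------------------------------------------------------------

def _candidate_pairs(a: Spectrum, b: Spectrum, frag_tol: float):
    """All (i, j, |offset error|) peak pairings, direct or precursor-shifted."""
    shift = a.precursor_mz - b.precursor_mz
    diff = a.mz[:, None] - b.mz[None, :]
    direct = np.abs(diff)
    cands = {}
    ii, jj = np.nonzero(direct <= frag_tol)
    for i, j in zip(ii.tolist(), jj.tolist()):
        cands[(i, j)] = direct[i, j]
    if abs(shift) > frag_tol:  # shifted pairing distinct from direct
        shifted = np.abs(diff - shift)
        ii, jj = np.nonzero(shifted <= frag_tol)
        for i, j in zip(ii.tolist(), jj.tolist()):
            err = shifted[i, j]
            if (i, j) not in cands or err < cands[(i, j)]:
                cands[(i, j)] = err
    return cands


def _sqrt_l2_weights(s: Spectrum) -> np.ndarray:
    w = np.sqrt(np.clip(s.intensity, 0, None))
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError(f"spectrum {s.scan_id!r} has no nonzero intensities")
    return w / norm


def modified_cosine(a: Spectrum, b: Spectrum, frag_tol: float = 0.01) -> tuple[float, int]:
    """Modified cosine similarity and matched-fragment count of two spectra.

    Greedy maximum-product pairing over direct and precursor-shifted
    candidates; each peak used at most once.  Symmetric, in [0, 1], equals
    1 for identical spectra, invariant to uniform intensity scaling.
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("modified_cosine requires non-empty peak lists")
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    wa, wb = _sqrt_l2_weights(a), _sqrt_l2_weights(b)
    cands = _candidate_pairs(a, b, frag_tol)
    if not cands:
        return 0.0, 0
    entries = sorted(
        ((wa[i] * wb[j], err, a.mz[i], i, j) for (i, j), err in cands.items()),
        key=lambda e: (-e[0], e[1], e[2]),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    score = 0.0
    n_matched = 0
    for w, _err, _mz, i, j in entries:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += w
        n_matched += 1
    return float(min(score, 1.0)), n_matched


# ---------------------------------------------------------------------------
# MS/MS clustering (consensus spectra)
# ---------------------------------------------------------------------------

def _consensus(members: list[Spectrum], frag_tol: float, scan_id: str) -> Spectrum:
    """Peak-wise intensity-weighted merge of member spectra."""
    mz = np.concatenate([m.mz for m in members])
    inten = np.concatenate([m.relative_intensity() for m in members])
    order = np.argsort(mz)
    mz, inten = mz[order], inten[order]
    group = np.zeros(mz.size, dtype=int)
    group[1:] = np.cumsum(np.diff(mz) > frag_tol)
    n = group[-1] + 1
    sums = np.bincount(group, weights=inten, minlength=n)
    cmz = np.bincount(group, weights=inten * mz, minlength=n) / np.where(sums > 0, sums, 1.0)
    cint = sums / len(members)
    prec = float(np.average([m.precursor_mz for m in members],
                            weights=[m.base_peak_intensity for m in members]))
    rts = [m.retention_time for m in members if m.retention_time is not None]
    files = sorted({m.source_file for m in members if m.source_file})
    return Spectrum(
        scan_id=scan_id,
        precursor_mz=prec,
        polarity=members[0].polarity,
        mz=cmz,
        intensity=cint,
        retention_time=float(np.mean(rts)) if rts else None,
        charge=members[0].charge,
        source_file=";".join(files),
        metadata={
            "member_scan_ids": [m.scan_id for m in members],
            "n_files": len(files) if files else 1,
        },
    )


def cluster_spectra(
    collection: SpectrumCollection,
    prec_tol: float = 0.01,
    frag_tol: float = 0.01,
    cosine_min: float = 0.7,
    min_files: int = 2,
) -> SpectrumCollection:
    """Greedy MS/MS clustering into consensus spectra with file support.

    Repeatedly seeds a cluster with the most intense unassigned spectrum and
    absorbs unassigned spectra within ``prec_tol`` of its precursor whose
    modified cosine to the seed is at least ``cosine_min``.  The consensus is
    a peak-wise intensity-weighted merge; clusters supported by fewer than
    ``min_files`` distinct source files are dropped.  ``min_files=1`` keeps
    every cluster.
    """
    remaining = sorted(collection, key=lambda s: (-s.base_peak_intensity, s.scan_id))
    consensus: list[Spectrum] = []
    n_dropped = 0
    idx = 0
    while remaining:
        seed = remaining.pop(0)
        members = [seed]
        keep = []
        for s in remaining:
            if (
                abs(s.precursor_mz - seed.precursor_mz) <= prec_tol
                and s.polarity == seed.polarity
                and modified_cosine(seed, s, frag_tol)[0] >= cosine_min
            ):
                members.append(s)
            else:
                keep.append(s)
        remaining = keep
        node = _consensus(members, frag_tol, scan_id=f"consensus_{idx:05d}")
        idx += 1
        if node.metadata["n_files"] >= min_files:
            consensus.append(node)
        else:
            n_dropped += 1
    logger.info("clustered %d spectra into %d consensus nodes (%d dropped by file support)",
                len(collection), len(consensus), n_dropped)
    return SpectrumCollection(consensus)


# ---------------------------------------------------------------------------
# Network build / prune / re-add
# ---------------------------------------------------------------------------

def _score_all_pairs(spectra: list[Spectrum], params: NetworkParams) -> list[Edge]:
    edges = []
    for i in range(len(spectra)):
        a = spectra[i]
        for j in range(i + 1, len(spectra)):
            b = spectra[j]
            cos, nm = modified_cosine(a, b, params.frag_tol)
            if cos >= params.cosine_min and nm >= params.min_matched:
                edges.append(Edge(a.scan_id, b.scan_id, cos, nm, a.precursor_mz - b.precursor_mz))
    return edges


def build_network(nodes, params: NetworkParams = NETWORK_PRESETS["biological"]) -> MolecularNetwork:
    """Score all node pairs and prune GNPS-style.

    Kept scored edges satisfy the cosine and matched-fragment thresholds and
    rank within the ``top_k`` highest-cosine edges of both endpoints; then,
    while any connected component exceeds ``max_component`` nodes, that
    component's lowest-cosine edge is removed (ties broken by lexicographic
    node-id pair).  Deterministic given the input order.
    """
    spectra = list(nodes)
    if len(spectra) < 2:
        raise ValueError("need at least 2 nodes to build a network")
    scored = _score_all_pairs(spectra, params)

    # mutual top-K
    per_node: dict[str, list[Edge]] = {}
    for e in scored:
        per_node.setdefault(e.node_a, []).append(e)
        per_node.setdefault(e.node_b, []).append(e)
    top: dict[str, set[tuple[str, str]]] = {}
    for node, es in per_node.items():
        es_sorted = sorted(es, key=lambda e: (-e.cosine, e.key()))
        top[node] = {e.key() for e in es_sorted[: params.top_k]}
    kept = [e for e in scored if e.key() in top[e.node_a] and e.key() in top[e.node_b]]

    g = nx.Graph()
    for s in spectra:
        g.add_node(s.scan_id, spectrum=s, precursor_mz=s.precursor_mz)
    for e in kept:
        g.add_edge(e.node_a, e.node_b, cosine=e.cosine, n_matched=e.n_matched,
                   delta_prec_mz=e.delta_prec_mz, origin="scored")

    # component-size cap: drop lowest-cosine edge of any oversized component
    while True:
        oversized = [c for c in nx.connected_components(g) if len(c) > params.max_component]
        if not oversized:
            break
        comp = oversized[0]
        worst = min(
            (e for e in g.edges(data=True) if e[0] in comp and e[1] in comp),
            key=lambda e: (e[2]["cosine"], tuple(sorted((e[0], e[1])))),
        )
        g.remove_edge(worst[0], worst[1])

    logger.info("network: %d nodes, %d scored pairs, %d edges kept", len(spectra), len(scored),
                g.number_of_edges())
    return MolecularNetwork(graph=g, params=params, scored_pairs=scored)


def readd_delta_edges(
    network: MolecularNetwork,
    scored_pairs: list[Edge] | None = None,
    targets=DEFAULT_DELTA_TARGETS,
    tol: float = DEFAULT_DELTA_TOL,
) -> MolecularNetwork:
    """Restore pruned edges whose |precursor delta| matches a conjugation shift.

    ``scored_pairs`` defaults to the network's own pre-pruning pair list
    (already thresholded at the build cosine/fragment minima).  Any such pair
    absent from the pruned graph whose absolute precursor difference is
    within ``tol`` of a target is added with ``origin="readded"``; existing
    edges are never removed, and re-added edges are exempt from the top-K and
    component-size limits.
    """
    targets = tuple(targets)
    if not targets:
        raise ValueError("targets must not be empty")
    pairs = network.scored_pairs if scored_pairs is None else scored_pairs
    g = network.graph.copy()
    n_added = 0
    for e in pairs:
        if g.has_edge(e.node_a, e.node_b):
            continue
        if any(abs(abs(e.delta_prec_mz) - t) <= tol for t in targets):
            g.add_edge(e.node_a, e.node_b, cosine=e.cosine, n_matched=e.n_matched,
                       delta_prec_mz=e.delta_prec_mz, origin="readded")
            n_added += 1
    logger.info("re-added %d delta-m/z edges (targets %s)", n_added, targets)
    return MolecularNetwork(graph=g, params=network.params, scored_pairs=list(pairs))


# ---------------------------------------------------------------------------
# Library matching and suspect propagation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryMatch:
    node_id: str
    compound_name: str
    cosine: float
    n_shared_peaks: int
    delta_prec_mz: float
    annotation_tier: str  # "library" | "suspected_isomer"


def _compound_name(s: Spectrum) -> str:
    for key in ("compound_name", "name"):
        if key in s.metadata:
            return str(s.metadata[key])
    return s.scan_id


def library_search(
    nodes,
    library: SpectrumCollection,
    cosine_min: float = 0.7,
    min_peaks: int = 4,
    prec_tol: float = 0.02,
    frag_tol: float = 0.02,
    rt_tol: float = 30.0,
) -> list[LibraryMatch]:
    """Best library match per node (highest cosine above the thresholds).

    Candidates must fall within ``prec_tol`` of the node's precursor and pass
    ``cosine_min`` / ``min_peaks`` on the MS/MS comparison.  A candidate whose
    retention time disagrees with the node's by more than ``rt_tol`` seconds
    (both known) is tiered ``suspected_isomer`` -- same mass and
    fragmentation, different chromatographic identity -- otherwise
    ``library``.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    matches = []
    for node in nodes:
        best: LibraryMatch | None = None
        for ref in library:
            if ref.polarity != node.polarity:
                continue
            dprec = node.precursor_mz - ref.precursor_mz
            if abs(dprec) > prec_tol:
                continue
            cos, nm = modified_cosine(node, ref, frag_tol)
            if cos < cosine_min or nm < min_peaks:
                continue
            rt_mismatch = (
                node.retention_time is not None
                and ref.retention_time is not None
                and abs(node.retention_time - ref.retention_time) > rt_tol
            )
            cand = LibraryMatch(
                node_id=node.scan_id,
                compound_name=_compound_name(ref),
                cosine=cos,
                n_shared_peaks=nm,
                delta_prec_mz=dprec,
                annotation_tier="suspected_isomer" if rt_mismatch else "library",
            )
            if best is None or cand.cosine > best.cosine:
                best = cand
        if best is not None:
            matches.append(best)
    return matches


def propagate_suspect_annotations(
    network: MolecularNetwork,
    matches: list[LibraryMatch],
    calls,
    delta_tol: float = DEFAULT_DELTA_TOL,
) -> pd.DataFrame:
    """Depth-1 suspect annotation of conjugates from annotated neighbors.

    An unannotated node flagged as glucuronide by the pattern filter that is
    connected by an edge whose |precursor delta| matches 176.032 or 194.042
    (within ``delta_tol``) to a library-annotated aglycone A receives the
    candidate label ``"suspect A glucuronide"``.  An unannotated node linked
    at the 96.075 delta to a library-annotated glucuronide ``"X glucuronide"``
    receives ``"suspect X sulfate"``.  Candidates from multiple neighbors are
    all listed, ranked by edge cosine; a direct library match is never
    overwritten.

    ``calls`` maps node id -> :class:`~gluconet.fingerprint.GlucuronideCall`
    (or is the DataFrame from ``filter_collection``).
    """
    if isinstance(calls, pd.DataFrame):
        is_glucuronide = dict(zip(calls["scan_id"].astype(str), calls["is_match"].astype(bool)))
    else:
        is_glucuronide = {k: bool(v.is_match) for k, v in calls.items()}
    by_node = {}
    for m in matches:
        if m.node_id not in by_node or m.cosine > by_node[m.node_id].cosine:
            by_node[m.node_id] = m
    annotated = {n: m for n, m in by_node.items() if m.annotation_tier == "library"}

    rows = []
    for node in network.graph.nodes:
        if node in annotated:
            continue
        candidates: list[tuple[float, str]] = []  # (edge cosine, label)
        for nbr in network.graph.neighbors(node):
            data = network.graph.edges[node, nbr]
            adelta = abs(data["delta_prec_mz"])
            nbr_match = annotated.get(nbr)
            if nbr_match is None:
                continue
            if is_glucuronide.get(node, False) and any(
                abs(adelta - t) <= delta_tol for t in GLUCURONIDE_DELTAS
            ):
                candidates.append((data["cosine"], f"suspect {nbr_match.compound_name} glucuronide"))
            if abs(adelta - chem.GLUCURONIDE_SULFATE_DELTA) <= delta_tol:
                name = nbr_match.compound_name
                if name.endswith(" glucuronide"):
                    aglycone = name[: -len(" glucuronide")]
                    candidates.append((data["cosine"], f"suspect {aglycone} sulfate"))
        if candidates:
            candidates.sort(key=lambda c: (-c[0], c[1]))
            rows.append(
                {
                    "node_id": node,
                    "suspect_annotation": candidates[0][1],
                    "candidates": ";".join(label for _, label in candidates),
                    "n_candidates": len(candidates),
                    "best_edge_cosine": candidates[0][0],
                }
            )
    return pd.DataFrame(
        rows, columns=["node_id", "suspect_annotation", "candidates", "n_candidates", "best_edge_cosine"]
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_network(
    network: MolecularNetwork,
    path,
    annotations: pd.DataFrame | None = None,
    edge_list_path=None,
) -> None:
    """Write GraphML (Cytoscape-importable) plus an edge-list TSV.

    The edge list carries ``node_a, node_b, cosine, n_matched, delta_prec_mz,
    origin``; node attributes include precursor m/z and any suspect
    annotation from ``annotations`` (a ``propagate_suspect_annotations``
    table).
    """
    g = nx.Graph()
    ann = {}
    if annotations is not None and len(annotations):
        ann = dict(zip(annotations["node_id"], annotations["suspect_annotation"]))
    for node, data in network.graph.nodes(data=True):
        attrs = {"precursor_mz": float(data["spectrum"].precursor_mz)}
        if node in ann:
            attrs["suspect_annotation"] = ann[node]
        g.add_node(node, **attrs)
    for a, b, data in network.graph.edges(data=True):
        g.add_edge(a, b, cosine=float(data["cosine"]), n_matched=int(data["n_matched"]),
                   delta_prec_mz=float(data["delta_prec_mz"]), origin=data["origin"])
    nx.write_graphml(g, str(path))
    if edge_list_path is None:
        edge_list_path = Path(path).with_suffix(".edges.tsv")
    pd.DataFrame(
        [
            {"node_a": a, "node_b": b, "cosine": d["cosine"], "n_matched": d["n_matched"],
             "delta_prec_mz": d["delta_prec_mz"], "origin": d["origin"]}
            for a, b, d in network.graph.edges(data=True)
        ],
        columns=["node_a", "node_b", "cosine", "n_matched", "delta_prec_mz", "origin"],
    ).to_csv(edge_list_path, sep="\t", index=False)
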