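"""Domain types and file I/O shared by the whole pipeline.

Four containers travel between modules:

* :class:`Alignment` — amino-acid sites over named taxa,
* :class:`Topology` — an unrooted binary tree with branch lengths,
* :class:`TimeCourse` — one replicate's (time, signal) trace from one of
  the three kinetic assays,
* :class:`Spectrum` — a wavelength-indexed absorbance curve.

File formats are delegated to Biopython (FASTA, relaxed PHYLIP) and
DendroPy (Newick); tables are CSV with a header, comma-delimited, UTF-8.
Times are seconds and wavelengths nanometres throughout.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DuplicateTaxon,
    EmptyFile,
    FewerThanThreeTips,
    MissingColumn,
    NonMonotoneTime,
    ParseError,
    RaggedAlignment,
)

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
#: integer code for "fully ambiguous" residue (gap, X, B, Z, ...)
UNKNOWN = 20

ASSAYS = ("gtpgs_dark", "fluor_light", "retinal_release")
CONDITIONS = ("pigment_n", "pigment_7mr", "with_Gt", "without_Gt", "plain")

#: branch length substituted when a Newick edge carries none
DEFAULT_BRANCH_LENGTH = 0.1


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """Amino-acid alignment: ``taxa[i]`` owns row ``i`` of ``sites``.

    ``sites`` holds integer codes 0..19 in ARNDCQEGHILKMFPSTWYV order;
    anything outside the 20 canonical residues is coded :data:`UNKNOWN`
    and treated as fully ambiguous by the likelihood engine.
    """

    taxa: tuple[str, ...]
    sites: np.ndarray  # (n_taxa, n_sites) int8

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise DuplicateTaxon(f"duplicate taxon names in {self.taxa}")
        if self.sites.ndim != 2 or self.sites.shape[0] != len(self.taxa):
            raise RaggedAlignment("site matrix shape does not match taxa")
        if self.sites.shape[1] < 1:
            raise EmptyFile("alignment has zero sites")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.sites.shape[1]

    def sequences(self) -> dict[str, str]:
        """Decode back to one-letter strings (ambiguous -> 'X')."""
        lookup = AMINO_ACIDS + "X"
        return {
            t: "".join(lookup[c] for c in row)
            for t, row in zip(self.taxa, self.sites)
        }

    def residue_frequencies(self) -> np.ndarray:
        """Empirical frequencies of the 20 residues (ambiguous ignored)."""
        counts = np.bincount(self.sites[self.sites < 20].ravel(), minlength=20)
        total = counts.sum()
        if total == 0:
            return np.full(20, 1 / 20)
        return counts / total


def encode_residues(seq: str) -> np.ndarray:
    codes = np.full(len(seq), UNKNOWN, dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        j = AMINO_ACIDS.find(ch)
        if j >= 0:
            codes[i] = j
    return codes


def alignment_from_sequences(named_seqs: list[tuple[str, str]]) -> Alignment:
    if not named_seqs:
        raise EmptyFile("no sequence records")
    names = [n for n, _ in named_seqs]
    if len(set(names)) != len(names):
        raise DuplicateTaxon(f"duplicate taxon names among {names}")
    lengths = {len(s) for _, s in named_seqs}
    if len(lengths) != 1:
        raise RaggedAlignment(f"sequence lengths differ: {sorted(lengths)}")
    sites = np.vstack([encode_residues(s) for _, s in named_seqs])
    return Alignment(tuple(names), sites)


def read_fasta(path: str | Path) -> Alignment:
    """Read an amino-acid FASTA file into an :class:`Alignment`."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    return alignment_from_sequences(records)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in aln.sequences().items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_phylip(path: str | Path) -> Alignment:
    """Read a relaxed-PHYLIP amino-acid alignment."""
    try:
        msa = AlignIO.read(str(path), "phylip-relaxed")
    except ValueError as exc:
        raise ParseError(f"not valid relaxed PHYLIP: {exc}") from exc
    return alignment_from_sequences([(r.id, str(r.seq)) for r in msa])


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

class Topology:
    """Unrooted binary tree over named tips with branch lengths.

    Nodes are integers; ids ``0..n_tips-1`` are the tips, in the order of
    :attr:`tips`.  Internal nodes have degree 3 (the tree is stored
    unrooted; a rooted Newick input has its degree-2 root collapsed).
    Branch lengths are expected substitutions per site.
    """

    def __init__(self, tips, edges, id: int | None = None):
        self.tips: tuple[str, ...] = tuple(tips)
        self.edges: list[tuple[int, int, float]] = [
            (int(u), int(v), float(w)) for u, v, w in edges
        ]
        self.id = id
        self._validate()

    # -- construction and validation ------------------------------------
    def _validate(self):
        n = len(self.tips)
        if n < 3:
            raise FewerThanThreeTips(f"{n} tips; an unrooted tree needs >= 3")
        if len(set(self.tips)) != n:
            raise DuplicateTaxon(f"duplicate tip names in {self.tips}")
        deg: dict[int, int] = {}
        for u, v, w in self.edges:
            if not np.isfinite(w) or w < 0:
                raise ParseError(f"branch length {w} on edge ({u},{v})")
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        for node, d in deg.items():
            if node < n and d != 1:
                raise ParseError(f"tip node {node} has degree {d}")
            if node >= n and d != 3:
                raise ParseError(f"internal node {node} has degree {d} != 3")
        # connectivity
        if len(self._component(self.edges[0][0])) != len(deg):
            raise ParseError("tree edges are not connected")

    def _component(self, start: int) -> set[int]:
        adj = self.adjacency()
        seen = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v, _ in adj.get(u, ()):
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        return seen

    # -- basic queries ----------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {}
        for u, v, w in self.edges:
            adj.setdefault(u, []).append((v, w))
            adj.setdefault(v, []).append((u, w))
        return adj

    def total_length(self) -> float:
        return sum(w for _, _, w in self.edges)

    def with_branch_lengths(self, lengths) -> "Topology":
        """Same shape with edge ``i`` set to ``lengths[i]``."""
        new_edges = [
            (u, v, float(l)) for (u, v, _), l in zip(self.edges, lengths)
        ]
        return Topology(self.tips, new_edges, id=self.id)

    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions, each encoded as the tip-name set on
        the side *not* containing the lexicographically first tip."""
        ref = min(self.tips)
        out = set()
        adj = self.adjacency()
        for u, v, _ in self.edges:
            side = self._side_tips(u, v, adj)
            if 1 < len(side) < self.n_tips - 1:
                names = frozenset(self.tips[i] for i in side)
                if ref in names:
                    names = frozenset(set(self.tips) - names)
                out.add(names)
        return frozenset(out)

    def _side_tips(self, u: int, v: int, adj) -> set[int]:
        """Tip ids on the ``u`` side of edge (u, v)."""
        seen = {u, v}
        queue = deque([u])
        tips = set()
        while queue:
            x = queue.popleft()
            if x < self.n_tips:
                tips.add(x)
            for y, _ in adj[x]:
                if y not in seen:
                    seen.add(y)
                    queue.append(y)
        return tips

    def same_shape(self, other: "Topology") -> bool:
        return set(self.tips) == set(other.tips) and self.splits() == other.splits()

    # -- traversal for the likelihood engine -----------------------------
    def postorder(self, root: int | None = None):
        """(node, parent, branch_length) in postorder below ``root``.

        ``root`` defaults to the highest-numbered internal node.  The root
        itself is yielded last with parent ``-1`` and length 0.
        """
        if root is None:
            root = max(max(u, v) for u, v, _ in self.edges)
        adj = self.adjacency()
        order = []
        stack = [(root, -1, 0.0)]
        while stack:
            node, parent, w = stack.pop()
            order.append((node, parent, w))
            for child, cw in adj[node]:
                if child != parent:
                    stack.append((child, node, cw))
        return order[::-1]

    # -- Newick -----------------------------------------------------------
    def to_newick(self) -> str:
        root = max(max(u, v) for u, v, _ in self.edges)
        adj = self.adjacency()

        def render(node: int, parent: int) -> str:
            children = [(c, w) for c, w in adj[node] if c != parent]
            if not children:
                # find length back to parent
                w = next(w for c, w in adj[parent] if c == node)
                return f"{self.tips[node]}:{w:.10g}"
            inner = ",".join(render(c, node) for c, _ in children)
            if parent == -1:
                return f"({inner})"
            w = next(w for c, w in adj[parent] if c == node)
            return f"({inner}):{w:.10g}"

        return render(root, -1) + ";"

    def __repr__(self):
        return f"Topology(id={self.id}, tips={self.tips}, newick={self.to_newick()!r})"


def topology_from_dendropy(tree: dendropy.Tree, id: int | None = None) -> Topology:
    """Convert a DendroPy tree, collapsing a degree-2 root if present."""
    leaves = [lf for lf in tree.leaf_node_iter()]
    names = []
    for lf in leaves:
        if lf.taxon is None or lf.taxon.label is None:
            raise ParseError("unnamed leaf in Newick tree")
        names.append(lf.taxon.label)
    if len(names) < 3:
        raise FewerThanThreeTips(f"{len(names)} tips; need >= 3")
    if len(set(names)) != len(names):
        raise DuplicateTaxon(f"duplicate tip labels {names}")

    ids: dict[int, int] = {id_of(lf): i for i, lf in enumerate(leaves)}
    next_id = len(leaves)
    edges: list[list[float | int]] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        for n in (node, node.parent_node):
            if id_of(n) not in ids:
                ids[id_of(n)] = next_id
                next_id += 1
        w = node.edge.length
        edges.append([
            ids[id_of(node.parent_node)],
            ids[id_of(node)],
            DEFAULT_BRANCH_LENGTH if w is None else float(w),
        ])

    # collapse degree-2 nodes (the root of a rooted newick)
    edges = _collapse_degree_two(edges, n_tips=len(leaves))
    return Topology(names, edges, id=id)


def id_of(obj) -> int:
    return id(obj)


def _collapse_degree_two(edges, n_tips):
    changed = True
    while changed:
        changed = False
        deg: dict[int, list[int]] = {}
        for i, (u, v, w) in enumerate(edges):
            deg.setdefault(u, []).append(i)
            deg.setdefault(v, []).append(i)
        for node, incident in deg.items():
            if node >= n_tips and len(incident) == 2:
                i, j = incident
                (u1, v1, w1), (u2, v2, w2) = edges[i], edges[j]
                a = u1 if v1 == node else v1
                b = u2 if v2 == node else v2
                new = [a, b, w1 + w2]
                edges = [e for k, e in enumerate(edges) if k not in (i, j)]
                edges.append(new)
                changed = True
                break
    # renumber internal ids contiguously
    internal = sorted({u for u, v, w in edges if u >= n_tips}
                      | {v for u, v, w in edges if v >= n_tips})
    remap = {old: n_tips + i for i, old in enumerate(internal)}
    return [
        (remap.get(u, u), remap.get(v, v), w) for u, v, w in edges
    ]


def read_newick(path_or_string: str | Path) -> Topology:
    """Read a single Newick tree; rooted input is unrooted on the fly."""
    text = None
    p = Path(str(path_or_string))
    if p.exists():
        text = p.read_text()
    else:
        s = str(path_or_string)
        if "(" in s and ";" in s:
            text = s
        else:
            raise ParseError(f"no such file and not a Newick string: {s!r}")
    if not text.strip():
        raise EmptyFile("empty Newick input")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"Newick parse failed: {exc}") from exc
    return topology_from_dendropy(tree)


def write_newick(topo: Topology, path: str | Path) -> None:
    Path(path).write_text(topo.to_newick() + "\n")


# ---------------------------------------------------------------------------
# TimeCourse
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeCourse:
    """One replicate's (time, signal) trace for one assay condition."""

    assay: str
    condition: str
    replicate: int
    times: np.ndarray  # seconds, strictly increasing
    signal: np.ndarray

    def __post_init__(self):
        if self.assay not in ASSAYS:
            raise ParseError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        if self.condition not in CONDITIONS:
            raise ParseError(f"unknown condition {self.condition!r}")
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", y)
        if t.size < 4:
            raise ParseError(f"trace needs >= 4 points, got {t.size}")
        if t.size != y.size:
            raise ParseError("times and signal lengths differ")
        if not (np.diff(t) > 0).all():
            raise NonMonotoneTime("times not strictly increasing")
        if not (np.isfinite(t).all() and np.isfinite(y).all()):
            raise ParseError("non-finite value in trace")


TIMECOURSE_COLUMNS = ["assay", "condition", "replicate", "time_s", "signal"]


def read_timecourse_table(path: str | Path) -> list[TimeCourse]:
    """Read ``timecourse.csv`` into one TimeCourse per
    (assay, condition, replicate), rows sorted by time within each trace."""
    df = pd.read_csv(path)
    missing = [c for c in TIMECOURSE_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumn(f"timecourse table lacks columns {missing}")
    if df.empty:
        raise EmptyFile(f"{path}: no data rows")
    out = []
    for (assay, cond, rep), grp in df.groupby(
        ["assay", "condition", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy(dtype=float)
        if (np.diff(t) <= 0).any():
            raise NonMonotoneTime(
                f"duplicate/unsorted times in ({assay}, {cond}, rep {rep})"
            )
        out.append(
            TimeCourse(assay, cond, int(rep), t, grp["signal"].to_numpy(float))
        )
    return out


def write_timecourse_table(traces: list[TimeCourse], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "assay": tc.assay,
                "condition": tc.condition,
                "replicate": tc.replicate,
                "time_s": tc.times,
                "signal": tc.signal,
            }
        )
        for tc in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spectrum:
    """Absorbance vs wavelength, with a free-text label (e.g. "t=600 dark")."""

    wavelengths: np.ndarray  # nm, strictly increasing
    absorbance: np.ndarray  # AU
    label: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.size != ab.size or wl.size < 2:
            raise ParseError("spectrum arrays malformed")
        if not (np.diff(wl) > 0).all():
            raise ParseError("wavelength grid not strictly increasing")

    def same_grid(self, other: "Spectrum") -> bool:
        return (
            self.wavelengths.size == other.wavelengths.size
            and np.array_equal(self.wavelengths, other.wavelengths)
        )

    def at(self, wavelength: float, bandwidth: float = 0.0) -> float:
        """Absorbance read at ``wavelength``.

        With ``bandwidth`` > 0 the reading is the mean over grid points
        within +/- bandwidth/2, emulating the spectral bandwidth of a
        monochromator readout (and suppressing grid-point noise).
        """
        if bandwidth > 0:
            mask = np.abs(self.wavelengths - wavelength) <= bandwidth / 2
            if mask.any():
                return float(self.absorbance[mask].mean())
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return float(self.absorbance[i])


SPECTRUM_COLUMNS = ["label", "wavelength_nm", "absorbance"]


def read_spectrum_table(path: str | Path) -> list[Spectrum]:
    df = pd.read_csv(path)
    missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumn(f"spectrum table lacks columns {missing}")
    if df.empty:
        raise EmptyFile(f"{path}: no data rows")
    out = []
    for label, grp in df.groupby("label", sort=False):
        grp = grp.sort_values("wavelength_nm")
        out.append(
            Spectrum(
                grp["wavelength_nm"].to_numpy(float),
                grp["absorbance"].to_numpy(float),
                label=str(label),
            )
        )
    return out


def write_spectrum_table(spectra: list[Spectrum], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "label": s.label,
                "wavelength_nm": s.wavelengths,
                "absorbance": s.absorbance,
            }
        )
        for s in spectra
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
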