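"""Likelihoods of amino-acid alignments on small unrooted trees.

The engine is Felsenstein pruning under a reversible empirical
exchangeability model (JTT by default, any 20x20 table accepted — e.g. a
transmembrane-specific variant supplied as a file) with Yang's
discrete-gamma model of among-site rate variation.  Trees are small
enough (<= 8 effective tips) that every unrooted binary topology can be
enumerated and scored exhaustively, which is exactly the regime in which
candidate gene-family branching orders are compared by per-site
log-likelihoods.

Sections, in pipeline order:

1. substitution model construction (``build_model``),
2. discrete-gamma rates (``discrete_gamma``),
3. per-site log-likelihoods by pruning (``site_log_likelihoods``),
4. branch-length and shape optimization,
5. exhaustive topology enumeration (with an optional fixed subtree),
6. ``exhaustive_ml`` producing the sites x topologies matrix consumed by
   the topology-test module, and RELL bootstrap split support.
"""

from __future__ import annotations

import hashlib
from collections import deque
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as gamma_dist

from .errors import (
    AsymmetricTable,
    BadFrequencies,
    BadShape,
    EmptyMatrix,
    ParseError,
    TaxonMismatch,
    TooManyTips,
)
from .io import (
    DEFAULT_BRANCH_LENGTH,
    UNKNOWN,
    Alignment,
    Topology,
)

#: bounds for maximum-likelihood branch lengths (substitutions/site)
MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 20.0
#: total-lnL convergence tolerance for coordinate-wise optimization
LNL_TOL = 1e-6
#: bounds for the gamma shape parameter during optimization
ALPHA_BOUNDS = (0.02, 100.0)


# ---------------------------------------------------------------------------
# 1. Substitution model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionModel:
    """Reversible amino-acid rate matrix with cached eigendecomposition.

    ``Q`` is normalized so the expected substitution rate at stationarity
    is 1, i.e. branch lengths are expected substitutions per site.
    """

    exchangeabilities: np.ndarray  # (20, 20) symmetric, zero diagonal
    frequencies: np.ndarray  # (20,) sums to 1
    Q: np.ndarray = field(init=False, repr=False)
    _evals: np.ndarray = field(init=False, repr=False)
    _evecs: np.ndarray = field(init=False, repr=False)  # D^{-1/2} V
    _evecs_inv: np.ndarray = field(init=False, repr=False)  # V' D^{1/2}

    def __post_init__(self):
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if S.shape != (20, 20) or not np.allclose(S, S.T):
            raise AsymmetricTable("exchangeability table must be 20x20 symmetric")
        off = S[~np.eye(20, dtype=bool)]
        if (off < 0).any():
            raise AsymmetricTable("negative off-diagonal exchangeability")
        if pi.shape != (20,) or (pi < 0).any() or abs(pi.sum() - 1) > 1e-4:
            raise BadFrequencies("frequencies must be non-negative and sum to 1")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        Q = Q / mu
        # symmetrize via D^{1/2} Q D^{-1/2} for a stable eigendecomposition
        sq = np.sqrt(pi)
        B = (Q / sq[None, :]) * sq[:, None]
        evals, V = np.linalg.eigh((B + B.T) / 2)
        object.__setattr__(self, "exchangeabilities", S)
        object.__setattr__(self, "frequencies", pi)
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "_evals", evals)
        object.__setattr__(self, "_evecs", V / sq[:, None])
        object.__setattr__(self, "_evecs_inv", V.T * sq[None, :])

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, P(0) = I."""
        if t < 0:
            raise ValueError("negative branch length")
        P = (self._evecs * np.exp(self._evals * t)) @ self._evecs_inv
        return np.clip(P, 0.0, None)

    def transition_matrices(self, ts) -> np.ndarray:
        """Stack of P(t) for several times, shape (len(ts), 20, 20)."""
        ts = np.asarray(ts, dtype=float)
        E = np.exp(np.outer(ts, self._evals))  # (m, 20)
        P = np.einsum("ij,mj,jk->mik", self._evecs, E, self._evecs_inv)
        return np.clip(P, 0.0, None)


def _read_rate_table(source) -> tuple[np.ndarray, np.ndarray]:
    """Parse a PAML-style table: 190 lower-triangle values then 20
    frequencies, comments starting with '#'."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    tokens = []
    for line in text.splitlines():
        line = line.split("#", 1)[0]
        tokens.extend(line.split())
    vals = np.array([float(x) for x in tokens])
    if vals.size < 190 + 20:
        raise ParseError(f"rate table has {vals.size} numbers, need 210")
    tri, pi = vals[:190], vals[190:210]
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = tri[k]
            k += 1
    return S, pi


def load_builtin_table(name: str = "JTT") -> tuple[np.ndarray, np.ndarray]:
    if name.upper() != "JTT":
        raise ParseError(f"unknown built-in table {name!r}; supply a file")
    ref = resources.files("dimlight") / "data" / "jtt.dat"
    return _read_rate_table(ref.open())


def build_model(
    exchangeability_table="JTT",
    frequencies="model",
    alignment: Alignment | None = None,
) -> SubstitutionModel:
    """Construct a reversible model from a named or user-supplied table.

    ``frequencies`` is ``"model"`` (the table's own frequencies),
    ``"empirical"`` (counted from ``alignment``), or an explicit array.
    """
    if isinstance(exchangeability_table, str) and exchangeability_table.upper() == "JTT":
        S, table_pi = load_builtin_table("JTT")
    elif isinstance(exchangeability_table, (str, Path)):
        S, table_pi = _read_rate_table(exchangeability_table)
    else:
        S = np.asarray(exchangeability_table, dtype=float)
        table_pi = None

    if isinstance(frequencies, str):
        if frequencies == "model":
            if table_pi is None:
                raise BadFrequencies("table carries no frequencies; pass them")
            pi = table_pi
        elif frequencies == "empirical":
            if alignment is None:
                raise BadFrequencies("empirical frequencies need an alignment")
            # floor unseen residues so the reversible model stays proper
            pi = np.clip(alignment.residue_frequencies(), 1e-6, None)
            pi = pi / pi.sum()
        else:
            raise BadFrequencies(f"unknown frequency mode {frequencies!r}")
    else:
        pi = np.asarray(frequencies, dtype=float)
    return SubstitutionModel(S, pi)


# ---------------------------------------------------------------------------
# 2. Discrete gamma rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaRates:
    """Yang's k-category equal-probability discretization of a mean-one
    gamma distribution of site rates; each category's rate is the mean of
    the gamma density over its inter-quantile slice."""

    alpha: float
    rates: np.ndarray

    @property
    def k(self) -> int:
        return self.rates.size


def discrete_gamma(alpha: float, k: int) -> GammaRates:
    if not (alpha > 0) or not np.isfinite(alpha):
        raise BadShape(f"gamma shape must be positive, got {alpha}")
    if k < 1:
        raise BadShape(f"need >= 1 category, got {k}")
    if k == 1:
        return GammaRates(float(alpha), np.array([1.0]))
    # Gamma(shape=alpha, rate=alpha): mean 1. Category means via the
    # incomplete-gamma identity E[X; X<b] = gammainc(alpha+1, alpha*b).
    probs = np.arange(1, k) / k
    bounds = gamma_dist.ppf(probs, alpha, scale=1.0 / alpha)
    upper = np.concatenate([gammainc(alpha + 1, alpha * bounds), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1, alpha * bounds)])
    rates = k * (upper - lower)
    rates = rates / rates.mean() * 1.0  # guard against ppf round-off
    return GammaRates(float(alpha), rates)


# ---------------------------------------------------------------------------
# 3. Per-site log-likelihoods (Felsenstein pruning)
# ---------------------------------------------------------------------------

def _encode_patterns(aln: Alignment, taxa_order: tuple[str, ...]):
    """Compress alignment columns into unique site patterns.

    Returns (patterns: (n_taxa, n_patterns) int8, site_to_pattern index).
    Rows follow ``taxa_order``.
    """
    rows = [aln.sites[aln.taxa.index(t)] for t in taxa_order]
    cols = np.vstack(rows).T  # (n_sites, n_taxa)
    patterns, inverse = np.unique(cols, axis=0, return_inverse=True)
    return patterns.T.copy(), inverse


def _pruning_log_likelihood(
    topo: Topology,
    patterns: np.ndarray,
    model: SubstitutionModel,
    rates: GammaRates,
) -> np.ndarray:
    """Per-pattern log-likelihood, averaged over gamma categories."""
    n_tips = topo.n_tips
    n_pat = patterns.shape[1]
    order = topo.postorder()
    pi = model.frequencies

    # tip partials are category-independent
    tip_partials = {}
    eye = np.eye(20)
    for tip in range(n_tips):
        codes = patterns[tip]
        part = np.ones((20, n_pat))
        known = codes < UNKNOWN
        part[:, known] = eye[:, codes[known]]
        tip_partials[tip] = part

    log_cat = np.empty((rates.k, n_pat))
    for c, r in enumerate(rates.rates):
        partial = {}
        log_scale = np.zeros(n_pat)
        for node, parent, blen in order:
            if node < n_tips:
                part = tip_partials[node]
            else:
                part = partial.pop(node)
                # rescale to dodge underflow; compensate in log space
                mx = part.max(axis=0)
                mx = np.where(mx > 0, mx, 1.0)
                part = part / mx
                log_scale += np.log(mx)
            if parent == -1:
                site_like = pi @ part
                log_cat[c] = np.log(np.clip(site_like, 1e-300, None)) + log_scale
                break
            P = model.transition_matrix(blen * r)
            msg = P @ part
            if parent in partial:
                partial[parent] = partial[parent] * msg
            else:
                partial[parent] = msg
    return logsumexp(log_cat, axis=0) - np.log(rates.k)


def site_log_likelihoods(
    aln: Alignment,
    topo: Topology,
    model: SubstitutionModel,
    rates: GammaRates,
) -> np.ndarray:
    """Log-likelihood of every alignment column on ``topo``.

    Ambiguity codes contribute all-ones tip partials; the result is
    invariant under re-rooting because the model is reversible.
    """
    if set(topo.tips) != set(aln.taxa):
        raise TaxonMismatch(
            f"tree tips {sorted(topo.tips)} != taxa {sorted(aln.taxa)}"
        )
    patterns, inverse = _encode_patterns(aln, topo.tips)
    per_pattern = _pruning_log_likelihood(topo, patterns, model, rates)
    return per_pattern[inverse]


def total_log_likelihood(aln, topo, model, rates) -> float:
    return float(site_log_likelihoods(aln, topo, model, rates).sum())


# ---------------------------------------------------------------------------
# 4. Branch-length and shape optimization
# ---------------------------------------------------------------------------

def _patterns_lnl(topo, patterns, weights, model, rates) -> float:
    per_pattern = _pruning_log_likelihood(topo, patterns, model, rates)
    return float(per_pattern @ weights)


def _tip_partials(patterns, n_tips):
    n_pat = patterns.shape[1]
    eye = np.eye(20)
    out = {}
    for tip in range(n_tips):
        codes = patterns[tip]
        part = np.ones((20, n_pat))
        known = codes < UNKNOWN
        part[:, known] = eye[:, codes[known]]
        out[tip] = part
    return out


def _directed_messages(topo, patterns, model, rates):
    """Conditional likelihood of the data on the ``x`` side of every
    directed edge (x, y), given the state at ``x``.

    Returns ``(msgs, scales)``: ``msgs[(x, y)]`` has shape
    (k, 20, n_patterns) and ``scales[(x, y)]`` (k, n_patterns) holds the
    per-pattern log rescaling factors.  With a reversible model the
    likelihood through edge (u, v) of length t is
    ``(pi * A)^T P(t) B`` for A = msgs[(u, v)], B = msgs[(v, u)].
    """
    n_tips = topo.n_tips
    n_pat = patterns.shape[1]
    k = rates.k
    adj = topo.adjacency()
    tips = _tip_partials(patterns, n_tips)

    msgs: dict = {}
    scales: dict = {}
    pending = deque(
        (x, y) for x, nb in adj.items() for y, _ in nb
    )
    while pending:
        x, y = pending.popleft()
        if (x, y) in msgs:
            continue
        if x < n_tips:
            msgs[(x, y)] = np.broadcast_to(tips[x], (k, 20, n_pat))
            scales[(x, y)] = np.zeros((k, n_pat))
            continue
        deps = [(z, w) for z, w in adj[x] if z != y]
        if any((z, x) not in msgs for z, _ in deps):
            pending.append((x, y))
            continue
        part = np.ones((k, 20, n_pat))
        scale = np.zeros((k, n_pat))
        for z, w in deps:
            P = model.transition_matrices(w * rates.rates)  # (k, 20, 20)
            part = part * np.einsum("cij,cjp->cip", P, msgs[(z, x)])
            scale = scale + scales[(z, x)]
        mx = part.max(axis=1)
        mx = np.where(mx > 0, mx, 1.0)
        part = part / mx[:, None, :]
        scale = scale + np.log(mx)
        msgs[(x, y)] = part
        scales[(x, y)] = scale
    return msgs, scales


def _edge_lnl(t, A, sA, B, sB, model, rates, weights):
    """Total lnL as a function of one edge's length, all else cached."""
    P = model.transition_matrices(t * rates.rates)  # (k, 20, 20)
    piA = model.frequencies[None, :, None] * A
    tmp = np.einsum("cji,cjp->cip", P, piA)  # P(t)^T (pi * A)
    Lc = np.clip((tmp * B).sum(axis=1), 1e-300, None)  # (k, n_pat)
    per_pat = logsumexp(np.log(Lc) + sA + sB, axis=0) - np.log(rates.k)
    return float(per_pat @ weights)


def optimize_branch_lengths(
    aln: Alignment,
    topo: Topology,
    model: SubstitutionModel,
    rates: GammaRates,
    max_cycles: int = 20,
    tol: float = LNL_TOL,
) -> tuple[Topology, float]:
    """Coordinate-wise ML branch lengths on a fixed topology.

    Cycles Brent's bounded minimizer over every branch until the total
    lnL improves by less than ``tol``.  lnL never decreases: a proposed
    branch value is kept only if it improves the total.
    """
    if set(topo.tips) != set(aln.taxa):
        raise TaxonMismatch("tree tips and alignment taxa differ")
    patterns, inverse = _encode_patterns(aln, topo.tips)
    weights = np.bincount(inverse, minlength=patterns.shape[1]).astype(float)

    lengths = [w for _, _, w in topo.edges]
    current = topo.with_branch_lengths(lengths)
    best = _patterns_lnl(current, patterns, weights, model, rates)
    first_cycle_improved = False

    for cycle in range(max_cycles):
        cycle_start = best
        for i, (u, v, _) in enumerate(current.edges):
            msgs, scales = _directed_messages(current, patterns, model, rates)
            A, sA = msgs[(u, v)], scales[(u, v)]
            B, sB = msgs[(v, u)], scales[(v, u)]
            res = minimize_scalar(
                lambda x: -_edge_lnl(x, A, sA, B, sB, model, rates, weights),
                bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
                method="bounded",
                options={"xatol": 1e-7},
            )
            if -res.fun > best:
                best = -res.fun
                lengths[i] = float(res.x)
                current = current.with_branch_lengths(lengths)
        if cycle == 0:
            first_cycle_improved = best > cycle_start
        if best - cycle_start < tol:
            break
    result = current.with_branch_lengths(lengths)
    result.no_improvement = not first_cycle_improved  # diagnostic flag
    return result, best


def optimize_shape(
    aln: Alignment,
    topo: Topology,
    model: SubstitutionModel,
    k: int = 4,
    alpha0: float = 1.0,
    rounds: int = 3,
) -> tuple[Topology, GammaRates, float]:
    """Alternate branch-length and gamma-shape optimization on one tree."""
    alpha = alpha0
    tree = topo
    lnl = -np.inf
    patterns, inverse = _encode_patterns(aln, topo.tips)
    weights = np.bincount(inverse, minlength=patterns.shape[1]).astype(float)
    for _ in range(rounds):
        tree, lnl = optimize_branch_lengths(aln, tree, model, discrete_gamma(alpha, k))

        def neg(log_a):
            r = discrete_gamma(float(np.exp(log_a)), k)
            return -_patterns_lnl(tree, patterns, weights, model, r)

        res = minimize_scalar(
            neg,
            bounds=(np.log(ALPHA_BOUNDS[0]), np.log(ALPHA_BOUNDS[1])),
            method="bounded",
            options={"xatol": 1e-4},
        )
        new_alpha = float(np.exp(res.x))
        new_lnl = -res.fun
        if new_lnl <= lnl + LNL_TOL:
            break
        alpha, lnl = new_alpha, new_lnl
    return tree, discrete_gamma(alpha, k), lnl


# ---------------------------------------------------------------------------
# 5. Exhaustive topology enumeration
# ---------------------------------------------------------------------------

def _parse_constraint(constraint):
    """A fixed rooted subtree, e.g. '(((RH1,RH2),SWS2),SWS1);', as nested
    tuples of tip names."""
    if constraint is None:
        return None
    if isinstance(constraint, tuple):
        return constraint
    topo_text = str(constraint)
    p = Path(topo_text)
    if p.exists():
        topo_text = p.read_text()
    import dendropy

    tree = dendropy.Tree.get(
        data=topo_text, schema="newick",
        suppress_internal_node_taxa=True, preserve_underscores=True,
    )

    def nest(node):
        children = node.child_nodes()
        if not children:
            return node.taxon.label
        if len(children) != 2:
            raise ParseError("constraint subtree must be strictly binary")
        return (nest(children[0]), nest(children[1]))

    return nest(tree.seed_node)


def _constraint_leaves(nested) -> list[str]:
    if isinstance(nested, str):
        return [nested]
    return _constraint_leaves(nested[0]) + _constraint_leaves(nested[1])


def enumerate_topologies(
    tips: list[str],
    constraint=None,
    branch_length: float = DEFAULT_BRANCH_LENGTH,
) -> list[Topology]:
    """All distinct unrooted binary topologies over ``tips``.

    With a ``constraint`` (rooted Newick subtree over a subset of tips),
    the subtree is treated as a single unit during stepwise addition and
    its internal structure grafted back afterwards, so the effective unit
    count is ``free tips + 1``.  The number of topologies is
    ``(2u - 5)!!`` for ``u`` effective units.  Ordering is deterministic:
    units are added in input order, each onto every existing branch in
    insertion order.
    """
    nested = _parse_constraint(constraint)
    tips = list(tips)
    if nested is not None:
        fixed = _constraint_leaves(nested)
        missing = set(fixed) - set(tips)
        if missing:
            raise TaxonMismatch(f"constraint tips {sorted(missing)} not in tips")
        units = [t for t in tips if t not in fixed] + ["__constraint__"]
    else:
        units = tips
    n_units = len(units)
    if not (3 <= n_units <= 8):
        raise TooManyTips(
            f"{n_units} effective units; exhaustive enumeration supports 3..8"
        )

    d = branch_length
    trees = [[(units[0], ("i", 0), d), (units[1], ("i", 0), d),
              (units[2], ("i", 0), d)]]
    for step, unit in enumerate(units[3:], start=1):
        new_trees = []
        for edges in trees:
            for idx in range(len(edges)):
                a, b, w = edges[idx]
                inode = ("i", step)
                grown = edges[:idx] + edges[idx + 1:]
                grown = grown + [(a, inode, d), (inode, b, d), (unit, inode, d)]
                new_trees.append(grown)
        trees = new_trees

    out = []
    for tid, edges in enumerate(trees):
        if nested is not None:
            edges = _graft(edges, "__constraint__", nested, d)
        out.append(_topology_from_label_edges(edges, tips, tid))
    return out


def _graft(edges, unit_label, nested, d):
    counter = [0]

    def expand(sub, new_edges):
        if isinstance(sub, str):
            return sub
        node = ("c", counter[0])
        counter[0] += 1
        for child in sub:
            new_edges.append((expand(child, new_edges), node, d))
        return node

    out = []
    attach = None
    for a, b, w in edges:
        if a == unit_label:
            attach = (b, w)
        elif b == unit_label:
            attach = (a, w)
        else:
            out.append((a, b, w))
    root = expand(nested, out)
    out.append((root, attach[0], attach[1]))
    return out


def _topology_from_label_edges(edges, tip_names, tid):
    """Edges over string tip labels / tuple internal labels -> Topology."""
    order = [t for t in tip_names]
    ids = {name: i for i, name in enumerate(order)}
    next_id = len(order)
    resolved = []
    for a, b, w in edges:
        for lbl in (a, b):
            if lbl not in ids:
                ids[lbl] = next_id
                next_id += 1
        resolved.append((ids[a], ids[b], w))
    return Topology(order, resolved, id=tid)


# ---------------------------------------------------------------------------
# 6. Exhaustive ML and bootstrap support
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteLikelihoodMatrix:
    """Per-site log-likelihoods, sites x topologies."""

    L: np.ndarray
    topology_ids: tuple[int, ...]
    fingerprint: str = ""

    def __post_init__(self):
        L = np.asarray(self.L, dtype=float)
        object.__setattr__(self, "L", L)
        if L.ndim != 2 or L.size == 0:
            raise EmptyMatrix("site-likelihood matrix must be 2-D, non-empty")
        if len(self.topology_ids) != L.shape[1]:
            raise EmptyMatrix("topology id count != number of columns")
        if not np.isfinite(L).all():
            raise EmptyMatrix("non-finite site log-likelihood")
        if (L > 0).any():
            # log of a probability over discrete site patterns
            raise EmptyMatrix("positive site log-likelihood entry")

    @property
    def n_sites(self) -> int:
        return self.L.shape[0]

    @property
    def n_topologies(self) -> int:
        return self.L.shape[1]

    def totals(self) -> np.ndarray:
        return self.L.sum(axis=0)


def alignment_fingerprint(aln: Alignment) -> str:
    h = hashlib.sha256()
    h.update("|".join(aln.taxa).encode())
    h.update(aln.sites.tobytes())
    return h.hexdigest()[:16]


@dataclass(frozen=True)
class ExhaustiveMLResult:
    topologies: tuple[Topology, ...]  # with ML branch lengths
    matrix: SiteLikelihoodMatrix
    ml_index: int
    alpha: float
    tie: bool

    def totals(self) -> np.ndarray:
        return self.matrix.totals()

    @property
    def ml_topology(self) -> Topology:
        return self.topologies[self.ml_index]


def exhaustive_ml(
    aln: Alignment,
    model: SubstitutionModel,
    tips: list[str] | None = None,
    alpha: float | str = "auto",
    k: int = 4,
    constraint=None,
) -> ExhaustiveMLResult:
    """Score every topology over ``tips`` by ML branch lengths.

    ``alpha="auto"`` first finds the ML topology at alpha = 1, optimizes
    the shape there, then re-scores all topologies with that single fixed
    alpha — mirroring the convention of reporting one optimized shape per
    analysis.  A float fixes alpha throughout.
    """
    tips = list(tips) if tips is not None else list(aln.taxa)
    topos = enumerate_topologies(tips, constraint=constraint)

    if alpha == "auto":
        rates1 = discrete_gamma(1.0, k)
        totals1 = []
        for t in topos:
            _, lnl = optimize_branch_lengths(aln, t, model, rates1)
            totals1.append(lnl)
        ml0 = int(np.argmax(totals1))
        _, rates, _ = optimize_shape(aln, topos[ml0], model, k=k, alpha0=1.0)
        alpha_val = rates.alpha
    else:
        alpha_val = float(alpha)
        rates = discrete_gamma(alpha_val, k)

    fitted = []
    columns = []
    for t in topos:
        tree, _ = optimize_branch_lengths(aln, t, model, rates)
        fitted.append(tree)
        columns.append(site_log_likelihoods(aln, tree, model, rates))
    L = np.column_stack(columns)
    matrix = SiteLikelihoodMatrix(
        L, tuple(t.id for t in topos), alignment_fingerprint(aln)
    )
    totals = matrix.totals()
    best = totals.max()
    ml_index = int(np.argmax(totals))  # canonical order breaks ties
    tie = int((totals >= best - 1e-9).sum()) > 1
    return ExhaustiveMLResult(tuple(fitted), matrix, ml_index, alpha_val, tie)


def bootstrap_support(
    result: ExhaustiveMLResult,
    B: int = 200,
    seed: int = 0,
    mode: str = "rell",
    aln: Alignment | None = None,
    model: SubstitutionModel | None = None,
) -> dict[frozenset, float]:
    """Bootstrap proportions per non-trivial split.

    Default is the RELL approximation: resample per-site log-likelihoods,
    tally each replicate's best topology's splits.  ``mode="full"``
    re-optimizes branch lengths on resampled alignment columns (small
    problems only).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    splits_per_topo = [t.splits() for t in result.topologies]
    counts: dict[frozenset, int] = {}
    n = result.matrix.n_sites

    if mode == "rell":
        W = rng.multinomial(n, np.full(n, 1.0 / n), size=B).astype(float)
        totals = W @ result.matrix.L  # (B, T)
        best = np.argmax(totals, axis=1)
        for b in best:
            for s in splits_per_topo[b]:
                counts[s] = counts.get(s, 0) + 1
    elif mode == "full":
        if aln is None or model is None:
            raise ValueError("full mode needs aln and model")
        rates = discrete_gamma(result.alpha, 4)
        for _ in range(B):
            idx = rng.integers(0, aln.n_sites, size=aln.n_sites)
            res_aln = Alignment(aln.taxa, aln.sites[:, idx])
            totals = []
            for t in result.topologies:
                _, lnl = optimize_branch_lengths(res_aln, t, model, rates)
                totals.append(lnl)
            b = int(np.argmax(totals))
            for s in splits_per_topo[b]:
                counts[s] = counts.get(s, 0) + 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {s: c / B for s, c in counts.items()}
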