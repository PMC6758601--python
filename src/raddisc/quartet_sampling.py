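"""Quartet Sampling branch and taxon support.

Every internal branch of an unrooted binary tree splits the taxa into four
disjoint subsets.  Each replicate draws one taxon per subset (subject to a
minimum pairwise non-missing overlap), resolves the quartet from the
alignment, and scores the draw as concordant with the focal branch,
discordant (two ways), or uninformative.  Replicate tallies per branch
give:

* QC (quartet concordance, [-1, 1]): entropy-based support, 1 when all
  informative replicates are concordant, negative when a discordant
  topology has the plurality;
* QD (quartet differential, [0, 1]): 1 - |t1 - t2| / (t1 + t2), the
  balance of the two discordant topologies -- high values are the
  symmetric signature of incomplete lineage sorting, low values the skew
  expected under introgression;
* QI (quartet informativeness, [0, 1]): informative fraction of the
  successfully drawn replicates;

and per taxon QF (quartet fidelity): the fraction of a taxon's informative
replicates that were concordant; low values flag rogue taxa.

The quartet resolution engine evaluates the three unrooted topologies by
maximum likelihood under JC69 (Felsenstein pruning, five branch lengths
fitted by cyclic one-dimensional search); an unweighted-parsimony engine
is available mainly as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd

from raddisc.io_formats import Alignment

_CODE = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
_MISS = 4

OUTCOMES = ("concordant", "discordant-1", "discordant-2", "uninformative", "failed-overlap")


@dataclass
class QSConfig:
    """Replicates, overlap rule and likelihood cutoff for Quartet Sampling."""

    n_replicates: int = 500
    min_overlap: int = 300_000
    lnl_cutoff: float = 2.0
    max_attempts: int = 100
    seed: int = 0
    engine: str = "ml"  # "ml" (JC69 likelihood) or "parsimony"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.min_overlap < 0 or self.lnl_cutoff < 0:
            raise ValueError("min_overlap and lnl_cutoff must be >= 0")


@dataclass
class QuartetReplicate:
    taxa: tuple[str, str, str, str]
    outcome: str
    delta_lnl: float = 0.0


@dataclass
class BranchScores:
    qc: Optional[float]
    qd: Optional[float]
    qi: Optional[float]
    t0: int
    t1: int
    t2: int
    n_uninformative: int
    n_failed: int = 0

    def label(self) -> str:
        """Render as the conventional "QC/QD/QI" branch annotation."""

        def fmt(v: Optional[float]) -> str:
            if v is None:
                return "-"
            s = f"{v:.2f}".rstrip("0").rstrip(".")
            return s if s not in ("-0", "") else "0"

        return "/".join(fmt(v) for v in (self.qc, self.qd, self.qi))


@dataclass
class TaxonScores:
    """Per-taxon quartet fidelity and participation counts."""

    qf: dict[str, float]
    informative: dict[str, int]
    concordant: dict[str, int]


# ---------------------------------------------------------------------------
# branch partitions
# ---------------------------------------------------------------------------


class _UnrootedTree:
    """Adjacency view of a dendropy tree with a degree-2 root suppressed."""

    def __init__(self, tree: dendropy.Tree):
        self.adj: dict[int, set[int]] = {}
        self.leaf_label: dict[int, str] = {}
        nodes = list(tree.preorder_node_iter())
        self.ids = {id(nd): i for i, nd in enumerate(nodes)}
        for nd in nodes:
            i = self.ids[id(nd)]
            self.adj.setdefault(i, set())
            if nd.is_leaf():
                self.leaf_label[i] = nd.taxon.label
            for ch in nd.child_nodes():
                j = self.ids[id(ch)]
                self.adj.setdefault(j, set())
                self.adj[i].add(j)
                self.adj[j].add(i)
        root = self.ids[id(tree.seed_node)]
        if len(self.adj[root]) == 2:  # suppress rooted bifurcation
            a, b = sorted(self.adj[root])
            self.adj[a].discard(root)
            self.adj[b].discard(root)
            self.adj[a].add(b)
            self.adj[b].add(a)
            del self.adj[root]

    def internal_edges(self) -> list[tuple[int, int]]:
        edges = []
        for u, nbrs in self.adj.items():
            for v in nbrs:
                if u < v and u not in self.leaf_label and v not in self.leaf_label:
                    edges.append((u, v))
        return sorted(edges)

    def leaves_beyond(self, start: int, blocked: int) -> frozenset[str]:
        """Leaf labels reachable from ``start`` without crossing ``blocked``."""
        seen = {blocked, start}
        stack = [start]
        out = set()
        while stack:
            u = stack.pop()
            if u in self.leaf_label:
                out.add(self.leaf_label[u])
            for v in self.adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return frozenset(out)


def branch_partitions(
    tree: dendropy.Tree, branch: Optional[tuple[int, int]] = None
) -> Union[
    tuple[frozenset[str], frozenset[str], frozenset[str], frozenset[str]],
    list[tuple[frozenset[str], frozenset[str], frozenset[str], frozenset[str]]],
]:
    """Four disjoint taxon subsets induced by an internal branch.

    With ``branch=None`` returns the list of partitions for every internal
    branch (in a stable order).  The first two subsets hang off one
    endpoint, the last two off the other; their union is all leaves.
    Terminal branches and polytomies adjacent to the branch are errors.
    """
    g = _UnrootedTree(tree)
    edges = g.internal_edges()
    if branch is None:
        return [branch_partitions(tree, e) for e in edges]
    u, v = branch
    if (min(branch), max(branch)) not in edges:
        raise ValueError(f"{branch} is not an internal branch")
    side_u = [w for w in g.adj[u] if w != v]
    side_v = [w for w in g.adj[v] if w != u]
    if len(side_u) != 2 or len(side_v) != 2:
        raise ValueError("branch endpoints must be binary (degree 3)")
    subsets = tuple(
        g.leaves_beyond(w, u) for w in side_u
    ) + tuple(g.leaves_beyond(w, v) for w in side_v)
    return subsets  # type: ignore[return-value]


def internal_branches(tree: dendropy.Tree) -> list[tuple[int, int]]:
    """Stable identifiers for the internal branches of the unrooted tree."""
    return _UnrootedTree(tree).internal_edges()


# ---------------------------------------------------------------------------
# quartet drawing
# ---------------------------------------------------------------------------


def draw_quartet(
    subsets: Sequence[Sequence[str]],
    overlap: pd.DataFrame,
    cfg: QSConfig,
    rng: np.random.Generator,
) -> Optional[tuple[str, str, str, str]]:
    """Draw one taxon per subset, enforcing the pairwise overlap rule.

    Returns the accepted quartet or None after ``cfg.max_attempts``
    rejections (recorded by the caller as a failed-overlap replicate).
    """
    subsets = [list(s) for s in subsets]
    for s in subsets:
        if not s:
            raise ValueError("cannot sample from an empty subset")
    for _ in range(cfg.max_attempts):
        picks = tuple(s[rng.integers(len(s))] for s in subsets)
        ok = True
        for i in range(4):
            for j in range(i + 1, 4):
                if overlap.loc[picks[i], picks[j]] < cfg.min_overlap:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return picks  # type: ignore[return-value]
    return None


def overlap_matrix(aln: Alignment) -> pd.DataFrame:
    """Pairwise count of columns non-missing (not N/-) in both taxa."""
    nonmiss = (aln.seqs != b"N") & (aln.seqs != b"-")
    counts = nonmiss.astype(np.int64) @ nonmiss.T.astype(np.int64)
    return pd.DataFrame(counts, index=aln.sample_ids, columns=aln.sample_ids)


# ---------------------------------------------------------------------------
# quartet resolution
# ---------------------------------------------------------------------------


def _code_alignment(aln: Alignment) -> np.ndarray:
    coded = np.full(aln.seqs.shape, _MISS, dtype=np.int8)
    for b, c in _CODE.items():
        coded[aln.seqs == b] = c
    return coded


def _jc_probs(t: float) -> tuple[float, float]:
    e = np.exp(-4.0 / 3.0 * max(t, 0.0))
    return 0.25 + 0.75 * e, 0.25 - 0.25 * e  # (same, different)


def _jc_matrix(t: float) -> np.ndarray:
    s, d = _jc_probs(t)
    return np.full((4, 4), d) + np.eye(4) * (s - d)


def _tip_partials(states: np.ndarray, t: float) -> np.ndarray:
    """(npat, 4) conditional probabilities P(tip state | ancestral state)."""
    s, d = _jc_probs(t)
    out = np.full((len(states), 4), d)
    out[np.arange(len(states)), states] = s
    return out


def _quartet_lnl(
    patterns: np.ndarray, counts: np.ndarray, order: tuple[int, int, int, int], br: np.ndarray
) -> float:
    """Log-likelihood of topology ((a,b),(c,d)) with branch lengths br[0..4].

    br[0..3] are the tip branches of a, b, c, d; br[4] the internal branch.
    """
    a, b, c, d = order
    pu = _tip_partials(patterns[a], br[0]) * _tip_partials(patterns[b], br[1])
    pv = _tip_partials(patterns[c], br[2]) * _tip_partials(patterns[d], br[3])
    m = _jc_matrix(br[4])
    site_l = 0.25 * np.sum(pu * (pv @ m.T), axis=1)
    return float(np.sum(counts * np.log(np.maximum(site_l, 1e-300))))


_TOPOLOGY_ORDERS = ((0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2))


def _line_max(
    f_coefs: tuple[np.ndarray, np.ndarray], counts: np.ndarray, lo: float = 1e-8, hi: float = 20.0
) -> tuple[float, float]:
    """Maximize lnl(x) = counts @ log(0.25*(d(x)*F + (s(x)-d(x))*G)) over x.

    Because the JC transition matrix is d + (s-d)*I, every coordinate
    objective reduces to per-pattern scalars (F, G); candidate branch
    lengths are evaluated in vectorized batches (coarse geometric grid,
    then two linear refinements around the incumbent).
    """
    F, G = f_coefs

    def batch(xs: np.ndarray) -> np.ndarray:
        e = np.exp(-4.0 / 3.0 * xs)[:, None]
        d = 0.25 - 0.25 * e
        site = 0.25 * (d * F[None, :] + e * G[None, :])  # (s-d) = e
        return np.log(np.maximum(site, 1e-300)) @ counts

    xs = np.geomspace(lo, hi, 33)
    vals = batch(xs)
    i = int(np.argmax(vals))
    best_x, best_v = float(xs[i]), float(vals[i])
    a, b = xs[max(i - 1, 0)], xs[min(i + 1, len(xs) - 1)]
    for _ in range(2):
        xs = np.linspace(a, b, 17)
        vals = batch(xs)
        i = int(np.argmax(vals))
        if vals[i] > best_v:
            best_x, best_v = float(xs[i]), float(vals[i])
        a, b = xs[max(i - 1, 0)], xs[min(i + 1, len(xs) - 1)]
    return best_x, best_v


def _fit_topology(
    patterns: np.ndarray,
    counts: np.ndarray,
    order: tuple[int, int, int, int],
    tol: float = 1e-6,
    max_sweeps: int = 25,
) -> float:
    """Maximize lnL over the five branch lengths by cyclic 1-D search.

    Each coordinate step holds the other four branches fixed, so their
    partials collapse into two per-pattern coefficients and the 1-D
    objective is evaluated on vectorized candidate grids.  Sweeps stop
    when the lnL gain drops below ``tol``.
    """
    onehot = [np.eye(4)[patterns[i]] for i in order]  # (npat, 4) per tip abcd
    states = [patterns[i] for i in order]
    npat = patterns.shape[1]
    rows = np.arange(npat)
    br = np.full(5, 0.1)

    def tip_p(i: int, t: float) -> np.ndarray:
        s, d = _jc_probs(t)
        return d + (s - d) * onehot[i]

    def lnl_of_sites(site_l: np.ndarray) -> float:
        return float(counts @ np.log(np.maximum(site_l, 1e-300)))

    def full_lnl() -> float:
        pu = tip_p(0, br[0]) * tip_p(1, br[1])
        pv = tip_p(2, br[2]) * tip_p(3, br[3])
        return lnl_of_sites(0.25 * np.sum(pu * (pv @ _jc_matrix(br[4]).T), axis=1))

    lnl = full_lnl()
    for _ in range(max_sweeps):
        prev = lnl
        for k in range(5):
            if k == 4:
                # site = 0.25*(d*sum(pu)*sum(pv) + (s-d)*sum(pu*pv))
                pu = tip_p(0, br[0]) * tip_p(1, br[1])
                pv = tip_p(2, br[2]) * tip_p(3, br[3])
                F = pu.sum(axis=1) * pv.sum(axis=1)
                G = np.sum(pu * pv, axis=1)
            else:
                m = _jc_matrix(br[4])
                if k < 2:
                    mate, far1, far2 = (1 - k, 2, 3)
                else:
                    mate, far1, far2 = (5 - k, 0, 1)
                fixed = tip_p(mate, br[mate]) * (
                    (tip_p(far1, br[far1]) * tip_p(far2, br[far2])) @ m
                )
                # site = 0.25*(d*sum(fixed) + (s-d)*fixed[observed state])
                F = fixed.sum(axis=1)
                G = fixed[rows, states[k]]
            x, v = _line_max((F, G), counts)
            if v > lnl:
                br[k] = x
                lnl = v
        if lnl - prev < tol:
            break
    return lnl


def resolve_quartet(
    columns: np.ndarray, cfg: Optional[QSConfig] = None
) -> tuple[str, float]:
    """Resolve a quartet from its aligned columns.

    ``columns`` is a (4, n_columns) array of bases (bytes ``S1`` or codes
    0-3 with 4 = missing); rows are taxa (a, b, c, d) with (a, b | c, d)
    the concordant split.  Columns with any missing state are ignored.
    Returns ``(outcome, delta_lnl)`` where outcome is ``concordant``,
    ``discordant-1`` (a, c | b, d), ``discordant-2`` (a, d | b, c) or
    ``uninformative`` when the best and second-best topology differ by
    less than ``cfg.lnl_cutoff`` (exact ties included).
    """
    cfg = cfg or QSConfig()
    columns = np.asarray(columns)
    if columns.dtype.kind == "S":
        coded = np.full(columns.shape, _MISS, dtype=np.int8)
        upper = np.char.upper(columns)
        for base, c in _CODE.items():
            coded[upper == base] = c
    else:
        coded = columns.astype(np.int8)
    keep = (coded < 4).all(axis=0)
    coded = coded[:, keep]
    if coded.shape[1] == 0:
        raise ValueError("no shared non-missing columns in quartet")
    patterns, counts = _canonical_patterns(coded)

    if cfg.engine == "parsimony":
        scores = _parsimony_support(patterns, counts)
    else:
        scores = np.array(
            [_fit_topology(patterns, counts, order) for order in _TOPOLOGY_ORDERS]
        )
    ranked = np.argsort(scores)[::-1]
    delta = float(scores[ranked[0]] - scores[ranked[1]])
    if delta < cfg.lnl_cutoff or np.isclose(scores[ranked[0]], scores[ranked[1]]):
        return "uninformative", delta
    return ("concordant", "discordant-1", "discordant-2")[ranked[0]], delta


def _build_pattern_tables() -> tuple[np.ndarray, np.ndarray]:
    """Map each of the 256 base combinations to its equality class.

    JC69 is symmetric under base relabelling, so the site likelihood
    depends only on which tips share a base: the 15 set partitions of four
    tips, with bases relabelled by first appearance within the column.
    """
    class_of: dict[tuple[int, ...], int] = {}
    reps: list[tuple[int, ...]] = []
    lookup = np.empty(256, dtype=np.int64)
    for code in range(256):
        col = ((code >> 6) & 3, (code >> 4) & 3, (code >> 2) & 3, code & 3)
        relabel: dict[int, int] = {}
        key = tuple(relabel.setdefault(b, len(relabel)) for b in col)
        if key not in class_of:
            class_of[key] = len(reps)
            reps.append(key)
        lookup[code] = class_of[key]
    return lookup, np.ascontiguousarray(np.array(reps, dtype=np.int8).T)


_CLASS_LOOKUP, _CLASS_PATTERNS = _build_pattern_tables()


def _canonical_patterns(coded: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse quartet columns to their (at most 15) equality classes."""
    c = coded.astype(np.int64)
    codes = (c[0] << 6) | (c[1] << 4) | (c[2] << 2) | c[3]
    raw_counts = np.bincount(codes, minlength=256)
    class_counts = np.bincount(
        _CLASS_LOOKUP, weights=raw_counts, minlength=_CLASS_PATTERNS.shape[1]
    )
    keep = class_counts > 0
    return np.ascontiguousarray(_CLASS_PATTERNS[:, keep]), class_counts[keep]


def _parsimony_support(patterns: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Counts of clean synapomorphies supporting each unrooted topology."""
    a, b, c, d = patterns
    support = np.zeros(3)
    for k, (w, x, y, z) in enumerate(((a, b, c, d), (a, c, b, d), (a, d, b, c))):
        mask = (w == x) & (y == z) & (w != y)
        support[k] = counts[mask].sum()
    return support


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------


def branch_and_taxon_scores(
    replicates: Sequence[QuartetReplicate],
) -> tuple[BranchScores, TaxonScores]:
    """Tally one branch's replicates into QC/QD/QI and per-taxon QF.

    QC uses base-3 entropy of the informative outcome frequencies, signed
    by whether the concordant topology holds the plurality; QD is the
    complement of the skew between the two discordant counts; QI is the
    informative fraction of successful draws.  ``s = 0`` leaves QC (and
    QD) undefined, rendered "-" in output.
    """
    t = {o: 0 for o in OUTCOMES}
    for r in replicates:
        t[r.outcome] += 1
    t0, t1, t2 = t["concordant"], t["discordant-1"], t["discordant-2"]
    n_success = t0 + t1 + t2 + t["uninformative"]
    s = t0 + t1 + t2
    if s == 0:
        qc = None
    else:
        ps = np.array([t0, t1, t2], dtype=float) / s
        ent = float(sum(p * np.log(p) / np.log(3.0) for p in ps if p > 0))
        qc = (1.0 + ent) if t0 == max(t0, t1, t2) else -(1.0 + ent)
    qd = 1.0 - abs(t1 - t2) / (t1 + t2) if (t1 + t2) > 0 else None
    qi = s / n_success if n_success > 0 else None
    branch = BranchScores(qc, qd, qi, t0, t1, t2, t["uninformative"], t["failed-overlap"])

    informative: dict[str, int] = {}
    concordant: dict[str, int] = {}
    for r in replicates:
        if r.outcome in ("concordant", "discordant-1", "discordant-2"):
            for tx in r.taxa:
                informative[tx] = informative.get(tx, 0) + 1
                if r.outcome == "concordant":
                    concordant[tx] = concordant.get(tx, 0) + 1
    qf = {tx: concordant.get(tx, 0) / n for tx, n in informative.items()}
    return branch, TaxonScores(qf, informative, concordant)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


@dataclass
class QSResult:
    branch_scores: dict[tuple[int, int], BranchScores]
    branch_subsets: dict[tuple[int, int], tuple[frozenset[str], ...]]
    taxon_scores: TaxonScores
    tree: dendropy.Tree
    replicates: dict[tuple[int, int], list[QuartetReplicate]]

    def branch_table(self) -> pd.DataFrame:
        rows = []
        for e, sc in self.branch_scores.items():
            subs = self.branch_subsets[e]
            rows.append(
                {
                    "branch": f"{e[0]}-{e[1]}",
                    "split": "|".join(
                        ",".join(sorted(s)) for s in (subs[0] | subs[1], subs[2] | subs[3])
                    ),
                    "QC": sc.qc,
                    "QD": sc.qd,
                    "QI": sc.qi,
                    "t_concordant": sc.t0,
                    "t_discordant1": sc.t1,
                    "t_discordant2": sc.t2,
                    "n_uninformative": sc.n_uninformative,
                    "n_failed_overlap": sc.n_failed,
                    "label": sc.label(),
                }
            )
        return pd.DataFrame(rows)

    def taxon_table(self) -> pd.DataFrame:
        ts = self.taxon_scores
        return pd.DataFrame(
            {
                "taxon": list(ts.qf),
                "QF": [ts.qf[t] for t in ts.qf],
                "n_informative": [ts.informative[t] for t in ts.qf],
                "n_concordant": [ts.concordant.get(t, 0) for t in ts.qf],
            }
        )


def run_quartet_sampling(
    aln: Alignment, tree: dendropy.Tree, cfg: Optional[QSConfig] = None
) -> QSResult:
    """Score every internal branch of ``tree`` from ``aln`` by quartet draws.

    Deterministic for a fixed ``cfg.seed`` (each branch gets its own
    substream).  Tree leaves must all be alignment samples and number at
    least four.
    """
    cfg = cfg or QSConfig()
    taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(taxa) < 4:
        raise ValueError("Quartet Sampling needs at least 4 taxa")
    missing = [t for t in taxa if t not in aln.sample_ids]
    if missing:
        raise ValueError(f"tree taxa absent from alignment: {missing}")
    row = {s: i for i, s in enumerate(aln.sample_ids)}
    coded = _code_alignment(aln)
    ov = overlap_matrix(aln)

    g_edges = internal_branches(tree)
    branch_scores: dict[tuple[int, int], BranchScores] = {}
    branch_subsets: dict[tuple[int, int], tuple[frozenset[str], ...]] = {}
    replicates: dict[tuple[int, int], list[QuartetReplicate]] = {}
    all_reps: list[QuartetReplicate] = []
    # same ordered draw -> same outcome; cache ML fits across replicates
    cache: dict[tuple[str, str, str, str], tuple[str, float]] = {}
    for b_idx, edge in enumerate(g_edges):
        subsets = branch_partitions(tree, edge)
        branch_subsets[edge] = subsets  # type: ignore[assignment]
        rng = np.random.default_rng([cfg.seed, b_idx])
        reps: list[QuartetReplicate] = []
        for _ in range(cfg.n_replicates):
            picks = draw_quartet(
                [sorted(s) for s in subsets], ov, cfg, rng
            )
            if picks is None:
                reps.append(QuartetReplicate(("", "", "", ""), "failed-overlap"))
                continue
            if picks in cache:
                outcome, delta = cache[picks]
            else:
                cols = coded[[row[p] for p in picks]]
                try:
                    outcome, delta = resolve_quartet(cols, cfg)
                except ValueError:
                    reps.append(QuartetReplicate(picks, "failed-overlap"))
                    continue
                cache[picks] = (outcome, delta)
            reps.append(QuartetReplicate(picks, outcome, delta))
        scores, _ = branch_and_taxon_scores(reps)
        branch_scores[edge] = scores
        replicates[edge] = reps
        all_reps.extend(reps)
    _, taxa_scores = branch_and_taxon_scores(all_reps)

    annotated = tree.clone(depth=1)
    _annotate(annotated, branch_scores)
    return QSResult(branch_scores, branch_subsets, taxa_scores, annotated, replicates)


def _annotate(tree: dendropy.Tree, scores: dict[tuple[int, int], BranchScores]) -> None:
    """Attach "QC/QD/QI" labels to the internal nodes subtending each branch."""
    g = _UnrootedTree(tree)
    # match edges back to child nodes: label the deeper endpoint's node
    nodes = list(tree.preorder_node_iter())
    by_idx = {g.ids[id(nd)]: nd for nd in nodes}
    for (u, v), sc in scores.items():
        # prefer labelling the endpoint that is a child of the other
        nd_u, nd_v = by_idx.get(u), by_idx.get(v)
        target = None
        if nd_v is not None and nd_v.parent_node is nd_u:
            target = nd_v
        elif nd_u is not None and nd_u.parent_node is nd_v:
            target = nd_u
        else:
            target = nd_v or nd_u
        if target is not None and not target.is_leaf():
            target.label = sc.label()
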