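"""RAD-like synthetic datasets with known ground truth.

The generator composes four stages, each deterministic for a fixed master
seed (per-stage substreams are derived with fixed offsets):

1. multispecies-coalescent gene trees, one per locus, on a rooted
   ultrametric species tree in coalescent units (time scaled by 2N
   generations), with optional admixture pulses applied backward in time
   as probabilistic lineage reassignment;
2. Jukes-Cantor sequence evolution along each gene tree;
3. independent Bernoulli locus dropout per (sample, locus), emulating RAD
   allele dropout (loci go all-missing per sample, not site-wise);
4. a minimum-samples-per-locus filter cascade.

Times are coalescent units; the per-site mutation rate ``mu`` is the
expected number of substitutions per site per coalescent unit, so a branch
of length t contributes t*mu substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd

from raddisc.io_formats import Alignment, CladeMap, SnpMatrix, alignment_to_snps

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


class ConfigError(ValueError):
    """Raised for an inconsistent simulation configuration."""


# ---------------------------------------------------------------------------
# species model
# ---------------------------------------------------------------------------


@dataclass
class SpeciesModel:
    """Rooted ultrametric species tree with tip sample counts.

    Branches are identified by the label of the node below them; internal
    nodes without a Newick label are auto-named ``n0, n1, ...`` in
    postorder.  ``pop_sizes`` are relative population sizes per branch
    (default 1 everywhere); ``samples_per_tip`` gives the number of haploid
    samples drawn from each tip population at time 0.
    """

    labels: list[str]
    parent: np.ndarray  # parent node index, -1 at root
    times: np.ndarray  # node times (tips at 0, increasing root-ward)
    is_tip: np.ndarray
    samples_per_tip: dict[str, int]
    pop_sizes: dict[str, float] = field(default_factory=dict)
    ploidy: int = 1

    def __post_init__(self) -> None:
        if np.any(self.times[self.is_tip] != 0):
            raise ConfigError("all tips must sit at time 0")
        for i, p in enumerate(self.parent):
            if p >= 0 and self.times[p] <= self.times[i] and not self.is_tip[i]:
                raise ConfigError("node times must strictly increase root-ward")
        for lab in self.samples_per_tip:
            if lab not in self.labels:
                raise ConfigError(f"unknown tip in samples_per_tip: {lab!r}")
        for lab in self.pop_sizes:
            if lab not in self.labels:
                raise ConfigError(f"unknown branch in pop_sizes: {lab!r}")

    @classmethod
    def from_newick(
        cls,
        newick: str,
        samples_per_tip: Mapping[str, int],
        pop_sizes: Optional[Mapping[str, float]] = None,
        ploidy: int = 1,
    ) -> "SpeciesModel":
        """Build from a Newick string with branch lengths in coalescent units."""
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        nodes = list(tree.postorder_node_iter())
        labels: list[str] = []
        auto = 0
        for nd in nodes:
            if nd.is_leaf():
                labels.append(nd.taxon.label)
            elif nd.label:
                labels.append(nd.label)
            else:
                labels.append(f"n{auto}")
                auto += 1
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        times = np.zeros(n)
        is_tip = np.zeros(n, dtype=bool)
        # tip-to-root times from edge lengths, checking ultrametricity
        depth: dict[int, float] = {}
        for nd in nodes:
            i = index[id(nd)]
            is_tip[i] = nd.is_leaf()
            if nd.is_leaf():
                times[i] = 0.0
            else:
                child_times = []
                for ch in nd.child_nodes():
                    j = index[id(ch)]
                    if ch.edge.length is None:
                        raise ConfigError("species tree needs branch lengths")
                    child_times.append(times[j] + ch.edge.length)
                if max(child_times) - min(child_times) > 1e-9:
                    raise ConfigError("species tree must be ultrametric")
                times[i] = child_times[0]
        for nd in nodes:
            for ch in nd.child_nodes():
                parent[index[id(ch)]] = index[id(nd)]
        return cls(
            labels,
            parent,
            times,
            is_tip,
            dict(samples_per_tip),
            dict(pop_sizes or {}),
            ploidy,
        )

    # -- helpers ---------------------------------------------------------

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ConfigError(f"unknown branch label: {label!r}") from None

    def branch_interval(self, label: str) -> tuple[float, float]:
        """Existence interval [start, end) of a branch in backward time."""
        i = self.index_of(label)
        p = self.parent[i]
        end = np.inf if p < 0 else float(self.times[p])
        return float(self.times[i]), end

    def pop_size(self, node_index: int) -> float:
        return float(self.pop_sizes.get(self.labels[node_index], 1.0))

    def sample_names(self) -> list[str]:
        names = []
        for i in np.flatnonzero(self.is_tip):
            tip = self.labels[i]
            for k in range(self.samples_per_tip.get(tip, 0)):
                names.append(f"{tip}_{k}")
        return names

    def clade_map(self, outgroup_clades: Iterable[str]) -> CladeMap:
        """Sample -> tip-clade assignment for the simulated samples."""
        assignment = {name: name.rsplit("_", 1)[0] for name in self.sample_names()}
        return CladeMap(assignment, frozenset(outgroup_clades))


@dataclass(frozen=True)
class AdmixturePulse:
    """Instantaneous admixture: backward in time, each lineage on the
    recipient branch at ``time`` reassigns to the donor with probability
    ``fraction``."""

    donor: str
    recipient: str
    time: float
    fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ConfigError("pulse fraction must lie in [0, 1]")

    def validate(self, model: SpeciesModel) -> None:
        for branch in (self.donor, self.recipient):
            lo, hi = model.branch_interval(branch)
            if not (lo <= self.time < hi):
                raise ConfigError(
                    f"pulse time {self.time} outside branch {branch!r} "
                    f"interval [{lo}, {hi})"
                )


@dataclass
class SimulationConfig:
    model: SpeciesModel
    pulses: list[AdmixturePulse] = field(default_factory=list)
    n_loci: int = 500
    locus_length: int = 64
    mu: float = 0.002
    dropout: Union[float, Mapping[str, float]] = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.locus_length < 1:
            raise ConfigError("n_loci and locus_length must be >= 1")
        if self.mu < 0:
            raise ConfigError("mu must be >= 0")
        for p in self.pulses:
            p.validate(self.model)

    def dropout_rate(self, sample: str) -> float:
        if isinstance(self.dropout, Mapping):
            clade = sample.rsplit("_", 1)[0]
            return float(self.dropout.get(clade, 0.0))
        return float(self.dropout)


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------


@dataclass
class GeneTree:
    """Binary gene tree as parent/time arrays; nodes 0..n-1 are the leaves."""

    parent: np.ndarray
    times: np.ndarray
    leaf_labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(len(self.parent))]
        for i, p in enumerate(self.parent):
            if p >= 0:
                out[p].append(i)
        return out

    def newick(self) -> str:
        children = self.children()
        root = int(np.flatnonzero(self.parent < 0)[0])

        def rec(i: int) -> str:
            p = self.parent[i]
            length = self.times[p] - self.times[i] if p >= 0 else 0.0
            if i < self.n_leaves:
                return f"{self.leaf_labels[i]}:{length:.6g}"
            inner = ",".join(rec(c) for c in children[i])
            return f"({inner}):{length:.6g}"

        s = rec(root)
        return s[: s.rfind(":")] + ";"

    def tmrca(self, label_a: str, label_b: str) -> float:
        """Time of the most recent common ancestor of two leaves."""
        ia = self.leaf_labels.index(label_a)
        ib = self.leaf_labels.index(label_b)
        anc_a = set()
        i = ia
        while i >= 0:
            anc_a.add(i)
            i = self.parent[i]
        i = ib
        while i >= 0:
            if i in anc_a:
                return float(self.times[i])
            i = self.parent[i]
        raise ValueError("leaves share no ancestor (malformed tree)")


def _simulate_locus(model: SpeciesModel, pulses: Sequence[AdmixturePulse], rng: np.random.Generator) -> GeneTree:
    leaf_labels = model.sample_names()
    n = len(leaf_labels)
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    times = np.zeros(n_nodes)
    next_node = n

    # lineages per population (species node index)
    active: dict[int, list[int]] = {}
    k = 0
    for i in np.flatnonzero(model.is_tip):
        tip = model.labels[i]
        cnt = model.samples_per_tip.get(tip, 0)
        if cnt:
            active[i] = list(range(k, k + cnt))
            k += cnt

    # event queue: species-node merges and pulses, in time order
    events: list[tuple[float, int, str, object]] = []
    for i in np.flatnonzero(~model.is_tip):
        events.append((float(model.times[i]), 0, "merge", int(i)))
    for p in pulses:
        events.append((p.time, 1, "pulse", p))
    events.sort(key=lambda e: (e[0], e[1]))

    t_prev = 0.0

    def coalesce_in_pop(pop: int, t_start: float, t_end: float) -> None:
        nonlocal next_node
        lineages = active.get(pop)
        if not lineages:
            return
        ne = model.pop_size(pop)
        t = t_start
        while len(lineages) > 1:
            kk = len(lineages)
            rate = kk * (kk - 1) / 2.0 / ne
            t += rng.exponential(1.0 / rate)
            if t >= t_end:
                return
            a, b = rng.choice(kk, size=2, replace=False)
            node = next_node
            next_node += 1
            parent[lineages[a]] = node
            parent[lineages[b]] = node
            times[node] = t
            for idx in sorted((a, b), reverse=True):
                lineages.pop(idx)
            lineages.append(node)

    for t_ev, _, kind, payload in events:
        for pop in list(active):
            coalesce_in_pop(pop, t_prev, t_ev)
        if kind == "merge":
            node = int(payload)
            merged: list[int] = []
            for i, p in enumerate(model.parent):
                if p == node and i in active:
                    merged.extend(active.pop(i))
            if merged:
                active.setdefault(node, []).extend(merged)
        else:
            pulse: AdmixturePulse = payload  # type: ignore[assignment]
            r = model.index_of(pulse.recipient)
            d = model.index_of(pulse.donor)
            lineages = active.get(r, [])
            moving = [l for l in lineages if rng.random() < pulse.fraction]
            if moving:
                active[r] = [l for l in lineages if l not in moving]
                active.setdefault(d, []).extend(moving)
        t_prev = t_ev

    # above the root: single panmictic population
    root_pop = int(np.flatnonzero(model.parent < 0)[0])
    remaining = []
    for pop in list(active):
        remaining.extend(active.pop(pop))
    active[root_pop] = remaining
    coalesce_in_pop(root_pop, t_prev, np.inf)
    return GeneTree(parent, times, leaf_labels)


def simulate_gene_trees(cfg: SimulationConfig) -> list[GeneTree]:
    """One multispecies-coalescent gene tree per locus (deterministic per seed)."""
    rng = np.random.default_rng([cfg.seed, 1])
    return [_simulate_locus(cfg.model, cfg.pulses, rng) for _ in range(cfg.n_loci)]


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def evolve_sequences(
    tree: GeneTree,
    locus_length: int,
    mu: float,
    rng: Union[int, np.random.Generator],
) -> np.ndarray:
    """Jukes-Cantor evolution along a gene tree.

    Returns a (n_leaves, locus_length) byte array of bases.  The root state
    is uniform over {A, C, G, T}; along a branch of coalescent length t the
    per-site substitution probability is the JC transition
    ``3/4 * (1 - exp(-4/3 * mu * t))``, with the new base uniform over the
    three alternatives.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    children = tree.children()
    root = int(np.flatnonzero(tree.parent < 0)[0])
    n_nodes = len(tree.parent)
    states = np.empty((n_nodes, locus_length), dtype=np.int8)
    states[root] = rng.integers(0, 4, size=locus_length)
    # root-first traversal
    stack = [root]
    order = []
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(children[i])
    for i in order:
        for c in children[i]:
            t = tree.times[i] - tree.times[c]
            if t < 0:
                raise ValueError("negative branch length in gene tree")
            p_sub = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * mu * t))
            seq = states[i].copy()
            hit = rng.random(locus_length) < p_sub
            n_hit = int(hit.sum())
            if n_hit:
                # uniform over the three other bases
                seq[hit] = (seq[hit] + rng.integers(1, 4, size=n_hit)) % 4
            states[c] = seq
    return _BASES[states[: tree.n_leaves]]


# ---------------------------------------------------------------------------
# dataset assembly, dropout, filtering
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    """Alignment + SNP matrix + ground-truth record for a simulated run.

    ``truth`` holds the gene trees (Newick), pulse parameters, per-locus
    retained-sample sets and the stage seeds; the SNP matrix is always
    derivable from the alignment via :func:`~raddisc.io_formats.alignment_to_snps`.
    """

    alignment: Alignment
    snps: SnpMatrix
    truth: dict

    @property
    def sample_ids(self) -> list[str]:
        return self.alignment.sample_ids

    def retained_per_locus(self) -> np.ndarray:
        """Number of samples with non-missing data per locus."""
        counts = []
        for start, end in self.alignment.locus_bounds or []:
            block = self.alignment.seqs[:, start:end]
            has_data = (block != b"N").any(axis=1)
            counts.append(int(has_data.sum()))
        return np.array(counts, dtype=int)


def _assemble(cfg: SimulationConfig, gene_trees: list[GeneTree]) -> Alignment:
    rng = np.random.default_rng([cfg.seed, 2])
    blocks = [
        evolve_sequences(gt, cfg.locus_length, cfg.mu, rng) for gt in gene_trees
    ]
    seqs = np.concatenate(blocks, axis=1)
    bounds = [
        (k * cfg.locus_length, (k + 1) * cfg.locus_length)
        for k in range(len(gene_trees))
    ]
    return Alignment(cfg.model.sample_names(), seqs, bounds)


def apply_rad_missingness(
    ds: SimulatedDataset,
    dropout: Union[float, Mapping[str, float]],
    seed: int,
) -> SimulatedDataset:
    """Erase whole (sample, locus) blocks with independent Bernoulli dropout.

    ``dropout`` is a global probability or a per-clade mapping (clade taken
    from the sample name prefix).  Erased blocks become N in the alignment;
    the SNP matrix is re-derived so both views agree.
    """
    aln = ds.alignment
    if aln.locus_bounds is None:
        raise ValueError("alignment must carry locus bounds")
    rng = np.random.default_rng([seed, 3])
    rates = np.array(
        [
            float(dropout.get(s.rsplit("_", 1)[0], 0.0))
            if isinstance(dropout, Mapping)
            else float(dropout)
            for s in aln.sample_ids
        ]
    )
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("dropout probabilities must lie in [0, 1]")
    n_loci = len(aln.locus_bounds)
    drop = rng.random((aln.n_samples, n_loci)) < rates[:, None]
    seqs = aln.seqs.copy()
    for k, (start, end) in enumerate(aln.locus_bounds):
        rows = np.flatnonzero(drop[:, k])
        if len(rows):
            seqs[np.ix_(rows, range(start, end))] = b"N"
    new_aln = Alignment(aln.sample_ids, seqs, list(aln.locus_bounds))
    truth = dict(ds.truth)
    truth["retained_samples"] = [
        [s for i, s in enumerate(aln.sample_ids) if not drop[i, k]]
        for k in range(n_loci)
    ]
    return SimulatedDataset(new_aln, alignment_to_snps(new_aln), truth)


def summarize(ds: SimulatedDataset) -> dict:
    """Locus count, concatenated length and SNP count of a dataset."""
    return {
        "n_loci": len(ds.alignment.locus_bounds or []),
        "total_length": ds.alignment.n_columns,
        "n_snps": ds.snps.n_sites,
    }


def filter_min_samples(ds: SimulatedDataset, min_n: int) -> SimulatedDataset:
    """Keep loci with at least ``min_n`` samples carrying non-missing data."""
    if min_n < 0:
        raise ValueError("min_n must be >= 0")
    aln = ds.alignment
    if aln.locus_bounds is None:
        raise ValueError("alignment must carry locus bounds")
    retained = ds.retained_per_locus() >= min_n
    keep = np.flatnonzero(retained)
    cols: list[np.ndarray] = []
    bounds: list[tuple[int, int]] = []
    pos = 0
    for k in keep:
        start, end = aln.locus_bounds[k]
        cols.append(aln.seqs[:, start:end])
        bounds.append((pos, pos + (end - start)))
        pos += end - start
    seqs = (
        np.concatenate(cols, axis=1)
        if cols
        else np.zeros((aln.n_samples, 0), dtype="S1")
    )
    new_aln = Alignment(aln.sample_ids, seqs, bounds)
    truth = dict(ds.truth)
    truth = {**truth, "kept_loci": [int(k) for k in keep], "min_samples": int(min_n)}
    for key in ("gene_trees", "retained_samples"):
        if key in truth and isinstance(truth[key], list):
            truth[key] = [truth[key][k] for k in keep]
    return SimulatedDataset(new_aln, alignment_to_snps(new_aln), truth)


def filter_cascade(ds: SimulatedDataset, thresholds: Sequence[int]) -> pd.DataFrame:
    """Summary table of the min-samples filter across thresholds."""
    rows = []
    for t in thresholds:
        s = summarize(filter_min_samples(ds, t))
        rows.append({"min_samples": t, **s})
    return pd.DataFrame(rows)


def generate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Simulate gene trees, sequences and dropout; byte-identical per seed."""
    gene_trees = simulate_gene_trees(cfg)
    aln = _assemble(cfg, gene_trees)
    truth = {
        "seed": cfg.seed,
        "n_loci": cfg.n_loci,
        "locus_length": cfg.locus_length,
        "mu": cfg.mu,
        "pulses": [
            {
                "donor": p.donor,
                "recipient": p.recipient,
                "time": p.time,
                "fraction": p.fraction,
            }
            for p in cfg.pulses
        ],
        "gene_trees": [gt.newick() for gt in gene_trees],
        "retained_samples": [list(aln.sample_ids) for _ in range(cfg.n_loci)],
    }
    ds = SimulatedDataset(aln, alignment_to_snps(aln), truth)
    return apply_rad_missingness(ds, cfg.dropout, cfg.seed)


# ---------------------------------------------------------------------------
# stock configurations
# ---------------------------------------------------------------------------


def five_clade_model(
    n_per_clade: int = 4,
    n_outgroup: int = 2,
    t_cherry12: float = 1.0,
    t_cherry34: float = 1.0,
    t_quartet: float = 1.5,
    t_v: float = 2.5,
    t_root: float = 4.0,
) -> SpeciesModel:
    """Five ingroup clades plus an outgroup on a balanced-quartet backbone.

    Topology ((((I,II),(III,IV)),V),OUT): clades I-IV form the symmetric
    quartet the partitioned D test consumes, V is the earliest-diverging
    ingroup clade, OUT a distant outgroup; V and OUT are pooled as O in the
    stock clade map.  Split times are in coalescent units; the two cherries
    may split at different times (branch labels: p12, p34, anc4, ing).
    """
    if not (0 < min(t_cherry12, t_cherry34) and max(t_cherry12, t_cherry34) < t_quartet < t_v < t_root):
        raise ConfigError("split times must be ordered 0 < cherries < quartet < V < root")
    nw = (
        f"((((I:{t_cherry12},II:{t_cherry12})p12:{t_quartet - t_cherry12},"
        f"(III:{t_cherry34},IV:{t_cherry34})p34:{t_quartet - t_cherry34})"
        f"anc4:{t_v - t_quartet},V:{t_v})ing:{t_root - t_v},OUT:{t_root})root;"
    )
    samples = {c: n_per_clade for c in ("I", "II", "III", "IV", "V")}
    samples["OUT"] = n_outgroup
    return SpeciesModel.from_newick(nw, samples)
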