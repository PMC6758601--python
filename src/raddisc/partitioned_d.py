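"""Partitioned five-taxon D-statistics with locus-bootstrap significance.

Three statistics are computed from the six discordant pattern totals:

    D1  = (nABBAA - nBABAA) / (nABBAA + nBABAA)
    D2  = (nABABA - nBAABA) / (nABABA + nBAABA)
    D12 = (nABBBA - nBABBA) / (nABBBA + nBABBA)

D1 attributes introgression signal to the P3a sublineage, D2 to P3b, and
D12 to their common ancestor; the sign says whether P2 (positive) or P1
(negative) is the exchange partner.  Significance comes from a
nonparametric bootstrap over loci: loci are resampled with replacement,
the whole frequency -> polarize -> pattern-count -> D pipeline is re-run
per replicate (exploiting that pattern totals are additive over loci), and
Z = |D_observed| / SD(D_replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import dendropy
import numpy as np
import pandas as pd

from raddisc.io_formats import CladeMap, SnpMatrix
from raddisc.site_patterns import (
    PatternCounts,
    RoleAssignment,
    lineage_frequencies,
    pattern_counts,
    per_locus_pattern_counts,
    polarize,
)


@dataclass
class BootstrapSpec:
    """Resampling parameters for the D-statistic significance test."""

    n_replicates: int = 1000
    seed: int = 0
    z_threshold: float = 2.55

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class DResult:
    """One row of the partitioned-D result table for one role configuration."""

    configuration: RoleAssignment
    d1: float
    d2: float
    d12: float
    z1: float
    z2: float
    z12: float
    counts: PatternCounts
    n_bootstrap: int
    z_threshold: float
    zero_denominator: tuple[bool, bool, bool] = (False, False, False)
    degenerate_bootstrap: tuple[bool, bool, bool] = (False, False, False)

    @property
    def significant(self) -> tuple[bool, bool, bool]:
        """(D1, D2, D12) significance flags at the configured Z threshold."""
        return (
            self.z1 > self.z_threshold,
            self.z2 > self.z_threshold,
            self.z12 > self.z_threshold,
        )


# ---------------------------------------------------------------------------
# D from pattern totals
# ---------------------------------------------------------------------------


def _d_from_totals(totals: np.ndarray) -> np.ndarray:
    """Map (..., 6) pattern totals to (..., 3) D values; 0/0 -> 0."""
    totals = np.asarray(totals, dtype=float)
    a = totals[..., 0::2]  # ABBAA, ABABA, ABBBA
    b = totals[..., 1::2]  # BABAA, BAABA, BABBA
    num = a - b
    den = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return d


def compute_d(counts: PatternCounts) -> tuple[float, float, float]:
    """(D1, D2, D12) from pattern totals; a zero denominator yields 0.

    Use :func:`compute_d_flagged` when the zero-denominator cases need to
    be distinguished from a true balanced signal.
    """
    d, _ = compute_d_flagged(counts)
    return d


def compute_d_flagged(
    counts: PatternCounts,
) -> tuple[tuple[float, float, float], tuple[bool, bool, bool]]:
    totals = counts.as_array()
    if np.any(totals < 0):
        raise ValueError("pattern totals must be non-negative")
    d = _d_from_totals(totals)
    zero = tuple(bool(totals[2 * k] + totals[2 * k + 1] == 0) for k in range(3))
    return (float(d[0]), float(d[1]), float(d[2])), zero


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_z(
    m: SnpMatrix,
    cmap: CladeMap,
    roles: RoleAssignment,
    spec: BootstrapSpec,
    min_clade_cov: float = 1.0 / 3.0,
) -> tuple[float, float, float]:
    """Bootstrap Z-scores (Z1, Z2, Z12) by resampling loci with replacement.

    A bootstrap SD of exactly 0 (e.g. a dataset of identical duplicated
    loci) yields Z = +inf; callers needing the flag use
    :func:`bootstrap_z_flagged`.
    """
    z, _ = bootstrap_z_flagged(m, cmap, roles, spec, min_clade_cov)
    return z


def bootstrap_z_flagged(
    m: SnpMatrix,
    cmap: CladeMap,
    roles: RoleAssignment,
    spec: BootstrapSpec,
    min_clade_cov: float = 1.0 / 3.0,
) -> tuple[tuple[float, float, float], tuple[bool, bool, bool]]:
    freqs = polarize(lineage_frequencies(m, cmap, roles, min_clade_cov))
    labels, per_locus = per_locus_pattern_counts(freqs)
    return _bootstrap_from_locus_totals(per_locus, spec)


def _bootstrap_from_locus_totals(
    per_locus: np.ndarray, spec: BootstrapSpec
) -> tuple[tuple[float, float, float], tuple[bool, bool, bool]]:
    n_loci = per_locus.shape[0]
    if n_loci < 2:
        raise ValueError(f"bootstrap needs >= 2 usable loci, got {n_loci}")
    rng = np.random.default_rng(spec.seed)
    d_obs = _d_from_totals(per_locus.sum(axis=0))
    # resample in chunks to bound memory at large replicate counts
    d_reps = np.empty((spec.n_replicates, 3))
    chunk = max(1, min(spec.n_replicates, 4_000_000 // max(n_loci, 1)))
    done = 0
    while done < spec.n_replicates:
        k = min(chunk, spec.n_replicates - done)
        idx = rng.integers(0, n_loci, size=(k, n_loci))
        rep_totals = per_locus[idx].sum(axis=1)
        d_reps[done : done + k] = _d_from_totals(rep_totals)
        done += k
    sd = d_reps.std(axis=0, ddof=1) if spec.n_replicates > 1 else np.zeros(3)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(degenerate, np.inf, np.abs(d_obs) / np.where(degenerate, 1.0, sd))
    z = np.where(degenerate & (d_obs == 0), 0.0, z)  # 0/0: no signal, no evidence
    return (float(z[0]), float(z[1]), float(z[2])), tuple(bool(x) for x in degenerate)


# ---------------------------------------------------------------------------
# configuration enumeration
# ---------------------------------------------------------------------------


def enumerate_configurations(
    tree: dendropy.Tree,
    outgroup_clades: Iterable[str],
    canonical: bool = False,
) -> list[RoleAssignment]:
    """All role assignments compatible with the symmetric five-taxon shape.

    ``tree`` has clade ids as leaves.  An assignment is compatible when
    {P1, P2} is a sister pair, {P3a, P3b} is a sister pair, the two pairs
    are sisters, and O (the declared outgroup clades plus any leaf outside
    the quartet) lies outside.  For one balanced quartet this yields 8
    assignments (both within-pair orders and the pair-role swap); with
    ``canonical=True`` the sign/swap-equivalent rows collapse to 2
    (one per choice of which pair plays (P1, P2)... collapsed further to 1
    by fixing the (P1, P2) pair as the first cherry in tree order).
    """
    outgroup_clades = set(outgroup_clades)
    work = tree.clone(depth=1)
    leaf_labels = {lf.taxon.label for lf in work.leaf_node_iter()}
    ingroup = leaf_labels - outgroup_clades
    if len(ingroup) >= 4 and ingroup != leaf_labels:
        work.retain_taxa_with_labels(list(ingroup))

    def cherry(node: dendropy.Node) -> Optional[tuple[str, str]]:
        kids = node.child_nodes()
        if len(kids) == 2 and all(k.is_leaf() for k in kids):
            return kids[0].taxon.label, kids[1].taxon.label
        return None

    groups: list[list[RoleAssignment]] = []
    for node in work.preorder_internal_node_iter():
        kids = node.child_nodes()
        if len(kids) != 2:
            continue
        left, right = cherry(kids[0]), cherry(kids[1])
        if left is None or right is None:
            continue
        quartet = set(left) | set(right)
        pooled_o = frozenset((ingroup - quartet) | outgroup_clades)
        if not pooled_o:
            continue
        group = [
            RoleAssignment.from_clades(p1, p2, p3a, p3b, pooled_o)
            for pair12, pair3 in ((left, right), (right, left))
            for p1, p2 in (pair12, pair12[::-1])
            for p3a, p3b in (pair3, pair3[::-1])
        ]
        groups.append(group)
    if canonical:
        return [g[0] for g in groups]
    return [a for g in groups for a in g]


# ---------------------------------------------------------------------------
# full table
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "configuration",
    "D12",
    "Z12",
    "D1",
    "Z1",
    "D2",
    "Z2",
    "n_ABBAA",
    "n_BABAA",
    "n_ABABA",
    "n_BAABA",
    "n_ABBBA",
    "n_BABBA",
    "n_loci_used",
    "n_sites_used",
    "sig_D1",
    "sig_D2",
    "sig_D12",
]


def run_partitioned_tests(
    m: SnpMatrix,
    cmap: CladeMap,
    tree: dendropy.Tree,
    spec: Optional[BootstrapSpec] = None,
    min_clade_cov: float = 1.0 / 3.0,
    canonical: bool = False,
) -> list[DResult]:
    """One :class:`DResult` per role configuration compatible with ``tree``.

    Note: the per-configuration tests share loci and are therefore not
    phylogenetically independent; interpret jointly significant rows with
    care.
    """
    spec = spec or BootstrapSpec()
    configs = enumerate_configurations(tree, cmap.outgroup_clades, canonical=canonical)
    if not configs:
        import warnings

        warnings.warn("no symmetric quartet of clades found in the tree")
    results: list[DResult] = []
    for i, roles in enumerate(configs):
        freqs = polarize(lineage_frequencies(m, cmap, roles, min_clade_cov))
        counts = pattern_counts(freqs)
        (d1, d2, d12), zero = compute_d_flagged(counts)
        _, per_locus = per_locus_pattern_counts(freqs)
        sub = BootstrapSpec(spec.n_replicates, spec.seed + i, spec.z_threshold)
        (z1, z2, z12), degen = _bootstrap_from_locus_totals(per_locus, sub)
        results.append(
            DResult(
                configuration=roles,
                d1=d1,
                d2=d2,
                d12=d12,
                z1=z1,
                z2=z2,
                z12=z12,
                counts=counts,
                n_bootstrap=spec.n_replicates,
                z_threshold=spec.z_threshold,
                zero_denominator=zero,
                degenerate_bootstrap=degen,
            )
        )
    return results


def results_table(results: list[DResult]) -> pd.DataFrame:
    """Result rows as a tidy table (configuration, D/Z triplets, counts)."""
    rows = []
    for r in results:
        c = r.counts
        sig = r.significant
        rows.append(
            {
                "configuration": r.configuration.label(),
                "D12": r.d12,
                "Z12": r.z12,
                "D1": r.d1,
                "Z1": r.z1,
                "D2": r.d2,
                "Z2": r.z2,
                "n_ABBAA": c.n_abbaa,
                "n_BABAA": c.n_babaa,
                "n_ABABA": c.n_ababa,
                "n_BAABA": c.n_baaba,
                "n_ABBBA": c.n_abbba,
                "n_BABBA": c.n_babba,
                "n_loci_used": c.n_loci_used,
                "n_sites_used": c.n_sites_used,
                "sig_D1": sig[0],
                "sig_D2": sig[1],
                "sig_D12": sig[2],
            }
        )
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_results_tsv(results: list[DResult], path) -> None:
    results_table(results).to_csv(path, sep="\t", index=False, float_format="%.6g")


def interpret(result: DResult) -> list[str]:
    """Human-readable donor/recipient statements for the significant D values.

    Positive D1 indicates exchange between P2 and P3a, negative between P1
    and P3a; D2 reads analogously for P3b; D12 implicates the common
    ancestor of P3a and P3b.
    """

    def names(s: frozenset[str]) -> str:
        return "&".join(sorted(s))

    roles = result.configuration
    msgs: list[str] = []
    trio = (
        ("D1", result.d1, names(roles.p3a)),
        ("D2", result.d2, names(roles.p3b)),
        ("D12", result.d12, f"ancestor of ({names(roles.p3a)}, {names(roles.p3b)})"),
    )
    for (name, value, donor), flagged in zip(trio, result.significant):
        if not flagged:
            continue
        partner = names(roles.p2) if value > 0 else names(roles.p1)
        msgs.append(
            f"{name} = {value:+.3f} (significant): introgression between "
            f"{partner} and {donor}"
        )
    if not msgs:
        msgs.append("no significant D statistic at this threshold")
    return msgs
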