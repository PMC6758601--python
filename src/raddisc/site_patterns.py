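"""Frequency-weighted five-taxon site-pattern counting.

Samples are pooled by clade and each clade set is assigned one of five
roles in the symmetric topology (((P1, P2), (P3a, P3b)), O).  Per usable
site the derived-allele frequency of each role is computed, alleles are
polarized against the outgroup, and the six discordant site patterns
(ABBAA, BABAA, ABABA, BAABA, ABBBA, BABBA) are accumulated as products of
the five lineage frequencies.  With fixed lineages (frequencies in {0,1})
the weighted totals reduce to the literal integer pattern tally; with
polymorphic pools they are fractional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from raddisc.io_formats import MISSING, CladeMap, SnpMatrix

#: Canonical role order used throughout the module.
ROLES: tuple[str, ...] = ("P1", "P2", "P3a", "P3b", "O")

#: Canonical discordant-pattern order used throughout the module.
PATTERNS: tuple[str, ...] = ("ABBAA", "BABAA", "ABABA", "BAABA", "ABBBA", "BABBA")


@dataclass(frozen=True)
class RoleAssignment:
    """Maps each of the five roles to a set of clade ids (O may pool several).

    Roles must be pairwise disjoint and all five present.
    """

    p1: frozenset[str]
    p2: frozenset[str]
    p3a: frozenset[str]
    p3b: frozenset[str]
    outgroup: frozenset[str]

    def __post_init__(self) -> None:
        sets = [self.p1, self.p2, self.p3a, self.p3b, self.outgroup]
        for s in sets:
            if not s:
                raise ValueError("every role needs at least one clade")
        union = set().union(*sets)
        if len(union) != sum(len(s) for s in sets):
            raise ValueError("role clade sets must be pairwise disjoint")

    @classmethod
    def from_clades(
        cls,
        p1: str | Iterable[str],
        p2: str | Iterable[str],
        p3a: str | Iterable[str],
        p3b: str | Iterable[str],
        outgroup: str | Iterable[str],
    ) -> "RoleAssignment":
        def fs(x: str | Iterable[str]) -> frozenset[str]:
            return frozenset([x]) if isinstance(x, str) else frozenset(x)

        return cls(fs(p1), fs(p2), fs(p3a), fs(p3b), fs(outgroup))

    def role_clades(self) -> dict[str, frozenset[str]]:
        return {
            "P1": self.p1,
            "P2": self.p2,
            "P3a": self.p3a,
            "P3b": self.p3b,
            "O": self.outgroup,
        }

    def label(self) -> str:
        def j(s: frozenset[str]) -> str:
            return "&".join(sorted(s))

        return (
            f"(({j(self.p1)}, {j(self.p2)}), ({j(self.p3a)}, {j(self.p3b)}), {j(self.outgroup)})"
        )

    def swap_p1_p2(self) -> "RoleAssignment":
        return RoleAssignment(self.p2, self.p1, self.p3a, self.p3b, self.outgroup)

    def swap_p3(self) -> "RoleAssignment":
        return RoleAssignment(self.p1, self.p2, self.p3b, self.p3a, self.outgroup)


@dataclass
class SiteFrequencies:
    """Per-site derived-allele frequency of each role plus usability flags.

    ``freqs`` and ``coverage`` are (5, n_sites) arrays in :data:`ROLES`
    order; frequencies are NaN where a role has zero coverage at the site.
    ``usable`` marks sites whose locus passes the per-clade coverage rule
    (and, after polarization, excludes outgroup-tie sites).
    """

    freqs: np.ndarray
    coverage: np.ndarray
    usable: np.ndarray
    locus_ids: np.ndarray
    polarized: bool = False

    @property
    def n_sites(self) -> int:
        return self.freqs.shape[1]


@dataclass
class PatternCounts:
    """Frequency-weighted totals of the six discordant five-taxon patterns."""

    n_abbaa: float
    n_babaa: float
    n_ababa: float
    n_baaba: float
    n_abbba: float
    n_babba: float
    n_sites_used: int
    n_loci_used: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.n_abbaa,
                self.n_babaa,
                self.n_ababa,
                self.n_baaba,
                self.n_abbba,
                self.n_babba,
            ]
        )

    @classmethod
    def from_array(
        cls, totals: np.ndarray, n_sites_used: int = 0, n_loci_used: int = 0
    ) -> "PatternCounts":
        if np.any(np.asarray(totals) < 0):
            raise ValueError("pattern totals must be non-negative")
        return cls(*(float(x) for x in totals), n_sites_used, n_loci_used)

    def __add__(self, other: "PatternCounts") -> "PatternCounts":
        return PatternCounts.from_array(
            self.as_array() + other.as_array(),
            self.n_sites_used + other.n_sites_used,
            self.n_loci_used + other.n_loci_used,
        )


# ---------------------------------------------------------------------------


def lineage_frequencies(
    m: SnpMatrix,
    cmap: CladeMap,
    roles: RoleAssignment,
    min_clade_cov: float = 1.0 / 3.0,
) -> SiteFrequencies:
    """Pooled derived(alt)-allele frequency per site for each role.

    A site is usable iff at its locus every clade taking part in any role
    retains at least ``min_clade_cov`` of its samples (a sample retains a
    locus when it has at least one non-missing call there).  Coverage is
    therefore evaluated at locus, not site, level, matching how RAD locus
    dropout operates.
    """
    role_clades = roles.role_clades()
    all_clades = set().union(*role_clades.values())
    sample_idx: dict[str, np.ndarray] = {}
    for clade in all_clades:
        members = [
            i for i, s in enumerate(m.sample_ids) if cmap.assignment.get(s) == clade
        ]
        if not members:
            raise ValueError(f"role clade {clade!r} has no samples in the matrix")
        sample_idx[clade] = np.array(members)

    observed = m.dosages != MISSING
    n_sites = m.n_sites
    freqs = np.full((len(ROLES), n_sites), np.nan)
    coverage = np.zeros((len(ROLES), n_sites))
    for r, role in enumerate(ROLES):
        rows = np.concatenate([sample_idx[c] for c in sorted(role_clades[role])])
        obs = observed[rows]
        alt = np.where(obs, m.dosages[rows], 0)
        denom = (obs * m.ploidy[rows, None]).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[r] = np.where(denom > 0, alt.sum(axis=0) / np.maximum(denom, 1), np.nan)
        coverage[r] = obs.mean(axis=0)

    # locus-level coverage rule, per clade
    usable = np.ones(n_sites, dtype=bool)
    for locus, sl in m.locus_site_slices().items():
        ok = True
        for clade in all_clades:
            rows = sample_idx[clade]
            covering = observed[rows, sl].any(axis=1).sum()
            if covering < min_clade_cov * len(rows):
                ok = False
                break
        if not ok:
            usable[sl] = False
    # a usable site needs a defined frequency for every role
    usable &= ~np.isnan(freqs).any(axis=0)
    return SiteFrequencies(freqs, coverage, usable, m.locus_ids.copy())


def polarize(freqs: SiteFrequencies) -> SiteFrequencies:
    """Orient alleles so the outgroup's minor allele is the derived one (B).

    Sites where the outgroup frequency is exactly 0.5 cannot be polarized
    and are flagged unusable.  Residual outgroup polymorphism after the
    flip is down-weighted downstream by the (1 - pO) factor in the pattern
    products.
    """
    o = ROLES.index("O")
    out = freqs.freqs.copy()
    usable = freqs.usable.copy()
    p_o = out[o]
    with np.errstate(invalid="ignore"):
        tie = p_o == 0.5
        flip = p_o > 0.5
    usable &= ~(tie & freqs.usable)
    out[:, flip] = 1.0 - out[:, flip]
    return SiteFrequencies(out, freqs.coverage.copy(), usable, freqs.locus_ids.copy(), polarized=True)


def _pattern_weights(f: np.ndarray) -> np.ndarray:
    """(6, n) weighted pattern contributions from (5, n) polarized freqs."""
    p1, p2, p3a, p3b, po = f
    q1, q2, q3a, q3b, qo = 1.0 - f
    return np.stack(
        [
            q1 * p2 * p3a * q3b * qo,  # ABBAA
            p1 * q2 * p3a * q3b * qo,  # BABAA
            q1 * p2 * q3a * p3b * qo,  # ABABA
            p1 * q2 * q3a * p3b * qo,  # BAABA
            q1 * p2 * p3a * p3b * qo,  # ABBBA
            p1 * q2 * p3a * p3b * qo,  # BABBA
        ]
    )


def thin_one_per_locus(freqs: SiteFrequencies) -> SiteFrequencies:
    """Keep only the first usable SNP of each locus.

    Deterministic alternative to using every SNP; mainly for sensitivity
    checks, since the locus bootstrap already accounts for within-locus
    correlation.
    """
    usable = freqs.usable.copy()
    seen: set = set()
    for i in np.flatnonzero(usable):
        locus = freqs.locus_ids[i]
        if locus in seen:
            usable[i] = False
        else:
            seen.add(locus)
    return SiteFrequencies(
        freqs.freqs.copy(), freqs.coverage.copy(), usable,
        freqs.locus_ids.copy(), polarized=freqs.polarized,
    )


def pattern_counts(freqs: SiteFrequencies) -> PatternCounts:
    """Accumulate weighted pattern totals over usable, polarized sites."""
    if not freqs.polarized:
        raise ValueError("pattern_counts requires polarized frequencies")
    use = freqs.usable
    f = freqs.freqs[:, use]
    totals = _pattern_weights(f).sum(axis=1) if f.size else np.zeros(6)
    n_loci = len(np.unique(freqs.locus_ids[use])) if use.any() else 0
    return PatternCounts.from_array(totals, int(use.sum()), n_loci)


def per_locus_pattern_counts(freqs: SiteFrequencies) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus weighted pattern totals, for locus-level resampling.

    Returns ``(locus_labels, totals)`` where ``totals`` has shape
    (n_loci_used, 6).  Summing rows reproduces :func:`pattern_counts`
    exactly: pattern accumulation is additive over loci.
    """
    if not freqs.polarized:
        raise ValueError("per_locus_pattern_counts requires polarized frequencies")
    use = freqs.usable
    loci = freqs.locus_ids[use]
    w = _pattern_weights(freqs.freqs[:, use])
    labels, inverse = np.unique(loci, return_inverse=True)
    totals = np.zeros((len(labels), 6))
    for k in range(6):
        np.add.at(totals[:, k], inverse, w[k])
    return labels, totals
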