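"""Shared fixtures: small hand-built matrices and alignments."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from raddisc.io_formats import MISSING, Alignment, CladeMap, SnpMatrix


def make_snp_matrix(
    sample_ids: list[str],
    dosages: np.ndarray,
    locus_of_site: list[str],
    ploidy: int = 1,
) -> SnpMatrix:
    """SnpMatrix from a dosage array with per-site locus labels."""
    dosages = np.asarray(dosages, dtype=np.int16)
    n_sites = dosages.shape[1]
    sites = pd.DataFrame(
        {
            "locus_id": locus_of_site,
            "position": np.arange(1, n_sites + 1),
            "ref": ["A"] * n_sites,
            "alt": ["T"] * n_sites,
        }
    )
    return SnpMatrix(
        sample_ids, sites, dosages, np.full(len(sample_ids), ploidy, dtype=np.int16)
    )


@pytest.fixture
def five_clade_fixed_matrix():
    """One haploid sample per role-clade; every site a fixed pattern.

    Returns (matrix, clade_map) with clades P1c, P2c, A3c, B3c, Oc and
    dosages chosen so each of the six discordant patterns appears a known
    number of times (plus concordant/uninformative filler).
    """
    samples = ["s1", "s2", "s3", "s4", "s5"]
    cmap = CladeMap(
        {"s1": "P1c", "s2": "P2c", "s3": "A3c", "s4": "B3c", "s5": "Oc"},
        frozenset({"Oc"}),
    )
    # columns: ABBAA x2, BABAA x1, ABABA x1, BAABA x3, ABBBA x1, BABBA x2,
    # plus monomorphic and concordant BBAAA filler
    patterns = (
        [(0, 1, 1, 0, 0)] * 2
        + [(1, 0, 1, 0, 0)] * 1
        + [(0, 1, 0, 1, 0)] * 1
        + [(1, 0, 0, 1, 0)] * 3
        + [(0, 1, 1, 1, 0)] * 1
        + [(1, 0, 1, 1, 0)] * 2
        + [(0, 0, 0, 0, 0), (1, 1, 1, 1, 1), (1, 1, 0, 0, 0)]
    )
    dosages = np.array(patterns).T
    m = make_snp_matrix(samples, dosages, [f"L{i}" for i in range(dosages.shape[1])])
    expected = {"ABBAA": 2, "BABAA": 1, "ABABA": 1, "BAABA": 3, "ABBBA": 1, "BABBA": 2}
    return m, cmap, expected
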