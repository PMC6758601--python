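"""Readers, writers and containers for the formats the pipeline touches.

SNP matrices travel as VCF, alignments as FASTA or relaxed PHYLIP, trees as
Newick, and clade assignments as 2-3 column TSV.  The in-memory containers
are thin dataclasses over numpy/pandas; all downstream statistics consume
pooled allele frequencies, so diploid genotypes are stored as unphased
dosages and phasing is discarded on input.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO

#: Sentinel for a missing dosage / genotype call.
MISSING: int = -1

_VALID_BASES = frozenset(b"ACGT")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class EmptyMatrixError(FormatError):
    """Raised when parsing yields zero usable biallelic sites."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SnpMatrix:
    """Samples x biallelic sites with integer dosages.

    Attributes
    ----------
    sample_ids : ordered sample labels.
    sites : DataFrame with columns ``locus_id``, ``position`` (1-based),
        ``ref``, ``alt``; one row per site, loci contiguous.
    dosages : int16 array of shape (n_samples, n_sites); counts of the alt
        allele, ``MISSING`` (-1) where no call was made.
    ploidy : per-sample ploidy (1 or 2).
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    dosages: np.ndarray
    ploidy: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int16)
        n_samples, n_sites = self.dosages.shape
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.sites) != n_sites:
            raise ValueError("sites length does not match dosage columns")
        if not np.all(np.isin(self.ploidy, (1, 2))):
            raise ValueError("ploidy must be 1 or 2")
        observed = self.dosages != MISSING
        if np.any(self.dosages[observed] > self.ploidy[:, None].repeat(n_sites, 1)[observed]):
            raise ValueError("dosage exceeds ploidy")
        locus = self.sites["locus_id"].to_numpy()
        # loci must label contiguous site runs
        if len(locus):
            change = np.flatnonzero(locus[1:] != locus[:-1]) + 1
            starts = np.concatenate(([0], change))
            if len(np.unique(locus[starts])) != len(starts):
                raise ValueError("locus_ids do not partition sites contiguously")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def locus_ids(self) -> np.ndarray:
        """Per-site locus label."""
        return self.sites["locus_id"].to_numpy()

    def locus_site_slices(self) -> dict[str, slice]:
        """Map locus_id -> contiguous slice of site columns."""
        locus = self.sites["locus_id"].to_numpy()
        out: dict[str, slice] = {}
        if not len(locus):
            return out
        change = np.flatnonzero(locus[1:] != locus[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(locus)]))
        for s, e in zip(starts, ends):
            out[locus[s]] = slice(int(s), int(e))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.sites.reset_index(drop=True).equals(other.sites.reset_index(drop=True))
            and np.array_equal(self.dosages, other.dosages)
            and np.array_equal(self.ploidy, other.ploidy)
        )


@dataclass
class Alignment:
    """Equal-length haploid sequences over {A, C, G, T, N, -}.

    ``seqs`` is a (n_samples, n_columns) byte array; ``locus_bounds`` is an
    optional list of half-open [start, end) column intervals tiling the
    columns, mapping columns to RAD loci.
    """

    sample_ids: list[str]
    seqs: np.ndarray
    locus_bounds: Optional[list[tuple[int, int]]] = None

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs, dtype="S1")
        if self.seqs.ndim != 2:
            raise ValueError("seqs must be 2-D (samples x columns)")
        if len(self.sample_ids) != self.seqs.shape[0]:
            raise ValueError("sample_ids length does not match sequence rows")
        if self.locus_bounds is not None:
            prev = 0
            for start, end in self.locus_bounds:
                if start != prev or end < start:
                    raise ValueError("locus_bounds must tile columns without overlap")
                prev = end
            if prev != self.seqs.shape[1]:
                raise ValueError("locus_bounds do not cover all columns")

    @property
    def n_samples(self) -> int:
        return self.seqs.shape[0]

    @property
    def n_columns(self) -> int:
        return self.seqs.shape[1]

    def sequence(self, i: int) -> str:
        return self.seqs[i].tobytes().decode("ascii")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.seqs, other.seqs)
            and self.locus_bounds == other.locus_bounds
        )


@dataclass
class CladeMap:
    """Assignment of samples to clades plus the declared outgroup clade(s)."""

    assignment: dict[str, str]
    outgroup_clades: frozenset[str]

    def __post_init__(self) -> None:
        self.outgroup_clades = frozenset(self.outgroup_clades)
        if not self.outgroup_clades:
            raise ValueError("at least one outgroup clade must be declared")
        clades = set(self.assignment.values())
        missing = self.outgroup_clades - clades
        if missing:
            raise ValueError(f"outgroup clade(s) with no samples: {sorted(missing)}")

    @property
    def clades(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.assignment.values():
            seen.setdefault(c)
        return list(seen)

    def samples_of(self, clade_id: str) -> list[str]:
        return [s for s, c in self.assignment.items() if c == clade_id]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | os.PathLike) -> SnpMatrix:
    """Read biallelic SNPs from a VCF 4.x file into a :class:`SnpMatrix`.

    Multiallelic and non-SNP records are dropped (the site-pattern framework
    is defined on biallelic sites).  CHROM becomes the locus label, POS is
    kept 1-based.  Half-calls and ``./.`` become :data:`MISSING`.
    """
    from cyvcf2 import VCF

    try:
        reader = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise FormatError(f"cannot read VCF {path!r}: {exc}") from exc

    sample_ids = list(reader.samples)
    n = len(sample_ids)
    records = []
    dosage_rows = []
    ploidy = np.full(n, 0, dtype=np.int16)
    for var in reader:
        if len(var.ALT) != 1:
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            continue
        row = np.full(n, MISSING, dtype=np.int16)
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1]]  # last entry is the phased flag
            if ploidy[i] == 0:
                ploidy[i] = len(alleles)
            if any(a < 0 for a in alleles):
                continue  # ./., .|x half-calls -> missing
            row[i] = sum(1 for a in alleles if a == 1)
        records.append((var.CHROM, var.POS, ref, alt))
        dosage_rows.append(row)
    reader.close()
    ploidy[ploidy == 0] = 2
    if not records:
        raise EmptyMatrixError(f"no biallelic SNP records with calls in {path!r}")
    sites = pd.DataFrame(records, columns=["locus_id", "position", "ref", "alt"])
    dosages = np.stack(dosage_rows, axis=1)
    if np.all(dosages == MISSING):
        raise EmptyMatrixError(f"all genotypes missing in {path!r}")
    return SnpMatrix(sample_ids, sites, dosages, ploidy)


def write_vcf(matrix: SnpMatrix, path: str | os.PathLike) -> None:
    """Write a :class:`SnpMatrix` as minimal VCF 4.2 (GT genotypes only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for locus in dict.fromkeys(matrix.sites["locus_id"]):
            fh.write(f"##contig=<ID={locus}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, rec in enumerate(matrix.sites.itertuples(index=False)):
            gts = []
            for i in range(matrix.n_samples):
                d = matrix.dosages[i, j]
                k = matrix.ploidy[i]
                if d == MISSING:
                    gts.append("./." if k == 2 else ".")
                elif k == 1:
                    gts.append(str(d))
                else:
                    gts.append("0/1" if d == 1 else ("1/1" if d == 2 else "0/0"))
            fh.write(
                f"{rec.locus_id}\t{rec.position}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def _clean_sequences(seqs: np.ndarray) -> np.ndarray:
    """Upper-case and map non-{ACGTN-} symbols (ambiguity codes) to N."""
    flat = np.char.upper(seqs)
    ok = np.isin(flat, np.array([b"A", b"C", b"G", b"T", b"N", b"-"], dtype="S1"))
    flat = np.where(ok, flat, b"N")
    return flat.astype("S1")


def read_alignment(path: str | os.PathLike, format: str = "fasta") -> Alignment:
    """Read a FASTA or relaxed sequential PHYLIP alignment.

    Sequences are upper-cased; ambiguity codes other than N map to N.
    Ragged sequence lengths raise :class:`FormatError`.
    """
    if format not in ("fasta", "phylip"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    bio_format = "fasta" if format == "fasta" else "phylip-relaxed"
    try:
        aln = AlignIO.read(str(path), bio_format)
    except ValueError as exc:
        raise FormatError(f"cannot parse {format} alignment {path!r}: {exc}") from exc
    sample_ids = [rec.id for rec in aln]
    seqs = np.array([list(str(rec.seq).encode("ascii")) for rec in aln], dtype=np.uint8)
    seqs = seqs.view("S1")
    return Alignment(sample_ids, _clean_sequences(seqs))


def write_alignment(aln: Alignment, path: str | os.PathLike, format: str = "fasta") -> None:
    """Write an alignment as FASTA or relaxed sequential PHYLIP."""
    with open(path, "w") as fh:
        if format == "phylip":
            fh.write(f"{aln.n_samples} {aln.n_columns}\n")
            for i, sid in enumerate(aln.sample_ids):
                fh.write(f"{sid}  {aln.sequence(i)}\n")
        elif format == "fasta":
            for i, sid in enumerate(aln.sample_ids):
                fh.write(f">{sid}\n{aln.sequence(i)}\n")
        else:
            raise ValueError(f"unsupported alignment format: {format!r}")


def alignment_to_snps(aln: Alignment) -> SnpMatrix:
    """Extract the biallelic variable columns of a haploid alignment.

    N and gap are missing and excluded from the allele tally.  Within a
    column the majority allele among non-missing states becomes the ref
    (dosage 0) and the minority the alt (dosage 1); ties break by
    alphabetical order of the allele.  Columns with <2 or >2 distinct
    alleles are dropped; an invariant alignment yields an empty matrix.
    """
    seqs = aln.seqs
    n_samples, n_cols = seqs.shape
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    # counts[b, j] = number of samples with base b in column j
    counts = np.stack([(seqs == b).sum(axis=0) for b in bases])
    n_alleles = (counts > 0).sum(axis=0)
    keep = np.flatnonzero(n_alleles == 2)

    if aln.locus_bounds is not None:
        starts = np.array([s for s, _ in aln.locus_bounds])
        ends = np.array([e for _, e in aln.locus_bounds])
        locus_names = [f"L{k}" for k in range(len(starts))]
    records = []
    dosage_cols = []
    for j in keep:
        col_counts = counts[:, j]
        present = np.flatnonzero(col_counts > 0)
        a, b = present  # exactly two alleles; a < b alphabetically by construction
        # majority -> ref; alphabetical wins ties (bases[] already sorted)
        if col_counts[b] > col_counts[a]:
            ref_i, alt_i = b, a
        else:
            ref_i, alt_i = a, b
        col = seqs[:, j]
        dos = np.full(n_samples, MISSING, dtype=np.int16)
        dos[col == bases[ref_i]] = 0
        dos[col == bases[alt_i]] = 1
        if aln.locus_bounds is not None:
            k = int(np.searchsorted(ends, j, side="right"))
            locus_id = locus_names[k]
            position = int(j - starts[k]) + 1
        else:
            locus_id = "aln"
            position = int(j) + 1
        records.append(
            (locus_id, position, bases[ref_i].decode(), bases[alt_i].decode())
        )
        dosage_cols.append(dos)

    sites = pd.DataFrame(records, columns=["locus_id", "position", "ref", "alt"])
    if dosage_cols:
        dosages = np.stack(dosage_cols, axis=1)
    else:
        dosages = np.zeros((n_samples, 0), dtype=np.int16)
    return SnpMatrix(aln.sample_ids, sites, dosages, np.ones(n_samples, dtype=np.int16))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def read_newick(path_or_string: str | os.PathLike) -> dendropy.Tree:
    """Parse a Newick tree from a path or a literal Newick string."""
    text: str
    if isinstance(path_or_string, (str,)) and path_or_string.strip().startswith("("):
        text = path_or_string
    else:
        with open(path_or_string) as fh:
            text = fh.read()
    try:
        return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:
        raise FormatError(f"cannot parse Newick: {exc}") from exc


def write_annotated_newick(
    tree: dendropy.Tree,
    path: str | os.PathLike,
    annotations: Optional[Mapping[int, str]] = None,
) -> None:
    """Write a tree as Newick, optionally labelling internal nodes.

    ``annotations`` maps ``id(node)`` to a label string (the convention used
    for branch scores is ``"QC/QD/QI"``, e.g. ``"1/-/1"`` for a fully
    concordant branch).  Labels replace any existing internal node labels.
    """
    if annotations:
        for node in tree.preorder_node_iter():
            if id(node) in annotations:
                node.label = annotations[id(node)]
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick", suppress_rooting=True, unquoted_underscores=True
            )
        )


# ---------------------------------------------------------------------------
# clade maps
# ---------------------------------------------------------------------------


def read_clade_map(path: str | os.PathLike) -> CladeMap:
    """Read a sample -> clade TSV, with outgroup clades flagged.

    Accepted layouts: two columns (``sample_id``, ``clade_id``) with a header
    line ``#outgroup: <clade>[,<clade>...]``, or three columns where the
    third is ``outgroup`` (case-insensitive) on the outgroup clades' rows.
    Duplicate sample rows are an error.
    """
    outgroups: set[str] = set()
    rows: list[tuple[str, ...]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("outgroup:"):
                    names = body.split(":", 1)[1]
                    outgroups.update(x.strip() for x in names.split(",") if x.strip())
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"clade map line has <2 columns: {line!r}")
            rows.append(tuple(p.strip() for p in parts))
    assignment: dict[str, str] = {}
    for parts in rows:
        sample, clade = parts[0], parts[1]
        if sample in assignment:
            raise FormatError(f"duplicate sample id in clade map: {sample!r}")
        assignment[sample] = clade
        if len(parts) >= 3 and parts[2].lower() == "outgroup":
            outgroups.add(clade)
    if not assignment:
        raise FormatError("clade map contains no samples")
    if not outgroups:
        raise FormatError("no outgroup clade flagged in clade map")
    return CladeMap(assignment, frozenset(outgroups))


def write_clade_map(cmap: CladeMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#outgroup: " + ",".join(sorted(cmap.outgroup_clades)) + "\n")
        for sample, clade in cmap.assignment.items():
            fh.write(f"{sample}\t{clade}\n")
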