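"""Readers and writers for every on-disk artifact the pipeline touches.

The one genuinely standardized format here is the Beagle genotype-likelihood
file: tab-delimited, header ``marker allele1 allele2`` followed by three
columns per individual (likelihood of homozygous-major, heterozygous and
homozygous-minor). Marker ids are ``chrom_pos`` with 1-based positions, e.g.
``LG18_17175832``. Dialects differ in whether triples are raw or scaled;
this package stores and writes them normalized to sum 1, since every
downstream computation uses only their ratios.

Missing data (zero reads at a site) is encoded as the uniform triple
(1/3, 1/3, 1/3); a boolean mask records missingness separately so that
imputation can distinguish "uninformative" from "observed but ambiguous".

All other tables (sites, phenotypes, FST windows, importances, assignment
curves) are plain tab-delimited files with a header row, read and written
through pandas. Site coordinates are 1-based everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ALLELE_CODES = ("A", "C", "G", "T")

__all__ = [
    "GenotypeLikelihoodMatrix",
    "BeagleParseError",
    "CongruenceError",
    "write_beagle",
    "read_beagle",
    "marker_id",
    "parse_marker_id",
    "write_table",
    "read_table",
    "read_phenotypes",
    "validate_phenotypes",
]


class BeagleParseError(ValueError):
    """Malformed Beagle file (ragged row, bad allele code, ...)."""


class CongruenceError(ValueError):
    """Two artifacts that must align (same sites / individuals) do not."""


@dataclass
class GenotypeLikelihoodMatrix:
    """Per-site, per-individual genotype likelihood triples.

    Attributes
    ----------
    values : ndarray, shape (n_sites, n_ind, 3)
        Likelihood triples ordered (hom major, het, hom minor), each triple
        normalized to sum 1.
    missing : ndarray of bool, shape (n_sites, n_ind)
        True where the individual has no data at the site; the triple there
        is the uniform (1/3, 1/3, 1/3).
    individuals : list of str
        Column labels, same order as axis 1.
    """

    values: np.ndarray
    missing: np.ndarray
    individuals: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("values must have shape (n_sites, n_ind, 3)")
        if self.missing is None:
            self.missing = np.zeros(self.values.shape[:2], dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.values.shape[:2]:
            raise ValueError("missing mask shape mismatch")
        if not self.individuals:
            self.individuals = [f"Ind{i}" for i in range(self.values.shape[1])]

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_ind(self) -> int:
        return self.values.shape[1]

    def normalized(self) -> "GenotypeLikelihoodMatrix":
        """Return a copy with every triple scaled to sum 1 (zero-sum triples
        become uniform and are flagged missing)."""
        v = self.values.copy()
        s = v.sum(axis=2)
        zero = s <= 0
        s[zero] = 1.0
        v /= s[:, :, None]
        v[zero] = 1.0 / 3.0
        return GenotypeLikelihoodMatrix(
            v, self.missing | zero, list(self.individuals)
        )

    def subset_sites(self, idx) -> "GenotypeLikelihoodMatrix":
        return GenotypeLikelihoodMatrix(
            self.values[idx], self.missing[idx], list(self.individuals)
        )


def marker_id(chrom: str, pos: int) -> str:
    """``(chrom, pos)`` -> ``chrom_pos`` locus name (1-based position)."""
    return f"{chrom}_{int(pos)}"


def parse_marker_id(marker: str) -> tuple:
    """Split a ``chrom_pos`` locus name on its last underscore."""
    chrom, _, pos = marker.rpartition("_")
    if not chrom or not pos.isdigit():
        raise BeagleParseError(f"cannot parse marker id {marker!r}")
    return chrom, int(pos)


def write_beagle(gl: GenotypeLikelihoodMatrix, sites: pd.DataFrame, path) -> None:
    """Write a Beagle genotype-likelihood file.

    ``sites`` must carry columns ``chrom``, ``pos``, ``major``, ``minor``
    (integer base codes 0-3) and align row-for-row with ``gl``. Triples are
    renormalized to sum 1 on the way out and round-trip through
    :func:`read_beagle` to at least 6 significant digits.
    """
    if len(sites) != gl.n_sites:
        raise CongruenceError(
            f"site table has {len(sites)} rows but GL matrix has {gl.n_sites} sites"
        )
    norm = gl.normalized()
    with open(path, "w") as fh:
        cols = ["marker", "allele1", "allele2"]
        for name in norm.individuals:
            cols.extend([name, name, name])
        fh.write("\t".join(cols) + "\n")
        chroms = sites["chrom"].to_numpy()
        poss = sites["pos"].to_numpy()
        majors = sites["major"].to_numpy()
        minors = sites["minor"].to_numpy()
        for s in range(norm.n_sites):
            row = [marker_id(chroms[s], poss[s]), str(int(majors[s])), str(int(minors[s]))]
            row.extend(f"{x:.6g}" for x in norm.values[s].ravel())
            fh.write("\t".join(row) + "\n")


def read_beagle(path):
    """Read a Beagle genotype-likelihood file.

    Returns ``(GenotypeLikelihoodMatrix, site DataFrame)``. Triples are
    renormalized to sum 1; an all-zero triple becomes the uniform triple and
    is flagged missing. Raises :class:`BeagleParseError` with the offending
    line number on ragged rows or non-integer allele codes.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or (len(header) - 3) % 3 != 0:
            raise BeagleParseError("header must be 'marker allele1 allele2' + 3 cols/ind")
        n_ind = (len(header) - 3) // 3
        individuals = [header[3 + 3 * i] for i in range(n_ind)]
        chroms, poss, majors, minors, triples = [], [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise BeagleParseError(
                    f"line {lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            chrom, pos = parse_marker_id(parts[0])
            for a in (parts[1], parts[2]):
                if not a.lstrip("-").isdigit():
                    raise BeagleParseError(
                        f"line {lineno}: allele code {a!r} is not an integer"
                    )
            a1, a2 = int(parts[1]), int(parts[2])
            if not (0 <= a1 <= 3 and 0 <= a2 <= 3):
                raise BeagleParseError(f"line {lineno}: allele code outside 0-3")
            chroms.append(chrom)
            poss.append(pos)
            majors.append(a1)
            minors.append(a2)
            triples.append([float(x) for x in parts[3:]])
    values = np.asarray(triples, dtype=float).reshape(len(triples), n_ind, 3)
    gl = GenotypeLikelihoodMatrix(
        values, np.zeros(values.shape[:2], dtype=bool), individuals
    ).normalized()
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "major": majors, "minor": minors}
    )
    return gl, sites


_FLOAT_FORMAT = "%.8g"


def write_table(df: pd.DataFrame, path) -> None:
    """Tab-delimited table with header; fixed float formatting so identical
    inputs produce byte-identical files."""
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_phenotypes(path) -> pd.DataFrame:
    df = read_table(path)
    validate_phenotypes(df)
    return df


def validate_phenotypes(df: pd.DataFrame, individuals=None) -> None:
    """Check a phenotype table: id + group columns, >=2 non-empty groups,
    and (optionally) individual order matching a GL matrix."""
    for col in ("individual_id", "group"):
        if col not in df.columns:
            raise CongruenceError(f"phenotype table lacks required column {col!r}")
    counts = df["group"].value_counts()
    if len(counts) < 2 or (counts == 0).any():
        raise CongruenceError("phenotype table needs >=2 non-empty groups")
    if individuals is not None:
        if list(df["individual_id"]) != list(individuals):
            raise CongruenceError("phenotype individual order does not match GL columns")
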