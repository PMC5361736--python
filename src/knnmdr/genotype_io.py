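"""Readers, writers and validation for case-control SNP genotype data.

Two plain-text dialects are supported:

* PLINK-style ``.ped``/``.map`` pairs (6 leading ped columns
  ``FID IID PAT MAT SEX PHENO`` followed by two space-separated allele
  labels per marker);
* a TSV matrix with a header row of marker ids, one row per individual,
  first column the individual id and entries in ``{0, 1, 2}``.

Genotypes are always stored as minor-allele counts.  The minor allele is
determined per marker from the sample allele frequencies; when both
alleles have frequency 0.5 the lexicographically smaller allele label is
taken as the minor allele so the coding is deterministic.  All distance
computations downstream are invariant to which allele is called minor
(``c -> 2 - c`` only flips the sign of pairwise differences).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeError",
    "ParseError",
    "FormatError",
    "ConsistencyError",
    "GenotypeMatrix",
    "MarkerMap",
    "PhenotypeVector",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "minor_allele_frequencies",
]

#: sentinel for a missing genotype (only legal when ``allows_missing`` is set)
MISSING = -1


class GenotypeError(ValueError):
    """Base class for all genotype-file errors."""


class ParseError(GenotypeError):
    """A line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FormatError(GenotypeError):
    """The file is structurally valid but violates the dialect contract."""


class ConsistencyError(GenotypeError):
    """Companion files (ped/map, genotype/phenotype) disagree."""


@dataclasses.dataclass
class GenotypeMatrix:
    """``n_individuals x n_markers`` table of minor-allele counts.

    Parameters
    ----------
    values
        Integer matrix with entries in ``{0, 1, 2}`` (plus :data:`MISSING`
        when ``allows_missing`` is set).
    individual_ids
        Unique identifier per row.
    allows_missing
        Whether the :data:`MISSING` sentinel is tolerated.
    """

    values: np.ndarray
    individual_ids: list[str]
    allows_missing: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.individual_ids = [str(i) for i in self.individual_ids]
        if self.values.ndim != 2:
            raise GenotypeError("genotype values must be a 2-D matrix")
        n_ind, n_mark = self.values.shape
        if n_ind < 2:
            raise GenotypeError("at least 2 individuals are required")
        if n_mark < 1:
            raise GenotypeError("at least 1 marker is required")
        if len(self.individual_ids) != n_ind:
            raise GenotypeError(
                f"{len(self.individual_ids)} ids for {n_ind} genotype rows"
            )
        if len(set(self.individual_ids)) != n_ind:
            raise GenotypeError("individual ids must be unique")
        legal = {0, 1, 2} | ({MISSING} if self.allows_missing else set())
        present = set(np.unique(self.values).tolist())
        if not present <= legal:
            raise GenotypeError(
                f"illegal genotype codes {sorted(present - legal)}; "
                "expected minor-allele counts in {0, 1, 2}"
            )

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool(np.any(self.values == MISSING))


@dataclasses.dataclass
class MarkerMap:
    """Per-marker metadata: id, chromosome, physical position, alleles.

    ``alleles``, when present, holds ``(minor, major)`` label pairs in the
    coding order of the companion :class:`GenotypeMatrix`.
    """

    ids: list[str]
    chromosomes: list[str]
    positions: np.ndarray
    alleles: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.chromosomes = [str(c) for c in self.chromosomes]
        self.positions = np.asarray(self.positions, dtype=np.int64)
        n = len(self.ids)
        if len(self.chromosomes) != n or len(self.positions) != n:
            raise GenotypeError("marker map columns have unequal lengths")
        if self.alleles is not None and len(self.alleles) != n:
            raise GenotypeError("allele labels length mismatch")
        if len(set(self.ids)) != n:
            raise GenotypeError("marker ids must be unique")
        for chrom in set(self.chromosomes):
            pos = self.positions[np.array(self.chromosomes) == chrom]
            if np.any(np.diff(pos) < 0):
                raise GenotypeError(
                    f"positions on chromosome {chrom} are not non-decreasing"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def default(cls, n_markers: int, chromosome: str = "1", spacing: int = 1000) -> "MarkerMap":
        """Placeholder map with evenly spaced positions on one chromosome."""
        return cls(
            ids=[f"snp{i + 1}" for i in range(n_markers)],
            chromosomes=[chromosome] * n_markers,
            positions=np.arange(1, n_markers + 1, dtype=np.int64) * spacing,
        )

    def subset(self, indices: Sequence[int]) -> "MarkerMap":
        idx = list(indices)
        return MarkerMap(
            ids=[self.ids[i] for i in idx],
            chromosomes=[self.chromosomes[i] for i in idx],
            positions=self.positions[idx],
            alleles=None if self.alleles is None else [self.alleles[i] for i in idx],
        )


@dataclasses.dataclass
class PhenotypeVector:
    """Binary case/control status per individual (``True`` = case)."""

    is_case: np.ndarray

    def __post_init__(self) -> None:
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if self.is_case.ndim != 1:
            raise GenotypeError("phenotype must be a 1-D vector")
        if not self.is_case.any():
            raise GenotypeError("at least one case required")
        if self.is_case.all():
            raise GenotypeError("at least one control required")

    def __len__(self) -> int:
        return len(self.is_case)

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())


def _minor_major(counts: dict[str, int]) -> tuple[str, str]:
    """Pick (minor, major) labels from allele tallies.

    Frequency ties are broken by taking the lexicographically smaller
    label as the minor allele.
    """
    (a, ca), (b, cb) = sorted(counts.items())
    if ca < cb:
        return a, b
    if cb < ca:
        return b, a
    return a, b  # tie: lexicographically smaller label is "minor"


def _read_ped_map(prefix: Path, allow_missing: bool) -> tuple[GenotypeMatrix, MarkerMap]:
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    for p in (ped_path, map_path):
        if not p.exists():
            raise FileNotFoundError(p)

    ids, chroms, positions = [], [], []
    with open(map_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            fields = raw.split()
            if not fields:
                continue
            if len(fields) not in (3, 4):
                raise ParseError(
                    f"expected 3 or 4 map columns, got {len(fields)}", lineno
                )
            chroms.append(fields[0])
            ids.append(fields[1])
            try:
                positions.append(int(fields[-1]))
            except ValueError as exc:
                raise ParseError(f"bad physical position {fields[-1]!r}", lineno) from exc
    n_mark = len(ids)
    if n_mark == 0:
        raise FormatError(f"{map_path} contains no markers")

    ind_ids: list[str] = []
    rows: list[list[str]] = []  # 2*n_mark allele labels per individual
    with open(ped_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            fields = raw.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_mark:
                raise ConsistencyError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * n_mark} fields "
                    f"for {n_mark} map markers, got {len(fields)}"
                )
            ind_ids.append(fields[1])
            rows.append(fields[6:])

    n_ind = len(ind_ids)
    alleles = np.array(rows, dtype=object).reshape(n_ind, n_mark, 2)
    values = np.zeros((n_ind, n_mark), dtype=np.int8)
    pairs: list[tuple[str, str]] = []
    for m in range(n_mark):
        col = alleles[:, m, :]
        labels, tallies = np.unique(col, return_counts=True)
        counts = dict(zip(labels.tolist(), tallies.tolist()))
        missing = counts.pop("0", 0)
        if missing and not allow_missing:
            raise ParseError(
                f"missing genotype at marker {ids[m]}; pass allow_missing=True"
            )
        if len(counts) > 2:
            raise FormatError(
                f"marker {ids[m]} has {len(counts)} alleles; only biallelic "
                "markers are supported"
            )
        if len(counts) == 0:
            raise FormatError(f"marker {ids[m]} is entirely missing")
        if len(counts) == 1:
            # monomorphic: the (unobserved) minor allele has count 0 everywhere
            major = next(iter(counts))
            pairs.append(("?", major))
            values[:, m] = 0
        else:
            minor, major = _minor_major(counts)
            pairs.append((minor, major))
            values[:, m] = (col == minor).sum(axis=1)
        if missing:
            values[(col == "0").any(axis=1), m] = MISSING

    gm = GenotypeMatrix(values, ind_ids, allows_missing=allow_missing)
    mm = MarkerMap(ids, chroms, np.array(positions), alleles=pairs)
    return gm, mm


def _read_tsv(path: Path, allow_missing: bool) -> tuple[GenotypeMatrix, MarkerMap]:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] < 1:
        raise FormatError(f"{path} has no marker columns")
    try:
        values = df.to_numpy(dtype=np.int64)
    except ValueError as exc:
        raise ParseError(f"non-integer genotype entry in {path}: {exc}") from exc
    gm = GenotypeMatrix(values, [str(i) for i in df.index], allows_missing=allow_missing)
    mm = MarkerMap.default(gm.n_markers)
    mm.ids = [str(c) for c in df.columns]
    return gm, mm


def read_genotypes(
    path: str | Path,
    format: str = "ped_map",
    allow_missing: bool = False,
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read a genotype matrix plus marker map.

    For ``format="ped_map"`` *path* is the common prefix of the ``.ped``
    and ``.map`` pair; for ``format="tsv"`` it is the matrix file itself.
    """
    path = Path(path)
    if format == "ped_map":
        return _read_ped_map(path, allow_missing)
    if format == "tsv":
        return _read_tsv(path, allow_missing)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(
    path: str | Path,
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap | None = None,
    format: str = "ped_map",
    phenotype: PhenotypeVector | None = None,
) -> None:
    """Write a genotype matrix in one of the two supported dialects.

    The TSV round-trip is the exact identity.  The ped round-trip is the
    identity whenever every column codes the sample minor allele (column
    mean <= 1); otherwise the reader re-derives the minor allele and the
    column comes back flipped ``c -> 2 - c``, which leaves all distances
    unchanged.
    """
    path = Path(path)
    if marker_map is None:
        marker_map = MarkerMap.default(genotypes.n_markers)
    if len(marker_map) != genotypes.n_markers:
        raise ConsistencyError("marker map length does not match genotype matrix")

    if format == "tsv":
        df = pd.DataFrame(
            genotypes.values, index=genotypes.individual_ids, columns=marker_map.ids
        )
        df.to_csv(path, sep="\t", index_label="individual_id")
        return
    if format != "ped_map":
        raise ValueError(f"unknown genotype format {format!r}")

    with open(path.with_suffix(".map"), "w") as fh:
        for i in range(len(marker_map)):
            fh.write(
                f"{marker_map.chromosomes[i]}\t{marker_map.ids[i]}\t0\t"
                f"{marker_map.positions[i]}\n"
            )

    freqs = genotypes.values.astype(float).mean(axis=0) / 2.0
    pheno = (
        np.where(phenotype.is_case, 2, 1)
        if phenotype is not None
        else np.zeros(genotypes.n_individuals, dtype=int)
    )
    with open(path.with_suffix(".ped"), "w") as fh:
        for i, iid in enumerate(genotypes.individual_ids):
            fields = [iid, iid, "0", "0", "0", str(int(pheno[i]))]
            for m in range(genotypes.n_markers):
                if marker_map.alleles is not None and marker_map.alleles[m][0] != "?":
                    minor, major = marker_map.alleles[m]
                else:
                    # label so that re-reading recovers the same coding:
                    # on a 0.5/0.5 tie the reader calls "A" minor
                    minor, major = ("A", "B") if freqs[m] == 0.5 else ("B", "A")
                c = int(genotypes.values[i, m])
                if c == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [minor] * c + [major] * (2 - c)
            fh.write(" ".join(fields) + "\n")


def read_phenotypes(
    path: str | Path,
    individual_ids: Sequence[str] | None = None,
    case_label: str = "2",
    control_label: str = "1",
) -> PhenotypeVector:
    """Read a two-column (id, status) TSV, realigned to *individual_ids*.

    Default status labels follow the PLINK text convention (2 = case,
    1 = control); other label pairs may be configured.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"expected 2 columns (id, status), got {df.shape[1]}")
    status = dict(zip(df[0], df[1]))
    if len(status) != len(df):
        raise ConsistencyError("duplicate individual id in phenotype file")
    unknown = set(status.values()) - {case_label, control_label}
    if unknown:
        raise FormatError(
            f"unknown status labels {sorted(unknown)}; expected "
            f"{case_label!r} (case) or {control_label!r} (control)"
        )
    order = list(df[0]) if individual_ids is None else [str(i) for i in individual_ids]
    missing = [i for i in order if i not in status]
    if missing:
        raise ConsistencyError(f"no phenotype for individuals {missing[:5]}")
    return PhenotypeVector(np.array([status[i] == case_label for i in order]))


def write_phenotypes(
    path: str | Path,
    phenotype: PhenotypeVector,
    individual_ids: Sequence[str],
    case_label: str = "2",
    control_label: str = "1",
) -> None:
    if len(individual_ids) != len(phenotype):
        raise ConsistencyError("phenotype / id length mismatch")
    with open(path, "w") as fh:
        for iid, case in zip(individual_ids, phenotype.is_case):
            fh.write(f"{iid}\t{case_label if case else control_label}\n")


def minor_allele_frequencies(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-marker MAF: ``min(p, 1 - p)`` with ``p = mean(count) / 2``.

    With missing data (only legal when ``allows_missing`` is set) the
    frequency is computed over the observed genotypes of each marker.
    """
    values = genotypes.values.astype(float)
    if genotypes.has_missing():
        if not genotypes.allows_missing:
            raise GenotypeError("missing genotypes present")
        values = np.where(values == MISSING, np.nan, values)
        p = np.nanmean(values, axis=0) / 2.0
    else:
        p = values.mean(axis=0) / 2.0
    return np.minimum(p, 1.0 - p)
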