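"""Readers, writers and the fitness-defect transform for chemical-genomic screens.

A HIP/HOP screen measures the growth of a library of gene-deletion strains
under compound treatment and under untreated control conditions.  The
fitness-defect score (FD-score) of strain *i* under compound *c* is the
log-ratio of the treated growth measurement to the strain's mean control
growth::

    FD_ic = log_b( r_ic / mean_controls(r_i) )

Low, negative FD-scores mean the strain is hypersensitive to the compound,
which is the raw signal behind target identification.  All matrices in this
package are oriented rows = genes, columns = compounds, with NaN as the
missing-value marker.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthTable",
    "FitnessMatrix",
    "BenchmarkSet",
    "GeneSetCollection",
    "compute_fd",
    "read_matrix",
    "write_matrix",
    "read_benchmark",
    "read_gmt",
]


@dataclass
class GrowthTable:
    """Raw growth-defect measurements, strains x conditions.

    ``values`` holds nonnegative growth measurements (NaN = missing);
    ``control_flags`` marks which conditions are untreated controls.
    """

    values: pd.DataFrame
    control_flags: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.control_flags = self.control_flags.astype(bool).reindex(self.values.columns)
        if self.control_flags.isna().any():
            missing = list(self.control_flags.index[self.control_flags.isna()])
            raise ValueError(f"control_flags missing for conditions: {missing}")
        finite = self.values.to_numpy()
        if np.nanmin(finite, initial=0.0) < 0:
            raise ValueError("growth measurements must be nonnegative")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class FitnessMatrix:
    """FD-scores, genes x compounds; NaN entries are missing measurements."""

    fd: pd.DataFrame

    def __post_init__(self) -> None:
        self.fd = self.fd.astype(float)
        if self.fd.index.duplicated().any():
            dups = sorted(set(self.fd.index[self.fd.index.duplicated()]))
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.fd.columns.duplicated().any():
            dups = sorted(set(self.fd.columns[self.fd.columns.duplicated()]))
            raise ValueError(f"duplicate compound ids: {dups}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.fd.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.fd.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.fd.isna()


@dataclass
class BenchmarkSet:
    """Known compound-target pairs with confidences in [0, 1]."""

    pairs: pd.DataFrame  # columns: compound, gene, confidence

    def __post_init__(self) -> None:
        required = ["compound", "gene", "confidence"]
        if list(self.pairs.columns[:3]) != required:
            self.pairs = self.pairs.rename(
                columns=dict(zip(self.pairs.columns[:3], required))
            )
        conf = self.pairs["confidence"].astype(float)
        if ((conf < 0) | (conf > 1)).any():
            bad = self.pairs.loc[(conf < 0) | (conf > 1)]
            raise ValueError(f"confidence outside [0, 1]: {bad.to_dict('records')}")
        if self.pairs.duplicated(subset=["compound", "gene"]).any():
            raise ValueError("duplicate (compound, gene) pairs in benchmark")

    def __len__(self) -> int:
        return len(self.pairs)

    def targets_of(self, compound: str) -> set[str]:
        sel = self.pairs["compound"] == compound
        return set(self.pairs.loc[sel, "gene"])

    @property
    def compounds(self) -> set[str]:
        return set(self.pairs["compound"])


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def compute_fd(growth: GrowthTable, log_base: float = 2.0) -> FitnessMatrix:
    """Compute FD-scores from raw growth measurements.

    For each strain the control reference is the arithmetic mean of its
    control-condition measurements.  Entries with missing or nonpositive
    treated measurement, or a nonpositive/undefined control mean, become
    missing (NaN) — never +/-inf.

    Parameters
    ----------
    growth:
        Raw measurements with control conditions flagged.
    log_base:
        Base of the logarithm; the default 2 is the convention for fitness
        log-ratios.  All downstream scores are covariant with this choice.
    """
    if log_base <= 0 or log_base == 1.0:
        raise ValueError("log_base must be positive and != 1")
    ctrl_cols = growth.control_flags[growth.control_flags].index
    if len(ctrl_cols) == 0:
        raise ValueError("FD computation requires at least one control condition")
    controls = growth.values[ctrl_cols]
    rbar = controls.mean(axis=1, skipna=True)  # mean control growth per strain
    all_missing = controls.isna().all(axis=1)
    if all_missing.any():
        logger.warning(
            "all control measurements missing for %d strain(s): %s",
            all_missing.sum(),
            list(growth.values.index[all_missing])[:10],
        )
    treated = growth.values.drop(columns=ctrl_cols)
    ratio = treated.div(rbar, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fd = np.log(ratio.to_numpy()) / np.log(log_base)
    # nonpositive ratios (r<=0 or rbar<=0) give nan/inf: mark missing
    fd[~np.isfinite(fd)] = np.nan
    return FitnessMatrix(pd.DataFrame(fd, index=treated.index, columns=treated.columns))


def _parse_float(token: str, missing_token: str) -> float:
    if token == missing_token or token == "":
        return float("nan")
    return float(token)


def read_matrix(path, missing_token: str = "NA") -> FitnessMatrix:
    """Read a genes-x-compounds TSV matrix (header row + header column).

    Lines starting with ``#`` are treated as comments and skipped.  Raises
    on ragged rows (with line number) and on duplicate gene ids.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header: list[str] | None = None
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, fields in enumerate(reader, start=1):
            if not fields or (fields[0].startswith("#")):
                continue
            if header is None:
                header = fields[1:]
                continue
            if len(fields) != len(header) + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header) + 1} fields, "
                    f"got {len(fields)}"
                )
            gene = fields[0]
            if gene in set(genes):
                raise ValueError(f"{path}: duplicate gene id {gene!r}")
            genes.append(gene)
            try:
                rows.append([_parse_float(tok, missing_token) for tok in fields[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
        if header is None:
            raise ValueError(f"{path}: empty matrix file")
    df = pd.DataFrame(rows, index=genes, columns=header, dtype=float)
    return FitnessMatrix(df)


def write_matrix(matrix: FitnessMatrix, path, missing_token: str = "NA",
                 header_comment: str | None = None) -> None:
    """Write a matrix TSV; finite values round-trip bit-exactly via ``repr``."""
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("gene\t" + "\t".join(map(str, matrix.compound_ids)) + "\n")
        values = matrix.fd.to_numpy()
        for i, gene in enumerate(matrix.gene_ids):
            cells = [
                missing_token if np.isnan(v) else repr(float(v)) for v in values[i]
            ]
            fh.write(str(gene) + "\t" + "\t".join(cells) + "\n")


def read_benchmark(path, min_confidence: float = 0.4) -> BenchmarkSet:
    """Read a compound-target benchmark TSV (compound, gene, confidence).

    Pairs with confidence strictly below ``min_confidence`` are removed
    (the STITCH-style low-confidence filter); the boundary value is kept.
    A header line is recognised if its third field is not numeric.
    """
    records: list[tuple[str, str, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, fields in enumerate(reader, start=1):
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 fields, got {len(fields)}"
                )
            try:
                conf = float(fields[2])
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric confidence {fields[2]!r}"
                ) from None
            if not 0.0 <= conf <= 1.0:
                raise ValueError(
                    f"{path}: line {lineno}: confidence {conf} outside [0, 1]"
                )
            records.append((fields[0], fields[1], conf))
    if not records:
        logger.warning("%s: empty benchmark file", path)
        return BenchmarkSet(pd.DataFrame(columns=["compound", "gene", "confidence"]))
    df = pd.DataFrame(records, columns=["compound", "gene", "confidence"])
    # collapse duplicate pairs keeping the highest confidence
    n_before = len(df)
    df = (
        df.sort_values("confidence", ascending=False)
        .drop_duplicates(subset=["compound", "gene"])
        .sort_index()
        .reset_index(drop=True)
    )
    if len(df) < n_before:
        logger.warning("collapsed %d duplicate benchmark pair(s)", n_before - len(df))
    kept = df[df["confidence"] >= min_confidence].reset_index(drop=True)
    logger.info(
        "benchmark: %d pairs read, %d removed below confidence %.3g",
        len(df), len(df) - len(kept), min_confidence,
    )
    return BenchmarkSet(kept)


def write_benchmark(bench: BenchmarkSet, path) -> None:
    bench.pairs.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format: name TAB description TAB member..."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need >= 3 fields "
                    f"(name, description, members...)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}: line {lineno}: gene set {name!r} has no members")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)
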