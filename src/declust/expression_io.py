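"""Tabular I/O for count matrices, strain designs, gene lists and DE call sets.

All formats are plain text. Count matrices are genes x samples with a header
row of sample ids and the gene id in the first column; the delimiter (tab or
comma) is sniffed from the first line unless given explicitly. Gene ids are
opaque strings with no coordinate semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError

logger = logging.getLogger(__name__)

RAW = "raw"
LOG = "log"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table.

    ``scale`` is ``"raw"`` for non-negative counts and ``"log"`` after the
    log transform; raw-scale values must be finite and >= 0.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise FormatError(f"duplicate gene id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise FormatError(f"duplicate sample id {dup!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.scale == RAW and np.any(self.values < 0):
            g, s = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative count {self.values[g, s]} at gene "
                f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Return a matrix restricted to gene rows ``keep`` (order preserved)."""
        keep = np.asarray(keep)
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            values=self.values[keep],
            scale=self.scale,
        )


@dataclass
class StrainDesign:
    """Assignment of each sample to one of exactly two strain labels."""

    assignment: dict[str, str]
    strains: tuple[str, str] = field(init=False)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for strain in self.assignment.values():
            if strain not in seen:
                seen.append(strain)
        if len(seen) != 2:
            raise DesignError(f"expected exactly 2 strains, found {len(seen)}: {seen}")
        counts = {s: 0 for s in seen}
        for strain in self.assignment.values():
            counts[strain] += 1
        for strain, n in counts.items():
            if n < 2:
                raise DesignError(
                    f"strain {strain!r} has {n} sample(s); at least 2 are "
                    "required for a defined sample standard deviation"
                )
        self.strains = (seen[0], seen[1])

    def samples_of(self, strain: str) -> list[str]:
        return [s for s, t in self.assignment.items() if t == strain]


@dataclass
class GeneSet:
    """A named set of gene ids (e.g. the call list of a statistical method)."""

    name: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    raise AssertionError("no duplicate present")


def sniff_delimiter(path: str | Path) -> str:
    """Guess tab vs comma from the first line of ``path``."""
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_counts(
    path: str | Path,
    delimiter: str | None = None,
    header: bool = True,
) -> ExpressionMatrix:
    """Read a raw count matrix: first column gene ids, remaining columns numeric.

    Raises :class:`FormatError` on duplicate gene ids and :class:`ValueError`
    naming the offending cell for non-numeric or negative entries.
    """
    path = Path(path)
    delim = delimiter or sniff_delimiter(path)
    df = pd.read_csv(
        path,
        sep=delim,
        header=0 if header else None,
        index_col=0,
        dtype=str,
    )
    gene_ids = [str(g) for g in df.index]
    if len(set(gene_ids)) != len(gene_ids):
        raise FormatError(
            f"duplicate gene id {_first_duplicate(gene_ids)!r} in {path}"
        )
    sample_ids = [str(c) for c in df.columns]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            gene = str(bad.index[0])
            raise ValueError(
                f"non-numeric value {bad.iloc[0]!r} at gene {gene!r}, "
                f"sample {sample_ids[j]!r} in {path}"
            ) from None
    if np.any(values < 0):
        g, s = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count {values[g, s]} at gene {gene_ids[g]!r}, "
            f"sample {sample_ids[s]!r} in {path}"
        )
    return ExpressionMatrix(gene_ids, sample_ids, values, scale=RAW)


def write_counts(X: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write a count matrix in the layout :func:`read_counts` expects."""
    df = pd.DataFrame(X.values, index=X.gene_ids, columns=X.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep=delimiter)


def read_design(path: str | Path, delimiter: str | None = None) -> StrainDesign:
    """Read a two-column sample_id / strain table into a :class:`StrainDesign`."""
    path = Path(path)
    delim = delimiter or sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim, header=None, dtype=str, comment="#")
    # tolerate an optional header line
    if df.shape[0] and df.iloc[0, 0].lower() in {"sample", "sample_id"}:
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise FormatError(f"design file {path} needs two columns (sample_id, strain)")
    assignment = {str(r[0]): str(r[1]) for r in df.itertuples(index=False)}
    if len(assignment) != df.shape[0]:
        raise DesignError(f"duplicate sample id in design file {path}")
    return StrainDesign(assignment)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a newline-delimited gene list; duplicates are dropped and logged."""
    path = Path(path)
    ids = [line.strip() for line in path.read_text().splitlines()]
    ids = [g for g in ids if g]
    unique = list(dict.fromkeys(ids))
    n_dup = len(ids) - len(unique)
    if n_dup:
        logger.info("gene list %s: dropped %d duplicate id(s)", path, n_dup)
    if not unique:
        logger.warning("gene list %s is empty", path)
    return GeneSet(name=name or path.stem, members=frozenset(unique))


def write_calls(calls, path: str | Path) -> None:
    """Write a :class:`~declust.pipeline.DifferentialCallSet` as TSV.

    Run parameters go first as ``#key=value`` comment lines; data rows are
    sorted by batch index, then by within-batch gene order, so repeated runs
    produce byte-identical files.
    """
    path = Path(path)
    lines: list[str] = []
    for key, value in calls.config_snapshot.items():
        lines.append(f"#{key}={value}")
    lines.append("gene_id\tbatch_index\tstage\tlabel")
    for call in sorted(calls.calls, key=lambda c: (c.batch_index, c.order_in_batch)):
        lines.append(f"{call.gene_id}\t{call.batch_index}\t{call.stage}\t{call.label}")
    path.write_text("\n".join(lines) + "\n")


def read_calls(path: str | Path):
    """Round-trip reader for :func:`write_calls` output."""
    from .pipeline import Call, DifferentialCallSet  # local import: avoid cycle

    path = Path(path)
    snapshot: dict[str, str] = {}
    calls: list[Call] = []
    order = 0
    last_batch = None
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            snapshot[key] = value
            continue
        if line.startswith("gene_id\t") or not line.strip():
            continue
        gene_id, batch_s, stage, label_s = line.split("\t")
        batch = int(batch_s)
        order = order + 1 if batch == last_batch else 0
        last_batch = batch
        calls.append(Call(gene_id, batch, stage, int(label_s), order))
    return DifferentialCallSet(calls=calls, config_snapshot=snapshot)
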