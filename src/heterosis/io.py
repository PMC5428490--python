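"""Readers, writers and validated containers for the external file formats.

The pipeline consumes four kinds of input:

* a gene-by-sample normalized expression matrix (TSV, first column ``gene_id``),
* a sample design table (TSV: ``sample_id, group, tissue, stage``) assigning each
  sample to one of the trio groups ``parentA`` / ``parentB`` / ``hybrid``,
* a pathway catalog in GMT (one gene set per line: name, description, members),
* promoter sequences in FASTA (record id up to the first whitespace is the gene id).

Expression units are taken as given (the pipeline never re-normalizes); gene
identifiers are opaque, case-sensitive strings. All TSV output uses UTF-8, tab
separators and "." decimals so re-runs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import DesignError, FormatError

logger = logging.getLogger(__name__)

GROUPS = ("parentA", "parentB", "hybrid")

PROMOTER_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class SampleDesign:
    """One row of the sample design table."""

    sample_id: str
    group: str
    tissue: str
    stage: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DesignError(
                f"sample {self.sample_id!r}: group {self.group!r} not one of {GROUPS}"
            )


@dataclass
class TrioExpressionSet:
    """Normalized expression for one tissue/stage trio of replicate groups.

    ``values`` is genes x samples, column order matching ``design``.
    """

    gene_ids: list[str]
    values: np.ndarray
    design: list[SampleDesign]
    tissue: str
    stage: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.design) != n_samples:
            raise FormatError(
                f"{len(self.design)} design rows for {n_samples} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene_id in expression matrix")
        ids = [d.sample_id for d in self.design]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate sample_id in design")
        if np.isnan(self.values).any():
            i, j = map(int, np.argwhere(np.isnan(self.values))[0])
            raise FormatError(
                f"non-numeric value at gene {self.gene_ids[i]!r}, sample {ids[j]!r}"
            )
        if (self.values < 0).any():
            i, j = map(int, np.argwhere(self.values < 0)[0])
            raise FormatError(
                f"negative value {self.values[i, j]} at gene "
                f"{self.gene_ids[i]!r}, sample {ids[j]!r}"
            )
        for group in GROUPS:
            if not any(d.group == group for d in self.design):
                raise DesignError(
                    f"no {group!r} sample for tissue={self.tissue!r} "
                    f"stage={self.stage!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [d.sample_id for d in self.design]

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices of the samples belonging to ``group``."""
        idx = [i for i, d in enumerate(self.design) if d.group == group]
        if not idx:
            raise DesignError(f"no samples in group {group!r}")
        return np.asarray(idx, dtype=int)

    def group_values(self, group: str) -> np.ndarray:
        """Genes x replicates sub-matrix for one trio group."""
        return self.values[:, self.group_columns(group)]

    def group_means(self, group: str) -> np.ndarray:
        return self.group_values(group).mean(axis=1)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class PathwayCatalog:
    """Named gene sets over a fixed gene universe."""

    pathways: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        clean: dict[str, frozenset[str]] = {}
        for name, members in self.pathways.items():
            members = frozenset(members)
            if not members:
                raise FormatError(f"pathway {name!r} is empty")
            stray = members - self.universe
            if stray:
                raise FormatError(
                    f"pathway {name!r} contains genes outside the universe: "
                    f"{sorted(stray)[:5]}"
                )
            clean[name] = members
        self.pathways = clean

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass
class PromoterSet:
    """Uppercase A/C/G/T/N promoter sequences keyed by gene id."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        for gene_id, seq in self.records.items():
            if not seq:
                raise FormatError(f"empty sequence for {gene_id!r}")
            bad = set(seq) - PROMOTER_ALPHABET
            if bad:
                pos = next(i for i, ch in enumerate(seq) if ch in bad)
                raise FormatError(
                    f"illegal character {seq[pos]!r} at position {pos} in "
                    f"promoter {gene_id!r}"
                )

    def __len__(self) -> int:
        return len(self.records)


def read_design(path: str | Path) -> list[SampleDesign]:
    """Read the sample design TSV (columns sample_id, group, tissue, stage)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "group", "tissue", "stage"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"design file {path} lacks columns {missing}")
    rows = [
        SampleDesign(r.sample_id, r.group, r.tissue, r.stage)
        for r in df.itertuples(index=False)
    ]
    ids = [r.sample_id for r in rows]
    if len(set(ids)) != len(ids):
        dup = next(s for s in ids if ids.count(s) > 1)
        raise DesignError(f"duplicate sample_id {dup!r} in design")
    return rows


def read_expression(
    matrix_path: str | Path,
    design_path: str | Path,
    tissue: str | None = None,
    stage: str | None = None,
) -> TrioExpressionSet:
    """Read an expression matrix TSV together with its sample design.

    When ``tissue``/``stage`` are given the design is filtered to that
    combination; otherwise the design must be homogeneous. Columns of the
    matrix are matched to design rows by sample id; design row order wins.
    """
    design = read_design(design_path)
    if tissue is not None:
        design = [d for d in design if d.tissue == tissue]
    if stage is not None:
        design = [d for d in design if d.stage == stage]
    if not design:
        raise DesignError(
            f"no design rows for tissue={tissue!r} stage={stage!r}"
        )
    tissues = {d.tissue for d in design}
    stages = {d.stage for d in design}
    if len(tissues) > 1 or len(stages) > 1:
        raise DesignError(
            "design covers multiple tissue/stage combinations "
            f"({sorted(tissues)} x {sorted(stages)}); pass tissue= and stage="
        )

    df = pd.read_csv(
        matrix_path, sep="\t", dtype={0: str}, float_precision="round_trip"
    )
    header = list(df.columns)
    gene_col = header[0]
    known = {d.sample_id for d in design}
    for col in header[1:]:
        if col not in known:
            raise FormatError(
                f"sample {col!r} in matrix header is absent from the design"
            )
    missing = known - set(header[1:])
    if missing:
        raise DesignError(
            f"design samples missing from matrix: {sorted(missing)}"
        )
    gene_ids = df[gene_col].tolist()
    ordered = [d.sample_id for d in design]
    block = df[ordered]
    numeric = block.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        i, j = map(int, np.argwhere(numeric.isna().to_numpy())[0])
        raise FormatError(
            f"non-numeric value {block.iat[i, j]!r} at gene "
            f"{gene_ids[i]!r}, sample {ordered[j]!r}"
        )
    return TrioExpressionSet(
        gene_ids=gene_ids,
        values=numeric.to_numpy(dtype=float),
        design=design,
        tissue=design[0].tissue,
        stage=design[0].stage,
    )


def write_expression(
    xs: TrioExpressionSet, matrix_path: str | Path, design_path: str | Path
) -> None:
    """Write the matrix and design back out in the dialect read_expression reads.

    Full-precision floats (repr round-trip) so write->read is the identity.
    """
    with open(matrix_path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(xs.sample_ids) + "\n")
        for gene, row in zip(xs.gene_ids, xs.values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    with open(design_path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\ttissue\tstage\n")
        for d in xs.design:
            fh.write(f"{d.sample_id}\t{d.group}\t{d.tissue}\t{d.stage}\n")


def read_gmt(path: str | Path, universe: Iterable[str]) -> PathwayCatalog:
    """Read a GMT pathway file, restricting members to ``universe``.

    Members outside the universe are dropped (count logged); pathways left
    empty after filtering are dropped with a warning.
    """
    universe = frozenset(universe)
    pathways: dict[str, frozenset[str]] = {}
    n_dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected name, description and at least one member"
                )
            name, _desc, *members = fields
            kept = frozenset(m for m in members if m in universe)
            n_dropped += len(set(members)) - len(kept)
            if not kept:
                logger.warning(
                    "pathway %r: no members in universe, dropped", name
                )
                continue
            pathways[name] = kept
    if n_dropped:
        logger.info("read_gmt: dropped %d members outside the universe", n_dropped)
    return PathwayCatalog(pathways=pathways, universe=universe)


def write_gmt(catalog: PathwayCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(catalog.pathways):
            members = "\t".join(sorted(catalog.pathways[name]))
            fh.write(f"{name}\tna\t{members}\n")


def read_fasta_promoters(path: str | Path) -> PromoterSet:
    """Read promoter FASTA; ids are taken up to the first whitespace."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if gene_id in records:
            raise FormatError(f"duplicate promoter record {gene_id!r}")
        records[gene_id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return PromoterSet(records=records)


def write_fasta_promoters(promoters: PromoterSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene_id, seq in promoters.records.items():
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fatty_acid_csv(path: str | Path) -> Mapping[str, float]:
    """Read a fatty-acid composition CSV (columns species, percent)."""
    df = pd.read_csv(path, dtype={"species": str})
    if not {"species", "percent"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns species, percent")
    return dict(zip(df["species"], df["percent"].astype(float)))
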