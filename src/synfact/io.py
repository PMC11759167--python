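"""Readers, writers and validation for counts, designs, phenotypes and gene sets.

All tabular formats are plain tab-delimited UTF-8 text with Unix newlines.
Counts are stored genes x samples with gene IDs in the first column and a
header row of sample IDs. Expression values are log2 CPM (counts per million
with a pseudocount), the substrate for every downstream model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ARM_LABELS = ("control", "uvssr", "ozone", "co")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with unique, ordered identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples), non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise FormatError(f"duplicate gene IDs: {sorted(dup_g)}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise FormatError(f"duplicate sample IDs: {sorted(dup_s)}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            g, s = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleDesign:
    """Per-sample binary exposure indicators and replicate labels.

    ``uv`` and ``ozone`` are 0/1; the four (uv, ozone) combinations are the
    four arms: control (0,0), UVSSR (1,0), ozone (0,1), co-exposure (1,1).
    """

    table: pd.DataFrame  # columns: sample_id, uv, ozone, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "uv", "ozone", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"design table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        if self.table["sample_id"].duplicated().any():
            dups = self.table["sample_id"][self.table["sample_id"].duplicated()]
            raise FormatError(f"duplicate sample IDs in design: {sorted(set(dups))}")
        for col in ("uv", "ozone"):
            vals = set(self.table[col].astype(int))
            if not vals <= {0, 1}:
                raise FormatError(f"design column {col!r} must be 0/1, got {vals}")
            self.table[col] = self.table[col].astype(int)
        arms = set(zip(self.table["uv"], self.table["ozone"]))
        if arms != {(0, 0), (1, 0), (0, 1), (1, 1)}:
            raise FormatError(f"design must contain all four arms, got {sorted(arms)}")
        sizes = self.table.groupby(["uv", "ozone"]).size()
        if (sizes < 2).any():
            raise FormatError("every arm needs at least 2 replicates")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def arm_mask(self, uv: int, ozone: int) -> np.ndarray:
        return ((self.table["uv"] == uv) & (self.table["ozone"] == ozone)).to_numpy()

    def arm_label(self) -> pd.Series:
        """Human-readable arm label per sample."""
        mapping = {(0, 0): "control", (1, 0): "uvssr", (0, 1): "ozone", (1, 1): "co"}
        return pd.Series(
            [mapping[(u, o)] for u, o in zip(self.table["uv"], self.table["ozone"])],
            index=self.table.index,
            name="arm",
        )


@dataclass
class ExpressionMatrix:
    """log2(CPM + pseudocount) expression values, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError("expression matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class PhenotypeTable:
    """Continuous phenotype replicates (e.g. CIELAB L* lightness) per arm."""

    table: pd.DataFrame  # columns: arm, replicate, value

    def __post_init__(self) -> None:
        required = {"arm", "replicate", "value"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"phenotype table missing columns: {sorted(missing)}")
        bad = set(self.table["arm"]) - set(ARM_LABELS)
        if bad:
            raise FormatError(f"unknown arm labels: {sorted(bad)}")
        sizes = self.table.groupby("arm").size()
        if (sizes < 2).any():
            raise FormatError("every arm needs at least 2 phenotype replicates")

    def arm_values(self, arm: str) -> np.ndarray:
        return self.table.loc[self.table["arm"] == arm, "value"].to_numpy(float)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        (dups if x in seen else seen).add(x)
    return dups


# ---------------------------------------------------------------------------
# readers / writers

def read_counts(path: str | Path) -> CountMatrix:
    """Read a tab-delimited gene x sample count matrix.

    First column holds gene IDs, the header row holds sample IDs, the body is
    non-negative integers. Row and column order are preserved. Malformed input
    (duplicate IDs, ragged rows, non-integer or negative entries) is rejected
    with positional context rather than coerced.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        gene_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(sample_ids) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, "
                    f"got {len(fields)}"
                )
            gene_ids.append(fields[0])
            try:
                rows.append([int(x) for x in fields[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer count: {exc}") from exc
    return CountMatrix(gene_ids, sample_ids, np.array(rows, dtype=np.int64))


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "replicate": str})
    return SampleDesign(df)


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_phenotype(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"arm": str, "replicate": str})
    return PhenotypeTable(df)


def write_phenotype(ph: PhenotypeTable, path: str | Path) -> None:
    ph.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format: name, description, members, tab-separated.

    Duplicate members within a line are deduplicated; duplicate set names and
    lines with fewer than three fields are errors.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {m for m in members if m}
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in gsc.sets.items():
            desc = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# normalization

def filter_low_expression(
    cm: CountMatrix, min_cpm: float = 1.0, min_samples: int = 3
) -> CountMatrix:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples.

    Gene order is preserved. The defaults (CPM 1 in at least one arm's worth
    of samples) follow common bulk RNA-seq practice.
    """
    if min_cpm < 0:
        raise ValueError("min_cpm must be >= 0")
    if not 0 <= min_samples <= cm.n_samples:
        raise ValueError("min_samples out of range")
    libsize = cm.counts.sum(axis=0).astype(float)
    if np.any(libsize == 0):
        bad = [cm.sample_ids[i] for i in np.flatnonzero(libsize == 0)]
        raise ValueError(f"samples with zero library size: {bad}")
    cpm = cm.counts / libsize * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return CountMatrix(
        [g for g, k in zip(cm.gene_ids, keep) if k],
        list(cm.sample_ids),
        cm.counts[keep],
    )


def log_cpm(cm: CountMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(count / library_size * 1e6 + pseudocount), library = column sum."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    libsize = cm.counts.sum(axis=0).astype(float)
    if np.any(libsize == 0):
        bad = [cm.sample_ids[i] for i in np.flatnonzero(libsize == 0)]
        raise ValueError(f"samples with zero library size: {bad}")
    values = np.log2(cm.counts / libsize * 1e6 + pseudocount)
    return ExpressionMatrix(list(cm.gene_ids), list(cm.sample_ids), values)
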