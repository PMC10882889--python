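"""Gene-by-sample expression matrices with a declared unit and sample metadata.

The container wraps a pandas DataFrame (genes as rows, samples as columns)
plus a sample-metadata table with ``condition``, ``patient_id`` and
``specimen_order`` columns. I/O covers plain TSV and GCT v1.2, including the
GTEx dialect whose second column is ``Description``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

__all__ = ["ExpressionMatrix", "concat_samples", "read_gct", "write_gct"]

VALID_UNITS = ("FPKM", "TPM", "counts")

_META_COLUMNS = ["condition", "patient_id", "specimen_order"]


@dataclass
class ExpressionMatrix:
    """Non-negative gene×sample abundances with a unit tag.

    ``values``: DataFrame indexed by gene id, columns are sample ids.
    ``sample_meta``: DataFrame indexed by sample id with columns
    ``condition``, ``patient_id``, ``specimen_order``; optional.
    """

    values: pd.DataFrame
    unit: str
    sample_meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.sample_meta is not None:
            missing = set(self.values.columns) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"samples missing from sample_meta: {sorted(missing)}")

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def condition_samples(self, condition: str) -> list:
        if self.sample_meta is None:
            raise ValueError("no sample metadata attached")
        mask = self.sample_meta["condition"] == condition
        samples = [s for s in self.samples if s in self.sample_meta.index[mask]]
        if not samples:
            raise KeyError(f"unknown condition {condition!r}")
        return samples

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    def meta_to_tsv(self, path) -> None:
        if self.sample_meta is None:
            raise ValueError("no sample metadata attached")
        self.sample_meta.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, unit: str, meta_path=None) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        meta = None
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values=values, unit=unit, sample_meta=meta)


def concat_samples(matrices) -> ExpressionMatrix:
    """Column-concatenate matrices sharing genes and unit (e.g. one per
    condition) into a single matrix with merged sample metadata."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("nothing to concatenate")
    units = {m.unit for m in matrices}
    if len(units) > 1:
        raise ValueError(f"mixed units: {sorted(units)}")
    first_genes = matrices[0].values.index
    for m in matrices[1:]:
        if not m.values.index.equals(first_genes):
            raise ValueError("matrices have different gene sets")
    values = pd.concat([m.values for m in matrices], axis=1)
    if values.columns.duplicated().any():
        raise ValueError("duplicate sample ids across matrices")
    metas = [m.sample_meta for m in matrices if m.sample_meta is not None]
    meta = pd.concat(metas) if len(metas) == len(matrices) else None
    return ExpressionMatrix(values=values, unit=units.pop(), sample_meta=meta)


def write_gct(expr: ExpressionMatrix, path, descriptions=None) -> None:
    """Write GCT v1.2: '#1.2' line, dims line, then Name/Description table."""
    df = expr.values
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        cols = "\t".join(str(c) for c in df.columns)
        fh.write(f"Name\tDescription\t{cols}\n")
        for gene, row in df.iterrows():
            desc = descriptions.get(gene, gene) if descriptions else gene
            vals = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{gene}\t{desc}\t{vals}\n")


def read_gct(path, unit: str, sample_meta: Optional[pd.DataFrame] = None) -> ExpressionMatrix:
    """Read GCT v1.2 (GTEx dialect: Name + Description columns)."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"not a GCT v1.2 file (header {version!r})")
        n_rows, n_cols = (int(x) for x in fh.readline().split()[:2])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"], errors="ignore")
    if df.shape != (n_rows, n_cols):
        raise ValueError(
            f"GCT dims line says {(n_rows, n_cols)}, table is {df.shape}"
        )
    df.index.name = "gene_id"
    return ExpressionMatrix(values=df, unit=unit, sample_meta=sample_meta)
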