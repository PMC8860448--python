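"""Tabular I/O: intensity matrices, sample annotations, and GMT gene sets.

All tables are UTF-8, tab-separated, single header row. Intensity tables
have the protein-group identifier in the first column, the mapped gene
symbol(s) in the second (semicolon-separated when a group maps to several
homologous genes), and one column per sample. Empty cells, ``NaN`` and the
literal token ``Filtered`` (the convention of library-free DIA search
output for sub-threshold quantifications) are all read as intensity 0,
meaning "not detected in this sample".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REGIONS = ("VM", "MFB", "STR", "STR_SYN")
CONDITIONS = ("APEX2", "CONTROL", "BULK")
PREPS = ("slice", "synaptosome", "bulk")

#: tokens that encode a missing quantification in an intensity table
_MISSING_TOKENS = {"", "nan", "NaN", "NA", "Filtered"}

ANNOTATION_COLUMNS = ["sample_id", "region", "condition", "replicate", "prep"]


@dataclass
class IntensityMatrix:
    """Protein groups x samples raw quantification intensities.

    Attributes
    ----------
    values : pandas.DataFrame
        Nonnegative intensities, index = protein-group ids, columns =
        sample ids. Exactly 0 means not detected.
    gene_symbols : pandas.Series
        One representative gene symbol per protein group (first listed
        entry of the group's mapping).
    gene_mapping : pandas.Series
        The full, possibly multi-gene mapping string per protein group.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series
    gene_mapping: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gene_mapping is None:
            self.gene_mapping = self.gene_symbols.copy()
        if (self.values.to_numpy() < 0).any():
            raise ValueError("intensity values must be nonnegative")
        if not self.values.index.is_unique:
            raise ValueError("protein-group identifiers must be unique")
        if not self.values.index.equals(self.gene_symbols.index):
            raise ValueError("gene_symbols index must match protein-group ids")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus an optional explicit background universe."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")


def resolve_gene_symbol(protein_group: str) -> str:
    """Reduce a (possibly multi-gene) protein-group mapping to one symbol.

    Protein groups mapped to several homologous genes are written as a
    semicolon-separated list; the first entry is the representative symbol
    used for all gene-level analyses.
    """
    first = protein_group.split(";")[0].strip()
    if not first:
        raise ValueError("protein group has no mapped gene symbol")
    return first


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table (TSV).

    Required columns: sample_id, region, condition, replicate, prep.
    """
    annot = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in annot.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    annot = annot[ANNOTATION_COLUMNS].copy()
    _validate_annotations(annot)
    annot["replicate"] = annot["replicate"].astype(int)
    return annot


def _validate_annotations(annot: pd.DataFrame) -> None:
    if annot["sample_id"].duplicated().any():
        dups = annot.loc[annot["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in annotations: {dups}")
    bad_region = set(annot["region"]) - set(REGIONS)
    if bad_region:
        raise ValueError(f"unknown regions: {sorted(bad_region)}")
    bad_cond = set(annot["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
    bad_prep = set(annot["prep"]) - set(PREPS)
    if bad_prep:
        raise ValueError(f"unknown preps: {sorted(bad_prep)}")
    if (annot["replicate"].astype(int) < 1).any():
        raise ValueError("replicate numbers must be positive integers")


def read_intensity_table(
    path: str | Path, annotation_path: str | Path
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Read a raw intensity table and bind its samples to annotations.

    Every sample column must have exactly one annotation row; matching is
    case-sensitive on sample_id. Missing cells map to intensity 0.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 3:
        raise ValueError("intensity table needs id, gene and >=1 sample column")
    id_col, gene_col = raw.columns[0], raw.columns[1]
    sample_cols = list(raw.columns[2:])

    values = raw[sample_cols].map(
        lambda s: 0.0 if s.strip() in _MISSING_TOKENS else float(s)
    )
    if (values.to_numpy() < 0).any():
        raise ValueError("negative intensity encountered")
    values.index = pd.Index(raw[id_col], name="protein_id")

    mapping = pd.Series(raw[gene_col].to_numpy(), index=values.index, name="genes")
    symbols = mapping.map(resolve_gene_symbol)

    annot = read_annotations(annotation_path)
    unannotated = [s for s in sample_cols if s not in set(annot["sample_id"])]
    if unannotated:
        raise ValueError(f"sample columns without annotation: {unannotated}")
    annot = annot[annot["sample_id"].isin(sample_cols)].reset_index(drop=True)

    matrix = IntensityMatrix(values=values, gene_symbols=symbols, gene_mapping=mapping)
    return matrix, annot


def write_intensity_table(matrix: IntensityMatrix, path: str | Path) -> None:
    """Write an intensity matrix in the format ``read_intensity_table`` reads."""
    out = matrix.values.copy()
    out.insert(0, "genes", matrix.gene_mapping)
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")


def write_annotations(annot: pd.DataFrame, path: str | Path) -> None:
    annot[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB gene1 TAB gene2 ...``.

    Duplicate genes within a set collapse (set semantics); a duplicated set
    name or a line with fewer than three fields is an error.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"GMT line {lineno}: set {name!r} has no genes")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def samples_matching(annot: pd.DataFrame, **criteria: str) -> list[str]:
    """Sample ids whose annotation matches all given field=value criteria.

    >>> samples_matching(annot, region="VM", condition="APEX2")
    """
    mask = np.ones(len(annot), dtype=bool)
    for key, value in criteria.items():
        if key not in annot.columns:
            raise KeyError(f"unknown annotation field {key!r}")
        mask &= (annot[key] == value).to_numpy()
    return annot.loc[mask, "sample_id"].tolist()
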