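"""Read protein-signature annotation output and build binary feature matrices.

The genotype representation used throughout the package is a strains ×
protein-families table of presence/absence indicators: a genome either has
at least one significant hit against a Pfam family (1) or it does not (0).
Hit multiplicity is deliberately discarded — gene dosage is not part of the
representation.

Annotation input follows the InterProScan 5 tab-separated layout (one row
per signature match). Only rows from the configured analysis (``Pfam`` by
default) that pass the e-value cutoff (``1e-20`` by default) contribute to
the matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Default e-value cutoff for retaining a Pfam hit.
DEFAULT_EVALUE_MAX = 1e-20

#: Column positions in the official InterProScan 5 TSV layout.
#: The file has 11 mandatory columns; 4 more appear when InterPro/GO/pathway
#: lookup is enabled, which does not move the positions used here.
IPS_COLUMNS = {"analysis": 3, "signature_accession": 4, "e_value": 8}

_IPS_MIN_COLUMNS = 11


@dataclass(frozen=True)
class AnnotationHit:
    """One retained protein-signature match.

    Parameters
    ----------
    genome_id : str
        Identifier of the genome/strain the protein belongs to.
    analysis : str
        Name of the member-database analysis (e.g. ``"Pfam"``).
    signature_accession : str
        Accession of the matched signature (e.g. ``"PF00115"``).
    e_value : float
        Match e-value; must be non-negative.
    """

    genome_id: str
    analysis: str
    signature_accession: str
    e_value: float

    def __post_init__(self) -> None:
        if not self.signature_accession:
            raise ValidationError("signature_accession must be non-empty")
        if not self.e_value >= 0:
            raise ValidationError(
                f"e_value must be non-negative, got {self.e_value!r}"
            )


class FeatureMatrix:
    """Binary strains × protein-family table.

    Wraps a :class:`pandas.DataFrame` whose index holds unique strain ids,
    whose columns hold unique family accessions, and whose cells are 0/1.
    """

    def __init__(self, data: pd.DataFrame, *, validate: bool = True):
        if validate:
            _validate_binary_frame(data)
        self._data = data.astype(np.int8, copy=True)

    # -- basic accessors -------------------------------------------------
    @property
    def strain_ids(self) -> list[str]:
        return [str(s) for s in self._data.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(c) for c in self._data.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying DataFrame (a defensive copy)."""
        return self._data.copy()

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def density(self) -> float:
        """Fraction of cells equal to 1 (0.0 for an empty matrix)."""
        n = self._data.size
        return float(self._data.to_numpy().sum() / n) if n else 0.0

    # -- operations ------------------------------------------------------
    def subset(
        self,
        strains: Sequence[str] | None = None,
        features: Sequence[str] | None = None,
    ) -> "FeatureMatrix":
        """Return a sub-matrix restricted to the given strains/features.

        Raises :class:`KeyError` naming the first missing id.
        """
        data = self._data
        if strains is not None:
            missing = [s for s in strains if s not in data.index]
            if missing:
                raise KeyError(f"strains not in matrix: {missing[:5]}")
            data = data.loc[list(strains)]
        if features is not None:
            missing = [f for f in features if f not in data.columns]
            if missing:
                raise KeyError(f"features not in matrix: {missing[:5]}")
            data = data[list(features)]
        return FeatureMatrix(data, validate=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return self._data.equals(other._data) and list(self._data.index) == list(
            other._data.index
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FeatureMatrix({self.shape[0]} strains × {self.shape[1]} features)"


def _validate_binary_frame(data: pd.DataFrame) -> None:
    if data.index.has_duplicates:
        dups = data.index[data.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate strain ids: {dups[:5]}")
    if data.columns.has_duplicates:
        dups = data.columns[data.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature ids: {dups[:5]}")
    if data.size:
        arr = data.to_numpy()
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary cell at strain {data.index[i]!r}, "
                f"feature {data.columns[j]!r}: {arr[i, j]!r}"
            )


def read_interproscan_tsv(
    path: str | Path,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    analysis_name: str = "Pfam",
    genome_id: str | None = None,
    column_indices: Mapping[str, int] | None = None,
) -> list[AnnotationHit]:
    """Read one InterProScan 5 TSV file and return the retained hits.

    Parameters
    ----------
    path : path
        Tab-separated annotation file, one signature match per line.
    evalue_max : float
        Retain only hits with e-value at or below this cutoff.
    analysis_name : str
        Retain only hits from this member-database analysis.
    genome_id : str, optional
        Genome identifier for all hits in the file; defaults to the file
        basename without extension.
    column_indices : mapping, optional
        Override the positions of the ``analysis``, ``signature_accession``
        and ``e_value`` columns (for non-standard dialects).

    Returns
    -------
    list of AnnotationHit
        Hits passing both the analysis and the e-value filter. Rows whose
        e-value field is non-numeric (InterProScan writes ``"-"`` for
        analyses without scores) are skipped with a logged warning.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ParseError
        If a line has fewer columns than the layout requires; the message
        names the line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    cols = dict(IPS_COLUMNS)
    if column_indices:
        cols.update(column_indices)
    needed = max(cols.values()) + 1
    min_columns = max(_IPS_MIN_COLUMNS, needed)
    gid = genome_id if genome_id is not None else path.name.split(".")[0]

    hits: list[AnnotationHit] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < min_columns:
                raise ParseError(
                    f"{path}, line {lineno}: expected at least {min_columns} "
                    f"columns, found {len(fields)}"
                )
            if fields[cols["analysis"]] != analysis_name:
                continue
            raw_e = fields[cols["e_value"]]
            try:
                e_value = float(raw_e)
            except ValueError:
                logger.warning(
                    "%s, line %d: non-numeric e-value %r, row skipped",
                    path, lineno, raw_e,
                )
                continue
            if e_value > evalue_max:
                continue
            hits.append(
                AnnotationHit(
                    genome_id=gid,
                    analysis=analysis_name,
                    signature_accession=fields[cols["signature_accession"]],
                    e_value=e_value,
                )
            )
    return hits


def build_feature_matrix(hits: Iterable[AnnotationHit]) -> FeatureMatrix:
    """Collapse annotation hits into a binary presence/absence matrix.

    One row per distinct genome (in order of first appearance), one column
    per distinct accession (lexicographic); a cell is 1 iff at least one hit
    exists for the pair. Duplicated hits have no effect.
    """
    pairs: set[tuple[str, str]] = set()
    genomes: list[str] = []
    seen: set[str] = set()
    accessions: set[str] = set()
    for hit in hits:
        if hit.genome_id not in seen:
            seen.add(hit.genome_id)
            genomes.append(hit.genome_id)
        accessions.add(hit.signature_accession)
        pairs.add((hit.genome_id, hit.signature_accession))
    if not genomes:
        raise ValidationError("cannot build a feature matrix from zero hits")
    features = sorted(accessions)
    col_pos = {f: j for j, f in enumerate(features)}
    row_pos = {g: i for i, g in enumerate(genomes)}
    arr = np.zeros((len(genomes), len(features)), dtype=np.int8)
    for g, a in pairs:
        arr[row_pos[g], col_pos[a]] = 1
    return FeatureMatrix(
        pd.DataFrame(arr, index=genomes, columns=features), validate=False
    )


def read_presence_table(path: str | Path) -> FeatureMatrix:
    """Read a TSV presence/absence table (first column = strain id).

    A gzip-compressed file (``.gz`` suffix) is accepted transparently.
    A header-only file yields a valid matrix with zero strains.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"presence table not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return FeatureMatrix(df)


def write_presence_table(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write ``matrix`` as a TSV presence table (round-trip stable)."""
    matrix.frame.to_csv(path, sep="\t", index_label="strain_id")
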