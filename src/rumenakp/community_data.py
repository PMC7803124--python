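"""Data model and I/O for OTU tables, taxonomy, sample metadata and distance matrices.

The central container is :class:`CommunityTable`, a samples x OTUs matrix of
nonnegative integer counts. Taxonomy is an OTU -> lineage map supporting
aggregation to any canonical rank; metadata carries the experimental
coordinates (vessel, condition, hours since start); distances are square
symmetric matrices exchanged in PHYLIP square format.

File dialects follow mothur conventions: the ``.shared`` table (columns
``label``, ``Group``, ``numOtus``, then one column per OTU), two-column
taxonomy TSV with semicolon-delimited lineages and optional bootstrap
confidence suffixes ``(NN)``, and square-matrix distance files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical taxonomic ranks, coarsest to finest.
CANONICAL_RANKS: tuple[str, ...] = (
    "kingdom", "phylum", "class", "order", "family", "genus",
)

#: OTU-definition label accepted in ``.shared`` files (97% identity clustering).
SHARED_LABEL = "0.03"


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} must be unique")


@dataclass
class CommunityTable:
    """Samples x OTUs matrix of nonnegative integer counts.

    Parameters
    ----------
    sample_ids, otu_ids:
        Opaque unique identifiers for rows and columns.
    counts:
        Integer matrix of shape ``(n_samples, n_otus)``; every retained
        sample must have a positive library size.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integral")
            counts = np.round(counts).astype(np.int64)
        counts = counts.astype(np.int64, copy=False)
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if (counts.sum(axis=1) == 0).any():
            raise ValueError("every sample must have a positive library size")
        _check_unique(self.sample_ids, "sample_ids")
        _check_unique(self.otu_ids, "otu_ids")
        self.counts = counts

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample total counts N."""
        return self.counts.sum(axis=1)

    def relative_abundances(self) -> np.ndarray:
        """Row-normalised proportions p_ik = x_ik / N_i."""
        return self.counts / self.library_sizes[:, None]

    def select_samples(self, sample_ids: Sequence[str]) -> "CommunityTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CommunityTable(list(sample_ids), list(self.otu_ids),
                              self.counts[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids,
                            columns=self.otu_ids)


@dataclass
class TaxonomyMap:
    """OTU -> ordered lineage, supporting aggregation to any canonical rank.

    Lineages are stored as tuples of ``(rank, name)`` in canonical order.
    Missing tail ranks are filled as ``unclassified_<nearest classified
    parent>`` so that aggregation at every rank is total.
    """

    lineages: dict[str, tuple[tuple[str, str], ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[tuple[str, str], ...]] = {}
        for otu, lineage in self.lineages.items():
            names = [name for _, name in lineage]
            ranks = [rank for rank, _ in lineage]
            if ranks != list(CANONICAL_RANKS[: len(ranks)]):
                raise ValueError(
                    f"lineage for {otu} has ranks {ranks}; expected a prefix "
                    f"of {list(CANONICAL_RANKS)}"
                )
            clean[str(otu)] = self._fill_tail(names)
        self.lineages = clean

    @staticmethod
    def _fill_tail(names: Sequence[str]) -> tuple[tuple[str, str], ...]:
        filled: list[str] = []
        for i, rank in enumerate(CANONICAL_RANKS):
            if i < len(names) and names[i] and not names[i].startswith("unclassified"):
                filled.append(names[i])
            else:
                parent = filled[-1] if filled else "root"
                base = parent.replace("unclassified_", "", 1) if parent.startswith(
                    "unclassified_") else parent
                filled.append(f"unclassified_{base}")
        return tuple(zip(CANONICAL_RANKS, filled))

    def name_at(self, otu_id: str, rank: str) -> str:
        if rank not in CANONICAL_RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        try:
            lineage = self.lineages[otu_id]
        except KeyError:
            raise KeyError(f"OTU {otu_id!r} has no taxonomy assignment") from None
        return dict(lineage)[rank]

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)


@dataclass
class SampleMetadata:
    """Per-sample experimental coordinates for the RUSITEC design.

    Columns: ``sample_id``, ``vessel``, ``condition`` (control/treatment),
    ``day`` (1-based), ``hours_post_feeding`` (4, 12 or 24) and ``time_h``
    = 24*(day-1) + hours_post_feeding.
    """

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "vessel", "condition", "day",
                "hours_post_feeding", "time_h")

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise ValueError(f"metadata missing columns {sorted(missing)}")
        bad = set(df["condition"]) - {"control", "treatment"}
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")
        expected = 24 * (df["day"].astype(int) - 1) + df["hours_post_feeding"].astype(float)
        if not np.allclose(df["time_h"].astype(float), expected):
            raise ValueError("time_h inconsistent with day and hours_post_feeding")
        if df.duplicated(subset=["vessel", "time_h"]).any():
            raise ValueError("(vessel, time_h) pairs must be unique")
        if (df.groupby("vessel")["condition"].nunique() > 1).any():
            raise ValueError("condition must be constant within a vessel")
        _check_unique(list(df["sample_id"]), "sample_id")
        self.frame = df.reset_index(drop=True)

    def condition_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in metadata")
        return str(row["condition"].iloc[0])

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with sample identifiers."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        _check_unique(self.ids, "ids")
        self.d = (d + d.T) / 2.0
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def between(self, id_a: str, id_b: str) -> float:
        return float(self.d[self.ids.index(id_a), self.ids.index(id_b)])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# mothur .shared dialect
# ---------------------------------------------------------------------------

def read_shared(path: str | Path) -> CommunityTable:
    """Read a mothur ``.shared`` OTU table.

    The file is tab-delimited with header ``label  Group  numOtus  <otu>...``;
    one row per sample (``Group``). A single clustering label is accepted.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["label", "Group", "numOtus"]:
            raise FormatError(
                f"{path}: expected header starting 'label\\tGroup\\tnumOtus', "
                f"got {header[:3]}"
            )
        otu_ids = header[3:]
        sample_ids: list[str] = []
        rows: list[list[int]] = []
        labels: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 + len(otu_ids):
                raise FormatError(
                    f"{path}:{lineno}: expected {3 + len(otu_ids)} fields, "
                    f"got {len(parts)}"
                )
            label, group, num_otus = parts[0], parts[1], parts[2]
            labels.add(label)
            if int(num_otus) != len(otu_ids):
                raise FormatError(
                    f"{path}:{lineno}: numOtus={num_otus} but file has "
                    f"{len(otu_ids)} OTU columns"
                )
            try:
                row = [int(v) for v in parts[3:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer count") from exc
            if any(v < 0 for v in row):
                raise ValueError(f"{path}:{lineno}: negative count")
            sample_ids.append(group)
            rows.append(row)
    if len(labels) > 1:
        raise FormatError(f"{path}: multiple OTU-definition labels {sorted(labels)}")
    return CommunityTable(sample_ids, otu_ids, np.array(rows, dtype=np.int64))


def write_shared(table: CommunityTable, path: str | Path,
                 label: str = SHARED_LABEL) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["label", "Group", "numOtus", *table.otu_ids]) + "\n")
        for sid, row in zip(table.sample_ids, table.counts):
            fields = [label, sid, str(table.n_otus), *map(str, row.tolist())]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# taxonomy, metadata, distance files
# ---------------------------------------------------------------------------

def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column TSV ``otu_id <tab> lineage``.

    Lineages are semicolon-delimited, optionally with bootstrap-confidence
    suffixes ``(NN)`` which are stripped. A ``k__``/``p__`` style prefix, if
    present, is removed. An optional header line ``OTU\\tTaxonomy`` is skipped.
    """
    path = Path(path)
    lineages: dict[str, tuple[tuple[str, str], ...]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if lineno == 1 and parts[0].lower() in {"otu", "otu_id"}:
                continue
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            otu, lineage_str = parts[0], parts[1]
            names = []
            for tok in lineage_str.strip().strip(";").split(";"):
                tok = tok.strip()
                if "(" in tok and tok.endswith(")"):
                    tok = tok[: tok.rindex("(")]
                if len(tok) > 3 and tok[1:3] == "__":
                    tok = tok[3:]
                names.append(tok)
            names = names[: len(CANONICAL_RANKS)]
            lineages[otu] = tuple(zip(CANONICAL_RANKS[: len(names)], names))
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("OTU\tTaxonomy\n")
        for otu, lineage in tax.lineages.items():
            fh.write(f"{otu}\t" + ";".join(name for _, name in lineage) + ";\n")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


def read_distance(path: str | Path) -> DistanceMatrix:
    """Read a PHYLIP square-format distance file (first line n, rows id + n reals)."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        try:
            n = int(first)
        except ValueError as exc:
            raise FormatError(f"{path}: first line must be the sample count") from exc
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != n + 1:
                raise FormatError(f"{path}:{lineno}: expected id + {n} values")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if len(ids) != n:
        raise FormatError(f"{path}: declared {n} rows, found {len(ids)}")
    return DistanceMatrix(ids, np.array(rows))


def write_distance(dm: DistanceMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{dm.n}\n")
        for sid, row in zip(dm.ids, dm.d):
            fh.write(sid + "\t" + "\t".join(f"{v:.10f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# table operations
# ---------------------------------------------------------------------------

def aggregate_to_rank(table: CommunityTable, tax: TaxonomyMap,
                      rank: str) -> CommunityTable:
    """Sum OTU counts into taxa at a canonical rank.

    Per-sample library sizes are conserved; output columns are the distinct
    taxon names at ``rank`` in first-appearance order.
    """
    if rank not in CANONICAL_RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {CANONICAL_RANKS}")
    names = [tax.name_at(otu, rank) for otu in table.otu_ids]
    taxa: list[str] = []
    index: dict[str, int] = {}
    for name in names:
        if name not in index:
            index[name] = len(taxa)
            taxa.append(name)
    out = np.zeros((table.n_samples, len(taxa)), dtype=np.int64)
    for j, name in enumerate(names):
        out[:, index[name]] += table.counts[:, j]
    return CommunityTable(list(table.sample_ids), taxa, out)


def rarefy(table: CommunityTable, depth: int, seed: int | np.random.Generator = 0,
           ) -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Subsampling is multivariate hypergeometric, so repeated draws have
    expectation ``depth * x_ik / N_i`` per OTU. Samples whose library size is
    below ``depth`` are dropped with a warning.
    """
    if depth <= 0:
        raise ValueError("rarefying depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = table.library_sizes >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        msg = (f"dropping {len(dropped)} sample(s) below rarefying depth "
               f"{depth}: {dropped}")
        logger.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    if not keep.any():
        raise ValueError("no sample reaches the rarefying depth")
    sample_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    rows = [
        rng.multivariate_hypergeometric(row, depth, method="marginals")
        for row in table.counts[keep]
    ]
    return CommunityTable(sample_ids, list(table.otu_ids),
                          np.array(rows, dtype=np.int64))


def filter_singletons(table: CommunityTable) -> CommunityTable:
    """Drop OTUs whose total count across all samples equals 1."""
    totals = table.counts.sum(axis=0)
    keep = totals != 1
    return CommunityTable(
        list(table.sample_ids),
        [o for o, k in zip(table.otu_ids, keep) if k],
        table.counts[:, keep],
    )
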