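"""Reading, writing and preprocessing of ASV count tables.

The analysis starts from an ASV (amplicon sequence variant) count table with
ASVs in rows and root samples in columns, plus sample metadata and a taxonomy
table carrying an ectomycorrhizal (EcM) guild flag per ASV.  Preprocessing
follows the usual amplicon hygiene rules: per-cell removal of presences
supported by fewer than ``min_count`` reads, removal of ASVs seen in a single
sample only, restriction to EcM taxa, and rarefaction (subsampling without
replacement) to a common depth.
"""

from __future__ import annotations

import json
import logging
import datetime
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AsvTable",
    "AsvTableError",
    "read_asv_table",
    "write_asv_table",
    "read_metadata",
    "read_taxonomy",
    "write_metadata",
    "write_taxonomy",
    "filter_low_counts",
    "filter_single_sample_asvs",
    "filter_ecm",
    "rarefy",
    "preprocess",
    "relative_abundance",
    "hellinger_transform",
]

METADATA_COLUMNS = ("sample_id", "host_species", "host_type", "stage", "replicate")
HOST_TYPES = ("conifer", "broadleaf")
STAGES = ("juvenile", "adult")


class AsvTableError(ValueError):
    """Raised for malformed ASV tables or violated invariants."""


@dataclass
class AsvTable:
    """Integer ASV-by-sample count matrix with row/column identifiers.

    Parameters
    ----------
    counts : ndarray of shape (n_asvs, n_samples)
        Non-negative integer read counts.
    asv_ids : list of str
        Unique ASV identifiers, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    """

    counts: np.ndarray
    asv_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise AsvTableError("counts must be a 2-D matrix (ASVs x samples)")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise AsvTableError("counts must be integers")
            counts = counts.astype(np.int64)
        self.counts = counts.astype(np.int64, copy=False)
        self.asv_ids = [str(a) for a in self.asv_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.asv_ids) != counts.shape[0]:
            raise AsvTableError(
                f"{len(self.asv_ids)} ASV ids for {counts.shape[0]} rows"
            )
        if len(self.sample_ids) != counts.shape[1]:
            raise AsvTableError(
                f"{len(self.sample_ids)} sample ids for {counts.shape[1]} columns"
            )
        if len(set(self.asv_ids)) != len(self.asv_ids):
            raise AsvTableError("duplicate ASV ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AsvTableError("duplicate sample ids")
        if counts.size and counts.min() < 0:
            raise AsvTableError("negative counts")

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def copy(self) -> "AsvTable":
        return AsvTable(self.counts.copy(), list(self.asv_ids), list(self.sample_ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.asv_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AsvTable":
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def select_asvs(self, mask_or_ids) -> "AsvTable":
        """Subset rows by boolean mask or explicit ASV-id list."""
        if isinstance(mask_or_ids, (list, tuple, set)):
            keep = [i for i, a in enumerate(self.asv_ids) if a in set(mask_or_ids)]
            mask = np.zeros(self.n_asvs, bool)
            mask[keep] = True
        else:
            mask = np.asarray(mask_or_ids, bool)
        return AsvTable(
            self.counts[mask],
            [a for a, m in zip(self.asv_ids, mask) if m],
            list(self.sample_ids),
        )

    def select_samples(self, sample_ids) -> "AsvTable":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise AsvTableError(f"unknown samples: {missing}")
        cols = [idx[s] for s in sample_ids]
        return AsvTable(self.counts[:, cols], list(self.asv_ids), list(sample_ids))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_asv_table(path, format: str | None = None) -> AsvTable:
    """Read an ASV table from TSV (ASVs in rows) or BIOM 2.1 (HDF5).

    ``format`` is inferred from the file suffix when not given
    (``.biom`` -> biom, otherwise tsv).
    """
    path = Path(path)
    if format is None:
        format = "biom" if path.suffix == ".biom" else "tsv"
    if format == "tsv":
        with open(path) as fh:  # pandas mangles duplicate headers silently
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            raise AsvTableError(f"duplicate sample columns in {path}")
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.has_duplicates:
            raise AsvTableError(f"duplicate ASV ids in {path}")
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise AsvTableError(f"non-numeric counts in {path}: {exc}") from None
        if np.isnan(values).any():
            raise AsvTableError(f"missing/non-numeric counts in {path}")
        if (values < 0).any():
            raise AsvTableError(f"negative counts in {path}")
        return AsvTable(values, list(df.index.astype(str)), list(df.columns.astype(str)))
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown format {format!r}")


def write_asv_table(table: AsvTable, path, format: str | None = None) -> None:
    """Write an ASV table as TSV or BIOM 2.1."""
    path = Path(path)
    if format is None:
        format = "biom" if path.suffix == ".biom" else "tsv"
    if format == "tsv":
        df = table.to_dataframe()
        df.index.name = "asv_id"
        df.to_csv(path, sep="\t")
    elif format == "biom":
        _write_biom(table, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_biom(path: Path) -> AsvTable:
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as h5:
        obs_ids = [x.decode() for x in h5["observation/ids"][:]]
        sample_ids = [x.decode() for x in h5["sample/ids"][:]]
        grp = h5["observation/matrix"]
        mat = csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(obs_ids), len(sample_ids)),
        )
    dense = np.asarray(mat.todense())
    return AsvTable(dense, obs_ids, sample_ids)


def _write_biom(table: AsvTable, path: Path) -> None:
    from scipy.sparse import csc_matrix, csr_matrix

    csr = csr_matrix(table.counts)
    csc = csc_matrix(table.counts)
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w") as h5:
        h5.attrs["id"] = "No Table ID"
        h5.attrs["type"] = "OTU table"
        h5.attrs["format-url"] = "http://biom-format.org"
        h5.attrs["format-version"] = (2, 1)
        h5.attrs["generated-by"] = "ecmassembly"
        h5.attrs["creation-date"] = datetime.datetime.now().isoformat()
        h5.attrs["shape"] = table.shape
        h5.attrs["nnz"] = csr.nnz
        h5.create_dataset("observation/ids", data=table.asv_ids, dtype=str_dt)
        h5.create_dataset("observation/matrix/data", data=csr.data.astype(float))
        h5.create_dataset("observation/matrix/indices", data=csr.indices)
        h5.create_dataset("observation/matrix/indptr", data=csr.indptr)
        h5.create_dataset("sample/ids", data=table.sample_ids, dtype=str_dt)
        # sample-major (CSC of the obs-major matrix) mirrors the BIOM layout
        h5.create_dataset("sample/matrix/data", data=csc.data.astype(float))
        h5.create_dataset("sample/matrix/indices", data=csc.indices)
        h5.create_dataset("sample/matrix/indptr", data=csc.indptr)
        for grp in ("observation", "sample"):
            h5.create_group(f"{grp}/metadata")
            h5.create_group(f"{grp}/group-metadata")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV; validates required columns and factor levels."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise AsvTableError(f"metadata missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise AsvTableError("duplicate sample_id rows in metadata")
    bad_type = set(df["host_type"]) - set(HOST_TYPES)
    if bad_type:
        raise AsvTableError(f"host_type must be one of {HOST_TYPES}, got {bad_type}")
    bad_stage = set(df["stage"]) - set(STAGES)
    if bad_stage:
        raise AsvTableError(f"stage must be one of {STAGES}, got {bad_stage}")
    return df.set_index("sample_id", drop=False)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> pd.DataFrame:
    """Read taxonomy TSV (asv_id, lineage, is_ecm; genus parsed if absent)."""
    df = pd.read_csv(path, sep="\t", dtype={"asv_id": str})
    for col in ("asv_id", "lineage", "is_ecm"):
        if col not in df.columns:
            raise AsvTableError(f"taxonomy missing column {col!r}")
    if df["asv_id"].duplicated().any():
        raise AsvTableError("duplicate asv_id rows in taxonomy")
    if df["is_ecm"].dtype == object:
        df["is_ecm"] = df["is_ecm"].map(
            {"True": True, "False": False, "true": True, "false": False,
             "yes": True, "no": False, True: True, False: False}
        )
    df["is_ecm"] = df["is_ecm"].astype(bool)
    if "genus" not in df.columns:
        df["genus"] = df["lineage"].map(_genus_from_lineage)
    return df.set_index("asv_id", drop=False)


def _genus_from_lineage(lineage: str) -> str:
    for rank in str(lineage).split(";"):
        rank = rank.strip()
        if rank.startswith("g__"):
            return rank[3:] or "unidentified"
    return "unidentified"


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_low_counts(table: AsvTable, min_count: int = 10) -> AsvTable:
    """Zero out cells with ``0 < count < min_count``; drop ASVs left empty.

    Per-cell zeroing removes presences supported by too few reads without
    discarding an ASV that is well supported elsewhere.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = table.counts.copy()
    counts[(counts > 0) & (counts < min_count)] = 0
    keep = counts.sum(axis=1) > 0
    return AsvTable(
        counts[keep],
        [a for a, m in zip(table.asv_ids, keep) if m],
        list(table.sample_ids),
    )


def filter_single_sample_asvs(table: AsvTable) -> AsvTable:
    """Drop ASVs detected (count > 0) in fewer than two samples."""
    keep = (table.counts > 0).sum(axis=1) >= 2
    return table.select_asvs(keep)


def filter_ecm(table: AsvTable, taxonomy: pd.DataFrame) -> AsvTable:
    """Retain ASVs flagged as ectomycorrhizal in the taxonomy table."""
    missing = [a for a in table.asv_ids if a not in taxonomy.index]
    if missing:
        raise AsvTableError(f"ASVs missing from taxonomy: {missing[:5]}")
    is_ecm = taxonomy.loc[table.asv_ids, "is_ecm"].to_numpy(bool)
    return table.select_asvs(is_ecm)


def rarefy(table: AsvTable, depth: int, seed: int) -> AsvTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped with a warning.  The
    draw is a multivariate hypergeometric per sample (equivalent to a random
    permutation of the sample's reads truncated at ``depth``), so a sample
    whose total equals ``depth`` is returned unchanged.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_sums()
    keep_cols = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep_cols) if not k]
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped,
        )
    out = np.zeros((table.n_asvs, int(keep_cols.sum())), dtype=np.int64)
    j_out = 0
    for j, keep in enumerate(keep_cols):
        if not keep:
            continue
        col = table.counts[:, j]
        out[:, j_out] = rng.multivariate_hypergeometric(col, depth)
        j_out += 1
    sub = AsvTable(
        out, list(table.asv_ids), [s for s, k in zip(table.sample_ids, keep_cols) if k]
    )
    nonzero = sub.counts.sum(axis=1) > 0
    return sub.select_asvs(nonzero)


def preprocess(
    table: AsvTable,
    taxonomy: pd.DataFrame | None = None,
    *,
    min_count: int = 10,
    drop_single_sample: bool = True,
    ecm_only: bool = True,
    depth: int | str | None = "min",
    seed: int = 0,
) -> tuple[AsvTable, dict]:
    """Run the standard filter chain and rarefaction; return table + provenance.

    Order: low-count cell zeroing -> single-sample ASV removal -> EcM guild
    filter -> rarefaction.  ``depth="min"`` rarefies to the smallest
    post-filter sample total; ``depth=None`` skips rarefaction.
    """
    prov: dict = {
        "min_count": min_count,
        "drop_single_sample": drop_single_sample,
        "ecm_only": bool(ecm_only and taxonomy is not None),
        "seed": seed,
        "input_shape": list(table.shape),
    }
    out = filter_low_counts(table, min_count=min_count)
    if drop_single_sample:
        out = filter_single_sample_asvs(out)
    if ecm_only and taxonomy is not None:
        out = filter_ecm(out, taxonomy)
    if depth is not None:
        totals = out.sample_sums()
        if len(totals) == 0 or totals.max() == 0:
            raise AsvTableError("no reads left after filtering; cannot rarefy")
        depth_val = int(totals.min()) if depth == "min" else int(depth)
        if depth_val > totals.max():
            raise AsvTableError(
                f"rarefaction depth {depth_val} exceeds every sample total "
                f"(max {int(totals.max())})"
            )
        before = set(out.sample_ids)
        out = rarefy(out, depth_val, seed)
        prov["depth"] = depth_val
        prov["dropped_samples"] = sorted(before - set(out.sample_ids))
    else:
        prov["depth"] = None
        prov["dropped_samples"] = []
    prov["output_shape"] = list(out.shape)
    prov["n_asvs_removed"] = table.n_asvs - out.n_asvs
    return out, prov


def write_provenance(prov: dict, path) -> None:
    Path(path).write_text(json.dumps(prov, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def relative_abundance(table: AsvTable) -> np.ndarray:
    """Per-sample proportions; columns sum to 1."""
    totals = table.sample_sums().astype(float)
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise AsvTableError(f"all-zero sample(s): {bad}")
    return table.counts / totals


def hellinger_transform(rel_abund: np.ndarray) -> np.ndarray:
    """Square root of relative abundances (variance-stabilizing)."""
    rel = np.asarray(rel_abund, float)
    if rel.size and rel.min() < 0:
        raise ValueError("relative abundances must be non-negative")
    return np.sqrt(rel)
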