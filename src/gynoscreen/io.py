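"""Reading and writing count matrices, sample metadata and transcript-gene maps.

The on-disk dialect is deliberately minimal and text-only:

* count matrix — TSV, first column ``transcript_id``, one column per sample,
  transcripts in rows (transcript-major RNA-seq convention);
* sample metadata — TSV with header ``sample_id, female_id, condition``
  where condition is ``control`` or ``gynogenetic``;
* gene map — headerless two-column TSV ``(transcript_id, gene_id)``.

Counts are expected to be non-negative integers ("estimated rounded effective
read counts"); non-integer values found at ingest are repaired by rounding
half-up, with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError

logger = logging.getLogger(__name__)

CONTROL = "control"
GYNOGENETIC = "gynogenetic"
CONDITIONS = (CONTROL, GYNOGENETIC)

__all__ = [
    "CONTROL",
    "GYNOGENETIC",
    "CONDITIONS",
    "CountMatrix",
    "GeneMap",
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_map",
    "write_gene_map",
]


@dataclass
class CountMatrix:
    """Raw transcript x sample read counts plus the sample design.

    Parameters
    ----------
    transcript_ids : sequence of str
        Unique row identifiers.
    sample_ids : sequence of str
        Unique column identifiers.
    counts : ndarray of int, shape (n_transcripts, n_samples)
        Non-negative integer counts.
    meta : DataFrame
        Indexed by sample_id with columns ``female_id`` and ``condition``;
        every (female_id, condition) pair occurs at most once.
    """

    transcript_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.transcript_ids = [str(t) for t in self.transcript_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.transcript_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.transcript_ids)} transcripts x {len(self.sample_ids)} samples"
            )
        if len(set(self.transcript_ids)) != len(self.transcript_ids):
            raise FormatError("duplicate transcript IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample IDs")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.floor(np.asarray(self.counts, dtype=float) + 0.5)
            if not np.allclose(rounded, self.counts):
                warnings.warn(
                    "non-integer counts rounded half-up at ingest", stacklevel=2
                )
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise FormatError("negative counts are not allowed")
        self._validate_meta()

    def _validate_meta(self) -> None:
        required = {"female_id", "condition"}
        if not required.issubset(self.meta.columns):
            raise FormatError(f"metadata must have columns {sorted(required)}")
        missing = set(self.sample_ids) - set(self.meta.index.astype(str))
        if missing:
            raise FormatError(f"samples absent from metadata: {sorted(missing)}")
        extra = set(self.meta.index.astype(str)) - set(self.sample_ids)
        if extra:
            raise FormatError(f"metadata lists samples absent from the matrix: {sorted(extra)}")
        bad = set(self.meta["condition"]) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        pairs = list(zip(self.meta["female_id"], self.meta["condition"]))
        if len(set(pairs)) != len(pairs):
            raise DesignError("duplicate (female_id, condition) pair in metadata")
        # keep metadata rows in sample order
        self.meta = self.meta.loc[self.sample_ids]

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def females(self) -> list[str]:
        """Female IDs in first-appearance order."""
        seen: dict[str, None] = {}
        for f in self.meta["female_id"]:
            seen.setdefault(str(f))
        return list(seen)

    def samples_for(self, condition: str) -> pd.DataFrame:
        """Metadata rows for one condition, ordered by :attr:`females`."""
        sub = self.meta[self.meta["condition"] == condition].copy()
        order = {f: i for i, f in enumerate(self.females)}
        return sub.iloc[np.argsort([order[str(f)] for f in sub["female_id"]], kind="stable")]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.transcript_ids, columns=self.sample_ids)


@dataclass
class GeneMap:
    """Many-to-one transcript -> gene mapping.

    Transcripts absent from the map are treated downstream as their own
    gene (self-mapped sentinel), which keeps gene tallies well defined
    without an annotation resource.
    """

    mapping: dict[str, str]

    def __len__(self) -> int:
        return len(self.mapping)

    def gene_for(self, transcript_id: str) -> str:
        return self.mapping.get(transcript_id, transcript_id)

    def genes(self, transcript_ids: Sequence[str]) -> list[str]:
        return [self.gene_for(t) for t in transcript_ids]

    @classmethod
    def empty(cls) -> "GeneMap":
        return cls({})

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "GeneMap":
        return cls(dict(mapping))


def read_count_matrix(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a count matrix TSV and its sample metadata TSV.

    Non-integer count values are rounded half-up with a warning; negative
    counts, samples missing from either file, and duplicated
    (female, condition) pairs raise.
    """
    path, meta_path = Path(path), Path(meta_path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed TSV
        raise FormatError(f"cannot parse count matrix {path}: {exc}") from exc
    if df.index.name != "transcript_id":
        raise FormatError(
            f"first column of {path} must be 'transcript_id', got {df.index.name!r}"
        )
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise FormatError(f"non-numeric count values in {path}")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    required = {"sample_id", "female_id", "condition"}
    if not required.issubset(meta.columns):
        raise FormatError(f"{meta_path} must have columns {sorted(required)}")
    if meta["sample_id"].duplicated().any():
        raise FormatError(f"duplicate sample_id in {meta_path}")
    meta = meta.set_index("sample_id")
    logger.info("read %d transcripts x %d samples from %s", *df.shape, path)
    return CountMatrix(
        transcript_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        counts=df.to_numpy(),
        meta=meta,
    )


def write_count_matrix(m: CountMatrix, path: str | Path, meta_path: str | Path) -> None:
    frame = m.to_frame()
    frame.index.name = "transcript_id"
    frame.to_csv(path, sep="\t")
    meta = m.meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")


def read_gene_map(path: str | Path) -> GeneMap:
    """Read a headerless two-column (transcript_id, gene_id) TSV.

    A transcript listed twice with conflicting genes is an error; an empty
    file yields an empty map (all transcripts self-map downstream).
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            tid, gid = parts
            if tid in mapping and mapping[tid] != gid:
                raise FormatError(
                    f"{path}:{lineno}: transcript {tid!r} mapped to both "
                    f"{mapping[tid]!r} and {gid!r}"
                )
            mapping[tid] = gid
    return GeneMap(mapping)


def write_gene_map(gm: GeneMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, gid in gm.mapping.items():
            fh.write(f"{tid}\t{gid}\n")
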