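"""Median-of-ratios library-size normalization and base means.

Raw library sizes differ between samples for purely technical reasons, so
counts are rescaled by per-sample *size factors* before any cross-sample
comparison.  The estimator is the median-of-ratios: each sample's factor is
the median, over a reference set of transcripts detected in every sample, of
the ratio between that sample's count and the transcript's geometric mean
across samples.  Geometric means are computed in log space and transcripts
with any zero count are excluded from the reference set.

The *base mean* of a transcript is the mean of its normalized counts over
all samples (both conditions pooled); ``base_mean > 1`` is the expression
filter used upstream of the correlation screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NormalizationError, UsageError
from .io import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "compute_size_factors",
    "normalize",
    "base_mean_filter",
]


@dataclass
class NormalizedMatrix:
    """Size-factor-normalized expression values.

    ``values[i, j] = counts[i, j] / size_factors[j]``;
    ``base_means[i]`` is the mean of ``values[i, :]`` over all samples.
    """

    transcript_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    size_factors: np.ndarray
    base_means: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.transcript_ids, columns=self.sample_ids)

    def write(self, matrix_path: str | Path, size_factor_path: str | Path | None = None,
              base_mean_path: str | Path | None = None) -> None:
        frame = self.to_frame()
        frame.index.name = "transcript_id"
        frame.to_csv(matrix_path, sep="\t")
        if size_factor_path is not None:
            pd.Series(self.size_factors, index=self.sample_ids, name="size_factor") \
                .rename_axis("sample_id").to_csv(size_factor_path, sep="\t")
        if base_mean_path is not None:
            pd.Series(self.base_means, index=self.transcript_ids, name="base_mean") \
                .rename_axis("transcript_id").to_csv(base_mean_path, sep="\t")


def compute_size_factors(m: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, one per sample.

    Raises :class:`NormalizationError` when no transcript is detected in all
    samples (empty reference set).
    """
    counts = m.counts if isinstance(m, CountMatrix) else np.asarray(m)
    if counts.ndim != 2 or counts.shape[0] == 0 or counts.shape[1] == 0:
        raise UsageError("count matrix must be 2-D and non-empty")
    reference = (counts > 0).all(axis=1)
    n_ref = int(reference.sum())
    if n_ref == 0:
        raise NormalizationError(
            "no transcript has positive counts in every sample "
            f"(0 of {counts.shape[0]} usable as reference)"
        )
    ref = counts[reference].astype(float)
    log_geomean = np.log(ref).mean(axis=1)
    # median over reference transcripts of count / geometric mean, per sample;
    # the median is taken on the ratio scale (midpoint of the central pair)
    ratios = np.exp(np.log(ref) - log_geomean[:, None])
    return np.median(ratios, axis=0)


def normalize(m: CountMatrix, size_factors: np.ndarray | None = None) -> NormalizedMatrix:
    """Divide each sample's counts by its size factor.

    When ``size_factors`` is omitted they are estimated from ``m``.
    Base means are computed over all samples, both conditions pooled.
    """
    if size_factors is None:
        size_factors = compute_size_factors(m)
    size_factors = np.asarray(size_factors, dtype=float)
    if size_factors.shape != (m.n_samples,):
        raise UsageError(
            f"expected {m.n_samples} size factors, got shape {size_factors.shape}"
        )
    if (size_factors <= 0).any():
        raise UsageError("size factors must be strictly positive")
    values = m.counts / size_factors[None, :]
    return NormalizedMatrix(
        transcript_ids=list(m.transcript_ids),
        sample_ids=list(m.sample_ids),
        values=values,
        size_factors=size_factors,
        base_means=values.mean(axis=1),
        meta=m.meta,
    )


def base_mean_filter(nm: NormalizedMatrix, threshold: float = 1.0) -> np.ndarray:
    """Indices of transcripts with base mean strictly greater than *threshold*."""
    if threshold < 0:
        raise UsageError("threshold must be >= 0")
    return np.flatnonzero(nm.base_means > threshold)
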