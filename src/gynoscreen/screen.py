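"""The transcript-survival correlation screen.

Each transcript's normalized expression across the four females is
correlated with the per-female gynogenesis efficiency (mean survival of the
gynogenetically activated eggs) twice: once over the non-activated control
samples and once over the gynogenetically activated samples.  The candidate
score is ``|r_control| + |r_gyno|``; a transcript is selected when its base
mean strictly exceeds 1 and its score strictly exceeds 1.99, i.e. when its
expression tracks the efficiency vector almost perfectly in *both* states
of the egg.  Selected transcripts are aggregated to distinct genes through
the transcript-gene map (unmapped transcripts count as their own gene).

The module exposes a statsmodels-style surface: build a
:class:`TranscriptSurvivalScreen` from a count matrix and a survival table,
call :meth:`~TranscriptSurvivalScreen.fit`, and work with the returned
:class:`ScreenResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DesignError, UsageError
from .io import CONTROL, GYNOGENETIC, CountMatrix, GeneMap, read_count_matrix, read_gene_map
from .normalization import NormalizedMatrix, normalize
from .survival import SurvivalTable, efficiency_vector, read_survival_table, survival_rates

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_r",
    "spearman_r",
    "run_screen",
    "gene_tally",
    "TranscriptSurvivalScreen",
    "ScreenResults",
]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN (not 0) when either input is constant.

    Requires n >= 3 aligned observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise UsageError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise UsageError("correlation needs at least 3 paired observations")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0.0:
        return float("nan")
    return float((xd * yd).sum() / denom)


def spearman_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank correlation: Pearson on midranks; NaN when either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise UsageError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise UsageError("correlation needs at least 3 paired observations")
    return pearson_r(scipy.stats.rankdata(x), scipy.stats.rankdata(y))


def _row_correlations(rows: np.ndarray, y: np.ndarray, method: str) -> np.ndarray:
    """Correlation of every matrix row with y; NaN rows where undefined."""
    if method == "spearman":
        rows = scipy.stats.rankdata(rows, axis=1)
        y = scipy.stats.rankdata(y)
    rows = rows - rows.mean(axis=1, keepdims=True)
    yd = y - y.mean()
    y_ss = float((yd * yd).sum())
    row_ss = (rows * rows).sum(axis=1)
    denom = np.sqrt(row_ss * y_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, rows @ yd / np.where(denom > 0, denom, 1.0), np.nan)
    if y_ss == 0:
        r[:] = np.nan
    return r


def _condition_columns(nm: NormalizedMatrix, condition: str,
                       females: Sequence[str]) -> list[int]:
    by_female: dict[str, int] = {}
    for j, sid in enumerate(nm.sample_ids):
        row = nm.meta.loc[sid]
        if row["condition"] == condition:
            by_female[str(row["female_id"])] = j
    missing = [f for f in females if f not in by_female]
    if missing:
        raise DesignError(f"females {missing} have no {condition} sample")
    return [by_female[f] for f in females]


def run_screen(nm: NormalizedMatrix,
               efficiency: pd.Series,
               gene_map: GeneMap | None = None,
               base_mean_threshold: float = 1.0,
               score_threshold: float = 1.99,
               method: str = "pearson",
               log2: bool = False) -> "ScreenResults":
    """Run the dual-condition correlation screen on a normalized matrix.

    ``efficiency`` is the per-female gynogenetic survival vector (percent),
    indexed by female ID.  Expression is used as normalized counts, or as
    ``log2(x + 1)`` when ``log2`` is set.  Both filter inequalities are
    strict.  Records are sorted by descending score, ties broken by
    transcript ID.
    """
    if method not in ("pearson", "spearman"):
        raise UsageError(f"unknown correlation method {method!r}")
    gene_map = gene_map or GeneMap.empty()
    females = [str(f) for f in efficiency.index]
    if len(females) < 3:
        raise UsageError("the screen needs at least 3 females")
    eff = efficiency.to_numpy(dtype=float)
    values = nm.values
    if log2:
        values = np.log2(values + 1.0)
    cols = {c: _condition_columns(nm, c, females) for c in (CONTROL, GYNOGENETIC)}
    r_control = _row_correlations(values[:, cols[CONTROL]], eff, method)
    r_gyno = _row_correlations(values[:, cols[GYNOGENETIC]], eff, method)

    defined = ~(np.isnan(r_control) | np.isnan(r_gyno))
    score = np.where(defined, np.abs(np.nan_to_num(r_control)) + np.abs(np.nan_to_num(r_gyno)), 0.0)
    passes = defined & (nm.base_means > base_mean_threshold) & (score > score_threshold)

    def _dir(rc: float, rg: float) -> str:
        if np.isnan(rc) or np.isnan(rg):
            return "na"
        return f"{'+' if rc >= 0 else '-'}/{'+' if rg >= 0 else '-'}"

    frame = pd.DataFrame({
        "transcript_id": nm.transcript_ids,
        "gene_id": gene_map.genes(nm.transcript_ids),
        "base_mean": nm.base_means,
        "r_control": r_control,
        "r_gyno": r_gyno,
        "score": score,
        "passes": passes,
        "direction": [_dir(rc, rg) for rc, rg in zip(r_control, r_gyno)],
    })
    frame = frame.sort_values(["score", "transcript_id"],
                              ascending=[False, True], kind="mergesort")
    frame = frame.reset_index(drop=True)
    if not passes.any():
        logger.info("no transcript passed the screen")
    return ScreenResults(
        candidates=frame,
        efficiency=efficiency.copy(),
        base_mean_threshold=base_mean_threshold,
        score_threshold=score_threshold,
        method=method,
        log2=log2,
        _normalized=nm,
    )


def gene_tally(result: "ScreenResults") -> tuple[int, int]:
    """(number of passing transcripts, number of distinct genes they map to)."""
    passing = result.candidates[result.candidates["passes"]]
    return len(passing), passing["gene_id"].nunique()


class TranscriptSurvivalScreen:
    """Model object tying a count matrix to gynogenetic survival.

    Parameters
    ----------
    counts : CountMatrix
        Raw counts with one sample per (female, condition).
    survival : SurvivalTable
        Replicate-level embryo counts per group.
    gene_map : GeneMap, optional
        Transcript-to-gene mapping for the gene tally.
    stage : {"eyed", "swimup"}
        Which survival checkpoint defines gynogenesis efficiency.

    ``fit()`` normalizes the counts (median-of-ratios), derives the
    efficiency vector, and runs the correlation screen, returning a
    :class:`ScreenResults`.
    """

    def __init__(self, counts: CountMatrix, survival: SurvivalTable,
                 gene_map: GeneMap | None = None, stage: str = "eyed") -> None:
        self.counts = counts
        self.survival = survival
        self.gene_map = gene_map or GeneMap.empty()
        self.stage = stage
        self.summary_table = survival_rates(survival)
        self.efficiency = efficiency_vector(self.summary_table, stage=stage,
                                            females=counts.females)

    @classmethod
    def from_files(cls, counts_path: str | Path, meta_path: str | Path,
                   survival_path: str | Path, gene_map_path: str | Path | None = None,
                   stage: str = "eyed") -> "TranscriptSurvivalScreen":
        counts = read_count_matrix(counts_path, meta_path)
        surv = read_survival_table(survival_path)
        gm = read_gene_map(gene_map_path) if gene_map_path else None
        return cls(counts, surv, gene_map=gm, stage=stage)

    def fit(self, method: str = "pearson", base_mean_threshold: float = 1.0,
            score_threshold: float = 1.99, log2: bool = False) -> "ScreenResults":
        nm = normalize(self.counts)
        res = run_screen(nm, self.efficiency, gene_map=self.gene_map,
                         base_mean_threshold=base_mean_threshold,
                         score_threshold=score_threshold,
                         method=method, log2=log2)
        res.model = self
        return res


@dataclass
class ScreenResults:
    """Outcome of the correlation screen.

    ``candidates`` holds one row per transcript (transcript_id, gene_id,
    base_mean, r_control, r_gyno, score, passes, direction), sorted by
    descending score.
    """

    candidates: pd.DataFrame
    efficiency: pd.Series
    base_mean_threshold: float
    score_threshold: float
    method: str
    log2: bool = False
    model: "TranscriptSurvivalScreen | None" = field(default=None, repr=False)
    _normalized: NormalizedMatrix | None = field(default=None, repr=False)

    @property
    def n_passing(self) -> int:
        return int(self.candidates["passes"].sum())

    @property
    def passing_ids(self) -> list[str]:
        return list(self.candidates.loc[self.candidates["passes"], "transcript_id"])

    def gene_tally(self) -> tuple[int, int]:
        return gene_tally(self)

    def structure(self, scaling: str = "unit_variance", linkage: str = "average",
                  n_components: int = 2):
        """Hierarchical clustering + PCA of the passing transcripts' expression."""
        from .structure import analyze_structure

        if self._normalized is None:
            raise UsageError("results carry no normalized matrix")
        if self.n_passing < 2:
            raise UsageError("structure analysis needs at least 2 passing transcripts")
        nm = self._normalized
        idx = [nm.transcript_ids.index(t) for t in self.passing_ids]
        values = nm.values[idx]
        if self.log2:
            values = np.log2(values + 1.0)
        return analyze_structure(values, [nm.transcript_ids[i] for i in idx],
                                 nm.sample_ids, scaling=scaling, linkage=linkage,
                                 n_components=n_components)

    def summary(self, top: int = 10) -> str:
        """Plain-text summary in the spirit of a regression results table."""
        n_t, n_g = self.gene_tally()
        eff = ", ".join(f"{f}={v:.1f}%" for f, v in self.efficiency.items())
        lines = [
            "Transcript-survival correlation screen",
            "=" * 62,
            f"Transcripts screened:      {len(self.candidates)}",
            f"Correlation method:        {self.method}"
            + (" (log2(x+1) expression)" if self.log2 else ""),
            f"Efficiency vector (%):     {eff}",
            f"Filters (strict):          base mean > {self.base_mean_threshold:g},"
            f" score > {self.score_threshold:g}",
            f"Passing transcripts:       {n_t}",
            f"Distinct genes:            {n_g}",
            "-" * 62,
        ]
        head = self.candidates.head(top)[
            ["transcript_id", "gene_id", "base_mean", "r_control", "r_gyno", "score", "passes"]
        ]
        lines.append(head.to_string(index=False,
                                    float_format=lambda v: f"{v:.4f}"))
        lines.append("=" * 62)
        return "\n".join(lines)

    def to_file(self, path: str | Path) -> None:
        out = self.candidates.copy()
        out["passes"] = out["passes"].map({True: "yes", False: "no"})
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")
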