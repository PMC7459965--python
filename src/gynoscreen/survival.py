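"""Survival rates, group summaries, and the gynogenesis-efficiency vector.

Embryo survival is scored twice per incubation replicate: at the eyed stage
(27 days post-fertilization) and at swim-up (57 dpf).  Each experimental
group (one female under one condition) is summarised as the arithmetic mean
and sample standard deviation of its replicate percentages.  The per-female
mean survival of the gynogenetically activated groups — the *efficiency
vector* — is the phenotype the correlation screen regresses expression
against.

Group differences are compared with the Kruskal-Wallis rank test
(tie-corrected H, chi-square approximation; an exact permutation p-value is
available for small pooled sizes).
"""

from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DataError, DesignError, FormatError, UsageError
from .io import CONDITIONS, GYNOGENETIC

__all__ = [
    "SurvivalTable",
    "SurvivalSummary",
    "read_survival_table",
    "survival_rates",
    "efficiency_vector",
    "kruskal_wallis",
]

STAGES = ("eyed", "swimup")


def _female_from_group(group_id: str) -> str:
    m = re.search(r"(\d+)$", group_id)
    if not m:
        raise FormatError(f"cannot derive a female ID from group {group_id!r}")
    return f"F{m.group(1)}"


@dataclass
class SurvivalTable:
    """Per-replicate embryo counts.

    ``records`` has columns group_id, condition, replicate, n_initial,
    n_eyed, n_swimup and (derived if absent) female_id, with the chain
    ``0 <= n_swimup <= n_eyed <= n_initial`` enforced per record.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["group_id", "condition", "replicate", "n_initial", "n_eyed", "n_swimup"]
        missing = set(required) - set(self.records.columns)
        if missing:
            raise FormatError(f"survival table missing columns {sorted(missing)}")
        rec = self.records.copy()
        for col in ("n_initial", "n_eyed", "n_swimup"):
            rec[col] = rec[col].astype(int)
        if "female_id" not in rec.columns:
            rec["female_id"] = [_female_from_group(str(g)) for g in rec["group_id"]]
        bad = set(rec["condition"]) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown conditions {sorted(bad)}")
        if (rec["n_initial"] <= 0).any():
            raise DataError("every replicate must start with n_initial > 0 eggs")
        chain = (rec["n_swimup"] >= 0) & (rec["n_swimup"] <= rec["n_eyed"]) & (
            rec["n_eyed"] <= rec["n_initial"])
        if not chain.all():
            raise DataError("counts must satisfy 0 <= n_swimup <= n_eyed <= n_initial")
        self.records = rec.reset_index(drop=True)

    def write(self, path: str | Path) -> None:
        cols = ["group_id", "condition", "female_id", "replicate",
                "n_initial", "n_eyed", "n_swimup"]
        self.records[cols].to_csv(path, sep="\t", index=False)


def read_survival_table(path: str | Path) -> SurvivalTable:
    """Read a replicate-level survival TSV (header: group_id, condition,
    replicate, n_initial, n_eyed, n_swimup [, female_id])."""
    df = pd.read_csv(path, sep="\t")
    return SurvivalTable(df)


@dataclass
class SurvivalSummary:
    """Mean +/- SD survival per group and stage, with replicate rates kept.

    ``groups`` is indexed by group_id with columns condition, female_id,
    n_replicates, eyed_mean, eyed_sd, swimup_mean, swimup_sd (percent);
    ``replicate_rates`` retains the per-replicate percentages.
    """

    groups: pd.DataFrame
    replicate_rates: pd.DataFrame = field(repr=False)

    def rates_for(self, group_id: str, stage: str) -> np.ndarray:
        sub = self.replicate_rates[self.replicate_rates["group_id"] == group_id]
        return sub[f"{stage}_rate"].to_numpy()

    def write(self, path: str | Path) -> None:
        out = self.groups.copy()
        for stage in STAGES:
            out[f"{stage}_mean_sd"] = [
                f"{m:.1f} ± {s:.2f}" for m, s in zip(out[f"{stage}_mean"], out[f"{stage}_sd"])
            ]
        out.rename_axis("group_id").to_csv(path, sep="\t")


def survival_rates(t: SurvivalTable) -> SurvivalSummary:
    """Per-group mean and sample SD of replicate survival percentages.

    Rates are ``100 * n_stage / n_initial``; the SD uses the n-1
    denominator; a single-replicate group reports SD 0 with a warning.
    """
    rec = t.records.copy()
    rec["eyed_rate"] = 100.0 * rec["n_eyed"] / rec["n_initial"]
    rec["swimup_rate"] = 100.0 * rec["n_swimup"] / rec["n_initial"]
    rows = []
    for gid, sub in rec.groupby("group_id", sort=False):
        if len(sub) == 1:
            warnings.warn(f"group {gid} has a single replicate; SD reported as 0")
        row = {
            "group_id": gid,
            "condition": sub["condition"].iloc[0],
            "female_id": sub["female_id"].iloc[0],
            "n_replicates": len(sub),
        }
        for stage in STAGES:
            rates = sub[f"{stage}_rate"].to_numpy()
            row[f"{stage}_mean"] = float(rates.mean())
            row[f"{stage}_sd"] = float(rates.std(ddof=1)) if len(rates) > 1 else 0.0
        rows.append(row)
    groups = pd.DataFrame(rows).set_index("group_id")
    keep = ["group_id", "condition", "female_id", "replicate", "eyed_rate", "swimup_rate"]
    return SurvivalSummary(groups=groups, replicate_rates=rec[keep])


def efficiency_vector(s: SurvivalSummary, stage: str = "eyed",
                      females: Sequence[str] | None = None) -> pd.Series:
    """Per-female mean gynogenetic survival (percent) at the chosen stage.

    ``females`` fixes the output order (it must match the expression-sample
    female order); by default females appear in summary order.
    """
    if stage not in STAGES:
        raise UsageError(f"stage must be one of {STAGES}")
    gyn = s.groups[s.groups["condition"] == GYNOGENETIC]
    vec = pd.Series(
        gyn[f"{stage}_mean"].to_numpy(),
        index=[str(f) for f in gyn["female_id"]],
        name=f"{stage}_efficiency",
    )
    if vec.index.duplicated().any():
        raise DesignError("more than one gynogenetic group per female")
    if females is not None:
        missing = set(map(str, females)) - set(vec.index)
        if missing:
            raise DesignError(f"no gynogenetic survival for females {sorted(missing)}")
        vec = vec.loc[list(map(str, females))]
    return vec


def _exact_kruskal_p(pooled: np.ndarray, sizes: Sequence[int], h_obs: float) -> float:
    """Exact permutation p-value: share of group relabelings with H >= h_obs."""
    n = len(pooled)
    idx = list(range(n))
    count = 0
    total = 0
    for assignment in _group_partitions(idx, list(sizes)):
        groups = [pooled[list(g)] for g in assignment]
        h, _ = _kruskal_h(groups)
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


def _group_partitions(idx: list[int], sizes: list[int]):
    if len(sizes) == 1:
        yield (tuple(idx),)
        return
    first, rest = sizes[0], sizes[1:]
    for combo in itertools.combinations(idx, first):
        remaining = [i for i in idx if i not in combo]
        for tail in _group_partitions(remaining, rest):
            yield (combo,) + tail


def _kruskal_h(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*groups)
    return float(h), float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]], exact: bool = False
                   ) -> tuple[float, float]:
    """Kruskal-Wallis H and p over >= 2 groups of observations.

    H is computed on midranks with the tie correction
    ``1 - sum(t^3 - t) / (N^3 - N)``; p comes from the chi-square
    approximation with k-1 degrees of freedom, or from exhaustive
    permutation when ``exact`` is set (pooled N <= 12 only).  When every
    observation is identical H is defined as 0 and p as 1.
    """
    if len(groups) < 2:
        raise UsageError("Kruskal-Wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise UsageError("every group needs at least one observation")
    n_total = sum(a.size for a in arrays)
    if n_total < 3:
        raise UsageError("need at least 3 observations in total")
    h, p = _kruskal_h(arrays)
    if exact:
        if n_total > 12:
            raise UsageError("exact permutation p only supported for N <= 12")
        if np.all(np.concatenate(arrays) == arrays[0][0]):
            return h, p
        p = _exact_kruskal_p(np.concatenate(arrays), [a.size for a in arrays], h)
    return h, min(p, 1.0) if not math.isnan(p) else p
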