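"""Synthetic egg-transcriptome and survival data with planted signal.

The generator emulates the structure the screen assumes: four females, each
contributing one non-activated (control) and one gynogenetically activated
egg sample; overdispersed transcript counts (negative binomial with
variance ``mu + phi * mu^2``) scaled by per-sample library-size factors;
and replicate survival counts drawn binomially around configured per-group
means.  A planted subset of transcripts has its log2 mean expression
shifted in proportion to each female's gynogenetic survival — in *both*
conditions, reflecting the divergence of the high-efficiency female in the
control as well as the activated eggs — and the identities and slopes of
those transcripts are returned as ground truth for recovery scoring.

All randomness flows from ``SimulationConfig.seed`` through named
substreams, so outputs are byte-identical across runs with the same
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .io import CONTROL, GYNOGENETIC, CountMatrix
from .survival import SurvivalTable

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_counts",
    "simulate_survival",
    "evaluate_recovery",
]


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic generator.

    Survival means (percent) default to the four observed gynogenetic
    groups at the eyed and swim-up checkpoints; controls sit near 94.5%
    (eyed) and 90.1% (swim-up).  ``effect_slope`` is the planted shift in
    log2 expression units per percentage point of survival; ``dispersion``
    is the negative-binomial overdispersion phi in ``var = mu + phi mu^2``
    (0 degenerates to Poisson).  ``up_fraction`` is the share of planted
    transcripts whose expression increases with survival; it defaults to 1
    (all up-regulated) because a linear correlation on the count scale is
    structurally insensitive to proportional down-regulation — a
    down-slope response saturates at zero for the high-survival female,
    which caps the noise-free candidate score below the selection
    threshold.  Lower it to explore that blind spot.
    """

    n_females: int = 4
    n_transcripts: int = 5000
    n_planted: int = 60
    effect_slope: float = 0.1
    dispersion: float = 0.1
    library_size_range: tuple[float, float] = (0.5, 2.0)
    baseline_mean_range: tuple[float, float] = (0.5, 500.0)
    planted_mean_range: tuple[float, float] = (10.0, 500.0)
    up_fraction: float = 1.0
    effect_slope_control: float | None = None  # None -> same slope in both conditions
    survival_means: tuple[float, ...] = (3.5, 57.2, 3.1, 6.2)
    survival_means_swimup: tuple[float, ...] = (0.8, 41.5, 1.0, 5.0)
    control_survival_mean: float = 94.5
    control_survival_mean_swimup: float = 90.1
    n_replicates_gyno: int = 3
    n_replicates_control: int = 2
    n_eggs_per_replicate: int = 327
    n_eggs_per_replicate_control: int = 120
    seed: int = 0

    def validate(self) -> None:
        if self.n_females < 3:
            raise UsageError("need at least 3 females for 4-point correlations")
        if not 0 <= self.n_planted <= self.n_transcripts:
            raise UsageError("n_planted must be in [0, n_transcripts]")
        if self.dispersion < 0:
            raise UsageError("dispersion must be >= 0")
        if len(self.survival_means) != self.n_females or \
                len(self.survival_means_swimup) != self.n_females:
            raise UsageError("survival means must list one value per female")
        for v in (*self.survival_means, *self.survival_means_swimup,
                  self.control_survival_mean, self.control_survival_mean_swimup):
            if not 0 <= v <= 100:
                raise UsageError("survival means must be percentages in [0, 100]")
        for lo, hi in (self.library_size_range, self.baseline_mean_range,
                       self.planted_mean_range):
            if not (0 < lo <= hi):
                raise UsageError("ranges must be positive with lo <= hi")
        if not 0 <= self.up_fraction <= 1:
            raise UsageError("up_fraction must be in [0, 1]")
        for c, s in ((self.n_replicates_gyno, "gyno"), (self.n_replicates_control, "control")):
            if c < 1:
                raise UsageError(f"need >= 1 {s} replicate")
        if min(self.n_eggs_per_replicate, self.n_eggs_per_replicate_control) < 1:
            raise UsageError("need >= 1 egg per replicate")

    def to_dict(self) -> dict:
        return asdict(self)

    def _streams(self) -> dict[str, np.random.Generator]:
        root = np.random.SeedSequence(self.seed)
        names = ("planting", "counts", "survival")
        return {n: np.random.default_rng(c)
                for n, c in zip(names, root.spawn(len(names)))}


@dataclass
class SyntheticTruth:
    """Ground truth of the planted association signal."""

    planted_ids: list[str]
    slopes: np.ndarray  # signed log2-per-% slope per planted transcript
    mean_expression: pd.DataFrame = field(repr=False)  # planted x female expected means
    library_factors: np.ndarray | None = None  # true per-sample library scale

    def __post_init__(self) -> None:
        if len(self.planted_ids) != len(self.slopes):
            raise UsageError("one slope per planted transcript required")

    def write(self, path) -> None:
        out = self.mean_expression.copy()
        out.insert(0, "slope", self.slopes)
        out.rename_axis("transcript_id").to_csv(path, sep="\t", float_format="%.6g")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with var = mu + phi mu^2 (Poisson when phi = 0)."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    size = 1.0 / phi
    # gamma-Poisson mixture keeps the parameterization explicit
    lam = rng.gamma(shape=size, scale=mean / size)
    return rng.poisson(lam)


def simulate_counts(cfg: SimulationConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a transcripts x samples count matrix plus its planted truth."""
    cfg.validate()
    streams = cfg._streams()
    rng_plant, rng_counts = streams["planting"], streams["counts"]

    n_t, n_f = cfg.n_transcripts, cfg.n_females
    females = [f"F{i + 1}" for i in range(n_f)]
    sample_ids = [f"Fc{i + 1}" for i in range(n_f)] + [f"Fg{i + 1}" for i in range(n_f)]
    conditions = [CONTROL] * n_f + [GYNOGENETIC] * n_f
    meta = pd.DataFrame(
        {"female_id": females * 2, "condition": conditions},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    width = len(str(n_t))
    transcript_ids = [f"t{i + 1:0{width}d}" for i in range(n_t)]

    lo, hi = cfg.baseline_mean_range
    baselines = np.exp(rng_plant.uniform(np.log(lo), np.log(hi), size=n_t))
    planted_idx = np.sort(rng_plant.choice(n_t, size=cfg.n_planted, replace=False))
    plo, phi_hi = cfg.planted_mean_range
    baselines[planted_idx] = np.exp(
        rng_plant.uniform(np.log(plo), np.log(phi_hi), size=cfg.n_planted))
    signs = np.where(rng_plant.random(cfg.n_planted) < cfg.up_fraction, 1.0, -1.0)
    slopes = signs * cfg.effect_slope
    slopes_control = signs * (cfg.effect_slope_control
                              if cfg.effect_slope_control is not None
                              else cfg.effect_slope)

    surv = np.asarray(cfg.survival_means, dtype=float)
    surv_dev = surv - surv.mean()

    # expected per-female means, per condition
    mean_by_cond = {}
    for cond, sl in ((CONTROL, slopes_control), (GYNOGENETIC, slopes)):
        mu = np.tile(baselines[:, None], (1, n_f)).astype(float)
        mu[planted_idx] = baselines[planted_idx, None] * 2.0 ** (sl[:, None] * surv_dev[None, :])
        mean_by_cond[cond] = mu

    lib_lo, lib_hi = cfg.library_size_range
    lib = np.exp(rng_counts.uniform(np.log(lib_lo), np.log(lib_hi), size=2 * n_f))

    counts = np.empty((n_t, 2 * n_f), dtype=np.int64)
    for j, (sid, cond) in enumerate(zip(sample_ids, conditions)):
        f = j % n_f
        mu_j = mean_by_cond[cond][:, f] * lib[j]
        counts[:, j] = _nb_draw(rng_counts, mu_j, cfg.dispersion)

    cm = CountMatrix(transcript_ids=transcript_ids, sample_ids=sample_ids,
                     counts=counts, meta=meta)
    truth = SyntheticTruth(
        planted_ids=[transcript_ids[i] for i in planted_idx],
        slopes=slopes,
        mean_expression=pd.DataFrame(
            mean_by_cond[GYNOGENETIC][planted_idx],
            index=[transcript_ids[i] for i in planted_idx],
            columns=females,
        ),
        library_factors=lib,
    )
    return cm, truth


def simulate_survival(cfg: SimulationConfig) -> SurvivalTable:
    """Two-stage binomial replicate survival counts matching the config means."""
    cfg.validate()
    rng = cfg._streams()["survival"]
    rows = []

    def add_group(gid: str, cond: str, female: str, n_reps: int, n_eggs: int,
                  eyed_pct: float, swim_pct: float) -> None:
        p_eyed = eyed_pct / 100.0
        p_cond = 0.0 if eyed_pct == 0 else min(swim_pct / eyed_pct, 1.0)
        for r in range(1, n_reps + 1):
            n_eyed = int(rng.binomial(n_eggs, p_eyed))
            n_swim = int(rng.binomial(n_eyed, p_cond)) if n_eyed else 0
            rows.append({
                "group_id": gid, "condition": cond, "female_id": female,
                "replicate": r, "n_initial": n_eggs,
                "n_eyed": n_eyed, "n_swimup": n_swim,
            })

    for i in range(cfg.n_females):
        add_group(f"Fc{i + 1}", CONTROL, f"F{i + 1}", cfg.n_replicates_control,
                  cfg.n_eggs_per_replicate_control,
                  cfg.control_survival_mean, cfg.control_survival_mean_swimup)
    for i in range(cfg.n_females):
        add_group(f"Fg{i + 1}", GYNOGENETIC, f"F{i + 1}", cfg.n_replicates_gyno,
                  cfg.n_eggs_per_replicate,
                  cfg.survival_means[i], cfg.survival_means_swimup[i])
    return SurvivalTable(pd.DataFrame(rows))


def evaluate_recovery(result, truth: SyntheticTruth) -> tuple[float, float]:
    """(precision, recall) of the screen's passing set against planted truth.

    ``result`` may be a :class:`~gynoscreen.screen.ScreenResults` or any
    sequence of passing transcript IDs.  Precision is NaN (undefined) for an
    empty passing set when transcripts were planted; it is 1.0 when the
    passing set is empty and nothing was planted.  Recall is the recovered
    fraction of planted transcripts.
    """
    passing_ids = result.passing_ids if hasattr(result, "passing_ids") else result
    passing = set(passing_ids)
    planted = set(truth.planted_ids)
    tp = len(passing & planted)
    if not passing:
        precision = 1.0 if not planted else float("nan")
    else:
        precision = tp / len(passing)
    recall = tp / len(planted) if planted else 1.0
    return precision, recall
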