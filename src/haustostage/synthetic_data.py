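"""Synthetic count matrices and Cq tables with planted ground truth.

The generator emulates the staged design the analysis assumes: four sample
types (niS, SWE, ATT, PEN) with three biological replicates each, NB-
distributed counts (variance = mu + phi*mu^2) over transcripts with lengths,
and Cq tables derived from expression through an amplification-efficiency
model with Gaussian cycle noise.

Three planted roles drive recovery tests:

* housekeepers — constant expected RPKM across all stages and, unlike every
  other transcript, neither extra biological (sample-to-sample log-normal)
  variability nor appreciable NB overdispersion (they draw near-Poisson
  counts with their own ``hk_dispersion``): stability is their defining
  property, and their replicate scatter then lands in the CV ~ 0.01 /
  MAD < 0.1 range observed for validated reference genes;
* markers — expected RPKM elevated by 2**marker_effect_log2fc in exactly one
  stage;
* noise — stage-constant expected RPKM spread over a wide log-normal range,
  with biological variability.

Expression levels are planted on the RPKM scale and converted to expected
counts via mu = rpkm * length_kb * library_millions, so constant-RPKM
housekeepers are constant after normalization rather than in raw counts.
One global seed drives a single generator for full reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    CQ_MAX,
    CountMatrix,
    CqTable,
    DataValidationError,
    ExpressionMatrix,
    SampleSheet,
    STAGES,
)

ROLE_HOUSEKEEPER = "housekeeper"
ROLE_NOISE = "noise"


def marker_role(stage: str) -> str:
    return f"marker:{stage}"


@dataclass
class SimulationConfig:
    n_transcripts: int = 1000
    n_housekeepers: int = 20
    n_markers_per_stage: dict[str, int] = field(
        default_factory=lambda: {s: 10 for s in STAGES}
    )
    baseline_log2_mean: float = 5.0  # log2 expected count at mean length/depth
    marker_effect_log2fc: float = 3.0
    nb_dispersion: float = 0.05  # phi in variance = mu + phi*mu^2
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    length_range_bp: tuple[int, int] = (500, 3000)
    replicates_per_stage: int = 3
    seed: int = 0
    # biological sample-to-sample variability (log2 sd) for non-housekeepers
    bio_sd_log2: float = 0.5
    # gene-level dispersion of planted housekeepers (near-Poisson: stability
    # is their defining property; cf. the transcriptome-wide nb_dispersion)
    hk_dispersion: float = 0.002
    # spread of stage-constant expression levels across transcripts (log2 sd)
    level_sd_log2: float = 1.5
    # qPCR model
    cq_intercept: float = 30.0
    cq_noise_sd: float = 0.2
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        n_planted = self.n_housekeepers + sum(self.n_markers_per_stage.values())
        if n_planted > self.n_transcripts:
            raise DataValidationError(
                f"{n_planted} planted roles exceed {self.n_transcripts} transcripts"
            )
        if self.marker_effect_log2fc < 0 or self.nb_dispersion < 0:
            raise DataValidationError("effect size and dispersion must be >= 0")
        if not (1 < self.efficiency <= 2):
            raise DataValidationError("amplification efficiency must lie in (1, 2]")
        for s in self.n_markers_per_stage:
            if s not in STAGES:
                raise DataValidationError(f"unknown stage in marker config: {s!r}")


def _sample_sheet(config: SimulationConfig, system: str = "host-free") -> SampleSheet:
    rows = [
        {
            "sample_id": f"{stage}_{rep}",
            "stage": stage,
            "replicate": rep,
            "system": system,
        }
        for stage in STAGES
        for rep in range(1, config.replicates_per_stage + 1)
    ]
    return SampleSheet(pd.DataFrame(rows))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, dict[str, str]]:
    """Draw a count matrix with planted roles; same seed, same output."""
    rng = np.random.default_rng(config.seed)
    sheet = _sample_sheet(config)
    n_t = config.n_transcripts
    transcript_ids = [f"T{i:05d}" for i in range(n_t)]

    roles: dict[str, str] = {}
    cursor = 0
    for _ in range(config.n_housekeepers):
        roles[transcript_ids[cursor]] = ROLE_HOUSEKEEPER
        cursor += 1
    for stage in STAGES:
        for _ in range(config.n_markers_per_stage.get(stage, 0)):
            roles[transcript_ids[cursor]] = marker_role(stage)
            cursor += 1
    for tid in transcript_ids[cursor:]:
        roles[tid] = ROLE_NOISE

    lengths = rng.integers(*config.length_range_bp, size=n_t, endpoint=True)
    libs = rng.integers(*config.library_size_range, size=len(sheet.sample_ids), endpoint=True)

    # planted expression on the RPKM scale; baseline_log2_mean is the log2
    # expected count of an average transcript in an average library
    mean_len_kb = np.mean(config.length_range_bp) / 1e3
    mean_lib_m = np.mean(config.library_size_range) / 1e6
    log2_rpkm0 = config.baseline_log2_mean - np.log2(mean_len_kb * mean_lib_m)

    log2_rpkm = np.empty((n_t, len(STAGES)))
    role_arr = np.array([roles[t] for t in transcript_ids])
    is_hk = role_arr == ROLE_HOUSEKEEPER
    is_noise = role_arr == ROLE_NOISE
    # housekeepers: high, stage-constant (>= the mean-log2RPKM selection floor)
    hk_levels = rng.uniform(5.5, 8.0, size=is_hk.sum())
    log2_rpkm[is_hk] = hk_levels[:, None]
    # noise: stage-constant, broad level distribution
    noise_levels = rng.normal(log2_rpkm0, config.level_sd_log2, size=is_noise.sum())
    log2_rpkm[is_noise] = noise_levels[:, None]
    # markers: moderate spread, boosted in their own stage
    for si, stage in enumerate(STAGES):
        sel = role_arr == marker_role(stage)
        base = rng.normal(log2_rpkm0, 0.5, size=sel.sum())
        log2_rpkm[sel] = base[:, None]
        log2_rpkm[sel, si] += config.marker_effect_log2fc

    stage_idx = np.array([STAGES.index(s) for s in sheet.stages.values])
    rpkm = 2.0 ** log2_rpkm[:, stage_idx]  # transcripts x samples

    bio = rng.normal(0.0, config.bio_sd_log2, size=rpkm.shape)
    bio[is_hk] = 0.0
    mu = (
        rpkm
        * (2.0**bio)
        * (lengths[:, None] / 1e3)
        * (libs[None, :] / 1e6)
    )
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    counts[is_hk] = _nb_draw(rng, mu[is_hk], config.hk_dispersion)

    cm = CountMatrix(
        counts=pd.DataFrame(
            counts.astype(np.int64), index=transcript_ids, columns=sheet.sample_ids
        ),
        lengths_bp=pd.Series(lengths.astype(int), index=transcript_ids),
        samples=sheet,
    )
    return cm, roles


def simulate_cq(expr: ExpressionMatrix, config: SimulationConfig) -> CqTable:
    """Invert the qPCR quantification model: Cq = intercept - expr/log2(E) + noise.

    ``expr`` must be on a log2 scale with finite values; two technical
    replicates are drawn per gene x sample cell.
    """
    if not expr.measure.startswith("log2"):
        raise DataValidationError("simulate_cq expects a log2-scale expression matrix")
    values = expr.values.values.astype(float)
    if not np.isfinite(values).all():
        raise DataValidationError("expression contains non-finite values")
    rng = np.random.default_rng(config.seed + 1)
    log2_eff = np.log2(config.efficiency)
    true_cq = config.cq_intercept - values / log2_eff
    cells: dict[tuple[str, str], list[float]] = {}
    for gi, gene in enumerate(expr.values.index):
        for si, sample in enumerate(expr.values.columns):
            reps = true_cq[gi, si] + rng.normal(0.0, config.cq_noise_sd, size=2)
            cells[(gene, sample)] = [float(np.clip(c, 1e-3, CQ_MAX)) for c in reps]
    return CqTable(cells)
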