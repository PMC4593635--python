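"""Size x connectance x replicate experiment orchestration.

Each scan cell (S, C, replicate) runs the full pipeline: generate a valid
niche web, assign trophic levels and bioenergetic parameters, integrate the
two-phase dynamics, run DEA on the post-transient trajectory, and compute
the predictor metrics on the surviving web.  Every realization gets its own
random stream spawned deterministically from the master seed and the cell
coordinates, so cells can run in any order with identical results.

The study's full design is 41 sizes (10..50) x 20 connectances
(0.10..0.48 step 0.02) x 250 replicates = 205,000 runs; scaled-down grids
are configured through :class:`ScanConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nichemodel import generate_web, WebGenerationError
from .trophic import parametrize, TrophicError
from .dynamics import run_protocol, EXTINCTION_THRESHOLD
from .environ import run_dea, DEFAULT_WINDOW
from .metrics import compute_metrics, METRIC_NAMES

__all__ = ["ScanConfig", "run_scan", "run_cell", "grid_summary", "DEFAULT_SIZES",
           "DEFAULT_CONNECTANCES"]

log = logging.getLogger(__name__)

DEFAULT_SIZES = tuple(range(10, 51))
DEFAULT_CONNECTANCES = tuple(np.round(np.arange(0.10, 0.4801, 0.02), 2))


@dataclass
class ScanConfig:
    """Scan design and dynamics settings (defaults = the study conditions)."""

    sizes: tuple = DEFAULT_SIZES
    connectances: tuple = DEFAULT_CONNECTANCES
    replicates: int = 250
    master_seed: int = 0
    duration_phase1: int = 1000
    duration_phase2: int = 1000
    dt: float = 0.01
    extinction_threshold: float = EXTINCTION_THRESHOLD
    window: int = DEFAULT_WINDOW
    producer_respiration: bool = True
    fi_definition: str = "ratio"

    @property
    def n_runs(self) -> int:
        return len(self.sizes) * len(self.connectances) * self.replicates


def _cell_rng(master_seed: int, s_idx: int, c_idx: int, rep: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(s_idx, c_idx, rep))
    return np.random.Generator(np.random.PCG64(ss))


def run_cell(config: ScanConfig, s_idx: int, c_idx: int, rep: int) -> dict:
    """Run one realization; returns a flat record dict."""
    S = int(config.sizes[s_idx])
    C = float(config.connectances[c_idx])
    rng = _cell_rng(config.master_seed, s_idx, c_idx, rep)
    record: dict = {
        "nominal_S": S, "nominal_C": C, "replicate": rep,
        "mean_FI": np.nan, "mean_FI_difference": np.nan,
        "valid": False, "valid_difference": False, "degenerate": False,
        "failed": False, "n_extinct": 0, "steady_state_gap": np.nan,
        "attempts": 0,
    }
    record.update({name: np.nan for name in METRIC_NAMES})
    try:
        web = generate_web(S, C, rng)
    except WebGenerationError:
        record["failed"] = True
        record["degenerate"] = True
        log.warning("web generation failed at S=%d C=%.2f rep=%d", S, C, rep)
        return record
    record["attempts"] = web.attempts
    try:
        pweb = parametrize(web)
    except TrophicError:
        # closed consumer cycle with no basal access: trophic levels (hence
        # body masses) are undefined, so the realization cannot be simulated
        record["failed"] = True
        record["degenerate"] = True
        log.info("trophic assignment failed at S=%d C=%.2f rep=%d", S, C, rep)
        return record
    sim = run_protocol(
        pweb, rng,
        duration_phase1=config.duration_phase1,
        duration_phase2=config.duration_phase2,
        dt=config.dt,
        extinction_threshold=config.extinction_threshold,
    )
    record["n_extinct"] = int(sim.extinct_ids.size)
    record["failed"] = sim.failed
    record["degenerate"] = sim.degenerate
    record["steady_state_gap"] = sim.steady_state_gap
    if sim.degenerate:
        return record
    dea = run_dea(
        sim, window=config.window,
        producer_respiration=config.producer_respiration,
        definition=config.fi_definition,
    )
    record["mean_FI"] = dea.mean_FI
    record["mean_FI_difference"] = dea.mean_FI_difference
    record["degenerate"] = dea.degenerate
    record["valid"] = dea.valid and not dea.degenerate
    record["valid_difference"] = dea.valid_difference and not dea.degenerate
    record.update(compute_metrics(sim.surviving_web))
    return record


def run_scan(config: ScanConfig, progress: bool = False) -> pd.DataFrame:
    """Run the full grid; one row per realization, flagged rows retained."""
    records = []
    total = config.n_runs
    done = 0
    for s_idx in range(len(config.sizes)):
        for c_idx in range(len(config.connectances)):
            for rep in range(config.replicates):
                records.append(run_cell(config, s_idx, c_idx, rep))
                done += 1
            if progress:
                log.info("scan progress: %d/%d runs", done, total)
    table = pd.DataFrame.from_records(records)
    n_invalid = int((~table["valid"]).sum())
    log.info("scan complete: %d runs, %d invalid/degenerate excluded from aggregates",
             len(table), n_invalid)
    return table


def grid_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(nominal S, nominal C) mean of web-level mean FI over valid runs."""
    valid = records[records["valid"]]
    out = (
        valid.groupby(["nominal_S", "nominal_C"])["mean_FI"]
        .agg(mean_FI="mean", n_valid="count")
        .reset_index()
    )
    # mark cells with no valid runs as missing
    all_cells = records[["nominal_S", "nominal_C"]].drop_duplicates()
    out = all_cells.merge(out, on=["nominal_S", "nominal_C"], how="left")
    return out.sort_values(["nominal_S", "nominal_C"]).reset_index(drop=True)
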