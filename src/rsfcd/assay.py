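"""Synthetic tethered-cell assay traces.

Emulates the flagellar-rotation measurement used to constrain the pathway
models: a surface-tethered cell's single flagellum rotates at 0-8 Hz, sampled
over ~600 s while the ligand steps from 0 to 100 uM at 245 s and back to 0
at 375 s.  The observation model is the noiseless simulated frequency plus
i.i.d. Gaussian noise, clipped to [0, f_max] (the physical ceiling of the
tethered flagellum).  Real traces additionally contain rotation-direction
switching and tracking artefacts, which are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathway import ChemotaxisModel, LigandProgram

__all__ = ["AssayConfig", "generate_trace", "noiseless_trace",
           "write_trace", "read_trace"]

TRACE_COLUMNS = ("t_s", "f_hz")


@dataclass
class AssayConfig:
    """Stimulus schedule, sampling and noise of one synthetic assay."""

    truth: ChemotaxisModel
    schedule: LigandProgram = field(default_factory=LigandProgram.tethered_assay_schedule)
    horizon: float = 600.0
    sample_rate: float = 1.0      # Hz
    noise_sd: float = 0.5         # Hz, additive Gaussian before clipping
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.truth.activity_form != "exact":
            raise ValueError(
                "assay schedules visit L = 0; the generating model must use "
                "the exact activity form")

    def sample_times(self) -> np.ndarray:
        dt = 1.0 / self.sample_rate
        return np.arange(dt, self.horizon + 0.5 * dt, dt)


def noiseless_trace(cfg: AssayConfig) -> pd.DataFrame:
    """Simulated flagellar frequency at the sample times, no noise."""
    t = cfg.sample_times()
    y0 = cfg.truth.steady_state(cfg.schedule.levels[0])
    traj = cfg.truth.simulate(cfg.schedule, t, y0)
    return pd.DataFrame({"t_s": traj.t, "f_hz": traj["f"]})


def generate_trace(cfg: AssayConfig) -> pd.DataFrame:
    """Noisy, clipped assay trace; reproducible for a fixed seed."""
    trace = noiseless_trace(cfg)
    rng = np.random.default_rng(cfg.seed)
    noisy = trace["f_hz"].to_numpy() + rng.normal(0.0, cfg.noise_sd, len(trace))
    trace["f_hz"] = np.clip(noisy, 0.0, cfg.truth.flagellar.f_max)
    return trace


def write_trace(trace: pd.DataFrame, path) -> None:
    missing = [c for c in TRACE_COLUMNS if c not in trace.columns]
    if missing:
        raise ValueError(f"trace is missing columns {missing}")
    trace.loc[:, TRACE_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_trace(path) -> pd.DataFrame:
    """Read and validate a (t_s, f_hz) CSV trace."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:  # pandas reports the offending line
        raise ValueError(f"malformed trace CSV {path}: {e}") from e
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV {path} is missing columns {missing}")
    df = df.loc[:, TRACE_COLUMNS].apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # header is line 1
        raise ValueError(f"trace CSV {path}: non-numeric or missing value at line {bad}")
    t = df["t_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 3
        raise ValueError(f"trace CSV {path}: times not strictly increasing at line {bad}")
    return df
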