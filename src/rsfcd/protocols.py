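"""Fold-change-detection (FCD) experiment protocols.

A system shows FCD when its transient output responses to two input programs
that are positive scalar multiples of each other — each run started from the
adapted state of its own background — are identical.  Under the log-regime
receptor activity this invariance is exact for all three pathway variants;
with the exact MWC activity it holds approximately while the sensed ligands
stay well inside (K_I, K_A), and fails outside that range.

The canonical discriminating stimulus pair is the step fall 1000 -> 200 uM
versus 500 -> 100 uM (a common fold change of 5 at a scale factor of 2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pathway import ChemotaxisModel, LigandProgram, Trajectory
from .receptors import ReceptorClusterParams, fcd_methylation_shift

__all__ = [
    "ScaledStepPair",
    "FCDVerdict",
    "CANONICAL_PAIR",
    "discrepancy",
    "run_scaled_pair",
    "equivariance_check",
    "fcd_range_scan",
    "robustness_sweep",
    "regime_violation_run",
    "mutant_fcd_suite",
    "set_model_param",
]

# tolerance classes: exact scale invariance under the log-regime activity
# versus approximate invariance deep inside the (K_I, K_A) window
TOL_EXACT = 1e-6
TOL_REGIME = 0.05


class ProtocolError(RuntimeError):
    pass


@dataclass(frozen=True)
class ScaledStepPair:
    """Two ligand steps that are scalar multiples of each other.

    Arm 1 steps L_pre_1 -> L_post_1 at ``step_time``; arm 2 likewise.  The
    pre- and post-level ratios must agree (common scale factor p), which is
    what makes the two programs fold-change equivalent.
    """

    L_pre_1: float
    L_post_1: float
    L_pre_2: float
    L_post_2: float
    step_time: float = 200.0

    def __post_init__(self) -> None:
        if min(self.L_pre_1, self.L_post_1, self.L_pre_2, self.L_post_2) <= 0:
            raise ValueError("all levels of a scaled pair must be > 0")
        p1 = self.L_pre_1 / self.L_pre_2
        p2 = self.L_post_1 / self.L_post_2
        if abs(p1 - p2) > 1e-9 * max(p1, p2):
            raise ValueError(
                f"pre and post scale factors differ ({p1} vs {p2}); "
                "the two steps are not scalings of each other")

    @property
    def p(self) -> float:
        return self.L_pre_1 / self.L_pre_2

    @property
    def fold(self) -> float:
        """Fold change of each arm's step (pre/post)."""
        return self.L_pre_1 / self.L_post_1

    def programs(self) -> tuple[LigandProgram, LigandProgram]:
        return (LigandProgram.step(self.step_time, self.L_pre_1, self.L_post_1),
                LigandProgram.step(self.step_time, self.L_pre_2, self.L_post_2))


CANONICAL_PAIR = ScaledStepPair(1000.0, 200.0, 500.0, 100.0)


@dataclass(frozen=True)
class FCDVerdict:
    """Outcome of one scaled-pair comparison on one observable channel."""

    discrepancy: float
    tol: float
    is_fcd: bool
    observable: str

    @classmethod
    def from_discrepancy(cls, d: float, tol: float, observable: str) -> "FCDVerdict":
        return cls(discrepancy=float(d), tol=float(tol),
                   is_fcd=bool(d <= tol), observable=observable)


def discrepancy(y1: np.ndarray, y2: np.ndarray) -> float:
    """Sup-norm difference normalized by the peak-to-peak range of y1.

    Returns 0 for two identical flat traces (0/0 guarded).
    """
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    num = float(np.max(np.abs(y1 - y2)))
    den = float(np.ptp(y1))
    if den == 0.0:
        return 0.0 if num == 0.0 else np.inf
    return num / den


def _default_tol(model: ChemotaxisModel) -> float:
    return TOL_EXACT if model.activity_form == "log" else TOL_REGIME


def _default_observable(model: ChemotaxisModel) -> str:
    # model III reports the (normalized) CheY6-P channel; I/II the flagellar
    # frequency, matching the observables the models were built to explain
    return "Y6p" if model.variant.id == "III" else "f"


def run_scaled_pair(model: ChemotaxisModel, pair: ScaledStepPair = CANONICAL_PAIR,
                    observable: str | None = None, tol: float | None = None,
                    horizon: float = 600.0, n_points: int = 1201,
                    ) -> tuple[Trajectory, Trajectory, FCDVerdict]:
    """Simulate both arms of a scaled step pair and judge FCD on one channel.

    Each arm starts from the adapted steady state of its own background
    level; both are evaluated on a common time grid.
    """
    if observable is None:
        observable = _default_observable(model)
    if tol is None:
        tol = _default_tol(model)
    prog1, prog2 = pair.programs()
    t_grid = np.linspace(0.0, horizon, n_points)
    trajs = []
    for prog in (prog1, prog2):
        y0 = model.steady_state(prog.levels[0])
        trajs.append(model.simulate(prog, t_grid, y0))
    d = discrepancy(trajs[0][observable], trajs[1][observable])
    return trajs[0], trajs[1], FCDVerdict.from_discrepancy(d, tol, observable)


_EQUIV_CHANNELS = ("a", "a_t", "A2p", "A34p", "Y3p", "Y4p", "Y6p", "B1p", "B2p")


def equivariance_check(model: ChemotaxisModel, program: LigandProgram,
                       p: float, horizon: float = 600.0,
                       n_points: int = 1201) -> float:
    """Numerically verify the scaling symmetry that underlies FCD.

    Simulates p*L(t) from the adapted state of L(0) with the methylation
    coordinates shifted by ln(p)/alpha (and, for the lag variant, the
    internal-ligand state scaled by p) and returns the absolute sup-norm
    difference of all activity and phospho channels against the unscaled
    run.  Exact only under the log-regime activity.
    """
    if model.activity_form != "log":
        raise ProtocolError(
            "equivariance is exact only under the log-regime activity; "
            "configure the model with activity_form='log'")
    if p <= 0:
        raise ProtocolError("scale factor must be > 0")
    t_grid = np.linspace(0.0, horizon, n_points)
    y0 = model.steady_state(program.levels[0])
    base = model.simulate(program, t_grid, y0)

    y0_shift = y0.copy()
    y0_shift[0] += fcd_methylation_shift(p, model.membrane.alpha)
    y0_shift[1] += fcd_methylation_shift(p, model.cytoplasmic.alpha)
    if model.has_Lt_state:
        y0_shift[2] *= p
    scaled = model.simulate(program.scaled(p), t_grid, y0_shift)

    return max(float(np.max(np.abs(base[c] - scaled[c]))) for c in _EQUIV_CHANNELS)


def fcd_range_scan(model: ChemotaxisModel, fold: float = 5.0,
                   backgrounds=(10.0, 50.0, 100.0, 500.0, 1000.0),
                   tol: float = TOL_REGIME, arm_scale: float = 2.0,
                   observable: str | None = None,
                   horizon: float = 600.0) -> pd.DataFrame:
    """Scan background ligand levels for approximate FCD with exact activities.

    At each background L the pair (L -> L/fold) vs (L/arm_scale -> L/(arm_scale*fold))
    is run with the exact MWC activity.  Backgrounds whose external and
    internal ligand excursions stay well inside (K_I, K_A) are accepted.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    m = model.with_(activity_form="exact")
    rows = []
    for L in backgrounds:
        pair = ScaledStepPair(L, L / fold, L / arm_scale, L / (arm_scale * fold))
        _, _, verdict = run_scaled_pair(m, pair, observable=observable, tol=tol,
                                        horizon=horizon)
        rows.append({"background_uM": L, "discrepancy": verdict.discrepancy,
                     "is_fcd": verdict.is_fcd, "observable": verdict.observable})
    return pd.DataFrame(rows)


def set_model_param(model: ChemotaxisModel, path: str, value: float) -> ChemotaxisModel:
    """Return a copy of the model with one dotted-path parameter replaced.

    Paths address the parameter blocks, e.g. ``methylation.k_B1``,
    ``phospho.totals.B1``, ``phospho.k_dephos.Y6`` (the k10 rate),
    ``flagellar.q``, ``membrane.K_I``.
    """
    head, _, rest = path.partition(".")
    blocks = {"phospho": model.phospho, "methylation": model.methylation,
              "flagellar": model.flagellar, "membrane": model.membrane,
              "cytoplasmic": model.cytoplasmic}
    if head not in blocks or not rest:
        raise KeyError(f"cannot resolve parameter path {path!r}")
    block = blocks[head]
    key, _, leaf = rest.partition(".")
    if leaf:  # nested mapping, e.g. totals.B1
        mapping = getattr(block, key, None)
        if mapping is None or leaf not in mapping:
            raise KeyError(f"cannot resolve parameter path {path!r}")
        new_map = dict(mapping)
        new_map[leaf] = value
        new_block = replace(block, **{key: new_map})
    else:
        if not hasattr(block, key):
            raise KeyError(f"cannot resolve parameter path {path!r}")
        new_block = replace(block, **{key: value})
    return model.with_(**{head: new_block})


def robustness_sweep(model: ChemotaxisModel, param_path: str, values,
                     pair: ScaledStepPair = CANONICAL_PAIR,
                     observable: str | None = None,
                     tol: float | None = None) -> pd.DataFrame:
    """FCD verdicts across a sweep of one parameter (value, discrepancy, is_fcd)."""
    rows = []
    for v in values:
        m = set_model_param(model, param_path, v)
        _, _, verdict = run_scaled_pair(m, pair, observable=observable, tol=tol)
        rows.append({"param": param_path, "value": v,
                     "discrepancy": verdict.discrepancy, "is_fcd": verdict.is_fcd})
    return pd.DataFrame(rows)


def regime_violation_run(model: ChemotaxisModel,
                         pair: ScaledStepPair = CANONICAL_PAIR,
                         K_I: float = 1800.0, K_A: float = 3000.0,
                         observable: str | None = None) -> FCDVerdict:
    """Run the pair with dissociation constants moved onto the stimulus range.

    With K_I = 1800 uM the backgrounds of the canonical pair violate
    K_I << L << K_A, the log-regime approximation breaks down, and the two
    arms' responses visibly differ (FCD verdict false).
    """
    recept_m = replace(model.membrane, K_I=K_I, K_A=K_A)
    recept_c = replace(model.cytoplasmic, K_I=K_I, K_A=K_A)
    m = model.with_(membrane=recept_m, cytoplasmic=recept_c, activity_form="exact")
    _, _, verdict = run_scaled_pair(m, pair, observable=observable, tol=TOL_REGIME)
    return verdict


# per-mutant observables: which channels the pathway still reports on
_MUTANT_OBSERVABLES = {
    "cheA2_del": ("Y6p",),
    "cheA3_del": ("Y3p", "Y4p", "Y6p"),
    "cheB2_del": ("f", "Y3p", "Y4p", "Y6p"),
    "cheY4_5x": ("f", "Y3p", "Y4p", "Y6p"),
}


def mutant_fcd_suite(model: ChemotaxisModel,
                     pair: ScaledStepPair = CANONICAL_PAIR,
                     tol: float | None = None) -> pd.DataFrame:
    """FCD verdicts for the in-silico mutants on their informative channels.

    cheA2-deletion leaves CheY6 phosphorylated only by the cytoplasmic
    cluster; cheA3-deletion leaves CheY3/CheY4/CheY6 fed only by the
    membrane cluster; cheB2-deletion removes a demethylase (for the model
    III wiring this is the cytoplasmic cluster's only one, which abolishes
    its adaptation — flagged instead of run); CheY4 overexpression
    five-fold rescales the internal-ligand attenuation.
    """
    rows = []
    for mutation, observables in _MUTANT_OBSERVABLES.items():
        mutant = model.with_mutations(mutation)
        if mutation == "cheB2_del" and not mutant.cytoplasmic_demethylation_possible() \
                and not model.variant.b2_demethylates_membrane:
            rows.append({"mutation": mutation, "observable": None,
                         "discrepancy": np.nan, "is_fcd": None,
                         "note": "cytoplasmic cluster loses its only demethylase; "
                                 "cytoplasmic adaptation lost"})
            continue
        for obs in observables:
            _, _, verdict = run_scaled_pair(mutant, pair, observable=obs, tol=tol)
            rows.append({"mutation": mutation, "observable": obs,
                         "discrepancy": verdict.discrepancy,
                         "is_fcd": verdict.is_fcd, "note": ""})
    return pd.DataFrame(rows)
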