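"""Closed-loop chemotaxis pathway: receptors, phosphotransfer network, flagellum.

The pathway couples three layers:

* two MWC receptor clusters (membrane, sensing external ligand L; cytoplasmic,
  sensing an internalized signal L-tilde), each with integral-feedback
  methylation dynamics driven by CheR (methylates inactive receptors, at
  saturation) and phosphorylated CheB (demethylates active receptors);
* a mass-action phosphotransfer network: the membrane-cluster activity gates
  CheA2 autophosphorylation, the cytoplasmic activity gates the CheA3A4
  complex; CheY3, CheY4, CheY6, CheB1, CheB2 draw phosphoryl groups from
  CheA2 while CheY6 and CheB2 also draw from CheA3A4; every phospho-protein
  auto-dephosphorylates (the CheY6 rate is conventionally called k10);
* a Hill-type flagellar output: the tethered rotation frequency f decreases
  from f_max as phosphorylated CheY accumulates, through an AND-type drive
  V = Y6p * (Y3p + Y4p) that needs CheY6-P plus at least one of
  CheY3-P/CheY4-P.

Three model variants differ in how the cytoplasmic cluster is fed:

* model I:   L-tilde = 10*L / (10 + Y3p + Y4p)  (static map with CheY feedback);
* model II:  first-order lag dL-tilde/dt = (L - L-tilde)/tau  (no protein feedback);
* model III: L-tilde = L, CheB1 demethylates only the membrane cluster and
  CheB2 only the cytoplasmic one, and N = N-tilde = 17.5.

Models I and II share the asymmetric demethylation wiring in which CheB2-P
acts on both clusters and CheB1-P only on the membrane cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .receptors import ReceptorClusterParams, ligand_free_energy

__all__ = [
    "PhosphoNetworkParams",
    "MethylationParams",
    "FlagellarParams",
    "ModelVariant",
    "LigandProgram",
    "Trajectory",
    "SolverOptions",
    "ChemotaxisModel",
    "internal_ligand_model_I",
    "internal_ligand_model_II_rhs",
    "methylation_rhs",
    "phospho_rhs",
    "flagellar_frequency",
    "assemble_model",
    "PHOSPHO_SPECIES",
    "MUTATIONS",
]

PHOSPHO_SPECIES = ("A2", "A34", "Y3", "Y4", "Y6", "B1", "B2")
A2_ACCEPTORS = ("Y3", "Y4", "Y6", "B1", "B2")
A34_ACCEPTORS = ("Y6", "B2")
MUTATIONS = ("cheA2_del", "cheA3_del", "cheB2_del", "cheY4_5x")

# Saturation guard: a cluster with no structurally reachable demethylation has
# no finite methylation fixed point (m -> infinity, activity -> 1).  Steady
# states pin such clusters at this activity deficit.
_SATURATION_DEFICIT = 1e-12


def _default_totals() -> dict:
    # CheY3/CheY4 totals are the experimentally constrained 3.2 / 13.2 uM;
    # the rest are plausible intracellular abundances (uM).
    return {"A2": 5.0, "A34": 5.0, "Y3": 3.2, "Y4": 13.2, "Y6": 10.0, "B1": 2.0, "B2": 2.0}


def _default_transfer() -> dict:
    return {f"A2->{j}": 1.0 for j in A2_ACCEPTORS} | {f"A34->{j}": 1.0 for j in A34_ACCEPTORS}


def _default_dephos() -> dict:
    return {"Y3": 1.0, "Y4": 1.0, "Y6": 1.0, "B1": 1.0, "B2": 1.0}


@dataclass(frozen=True)
class PhosphoNetworkParams:
    """Totals (uM) and rate constants of the phosphotransfer network.

    ``k_dephos["Y6"]`` is the CheY6 auto-dephosphorylation rate k10.
    ``R2``/``R3`` are the (constant, saturating) CheR2/CheR3 concentrations,
    normalized to 1 uM; they multiply the respective methylation rates.
    """

    totals: Mapping[str, float] = field(default_factory=_default_totals)
    k_auto_A2: float = 10.0
    k_auto_A34: float = 10.0
    k_transfer: Mapping[str, float] = field(default_factory=_default_transfer)
    k_dephos: Mapping[str, float] = field(default_factory=_default_dephos)
    R2: float = 1.0
    R3: float = 1.0

    def __post_init__(self) -> None:
        for name in PHOSPHO_SPECIES:
            if name not in self.totals:
                raise ValueError(f"missing total concentration for {name}")
            if self.totals[name] < 0:
                raise ValueError(f"total[{name}] must be >= 0")
        for k, v in {**self.k_transfer, **self.k_dephos}.items():
            if v < 0:
                raise ValueError(f"rate {k} must be >= 0")
        if min(self.k_auto_A2, self.k_auto_A34, self.R2, self.R3) < 0:
            raise ValueError("rates and CheR concentrations must be >= 0")

    @property
    def k10(self) -> float:
        return float(self.k_dephos["Y6"])


@dataclass(frozen=True)
class MethylationParams:
    """Methylation (1/s) and demethylation (1/(uM*s)) rate constants.

    k_R / k_Rt act on the membrane / cytoplasmic cluster; k_B1 and k_B2 are
    the membrane-cluster demethylation rates by CheB1-P and CheB2-P, k_B2t
    the cytoplasmic-cluster rate by CheB2-P.  Which terms are wired in is
    decided by the model variant, not here.
    """

    k_R: float = 0.01
    k_Rt: float = 0.01
    k_B1: float = 0.01
    k_B2: float = 0.01
    k_B2t: float = 0.01

    def __post_init__(self) -> None:
        if min(self.k_R, self.k_Rt) <= 0:
            raise ValueError("methylation rates must be > 0")
        if min(self.k_B1, self.k_B2, self.k_B2t) < 0:
            raise ValueError("demethylation rates must be >= 0")


@dataclass(frozen=True)
class FlagellarParams:
    """Hill output of the tethered flagellum: f = f_max / (1 + (V/q)^n)."""

    f_max: float = 8.0
    q: float = 64.0
    hill_n: float = 4.0

    def __post_init__(self) -> None:
        if self.q <= 0 or self.f_max <= 0 or self.hill_n <= 0:
            raise ValueError("flagellar parameters must be > 0")


@dataclass(frozen=True)
class ModelVariant:
    """Which internal-ligand map, demethylation wiring and mutations to use."""

    id: str = "I"
    tau_Lt: float = 10.0
    mutations: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.id not in ("I", "II", "III"):
            raise ValueError(f"unknown model variant {self.id!r}")
        if self.tau_Lt <= 0:
            raise ValueError("tau_Lt must be > 0")
        bad = set(self.mutations) - set(MUTATIONS)
        if bad:
            raise ValueError(f"unknown mutations: {sorted(bad)}")

    @property
    def b2_demethylates_membrane(self) -> bool:
        # models I/II: CheB2 covers both clusters; model III: cytoplasmic only
        return self.id in ("I", "II")


@dataclass(frozen=True)
class LigandProgram:
    """Piecewise-constant external ligand signal L(t).

    ``levels`` has one more entry than ``breakpoints``: levels[i] holds on
    [breakpoints[i-1], breakpoints[i]).
    """

    breakpoints: tuple = ()
    levels: tuple = (0.0,)

    def __post_init__(self) -> None:
        bp = tuple(float(t) for t in self.breakpoints)
        lv = tuple(float(v) for v in self.levels)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "levels", lv)
        if len(lv) != len(bp) + 1:
            raise ValueError("need exactly len(breakpoints)+1 levels")
        if any(v < 0 for v in lv):
            raise ValueError("ligand levels must be >= 0")
        if any(later <= earlier for earlier, later in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")

    @classmethod
    def constant(cls, L: float) -> "LigandProgram":
        return cls((), (L,))

    @classmethod
    def step(cls, t_step: float, L_pre: float, L_post: float) -> "LigandProgram":
        return cls((t_step,), (L_pre, L_post))

    @classmethod
    def tethered_assay_schedule(cls) -> "LigandProgram":
        """Canonical tethered-cell assay stimulus: 0 -> 100 uM at 245 s, back to 0 at 375 s."""
        return cls((245.0, 375.0), (0.0, 100.0, 0.0))

    def level_at(self, t: float) -> float:
        i = np.searchsorted(self.breakpoints, t, side="right")
        return self.levels[i]

    def scaled(self, p: float) -> "LigandProgram":
        if p <= 0:
            raise ValueError("scale factor must be > 0")
        return LigandProgram(self.breakpoints, tuple(p * v for v in self.levels))


# state layout: [m, m_t, (L_t if model II), A2p, A34p, Y3p, Y4p, Y6p, B1p, B2p]
_X_NAMES = ("A2p", "A34p", "Y3p", "Y4p", "Y6p", "B1p", "B2p")
CHANNELS = ("m", "m_t", "a", "a_t", "L", "L_t") + _X_NAMES + ("f",)


@dataclass
class Trajectory:
    """Time grid plus named channels of a pathway simulation."""

    t: np.ndarray
    series: dict

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]

    def to_wide(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, **self.series})

    def to_tidy(self) -> pd.DataFrame:
        wide = self.to_wide()
        return wide.melt(id_vars="t_s", var_name="channel", value_name="value")

    def write_csv(self, path, tidy: bool = False) -> None:
        (self.to_tidy() if tidy else self.to_wide()).to_csv(path, index=False)


@dataclass(frozen=True)
class SolverOptions:
    method: str = "LSODA"
    rtol: float = 1e-10
    atol: float = 1e-12
    max_step: float = math.inf


def internal_ligand_model_I(L, Y3p, Y4p):
    """Model I internal-ligand map: L-tilde = 10*L / (10 + Y3p + Y4p) (uM).

    Linear in L at fixed protein state; identity when no CheY3/CheY4 is
    phosphorylated; worst-case attenuation L/L-tilde = (10 + Y3_tot + Y4_tot)/10.
    """
    return 10.0 * np.asarray(L, dtype=float) / (10.0 + Y3p + Y4p)


def internal_ligand_model_II_rhs(L_t, L, tau_Lt):
    """First-order lag dL-tilde/dt = (L - L-tilde)/tau_Lt (uM/s)."""
    if tau_Lt <= 0:
        raise ValueError("tau_Lt must be > 0")
    return (L - L_t) / tau_Lt


def methylation_rhs(a, a_t, B1p, B2p, params: MethylationParams,
                    variant: ModelVariant, R2: float = 1.0, R3: float = 1.0,
                    leak: float = 0.0, m: float = 0.0, m_t: float = 0.0):
    """(dm/dt, dm_t/dt): CheR methylates inactive, CheB-P demethylates active.

    Neither expression depends on m except through the activities (integral
    feedback); a nonzero ``leak`` adds an explicit -leak*m term, which breaks
    exact adaptation and serves as the non-FCD negative control.
    """
    demeth_mem = params.k_B1 * B1p
    if variant.b2_demethylates_membrane:
        demeth_mem += params.k_B2 * B2p
    dm = params.k_R * R2 * (1.0 - a) - demeth_mem * a - leak * m
    dmt = params.k_Rt * R3 * (1.0 - a_t) - params.k_B2t * B2p * a_t - leak * m_t
    return dm, dmt


def phospho_rhs(x: Sequence[float], a: float, a_t: float,
                params: PhosphoNetworkParams,
                totals: Mapping[str, float] | None = None) -> np.ndarray:
    """Mass-action phosphotransfer derivatives for (A2p, A34p, Y3p, ..., B2p).

    Autophosphorylation of each kinase is gated by its cluster's activity;
    each acceptor drains its donor with rate k_transfer * donor_p * free
    acceptor; every species auto-dephosphorylates.  Phosphoryl flux is
    conserved edge by edge: the donor loss term equals the acceptor gain.
    """
    tot = totals if totals is not None else params.totals
    A2p, A34p, Y3p, Y4p, Y6p, B1p, B2p = x
    xp = {"Y3": Y3p, "Y4": Y4p, "Y6": Y6p, "B1": B1p, "B2": B2p}
    ktr = params.k_transfer

    out_A2 = {j: ktr[f"A2->{j}"] * A2p * (tot[j] - xp[j]) for j in A2_ACCEPTORS}
    out_A34 = {j: ktr[f"A34->{j}"] * A34p * (tot[j] - xp[j]) for j in A34_ACCEPTORS}

    dA2 = params.k_auto_A2 * a * (tot["A2"] - A2p) - sum(out_A2.values())
    dA34 = params.k_auto_A34 * a_t * (tot["A34"] - A34p) - sum(out_A34.values())
    dx = {j: out_A2.get(j, 0.0) + out_A34.get(j, 0.0) - params.k_dephos[j] * xp[j]
          for j in xp}
    return np.array([dA2, dA34, dx["Y3"], dx["Y4"], dx["Y6"], dx["B1"], dx["B2"]])


def flagellar_frequency(Y3p, Y4p, Y6p, params: FlagellarParams):
    """Tethered-flagellum rotation frequency f = f_max / (1 + (V/q)^n), Hz.

    V = Y6p * (Y3p + Y4p) is the minimal smooth AND of the two signalling
    branches: the flagellum responds only when CheY6-P and at least one of
    CheY3-P/CheY4-P are present.  f = f_max when either branch is silent.
    """
    V = np.abs(np.asarray(Y6p, dtype=float) * (np.asarray(Y3p) + np.asarray(Y4p)))
    out = params.f_max / (1.0 + (V / params.q) ** params.hill_n)
    return out if out.ndim else float(out)


class SteadyStateError(RuntimeError):
    pass


class ChemotaxisModel:
    """Assembled closed-loop ODE system for one model variant.

    ``activity_form`` selects the exact MWC activity (default; valid at
    L = 0) or the log-regime approximation, under which the closed loop is
    exactly scale invariant.  ``methylation_leak`` > 0 intentionally breaks
    the integral-feedback structure (negative control for FCD tests).
    """

    def __init__(self,
                 variant: ModelVariant = ModelVariant(),
                 membrane: ReceptorClusterParams = ReceptorClusterParams(),
                 cytoplasmic: ReceptorClusterParams | None = None,
                 phospho: PhosphoNetworkParams = PhosphoNetworkParams(),
                 methylation: MethylationParams = MethylationParams(),
                 flagellar: FlagellarParams = FlagellarParams(),
                 activity_form: str = "exact",
                 methylation_leak: float = 0.0,
                 solver: SolverOptions = SolverOptions()):
        if activity_form not in ("exact", "log"):
            raise ValueError(f"unknown activity_form {activity_form!r}")
        self.variant = variant
        self.membrane = membrane
        self.cytoplasmic = cytoplasmic if cytoplasmic is not None else membrane
        self.phospho = phospho
        self.methylation = methylation
        self.flagellar = flagellar
        self.activity_form = activity_form
        self.methylation_leak = methylation_leak
        self.solver = solver

        self.totals = dict(phospho.totals)
        muts = variant.mutations
        if "cheA2_del" in muts:
            self.totals["A2"] = 0.0
        if "cheA3_del" in muts:
            self.totals["A34"] = 0.0
        if "cheB2_del" in muts:
            self.totals["B2"] = 0.0
        if "cheY4_5x" in muts:
            self.totals["Y4"] = 5.0 * self.totals["Y4"]

        self.has_Lt_state = variant.id == "II"
        self.n_states = 10 if self.has_Lt_state else 9
        self._x0 = 3 if self.has_Lt_state else 2
        names = ["m", "m_t"] + (["L_t"] if self.has_Lt_state else []) + list(_X_NAMES)
        self.state_names = tuple(names)

    # -- structural introspection -------------------------------------------------

    def with_(self, **kwargs) -> "ChemotaxisModel":
        """Copy of this model with some blocks replaced."""
        base = dict(variant=self.variant, membrane=self.membrane,
                    cytoplasmic=self.cytoplasmic, phospho=self.phospho,
                    methylation=self.methylation, flagellar=self.flagellar,
                    activity_form=self.activity_form,
                    methylation_leak=self.methylation_leak, solver=self.solver)
        base.update(kwargs)
        return ChemotaxisModel(**base)

    def with_mutations(self, *mutations: str) -> "ChemotaxisModel":
        return self.with_(variant=replace(self.variant,
                                          mutations=frozenset(mutations)))

    def _b_reachable(self, name: str) -> bool:
        """Can CheB``name``-P ever be nonzero, given deletions and rates?"""
        if self.totals[name] <= 0:
            return False
        via_A2 = (self.totals["A2"] > 0 and self.phospho.k_auto_A2 > 0
                  and self.phospho.k_transfer[f"A2->{name}"] > 0)
        via_A34 = (name in A34_ACCEPTORS and self.totals["A34"] > 0
                   and self.phospho.k_auto_A34 > 0
                   and self.phospho.k_transfer[f"A34->{name}"] > 0)
        return via_A2 or via_A34

    def membrane_demethylation_possible(self) -> bool:
        ok = self.methylation.k_B1 > 0 and self._b_reachable("B1")
        if self.variant.b2_demethylates_membrane:
            ok = ok or (self.methylation.k_B2 > 0 and self._b_reachable("B2"))
        return ok

    def cytoplasmic_demethylation_possible(self) -> bool:
        return self.methylation.k_B2t > 0 and self._b_reachable("B2")

    # -- activities ---------------------------------------------------------------

    def _activity(self, m: float, L: float, params: ReceptorClusterParams) -> float:
        if self.activity_form == "log":
            if L <= 0.0:
                raise ValueError("log-regime activity needs L > 0")
            g = math.log(L / params.K_I)
        else:
            g = math.log1p(L / params.K_I) - math.log1p(L / params.K_A)
        z = params.N * (g + params.alpha * (params.m0 - m))
        if z > 700.0:
            z = 700.0
        elif z < -700.0:
            z = -700.0
        return 1.0 / (1.0 + math.exp(z))

    def internal_ligand(self, L: float, y: np.ndarray) -> float:
        if self.variant.id == "I":
            return float(internal_ligand_model_I(L, y[self._x0 + 2], y[self._x0 + 3]))
        if self.variant.id == "II":
            return float(y[2])
        return float(L)  # model III: static identity map

    # -- right-hand side ----------------------------------------------------------

    def rhs(self, t: float, y: np.ndarray, L: float) -> np.ndarray:
        m, m_t = y[0], y[1]
        x = y[self._x0:]
        L_t = self.internal_ligand(L, y)
        a = self._activity(m, L, self.membrane)
        a_t = self._activity(m_t, L_t, self.cytoplasmic)

        dm, dmt = methylation_rhs(a, a_t, x[5], x[6], self.methylation,
                                  self.variant, self.phospho.R2, self.phospho.R3,
                                  self.methylation_leak, m, m_t)
        dx = phospho_rhs(x, a, a_t, self.phospho, self.totals)
        if self.has_Lt_state:
            dLt = internal_ligand_model_II_rhs(y[2], L, self.variant.tau_Lt)
            return np.concatenate(([dm, dmt, dLt], dx))
        return np.concatenate(([dm, dmt], dx))

    # -- steady states ------------------------------------------------------------

    def _pin_value(self, L_t: float, params: ReceptorClusterParams) -> float:
        """Methylation value at which the activity sits at 1 - _SATURATION_DEFICIT."""
        if self.activity_form == "log":
            g = math.log(L_t / params.K_I)
        else:
            g = math.log1p(L_t / params.K_I) - math.log1p(L_t / params.K_A)
        # solve N*(g + alpha*(m0 - m)) = ln(deficit/(1-deficit))
        target = math.log(_SATURATION_DEFICIT)
        return params.m0 + (g - target / params.N) / params.alpha

    def steady_state(self, L_const: float, t_relax: float = 6000.0) -> np.ndarray:
        """Full adapted state at constant ligand L_const.

        Long relaxation integration followed by a Newton polish.  Clusters
        left without any structurally reachable demethylase (e.g. the
        cytoplasmic cluster under cheB2 deletion) have no finite methylation
        fixed point and are pinned at their activity asymptote.
        """
        if L_const < 0:
            raise ValueError("L_const must be >= 0")
        if self.activity_form == "log" and L_const <= 0:
            raise ValueError("log-regime model needs L_const > 0")
        pin_mem = not self.membrane_demethylation_possible()
        pin_cyt = not self.cytoplasmic_demethylation_possible()

        y0 = self._initial_guess(L_const)
        sol = solve_ivp(self.rhs, (0.0, t_relax), y0, args=(L_const,),
                        method=self.solver.method, rtol=1e-9, atol=1e-11)
        if not sol.success:
            raise SteadyStateError(f"relaxation failed: {sol.message}")
        y = sol.y[:, -1]

        free = np.ones(self.n_states, dtype=bool)
        if pin_mem:
            free[0] = False
        if pin_cyt:
            free[1] = False

        def pinned(yf: np.ndarray) -> np.ndarray:
            full = y.copy()
            full[free] = yf
            if pin_mem:
                full[0] = self._pin_value(L_const, self.membrane)
            if pin_cyt:
                L_t = self.internal_ligand(L_const, full)
                full[1] = self._pin_value(L_t, self.cytoplasmic)
            return full

        def residual(yf: np.ndarray) -> np.ndarray:
            return self.rhs(0.0, pinned(yf), L_const)[free]

        sol_r = root(residual, y[free], method="hybr", tol=1e-13)
        y_star = pinned(sol_r.x)
        res = self.rhs(0.0, y_star, L_const)
        if np.max(np.abs(res[free])) > 1e-8:
            raise SteadyStateError(
                f"steady state did not converge at L={L_const} "
                f"(max residual {np.max(np.abs(res[free])):.3g})")
        return y_star

    def _initial_guess(self, L: float) -> np.ndarray:
        mem, cyt = self.membrane, self.cytoplasmic
        if self.activity_form == "log":
            g = math.log(L / mem.K_I)
            gt = math.log(L / cyt.K_I)
        else:
            g = float(ligand_free_energy(L, mem))
            gt = float(ligand_free_energy(L, cyt))
        y = np.zeros(self.n_states)
        y[0] = mem.m0 + g / mem.alpha
        y[1] = cyt.m0 + gt / cyt.alpha
        if self.has_Lt_state:
            y[2] = L
        return y

    # -- simulation ---------------------------------------------------------------

    def simulate(self, program: LigandProgram, t_grid: np.ndarray,
                 initial: np.ndarray) -> Trajectory:
        """Integrate the closed loop over a stimulus program.

        Integration restarts exactly at every ligand breakpoint (steps are
        not smoothed); the state carries over continuously.
        """
        t_grid = np.asarray(t_grid, dtype=float)
        if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
            raise ValueError("t_grid must be 1-D strictly increasing")
        y = np.asarray(initial, dtype=float)
        if y.shape != (self.n_states,) or not np.all(np.isfinite(y)):
            raise ValueError("initial state has wrong shape or is not finite")

        edges = [t_grid[0]] + [b for b in program.breakpoints
                               if t_grid[0] < b < t_grid[-1]] + [t_grid[-1]]
        cols = [y.copy()[:, None]] if t_grid[0] == edges[0] else []
        times = [np.array([t_grid[0]])] if cols else []
        for t0, t1 in zip(edges[:-1], edges[1:]):
            L = program.level_at(0.5 * (t0 + t1))
            mask = (t_grid > t0) & (t_grid <= t1)
            t_eval = t_grid[mask]
            sol = solve_ivp(self.rhs, (t0, t1), y, args=(L,),
                            method=self.solver.method, rtol=self.solver.rtol,
                            atol=self.solver.atol, max_step=self.solver.max_step,
                            t_eval=t_eval if t_eval.size else None,
                            dense_output=False)
            if not sol.success:
                raise RuntimeError(f"integration failed near t={t0}: {sol.message}")
            if t_eval.size:
                times.append(sol.t)
                cols.append(sol.y)
            # advance to the exact segment end regardless of the grid
            if not t_eval.size or sol.t[-1] != t1:
                tail = solve_ivp(self.rhs, (t_eval[-1] if t_eval.size else t0, t1),
                                 sol.y[:, -1] if t_eval.size else y, args=(L,),
                                 method=self.solver.method, rtol=self.solver.rtol,
                                 atol=self.solver.atol, max_step=self.solver.max_step)
                if not tail.success:
                    raise RuntimeError(f"integration failed near t={t1}: {tail.message}")
                y = tail.y[:, -1]
            else:
                y = sol.y[:, -1]
        t = np.concatenate(times)
        Y = np.concatenate(cols, axis=1)
        return self._to_trajectory(t, Y, program)

    def _to_trajectory(self, t: np.ndarray, Y: np.ndarray,
                       program: LigandProgram) -> Trajectory:
        m, m_t = Y[0], Y[1]
        X = Y[self._x0:]
        L = np.array([program.level_at(ti) for ti in t])
        if self.variant.id == "I":
            L_t = internal_ligand_model_I(L, X[2], X[3])
        elif self.variant.id == "II":
            L_t = Y[2]
        else:
            L_t = L.copy()
        a = np.array([self._activity(mi, Li, self.membrane) for mi, Li in zip(m, L)])
        a_t = np.array([self._activity(mi, Li, self.cytoplasmic)
                        for mi, Li in zip(m_t, L_t)])
        # clip solver-level negative overshoot on concentrations
        X = np.clip(X.copy(), 0.0, None)
        for i, nm in enumerate(_X_NAMES):
            X[i] = np.minimum(X[i], self.totals[nm[:-1]])
        f = flagellar_frequency(X[2], X[3], X[4], self.flagellar)
        series = {"m": m, "m_t": m_t, "a": a, "a_t": a_t, "L": L, "L_t": np.asarray(L_t)}
        series.update({nm: X[i] for i, nm in enumerate(_X_NAMES)})
        series["f"] = np.asarray(f)
        return Trajectory(t=t, series=series)


def assemble_model(variant: ModelVariant | str, **blocks) -> ChemotaxisModel:
    """Build a ChemotaxisModel for a variant, applying its structural rules.

    Model III gets the constant cluster size N = N-tilde = 17.5 unless the
    receptor blocks are given explicitly.
    """
    if isinstance(variant, str):
        variant = ModelVariant(id=variant)
    if variant.id == "III":
        blocks.setdefault("membrane", ReceptorClusterParams(N=17.5))
        blocks.setdefault("cytoplasmic", ReceptorClusterParams(N=17.5))
    return ChemotaxisModel(variant=variant, **blocks)
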