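"""Monod-Wyman-Changeux (MWC) activities of chemoreceptor clusters.

A receptor cluster is modelled as a two-state (active/inactive) allosteric
unit whose activity is a Boltzmann function of the free-energy difference
between the two states.  The free-energy difference has a methylation part,
affine in the average methylation level ``m``, and a ligand part that grows
logarithmically with the sensed ligand concentration ``L`` between the
inactive- and active-state dissociation constants ``K_I < K_A``.

In the intermediate regime ``K_I << L << K_A`` the ligand part is well
approximated by ``ln(L/K_I)``; under that approximation the activity is
*exactly* invariant under the joint rescaling ``(L, m) -> (p*L, m + ln(p)/alpha)``
for any ``p > 0``.  This equivariance is the algebraic root of fold-change
detection (scale invariance) in the closed-loop chemotaxis pathway.

Units: energies are in kT (dimensionless), ``alpha`` in kT per methylation
unit, ligand concentrations in micromolar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReceptorClusterParams",
    "ClusterState",
    "ligand_free_energy",
    "methylation_free_energy",
    "activity_exact",
    "activity_log_regime",
    "fcd_methylation_shift",
]


@dataclass(frozen=True)
class ReceptorClusterParams:
    """MWC energetics of one receptor cluster.

    Parameters
    ----------
    N : float
        Receptor cooperativity (number of allosterically coupled units in
        the cluster); multiplies the per-receptor free-energy difference.
    alpha : float
        Sensitivity of the free-energy difference to methylation
        (kT per methylation unit).
    m0 : float
        Methylation offset: at ``m = m0`` and ``L = 0`` the two states are
        isoenergetic and the activity is 1/2.
    K_A, K_I : float
        Ligand dissociation constants of the active and inactive receptor
        states (uM).  Ligand binds the inactive state more tightly, so
        ``K_A > K_I``.
    """

    N: float = 6.0
    alpha: float = 2.0
    m0: float = 5.0
    K_A: float = 3000.0
    K_I: float = 18.0

    def __post_init__(self) -> None:
        if not (self.K_A > self.K_I > 0.0):
            raise ValueError(
                f"require K_A > K_I > 0, got K_A={self.K_A}, K_I={self.K_I}"
            )
        if self.N <= 0.0:
            raise ValueError(f"require N > 0, got {self.N}")
        if self.alpha <= 0.0:
            raise ValueError(f"require alpha > 0, got {self.alpha}")


@dataclass(frozen=True)
class ClusterState:
    """Instantaneous state of a cluster: methylation level and sensed ligand.

    ``m`` is an unbounded real (no saturation clamp: the fold-change symmetry
    requires methylation to absorb arbitrary ``ln(p)/alpha`` shifts).
    """

    m: float
    L: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.L) < 0.0):
            raise ValueError(f"ligand concentration must be >= 0, got {self.L}")


def ligand_free_energy(L, params: ReceptorClusterParams):
    """Ligand-binding contribution g_L(L) = ln((1 + L/K_I)/(1 + L/K_A)) in kT.

    Strictly increasing in L, zero at L = 0, saturating at ln(K_A/K_I).
    Accepts scalars or arrays.
    """
    L = np.asarray(L, dtype=float)
    if np.any(L < 0.0):
        raise ValueError("ligand concentration must be >= 0")
    out = np.log1p(L / params.K_I) - np.log1p(L / params.K_A)
    return out if out.ndim else float(out)


def methylation_free_energy(m, params: ReceptorClusterParams):
    """Methylation contribution g_m(m) = alpha*(m0 - m) in kT.

    The sign is fixed so that activity increases with methylation, making
    the CheR/CheB loop (methylate inactive, demethylate active receptors) a
    stable negative feedback.
    """
    m = np.asarray(m, dtype=float)
    out = params.alpha * (params.m0 - m)
    return out if out.ndim else float(out)


def _boltzmann(free_energy_arg):
    # activity = 1/(1 + exp(N*(g_L + g_m))); clip the exponent to avoid
    # overflow warnings for deeply saturated clusters
    z = np.clip(free_energy_arg, -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(z))


def activity_exact(state: ClusterState, params: ReceptorClusterParams):
    """Exact MWC activity: Boltzmann weight of the active state.

    ``a = 1 / (1 + exp(N * [g_L(L) + alpha*(m0 - m)]))``, in (0, 1);
    strictly decreasing in L and strictly increasing in m.
    """
    gl = ligand_free_energy(state.L, params)
    gm = methylation_free_energy(state.m, params)
    out = _boltzmann(params.N * (np.asarray(gl) + np.asarray(gm)))
    return out if out.ndim else float(out)


def activity_log_regime(state: ClusterState, params: ReceptorClusterParams):
    """MWC activity with the log-regime approximation g_L ~ ln(L/K_I).

    Valid for K_I << L << K_A; exactly equivariant under
    (L, m) -> (p*L, m + ln(p)/alpha).  L must be positive.
    """
    L = np.asarray(state.L, dtype=float)
    if np.any(L <= 0.0):
        raise ValueError(
            "activity_log_regime requires L > 0 (logarithm undefined at 0); "
            "use activity_exact for stimuli that visit L = 0"
        )
    gl = np.log(L / params.K_I)
    gm = methylation_free_energy(state.m, params)
    out = _boltzmann(params.N * (gl + np.asarray(gm)))
    return out if out.ndim else float(out)


def fcd_methylation_shift(p: float, alpha: float) -> float:
    """Methylation offset ln(p)/alpha absorbing a p-fold input scaling.

    Shifting m by this amount while scaling L by p leaves the log-regime
    activity unchanged; shifts compose additively (p1 then p2 == p1*p2).
    """
    if p <= 0.0:
        raise ValueError(f"scale factor must be > 0, got {p}")
    if alpha <= 0.0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    return float(np.log(p) / alpha)
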