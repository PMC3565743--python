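# Methods

## The model

`rsfcd` simulates the chemotaxis signalling pathway of *Rhodobacter
sphaeroides* as a closed-loop ODE system with three layers.

**Receptor clusters.** The bacterium has two sensory arrays: a transmembrane
cluster sensing the external ligand concentration L (µM) and a cytoplasmic
cluster sensing an internalized signal L̃.  Each cluster is a two-state
(active/inactive) MWC allosteric unit.  With average methylation level m, the
activity (probability of the active state) is

    a = 1 / (1 + exp(N·[g_L(L) + α(m₀ − m)])),
    g_L(L) = ln((1 + L/K_I) / (1 + L/K_A)),

where N is the cluster cooperativity, α (kT per methylation unit) the
sensitivity of the free-energy difference to methylation, m₀ the bias at
which a = 1/2 in the absence of ligand, and K_I < K_A the dissociation
constants of the inactive and active receptor states.  Ligand binds the
inactive state more tightly, so activity falls with L and rises with m.  The
sign of the methylation term is fixed so that the CheR/CheB loop below is a
stable negative feedback.

In the window K_I ≪ L ≪ K_A, g_L(L) ≈ ln(L/K_I) (the *log regime*).  Under
that approximation the activity is exactly invariant under the joint
transformation (L, m) → (pL, m + ln p / α) for any p > 0.  This equivariance
is the algebraic root of fold-change detection (FCD): because every other
state variable is driven only through the activities, scaling the whole
input program by p and shifting the methylation coordinates of the adapted
initial state by ln p / α reproduces the identical trajectory of every
activity, phospho-protein and output channel.

**Methylation (integral feedback).** CheR methyltransferases work at
saturation on inactive receptors; phosphorylated CheB demethylases act on
active receptors:

    dm/dt  = k_R·R₂·(1 − a) − (k_B1·B1p + k_B2·B2p)·a      (membrane, models I/II)
    dm̃/dt = k̃_R·R₃·(1 − ã) − k̃_B2·B2p·ã                   (cytoplasmic)

Model III rewires demethylation: CheB1-P acts only on the membrane cluster
and CheB2-P only on the cytoplasmic one, so the membrane equation drops the
k_B2 term.  Neither right-hand side depends explicitly on m — this is the
integral-feedback structure that forces exact adaptation: at any steady
state the membrane activity satisfies a* = k_R/(k_R + k_B1·B1p* + k_B2·B2p*)
independently of L.  Methylation is an unbounded real; a saturation clamp
would destroy the ability of m to absorb ln p / α shifts and is therefore
not applied.

**Phosphotransfer network.** Mass action with activity-gated
autophosphorylation.  CheA2 (gated by a) feeds CheY3, CheY4, CheY6, CheB1
and CheB2; the CheA3A4 complex (gated by ã) feeds CheY6 and CheB2; every
phospho-protein auto-dephosphorylates (the CheY6 rate is the conventional
k10).  For donor D with acceptor set J:

    dDp/dt = k_auto·gate·(D_tot − Dp) − Σ_{j∈J} k_t[D→j]·Dp·(j_tot − jp)
    djp/dt = Σ_D k_t[D→j]·Dp·(j_tot − jp) − k_dephos[j]·jp

Phosphoryl flux is conserved edge by edge, which keeps every concentration
inside [0, total].

**Flagellar output.** The tethered-cell rotation frequency is a Hill
function of an AND-type drive V = Y6p·(Y3p + Y4p):

    f = f_max / (1 + (V/q)^n),   f_max = 8 Hz, n = 4.

The product is the minimal smooth AND: chemotactic output requires CheY6-P
plus at least one of CheY3-P/CheY4-P, and f = f_max when either branch is
silent.  Whether the two branches combine additively or multiplicatively
inside the Hill function is not experimentally determined; the product form
is chosen because it realizes the AND logic with a single scale parameter.

**Internal-ligand maps (model variants).**

* Model I: L̃ = 10·L/(10 + Y3p + Y4p) — a static map with feedback from the
  membrane branch's response regulators.  Linear in L at fixed protein
  state, which is exactly what preserves the scaling symmetry.
* Model II: dL̃/dt = (L − L̃)/τ, a first-order lag (τ = 10 s default).  Any
  stable positive LTI filter commutes with input scaling and confines L̃ to
  [L_a, L_b) after a step; first order is the minimal choice.
* Model III: L̃ = L, no protein feedback onto the receptors, the rewired
  demethylation above, and constant cluster sizes N = Ñ = 17.5.

Mutants are applied structurally: cheA2Δ/cheA3Δ/cheB2Δ zero the respective
total; CheY4 overexpression multiplies its total by five.

## Parameters, units and defaults

Time in seconds, concentrations in µM, energies in kT.

| parameter | default | why |
|---|---|---|
| K_I, K_A | 18, 3000 µM | adopted from the *E. coli* chemoreceptor literature; not measured in *R. sphaeroides* |
| α, m₀ | 2 kT/unit, 5 | α is unidentifiable from output (see degeneracy below); m₀ only shifts the adapted methylation level |
| N (models I/II) | 6 | typical MWC cluster size fitted for *E. coli* arrays; model III uses its stated 17.5 |
| CheY3, CheY4 totals | 3.2, 13.2 µM | measured intracellular totals; they set the FCD-range factors 2.64 and 7.92 |
| other totals (A2, A34, Y6, B1, B2) | 5, 5, 10, 2, 2 µM | plausible intracellular abundances; config-overridable |
| k_auto, k_transfer, k_dephos | 10 /s, 1 /(µM·s), 1 /s | give sub-second phosphotransfer equilibration, far faster than methylation |
| k_R, k̃_R, k_B1, k_B2, k̃_B2 | 0.01 (1/s, 1/(µM·s)) | chosen once so an up-step of 100 µM re-adapts in ~100 s, the timescale of tethered-cell assays |
| q | 64 µM² | the steady-state drive V* of the default network, so baseline f ≈ 4 Hz sits mid-range |
| R₂, R₃ | 1 µM | CheR concentrations normalized to 1 (absorbed into k_R otherwise) |

The exact supplementary rate listings of the source models are not
available; the phosphotransfer defaults above are this package's own
mass-action instantiation honouring the stated connectivity.  All rates are
config-overridable and nothing in the FCD analysis depends on their exact
values — that robustness is itself one of the tested claims.

## Numerical choices

* Integration: `scipy.integrate.solve_ivp` with LSODA, rtol 1e−10 /
  atol 1e−12 for protocol runs.  The system is mildly stiff (phosphotransfer
  at ~10/s against methylation at ~0.01/s).  Ligand steps are handled by
  segment-wise integration restarted exactly at each breakpoint; no
  smoothing of the discontinuity.
* Steady states: a long relaxation integration followed by a Newton
  (`hybr`) polish to residual < 1e−8.  The discrepancy tolerances of the
  exactness tests (1e−6 relative, 1e−8 absolute) sit two orders above the
  combined solver error.
* Saturated clusters: a cluster left without any structurally reachable
  demethylase (e.g. cytoplasmic under cheB2Δ in the I/II wiring) has no
  finite methylation fixed point — m̃ grows logarithmically while ã → 1.
  `steady_state` pins such a cluster at activity 1 − 1e−12.  The pinned
  methylation values of the two arms of a scaled pair are exactly
  shift-related, so the pinning preserves the scaling symmetry, and the
  mutant keeps FCD through the unaffected branch while its mean rotation
  frequency collapses.
* Discrepancy metric: sup over the common time grid of |y₁ − y₂| divided by
  the peak-to-peak range of y₁; 0/0 (two identical flat traces) is defined
  as 0.  Tolerance 1e−6 for log-regime runs (exact FCD), 0.05 for
  exact-activity runs inside the regime (approximate FCD).
* Each arm of a scaled pair starts from the adapted state of its own
  background — FCD is a statement about adapted initial conditions, and
  comparing from a shared state would conflate invariance with transient
  relaxation.

## Synthetic assay and fitting

The synthetic tethered-cell assay emulates the measurement the models were
originally constrained by: flagellar frequency in [0, 8] Hz sampled at 1 Hz
over 600 s, ligand stepping 0 → 100 µM at 245 s and back at 375 s.  The
observation model is additive i.i.d. Gaussian noise (default sd 0.5 Hz, a
placeholder — the real assay's noise is unreported) clipped to [0, 8] Hz.
It does not model rotation-direction switching, stop events or tracking
artefacts, so parameter-recovery results bound what the fitting machinery
can do on clean data, not what it would achieve on real traces.

Fitting frees the six parameters the assay can constrain (k_R, k̃_R, k_B1,
k_B2, k̃_B2, q) over box bounds ([1e−3, 0.1] for rates, [5, 300] for q) and
minimizes the RMSE of f at the sample times.  The global stage is seeded
differential evolution in log-parameter space (the bounds span two
decades), Sobol-initialized; population-based exploration proved markedly
more reliable here than trajectory-based annealing searches, which stall in
the flat valleys described next.  The objective has shallow spurious
valleys along a correlated (k̃_R, k̃_B2) direction — both rescale the
cytoplasmic cluster's steady activity, and q partially compensates the
resulting output shift — so the best mutually distinct members of the final
population are each polished by bounded least squares and the best polished
point wins.  `degeneracy_report` profiles the objective over each
parameter around the optimum and flags flat directions; the analytic
degeneracy (α → εα compensated by dividing the k-sets by ε, a change of
variables in the methylation coordinate) is verified numerically to 1e−8
rather than fitted.

Problem sizes used in the shipped tests: 600-sample traces, global-search
budgets of ~2000 objective evaluations for recovery runs and ~250 for
noise-floor runs, with up to 3 (respectively 2) polish candidates.

## Known limitations

* The phosphotransfer rate constants are an instantiation, not a fit to the
  original (unavailable) listings; quantitative trajectories are therefore
  not comparable to the source figures, only the invariance/robustness
  phenomenology is.
* The theoretical FCD result covers a general class of internal-ligand
  dynamics; the package tests the three concrete instances only.
* The exact-activity FCD verdict at the canonical 1000/500 µM backgrounds
  is marginal by construction (1000 µM is only 3× below K_A); the 0.05
  tolerance encodes "visually identical", not a sharp physical boundary.
* No stochastic (Gillespie) simulation, motor-switching statistics, spatial
  swimming behaviour or cell-to-cell variability.
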