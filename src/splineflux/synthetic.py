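"""Simulated experiments: reference kinetics, forward simulation, noise.

Two built-in protocols mirror the study conditions the estimator is designed
for:

* ``small`` — a batch culture on a 7-flux network (4 internal metabolites,
  3 extracellular metabolites + biomass, d = 3).  The free fluxes 1, 4, 5
  follow saturating/inhibition rate laws in the extracellular concentrations;
  21 equidistant samples of all 4 states on [0, 20] h give 84 measurements.
  Noise is either near-zero (variance 1e-8) or per-point "realistic".
* ``medium`` — a dilution-controlled continuous culture on a 68-flux network
  (62 internal metabolites, 10 extracellular metabolites incl. biomass,
  d = 6, 44 irreversible fluxes).  31 equidistant samples on [0, 10] h of 8
  concentrations plus the O2-uptake and CO2-production fluxes give 310
  measurements.  Only glucose (20 mmol/L) is in the feed.

Both networks are reconstructions built to satisfy every published structural
constraint (flux/metabolite counts, free-flux sets, reversibilities, kinetic
bindings); the exact stoichiometric entries of the original networks are not
available in text form, so the entries here are synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .dynamics import DilutionProfile, DynamicModel, OutputMap, model_rhs
from .estimation import MeasurementSet
from .network import MetabolicNetwork, NullSpaceBasis, rational_basis

__all__ = [
    "ReferenceKinetics",
    "ExperimentProtocol",
    "small_network",
    "medium_network",
    "small_kinetics",
    "medium_kinetics",
    "simulate_truth",
    "sample_measurements",
    "builtin_protocol",
]


@dataclass(frozen=True)
class ReferenceKinetics:
    """Free-flux rate laws u_ref(x): one callable per free flux.

    Each rate law maps the full state vector x to the flux value; the standard
    forms are Monod (Vmax * c / (Km + c)), constant, and product inhibition
    (Vmax / (Ki + c)).
    """

    rate_laws: tuple  # d callables x -> float

    @property
    def d(self) -> int:
        return len(self.rate_laws)

    def __call__(self, x) -> np.ndarray:
        return np.array([law(np.asarray(x, dtype=float))
                         for law in self.rate_laws])


@dataclass(frozen=True)
class ExperimentProtocol:
    sampling_times: np.ndarray
    x0: np.ndarray
    mode: str = "batch"
    dilution: DilutionProfile | None = None
    x_in: np.ndarray | None = None
    output_map: OutputMap | None = None
    #: either a scalar variance or "relative" (sd = max(a|m|, b))
    noise: str | float = 1e-8
    noise_rel: float = 0.05
    noise_floor: float = 0.05

    def __post_init__(self):
        object.__setattr__(self, "sampling_times",
                           np.asarray(self.sampling_times, dtype=float))
        object.__setattr__(self, "x0", np.asarray(self.x0, dtype=float))


# ---------------------------------------------------------------------------
# small-scale network (reconstruction; see module docstring)
# ---------------------------------------------------------------------------

def small_network() -> MetabolicNetwork:
    """Batch case-study network: 7 fluxes, 4 internal metabolites (A-D),
    extracellular A_ext, E_ext, F_ext and biomass; d = 3.

    Reactions: 1 A_ext->A, 2 A->B, 3 B<->C, 4 E_ext->D, 5 C->F_ext,
    6 C<->E_ext, 7 B+D->biomass.  Fluxes 3 and 6 are the only reversible
    ones; the free-flux sets {1,4,5} and {3,6,7} are both valid rational
    selections.
    """
    reaction_ids = tuple(str(i) for i in range(1, 8))
    metabolite_ids = ("A", "B", "C", "D", "A_ext", "E_ext", "F_ext", "biomass")
    roles = ("internal",) * 4 + ("external",) * 3 + ("biomass",)
    S = np.array([
        #     1   2   3   4   5   6   7
        [1, -1, 0, 0, 0, 0, 0],    # A
        [0, 1, -1, 0, 0, 0, -1],   # B
        [0, 0, 1, 0, -1, -1, 0],   # C
        [0, 0, 0, 1, 0, 0, -1],    # D
        [-1, 0, 0, 0, 0, 0, 0],    # A_ext
        [0, 0, 0, -1, 0, 1, 0],    # E_ext
        [0, 0, 0, 0, 1, 0, 0],     # F_ext
        [0, 0, 0, 0, 0, 0, 1],     # biomass
    ], dtype=float)
    reversible = np.array([0, 0, 1, 0, 0, 1, 0], dtype=bool)
    return MetabolicNetwork(reaction_ids=reaction_ids,
                            metabolite_ids=metabolite_ids, S=S,
                            roles=roles, reversible=reversible)


def small_kinetics() -> ReferenceKinetics:
    """Reference rate laws of the batch case study.

    u1 = c_Aext / (1.5 + c_Aext); u4 = 0.2 c_Eext / (3 + c_Eext);
    u5 = 1 / (1 + c_Fext).  State order: (A_ext, E_ext, F_ext, biomass).
    """
    return ReferenceKinetics(rate_laws=(
        lambda x: x[0] / (1.5 + x[0]),
        lambda x: 0.2 * x[1] / (3.0 + x[1]),
        lambda x: 1.0 / (1.0 + x[2]),
    ))


# ---------------------------------------------------------------------------
# medium-scale network (synthetic stand-in; see module docstring)
# ---------------------------------------------------------------------------

EXT_MEDIUM = ("Gluc", "Glyc", "NH3", "SO4", "Cit", "PDO", "Ac", "CO2", "O2")

# biomass yield of the growth reaction (stoichiometric coefficient of the
# biomass pseudo-metabolite); sets mu = 0.2 * v_growth
_BIO_YIELD = 0.2
_SULFUR_DEMAND = 0.1  # SO4 consumed per unit growth flux


def medium_network() -> MetabolicNetwork:
    """Synthetic continuous-culture network with the published dimensions.

    68 fluxes, 62 internal metabolites I1..I62, 9 extracellular metabolites
    plus biomass, d = 6, 44 irreversible fluxes.  Exchange reactions occupy
    columns 59-68: 59 SO4 uptake, 60 PDO export, 61 CO2 export, 62 glycerol
    exchange (reversible), 63 glucose uptake, 64 growth, 65 NH3 uptake,
    66 citrate exchange (reversible), 67 acetate excretion, 68 O2 uptake.
    Free fluxes: {62, 63, 65, 66, 67, 68}.

    The internal part is a hub-and-chain backbone: uptakes feed anchor
    metabolites I1..I7 which merge into hub I8; a linear pathway runs from
    the hub to I62 (the CO2 precursor) with an acetate branch at I28 and two
    side branches producing the PDO precursor I60 and the growth precursor
    I61.  This is a stand-in for the original network, whose stoichiometry is
    only available as supplementary material of the source study.
    """
    m_int, n = 62, 68
    int_ids = tuple(f"I{i}" for i in range(1, m_int + 1))
    metabolite_ids = int_ids + EXT_MEDIUM + ("biomass",)
    roles = ("internal",) * m_int + ("external",) * len(EXT_MEDIUM) + ("biomass",)
    reaction_ids = tuple(str(i) for i in range(1, n + 1))
    S = np.zeros((len(metabolite_ids), n))
    met = {m: i for i, m in enumerate(metabolite_ids)}

    col = 0  # 0-based column of reaction "1"

    def rxn(consume, produce):
        nonlocal col
        for m, c in consume:
            S[met[m], col] -= c
        for m, c in produce:
            S[met[m], col] += c
        col += 1

    # internal reactions 1-5: anchors -> hub I8 (Gluc, O2, NH3, Cit, Glyc)
    for anchor in ("I1", "I2", "I3", "I6", "I7"):
        rxn([(anchor, 1)], [("I8", 1)])
    # reaction 6: acetate branch off the main chain
    rxn([("I28", 1)], [("I5", 1)])
    # reactions 7-58: main chain I8 -> ... -> I59 -> I62 with two side branches
    chain = [f"I{i}" for i in range(8, 60)] + ["I62"]  # I8..I59, I62
    branch_at = {"I30": "I60", "I45": "I61"}  # PDO and growth precursors
    for a, b in zip(chain[:-1], chain[1:]):
        side = branch_at.get(a)
        rxn([(a, 1)], [(b, 1)] + ([(side, 1)] if side else []))
    assert col == 58, col

    # exchange reactions 59-68
    rxn([("SO4", 1)], [("I4", 1)])                        # 59 SO4 uptake
    rxn([("I60", 1)], [("PDO", 1)])                       # 60 PDO export
    rxn([("I62", 1)], [("CO2", 1)])                       # 61 CO2 export
    rxn([("Glyc", 1)], [("I7", 1)])                       # 62 glycerol exchange
    rxn([("Gluc", 1)], [("I1", 1)])                       # 63 glucose uptake
    rxn([("I61", 1), ("I4", _SULFUR_DEMAND)],
        [("biomass", _BIO_YIELD)])                        # 64 growth
    rxn([("NH3", 1)], [("I3", 1)])                        # 65 NH3 uptake
    rxn([("Cit", 1)], [("I6", 1)])                        # 66 citrate exchange
    rxn([("I5", 1)], [("Ac", 1)])                         # 67 acetate excretion
    rxn([("O2", 1)], [("I2", 1)])                         # 68 O2 uptake
    assert col == n

    reversible = np.zeros(n, dtype=bool)
    reversible[[61, 65]] = True  # fluxes 62 and 66 (glycerol, citrate)
    # 22 reversible internal reactions keep n_irr at 44
    reversible[np.arange(6, 50, 2)] = True  # fluxes 7, 9, ..., 49
    net = MetabolicNetwork(reaction_ids=reaction_ids,
                           metabolite_ids=metabolite_ids, S=S,
                           roles=roles, reversible=reversible)
    assert net.n_irr == 44, net.n_irr
    return net


def medium_kinetics() -> ReferenceKinetics:
    """Reference rate laws of the continuous case study (state order: Gluc,
    Glyc, NH3, SO4, Cit, PDO, Ac, CO2, O2, biomass)."""
    return ReferenceKinetics(rate_laws=(
        lambda x: 0.0995,                                   # u62 glycerol
        lambda x: 0.5605 * x[0] / (9.89 + x[0]),            # u63 glucose
        lambda x: 0.122 * x[2] / (0.1919 + x[2]),           # u65 ammonia
        lambda x: 0.0207 * x[4] / (5.575 + x[4]),           # u66 citrate
        lambda x: 0.8834 / (10.0 + x[6]),                   # u67 acetate
        lambda x: 0.438 * x[8] / (9.706 + x[8]),            # u68 oxygen
    ))


#: dilution-rate schedule of the continuous protocol.  The original study
#: controls D between 0 and 1 along a profile published only graphically;
#: this piecewise-constant stand-in switches at the quarter-horizon marks.
def default_dilution(t_end: float = 10.0) -> DilutionProfile:
    return DilutionProfile(times=np.array([0.0, 0.25, 0.5, 0.75]) * t_end,
                           rates=np.array([0.0, 0.5, 0.2, 0.8]))


# ---------------------------------------------------------------------------
# simulation and sampling
# ---------------------------------------------------------------------------

@dataclass
class TruthTrajectories:
    times: np.ndarray       # dense grid
    states: np.ndarray      # (n_states, n_dense)
    fluxes: np.ndarray      # (n, n_dense) all network fluxes
    free_fluxes: np.ndarray  # (d, n_dense)
    model: DynamicModel = field(repr=False, default=None)

    def at(self, t) -> tuple:
        """Interpolate states and free fluxes onto times t."""
        t = np.asarray(t, dtype=float)
        xs = np.vstack([np.interp(t, self.times, s) for s in self.states])
        us = np.vstack([np.interp(t, self.times, u) for u in self.free_fluxes])
        return xs, us


def simulate_truth(net: MetabolicNetwork, basis: NullSpaceBasis,
                   kinetics: ReferenceKinetics, protocol: ExperimentProtocol,
                   rtol: float = 1e-9, n_dense: int = 1001) -> TruthTrajectories:
    """Integrate the reduced model with u(t) = kinetics(x(t)).

    Uses an adaptive high-order integrator; returns states and all n fluxes
    on a dense grid covering the sampling horizon.
    """
    model = DynamicModel(net=net, basis=basis, mode=protocol.mode,
                         dilution=protocol.dilution, x_in=protocol.x_in)
    t0, t_end = protocol.sampling_times[0], protocol.sampling_times[-1]

    def rhs(t, x):
        return model_rhs(model, x, kinetics(x), t)

    t_dense = np.union1d(np.linspace(t0, t_end, n_dense),
                         protocol.sampling_times)
    sol = solve_ivp(rhs, (t0, t_end), protocol.x0, method="LSODA",
                    t_eval=t_dense, rtol=rtol, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"truth integration failed: {sol.message}")
    u = np.column_stack([kinetics(x) for x in sol.y.T])
    v = basis.K @ u
    return TruthTrajectories(times=sol.t, states=sol.y, fluxes=v,
                             free_fluxes=u, model=model)


def sample_measurements(truth: TruthTrajectories,
                        protocol: ExperimentProtocol,
                        seed: int) -> MeasurementSet:
    """Draw m_ij = y_j(t_i) + Normal(0, sigma_ij^2) on the sampling grid."""
    omap = protocol.output_map
    if omap is None:
        omap = OutputMap.states_only(truth.states.shape[0])
    ts = protocol.sampling_times
    xs, us = truth.at(ts)
    parts = []
    if omap.n_state_out:
        parts.append(omap.state_selection @ xs)
    if omap.n_flux_out:
        parts.append(omap.flux_selection @ truth.model.basis.K @ us)
    y = np.vstack(parts).T  # (n_time, n_out)

    if protocol.noise == "relative":
        sds = np.maximum(protocol.noise_rel * np.abs(y), protocol.noise_floor)
    else:
        sds = np.full_like(y, float(np.sqrt(float(protocol.noise))))
    rng = np.random.default_rng(seed)
    means = y + rng.normal(0.0, sds)
    return MeasurementSet(times=ts, output_ids=omap.output_ids,
                          means=means, sds=sds)


# ---------------------------------------------------------------------------
# built-in protocols
# ---------------------------------------------------------------------------

def builtin_protocol(name: str):
    """Return (net, basis, kinetics, protocol) for a named case study.

    Names: ``small_low_noise`` (variance 1e-8), ``small_realistic``
    (relative noise model), ``medium`` (continuous reactor, relative noise).
    """
    if name in ("small_low_noise", "small_realistic"):
        net = small_network()
        basis = rational_basis(net, ("1", "4", "5"))
        kin = small_kinetics()
        proto = ExperimentProtocol(
            sampling_times=np.linspace(0.0, 20.0, 21),
            x0=np.array([10.0, 15.0, 0.0, 0.1]),
            mode="batch",
            output_map=OutputMap.states_only(4, output_ids=net.state_ids),
            noise=(1e-8 if name == "small_low_noise" else "relative"),
        )
        return net, basis, kin, proto
    if name == "medium":
        net = medium_network()
        basis = rational_basis(net, ("62", "63", "65", "66", "67", "68"))
        kin = medium_kinetics()
        # measured: 8 concentrations + O2 uptake and CO2 production fluxes
        conc_ids = ("Gluc", "Glyc", "NH3", "SO4", "Cit", "PDO", "Ac", "biomass")
        state_ids = net.state_ids
        sel = np.zeros((8, 10))
        for r, cid in enumerate(conc_ids):
            sel[r, state_ids.index(cid)] = 1.0
        flux_sel = np.zeros((2, net.n))
        flux_sel[0, 67] = 1.0   # O2 uptake (flux 68), positive for uptake
        flux_sel[1, 60] = 1.0   # CO2 production (flux 61)
        proto = ExperimentProtocol(
            sampling_times=np.linspace(0.0, 10.0, 31),
            x0=np.array([100.0, 53.15, 38.45, 62.61, 0.0, 0.0, 0.0,
                         6.78, 100.0, 2.14]),
            mode="continuous",
            dilution=default_dilution(10.0),
            x_in=np.concatenate([[20.0], np.zeros(9)]),
            output_map=OutputMap(
                state_selection=sel, flux_selection=flux_sel,
                output_ids=conc_ids + ("O2_uptake", "CO2_production")),
            noise="relative",
        )
        return net, basis, kin, proto
    raise ValueError(f"unknown protocol {name!r}")
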