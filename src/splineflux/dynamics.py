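"""Reduced extracellular dynamics and measurement output maps.

Under the pseudo steady-state reduction the only remaining states are the
extracellular concentrations plus biomass, x = [c_ext; c_bio].  For a batch
reactor

    dx/dt = S_e @ K @ u(t) * (q_bio' x)

(specific fluxes are per gram dry weight, hence the multiplication with the
biomass concentration), and a continuous reactor adds the dilution term
D(t) * (x_in - x).  Irreversible fluxes are the algebraic outputs
z = I_irr @ K @ u and are kept nonnegative by the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import MetabolicNetwork, NullSpaceBasis

__all__ = [
    "DilutionProfile",
    "DynamicModel",
    "OutputMap",
    "model_rhs",
    "irreversible_fluxes",
    "evaluate_outputs",
]


@dataclass(frozen=True)
class DilutionProfile:
    """Right-continuous piecewise-constant dilution rate D(t) [1/h]."""

    times: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        r = np.atleast_1d(np.asarray(self.rates, dtype=float))
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "rates", r)
        if t.size != r.size or t.size == 0:
            raise ValueError("times and rates must be equal-length, nonempty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("switch times must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("dilution rates must be nonnegative")

    def __call__(self, t):
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, None)
        return self.rates[idx]


@dataclass(frozen=True)
class DynamicModel:
    """Network + basis + reactor mode; evaluates the state derivative."""

    net: MetabolicNetwork
    basis: NullSpaceBasis
    mode: str = "batch"  # batch | continuous
    dilution: DilutionProfile | None = None
    x_in: np.ndarray | None = None  # feed concentrations, length m_ext+1

    def __post_init__(self):
        if self.mode not in ("batch", "continuous"):
            raise ValueError(f"unknown reactor mode {self.mode!r}")
        if self.mode == "continuous":
            if self.dilution is None:
                raise ValueError("continuous mode requires a dilution profile")
            x_in = np.zeros(self.n_states) if self.x_in is None else \
                np.asarray(self.x_in, dtype=float)
            if x_in.size != self.n_states:
                raise ValueError(f"x_in must have length m_ext+1 = {self.n_states}")
            object.__setattr__(self, "x_in", x_in)

    @property
    def n_states(self) -> int:
        return self.net.m_ext + 1

    @property
    def q_bio(self) -> np.ndarray:
        """Selector of the biomass entry (the last state)."""
        q = np.zeros(self.n_states)
        q[-1] = 1.0
        return q

    @property
    def SeK(self) -> np.ndarray:
        """(m_ext+1 x d) reduced stoichiometry acting on the free fluxes."""
        return self.net.S_e @ self.basis.K

    def rhs(self, x, u, t=0.0):
        return model_rhs(self, x, u, t)


def model_rhs(model: DynamicModel, x, u, t=0.0) -> np.ndarray:
    """dx/dt at state x, free fluxes u and (for continuous mode) time t."""
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    dx = model.SeK @ u * x[-1]
    if model.mode == "continuous":
        dx = dx + float(model.dilution(t)) * (model.x_in - x)
    return dx


def irreversible_fluxes(basis: NullSpaceBasis, net: MetabolicNetwork, u) -> np.ndarray:
    """z = I_irr @ K @ u: the algebraic irreversible-flux outputs."""
    u = np.asarray(u, dtype=float)
    return net.I_irr @ basis.K @ u


@dataclass(frozen=True)
class OutputMap:
    """Linear selection of measured states and measured fluxes.

    y = [state_selection @ x ; flux_selection @ K @ u].  Off-gas fluxes carry
    their sign in flux_selection so that measured uptake/production rates are
    nonnegative numbers.
    """

    state_selection: np.ndarray
    flux_selection: np.ndarray
    output_ids: tuple = field(default=())

    def __post_init__(self):
        ss = np.atleast_2d(np.asarray(self.state_selection, dtype=float))
        fs = np.atleast_2d(np.asarray(self.flux_selection, dtype=float))
        object.__setattr__(self, "state_selection", ss)
        object.__setattr__(self, "flux_selection", fs)
        if self.n_out < 1:
            raise ValueError("at least one output required")
        if not self.output_ids:
            object.__setattr__(self, "output_ids",
                               tuple(f"y{i+1}" for i in range(self.n_out)))
        if len(self.output_ids) != self.n_out:
            raise ValueError("one id per output required")

    @property
    def n_state_out(self) -> int:
        return 0 if self.state_selection.size == 0 else self.state_selection.shape[0]

    @property
    def n_flux_out(self) -> int:
        return 0 if self.flux_selection.size == 0 else self.flux_selection.shape[0]

    @property
    def n_out(self) -> int:
        return self.n_state_out + self.n_flux_out

    @classmethod
    def states_only(cls, n_states: int, output_ids=()) -> "OutputMap":
        return cls(state_selection=np.eye(n_states),
                   flux_selection=np.empty((0, 0)), output_ids=tuple(output_ids))


def evaluate_outputs(omap: OutputMap, basis: NullSpaceBasis, x, u) -> np.ndarray:
    """y = [state_selection @ x ; flux_selection @ K @ u]."""
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    parts = []
    if omap.n_state_out:
        parts.append(omap.state_selection @ x)
    if omap.n_flux_out:
        parts.append(omap.flux_selection @ basis.K @ u)
    return np.concatenate(parts)
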