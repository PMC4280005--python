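"""File formats and run configuration.

CSV/TSV conventions: comma-separated CSV with '.' decimals and a mandatory
header row; network files are tab-separated.  Units: time in hours,
concentrations in mmol/L (biomass gDW/L), specific fluxes in mmol/gDW/h.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bspline import FreeFluxSet, SplineFunction
from .dynamics import DilutionProfile
from .estimation import FitResult, MeasurementSet
from .network import MetabolicNetwork, load_network, save_network

__all__ = [
    "RunConfig",
    "read_measurements",
    "write_measurements",
    "read_dilution",
    "write_dilution",
    "write_result",
    "read_result",
    "load_small_fixture",
]


_CONFIG_FIELDS = {
    "k_mode": str, "free_fluxes": list, "spline_degree": int,
    "solver_tol": float, "solver_maxiter": int, "confidence": float,
    "reactor_mode": str, "bootstrap_replicates": int, "seed": int,
    "dilution_csv": str, "feed": list,
}


@dataclass
class RunConfig:
    """Validated run configuration (YAML-serializable)."""

    k_mode: str = "rational"           # rational | orthonormal | optimal
    free_fluxes: list = field(default_factory=list)
    spline_degree: int = 2
    solver_tol: float = 1e-8
    solver_maxiter: int = 300
    confidence: float = 0.95
    reactor_mode: str = "batch"
    bootstrap_replicates: int = 1000
    seed: int = 0
    dilution_csv: str = ""
    feed: list = field(default_factory=list)

    def __post_init__(self):
        if self.k_mode not in ("rational", "orthonormal", "optimal"):
            raise ValueError(f"invalid k_mode {self.k_mode!r}")
        if self.reactor_mode not in ("batch", "continuous"):
            raise ValueError(f"invalid reactor_mode {self.reactor_mode!r}")
        if self.k_mode == "rational" and not self.free_fluxes:
            raise ValueError("k_mode=rational requires free_fluxes")
        if not (0 < self.confidence < 1):
            raise ValueError("confidence must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(_CONFIG_FIELDS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def read_measurements(path) -> MeasurementSet:
    """Long-format CSV with columns time, output_id, mean, sd."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time", "output_id", "mean", "sd"):
        if col not in df.columns:
            raise ValueError(f"measurements file lacks column {col!r}")
    df["output_id"] = df["output_id"].astype(str)
    output_ids = tuple(dict.fromkeys(df["output_id"]))  # keep file order
    times = np.sort(df["time"].unique())
    means = df.pivot_table(index="time", columns="output_id", values="mean",
                           sort=True).reindex(columns=list(output_ids))
    sds = df.pivot_table(index="time", columns="output_id", values="sd",
                         sort=True).reindex(columns=list(output_ids))
    if means.isna().any().any() or sds.isna().any().any():
        raise ValueError("incomplete measurement grid (every output must be "
                         "measured at every time)")
    return MeasurementSet(times=times, output_ids=output_ids,
                          means=means.to_numpy(), sds=sds.to_numpy())


def write_measurements(ms: MeasurementSet, path) -> None:
    rows = []
    for i, t in enumerate(ms.times):
        for j, oid in enumerate(ms.output_ids):
            rows.append((t, oid, ms.means[i, j], ms.sds[i, j]))
    pd.DataFrame(rows, columns=["time", "output_id", "mean", "sd"]).to_csv(
        path, index=False, float_format=lambda x: repr(float(x)))


def read_dilution(path) -> DilutionProfile:
    df = pd.read_csv(path)
    for col in ("time", "D"):
        if col not in df.columns:
            raise ValueError(f"dilution file lacks column {col!r}")
    return DilutionProfile(times=df["time"].to_numpy(),
                           rates=df["D"].to_numpy())


def write_dilution(profile: DilutionProfile, path) -> None:
    pd.DataFrame({"time": profile.times, "D": profile.rates}).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_result(fit: FitResult, path) -> None:
    """JSON dump of everything needed to reconstruct the fit."""
    doc = {
        "splines": [s.to_dict() for s in fit.flux_set.splines],
        "x0": [float(v) for v in fit.x0],
        "K": np.asarray(fit.K).tolist(),
        "f": float(fit.f),
        "n_p": int(fit.n_p),
        "n_meas": int(fit.n_meas),
        "aicc": float(fit.aicc),
        "optimal_K": bool(fit.optimal_K),
        "chi2_pass": fit.chi2_pass,
        "chi2_critical": fit.chi2_critical,
        "chi2_dof": fit.chi2_dof,
        "history": [h.to_dict() for h in fit.history],
        "solver_status": fit.solver_status,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_result(path) -> FitResult:
    doc = json.loads(Path(path).read_text())
    from .estimation import IterationRecord
    return FitResult(
        flux_set=FreeFluxSet(tuple(SplineFunction.from_dict(s)
                                   for s in doc["splines"])),
        x0=np.asarray(doc["x0"], dtype=float),
        K=np.asarray(doc["K"], dtype=float),
        f=doc["f"], n_p=doc["n_p"], n_meas=doc["n_meas"], aicc=doc["aicc"],
        optimal_K=doc["optimal_K"], chi2_pass=doc["chi2_pass"],
        chi2_critical=doc["chi2_critical"], chi2_dof=doc["chi2_dof"],
        history=[IterationRecord(**h) for h in doc["history"]],
        solver_status=doc.get("solver_status", "loaded"))


def write_flux_profiles(fit: FitResult, reaction_ids, path,
                        n_dense: int = 201) -> None:
    """CSV of all n flux profiles v = K u on a dense time grid."""
    t = np.linspace(fit.flux_set.t0, fit.flux_set.t_end, n_dense)
    V = fit.flux_profiles(t)
    df = pd.DataFrame(V.T, columns=[str(r) for r in reaction_ids])
    df.insert(0, "time", t)
    df.to_csv(path, index=False)


def load_small_fixture() -> MetabolicNetwork:
    """Bundled 7-flux batch case-study network (TSV fixture)."""
    base = resources.files("splineflux") / "data" / "small"
    return load_network(str(base / "stoichiometry.tsv"),
                        str(base / "metabolites.tsv"),
                        str(base / "reactions.tsv"))


def save_network_dir(net: MetabolicNetwork, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_network(net, outdir / "stoichiometry.tsv",
                 outdir / "metabolites.tsv", outdir / "reactions.tsv")
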