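"""Metabolic network container, partitioning, and null-space bases.

A metabolic network is described by its stoichiometric matrix ``S`` of shape
``(m+1, n)`` (one row per metabolite plus a biomass pseudo-metabolite, one
column per reaction), per-metabolite roles (``internal`` / ``external`` /
``biomass``) and per-reaction reversibility flags.  Under the pseudo
steady-state assumption the internal balances reduce to ``S_int @ v = 0``, so
every admissible flux vector is ``v = K @ u`` with ``K`` a basis of the null
space of ``S_int`` and ``u`` the d free fluxes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = [
    "MetabolicNetwork",
    "NullSpaceBasis",
    "BasisReport",
    "load_network",
    "degrees_of_freedom",
    "rational_basis",
    "orthonormal_basis",
    "check_basis",
]

#: singular values below RANK_RTOL * sigma_max count as zero.  Integer
#: stoichiometries keep the spectrum well separated, so this is uncritical.
RANK_RTOL = 1e-10

ROLES = ("internal", "external", "biomass")


@dataclass(frozen=True)
class MetabolicNetwork:
    """Stoichiometric network with its standard partitions.

    ``S`` stacks rows in file order; ``S_int``, ``S_ext`` and ``s_bio`` are the
    rows with role internal / external / biomass, and ``S_e`` is
    ``[S_ext; s_bio]`` — the part that drives the extracellular dynamics.
    """

    reaction_ids: tuple
    metabolite_ids: tuple
    S: np.ndarray
    roles: tuple
    reversible: np.ndarray  # boolean, per reaction

    def __post_init__(self):
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "reversible", np.asarray(self.reversible, dtype=bool))
        if S.shape != (len(self.metabolite_ids), len(self.reaction_ids)):
            raise ValueError(
                f"S has shape {S.shape}, expected "
                f"({len(self.metabolite_ids)}, {len(self.reaction_ids)})"
            )
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            raise ValueError("duplicate reaction ids")
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise ValueError("duplicate metabolite ids")
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise ValueError(f"invalid metabolite roles: {sorted(bad)}")
        if sum(r == "biomass" for r in self.roles) != 1:
            raise ValueError("no biomass pseudo-metabolite (exactly one required)")
        if len(self.reversible) != len(self.reaction_ids):
            raise ValueError("reversibility flags do not match reactions")

    # -- dimensions ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.reaction_ids)

    @property
    def m_int(self) -> int:
        return sum(r == "internal" for r in self.roles)

    @property
    def m_ext(self) -> int:
        return sum(r == "external" for r in self.roles)

    @property
    def n_irr(self) -> int:
        return int(np.sum(~self.reversible))

    @property
    def n_rev(self) -> int:
        return int(np.sum(self.reversible))

    # -- partitions ---------------------------------------------------------
    def _rows(self, role: str) -> np.ndarray:
        idx = [i for i, r in enumerate(self.roles) if r == role]
        return self.S[idx, :]

    @property
    def S_int(self) -> np.ndarray:
        return self._rows("internal")

    @property
    def S_ext(self) -> np.ndarray:
        return self._rows("external")

    @property
    def s_bio(self) -> np.ndarray:
        return self._rows("biomass")

    @property
    def S_e(self) -> np.ndarray:
        return np.vstack([self.S_ext, self.s_bio])

    @property
    def I_irr(self) -> np.ndarray:
        """(n_irr x n) 0/1 selector of the irreversible fluxes."""
        idx = np.flatnonzero(~self.reversible)
        M = np.zeros((idx.size, self.n))
        M[np.arange(idx.size), idx] = 1.0
        return M

    @property
    def external_ids(self) -> tuple:
        return tuple(
            m for m, r in zip(self.metabolite_ids, self.roles) if r == "external"
        )

    @property
    def state_ids(self) -> tuple:
        """External metabolites followed by biomass: the state ordering of x."""
        bio = [m for m, r in zip(self.metabolite_ids, self.roles) if r == "biomass"]
        return self.external_ids + tuple(bio)


@dataclass(frozen=True)
class NullSpaceBasis:
    """(n x d) basis K of the null space of S_int; v = K @ u."""

    K: np.ndarray
    mode: str  # rational | orthonormal | optimal
    free_flux_ids: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "K", np.asarray(self.K, dtype=float))
        if self.mode not in ("rational", "orthonormal", "optimal"):
            raise ValueError(f"unknown basis mode {self.mode!r}")

    @property
    def d(self) -> int:
        return self.K.shape[1]


@dataclass
class BasisReport:
    nullspace_residual: float
    orthonormality_residual: float
    column_rank: int
    d: int
    passed: bool
    messages: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# construction / IO
# ---------------------------------------------------------------------------

def load_network(stoichiometry, metabolite_roles, reaction_reversibility) -> MetabolicNetwork:
    """Build a :class:`MetabolicNetwork` from tabular streams.

    Parameters
    ----------
    stoichiometry:
        TSV path/stream: first column metabolite ids, header row reaction ids,
        entries the stoichiometric coefficients (exact decimals).
    metabolite_roles:
        TSV path/stream with columns ``metabolite_id``, ``role``.
    reaction_reversibility:
        TSV path/stream with columns ``reaction_id``, ``reversible`` (0/1).
    """
    mat = pd.read_csv(stoichiometry, sep="\t", index_col=0)
    roles_df = pd.read_csv(metabolite_roles, sep="\t")
    rev_df = pd.read_csv(reaction_reversibility, sep="\t")

    for col in ("metabolite_id", "role"):
        if col not in roles_df.columns:
            raise ValueError(f"metabolite role table lacks column {col!r}")
    for col in ("reaction_id", "reversible"):
        if col not in rev_df.columns:
            raise ValueError(f"reversibility table lacks column {col!r}")

    role_map = dict(zip(roles_df["metabolite_id"].astype(str), roles_df["role"]))
    rev_map = dict(zip(rev_df["reaction_id"].astype(str), rev_df["reversible"]))

    metabolite_ids = tuple(str(m) for m in mat.index)
    reaction_ids = tuple(str(r) for r in mat.columns)
    if len(reaction_ids) != len(rev_map):
        raise ValueError(
            f"matrix has {len(reaction_ids)} reactions, "
            f"reversibility table has {len(rev_map)}"
        )
    missing = [m for m in metabolite_ids if m not in role_map]
    if missing:
        raise ValueError(f"metabolites without role: {missing}")
    missing = [r for r in reaction_ids if r not in rev_map]
    if missing:
        raise ValueError(f"reactions without reversibility flag: {missing}")

    roles = tuple(role_map[m] for m in metabolite_ids)
    reversible = np.array([bool(int(rev_map[r])) for r in reaction_ids])
    return MetabolicNetwork(
        reaction_ids=reaction_ids,
        metabolite_ids=metabolite_ids,
        S=mat.to_numpy(dtype=float),
        roles=roles,
        reversible=reversible,
    )


def save_network(net: MetabolicNetwork, stoich_path, roles_path, rev_path) -> None:
    """Write the three network TSVs (inverse of :func:`load_network`)."""
    pd.DataFrame(net.S, index=list(net.metabolite_ids),
                 columns=list(net.reaction_ids)).to_csv(stoich_path, sep="\t")
    pd.DataFrame({"metabolite_id": list(net.metabolite_ids),
                  "role": list(net.roles)}).to_csv(roles_path, sep="\t", index=False)
    pd.DataFrame({"reaction_id": list(net.reaction_ids),
                  "reversible": net.reversible.astype(int)}).to_csv(
        rev_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# null-space machinery
# ---------------------------------------------------------------------------

def degrees_of_freedom(net: MetabolicNetwork) -> int:
    """d = n - rank(S_int), rank via singular-value threshold."""
    S_int = net.S_int
    if S_int.size == 0:
        raise ValueError("S_int is empty")
    sv = np.linalg.svd(S_int, compute_uv=False)
    rank = int(np.sum(sv > RANK_RTOL * max(sv[0], 1.0))) if sv.size else 0
    d = net.n - rank
    if d == 0:
        warnings.warn("fully determined system; no free fluxes", stacklevel=2)
    return d


def exact_rank(M) -> int:
    """Rank over rational arithmetic (fraction RREF); oracle-grade, O(m n^2)."""
    rows = [[Fraction(x).limit_denominator(10**9) for x in row] for row in np.asarray(M)]
    rank, ncols, prow = 0, len(rows[0]) if rows else 0, 0
    for col in range(ncols):
        piv = next((r for r in range(prow, len(rows)) if rows[r][col] != 0), None)
        if piv is None:
            continue
        rows[prow], rows[piv] = rows[piv], rows[prow]
        pv = rows[prow][col]
        rows[prow] = [x / pv for x in rows[prow]]
        for r in range(len(rows)):
            if r != prow and rows[r][col] != 0:
                f = rows[r][col]
                rows[r] = [a - f * b for a, b in zip(rows[r], rows[prow])]
        prow += 1
        rank += 1
        if prow == len(rows):
            break
    return rank


def rational_basis(net: MetabolicNetwork, free_flux_ids) -> NullSpaceBasis:
    """Null-space basis in which the chosen free fluxes appear untouched.

    The rows of K at the selected reactions form the identity, i.e. the free
    fluxes are d of the actual network fluxes and the remaining fluxes are the
    linear combinations dictated by the internal balances (the reduced
    row-echelon construction).
    """
    free_flux_ids = tuple(str(f) for f in free_flux_ids)
    d = degrees_of_freedom(net)
    if len(free_flux_ids) != d:
        raise ValueError(f"need exactly d={d} free fluxes, got {len(free_flux_ids)}")
    unknown = [f for f in free_flux_ids if f not in net.reaction_ids]
    if unknown:
        raise ValueError(f"unknown reaction ids: {unknown}")
    idx_free = [net.reaction_ids.index(f) for f in free_flux_ids]
    idx_dep = [j for j in range(net.n) if j not in idx_free]

    A = net.S_int[:, idx_dep]   # (m_int x (n-d))
    B = net.S_int[:, idx_free]  # (m_int x d)
    # dependent fluxes solve A @ v_dep = -B @ u; the selection is feasible iff
    # A has full column rank n-d (= rank(S_int))
    sv = np.linalg.svd(A, compute_uv=False)
    if sv.size < A.shape[1] or sv[A.shape[1] - 1] <= RANK_RTOL * max(sv[0], 1.0):
        raise ValueError("invalid free-flux set (dependent subsystem singular)")
    V_dep = np.linalg.lstsq(A, -B, rcond=None)[0]
    if np.max(np.abs(A @ V_dep + B)) > 1e-8 * max(1.0, np.max(np.abs(B))):
        raise ValueError("invalid free-flux set (dependent subsystem inconsistent)")

    K = np.zeros((net.n, d))
    K[idx_free, :] = np.eye(d)
    K[idx_dep, :] = V_dep
    return NullSpaceBasis(K=K, mode="rational", free_flux_ids=free_flux_ids)


def orthonormal_basis(net: MetabolicNetwork) -> NullSpaceBasis:
    """SVD null-space basis of S_int with a fixed sign convention.

    Columns are the right singular vectors for (numerically) zero singular
    values; each column's largest-magnitude entry is forced positive so the
    result is deterministic across runs.
    """
    d = degrees_of_freedom(net)
    if d < 1:
        raise ValueError("d = 0: no null space")
    _, sv, Vt = np.linalg.svd(net.S_int)
    K = Vt[net.n - d:, :].T.copy()
    for j in range(K.shape[1]):
        i = int(np.argmax(np.abs(K[:, j])))
        if K[i, j] < 0:
            K[:, j] = -K[:, j]
    return NullSpaceBasis(K=K, mode="orthonormal")


def check_basis(net: MetabolicNetwork, K, orthonormal_required: bool = False) -> BasisReport:
    """Validate the two basis constraint blocks S_int@K = 0 and K'K = I."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != net.n:
        raise ValueError(f"K has shape {K.shape}, expected ({net.n}, d)")
    d = K.shape[1]
    S_int = net.S_int
    null_res = float(np.max(np.abs(S_int @ K))) if K.size else 0.0
    scale = max(1.0, float(np.max(np.abs(S_int) @ np.abs(K)))) if K.size else 1.0
    orth_res = float(np.max(np.abs(K.T @ K - np.eye(d)))) if K.size else 0.0
    rank = int(np.linalg.matrix_rank(K, tol=RANK_RTOL * max(1.0, np.abs(K).max())))

    msgs = []
    ok = True
    if null_res > 1e-10 * scale:
        ok = False
        msgs.append(f"null-space residual {null_res:.3e} exceeds tolerance")
    if rank < d:
        ok = False
        msgs.append(f"columns rank-deficient (rank {rank} < d {d})")
    if orthonormal_required and orth_res > 1e-8:
        ok = False
        msgs.append(f"orthonormality residual {orth_res:.3e} exceeds 1e-8")
    return BasisReport(
        nullspace_residual=null_res,
        orthonormality_residual=orth_res,
        column_rank=rank,
        d=d,
        passed=ok,
        messages=msgs,
    )
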