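"""Flux balance analysis and the lethality predicate.

FBA maximizes the flux of the objective reaction subject to steady-state mass
balance (S v = 0) and flux bounds. All linear programs are solved with the
HiGHS solver behind :func:`scipy.optimize.linprog`, which is deterministic
for a fixed problem.

A knockout set is *lethal* when the optimal objective value of the
knocked-out model falls to (numerical) zero: at or below
``max(1e-6, 1e-3 x wild-type objective)`` unless the configuration supplies
an explicit ``lethality_epsilon``. An infeasible program counts as lethal.

:class:`FBASession` caches the stoichiometric matrix, the wild-type optimum,
lethality verdicts and minimum-L1-norm flux supports, so the enumeration
layer never re-solves an LP it has already seen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Optional

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import AnalysisConfig, MetabolicModel, disabled_reactions

__all__ = ["FluxSolution", "FBAError", "FBASession", "solve_fba", "is_lethal"]


class FBAError(RuntimeError):
    """Raised when the LP solver fails for a reason other than infeasibility."""


@dataclass
class FluxSolution:
    status: str  # "optimal" | "infeasible"
    objective_value: float
    fluxes: Dict[str, float]


_SCIPY_STATUS = {0: "optimal", 2: "infeasible"}


class FBASession:
    """Reusable LP state for one model.

    Parameters
    ----------
    model:
        The model to analyze. Its structure is frozen into matrices at
        construction; later mutation of the model is not seen.
    config:
        Supplies the solver name, lethality epsilon and the zero-flux
        tolerance used when extracting flux supports.
    """

    def __init__(self, model: MetabolicModel, config: Optional[AnalysisConfig] = None):
        self.model = model
        self.config = config or AnalysisConfig()
        self._rxn_pos = {r.id: i for i, r in enumerate(model.reactions)}
        met_pos = {m.id: i for i, m in enumerate(model.metabolites)}
        n_met, n_rxn = len(model.metabolites), len(model.reactions)
        rows, cols, vals = [], [], []
        for j, r in enumerate(model.reactions):
            for m, c in r.stoichiometry.items():
                rows.append(met_pos[m])
                cols.append(j)
                vals.append(float(c))
        self.S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(n_met, n_rxn), dtype=float
        )
        self.lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        self.ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
        self.obj_idx = self._rxn_pos[model.objective_id]
        self._c = np.zeros(n_rxn)
        self._c[self.obj_idx] = -1.0
        self._b_eq = np.zeros(n_met)
        self._wild_type: Optional[float] = None
        self._lethal_cache: Dict[FrozenSet[int], bool] = {}
        self._support_cache: Dict[FrozenSet[int], FrozenSet[int]] = {}
        self._lp_count = 0

    # -- low-level ------------------------------------------------------
    def _method(self) -> str:
        name = self.config.solver_name
        return "highs" if name in ("highs", "default", "") else name

    def _bounds(self, blocked: FrozenSet[int]) -> np.ndarray:
        b = np.column_stack([self.lb, self.ub])
        if blocked:
            idx = list(blocked)
            b[idx, 0] = 0.0
            b[idx, 1] = 0.0
        return b

    def optimize(self, blocked: FrozenSet[int] = frozenset()):
        """Maximize the objective with the given reactions blocked.

        Returns ``(status, objective_value, flux_vector_or_None)``.
        """
        self._lp_count += 1
        res = linprog(
            self._c,
            A_eq=self.S,
            b_eq=self._b_eq,
            bounds=self._bounds(blocked),
            method=self._method(),
        )
        if res.status == 0:
            return "optimal", float(-res.fun), res.x
        if res.status == 2:
            return "infeasible", 0.0, None
        raise FBAError(
            f"LP solver failed (status {res.status}): {res.message}"
        )

    def rxn_indices(self, rxn_ids: Iterable[str]) -> FrozenSet[int]:
        try:
            return frozenset(self._rxn_pos[r] for r in rxn_ids)
        except KeyError as exc:
            raise KeyError(f"unknown reaction id: {exc.args[0]!r}") from None

    # -- cached quantities ----------------------------------------------
    @property
    def wild_type_objective(self) -> float:
        if self._wild_type is None:
            status, value, _ = self.optimize()
            if status != "optimal":
                raise FBAError("wild-type model is infeasible")
            self._wild_type = value
        return self._wild_type

    @property
    def epsilon(self) -> float:
        if self.config.lethality_epsilon is not None:
            return self.config.lethality_epsilon
        return max(1e-6, 1e-3 * self.wild_type_objective)

    @property
    def lp_count(self) -> int:
        """Number of linear programs solved so far (for reporting)."""
        return self._lp_count

    def objective_value(self, blocked: FrozenSet[int] = frozenset()) -> float:
        _, value, _ = self.optimize(blocked)
        return value

    def is_lethal_indices(self, blocked: FrozenSet[int]) -> bool:
        cached = self._lethal_cache.get(blocked)
        if cached is not None:
            return cached
        status, value, _ = self.optimize(blocked)
        lethal = status == "infeasible" or value <= self.epsilon
        self._lethal_cache[blocked] = lethal
        return lethal

    def min_norm_support(self, blocked: FrozenSet[int]) -> FrozenSet[int]:
        """Reactions carrying flux in a minimum-L1-norm optimal solution.

        The flux support of the solution minimizing sum(|v|) subject to mass
        balance, bounds (with ``blocked`` forced to zero) and the objective
        held at its knockout optimum. This is the Fast-SL pruning device: a
        knockout candidate absent from this support can be deleted on top of
        ``blocked`` without disturbing the exhibited optimal solution, hence
        cannot complete a lethal set with it.
        """
        cached = self._support_cache.get(blocked)
        if cached is not None:
            return cached
        status, fmax, _ = self.optimize(blocked)
        if status != "optimal" or fmax <= self.epsilon:
            support: FrozenSet[int] = frozenset()
            self._support_cache[blocked] = support
            return support
        n = len(self.lb)
        # variables [v, u]; minimize sum(u) with -u <= v <= u and v_obj >= t
        c = np.concatenate([np.zeros(n), np.ones(n)])
        A_eq = sparse.hstack([self.S, sparse.csr_matrix(self.S.shape)], format="csr")
        eye = sparse.identity(n, format="csr")
        A_ub = sparse.vstack(
            [
                sparse.hstack([eye, -eye]),      # v - u <= 0
                sparse.hstack([-eye, -eye]),     # -v - u <= 0
            ],
            format="csr",
        )
        b_ub = np.zeros(2 * n)
        t = fmax * (1.0 - 1e-6)
        row = sparse.csr_matrix(
            (np.array([-1.0]), (np.array([0]), np.array([self.obj_idx]))),
            shape=(1, 2 * n),
        )
        A_ub = sparse.vstack([A_ub, row], format="csr")
        b_ub = np.append(b_ub, -t)
        vb = self._bounds(blocked)
        umax = np.maximum(np.abs(vb[:, 0]), np.abs(vb[:, 1]))
        bounds = np.vstack([vb, np.column_stack([np.zeros(n), umax])])
        self._lp_count += 1
        res = linprog(
            c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=A_eq,
            b_eq=self._b_eq,
            bounds=bounds,
            method=self._method(),
        )
        if res.status != 0:
            raise FBAError(
                f"minimum-norm LP failed (status {res.status}): {res.message}"
            )
        v = res.x[:n]
        support = frozenset(np.flatnonzero(np.abs(v) > self.config.zero_flux_tol))
        self._support_cache[blocked] = support
        return support


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def solve_fba(
    model: MetabolicModel, config: Optional[AnalysisConfig] = None
) -> FluxSolution:
    """One-shot FBA on ``model``."""
    session = FBASession(model, config)
    status, value, x = session.optimize()
    fluxes = (
        {r.id: float(x[i]) for i, r in enumerate(model.reactions)}
        if x is not None
        else {}
    )
    return FluxSolution(status=status, objective_value=value, fluxes=fluxes)


def is_lethal(
    model: MetabolicModel,
    knockout: Iterable[str],
    targets: str = "reactions",
    config: Optional[AnalysisConfig] = None,
) -> bool:
    """Whether the knockout abolishes objective flux.

    ``knockout`` holds reaction ids or gene ids according to ``targets``.
    """
    config = config or AnalysisConfig()
    session = FBASession(model, config)
    ko = set(knockout)
    if targets == "reactions":
        blocked = session.rxn_indices(ko)
    elif targets == "genes":
        unknown = ko - set(model.genes)
        if unknown:
            raise KeyError(f"unknown gene ids: {sorted(unknown)}")
        blocked = session.rxn_indices(disabled_reactions(model, ko))
    else:
        raise ValueError(f"unknown target kind: {targets!r}")
    return session.is_lethal_indices(blocked)
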