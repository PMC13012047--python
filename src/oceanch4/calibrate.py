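"""Parameter optimization against cruise transects, and bootstrap.

Every model configuration optimizes five free parameters: the oxidation
pair (k_ox, C_crit) plus the three parameters of its production pathway.
The search is a derivative-free simplex (Nelder–Mead) over transformed
parameters — log for positive quantities, logit for the threshold
fraction b_s, log(q10 - 1) for the Q10 coefficient — so the physical
bounds are enforced by construction.  Each evaluation is one full forward
solution: preindustrial spin-up, historical integration, and the weighted
transect cost.

Uncertainty is propagated by reoptimizing on random 80% subsets of the
datapoints (stratified within each transect so all regions stay
represented), 12 times by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .forcing import gas_exchange_operator
from .model import (
    OxidationParams,
    TimeStepper,
    historical_output_years,
    solve_steady_state,
)
from .observations import cost as transect_cost
from .observations import disequilibrium, sample_model
from .production import PATHWAY_PARAMS, ProductionConfig, production_rate

__all__ = [
    "OptimResult",
    "BootstrapEnsemble",
    "ForwardProblem",
    "optimize",
    "compare_pathways",
    "bootstrap",
    "surface_delta_r2",
    "DEFAULT_INIT",
]

#: order-of-magnitude initial guesses (oxidation pair + pathway parameters)
DEFAULT_INIT = {
    "none": {"k_ox": 0.005, "c_crit": 0.3},
    "npp": {"k_ox": 0.005, "c_crit": 0.3, "a_m": 0.1, "a_n": 0.1, "a_p": 0.1},
    "zoo": {"k_ox": 0.005, "c_crit": 0.3, "a_zoo": 0.5, "q10": 2.0, "k_o2": 30.0},
    "dms": {"k_ox": 0.005, "c_crit": 0.3, "a_s": 20.0, "k_s": 2.0, "b_s": 0.1},
    "labile": {"k_ox": 0.005, "c_crit": 0.3, "a_s": 20.0, "k_s": 5.0, "b_s": 0.1},
    "semilabile": {"k_ox": 0.005, "c_crit": 0.3, "a_s": 20.0, "k_s": 5.0, "b_s": 0.1},
    "po4": {"k_ox": 0.005, "c_crit": 0.3, "a_0": 10.0, "p_crit": 0.3, "w": 0.2},
    "po4_semilabile": {"k_ox": 0.005, "c_crit": 0.3, "a_0": 10.0, "p_crit": 0.3, "w": 0.2, "k_s": 5.0},
    "npp_plus_po4": {"k_ox": 0.005, "c_crit": 0.3, "a_m": 0.1, "a_n": 0.1, "a_p": 0.1,
                     "a_0": 10.0, "p_crit": 0.3, "w": 0.2},
}

_EPS = 1e-12


def _param_names(pathway: str) -> list[str]:
    return ["k_ox", "c_crit", *PATHWAY_PARAMS[pathway]]


def _to_transformed(params: dict, names: list[str]) -> np.ndarray:
    out = []
    for n in names:
        v = float(params[n])
        if n == "b_s":
            v = min(max(v, _EPS), 1.0 - 1e-9)
            out.append(np.log(v / (1.0 - v)))
        elif n == "q10":
            out.append(np.log(max(v - 1.0, _EPS)))
        else:
            out.append(np.log(max(v, _EPS)))
    return np.array(out)


def _from_transformed(x: np.ndarray, names: list[str]) -> dict:
    params = {}
    for v, n in zip(x, names):
        if n == "b_s":
            params[n] = float(1.0 / (1.0 + np.exp(-v)))
        elif n == "q10":
            params[n] = float(1.0 + np.exp(v))
        else:
            params[n] = float(np.exp(v))
    return params


@dataclass
class OptimResult:
    """Outcome of one optimization: best parameters and bookkeeping."""

    pathway: str
    params: dict
    cost: float
    initial_cost: float
    per_transect_rmse: dict
    n_forward: int
    converged: bool
    seed: int
    r2_surface: float | None = None

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps({
            "pathway": self.pathway,
            "params": self.params,
            "cost": self.cost,
            "initial_cost": self.initial_cost,
            "per_transect_rmse": self.per_transect_rmse,
            "n_forward": self.n_forward,
            "converged": self.converged,
            "seed": self.seed,
            "r2_surface": self.r2_surface,
        }, indent=2))


@dataclass
class BootstrapEnsemble:
    """Reoptimizations on random data subsets and their spread."""

    pathway: str
    members: list
    subset_fractions: list
    param_names: list
    failures: int = 0

    @property
    def param_matrix(self) -> np.ndarray:
        return np.array([[m.params[n] for n in self.param_names] for m in self.members])

    def mean(self) -> dict:
        mat = self.param_matrix
        return dict(zip(self.param_names, mat.mean(axis=0)))

    def sd(self) -> dict:
        """Raw ensemble standard deviation per parameter."""
        mat = self.param_matrix
        return dict(zip(self.param_names, mat.std(axis=0, ddof=1)))

    def sd_full_sample(self) -> dict:
        """Full-sample-equivalent SD via the m-out-of-n correction.

        An estimator refit on a random fraction f of the data (without
        replacement) scatters around the full-data estimate with variance
        (1/m - 1/n) sigma-squared-ish, i.e. a factor (1-f)/f smaller than
        the full estimator's own sampling variance; multiplying the raw
        ensemble SD by sqrt(f/(1-f)) recovers the full-sample error bar.
        """
        f = float(np.mean(self.subset_fractions))
        scale = np.sqrt(f / (1.0 - f))
        return {k: scale * v for k, v in self.sd().items()}

    def summary_csv(self, path) -> None:
        """Per-member parameters and costs, plus mean/sd rows."""
        import pandas as pd

        rows = [
            {"member": i, "seed": m.seed, "cost": m.cost,
             **{k: m.params[k] for k in self.param_names}}
            for i, m in enumerate(self.members)
        ]
        df = pd.DataFrame(rows)
        mean = {"member": "mean", "seed": "", "cost": df["cost"].mean(), **self.mean()}
        sd = {"member": "sd", "seed": "", "cost": df["cost"].std(ddof=1), **self.sd()}
        pd.concat([df, pd.DataFrame([mean, sd])], ignore_index=True).to_csv(path, index=False)


class ForwardProblem:
    """Binds a world and a transect set; evaluates parameter vectors.

    Holds the cached time stepper (the Crank–Nicolson factorization does
    not depend on the optimized parameters), the output cadence, and the
    forward-solve counter.  The integration runs to the latest cruise
    year; output snapshots include every cruise year so the time
    interpolation there is exact.
    """

    def __init__(self, world, transects, pathway: str, dt: float = 0.5):
        if not transects:
            raise ValueError("at least one transect is required")
        self.world = world
        self.transects = list(transects)
        self.pathway = pathway
        self.gx = gas_exchange_operator(world.forcing, world.grid)
        self.stepper = TimeStepper(world.transport, self.gx, world.grid, dt=dt)
        self.t_end = max(c.year for c in transects)
        cruise_years = np.array(sorted({c.year for c in transects}))
        self.output_years = np.union1d(historical_output_years(self.t_end), cruise_years)
        self.n_forward = 0

    def run(self, params: dict):
        """One forward solution; returns (states, predictions per transect)."""
        self.n_forward += 1
        ox = OxidationParams(k_ox=params["k_ox"], c_crit=params["c_crit"])
        prod = ProductionConfig(
            self.pathway, {k: params[k] for k in PATHWAY_PARAMS[self.pathway]}
        )
        jp = production_rate(self.world.bio, prod, self.world.grid)
        ss = solve_steady_state(
            self.world.transport, self.gx, jp, ox, self.world.grid,
            self.world.atmosphere.preindustrial_ppb,
        )
        states = self.stepper.run(
            ss, jp, ox, self.world.atmosphere, self.t_end, output_years=self.output_years
        )
        preds = [sample_model(states, c, self.world.grid) for c in self.transects]
        return states, preds

    def cost_of(self, params: dict) -> float:
        try:
            _, preds = self.run(params)
        except RuntimeError:
            return 1e3  # solver failure: repel the simplex
        return transect_cost(preds, self.transects).total


def optimize(
    pathway: str,
    init_params: dict | None,
    transects,
    world,
    max_forward: int = 400,
    n_restarts: int = 2,
    dt: float = 0.5,
    seed: int = 0,
    problem: ForwardProblem | None = None,
) -> OptimResult:
    """Minimize the transect cost over the five (or more) free parameters.

    Simplex search with ``n_restarts`` restarts from a jittered best point
    (the piecewise-linear oxidation threshold can flatten the cost
    surface locally); the total budget is capped at ``max_forward``
    forward solutions and exceeding it flags the result non-converged.
    """
    init = dict(DEFAULT_INIT[pathway]) if init_params is None else dict(init_params)
    names = _param_names(pathway)
    prob = problem or ForwardProblem(world, transects, pathway, dt=dt)
    rng = np.random.default_rng(seed)

    def fun(x):
        return prob.cost_of(_from_transformed(x, names))

    x_best = _to_transformed(init, names)
    initial_cost = fun(x_best)
    f_best = initial_cost
    start = prob.n_forward
    n_stages = 1 + n_restarts
    for stage in range(n_stages):
        remaining = max_forward - (prob.n_forward - start)
        if remaining <= len(names) + 1:
            break
        budget = min(remaining, max(max_forward // n_stages, len(names) + 2))
        x0 = x_best if stage == 0 else x_best + rng.normal(0.0, 0.05, size=x_best.size)
        res = minimize(
            fun, x0, method="Nelder-Mead",
            options={"maxfev": budget, "xatol": 1e-3, "fatol": 1e-6, "adaptive": True},
        )
        if res.fun < f_best:
            f_best = float(res.fun)
            x_best = np.asarray(res.x)

    params = _from_transformed(x_best, names)
    n_used = prob.n_forward - start
    _, preds = prob.run(params)
    breakdown = transect_cost(preds, prob.transects)
    return OptimResult(
        pathway=pathway,
        params=params,
        cost=breakdown.total,
        initial_cost=float(initial_cost),
        per_transect_rmse=dict(zip(breakdown.cruise_ids, breakdown.rmse)),
        n_forward=n_used,
        converged=n_used < max_forward,
        seed=seed,
    )


def surface_delta_r2(predictions, transects, world) -> float:
    """R² of predicted vs. observed surface (top 100 m) disequilibrium.

    R² = 1 - SSE/SST over all surface samples pooled across transects;
    can be negative when the model does worse than the observed mean.
    """
    obs_all, pred_all = [], []
    for pred, c in zip(predictions, transects):
        d_obs, surf = disequilibrium(c, world.forcing, world.atmosphere, world.grid)
        d_pred, _ = disequilibrium(
            c, world.forcing, world.atmosphere, world.grid, values=pred
        )
        obs_all.append(d_obs[surf])
        pred_all.append(d_pred[surf])
    obs = np.concatenate(obs_all)
    pred = np.concatenate(pred_all)
    sse = float(((obs - pred) ** 2).sum())
    sst = float(((obs - obs.mean()) ** 2).sum())
    return 1.0 - sse / sst if sst > 0 else np.nan


def compare_pathways(
    transects,
    world,
    pathways,
    inits: dict | None = None,
    **opt_kwargs,
) -> list[OptimResult]:
    """Optimize each pathway on the same data; rank by cost.

    Attaches the surface-disequilibrium R² to each result (the companion
    skill metric for the geographic supersaturation pattern).
    """
    results = []
    for pathway in pathways:
        init = None if inits is None else inits.get(pathway)
        res = optimize(pathway, init, transects, world, **opt_kwargs)
        prob = ForwardProblem(world, transects, pathway, dt=opt_kwargs.get("dt", 0.5))
        _, preds = prob.run(res.params)
        res.r2_surface = surface_delta_r2(preds, transects, world)
        results.append(res)
    return sorted(results, key=lambda r: r.cost)


def _stratified_subset(transect, frac: float, rng) -> np.ndarray:
    n = transect.n_samples
    n_keep = max(1, int(round(frac * n)))
    return np.sort(rng.choice(n, size=n_keep, replace=False))


def bootstrap(
    pathway: str,
    transects,
    world,
    init_params: dict | None = None,
    n_rep: int = 12,
    frac: float = 0.8,
    seed: int = 0,
    resample_unit: str = "datapoints",
    **opt_kwargs,
) -> BootstrapEnsemble:
    """Reoptimize on random 80% data subsets to propagate uncertainty.

    The default resampling unit is datapoints stratified within each
    transect, which keeps every region represented in every member;
    ``resample_unit='transects'`` draws whole transects instead.  Member
    seeds are derived from ``seed`` by fixed offsets.  A failed member is
    recorded and skipped; the ensemble proceeds if at least half succeed.
    """
    members, fractions = [], []
    failures = 0
    for m in range(n_rep):
        member_seed = seed + 7919 * (m + 1)
        rng = np.random.default_rng(member_seed)
        if resample_unit == "transects":
            k = max(1, int(round(frac * len(transects))))
            idx = rng.choice(len(transects), size=k, replace=False)
            subset = [transects[i] for i in sorted(idx)]
        else:
            subset = [c.subset(_stratified_subset(c, frac, rng)) for c in transects]
        try:
            res = optimize(
                pathway, init_params, subset, world, seed=member_seed, **opt_kwargs
            )
        except (RuntimeError, ValueError):
            failures += 1
            continue
        members.append(res)
        n_tot = sum(c.n_samples for c in transects)
        n_sub = sum(c.n_samples for c in subset)
        fractions.append(n_sub / n_tot)
    if len(members) < n_rep / 2:
        raise RuntimeError(f"bootstrap failed: only {len(members)}/{n_rep} members succeeded")
    return BootstrapEnsemble(
        pathway=pathway,
        members=members,
        subset_fractions=fractions,
        param_names=_param_names(pathway),
        failures=failures,
    )
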