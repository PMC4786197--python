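"""Normalized multi-objective cost and bounded Nelder-Mead optimization.

Each protocol contributes a sum of squared errors between observed and
simulated summary points, divided by its number of points so a 9-point
availability curve and a single mean-open-time value weigh equally per unit
misfit.  Per-protocol costs are mutually independent (fork), evaluated
optionally in parallel, and combined in fixed registration order (join) so
the total is bitwise reproducible for any worker count.

The search is a derivative-free Nelder-Mead simplex on a smooth bounded
transform of parameter space (log for one-sided positivity bounds, sin^2 for
two-sided boxes), terminating when both the simplex cost spread and the
parameter spread fall below their tolerances.  Sequential/factorial protocol
scheduling and perturbation restarts support the initial-condition analyses.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from joblib import Parallel, delayed
from scipy.optimize import minimize

from .errors import AlignmentError, InvalidStartError, ParameterDomainError

_INF = float("inf")


@dataclass
class ExperimentDataset:
    """Observed summary points for one protocol.

    ``x`` is the protocol sweep axis (mV, ms, Hz or pulse index), ``y`` the
    observed values (dimensionless fractions or ms), ``sd`` optional
    per-point standard deviations (annotation only; the cost is unweighted).
    """

    protocol: str
    x: np.ndarray
    y: np.ndarray
    sd: Optional[np.ndarray] = None
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise AlignmentError("x and y must be 1-D arrays of equal length")
        if self.x.size < 1:
            raise AlignmentError("dataset needs at least one point")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.x.shape:
                raise AlignmentError("sd must match x in length")

    @property
    def n_points(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class OptimizerOptions:
    """Options for the bounded simplex search.

    ``cost_tol``/``param_tol`` are the simplex spread tolerances on the cost
    function and the (transformed) parameters; convergence requires both
    simultaneously.  Bounds are per-parameter (lower, upper) with ``inf``
    allowed; the default is positivity.
    """

    cost_tol: float = 0.01
    param_tol: float = 0.01
    max_iter: int = 2000
    lower: Optional[np.ndarray] = None
    upper: Optional[np.ndarray] = None
    seed: Optional[int] = None
    workers: int = 1

    def __post_init__(self) -> None:
        if self.cost_tol <= 0 or self.param_tol <= 0:
            raise ParameterDomainError("tolerances must be positive")


@dataclass
class CostReport:
    """Per-protocol normalized SSE decomposition of one cost evaluation."""

    components: Dict[str, float]
    total: float
    iteration: Optional[int] = None

    @classmethod
    def from_components(cls, components: Dict[str, float], iteration=None) -> "CostReport":
        return cls(components=dict(components), total=float(sum(components.values())),
                   iteration=iteration)


def protocol_cost(dataset: ExperimentDataset, simulated: Sequence[float]) -> float:
    """Sum of squared errors divided by the number of points of the protocol."""
    sim = np.asarray(simulated, dtype=float)
    if sim.shape != dataset.y.shape:
        raise AlignmentError(
            f"simulated readouts for {dataset.protocol!r} have length {sim.size}, "
            f"dataset has {dataset.n_points}"
        )
    return float(np.sum((sim - dataset.y) ** 2) / dataset.n_points)


def total_cost(
    datasets: Sequence[ExperimentDataset],
    simulate: Callable[[ExperimentDataset], Sequence[float]],
    workers: int = 1,
) -> CostReport:
    """Fork-join evaluation of all protocol costs.

    ``simulate`` maps a dataset to its simulated readouts (aligned 1:1 with
    ``dataset.x``).  Evaluations are independent; with ``workers > 1`` they
    run in a joblib pool.  A failing protocol contributes an infinite cost
    (sentinel) instead of raising, so a pathological parameter set does not
    abort the simplex.  The combination is ordered by dataset registration,
    making the report identical for any worker count.
    """

    def one(ds: ExperimentDataset) -> float:
        try:
            return protocol_cost(ds, simulate(ds))
        except AlignmentError:
            raise
        except Exception:
            return _INF

    if workers > 1 and len(datasets) > 1:
        values = Parallel(n_jobs=workers, backend="threading")(
            delayed(one)(ds) for ds in datasets
        )
    else:
        values = [one(ds) for ds in datasets]
    components = {ds.protocol: v for ds, v in zip(datasets, values)}
    return CostReport.from_components(components)


# ---------------------------------------------------------------------------
# bounded transform

class BoundedTransform:
    """Smooth invertible map between bounded parameters and free variables.

    Per coordinate: unbounded -> identity; lower bound only -> x = lb + e^z
    (boundary reachable in the limit); two-sided -> x = lb + (ub-lb) sin^2(z),
    mirroring the classic bounded-simplex trick so the simplex never leaves
    the box yet moves freely.
    """

    def __init__(self, lower: Optional[Sequence[float]], upper: Optional[Sequence[float]], n: int):
        self.lb = np.full(n, -np.inf) if lower is None else np.asarray(lower, dtype=float)
        self.ub = np.full(n, np.inf) if upper is None else np.asarray(upper, dtype=float)
        if self.lb.shape != (n,) or self.ub.shape != (n,):
            raise ParameterDomainError("bounds must match the parameter dimension")
        if np.any(self.lb >= self.ub):
            raise ParameterDomainError("lower bounds must be below upper bounds")

    def to_free(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = np.empty_like(x)
        for i, (v, lo, hi) in enumerate(zip(x, self.lb, self.ub)):
            if np.isinf(lo) and np.isinf(hi):
                z[i] = v
            elif np.isinf(hi):
                if v <= lo:
                    raise ParameterDomainError(f"start value {v} at/below lower bound {lo}")
                z[i] = math.log(v - lo)
            elif np.isinf(lo):
                if v >= hi:
                    raise ParameterDomainError(f"start value {v} at/above upper bound {hi}")
                z[i] = math.log(hi - v)
            else:
                if not lo <= v <= hi:
                    raise ParameterDomainError(f"start value {v} outside [{lo}, {hi}]")
                frac = (v - lo) / (hi - lo)
                z[i] = math.asin(math.sqrt(frac))
        return z

    def to_bounded(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        x = np.empty_like(z)
        for i, (v, lo, hi) in enumerate(zip(z, self.lb, self.ub)):
            if np.isinf(lo) and np.isinf(hi):
                x[i] = v
            elif np.isinf(hi):
                x[i] = lo + math.exp(min(v, 700.0))
            elif np.isinf(lo):
                x[i] = hi - math.exp(min(v, 700.0))
            else:
                x[i] = lo + (hi - lo) * math.sin(v) ** 2
        return x


@dataclass
class OptimizationResult:
    """Outcome of one bounded Nelder-Mead run."""

    x: np.ndarray
    cost: float
    iterations: int
    n_evaluations: int
    converged: bool
    history: List[Tuple[int, float]] = field(default_factory=list)


def minimize_bounded(
    cost: Callable[[np.ndarray], float],
    x0: Sequence[float],
    options: OptimizerOptions,
) -> OptimizationResult:
    """Bounded Nelder-Mead minimization of ``cost`` starting at ``x0``.

    ``cost`` receives parameters in the original (bounded) space and may
    return ``inf`` for pathological regions; an infinite cost at the start
    raises InvalidStartError.  The best-so-far cost per iteration is logged in
    ``history``.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    tr = BoundedTransform(options.lower, options.upper, n)
    z0 = tr.to_free(x0)

    f0 = cost(x0)
    if not np.isfinite(f0):
        raise InvalidStartError("cost is not finite at the initial point")

    history: List[Tuple[int, float]] = []

    def objective(z: np.ndarray) -> float:
        v = cost(tr.to_bounded(z))
        return v if np.isfinite(v) else _INF

    it_counter = {"i": 0}

    def callback(zk):
        it_counter["i"] += 1
        history.append((it_counter["i"], float(objective_best["f"])))

    objective_best = {"f": f0}

    def tracking_objective(z):
        v = objective(z)
        if v < objective_best["f"]:
            objective_best["f"] = v
        return v

    res = minimize(
        tracking_objective,
        z0,
        method="Nelder-Mead",
        callback=callback,
        options={
            "xatol": options.param_tol,
            "fatol": options.cost_tol,
            "maxiter": options.max_iter,
            "adaptive": n > 6,
        },
    )
    return OptimizationResult(
        x=tr.to_bounded(res.x),
        cost=float(res.fun),
        iterations=int(res.nit),
        n_evaluations=int(res.nfev),
        converged=bool(res.success),
        history=history,
    )


def sequential_schedule(
    cost_builder: Callable[[Sequence[int]], Callable[[np.ndarray], float]],
    n_groups: int,
    x0: Sequence[float],
    options: OptimizerOptions,
    block_iterations: int = 100,
    ordering_mode: str = "all-factorial",
    orderings: Optional[Sequence[Sequence[int]]] = None,
    final_options: Optional[OptimizerOptions] = None,
) -> Dict[str, object]:
    """Sequential (cumulative) protocol-group optimization over orderings.

    ``cost_builder(group_indices)`` returns the cost function restricted to
    those protocol groups.  For each ordering of the ``n_groups`` groups the
    search runs ``block_iterations`` Nelder-Mead iterations on group 1, then
    on groups 1+2, and so on (``n_groups * block_iterations`` scheduled
    initial iterations); the ordering with the lowest scheduled cost is then
    continued to convergence on all groups.  ``ordering_mode`` is ``"one"``
    (identity ordering only) or ``"all-factorial"`` (every permutation, 4! =
    24 orderings for four groups).
    """
    if n_groups < 1:
        raise ParameterDomainError("need at least one protocol group")
    x0 = np.asarray(x0, dtype=float)
    if orderings is None:
        if ordering_mode == "one":
            orderings = [tuple(range(n_groups))]
        elif ordering_mode == "all-factorial":
            orderings = list(itertools.permutations(range(n_groups)))
        else:
            raise ParameterDomainError(f"unknown ordering_mode {ordering_mode!r}")

    if n_groups == 1:
        full = cost_builder(list(range(n_groups)))
        res = minimize_bounded(full, x0, options)
        return {"orderings": {(0,): res}, "best_ordering": (0,), "final": res}

    block_opts = OptimizerOptions(
        cost_tol=1e-12, param_tol=1e-12, max_iter=block_iterations,
        lower=options.lower, upper=options.upper, workers=options.workers,
    )
    per_ordering: Dict[Tuple[int, ...], OptimizationResult] = {}
    for ordering in orderings:
        x = x0.copy()
        res = None
        for k in range(1, len(ordering) + 1):
            fk = cost_builder(list(ordering[:k]))
            res = minimize_bounded(fk, x, block_opts)
            x = res.x
        per_ordering[tuple(ordering)] = res
    best = min(per_ordering, key=lambda o: per_ordering[o].cost)
    full = cost_builder(list(range(n_groups)))
    final = minimize_bounded(full, per_ordering[best].x, final_options or options)
    return {"orderings": per_ordering, "best_ordering": best, "final": final}


def restart_perturbed(
    cost: Callable[[np.ndarray], float],
    x: Sequence[float],
    options: OptimizerOptions,
    pct: float = 10.0,
    seed: Optional[int] = None,
) -> OptimizationResult:
    """Re-run the optimization from a +/- pct% multiplicative random restart.

    Each parameter is multiplied by an independent uniform factor in
    [1 - pct/100, 1 + pct/100], clipped to the bounds, and the search is
    restarted; the perturbation is reproducible through ``seed``.
    """
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed if seed is not None else options.seed)
    factors = rng.uniform(1.0 - pct / 100.0, 1.0 + pct / 100.0, size=x.size)
    xp = x * factors
    lo = options.lower if options.lower is not None else np.full(x.size, -np.inf)
    hi = options.upper if options.upper is not None else np.full(x.size, np.inf)
    eps = 1e-12
    xp = np.minimum(np.maximum(xp, np.asarray(lo) + eps), np.asarray(hi) - eps)
    return minimize_bounded(cost, xp, options)


# ---------------------------------------------------------------------------
# glue between datasets, protocols and channel models

class MultiProtocolObjective:
    """Cost function over a battery of protocol datasets for a channel model.

    ``model_builder(x, dataset)`` turns a parameter vector into the
    :class:`~navfit.clamp_engine.ChannelModel` appropriate for that dataset
    (drug concentration and neutral-analog conditions travel in
    ``dataset.meta``).  Each dataset's protocol is re-swept onto the
    dataset's x-axis so simulation and observation align 1:1.  Calling the
    objective returns the total normalized cost; :meth:`report` returns the
    per-protocol decomposition.
    """

    def __init__(
        self,
        datasets: Sequence[ExperimentDataset],
        protocols: Dict[str, object],
        model_builder: Callable[[np.ndarray, ExperimentDataset], object],
        workers: int = 1,
        sample_dt: float = 0.05,
    ):
        from dataclasses import replace as _replace

        self.datasets = list(datasets)
        self.model_builder = model_builder
        self.workers = workers
        self.sample_dt = sample_dt
        self._protocols = {}
        for ds in self.datasets:
            base_name = str(ds.meta.get("base_protocol", ds.protocol))
            if base_name not in protocols:
                raise AlignmentError(f"dataset names unknown protocol {base_name!r}")
            proto = protocols[base_name]
            self._protocols[ds.protocol] = _replace(proto, sweep=tuple(ds.x))

    def simulate(self, x: np.ndarray, dataset: ExperimentDataset) -> np.ndarray:
        from .clamp_engine import run_protocol

        model = self.model_builder(np.asarray(x, dtype=float), dataset)
        proto = self._protocols[dataset.protocol]
        results = run_protocol(model, proto, sample_dt=self.sample_dt)
        return np.array([r.value for r in results])

    def report(self, x: np.ndarray) -> CostReport:
        return total_cost(
            self.datasets, lambda ds: self.simulate(x, ds), workers=self.workers
        )

    def __call__(self, x: np.ndarray) -> float:
        return self.report(x).total

    def subset(self, indices: Sequence[int]) -> "MultiProtocolObjective":
        obj = MultiProtocolObjective.__new__(MultiProtocolObjective)
        obj.datasets = [self.datasets[i] for i in indices]
        obj.model_builder = self.model_builder
        obj.workers = self.workers
        obj.sample_dt = self.sample_dt
        obj._protocols = self._protocols
        return obj


def drug_free_objective(
    datasets: Sequence[ExperimentDataset],
    protocols: Dict[str, object],
    workers: int = 1,
    sample_dt: float = 0.05,
) -> MultiProtocolObjective:
    """Objective over the drug-free battery; x is the 16-parameter vector."""
    from .clamp_engine import ChannelModel
    from .core_model import RateParams

    def builder(x, _ds):
        return ChannelModel(RateParams.from_vector(x))

    return MultiProtocolObjective(datasets, protocols, builder, workers, sample_dt)


def drug_objective(
    datasets: Sequence[ExperimentDataset],
    protocols: Dict[str, object],
    params,
    drug_template,
    scalar_names: Sequence[str],
    fixed_scalars: Optional[Dict[str, float]] = None,
    workers: int = 1,
    sample_dt: float = 0.05,
) -> MultiProtocolObjective:
    """Objective over drug protocols; x holds the named drug scalars.

    ``params`` (drug-free rates) and the remaining scalars stay fixed.  Each
    dataset's ``meta`` may set ``concentration`` (molar) and
    ``neutral_analog`` (True forces a fully neutral species, emulating the
    neutral flecainide derivative used to isolate the neutral rates).
    """
    from dataclasses import replace as _replace

    from .clamp_engine import ChannelModel
    from .drug_extension import DrugScalars

    fixed = dict(fixed_scalars or {})
    names = list(scalar_names)

    def builder(x, ds):
        values = dict(fixed)
        values.update(dict(zip(names, x)))
        scalars = DrugScalars(**values)
        conc = float(ds.meta.get("concentration", drug_template.concentration))
        spec = _replace(
            drug_template,
            concentration=conc,
            charged_fraction_override=0.0
            if ds.meta.get("neutral_analog", False)
            else drug_template.charged_fraction_override,
        )
        return ChannelModel(params, drug=spec, scalars=scalars)

    return MultiProtocolObjective(datasets, protocols, builder, workers, sample_dt)


def two_stage_drug_fit(
    neutral_datasets: Sequence[ExperimentDataset],
    charged_datasets: Sequence[ExperimentDataset],
    protocols: Dict[str, object],
    params,
    drug_template,
    initial_scalars,
    options: OptimizerOptions,
    sample_dt: float = 0.05,
) -> Tuple[object, OptimizationResult, OptimizationResult]:
    """Neutral-then-charged two-stage drug parameter fit.

    Stage 1 optimizes the 8 neutral scalars against the neutral-analog
    datasets; after convergence those rates are frozen while stage 2
    optimizes the 8 charged scalars over the charged-drug battery.  Returns
    (fitted DrugScalars, stage-1 result, stage-2 result).
    """
    from .drug_extension import CHARGED_SCALAR_NAMES, DrugScalars, NEUTRAL_SCALAR_NAMES

    init = initial_scalars.to_dict()
    neutral_obj = drug_objective(
        neutral_datasets, protocols, params, drug_template,
        NEUTRAL_SCALAR_NAMES, fixed_scalars=init, workers=options.workers,
        sample_dt=sample_dt,
    )
    x0n = np.array([init[n] for n in NEUTRAL_SCALAR_NAMES])
    res_n = minimize_bounded(neutral_obj, x0n, options)
    fitted = dict(init)
    fitted.update(dict(zip(NEUTRAL_SCALAR_NAMES, res_n.x)))

    charged_obj = drug_objective(
        charged_datasets, protocols, params, drug_template,
        CHARGED_SCALAR_NAMES, fixed_scalars=fitted, workers=options.workers,
        sample_dt=sample_dt,
    )
    x0c = np.array([fitted[n] for n in CHARGED_SCALAR_NAMES])
    res_c = minimize_bounded(charged_obj, x0c, options)
    fitted.update(dict(zip(CHARGED_SCALAR_NAMES, res_c.x)))
    return DrugScalars(**fitted), res_n, res_c
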