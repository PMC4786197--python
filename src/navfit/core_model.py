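"""Drug-free 8-state Markov scheme of the cardiac Na+ channel.

The wild-type scheme has three closed states (C3, C2, C1), one conducting open
state (O), fast- and slow-inactivated states (IF, IS) and two closed-inactivated
states (IC3, IC2).  Twelve voltage-dependent transition rates are generated
from 16 free scalar parameters; the recovery rate IF->O (beta2) is never free
but is constrained by microscopic reversibility around the C1-O-IF loop:

    beta2 = (alpha13 * alpha2 * alpha3) / (beta13 * beta3)

so that at equilibrium the product of forward rates equals the product of
reverse rates on every closed loop of the scheme.

The master equation is written dP/dt = Q P with the *columns-as-source*
convention: Q[j, i] is the rate from state i to state j, and every column of Q
sums to zero (probability conservation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Dict, List, Mapping, Sequence, Tuple

import networkx as nx
import numpy as np

from .errors import (
    DetailedBalanceError,
    EquilibriumError,
    GeneratorError,
    ParameterDomainError,
    RateEvaluationError,
    SchemeDefinitionError,
)

#: exponent cap; exp() is evaluated in log space and clipped at e**EXP_CAP so
#: that extreme voltages explored by the optimizer cannot overflow to inf.
EXP_CAP = 700.0

#: the 16 free parameters of the drug-free model, in canonical order.
PARAM_NAMES: Tuple[str, ...] = (
    "a11_v1",
    "a11_v2",
    "a12",
    "a13",
    "b11_v1",
    "b11_v2",
    "b12",
    "b13",
    "a3_v1",
    "a3_v2",
    "b3_v1",
    "b3_v2",
    "a2_v1",
    "a2_v2",
    "ax",
    "bx",
)

#: the 12 transition-rate labels; beta2 is the reversibility-constrained one.
RATE_LABELS: Tuple[str, ...] = (
    "a11",
    "a12",
    "a13",
    "b11",
    "b12",
    "b13",
    "a3",
    "b3",
    "a2",
    "b2",
    "ax",
    "bx",
)

#: independent rate constants (all labels except the constrained beta2).
N_INDEPENDENT_RATES = len(RATE_LABELS) - 1


@dataclass(frozen=True)
class RateParams:
    """The 16 free, strictly positive scalar parameters of the drug-free model.

    ``a11_v1``/``b11_v1`` carry ms (they sit under a reciprocal), ``a11_v2``,
    ``b11_v2``, ``a3_v2``, ``b3_v2``, ``a2_v2`` are voltage slopes in mV,
    ``a3_v1``/``b3_v1``/``a2_v1`` are ms^-1, and ``a12``, ``a13``, ``b12``,
    ``b13``, ``ax``, ``bx`` are dimensionless multipliers.
    """

    a11_v1: float
    a11_v2: float
    a12: float
    a13: float
    b11_v1: float
    b11_v2: float
    b12: float
    b13: float
    a3_v1: float
    a3_v2: float
    b3_v1: float
    b3_v2: float
    a2_v1: float
    a2_v2: float
    ax: float
    bx: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ParameterDomainError(
                    f"parameter {f.name} must be a finite positive number, got {v!r}"
                )

    def to_dict(self) -> Dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "RateParams":
        unknown = set(mapping) - set(PARAM_NAMES)
        if unknown:
            raise ParameterDomainError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(mapping)
        if missing:
            raise ParameterDomainError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "RateParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(PARAM_NAMES),):
            raise ParameterDomainError(
                f"parameter vector must have length {len(PARAM_NAMES)}, got {vec.shape}"
            )
        return cls(**dict(zip(PARAM_NAMES, vec.tolist())))


@dataclass(frozen=True)
class RateSet:
    """The 12 evaluated transition rates (ms^-1) at one membrane potential."""

    a11: float
    a12: float
    a13: float
    b11: float
    b12: float
    b13: float
    a3: float
    b3: float
    a2: float
    b2: float
    ax: float
    bx: float
    V: float = float("nan")  # membrane potential the set was evaluated at (mV)

    def __getitem__(self, label: str) -> float:
        if label not in RATE_LABELS:
            raise KeyError(label)
        return getattr(self, label)

    def to_dict(self) -> Dict[str, float]:
        return {label: float(getattr(self, label)) for label in RATE_LABELS}


@dataclass(frozen=True)
class ChannelScheme:
    """Labelled reversible directed graph of conformational states.

    ``edges`` lists one entry per *directed* transition as
    ``(from_state, to_state, rate_label)``.  Every edge must have its reverse
    present, states must be unique, and each directed edge carries exactly one
    label (labels may be shared between edges, as in the Na+ scheme where
    alpha11 drives both IC3->IC2 and C3->C2).
    """

    states: Tuple[str, ...]
    edges: Tuple[Tuple[str, str, str], ...]
    conducting_states: Tuple[str, ...] = ("O",)

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise SchemeDefinitionError("duplicate state labels")
        known = set(self.states)
        directed = {}
        for frm, to, label in self.edges:
            if frm not in known or to not in known:
                raise SchemeDefinitionError(f"edge ({frm}, {to}) references unknown state")
            if frm == to:
                raise SchemeDefinitionError(f"self-loop on {frm}")
            if (frm, to) in directed:
                raise SchemeDefinitionError(f"duplicate directed edge ({frm}, {to})")
            directed[(frm, to)] = label
        for frm, to in directed:
            if (to, frm) not in directed:
                raise SchemeDefinitionError(
                    f"edge ({frm}, {to}) has no reverse edge; scheme must be reversible"
                )
        for s in self.conducting_states:
            if s not in known:
                raise SchemeDefinitionError(f"conducting state {s} not in states")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)

    def undirected_pairs(self) -> List[Tuple[str, str]]:
        """Each reversible edge once, ordered (frm, to) by first appearance."""
        seen = set()
        pairs = []
        for frm, to, _ in self.edges:
            key = frozenset((frm, to))
            if key not in seen:
                seen.add(key)
                pairs.append((frm, to))
        return pairs

    def label(self, frm: str, to: str) -> str:
        for f, t, lab in self.edges:
            if f == frm and t == to:
                return lab
        raise SchemeDefinitionError(f"no edge ({frm}, {to})")


#: Fig-1 topology of the wild-type channel.  State order fixed for
#: reproducible serialization.
_WT_STATES = ("IC3", "IC2", "IF", "IS", "C3", "C2", "C1", "O")

_WT_EDGES = (
    # closed-inactivated row
    ("IC3", "IC2", "a11"),
    ("IC2", "IC3", "b11"),
    ("IC2", "IF", "a12"),
    ("IF", "IC2", "b12"),
    # closed row / opening
    ("C3", "C2", "a11"),
    ("C2", "C3", "b11"),
    ("C2", "C1", "a12"),
    ("C1", "C2", "b12"),
    ("C1", "O", "a13"),
    ("O", "C1", "b13"),
    # vertical recovery / closed-state inactivation
    ("IC3", "C3", "a3"),
    ("C3", "IC3", "b3"),
    ("IC2", "C2", "a3"),
    ("C2", "IC2", "b3"),
    ("IF", "C1", "a3"),
    ("C1", "IF", "b3"),
    # open-state fast inactivation (b2 constrained by reversibility)
    ("O", "IF", "a2"),
    ("IF", "O", "b2"),
    # slow inactivation
    ("O", "IS", "ax"),
    ("IS", "O", "bx"),
)


def default_scheme() -> ChannelScheme:
    """The wild-type 8-state Na+ channel scheme (10 reversible edges)."""
    return ChannelScheme(states=_WT_STATES, edges=_WT_EDGES, conducting_states=("O",))


def _bounded_exp(x: float, context: str) -> float:
    """exp with a cap at e**EXP_CAP; raises on non-finite argument."""
    if not math.isfinite(x):
        raise RateEvaluationError(f"non-finite exponent while evaluating {context}")
    return math.exp(min(x, EXP_CAP))


def eval_rates(params: RateParams, V: float) -> RateSet:
    """Evaluate the 12 voltage-dependent transition rates at potential V (mV).

    beta2 is always computed from the microscopic-reversibility constraint
    beta2 = alpha13*alpha2*alpha3 / (beta13*beta3); it is never a free
    parameter.  Exponentials are capped (see :data:`EXP_CAP`) so extreme
    voltages met during optimization degrade gracefully instead of
    overflowing.
    """
    if not math.isfinite(V):
        raise RateEvaluationError("membrane potential V must be finite")
    p = params
    a11 = 1.0 / (p.a11_v1 * _bounded_exp(-V / p.a11_v2, "a11"))
    a12 = p.a12 * a11
    a13 = p.a13 * a11
    b11 = 1.0 / (p.b11_v1 * _bounded_exp(V / p.b11_v2, "b11"))
    b12 = p.b12 * b11
    b13 = p.b13 * b11
    a3 = p.a3_v1 * _bounded_exp(-V / p.a3_v2, "a3")
    b3 = p.b3_v1 * _bounded_exp(V / p.b3_v2, "b3")
    a2 = p.a2_v1 * _bounded_exp(V / p.a2_v2, "a2")
    ax = p.ax * a2
    bx = p.bx * a3
    # reversibility closure of the C1-O-IF loop, computed in log space to
    # survive extreme rate magnitudes
    log_b2 = (
        math.log(a13) + math.log(a2) + math.log(a3) - math.log(b13) - math.log(b3)
    )
    b2 = _bounded_exp(log_b2, "b2")
    rates = RateSet(
        a11=a11, a12=a12, a13=a13, b11=b11, b12=b12, b13=b13,
        a3=a3, b3=b3, a2=a2, b2=b2, ax=ax, bx=bx, V=float(V),
    )
    for label in RATE_LABELS:
        v = rates[label]
        if not (math.isfinite(v) and v >= 0):
            raise RateEvaluationError(f"rate {label} evaluated to {v} at V={V}")
    return rates


def build_generator(
    scheme: ChannelScheme, rates: RateSet | Mapping[str, float]
) -> np.ndarray:
    """Assemble the master-equation generator Q (columns-as-source).

    Q[j, i] holds the rate i -> j; diagonal entries make every column sum to
    zero.  Every rate label in the scheme must resolve to a value in
    ``rates``.
    """
    lookup = rates.to_dict() if isinstance(rates, RateSet) else dict(rates)
    n = scheme.n_states
    Q = np.zeros((n, n))
    idx = {s: i for i, s in enumerate(scheme.states)}
    for frm, to, label in scheme.edges:
        if label not in lookup:
            raise SchemeDefinitionError(f"rate label {label!r} not resolvable")
        k = float(lookup[label])
        if not (math.isfinite(k) and k >= 0):
            raise GeneratorError(f"rate {label} = {k} is not a finite non-negative value")
        Q[idx[to], idx[frm]] += k
        Q[idx[frm], idx[frm]] -= k
    return Q


def check_conservative(Q: np.ndarray, rtol: float = 1e-12) -> None:
    """Raise GeneratorError unless columns sum to 0 and off-diagonals are >= 0.

    The zero-sum check is relative to the largest rate magnitude in Q so that
    schemes with very fast rates are not rejected for benign rounding.
    """
    Q = np.asarray(Q)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise GeneratorError("Q must be square")
    scale = max(1.0, float(np.abs(Q).max()))
    col = np.abs(Q.sum(axis=0)).max()
    if col > rtol * scale * Q.shape[0]:
        raise GeneratorError(f"columns do not sum to zero (max |sum| = {col:.3g})")
    off = Q - np.diag(np.diag(Q))
    if off.min() < -rtol * scale:
        raise GeneratorError("negative off-diagonal entry in generator")


def equilibrium_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary occupancy pi with Q pi = 0, sum(pi) = 1, pi >= 0.

    Solved from the one-dimensional null space of Q; a nullity other than one
    (reducible or defective generator) raises EquilibriumError.
    """
    check_conservative(Q)
    n = Q.shape[0]
    if n == 1:
        return np.array([1.0])
    s = np.linalg.svd(Q, compute_uv=False)
    tol = max(Q.shape) * np.abs(s[0] if s.size else 1.0) * np.finfo(float).eps * 100
    nullity = int(np.sum(s <= tol))
    if nullity != 1:
        raise EquilibriumError(
            f"equilibrium not unique: generator null space has dimension {nullity}"
        )
    # solve the augmented system [Q; 1^T] pi = [0; 1]: better conditioned than
    # reading the SVD null vector when rates span many orders of magnitude
    A = np.vstack([Q, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    if pi.min() < -1e-8 * max(pi.max(), 1e-300):
        raise EquilibriumError("stationary vector has significantly negative entries")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _rate_lookup(scheme: ChannelScheme, rates: RateSet | Mapping[str, float]):
    lookup = rates.to_dict() if isinstance(rates, RateSet) else dict(rates)

    def get(frm: str, to: str) -> float:
        return float(lookup[scheme.label(frm, to)])

    return get


def cycle_residuals(
    scheme: ChannelScheme, rates: RateSet | Mapping[str, float]
) -> List[Tuple[Tuple[str, ...], float]]:
    """Log product-ratio residual for each independent cycle of the scheme.

    For each cycle of a cycle basis of the (undirected) scheme graph the
    residual is log(prod forward rates / prod reverse rates); all residuals
    vanish (|r| < 1e-10) iff detailed balance holds.  A zero rate on a cycle
    edge makes the residual undefined and raises DetailedBalanceError.
    """
    get = _rate_lookup(scheme, rates)
    G = nx.Graph()
    G.add_nodes_from(scheme.states)
    G.add_edges_from(scheme.undirected_pairs())
    residuals: List[Tuple[Tuple[str, ...], float]] = []
    for cycle in nx.cycle_basis(G):
        r = 0.0
        m = len(cycle)
        for i in range(m):
            frm, to = cycle[i], cycle[(i + 1) % m]
            fwd, rev = get(frm, to), get(to, frm)
            if fwd <= 0 or rev <= 0:
                raise DetailedBalanceError(
                    f"zero rate on cycle edge ({frm}, {to}); detailed balance undefined"
                )
            r += math.log(fwd) - math.log(rev)
        residuals.append((tuple(cycle), r))
    return residuals
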