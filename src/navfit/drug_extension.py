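"""State-dependent drug block: charged/neutral drug-bound scheme extension.

A weak base such as flecainide partitions between a protonated (charged) and
a neutral species (Henderson-Hasselbalch).  Each species gets its own mirror
copy of the gating scheme:

* the charged species binds only the open state (with an Eyring
  voltage-dependent affinity Kd(V) = Kd0 * exp(-d*V*F/(R*T))) and the closed
  states (affinity evaluated at a fixed reference potential), and its bound
  branch includes an extra trapped inactivated state (DIT);
* the neutral species reaches every conformation: closed and open states bind
  with fixed affinities, inactivated states through the (free) association /
  dissociation pair ki_on / ki_off.

Drug-bound gating rates are scalar multiples of the drug-free rates
(e.g. alphax1 = A * alphax); 8 charged and 8 neutral scalars are free, and
every remaining reverse rate is closed by microscopic reversibility with a
spanning-tree / state-potential construction (:func:`close_cycles`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Dict, List, Mapping, Optional, Tuple

import networkx as nx
import numpy as np

from .core_model import ChannelScheme, RateSet, check_conservative
from .errors import (
    DetailedBalanceError,
    ParameterDomainError,
    ReversibilityError,
    SchemeDefinitionError,
)

#: Faraday's constant (C/mol) and universal gas constant (mJ/(mol*K)); with R
#: in millijoules the ratio F*V/(R*T) is dimensionless for V in mV.
FARADAY = 96485.3415
GAS_CONSTANT = 8314.472


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physical constants used by the Eyring relation."""

    F: float = FARADAY
    R: float = GAS_CONSTANT


CHARGED_SCALAR_NAMES: Tuple[str, ...] = (
    "ax1", "bx1", "a13c", "a22", "b33", "a33", "a44", "b44",
)
NEUTRAL_SCALAR_NAMES: Tuple[str, ...] = (
    "ax2", "a13n", "a_22", "b_33", "a_44", "b_44", "ki_on", "ki_off",
)


@dataclass(frozen=True)
class DrugSpec:
    """Physicochemical constants of the drug (defaults: flecainide, Table-style).

    Units: pKa/pH dimensionless; ``diffusion`` and ``ki_on`` M^-1 ms^-1;
    ``concentration`` and the Kd's in molar; ``d`` the fractional electrical
    charge in [0, 1]; ``T`` kelvin.  ``closed_ref_voltage`` (mV) is where the
    charged closed-state affinity is evaluated.  ``charged_fraction_override``
    forces the charged fraction (e.g. 0.0 for a fully neutral analog such as
    NUFL) instead of computing it from pKa/pH.
    """

    pKa: float = 9.3
    pH: float = 7.4
    diffusion: float = 5500.0
    concentration: float = 0.0
    d: float = 0.7
    T: float = 295.0
    kd0_charged_open: float = 11.2e-6
    kd_neutral_open: float = 400e-6
    kd_neutral_closed: float = 800e-6
    kd_neutral_inactivated: float = 5.4e-6
    closed_ref_voltage: float = -100.0
    charged_fraction_override: Optional[float] = None

    def __post_init__(self) -> None:
        positive = (
            "diffusion", "T", "kd0_charged_open", "kd_neutral_open",
            "kd_neutral_closed", "kd_neutral_inactivated",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParameterDomainError(f"{name} must be positive")
        if self.concentration < 0:
            raise ParameterDomainError("concentration must be >= 0")
        if not 0.0 <= self.d <= 1.0:
            raise ParameterDomainError("fractional charge d must lie in [0, 1]")
        if self.charged_fraction_override is not None and not (
            0.0 <= self.charged_fraction_override <= 1.0
        ):
            raise ParameterDomainError("charged_fraction_override must lie in [0, 1]")

    @property
    def fraction_charged(self) -> float:
        if self.charged_fraction_override is not None:
            return self.charged_fraction_override
        return charged_fraction(self.pKa, self.pH)


@dataclass(frozen=True)
class DrugScalars:
    """The 16 free drug rate scalars (8 charged + 8 neutral).

    All are dimensionless multipliers of drug-free rates except ``ki_on``
    (association rate to neutral-inactivated states, M^-1 ms^-1) and
    ``ki_off`` (the matching dissociation rate, ms^-1).
    """

    # charged branch
    ax1: float = 1.0
    bx1: float = 1.0
    a13c: float = 1.0
    a22: float = 1.0
    b33: float = 1.0
    a33: float = 1.0
    a44: float = 1.0
    b44: float = 1.0
    # neutral branch
    ax2: float = 1.0
    a13n: float = 1.0
    a_22: float = 1.0
    b_33: float = 1.0
    a_44: float = 1.0
    b_44: float = 1.0
    ki_on: float = 5500.0
    ki_off: float = 5.4e-6 * 5500.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ParameterDomainError(f"drug scalar {f.name} must be positive")

    def to_dict(self) -> Dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "DrugScalars":
        valid = CHARGED_SCALAR_NAMES + NEUTRAL_SCALAR_NAMES
        unknown = set(mapping) - set(valid)
        if unknown:
            raise ParameterDomainError(f"unknown drug scalar keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


def charged_fraction(pKa: float, pH: float) -> float:
    """Henderson-Hasselbalch fraction of the protonated (charged) base."""
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def eyring_kd(
    Kd0: float, V: float, d: float, T: float, constants: PhysicalConstants = PhysicalConstants()
) -> float:
    """Voltage-dependent dissociation constant Kd = Kd0 * exp(-d*V*F/(R*T)).

    ``Kd0`` is the affinity at 0 mV (molar), ``V`` in mV, ``d`` the fraction
    of the membrane field sensed at the binding site, ``T`` in kelvin.  With R
    in mJ/(mol K) the exponent is dimensionless for millivolt arguments.
    """
    if Kd0 <= 0:
        raise ParameterDomainError("Kd0 must be positive")
    return Kd0 * math.exp(-d * V * constants.F / (constants.R * T))


def binding_rates(concentration: float, D: float, Kd: float) -> Tuple[float, float]:
    """Diffusion-limited binding: kon = [drug]*D, koff = Kd*D (both ms^-1)."""
    if concentration < 0 or D <= 0 or Kd <= 0:
        raise ParameterDomainError("binding_rates requires conc >= 0, D > 0, Kd > 0")
    return concentration * D, Kd * D


# ---------------------------------------------------------------------------
# extended scheme plumbing

Edge = Tuple[str, str]


@dataclass
class ExtendedScheme:
    """Drug-extended scheme: base states plus charged/neutral bound mirrors.

    ``rates`` maps each *directed* edge to its rate in ms^-1, or ``None`` for
    a rate still to be derived by :func:`close_cycles`.  ``edge_map``
    documents the provenance of each assigned drug-branch rate as
    ``(drug-free rate label, scalar name)`` (label ``None`` for binding
    edges); it is data and can be overridden to change the drug-bound
    topology/scalar assignment.
    """

    states: Tuple[str, ...]
    rates: Dict[Edge, Optional[float]]
    conducting_states: Tuple[str, ...] = ("O",)
    base_states: Tuple[str, ...] = ()
    edge_map: Dict[Edge, Tuple[Optional[str], Optional[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.states)
        for frm, to in self.rates:
            if frm not in known or to not in known:
                raise SchemeDefinitionError(f"edge ({frm}, {to}) references unknown state")
            if (to, frm) not in self.rates:
                raise SchemeDefinitionError(f"edge ({frm}, {to}) has no reverse edge")

    def undirected_pairs(self) -> List[Edge]:
        seen, pairs = set(), []
        for frm, to in self.rates:
            key = frozenset((frm, to))
            if key not in seen:
                seen.add(key)
                pairs.append((frm, to))
        return pairs

    @property
    def n_states(self) -> int:
        return len(self.states)

    def to_generator(self) -> np.ndarray:
        """Assemble the columns-as-source generator; all rates must be set."""
        n = len(self.states)
        idx = {s: i for i, s in enumerate(self.states)}
        Q = np.zeros((n, n))
        for (frm, to), k in self.rates.items():
            if k is None:
                raise ReversibilityError(
                    f"rate ({frm} -> {to}) unassigned; run close_cycles first"
                )
            Q[idx[to], idx[frm]] += k
            Q[idx[frm], idx[frm]] -= k
        check_conservative(Q)
        return Q


def extended_cycle_residuals(
    scheme: ExtendedScheme,
) -> List[Tuple[Tuple[str, ...], float]]:
    """Per-cycle log forward/reverse product ratios for an extended scheme."""
    G = nx.Graph()
    G.add_nodes_from(scheme.states)
    G.add_edges_from(scheme.undirected_pairs())
    out = []
    for cycle in nx.cycle_basis(G):
        r = 0.0
        m = len(cycle)
        for i in range(m):
            frm, to = cycle[i], cycle[(i + 1) % m]
            fwd, rev = scheme.rates[(frm, to)], scheme.rates[(to, frm)]
            if not fwd or not rev:
                raise DetailedBalanceError(
                    f"zero/unassigned rate on cycle edge ({frm}, {to})"
                )
            r += math.log(fwd) - math.log(rev)
        out.append((tuple(cycle), r))
    return out


def close_cycles(scheme: ExtendedScheme, rtol: float = 1e-8) -> ExtendedScheme:
    """Fill every unassigned reverse rate so all cycles satisfy detailed balance.

    Construction: edges with both directions assigned define log-potential
    differences between their endpoints (log pi_j - log pi_i =
    log(k_ij / k_ji)); a spanning tree of that subgraph fixes the potentials,
    and every remaining both-assigned edge (a chord) is checked for
    consistency -- a contradiction means the cycle is over-constrained.  Each
    edge with exactly one direction assigned then gets its reverse from the
    potential difference, which makes its fundamental cycle's product ratio
    exactly one.  The operation is idempotent.

    Raises ReversibilityError for over-constrained cycles, under-determined
    edges (endpoints in disconnected potential components) or edges with
    neither direction assigned.
    """
    rates = dict(scheme.rates)
    both: List[Edge] = []
    half: List[Edge] = []
    for frm, to in scheme.undirected_pairs():
        kf, kr = rates[(frm, to)], rates[(to, frm)]
        if kf is None and kr is None:
            raise ReversibilityError(f"edge ({frm}, {to}) has neither direction assigned")
        if kf is not None and kr is not None:
            if kf <= 0 or kr <= 0:
                raise ReversibilityError(f"non-positive assigned rate on ({frm}, {to})")
            both.append((frm, to))
        else:
            half.append((frm, to) if kf is not None else (to, frm))

    # potentials from the both-assigned subgraph: log pi_to - log pi_frm =
    # log(k_frm_to / k_to_frm) along a spanning tree of each component
    G = nx.Graph()
    G.add_nodes_from(scheme.states)
    G.add_edges_from(both)
    phi: Dict[str, float] = {}
    comp_id: Dict[str, int] = {}
    for ci, comp in enumerate(nx.connected_components(G)):
        root = next(iter(comp))
        phi[root] = 0.0
        comp_id[root] = ci
        for parent, child in nx.bfs_edges(G, root):
            d = math.log(rates[(parent, child)]) - math.log(rates[(child, parent)])
            phi[child] = phi[parent] + d
            comp_id[child] = ci
    # consistency of every both-assigned edge against the potentials; a
    # violated chord means its fundamental cycle is over-constrained
    for frm, to in both:
        resid = (math.log(rates[(frm, to)]) - math.log(rates[(to, frm)])) - (
            phi[to] - phi[frm]
        )
        if abs(resid) > rtol:
            raise ReversibilityError(
                f"over-constrained cycle through edge ({frm}, {to}): "
                f"log residual {resid:.3e}"
            )
    # derive missing reverses
    for frm, to in half:
        if comp_id[frm] != comp_id[to]:
            raise ReversibilityError(
                f"cannot derive reverse of ({frm}, {to}): no cycle constrains it "
                "(endpoints not connected by assigned-rate edges)"
            )
        rates[(to, frm)] = rates[(frm, to)] * math.exp(phi[frm] - phi[to])
    return replace(scheme, rates=rates)


# ---------------------------------------------------------------------------
# default flecainide topology

def _charged_states(base: ChannelScheme) -> List[str]:
    return ["D" + s for s in base.states] + ["DIT"]


def _neutral_states(base: ChannelScheme) -> List[str]:
    return ["N" + s for s in base.states]


#: charged drug-bound gating map: directed edge -> (base rate label, scalar
#: name); scalar None means the drug-free rate applies unscaled, rate None in
#: the built scheme means "derived by reversibility".
_CHARGED_GATING: Dict[Edge, Tuple[str, Optional[str]]] = {
    # horizontals, unscaled both ways
    ("DIC3", "DIC2"): ("a11", None),
    ("DIC2", "DIC3"): ("b11", None),
    ("DIC2", "DIF"): ("a12", None),
    ("DIF", "DIC2"): ("b12", None),
    ("DC3", "DC2"): ("a11", None),
    ("DC2", "DC3"): ("b11", None),
    ("DC2", "DC1"): ("a12", None),
    ("DC1", "DC2"): ("b12", None),
    # verticals, scaled symmetrically (a33 up / b33 down)
    ("DIC3", "DC3"): ("a3", "a33"),
    ("DC3", "DIC3"): ("b3", "b33"),
    ("DIC2", "DC2"): ("a3", "a33"),
    ("DC2", "DIC2"): ("b3", "b33"),
    ("DIF", "DC1"): ("a3", "a33"),
    ("DC1", "DIF"): ("b3", "b33"),
    # opening / open-state inactivation; the two reverses are derived
    ("DC1", "DO"): ("a13", "a13c"),
    ("DO", "DIF"): ("a2", "a22"),
    # slow inactivation of the bound channel
    ("DO", "DIS"): ("ax", "ax1"),
    ("DIS", "DO"): ("bx", "bx1"),
    # trapping into / out of DIT
    ("DO", "DIT"): ("a2", "a44"),
    ("DIT", "DO"): ("b2", "b44"),
}
#: charged edges whose rate is derived by close_cycles
_CHARGED_DERIVED: Tuple[Edge, ...] = (("DO", "DC1"), ("DIF", "DO"))

#: neutral drug-bound gating map; exactly one direction per edge is assigned
#: (the mirror states all carry binding edges, so assigning both directions
#: would over-constrain the binding squares); every reverse is derived.
_NEUTRAL_GATING: Dict[Edge, Tuple[str, Optional[str]]] = {
    ("NIC3", "NIC2"): ("a11", "a_44"),
    ("NIC2", "NIF"): ("a12", "a_44"),
    ("NC3", "NC2"): ("a11", None),
    ("NC2", "NC1"): ("a12", None),
    ("NC1", "NO"): ("a13", "a13n"),
    ("NO", "NIF"): ("a2", "a_22"),
    ("NO", "NIS"): ("ax", "ax2"),
    ("NC3", "NIC3"): ("b3", "b_33"),
    ("NC2", "NIC2"): ("b3", "b_33"),
    ("NC1", "NIF"): ("b3", "b_44"),
}
_NEUTRAL_DERIVED: Tuple[Edge, ...] = (
    ("NIC2", "NIC3"), ("NIF", "NIC2"), ("NC2", "NC3"), ("NC1", "NC2"),
    ("NO", "NC1"), ("NIF", "NO"), ("NIS", "NO"),
    ("NIC3", "NC3"), ("NIC2", "NC2"), ("NIF", "NC1"),
)

#: base states the charged species can bind (closed + open only)
_CHARGED_BINDING = ("C3", "C2", "C1", "O")
_NEUTRAL_CLOSED = ("C3", "C2", "C1")
_NEUTRAL_INACTIVATED = ("IC3", "IC2", "IF", "IS")


def build_drug_scheme(
    base: ChannelScheme,
    base_rates: RateSet,
    spec: DrugSpec,
    scalars: DrugScalars,
    V: Optional[float] = None,
) -> Tuple[ExtendedScheme, np.ndarray]:
    """Assemble the drug-extended scheme and its generator at potential V.

    The total concentration is split into charged/neutral fractions by
    Henderson-Hasselbalch; charged binding attaches to the open state with the
    Eyring Kd(V) and to closed states with the Kd at ``closed_ref_voltage``;
    neutral binding attaches everywhere.  Drug-bound gating rates are scalar
    multiples of the drug-free rates per the default edge map, and the
    remaining reverses are closed by :func:`close_cycles`.

    At zero concentration all kon vanish and the drug-bound states are simply
    unreachable; the derived gating rates are concentration-independent (every
    kon in a branch scales linearly with concentration, which cancels in the
    potential differences between two bound states), so closure is performed
    at a surrogate concentration and the true kon are written afterwards.
    """
    if V is None:
        V = base_rates.V
    if not math.isfinite(V):
        raise ParameterDomainError("membrane potential V must be finite")
    f = spec.fraction_charged
    c_plus = spec.concentration * f
    c_neut = spec.concentration * (1.0 - f)
    D = spec.diffusion
    base_lookup = base_rates.to_dict()
    sc = scalars.to_dict()

    states = tuple(base.states) + tuple(_charged_states(base)) + tuple(_neutral_states(base))
    rates: Dict[Edge, Optional[float]] = {}
    edge_map: Dict[Edge, Tuple[Optional[str], Optional[str]]] = {}

    for frm, to, label in base.edges:
        rates[(frm, to)] = base_lookup[label]
        edge_map[(frm, to)] = (label, None)

    def add_gating(mapping, derived):
        for (frm, to), (label, scalar) in mapping.items():
            k = base_lookup[label] * (sc[scalar] if scalar else 1.0)
            rates[(frm, to)] = k
            edge_map[(frm, to)] = (label, scalar)
        for frm, to in derived:
            rates[(frm, to)] = None
            edge_map[(frm, to)] = (None, None)

    add_gating(_CHARGED_GATING, _CHARGED_DERIVED)
    add_gating(_NEUTRAL_GATING, _NEUTRAL_DERIVED)

    # --- binding edges (kon with surrogate concentration for closure) ---
    surrogate_plus = c_plus if c_plus > 0 else 1e-6
    surrogate_neut = c_neut if c_neut > 0 else 1e-6
    kd_open_plus = eyring_kd(spec.kd0_charged_open, V, spec.d, spec.T)
    kd_closed_plus = eyring_kd(
        spec.kd0_charged_open, spec.closed_ref_voltage, spec.d, spec.T
    )
    binding: Dict[Edge, Tuple[float, float]] = {}  # (frm, to)=(base, bound): (kon_true, kon_surrogate)
    for s in _CHARGED_BINDING:
        kd = kd_open_plus if s == "O" else kd_closed_plus
        kon, koff = binding_rates(surrogate_plus, D, kd)
        rates[(s, "D" + s)] = kon
        rates[("D" + s, s)] = koff
        edge_map[(s, "D" + s)] = (None, "kon_charged")
        edge_map[("D" + s, s)] = (None, "koff_charged")
        binding[(s, "D" + s)] = (c_plus * D, kon)
    for s in _NEUTRAL_CLOSED + ("O",):
        kd = spec.kd_neutral_open if s == "O" else spec.kd_neutral_closed
        kon, koff = binding_rates(surrogate_neut, D, kd)
        rates[(s, "N" + s)] = kon
        rates[("N" + s, s)] = koff
        edge_map[(s, "N" + s)] = (None, "kon_neutral")
        edge_map[("N" + s, s)] = (None, "koff_neutral")
        binding[(s, "N" + s)] = (c_neut * D, kon)
    for s in _NEUTRAL_INACTIVATED:
        kon = surrogate_neut * scalars.ki_on
        rates[(s, "N" + s)] = kon
        rates[("N" + s, s)] = scalars.ki_off
        edge_map[(s, "N" + s)] = (None, "ki_on")
        edge_map[("N" + s, s)] = (None, "ki_off")
        binding[(s, "N" + s)] = (c_neut * scalars.ki_on, kon)

    ext = ExtendedScheme(
        states=states,
        rates=rates,
        conducting_states=tuple(base.conducting_states),
        base_states=tuple(base.states),
        edge_map=edge_map,
    )
    ext = close_cycles(ext)
    # restore the true (possibly zero) kon values
    for edge, (kon_true, _) in binding.items():
        ext.rates[edge] = kon_true
    Q = ext.to_generator()
    return ext, Q
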