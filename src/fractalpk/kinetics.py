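"""Fractal-kinetic building blocks for compartment PK models.

Classical compartment models move drug between well-mixed pools at
first-order rates with constant rate coefficients.  Under fractal-like
(heterogeneous-medium) kinetics the coefficient becomes an instantaneous
rate that decays with the time elapsed since dosing,

    rate(t) = theta / t**h,        0 <= h <= 1,

where ``theta`` is the rate coefficient at elapsed time 1 and ``h`` is the
heterogeneity exponent.  ``h = 0`` recovers ordinary Fickian kinetics.  This
module defines the rate object, structural model specifications, and the
right-hand-side assembly for 1- and 2-compartment models with optional
first-order / transit-chain absorption, dose fractionation into fast and
slow pathways, and a per-dose fractal-clock reset.

Amounts are tracked for every pool, including an explicit ``eliminated``
accumulator and (for transit absorption) an ``in_transit`` balance state, so
mass conservation is checkable at any output time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "RATE_NAMES",
    "FractalRate",
    "PKParameters",
    "ModelSpec",
    "DoseEvent",
    "instantaneous_rate",
    "build_rhs",
    "apply_dose_event",
    "stirling_factorial",
]

#: Micro-rate names a fractal exponent may be placed on.
RATE_NAMES = ("Ka", "Ke", "Kcp", "Kpc")

#: Dose routes understood by :class:`ModelSpec.dose_fractions`.
DOSE_ROUTES = ("first_order", "transit", "central")


@dataclass(frozen=True)
class FractalRate:
    """Time-dependent rate coefficient ``theta / max(t - t_ref, epsilon)**h``.

    Parameters
    ----------
    theta : float
        Rate coefficient at elapsed time 1 (1/h).
    h : float
        Heterogeneity exponent, restricted to [0, 1].  ``h = 0`` gives a
        constant (classical) rate.
    epsilon : float
        Regularization of the elapsed time near zero (hours).  For ``h < 1``
        the cumulative hazard integral is finite, so ``epsilon`` only keeps
        the right-hand side bounded for the solver; results are insensitive
        to it (halving ``epsilon`` moves profiles by < 1e-6 relative).
    """

    theta: float
    h: float
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 <= self.h <= 1.0):
            raise ValueError(f"heterogeneity exponent h={self.h} outside [0, 1]")
        if self.theta < 0.0:
            raise ValueError(f"theta={self.theta} must be non-negative")
        if self.epsilon <= 0.0:
            raise ValueError(f"epsilon={self.epsilon} must be positive")

    def at(self, t, t_ref: float = 0.0):
        return instantaneous_rate(self, t, t_ref)


def instantaneous_rate(rate: FractalRate, t, t_ref: float = 0.0):
    """Evaluate the instantaneous rate coefficient at time(s) ``t``.

    ``t_ref`` is the fractal-clock origin (time of dosing).  Negative elapsed
    time signals an event-ordering bug and raises.  Returns a scalar for
    scalar input, an ndarray otherwise.
    """
    t_arr = np.asarray(t, dtype=float)
    elapsed = t_arr - t_ref
    if np.any(elapsed < -1e-12):
        raise ValueError(
            f"negative elapsed time (t={t!r}, t_ref={t_ref}): events out of order"
        )
    if rate.h == 0.0:
        out = np.full_like(t_arr, rate.theta, dtype=float)
    else:
        out = rate.theta / np.maximum(elapsed, rate.epsilon) ** rate.h
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def stirling_factorial(n: int) -> float:
    """Stirling's approximation ``n! ~ sqrt(2*pi) * n**(n+1/2) * exp(-n)``."""
    if n < 1:
        raise ValueError("transit chain needs n >= 1 for Stirling's approximation")
    return math.sqrt(2.0 * math.pi) * n ** (n + 0.5) * math.exp(-n)


@dataclass(frozen=True)
class PKParameters:
    """Structural PK parameters (clearance parameterization).

    Micro rate constants are derived: ``Ke = CL/V1``, ``Kcp = Q/V1``,
    ``Kpc = Q/V2``.  ``Ka``/``Q``/``V2`` are optional for structures that do
    not use them.  Units: volumes in L, clearances in L/h, Ka in 1/h.
    """

    CL: float
    V1: float
    Ka: float | None = None
    Q: float | None = None
    V2: float | None = None

    def __post_init__(self) -> None:
        for name in ("CL", "V1"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("Ka", "Q", "V2"):
            v = getattr(self, name)
            if v is not None and v <= 0.0:
                raise ValueError(f"{name} must be strictly positive when given")

    @property
    def Ke(self) -> float:
        return self.CL / self.V1

    @property
    def Kcp(self) -> float:
        if self.Q is None:
            raise ValueError("Kcp undefined: Q not set")
        return self.Q / self.V1

    @property
    def Kpc(self) -> float:
        if self.Q is None or self.V2 is None:
            raise ValueError("Kpc undefined: Q/V2 not set")
        return self.Q / self.V2

    def micro_rate(self, name: str) -> float:
        if name == "Ka":
            if self.Ka is None:
                raise ValueError("Ka not set")
            return self.Ka
        if name == "Ke":
            return self.Ke
        if name == "Kcp":
            return self.Kcp
        if name == "Kpc":
            return self.Kpc
        raise KeyError(name)


@dataclass(frozen=True)
class ModelSpec:
    """Structural model: compartments, absorption, fractal placement, dosing.

    ``fractal_on`` maps a micro-rate name to either a full
    :class:`FractalRate` (overriding the parameter value with its own
    ``theta``) or a bare exponent ``h`` (float), in which case ``theta`` is
    the micro-rate from :class:`PKParameters` and ``epsilon`` is taken from
    this ModelSpec.

    ``dose_fractions`` splits each dose over absorption routes, e.g.
    ``((0.3, "first_order"), (0.7, "transit"))`` for a fast/slow split.
    When ``None`` the whole dose follows ``absorption``.

    ``reset_on_dose`` implements the multiple-dose rule where every new dose
    resets the fractal clock to zero and empties the remaining depot /
    in-transit amount before the new amount is added.
    """

    n_compartments: int = 1
    absorption: str = "first_order"  # first_order | transit | bolus
    n_transit: int = 3
    ktr: float = 1.0
    fractal_on: Mapping[str, "FractalRate | float"] = field(default_factory=dict)
    dose_fractions: tuple[tuple[float, str], ...] | None = None
    reset_on_dose: bool = False
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        if self.absorption not in ("first_order", "transit", "bolus"):
            raise ValueError(f"unknown absorption model {self.absorption!r}")
        if self.absorption == "transit" or any(
            r == "transit" for _, r in self.fractions()
        ):
            if self.n_transit < 1:
                raise ValueError("n_transit must be >= 1")
            if self.ktr <= 0.0:
                raise ValueError("ktr must be strictly positive")
        if self.epsilon <= 0.0:
            raise ValueError("epsilon must be positive")
        total = sum(f for f, _ in self.fractions())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"dose fractions sum to {total}, expected 1")
        for f, route in self.fractions():
            if f <= 0.0:
                raise ValueError("dose fractions must be positive")
            if route not in DOSE_ROUTES:
                raise ValueError(f"unknown dose route {route!r}")
        allowed = set(self.rate_names())
        for name, val in self.fractal_on.items():
            if name not in allowed:
                raise ValueError(
                    f"fractal rate {name!r} does not exist for this structure "
                    f"(allowed: {sorted(allowed)})"
                )
            if not isinstance(val, FractalRate):
                FractalRate(theta=1.0, h=float(val), epsilon=self.epsilon)

    # -- structure queries -------------------------------------------------
    def fractions(self) -> tuple[tuple[float, str], ...]:
        if self.dose_fractions is not None:
            return tuple(self.dose_fractions)
        route = {"first_order": "first_order", "transit": "transit", "bolus": "central"}[
            self.absorption
        ]
        return ((1.0, route),)

    def has_route(self, route: str) -> bool:
        return any(r == route for _, r in self.fractions())

    def rate_names(self) -> tuple[str, ...]:
        names = []
        if self.has_route("first_order"):
            names.append("Ka")
        names.append("Ke")
        if self.n_compartments == 2:
            names += ["Kcp", "Kpc"]
        return tuple(names)

    def compartments(self) -> tuple[str, ...]:
        labels = []
        if self.has_route("first_order"):
            labels.append("depot")
        labels.append("central")
        if self.n_compartments == 2:
            labels.append("peripheral")
        labels.append("eliminated")
        if self.has_route("transit"):
            labels.append("in_transit")
        return tuple(labels)

    def index(self, label: str) -> int:
        return self.compartments().index(label)

    @property
    def obs_cmt(self) -> int:
        """1-based index of the central (observed) compartment."""
        return self.index("central") + 1

    @property
    def dose_cmt(self) -> int:
        """1-based index of the compartment doses nominally target."""
        return 1

    def resolve_rate(self, params: PKParameters, name: str):
        """Return ``("const", k)`` or ``("fractal", FractalRate)`` for a rate."""
        val = self.fractal_on.get(name)
        if val is None:
            return ("const", params.micro_rate(name))
        if isinstance(val, FractalRate):
            return ("fractal", val)
        return (
            "fractal",
            FractalRate(theta=params.micro_rate(name), h=float(val), epsilon=self.epsilon),
        )


@dataclass(frozen=True)
class DoseEvent:
    """A dose of ``amount`` at ``time`` (h); ``cmt`` optionally validates the
    NONMEM-style target compartment index."""

    time: float
    amount: float
    cmt: int | None = None

    def __post_init__(self) -> None:
        if self.amount <= 0.0:
            raise ValueError("dose amount must be positive")


def _validate_consistency(spec: ModelSpec, params: PKParameters) -> None:
    if spec.has_route("first_order") and params.Ka is None and "Ka" not in spec.fractal_on:
        raise ValueError("first-order absorption requires Ka (or a fractal Ka override)")
    if spec.n_compartments == 2 and (params.Q is None or params.V2 is None):
        raise ValueError("2-compartment model requires Q and V2")


def build_rhs(
    spec: ModelSpec,
    params: PKParameters,
    t_ref: float = 0.0,
    transit_doses: Sequence[tuple[float, float]] = (),
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Assemble the amount-derivative function for one integration segment.

    ``t_ref`` is the current fractal-clock origin; ``transit_doses`` is the
    list of ``(dose_time, amount)`` pairs currently feeding the transit
    chain.  Returns ``f(t, y) -> dy`` over the compartment layout of
    :meth:`ModelSpec.compartments`.
    """
    _validate_consistency(spec, params)
    labels = spec.compartments()
    i_central = labels.index("central")
    i_elim = labels.index("eliminated")
    i_depot = labels.index("depot") if "depot" in labels else -1
    i_peri = labels.index("peripheral") if "peripheral" in labels else -1
    i_transit = labels.index("in_transit") if "in_transit" in labels else -1

    resolved = {name: spec.resolve_rate(params, name) for name in spec.rate_names()}

    def rate_at(name: str, t: float) -> float:
        kind, val = resolved[name]
        if kind == "const":
            return val
        elapsed = max(t - t_ref, val.epsilon)
        return val.theta / elapsed**val.h

    n = spec.n_transit
    ktr = spec.ktr
    norm = stirling_factorial(n) if i_transit >= 0 else 1.0
    tdoses = tuple(transit_doses)

    def transit_input(t: float) -> float:
        total = 0.0
        for td, amt in tdoses:
            x = ktr * (t - td)
            if x > 0.0:
                total += amt * ktr * x**n * math.exp(-x) / norm
        return total

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        ke = rate_at("Ke", t)
        central = y[i_central]
        if i_depot >= 0:
            ka = rate_at("Ka", t)
            absorbed = ka * y[i_depot]
            dy[i_depot] = -absorbed
            dy[i_central] += absorbed
        if i_transit >= 0:
            inp = transit_input(t)
            dy[i_transit] = -inp
            dy[i_central] += inp
        if i_peri >= 0:
            kcp = rate_at("Kcp", t)
            kpc = rate_at("Kpc", t)
            dy[i_central] += kpc * y[i_peri] - kcp * central
            dy[i_peri] = kcp * central - kpc * y[i_peri]
        dy[i_central] -= ke * central
        dy[i_elim] = ke * central
        return dy

    return rhs


def apply_dose_event(
    state: np.ndarray,
    event: DoseEvent,
    spec: ModelSpec,
    t_ref: float = 0.0,
    transit_doses: Sequence[tuple[float, float]] = (),
):
    """Apply a dose record to the state vector.

    Returns ``(new_state, new_t_ref, new_transit_doses)``.  With
    ``reset_on_dose`` the fractal clock is reset to the event time and the
    depot / in-transit amounts are emptied *before* the new amount is added;
    otherwise doses superpose additively and the clock is unchanged.
    """
    labels = spec.compartments()
    if event.cmt is not None and not (1 <= event.cmt <= len(labels)):
        raise ValueError(
            f"dose targets compartment {event.cmt}, model has {len(labels)} "
            f"compartments ({', '.join(labels)})"
        )
    state = np.array(state, dtype=float)
    tdoses = list(transit_doses)
    if spec.reset_on_dose:
        if "depot" in labels:
            state[labels.index("depot")] = 0.0
        if "in_transit" in labels:
            state[labels.index("in_transit")] = 0.0
        tdoses = []
        t_ref = event.time
    for frac, route in spec.fractions():
        amt = frac * event.amount
        if route == "first_order":
            state[labels.index("depot")] += amt
        elif route == "central":
            state[labels.index("central")] += amt
        else:  # transit
            state[labels.index("in_transit")] += amt
            tdoses.append((event.time, amt))
    return state, t_ref, tuple(tdoses)


def with_fractal_h(spec: ModelSpec, h_values: Mapping[str, float]) -> ModelSpec:
    """Return a copy of ``spec`` with the given heterogeneity exponents.

    Existing :class:`FractalRate` overrides keep their theta/epsilon; bare
    exponents are replaced.
    """
    new = dict(spec.fractal_on)
    for name, h in h_values.items():
        cur = new.get(name)
        if isinstance(cur, FractalRate):
            new[name] = replace(cur, h=float(h))
        else:
            new[name] = float(h)
    return replace(spec, fractal_on=new)
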