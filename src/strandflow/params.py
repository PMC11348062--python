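"""Model parameters and their derivation from summary statistics.

All rates are per minute, all lengths in micrometres (units of the printed
G2 drift speed, 0.05 um/min).  The five cell-cycle phases are indexed in
their sequential order G0, G1, S, G2, M; phase ``i`` is entered from phase
``i - 1`` at exponential rate ``e_i`` (cyclically: G0 is entered from M,
with two daughters per division, hence the source factor a_G0 = 2).

The transition rates are not free parameters: they are derived from the
experimentally observed stable phase fractions so that a well-mixed
population (reaction terms plus the dilution exerted by the passive bulk
flow) is stationary exactly at those fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

PHASES = ("G0", "G1", "S", "G2", "M")

__all__ = [
    "PHASES",
    "StableFractions",
    "ModelParams",
    "derive_base_rate",
    "derive_diffusion",
    "derive_transition_rates",
    "derive_refractory_rate",
    "max_refractory_period",
    "entry_rate_profile",
]


@dataclass(frozen=True)
class StableFractions:
    """Stationary (far-field) fraction of each cell-cycle phase.

    These are the fractions observed at follower positions far from the
    strand tip; they anchor the transition-rate derivation.
    """

    g0: float
    g1: float
    s: float
    g2: float
    m: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals <= 0.0) or np.any(vals >= 1.0):
            raise ValueError(
                f"phase fractions must lie strictly in (0, 1); got {vals}"
            )
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"phase fractions must sum to 1 (got {vals.sum():.12f})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.g0, self.g1, self.s, self.g2, self.m], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(PHASES, self.as_array()))


def derive_base_rate(t_double: float) -> float:
    """Base proliferation rate e_base = ln(2) / t_double [1/min].

    ``t_double`` is the average doubling time (min) of cells in exponential
    growth.
    """
    if t_double <= 0:
        raise ValueError(f"t_double must be positive, got {t_double}")
    return math.log(2.0) / t_double


def derive_diffusion(rmsd: float, dt: float) -> float:
    """Diffusion coefficient D = rmsd^2 / (2 dt) [um^2/min].

    ``rmsd`` is the root-mean-square displacement of randomly migrating
    cells measured over the time interval ``dt`` (min).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if rmsd < 0:
        raise ValueError(f"rmsd must be non-negative, got {rmsd}")
    return rmsd * rmsd / (2.0 * dt)


def derive_transition_rates(stable: StableFractions, e_base: float) -> dict[str, float]:
    """Per-phase entry rates e_i making the stable fractions stationary.

    With dilution rate e_G0 * rho_M (the specific growth rate of the
    population) the well-mixed fraction system

        d rho_i / dt = a_i e_i rho_{i-1} - e_{i+1} rho_i - rho_i e_G0 rho_M

    is stationary exactly at ``stable``.  The rates follow from balancing
    each phase in turn starting from the division flux e_base = e_G0 rho_M:

        e_G0 = e_base / rho_M
        e_G1 = (2 - rho_G0) / rho_G0 * e_base
        e_S  = (2 - rho_G0 - rho_G1) / rho_G1 * e_base
        e_G2 = (2 - rho_G0 - rho_G1 - rho_S) / rho_S * e_base
        e_M  = (2 - rho_G0 - rho_G1 - rho_S - rho_G2) / rho_G2 * e_base
    """
    if e_base <= 0:
        raise ValueError(f"e_base must be positive, got {e_base}")
    r = stable
    rates = {
        "G0": e_base / r.m,
        "G1": (2.0 - r.g0) / r.g0 * e_base,
        "S": (2.0 - r.g0 - r.g1) / r.g1 * e_base,
        "G2": (2.0 - r.g0 - r.g1 - r.s) / r.s * e_base,
        "M": (2.0 - r.g0 - r.g1 - r.s - r.g2) / r.g2 * e_base,
    }
    assert all(v > 0 for v in rates.values())
    return rates


def max_refractory_period(e_m: float, e_base: float) -> float:
    """Largest admissible G2 refractory period, ln((e_base+e_m)/e_m)/e_base."""
    return math.log((e_base + e_m) / e_m) / e_base


def derive_refractory_rate(e_m: float, e_base: float, tau_prime: float) -> float:
    """G2->M exit rate e_M' for non-refractory G2 cells of age > tau_prime.

    Chosen so that the stationary flux of cells entering M is independent
    of the refractory period (e_M rho_G2 = e_M' rho_{G2, tau > tau_prime}):

        e_M' = e_M e_base / [(e_base + e_M) exp(-e_base tau_prime) - e_M]

    e_M'(0) = e_M and e_M' increases with tau_prime, diverging at the bound
    returned by :func:`max_refractory_period`.
    """
    if e_m <= 0 or e_base <= 0:
        raise ValueError("e_m and e_base must be positive")
    if tau_prime < 0:
        raise ValueError(f"tau_prime must be non-negative, got {tau_prime}")
    if tau_prime == 0:
        return e_m                       # identity, exact
    denom = (e_base + e_m) * math.exp(-e_base * tau_prime) - e_m
    if denom <= 0:
        bound = max_refractory_period(e_m, e_base)
        raise ValueError(
            "refractory period too long: tau_prime must be smaller than "
            f"ln((e_base+e_m)/e_m)/e_base = {bound:.6g} min (got {tau_prime})"
        )
    return e_m * e_base / denom


def entry_rate_profile(x, c1: float, c2: float, c3: float):
    """Position-dependent cell-cycle entry (G0 -> G1) rate [1/min].

        e_G1(x) = c3 * (c1 * erf(x / c2) + 1) / (c1 + 1)

    The rate is suppressed near the strand tip (x = 0) by the dimensionless
    amplitude ``c1`` over the length scale ``c2`` (um), and saturates at the
    far-field value ``c3`` (the stable entry rate at x = x_max >> c2).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("positions must be non-negative")
    if c2 <= 0:
        raise ValueError(f"c2 must be positive, got {c2}")
    if c1 < 0:
        raise ValueError(f"c1 must be non-negative, got {c1}")
    if c3 <= 0:
        raise ValueError(f"c3 must be positive, got {c3}")
    out = c3 * (c1 * erf(x / c2) + 1.0) / (c1 + 1.0)
    return out if out.ndim else float(out)


@dataclass
class ModelParams:
    """Every symbol of the strand RAD model in one validated record.

    Parameters
    ----------
    stable : StableFractions
        Far-field stationary phase fractions.
    t_double : float
        Population doubling time, min.
    D : float
        Cell diffusion coefficient, um^2/min (shared by all phases).
    V : dict
        Active (phase-specific) advection speed per phase, um/min.
        Negative values point toward the strand tip.  Default: -0.05 for
        G2, 0 elsewhere (M cells are treated as non-migratory).
    c : float
        Extra source rate (apoptosis, lateral expansion ...), 1/min.
    c1, c2 : float
        Entry-suppression amplitude (dimensionless) and length scale (um).
    tau_prime : float
        G2 refractory period before mitotic entry is permitted, min.
    tau0 : float
        EdU incubation window, min.
    x_max : float
        Domain length, um.
    a, b : dict
        Per-phase source/sink factors; a_G0 = 2 (two daughters per
        division), all others 1.
    """

    stable: StableFractions
    t_double: float = 1440.0
    D: float = 2.5
    V: dict = field(default_factory=lambda: {p: 0.0 for p in PHASES} | {"G2": -0.05})
    c: float = 0.0
    c1: float = 3.0
    c2: float = 50.0
    tau_prime: float = 60.0
    tau0: float = 120.0
    x_max: float = 400.0
    a: dict = field(default_factory=lambda: {p: 1.0 for p in PHASES} | {"G0": 2.0})
    b: dict = field(default_factory=lambda: {p: 1.0 for p in PHASES})

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if self.t_double <= 0:
            raise ValueError("t_double must be positive")
        if self.x_max <= 0:
            raise ValueError("x_max must be positive")
        if self.c1 < 0 or self.c2 <= 0:
            raise ValueError("require c1 >= 0 and c2 > 0")
        if self.tau_prime < 0 or self.tau0 < 0:
            raise ValueError("tau_prime and tau0 must be non-negative")
        for d in (self.V, self.a, self.b):
            missing = set(PHASES) - set(d)
            if missing:
                raise ValueError(f"missing phases {missing} in {d}")
        # derived quantities
        self.e_base = derive_base_rate(self.t_double)
        self.rates = derive_transition_rates(self.stable, self.e_base)
        self.c3 = self.rates["G1"]
        self.e_m_prime = derive_refractory_rate(
            self.rates["M"], self.e_base, self.tau_prime
        )

    def entry_rate(self, x):
        """e_G1(x) with this parameter set's c1, c2, c3."""
        return entry_rate_profile(x, self.c1, self.c2, self.c3)

    def with_overrides(self, **kwargs) -> "ModelParams":
        """A copy with the given fields replaced (derived values refresh)."""
        return replace(self, **kwargs)
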