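"""Finite-volume integrator for the strand phase-fraction equations.

The five phase fractions rho_i(x, t) obey

    d rho_i / dt = d/dx ( D d rho_i / dx ) - d( (V + V_i) rho_i )/dx
                   + a_i e_i rho_{i-1} - b_i e_{i+1} rho_i + c rho_i

on 0 <= x <= x_max with the strand tip at x = 0 (co-moving frame).  The
passive bulk velocity V(x) is not a free field: because the total density
is constant (fractions sum to one), conservation forces

    V(x) = int_0^x ( e_G0 rho_M + c ) dx'  -  sum_i V_i rho_i(x).

The G2 phase is age-structured: psi_G2(x, t, tau) is the density of G2
cells of age tau, transported in age at unit speed, fed at tau = 0 by the
S -> G2 flux e_G2 rho_S, and drained to M at rate e_M' only beyond the
refractory age tau_prime.  rho_G2 is the trapezoidal age integral of psi.

Numerics: operator splitting per step in the order reaction -> age
advection -> spatial advection (first-order upwind, flux form) -> explicit
diffusion -> proportional renormalization of the fraction sum.  The tip
boundary carries zero advective and zero diffusive flux (together the
discrete analogue of the no-net-flux Robin condition); the far boundary is
zero-gradient.  Stability requires dt * max|V + V_i| / dx <= 0.9 and
D dt / dx^2 <= 0.45; violations raise a configuration error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from strandflow.params import PHASES, ModelParams

__all__ = [
    "Grid",
    "PhaseField",
    "AgeField",
    "Trajectory",
    "RadSolver",
    "closed_form_age_density",
]

_IDX = {p: k for k, p in enumerate(PHASES)}


@dataclass(frozen=True)
class Grid:
    """Uniform space/age discretization.  The age step equals dt."""

    dx: float
    dt: float
    x_max: float
    tau_max: float

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")
        if self.x_max <= 0 or self.tau_max <= 0:
            raise ValueError("x_max and tau_max must be positive")

    @property
    def dtau(self) -> float:
        return self.dt

    @property
    def x_nodes(self) -> np.ndarray:
        n = int(round(self.x_max / self.dx)) + 1
        return np.linspace(0.0, self.x_max, n)

    @property
    def tau_nodes(self) -> np.ndarray:
        n = int(np.ceil(self.tau_max / self.dtau)) + 1
        return np.arange(n) * self.dtau

    @classmethod
    def for_params(
        cls,
        params: ModelParams,
        dx: float = 5.0,
        dt: float | None = None,
        tau_max: float | None = None,
    ) -> "Grid":
        """Grid sized to the model: age axis truncated at tau' + 10/e_M'."""
        if dt is None:
            dt = 0.4 * dx * dx / params.D if params.D > 0 else 5.0
            dt = float(min(dt, 5.0))
        if tau_max is None:
            tau_max = params.tau_prime + 10.0 / params.e_m_prime
        return cls(dx=dx, dt=dt, x_max=params.x_max, tau_max=tau_max)


@dataclass
class PhaseField:
    """Phase fractions on the spatial grid: rho[i, j] for phase i, node j."""

    rho: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.ndim != 2 or self.rho.shape[0] != len(PHASES):
            raise ValueError("rho must have shape (5, n_x)")

    def phase(self, name: str) -> np.ndarray:
        return self.rho[_IDX[name]]

    def total(self) -> np.ndarray:
        return self.rho.sum(axis=0)

    def validate(self, tol: float = 1e-6) -> None:
        if np.any(self.rho < -tol) or np.any(self.rho > 1 + tol):
            raise ValueError("phase fractions out of [0, 1]")
        err = np.abs(self.total() - 1.0).max()
        if err > tol:
            raise ValueError(f"fractions do not sum to 1 (max error {err:.3g})")

    def copy(self) -> "PhaseField":
        return PhaseField(self.rho.copy(), self.t)


@dataclass
class AgeField:
    """Age-resolved G2 density psi[j, k] at node j, age tau_k (units 1/min)."""

    psi: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        if self.psi.ndim != 2:
            raise ValueError("psi must have shape (n_x, n_tau)")

    def rho_g2(self, grid: Grid) -> np.ndarray:
        return np.trapezoid(self.psi, dx=grid.dtau, axis=1)

    def copy(self) -> "AgeField":
        return AgeField(self.psi.copy(), self.t)


@dataclass
class Trajectory:
    """Stored output of a run: times, stacked rho arrays, final age field."""

    times: np.ndarray
    rho: np.ndarray            # (n_out, 5, n_x)
    grid: Grid
    final_age: AgeField | None = None

    def field(self, k: int) -> PhaseField:
        return PhaseField(self.rho[k].copy(), float(self.times[k]))

    def to_frame(self):
        """Tidy table with columns time_min, x_um, phase, fraction."""
        import pandas as pd

        x = self.grid.x_nodes
        recs = {
            "time_min": np.repeat(self.times, len(PHASES) * len(x)),
            "phase": np.tile(np.repeat(PHASES, len(x)), len(self.times)),
            "x_um": np.tile(x, len(self.times) * len(PHASES)),
            "fraction": self.rho.reshape(-1),
        }
        return pd.DataFrame(recs)


def closed_form_age_density(tau, params: ModelParams) -> np.ndarray:
    """Stationary well-mixed G2 age profile, up to overall normalization.

    psi(tau) = exp(-e_base tau)                                tau <  tau'
             = exp(-e_base tau') exp(-(e_base+e_M')(tau-tau')) tau >= tau'
    """
    tau = np.asarray(tau, dtype=float)
    eb, emp, tp = params.e_base, params.e_m_prime, params.tau_prime
    out = np.where(
        tau < tp,
        np.exp(-eb * tau),
        np.exp(-eb * tp) * np.exp(-(eb + emp) * np.clip(tau - tp, 0, None)),
    )
    return out


def _integrate_to(psi: np.ndarray, tau_nodes: np.ndarray, tau0: float) -> np.ndarray:
    """Trapezoidal integral of psi over ages [0, tau0], per spatial node."""
    if tau0 <= 0:
        return np.zeros(psi.shape[0])
    if tau0 >= tau_nodes[-1]:
        return np.trapezoid(psi, tau_nodes, axis=1)
    k = int(np.searchsorted(tau_nodes, tau0, side="right")) - 1
    out = np.trapezoid(psi[:, : k + 1], tau_nodes[: k + 1], axis=1)
    # fractional last cell, psi linear between nodes k and k+1
    frac = (tau0 - tau_nodes[k]) / (tau_nodes[k + 1] - tau_nodes[k])
    psi_at = psi[:, k] * (1 - frac) + psi[:, k + 1] * frac
    out += 0.5 * (psi[:, k] + psi_at) * (tau0 - tau_nodes[k])
    return out


class RadSolver:
    """Integrates the coupled phase-fraction and G2-age equations.

    Parameters
    ----------
    params : ModelParams
    grid : Grid, optional
        Defaults to :meth:`Grid.for_params` (dx = 5 um, dt from the
        diffusive stability bound).

    Attributes
    ----------
    max_conservation_drift : float
        Largest per-step deviation of the fraction sum from 1 seen before
        renormalization.
    total_clipped : float
        Accumulated magnitude of negativity clipping.
    """

    def __init__(self, params: ModelParams, grid: Grid | None = None):
        self.params = params
        self.grid = grid if grid is not None else Grid.for_params(params)
        g = self.grid
        if params.D * g.dt / g.dx**2 > 0.45 + 1e-12:
            raise ValueError(
                f"diffusive stability violated: D*dt/dx^2 = "
                f"{params.D * g.dt / g.dx**2:.3f} > 0.45; reduce dt"
            )
        self._x = g.x_nodes
        self._tau = g.tau_nodes
        self._eg1x = params.entry_rate(self._x)
        # exact characteristic survival for the age shift tau_{k-1} -> tau_k:
        # decay acts only on the part of the step spent beyond tau_prime
        exposed = np.clip(
            self._tau[1:] - np.maximum(params.tau_prime, self._tau[:-1]), 0.0, g.dt
        )
        self._shift_survival = np.exp(-params.e_m_prime * exposed)
        self.max_conservation_drift = 0.0
        self.total_clipped = 0.0

    # ------------------------------------------------------------------
    # state constructors
    # ------------------------------------------------------------------
    def uniform_stable_state(self) -> tuple[PhaseField, AgeField]:
        """Spatially uniform state at the stable fractions, with the
        closed-form G2 age profile normalized to rho_G2 per node."""
        p = self.params
        nx = len(self._x)
        rho = np.tile(p.stable.as_array()[:, None], (1, nx))
        shape = closed_form_age_density(self._tau, p)
        norm = np.trapezoid(shape, self._tau)
        psi = np.tile(shape / norm * p.stable.g2, (nx, 1))
        return PhaseField(rho, 0.0), AgeField(psi, 0.0)

    def random_state(self, rng: np.random.Generator) -> tuple[PhaseField, AgeField]:
        """A random valid initial condition (Dirichlet fractions per node,
        exponential-in-age G2 density)."""
        nx = len(self._x)
        rho = rng.dirichlet(np.ones(len(PHASES)), size=nx).T
        shape = np.exp(-self.params.e_base * self._tau)
        psi = rho[_IDX["G2"]][:, None] * shape[None, :] / np.trapezoid(shape, self._tau)
        return PhaseField(rho, 0.0), AgeField(psi, 0.0)

    # ------------------------------------------------------------------
    # physics pieces
    # ------------------------------------------------------------------
    def passive_velocity(self, field: PhaseField) -> np.ndarray:
        """Conservation-derived bulk velocity V(x) on the nodes."""
        p = self.params
        source = p.rates["G0"] * field.phase("M") + p.c
        integral = cumulative_trapezoid(source, self._x, initial=0.0)
        active = sum(p.V[ph] * field.phase(ph) for ph in PHASES)
        return integral - active

    def _advect(self, u: np.ndarray, v_nodes: np.ndarray) -> np.ndarray:
        """One upwind advection step in flux form.

        ``u`` is (n_x,) or (n_x, n_tau); ``v_nodes`` the signed velocity at
        the nodes.  Zero flux at the tip face; zero-gradient ghost at the
        far face (outflow or inflow at the ambient value).
        """
        g = self.grid
        vf = 0.5 * (v_nodes[:-1] + v_nodes[1:])        # inner faces
        v_far = 1.5 * v_nodes[-1] - 0.5 * v_nodes[-2]  # extrapolated far face
        if u.ndim == 1:
            flux = np.where(vf > 0, vf * u[:-1], vf * u[1:])
            fr = v_far * u[-1]
        else:
            vfc = vf[:, None]
            flux = np.where(vfc > 0, vfc * u[:-1, :], vfc * u[1:, :])
            fr = v_far * u[-1, :]
        div = np.empty_like(u)
        div[0] = flux[0]
        div[1:-1] = flux[1:] - flux[:-1]
        div[-1] = fr - flux[-1]
        return u - g.dt / g.dx * div

    def _diffuse(self, u: np.ndarray) -> np.ndarray:
        """Explicit diffusion with zero-flux ends (along axis 0)."""
        g = self.grid
        lam = self.params.D * g.dt / g.dx**2
        if lam == 0.0:
            return u
        lap = np.empty_like(u)
        lap[0] = u[1] - u[0]
        lap[1:-1] = u[2:] - 2.0 * u[1:-1] + u[:-2]
        lap[-1] = u[-2] - u[-1]
        return u + lam * lap

    # ------------------------------------------------------------------
    # time stepping
    # ------------------------------------------------------------------
    def step(
        self, field: PhaseField, age: AgeField, check: bool = True
    ) -> tuple[PhaseField, AgeField]:
        """Advance the coupled state by one dt."""
        p, g = self.params, self.grid
        rho = field.rho.copy()
        psi = age.psi.copy()
        dt = g.dt

        if check:
            mism = np.abs(np.trapezoid(psi, self._tau, axis=1) - rho[_IDX["G2"]]).max()
            if mism > 1e-4:
                raise ValueError(
                    f"age-integral of psi inconsistent with rho_G2 "
                    f"(max mismatch {mism:.3g})"
                )

        g0, g1, s, m = (rho[_IDX[k]] for k in ("G0", "G1", "S", "M"))
        e = p.rates

        # (i)+(ii) reaction and age transport.  The G2 column is advanced
        # along characteristics: shift by one age cell with the exact
        # survival factor for the part of the step spent beyond the
        # refractory age; everything the column loses (mitotic exit plus
        # the truncated oldest cell) is handed to M, so the reaction stage
        # conserves the fraction sum exactly up to the intended division
        # source term.
        f_entry = self._eg1x * g0 * dt                      # G0 -> G1
        f_g1s = e["S"] * g1 * dt                            # G1 -> S
        f_sg2 = e["G2"] * s * dt                            # S  -> G2
        f_mg0 = e["G0"] * m * dt                            # M  -> G0 (division)
        g2_before = np.trapezoid(psi, self._tau, axis=1)
        psi[:, 1:] = psi[:, :-1] * self._shift_survival[None, :]
        psi[:, 0] = e["G2"] * s                             # S -> G2 inflow
        f_g2m = g2_before + f_sg2 - np.trapezoid(psi, self._tau, axis=1)
        cdt = p.c * dt
        rho[_IDX["G0"]] = g0 + p.a["G0"] * f_mg0 - p.b["G0"] * f_entry + cdt * g0
        rho[_IDX["G1"]] = g1 + p.a["G1"] * f_entry - p.b["G1"] * f_g1s + cdt * g1
        rho[_IDX["S"]] = s + p.a["S"] * f_g1s - p.b["S"] * f_sg2 + cdt * s
        rho[_IDX["M"]] = m + p.a["M"] * f_g2m - p.b["M"] * f_mg0 + cdt * m
        if p.c != 0.0:
            psi *= 1.0 + cdt

        # (iii) spatial advection with the conservation-derived velocity
        rho[_IDX["G2"]] = np.trapezoid(psi, self._tau, axis=1)
        v = self.passive_velocity(PhaseField(rho, field.t))
        cfl = np.abs(v).max() + max(abs(val) for val in p.V.values())
        if cfl * dt / g.dx > 0.9:
            raise ValueError(
                f"advective CFL violated: max|V+V_i|*dt/dx = "
                f"{cfl * dt / g.dx:.3f} > 0.9; reduce dt"
            )
        for ph in ("G0", "G1", "S", "M"):
            rho[_IDX[ph]] = self._advect(rho[_IDX[ph]], v + p.V[ph])
        psi = self._advect(psi, v + p.V["G2"])

        # (iv) diffusion
        for ph in ("G0", "G1", "S", "M"):
            rho[_IDX[ph]] = self._diffuse(rho[_IDX[ph]])
        psi = self._diffuse(psi)

        # (v) clip negativity, renormalize the fraction sum to 1
        clip = -np.minimum(rho, 0.0).sum() - np.minimum(psi, 0.0).sum() * g.dtau
        if clip > 0:
            self.total_clipped += float(clip)
            np.clip(rho, 0.0, None, out=rho)
            np.clip(psi, 0.0, None, out=psi)
        rho[_IDX["G2"]] = np.trapezoid(psi, self._tau, axis=1)
        total = rho.sum(axis=0)
        self.max_conservation_drift = max(
            self.max_conservation_drift, float(np.abs(total - 1.0).max())
        )
        rho /= total[None, :]
        psi /= total[:, None]

        t_new = field.t + dt
        return PhaseField(rho, t_new), AgeField(psi, t_new)

    def run(
        self,
        t_end: float,
        init: tuple[PhaseField, AgeField] | str = "uniform",
        output_every: float | None = None,
        store_age: bool = False,
    ) -> Trajectory:
        """Integrate for ``t_end`` minutes, storing fields at the cadence
        ``output_every`` (defaults to 10 outputs over the run)."""
        if t_end <= 0:
            raise ValueError("t_end must be positive")
        if init == "uniform":
            fld, age = self.uniform_stable_state()
        elif init == "stationary":
            fld, age = self.stationary_state()
        else:
            fld, age = init
            fld, age = fld.copy(), age.copy()
        dt = self.grid.dt
        n_steps = int(round(t_end / dt))
        if output_every is None:
            output_every = max(t_end / 10.0, dt)
        out_stride = max(int(round(output_every / dt)), 1)
        times = [fld.t]
        rhos = [fld.rho.copy()]
        for k in range(1, n_steps + 1):
            fld, age = self.step(fld, age, check=(k == 1))
            if k % out_stride == 0 or k == n_steps:
                times.append(fld.t)
                rhos.append(fld.rho.copy())
        return Trajectory(
            times=np.array(times),
            rho=np.stack(rhos),
            grid=self.grid,
            final_age=age if store_age else None,
        )

    def stationary_state(
        self,
        tol: float = 1e-8,
        max_t: float | None = None,
        init: tuple[PhaseField, AgeField] | None = None,
    ) -> tuple[PhaseField, AgeField]:
        """Relax to the steady state: integrate until the maximal field
        change per minute drops below ``tol``."""
        if tol <= 0:
            raise ValueError("tol must be positive")
        p = self.params
        if max_t is None:
            max_t = 80.0 / p.e_base
        fld, age = self.uniform_stable_state() if init is None else init
        dt = self.grid.dt
        chunk = max(int(round(200.0 / dt)), 1)     # compare every ~200 min
        t = 0.0
        first = True
        while t < max_t:
            prev = fld.rho.copy()
            for _ in range(chunk):
                fld, age = self.step(fld, age, check=first)
                first = False
            t += chunk * dt
            rate = np.abs(fld.rho - prev).max() / (chunk * dt)
            if rate < tol:
                fld.t = 0.0
                age.t = 0.0
                return fld, age
        raise RuntimeError(
            f"no steady state within {max_t:.0f} min "
            f"(residual change rate {rate:.3g}/min > tol {tol:.3g})"
        )

    # ------------------------------------------------------------------
    # readouts
    # ------------------------------------------------------------------
    def early_late_split(
        self, age: AgeField, tau0: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-node fractions of early (age <= tau0) and late G2 cells."""
        if tau0 < 0:
            raise ValueError("tau0 must be non-negative")
        total = np.trapezoid(age.psi, self._tau, axis=1)
        early = _integrate_to(age.psi, self._tau, tau0)
        return early, total - early

    def age_profile_check(self, age: AgeField, uniform_tol: float = 0.05) -> float:
        """Relative L1 distance between the (spatially uniform, stationary)
        age profile and the closed-form stationary density."""
        psi_mean = age.psi.mean(axis=0)
        spread = np.abs(age.psi - psi_mean[None, :]).max()
        if spread > uniform_tol * max(psi_mean.max(), 1e-300):
            raise ValueError(
                "age profile is not spatially uniform; relax a well-mixed "
                "system (D = 0 irrelevant, speeds 0, c1 = 0) first"
            )
        ref = closed_form_age_density(self._tau, self.params)
        ref = ref / np.trapezoid(ref, self._tau) * np.trapezoid(psi_mean, self._tau)
        num = np.trapezoid(np.abs(psi_mean - ref), self._tau)
        den = np.trapezoid(ref, self._tau)
        return float(num / den)
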