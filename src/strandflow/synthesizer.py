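"""Agent-based stochastic twin of the strand model and synthetic-data source.

Discrete, non-interacting cells live on the 1D strand axis.  Each agent
carries a position (distance to tip, um), a cell-cycle phase, the time
spent in that phase, and an EdU bookkeeping field.  Per time step an agent

1. transitions to the next phase with probability 1 - exp(-e dt), using
   the position-dependent entry rate for G0 -> G1 and the refractory-gated
   rate e_M' (only when the G2 age exceeds tau') for G2 -> M; an M -> G0
   transition duplicates the agent in place (cell division, recorded as an
   event);
2. moves by a Gaussian displacement of standard deviation sqrt(2 D dt)
   plus the drift (V(x) + V_phase) dt, where the passive V(x) is computed
   from the current empirical phase fractions exactly as in the continuum
   model; the tip is reflecting, the far end absorbing (cells pushed past
   x_max leave the modeled window);
3. accrues phase age.

Crowding is represented only through the shared mean-field V(x) — the
agents do not interact pairwise, mirroring the continuum model they are
meant to check.  Daughters inherit the parent's position and EdU label and
start at phase age zero.

Runs are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from strandflow.params import PHASES, ModelParams
from strandflow.solver import AgeField, Grid, PhaseField, closed_form_age_density

__all__ = ["SynthConfig", "SimResult", "simulate_agents", "emulate_edu_pulse",
           "emulate_markers", "sample_strands"]

_NEVER = -1.0e18        # sentinel "never was in S"


@dataclass
class SynthConfig:
    """Configuration of one synthetic run."""

    params: ModelParams
    n_agents: int = 10000
    t_end: float = 720.0
    dt: float = 2.5
    snapshot_times: tuple = ()
    edu_window: float | None = None        # defaults to params.tau0
    dropout: float = 0.0
    seed: int = 0
    record_tracks_every: float | None = None   # min; None = no track table
    init: tuple[PhaseField, AgeField] | None = None
    grid: Grid | None = None               # binning grid for the mean field
    movement: bool = True                  # False: pure well-mixed birth-death

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.t_end <= 0 or self.dt <= 0:
            raise ValueError("t_end and dt must be positive")
        if self.edu_window is None:
            self.edu_window = self.params.tau0


@dataclass
class SimResult:
    tracks: pd.DataFrame | None
    events: pd.DataFrame
    snapshots: dict
    final: pd.DataFrame
    manifest: dict


def _init_agents(cfg: SynthConfig, rng: np.random.Generator):
    """Draw the initial population, either uniform at the stable fractions
    or from a continuum state (positions by node weight, phases by the
    local fractions, G2 ages from the local age density)."""
    p = cfg.params
    n = cfg.n_agents
    if cfg.init is None:
        x = rng.uniform(0.0, p.x_max, n)
        phase = rng.choice(len(PHASES), size=n, p=p.stable.as_array())
        tau = np.linspace(0.0, p.tau_prime + 10.0 / p.e_m_prime, 400)
        age_pdf = closed_form_age_density(tau, p)
        age_pdf /= age_pdf.sum()
        phase_age = np.zeros(n)
        exit_rate = {
            0: p.c3, 1: p.rates["S"], 2: p.rates["G2"], 4: p.rates["G0"],
        }
        for k, rate in exit_rate.items():
            sel = phase == k
            phase_age[sel] = rng.exponential(1.0 / rate, sel.sum())
        sel = phase == 3
        phase_age[sel] = rng.choice(tau, size=sel.sum(), p=age_pdf)
    else:
        fld, agef = cfg.init
        grid = cfg.grid if cfg.grid is not None else Grid.for_params(p)
        xn = grid.x_nodes
        w = np.ones(len(xn))
        w[0] = w[-1] = 0.5                       # trapezoid node weights
        x = rng.choice(xn, size=n, p=w / w.sum())
        x = x + rng.uniform(-0.5, 0.5, n) * grid.dx
        x = np.clip(x, 0.0, p.x_max)
        idx = np.clip(np.round(x / grid.dx).astype(int), 0, len(xn) - 1)
        fr = fld.rho[:, idx].T
        fr = np.clip(fr, 0, None)
        fr /= fr.sum(axis=1, keepdims=True)
        u = rng.uniform(size=n)
        phase = (u[:, None] > np.cumsum(fr, axis=1)).sum(axis=1)
        phase_age = np.zeros(n)
        exit_rate = {
            0: p.c3, 1: p.rates["S"], 2: p.rates["G2"], 4: p.rates["G0"],
        }
        for k, rate in exit_rate.items():
            sel = phase == k
            phase_age[sel] = rng.exponential(1.0 / rate, sel.sum())
        sel = phase == 3
        if sel.any():
            taun = grid.tau_nodes
            for j in np.unique(idx[sel]):
                jj = sel & (idx == j)
                pdf = np.clip(agef.psi[j], 0, None)
                if pdf.sum() <= 0:
                    continue
                phase_age[jj] = rng.choice(taun, size=jj.sum(), p=pdf / pdf.sum())
    last_s = np.full(n, _NEVER)
    last_s[phase == 2] = 0.0                     # in S right now
    sel = phase == 3
    last_s[sel] = -phase_age[sel]                # left S when G2 began
    return x, phase, phase_age, last_s


def _mean_field_velocity(x, phase, params: ModelParams, grid: Grid,
                         min_per_bin: int = 5):
    """Passive V at the agents' positions from binned empirical fractions.

    Bins of width dx on the continuum grid; bins with fewer than
    ``min_per_bin`` agents fall back to the stable fractions (variance
    control near the sparsely populated tip).
    """
    edges = np.arange(0.0, params.x_max + grid.dx * 0.5, grid.dx)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nb = len(centers)
    ib = np.clip(np.digitize(x, edges) - 1, 0, nb - 1)
    counts = np.bincount(ib, minlength=nb)
    frac = np.empty((len(PHASES), nb))
    for k in range(len(PHASES)):
        frac[k] = np.bincount(ib[phase == k], minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = frac / counts[None, :]
    sparse = counts < min_per_bin
    frac[:, sparse] = params.stable.as_array()[:, None]
    source = params.rates["G0"] * frac[4] + params.c
    integral = cumulative_trapezoid(source, centers, initial=0.0)
    integral += source[0] * centers[0]           # from x = 0 to first center
    active = sum(params.V[ph] * frac[k] for k, ph in enumerate(PHASES))
    v_centers = integral - active
    return np.interp(x, centers, v_centers), ib, counts


def simulate_agents(config: SynthConfig) -> SimResult:
    """Run the stochastic strand; returns tracks, division events and
    snapshots (see :class:`SynthConfig`)."""
    p = config.params
    rng = np.random.default_rng(config.seed)
    grid = config.grid if config.grid is not None else Grid.for_params(p)
    x, phase, phase_age, last_s = _init_agents(config, rng)
    n = len(x)
    ids = np.arange(n, dtype=np.int64)
    lineage = np.full(n, -1, dtype=np.int64)
    birth = np.zeros(n)
    next_id = n

    dt = config.dt
    n_steps = int(round(config.t_end / dt))
    snap_steps = {int(round(t / dt)) for t in config.snapshot_times}
    rec_stride = None
    if config.record_tracks_every is not None:
        rec_stride = max(int(round(config.record_tracks_every / dt)), 1)

    v_phase = np.array([p.V[ph] for ph in PHASES])
    sigma = np.sqrt(2.0 * p.D * dt)

    track_chunks, events, snapshots = [], [], {}

    def record_tracks(t):
        track_chunks.append(pd.DataFrame({
            "time_min": t, "id": ids.copy(), "x_um": x.copy(),
            "phase": np.array(PHASES)[phase],
            "phase_age_min": phase_age.copy(),
            "edu": last_s >= t - config.edu_window,
        }))

    def take_snapshot(t):
        snapshots[t] = pd.DataFrame({
            "id": ids.copy(), "x_um": x.copy(),
            "phase": np.array(PHASES)[phase],
            "phase_age_min": phase_age.copy(),
            "edu": last_s >= t - config.edu_window,
        })

    if rec_stride is not None:
        record_tracks(0.0)
    if 0 in snap_steps:
        take_snapshot(0.0)

    for step in range(1, n_steps + 1):
        t = step * dt
        # --- transitions -------------------------------------------------
        rate = np.empty(len(x))
        rate[phase == 0] = p.entry_rate(x[phase == 0])
        rate[phase == 1] = p.rates["S"]
        rate[phase == 2] = p.rates["G2"]
        g2 = phase == 3
        rate[g2] = np.where(phase_age[g2] > p.tau_prime, p.e_m_prime, 0.0)
        m = phase == 4
        rate[m] = p.rates["G0"]
        jump = rng.uniform(size=len(x)) < -np.expm1(-rate * dt)

        in_s_now = (phase == 2) | (jump & (phase == 1))
        last_s[in_s_now] = t

        dividing = jump & m
        phase = np.where(jump, (phase + 1) % len(PHASES), phase)
        phase_age = np.where(jump, 0.0, phase_age + dt)

        if dividing.any():
            nd = int(dividing.sum())
            new_ids = np.arange(next_id, next_id + nd, dtype=np.int64)
            next_id += nd
            events.append(pd.DataFrame({
                "time_min": t, "x_um": x[dividing],
                "parent_id": ids[dividing], "child_id": new_ids,
            }))
            x = np.concatenate([x, x[dividing]])
            phase = np.concatenate([phase, phase[dividing]])
            phase_age = np.concatenate([phase_age, np.zeros(nd)])
            last_s = np.concatenate([last_s, last_s[dividing]])
            lineage = np.concatenate([lineage, ids[dividing]])
            birth = np.concatenate([birth, np.full(nd, t)])
            ids = np.concatenate([ids, new_ids])

        # --- movement ----------------------------------------------------
        if config.movement:
            v_pass, _, _ = _mean_field_velocity(x, phase, p, grid)
            drift = (v_pass + v_phase[phase]) * dt
            disp = drift + (rng.normal(0.0, sigma, len(x)) if sigma > 0 else 0.0)
            x = np.abs(x + disp)                 # reflect at the tip
            keep = x <= p.x_max                  # absorbing far end
            if not keep.all():
                x, phase, phase_age = x[keep], phase[keep], phase_age[keep]
                last_s, lineage = last_s[keep], lineage[keep]
                birth, ids = birth[keep], ids[keep]

        if rec_stride is not None and step % rec_stride == 0:
            record_tracks(t)
        if step in snap_steps:
            take_snapshot(t)

    final = pd.DataFrame({
        "id": ids, "x_um": x, "phase": np.array(PHASES)[phase],
        "phase_age_min": phase_age,
        "edu": last_s >= config.t_end - config.edu_window,
        "lineage": lineage, "birth_min": birth,
    })
    tracks = (pd.concat(track_chunks, ignore_index=True)
              if track_chunks else None)
    events = (pd.concat(events, ignore_index=True) if events
              else pd.DataFrame(columns=["time_min", "x_um", "parent_id",
                                         "child_id"]))
    manifest = {
        "seed": config.seed, "n_agents_initial": config.n_agents,
        "n_agents_final": len(ids), "t_end": config.t_end, "dt": config.dt,
        "edu_window": config.edu_window, "n_divisions": len(events),
    }
    return SimResult(tracks, events, snapshots, final, manifest)


def emulate_edu_pulse(tracks: pd.DataFrame, edu_window: float,
                      events: pd.DataFrame | None = None) -> pd.Series:
    """EdU labels from a track table: an agent is EdU+ iff it was recorded
    in S at any time during the final ``edu_window`` before the last
    recorded time; daughters born within the window inherit the parent's
    label (heritable thymidine-analog incorporation)."""
    t_end = tracks["time_min"].max()
    t0 = t_end - edu_window
    if t0 < tracks["time_min"].min() - 1e-9:
        raise ValueError("EdU window longer than the recorded history")
    recent = tracks[tracks["time_min"] >= t0]
    s_pos = set(recent.loc[recent["phase"] == "S", "id"].unique())
    labels = {i: (i in s_pos) for i in tracks["id"].unique()}
    if events is not None and len(events):
        for ev in events.sort_values("time_min").itertuples():
            if ev.time_min >= t0 and ev.parent_id in labels:
                labels[ev.child_id] = labels.get(ev.child_id, False) or \
                    labels[ev.parent_id]
    return pd.Series(labels, name="edu")


_MARKERS = ("EdU", "Ki67", "H3S10p", "CB1")


def emulate_markers(snapshot: pd.DataFrame, dropout: float = 0.0,
                    seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Immunostaining flags from true phases.

    Ki67+ for any non-G0 cell, H3S10p+ for M, cyclin B1 (CB1)+ for G2 and
    M, EdU from the pulse bookkeeping.  Each flag is independently
    replaced by "undetermined" with probability ``dropout`` (ambiguous
    staining excluded from analysis downstream).
    """
    if not (0.0 <= dropout < 1.0):
        raise ValueError("dropout must be in [0, 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = snapshot.copy()
    phase = out["phase"]
    flags = {
        "EdU": out["edu"].to_numpy(bool) if "edu" in out else phase.eq("S").to_numpy(),
        "Ki67": (~phase.eq("G0")).to_numpy(),
        "H3S10p": phase.eq("M").to_numpy(),
        "CB1": phase.isin(["G2", "M"]).to_numpy(),
    }
    for name, val in flags.items():
        col = np.where(val, "+", "-")
        if dropout > 0:
            col = np.where(rng.uniform(size=len(col)) < dropout,
                           "undetermined", col)
        out[name] = col
    return out


def sample_strands(field: PhaseField, age: AgeField, grid: Grid,
                   params: ModelParams, n_strands: int = 200,
                   n_cells: int = 10, cell_length: float = 15.0,
                   jitter: float = 2.0, dropout: float = 0.0,
                   seed: int = 0) -> pd.DataFrame:
    """Synthetic "fixed and stained" strands drawn from a continuum state.

    Each strand places ``n_cells`` nuclei at spacing ``cell_length``
    (position jittered), draws each cell's phase from the local fractions
    and, for G2 cells, an age from the local age density; marker flags
    follow :func:`emulate_markers` with EdU+ meaning S now or G2 of age at
    most params.tau0.  This is the unit of observation of the per-order
    quantification.
    """
    rng = np.random.default_rng(seed)
    xn = grid.x_nodes
    rows = []
    psi = np.clip(age.psi, 0, None)
    taun = grid.tau_nodes
    for sid in range(n_strands):
        base = (np.arange(n_cells) + 0.5) * cell_length
        pos = np.clip(base + rng.normal(0.0, jitter, n_cells), 0.0,
                      params.x_max)
        pos = np.sort(pos)
        idx = np.clip(np.round(pos / grid.dx).astype(int), 0, len(xn) - 1)
        fr = np.clip(field.rho[:, idx].T, 0, None)
        fr /= fr.sum(axis=1, keepdims=True)
        u = rng.uniform(size=n_cells)
        ph = (u[:, None] > np.cumsum(fr, axis=1)).sum(axis=1)
        age_min = np.zeros(n_cells)
        for j in np.nonzero(ph == 3)[0]:
            pdf = psi[idx[j]]
            if pdf.sum() > 0:
                age_min[j] = rng.choice(taun, p=pdf / pdf.sum())
        edu = (ph == 2) | ((ph == 3) & (age_min <= params.tau0))
        rows.append(pd.DataFrame({
            "strand_id": sid, "x_um": pos,
            "phase": np.array(PHASES)[ph], "phase_age_min": age_min,
            "edu": edu,
        }))
    snap = pd.concat(rows, ignore_index=True)
    return emulate_markers(snap, dropout=dropout, seed=rng)
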