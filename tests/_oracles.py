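"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's solver machinery: the well-mixed
phase-fraction system is integrated with scipy's ODE solver, and the
age-structured well-mixed variant with a plain fine-grid characteristics
scheme written from scratch here.
"""

import numpy as np
from scipy.integrate import solve_ivp

PHASES = ("G0", "G1", "S", "G2", "M")


def well_mixed_rhs(rho, rates, c=0.0):
    """d rho / dt of the well-mixed fraction system with dilution.

    rho ordered (G0, G1, S, G2, M); rates is the dict of entry rates e_i.
    Influx into phase i is a_i e_i rho_{i-1} (a_G0 = 2: division yields
    two daughters), efflux e_{i+1} rho_i, and every phase is diluted by
    the population growth rate e_G0 rho_M + c so the fractions stay
    normalized.
    """
    g0, g1, s, g2, m = rho
    e = rates
    growth = e["G0"] * m + c
    return np.array([
        2.0 * e["G0"] * m - e["G1"] * g0 - g0 * growth + c * g0,
        e["G1"] * g0 - e["S"] * g1 - g1 * growth + c * g1,
        e["S"] * g1 - e["G2"] * s - s * growth + c * s,
        e["G2"] * s - e["M"] * g2 - g2 * growth + c * g2,
        e["M"] * g2 - e["G0"] * m - m * growth + c * m,
    ])


def integrate_well_mixed(rho0, rates, t_end, c=0.0, entry_rate=None):
    """Integrate the 5-phase well-mixed system to t_end (min)."""
    e = dict(rates)
    if entry_rate is not None:
        e["G1"] = entry_rate

    sol = solve_ivp(lambda t, r: well_mixed_rhs(r, e, c),
                    (0.0, t_end), np.asarray(rho0, dtype=float),
                    rtol=1e-10, atol=1e-12, method="LSODA")
    return sol.y[:, -1]


def integrate_age_structured_well_mixed(rho0, params, t_end, dt=0.5):
    """Fine-grid characteristics integration of the well-mixed system
    with the age-resolved G2 compartment and refractory period.

    Independent of the package's solver: age cells of width ``dt`` are
    shifted exactly each step with survival exp(-e_M' * exposure beyond
    tau'), G2 entry feeds age zero, everything is diluted by the growth
    rate, and the fractions are renormalized.  Returns (rho, psi, tau).
    """
    e = params.rates
    emp = params.e_m_prime
    tp = params.tau_prime
    tau_max = tp + 12.0 / emp
    n_tau = int(np.ceil(tau_max / dt)) + 1
    tau = np.arange(n_tau) * dt
    g0, g1, s, g2, m = (float(v) for v in rho0)
    # start G2 ages exponential at the base-rate scale
    psi = np.exp(-params.e_base * tau)
    psi *= g2 / np.trapezoid(psi, tau)
    exposed = np.clip(tau[1:] - np.maximum(tp, tau[:-1]), 0.0, dt)
    surv = np.exp(-emp * exposed)
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        f_entry = e["G1"] * g0 * dt
        f_g1s = e["S"] * g1 * dt
        f_sg2 = e["G2"] * s * dt
        f_mg0 = e["G0"] * m * dt
        g2_before = np.trapezoid(psi, tau)
        psi[1:] = psi[:-1] * surv
        psi[0] = e["G2"] * s
        f_g2m = g2_before + f_sg2 - np.trapezoid(psi, tau)
        g0 += 2.0 * f_mg0 - f_entry
        g1 += f_entry - f_g1s
        s += f_g1s - f_sg2
        m += f_g2m - f_mg0
        g2 = np.trapezoid(psi, tau)
        total = g0 + g1 + s + g2 + m
        g0, g1, s, m = g0 / total, g1 / total, s / total, m / total
        psi /= total
        g2 /= total
    return np.array([g0, g1, s, g2, m]), psi, tau


def pearson_chi2(table):
    """Hand-rolled chi-square of independence, Sum (O-E)^2 / E."""
    t = np.asarray(table, dtype=float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    exp = row * col / t.sum()
    return float(((t - exp) ** 2 / exp).sum())


def exact_binomial_two_sided(k, n, p):
    """Two-sided exact binomial p-value by full enumeration: sum the
    probabilities of outcomes no more likely than the observed one."""
    from math import comb

    pmf = np.array([comb(n, i) * p**i * (1 - p) ** (n - i)
                    for i in range(n + 1)])
    return float(min(pmf[pmf <= pmf[k] * (1 + 1e-12)].sum(), 1.0))


def mann_whitney_exact(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all assignments of
    the pooled ranks (tie-free samples only)."""
    from itertools import combinations

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = pooled.argsort().argsort() + 1
    n1 = len(a)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = len(pooled)
    us = []
    for idx in combinations(range(n), n1):
        r = np.sort(ranks)[list(idx)]
        us.append(r.sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    mean_u = n1 * (n - n1) / 2
    p = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
    return float(min(p, 1.0))


def otsu_exhaustive(values, bins=256):
    """Threshold maximizing between-class variance by exhaustive search
    over histogram splits."""
    v = np.asarray(values, dtype=float)
    counts, edges = np.histogram(v, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = counts / counts.sum()
    best, best_t = -np.inf, None
    for k in range(1, bins):
        w0, w1 = p[:k].sum(), p[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (p[:k] * centers[:k]).sum() / w0
        m1 = (p[k:] * centers[k:]).sum() / w1
        bc = w0 * w1 * (m0 - m1) ** 2
        if bc > best:
            best, best_t = bc, centers[k - 1]
    return best_t
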