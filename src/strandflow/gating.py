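"""Cell-cycle and bioenergetics gating utilities.

Three independent tool sets:

* a single-cycle DNA-content histogram deconvolution (G0/G1 and G2/M as
  Gaussians, the S compartment as a train of Gaussian-broadened slabs
  between the two peaks), returning phase percentages and the intensity
  gates used to stage individual cells;
* Fucci4 four-channel threshold classification (Otsu threshold, positive
  above it, negative below half of it, undetermined in between);
* the PercevalHR ATP:ADP probe's pH correction against the pHRed probe
  (linear calibration r_PercevalHR = k r_pHRed + q; corrected ratio
  r_corr = r_PercevalHR - k r_pHRed) and its normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import norm as _norm
from skimage.filters import threshold_otsu

__all__ = [
    "DnaHistogram",
    "CellCycleFit",
    "fit_dna_histogram",
    "gate_cells",
    "perceval_calibrate",
    "perceval_correct",
    "otsu_threshold",
    "fucci4_classify",
]


@dataclass
class DnaHistogram:
    """Integrated DNA-stain intensity histogram."""

    bin_centers: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_centers.ndim != 1 or self.counts.shape != self.bin_centers.shape:
            raise ValueError("bin_centers and counts must be matching 1D arrays")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if np.any(self.counts < 0) or self.counts.sum() <= 0:
            raise ValueError("counts must be non-negative with positive total")

    @classmethod
    def from_intensities(cls, values, bins: int = 100) -> "DnaHistogram":
        counts, edges = np.histogram(np.asarray(values, dtype=float), bins=bins)
        return cls(0.5 * (edges[:-1] + edges[1:]), counts)


@dataclass
class CellCycleFit:
    """Result of the single-cycle DNA-histogram deconvolution."""

    mu_g1: float
    sigma_g1: float
    mu_g2m: float
    sigma_g2m: float
    s_weights: np.ndarray
    w_g1: float
    w_g2m: float
    percentages: dict
    gate_low: float
    gate_high: float
    residual_rel: float

    def as_dict(self) -> dict:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.__dict__.items()}
        return d


def _components(x, mu1, s1, mu2, s2, n_slabs):
    """Column design: G1 Gaussian | S slabs | G2/M Gaussian (densities)."""
    cols = [_norm.pdf(x, mu1, s1)]
    centers = mu1 + (np.arange(n_slabs) + 0.5) / n_slabs * (mu2 - mu1)
    s_broad = 0.5 * (s1 + s2)
    for c in centers:
        cols.append(_norm.pdf(x, c, s_broad))
    cols.append(_norm.pdf(x, mu2, s2))
    return np.column_stack(cols)


def _solve_weights(A, y, smooth: float):
    """Non-negative least squares with a second-difference penalty on the
    S-slab weights (regularizes the slab train toward smoothness)."""
    n_slabs = A.shape[1] - 2
    pen = np.zeros((n_slabs - 2, A.shape[1]))
    lam = smooth * np.abs(y).max()
    for i in range(n_slabs - 2):
        pen[i, 1 + i: 4 + i] = lam * np.array([1.0, -2.0, 1.0])
    A_aug = np.vstack([A, pen])
    y_aug = np.concatenate([y, np.zeros(len(pen))])
    w, _ = optimize.nnls(A_aug, y_aug)
    resid = A @ w - y
    return w, float(np.sqrt(np.sum(resid**2)))


def fit_dna_histogram(hist: DnaHistogram, n_slabs: int = 20,
                      ratio_bounds: tuple = (1.8, 2.1),
                      smooth: float = 0.05,
                      max_residual_rel: float = 0.25) -> CellCycleFit:
    """Deconvolve a DNA-content histogram into G0/G1, S and G2/M.

    Two-stage fit.  Each peak is first characterized locally by a
    Gaussian plus a constant baseline (the baseline absorbs the roughly
    flat S-phase density under the peak, which otherwise makes the peak
    width unidentifiable).  With the peak positions and widths fixed, all
    component weights — G0/G1, the smoothness-regularized S slabs, G2/M —
    are solved by a single non-negative least squares.

    Percentages come from component in-range areas; the gates sit where
    adjacent fitted component densities cross.  Raises on non-convergence
    (large relative residual — e.g. when the data cannot be explained
    with a G2/G1 ratio inside ``ratio_bounds``).
    """
    x, y = hist.bin_centers, hist.counts
    if len(x) < 20:
        raise ValueError("need at least 20 histogram bins")
    lo, hi = ratio_bounds
    binw = x[1] - x[0]

    def local_peak(center0, span):
        """Gaussian + baseline fit within ``span`` of ``center0``."""
        sel = np.abs(x - center0) <= span
        if sel.sum() < 5:
            return center0, 0.05 * center0, 0.0
        xx, yy = x[sel], y[sel]

        def model(t, amp, mu, sig, base):
            return amp * np.exp(-0.5 * ((t - mu) / sig) ** 2) + base

        p0 = (max(yy.max() - np.median(yy), 1.0), center0,
              0.04 * center0, np.median(yy))
        try:
            popt, _ = optimize.curve_fit(
                model, xx, yy, p0=p0,
                bounds=([0.0, center0 - span, binw, 0.0],
                        [np.inf, center0 + span, span, np.inf]),
                maxfev=5000)
        except RuntimeError:
            return center0, 0.05 * center0, 0.0
        amp, mu, sig, _ = popt
        return float(mu), float(sig), float(amp)

    # the global mode can only be the G2/M peak if cells with half its
    # DNA content are visibly present
    mode = x[np.argmax(y)]
    half = (x >= 0.85 * mode / 1.95) & (x <= 1.15 * mode / 1.95)
    if half.any() and y[half].max() >= 0.2 * y.max():
        mu1_0 = mode / 1.95 if y[half].max() > y.max() * 0.999 else mode
        # ambiguous only if the half-DNA region rivals the mode itself;
        # resolve by comparing local peak amplitudes
        m_lo, s_lo, a_lo = local_peak(mode / 1.95, 0.1 * mode)
        if a_lo > 0.5 * y.max():
            mu1_0 = m_lo
        else:
            mu1_0 = mode
    else:
        mu1_0 = mode
    mu1, s1, _ = local_peak(mu1_0, 0.12 * mu1_0)
    # G2/M peak: strongest location inside the admissible ratio window
    win = (x >= lo * mu1) & (x <= hi * mu1)
    mu2_0 = x[win][np.argmax(y[win])] if win.any() else 1.95 * mu1
    mu2, s2, _ = local_peak(mu2_0, 0.1 * mu2_0)
    mu2 = float(np.clip(mu2, lo * mu1, hi * mu1))
    if s2 <= 0 or not np.isfinite(s2):
        s2 = 1.95 * s1

    # polish the peak parameters around the local estimates; the sigmas
    # stay within +/-30% of the locally identified widths so the S slabs
    # cannot masquerade as peak shoulders
    def unpack(theta):
        t = np.clip(theta, -60.0, 60.0)
        m1 = mu1 * (0.96 + 0.08 / (1.0 + np.exp(-t[0])))
        sg1 = s1 * (0.7 + 0.6 / (1.0 + np.exp(-t[1])))
        ratio = lo + (hi - lo) / (1.0 + np.exp(-t[2]))
        sg2 = s2 * (0.7 + 0.6 / (1.0 + np.exp(-t[3])))
        return m1, sg1, m1 * ratio, sg2

    def objective(theta):
        m1, sg1, m2, sg2 = unpack(theta)
        A = _components(x, m1, sg1, m2, sg2, n_slabs)
        _, rn = _solve_weights(A, y, smooth)
        return rn

    r0 = np.clip(mu2 / mu1, lo + 1e-6, hi - 1e-6)
    theta0 = np.array([0.0, 0.0, np.log((r0 - lo) / (hi - r0)), 0.0])
    res = optimize.minimize(objective, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-3, "fatol": 1e-6,
                                     "maxiter": 250})
    mu1, s1, mu2, s2 = unpack(res.x)
    A = _components(x, mu1, s1, mu2, s2, n_slabs)
    w, rnorm = _solve_weights(A, y, smooth)
    resid_rel = rnorm / np.linalg.norm(y)
    if resid_rel > max_residual_rel:
        raise RuntimeError(
            f"histogram fit did not converge (relative residual "
            f"{resid_rel:.3f}); peaks mu_g1={mu1:.1f}, mu_g2m={mu2:.1f} — "
            "the data may violate the G2/G1 ratio constraint "
            f"{ratio_bounds}"
        )
    # percentages from the mass each component contributes within the
    # observed intensity range (an off-range component can carry a huge
    # nominal weight at zero observable density)
    contrib = w * A.sum(axis=0)
    total = contrib.sum()
    pct = {
        "G0/G1": 100.0 * contrib[0] / total,
        "S": 100.0 * contrib[1:-1].sum() / total,
        "G2/M": 100.0 * contrib[-1] / total,
    }
    # gates at the crossings of adjacent component densities
    fine = np.linspace(mu1, mu2, 2001)
    Af = _components(fine, mu1, s1, mu2, s2, n_slabs)
    d_g1 = Af[:, 0] * w[0]
    d_s = Af[:, 1:-1] @ w[1:-1]
    d_g2 = Af[:, -1] * w[-1]
    cross_lo = np.nonzero(d_s > d_g1)[0]
    gate_low = float(fine[cross_lo[0]]) if len(cross_lo) else float(mu1 + 2 * s1)
    cross_hi = np.nonzero(d_g2 > d_s)[0]
    gate_high = float(fine[cross_hi[0]]) if len(cross_hi) else float(mu2 - 2 * s2)
    if not gate_low < gate_high:
        gate_low, gate_high = float(mu1 + 2 * s1), float(mu2 - 2 * s2)
    return CellCycleFit(
        mu_g1=float(mu1), sigma_g1=float(s1), mu_g2m=float(mu2),
        sigma_g2m=float(s2), s_weights=w[1:-1], w_g1=float(w[0]),
        w_g2m=float(w[-1]), percentages=pct, gate_low=gate_low,
        gate_high=gate_high, residual_rel=float(resid_rel),
    )


def gate_cells(intensities, fit: CellCycleFit) -> np.ndarray:
    """Stage cells from integrated DNA intensity using the fitted gates.

    Below gate_low: G0/G1; from gate_low (inclusive) up to gate_high
    (exclusive): S; at and above gate_high: G2/M.
    """
    x = np.asarray(intensities, dtype=float)
    labels = np.where(x < fit.gate_low, "G0/G1",
                      np.where(x < fit.gate_high, "S", "G2/M"))
    return labels


def perceval_calibrate(r_perceval, r_phred):
    """OLS slope and intercept of r_PercevalHR = k r_pHRed + q from a
    transient-alkalization calibration series."""
    rp = np.asarray(r_perceval, dtype=float)
    rh = np.asarray(r_phred, dtype=float)
    if rp.shape != rh.shape or rp.size < 3:
        raise ValueError("need at least 3 paired calibration points")
    if np.var(rh) == 0:
        raise ValueError("r_pHRed has zero variance; calibration impossible")
    k, q = np.polyfit(rh, rp, 1)
    return float(k), float(q)


def perceval_correct(records, k: float, mode: str = "control-mean"):
    """pH-corrected and normalized ATP:ADP ratio.

    ``records`` is a DataFrame with columns r_perceval and r_phred plus,
    for mode "control-mean", a boolean column ``control``, or, for mode
    "first-division", columns ``cell_id`` and boolean ``first_division``
    marking each cell's reference frame.  Adds columns r_corr and r_norm.
    """
    df = records.copy()
    df["r_corr"] = df["r_perceval"] - k * df["r_phred"]
    if mode == "control-mean":
        if "control" not in df or not df["control"].any():
            raise ValueError("control-mean mode needs a non-empty control set")
        ref = df.loc[df["control"], "r_corr"].mean()
        if ref == 0:
            raise ValueError("zero control-mean normalizer")
        df["r_norm"] = df["r_corr"] / ref
    elif mode == "first-division":
        ref = (df[df["first_division"]]
               .set_index("cell_id")["r_corr"])
        if ref.index.has_duplicates:
            raise ValueError("multiple first-division frames for one cell")
        base = df["cell_id"].map(ref)
        if base.isna().any() or (base == 0).any():
            raise ValueError("missing or zero first-division reference")
        df["r_norm"] = df["r_corr"] / base
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return df


def otsu_threshold(values, bins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance."""
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("constant input has no threshold")
    return float(threshold_otsu(v, nbins=bins))


_FUCCI_CHANNELS = ("mKO2", "mTurquoise2", "Clover", "mMaroon1")


def _channel_state(value: float, threshold: float) -> str:
    if value >= threshold:
        return "+"
    if value < 0.5 * threshold:
        return "-"
    return "undetermined"


def fucci4_classify(intensities: dict, thresholds: dict,
                    condensed: bool = False) -> str:
    """Cell-cycle stage from Fucci4 nuclear intensities.

    Channel calls: at or above the (Otsu) threshold positive, below half
    of it negative, in between undetermined.  mMaroon1 (histone-fused,
    never fully absent) only distinguishes construct expression (at or
    above half threshold) from undetermined.  Stages:

    * G1(0): mKO2+, Clover-
    * S: Clover+ and (mTurquoise2+ or mKO2+)
    * G2: mTurquoise2-, mKO2-, mMaroon1 expressing, nucleus not condensed
    * M: as G2 but condensed

    Negative calls alone never force a stage; anything else is
    "undetermined".
    """
    missing = [c for c in _FUCCI_CHANNELS if c not in intensities
               or c not in thresholds]
    if missing:
        raise KeyError(f"missing Fucci4 channel(s): {missing}")
    k = _channel_state(intensities["mKO2"], thresholds["mKO2"])
    t = _channel_state(intensities["mTurquoise2"], thresholds["mTurquoise2"])
    c = _channel_state(intensities["Clover"], thresholds["Clover"])
    maroon_expr = intensities["mMaroon1"] >= 0.5 * thresholds["mMaroon1"]
    if k == "+" and c == "-":
        return "G1(0)"
    if c == "+" and (t == "+" or k == "+"):
        return "S"
    if t == "-" and k == "-" and maroon_expr:
        return "M" if condensed else "G2"
    return "undetermined"
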