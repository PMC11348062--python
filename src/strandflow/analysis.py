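"""Quantification of cell-cycle distributions along invading strands.

The observation unit is a strand snapshot: a table of cells with a
distance to the strand tip and marker flags (EdU, Ki-67, H3S10p, cyclin
B1, each "+", "-" or "undetermined").  Cells are ranked by distance
("cell order", 1 = leader); only the first eight physically connected
cells are analysed, with orders five to eight pooled into one group.
Marker positivity fractions per order are the central readout, together
with the relative percentages (e.g. S or M cells among all Ki-67+
proliferating cells), a distance-to-order bridge, division-frequency
profiles, tip-approach speed summaries and a slope-based classification
of profiles as front- or rear-concentrated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ORDER_BINS",
    "ORDER_ABSCISSA",
    "assign_orders",
    "order_bin",
    "classify_cells",
    "fraction_by_order",
    "relative_percentage",
    "distance_to_order_map",
    "predict_order",
    "order_band_edges",
    "profile_by_order",
    "division_frequency",
    "approach_speed",
    "speed_summary",
    "invasive_index",
    "slope_classification",
]

ORDER_BINS = ("1", "2", "3", "4", "5-8")
#: numeric abscissa for slope fits; the pooled bin sits at its mean order
ORDER_ABSCISSA = np.array([1.0, 2.0, 3.0, 4.0, 6.5])

#: marker requirements of each derived cell class: (flag, wanted) pairs
CLASS_RULES = {
    "S": (("EdU", "+"),),
    "M": (("H3S10p", "+"),),
    "proliferating": (("Ki67", "+"),),
    "G2": (("CB1", "+"), ("H3S10p", "-")),
    "early G2": (("CB1", "+"), ("H3S10p", "-"), ("EdU", "+")),
    "late G2": (("CB1", "+"), ("H3S10p", "-"), ("EdU", "-")),
}


def assign_orders(distances) -> np.ndarray:
    """Rank cells of one strand by distance to the tip (1 = leader).

    Ties keep the input sequence (stable sort).  Returns the raw rank for
    every cell; ranks above eight are excluded downstream.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        return np.array([], dtype=int)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    ranks = np.empty(len(d), dtype=int)
    ranks[np.argsort(d, kind="stable")] = np.arange(1, len(d) + 1)
    return ranks


def order_bin(rank: int) -> str | None:
    """Order bin label for a rank; None beyond the first eight cells."""
    if rank <= 0:
        raise ValueError("ranks are 1-based")
    if rank <= 4:
        return str(rank)
    if rank <= 8:
        return "5-8"
    return None


def _with_orders(snapshots: pd.DataFrame,
                 distance_col: str = "x_um") -> pd.DataFrame:
    df = snapshots.copy()
    if "strand_id" not in df:
        df["strand_id"] = 0
    df["order"] = (
        df.groupby("strand_id", sort=False)[distance_col]
        .transform(lambda s: assign_orders(s.to_numpy()))
    )
    df["order_bin"] = df["order"].map(
        lambda r: order_bin(int(r)) if r <= 8 else None
    )
    return df[df["order_bin"].notna()]


def classify_cells(snapshots: pd.DataFrame, cls: str) -> pd.Series:
    """Tri-state membership of each cell in a marker class.

    Returns +1 (member), 0 (non-member) or -1 (undetermined: some
    required flag could not be called and the remaining flags do not
    already exclude membership).
    """
    if cls in CLASS_RULES:
        rules = CLASS_RULES[cls]
    elif cls in snapshots.columns:
        rules = ((cls, "+"),)
    else:
        raise KeyError(f"unknown class or marker {cls!r}")
    member = np.ones(len(snapshots), dtype=bool)
    undet = np.zeros(len(snapshots), dtype=bool)
    excluded = np.zeros(len(snapshots), dtype=bool)
    for flag, wanted in rules:
        col = snapshots[flag].to_numpy()
        undet |= col == "undetermined"
        excluded |= (col != wanted) & (col != "undetermined")
        member &= col == wanted
    out = np.where(member, 1, np.where(excluded, 0, -1))
    return pd.Series(out, index=snapshots.index, name=cls)


def fraction_by_order(snapshots: pd.DataFrame, cls: str,
                      distance_col: str = "x_um") -> pd.DataFrame:
    """Pooled positivity fraction of a marker class per order bin.

    Cells whose class membership is undetermined are excluded from both
    numerator and denominator.  Returns a table with columns order,
    positive, total, fraction and the binomial standard error; zero
    denominators yield NaN fractions and are flagged.
    """
    df = _with_orders(snapshots, distance_col)
    state = classify_cells(df, cls)
    df = df.assign(_state=state.to_numpy())
    df = df[df["_state"] >= 0]
    rows = []
    for ob in ORDER_BINS:
        sub = df[df["order_bin"] == ob]
        total = len(sub)
        pos = int((sub["_state"] == 1).sum())
        frac = pos / total if total else np.nan
        se = (np.sqrt(frac * (1 - frac) / total)
              if total and not np.isnan(frac) else np.nan)
        rows.append({"order": ob, "positive": pos, "total": total,
                     "fraction": frac, "se": se,
                     "undefined": total == 0})
    out = pd.DataFrame(rows)
    out.attrs["class"] = cls
    return out


def relative_percentage(snapshots: pd.DataFrame, numerator: str,
                        reference: str,
                        distance_col: str = "x_um") -> pd.DataFrame:
    """Per-order ratio of numerator-class to reference-class positives
    (e.g. S or M cells among Ki-67+ proliferating cells, or G2/S)."""
    num = fraction_by_order(snapshots, numerator, distance_col)
    ref = fraction_by_order(snapshots, reference, distance_col)
    ratio = num["positive"] / ref["positive"].where(ref["positive"] > 0)
    return pd.DataFrame({
        "order": num["order"], "numerator": num["positive"],
        "reference": ref["positive"], "ratio": ratio,
        "undefined": ref["positive"] == 0,
    })


def distance_to_order_map(snapshots: pd.DataFrame,
                          distance_col: str = "x_um",
                          max_order: int = 8) -> pd.DataFrame:
    """Mean +/- SE distance to tip per cell order (the strand-geometry
    bridge between distance- and order-based readouts)."""
    df = snapshots.copy()
    if "strand_id" not in df:
        df["strand_id"] = 0
    df["order"] = (
        df.groupby("strand_id", sort=False)[distance_col]
        .transform(lambda s: assign_orders(s.to_numpy()))
    )
    df = df[df["order"] <= max_order]
    g = df.groupby("order")[distance_col]
    out = pd.DataFrame({
        "order": g.mean().index,
        "mean_um": g.mean().to_numpy(),
        "se_um": (g.std(ddof=1) / np.sqrt(g.count())).to_numpy(),
        "n": g.count().to_numpy(),
    }).reset_index(drop=True)
    if not np.all(np.diff(out["mean_um"]) > 0):
        import warnings

        warnings.warn("per-order mean distances are not monotone; the "
                      "nearest-mean rule is still applied")
    return out


def predict_order(distance, order_map: pd.DataFrame):
    """Inverse bridge: assign each distance the order with the nearest
    mean distance (midpoint rule, ties toward the tip; distances beyond
    the last mean clamp to the last order)."""
    means = order_map.sort_values("order")["mean_um"].to_numpy()
    orders = order_map.sort_values("order")["order"].to_numpy()
    mids = 0.5 * (means[:-1] + means[1:])
    idx = np.searchsorted(mids, np.atleast_1d(distance), side="left")
    out = orders[idx]
    return out if np.ndim(distance) else int(out[0])


def order_band_edges(order_map: pd.DataFrame) -> np.ndarray:
    """Distance-band edges for the five order bins (1..4 and 5-8) by the
    midpoint rule on the measured per-order mean distances."""
    means = order_map.sort_values("order")["mean_um"].to_numpy()
    if len(means) < 8:
        raise ValueError("order map must cover orders 1..8")
    mids = 0.5 * (means[:-1] + means[1:])
    upper8 = means[7] + 0.5 * (means[7] - means[6])
    return np.array([0.0, mids[0], mids[1], mids[2], mids[3], upper8])


def profile_by_order(values: np.ndarray, x_nodes: np.ndarray,
                     edges: np.ndarray) -> np.ndarray:
    """Average a continuum profile over the order distance bands."""
    out = np.empty(len(edges) - 1)
    for k in range(len(edges) - 1):
        sel = (x_nodes >= edges[k]) & (x_nodes < edges[k + 1])
        out[k] = values[sel].mean() if sel.any() else np.nan
    return out


def division_frequency(events: pd.DataFrame, bin_edges,
                       total_duration: float, normalize: bool = False,
                       tip_exclusion: float = 0.0) -> pd.DataFrame:
    """Division events per unit time per unit strand length.

    count(bin) / (total_duration * bin_length); ``normalize`` divides by
    the mean across (included) bins; bins fully within ``tip_exclusion``
    um of the tip are flagged and excluded from the normalizer (the
    nuclear center rarely reaches that range, so frequencies there are
    not meaningful).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if total_duration <= 0:
        raise ValueError("total_duration must be positive")
    xs = events["x_um"].to_numpy()
    if len(xs) and (xs.min() < edges[0] or xs.max() >= edges[-1]):
        raise ValueError("bins do not cover all events")
    counts, _ = np.histogram(xs, bins=edges)
    widths = np.diff(edges)
    freq = counts / (total_duration * widths)
    excluded = edges[1:] <= tip_exclusion
    out = pd.DataFrame({
        "x_lo": edges[:-1], "x_hi": edges[1:], "count": counts,
        "frequency_per_um_min": freq, "excluded": excluded,
    })
    if normalize:
        mean = freq[~excluded].mean()
        out["normalized"] = freq / mean if mean > 0 else np.nan
    return out


def approach_speed(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-interval tip-approach speed from tracks of distance to tip.

    Positive speed means the distance to the tip is decreasing.  Tracks
    with a single point are skipped.  The phase label of the interval's
    start is kept when present.
    """
    cols = ["id", "time_min", "x_um"] + (
        ["phase"] if "phase" in tracks else [])
    df = tracks[cols].sort_values(["id", "time_min"])
    g = df.groupby("id", sort=False)
    dt = g["time_min"].diff().shift(-1)
    dx = g["x_um"].diff().shift(-1)
    out = df.assign(speed_um_min=-dx / dt).dropna(subset=["speed_um_min"])
    return out


def speed_summary(speeds: pd.DataFrame, by: str, bins,
                  per_phase: bool = False) -> pd.DataFrame:
    """Binned mean +/- SE of approach speed versus ``by`` (a column such
    as distance to tip or time before division)."""
    df = speeds.copy()
    df["_bin"] = pd.cut(df[by], bins)
    keys = (["phase", "_bin"] if per_phase and "phase" in df else ["_bin"])
    g = df.groupby(keys, observed=True)["speed_um_min"]
    out = g.agg(["mean", "count", "sem"]).reset_index()
    return out.rename(columns={"mean": "speed_mean", "sem": "speed_se",
                               "count": "n"})


def invasive_index(area_t0: float, area_t: float) -> float:
    """Relative projected-area outgrowth of a spheroid, A_t/A_0 - 1."""
    if area_t0 <= 0:
        raise ValueError("initial area must be positive")
    return area_t / area_t0 - 1.0


def slope_classification(fractions, se=None, weights=None,
                         abscissa=ORDER_ABSCISSA, flat_se_factor: float = 2.0,
                         flat_tol: float = 0.0):
    """Classify a per-order profile as front-/rear-concentrated or flat.

    Fits a (weighted) least-squares line of fraction against order index
    (the pooled 5-8 bin sits at 6.5).  The profile is called flat when
    |slope| stays below ``flat_se_factor`` times the slope's standard
    error (count-based tables) or below the absolute ``flat_tol``
    (noise-free continuum profiles); a more negative slope is
    front-concentrated, a more positive one rear-concentrated.

    Returns (label, slope, slope_se).
    """
    y = np.asarray(fractions, dtype=float)
    xs = np.asarray(abscissa, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least three defined order bins")
    y, xs = y[ok], xs[ok]
    if weights is not None:
        w = np.asarray(weights, dtype=float)[ok]
    elif se is not None:
        s = np.asarray(se, dtype=float)[ok]
        w = 1.0 / np.clip(s, 1e-12, None) ** 2
    else:
        w = np.ones_like(y)
    wsum = w.sum()
    xbar = np.average(xs, weights=w)
    ybar = np.average(y, weights=w)
    sxx = np.sum(w * (xs - xbar) ** 2)
    slope = np.sum(w * (xs - xbar) * (y - ybar)) / sxx
    resid = y - ybar - slope * (xs - xbar)
    dof = max(len(y) - 2, 1)
    sigma2 = np.sum(w * resid**2) / dof
    slope_se = float(np.sqrt(sigma2 / sxx))
    band = max(flat_tol, flat_se_factor * slope_se
               if (se is not None or weights is not None) else flat_tol)
    if abs(slope) <= band:
        label = "flat"
    elif slope < 0:
        label = "front-concentrated"
    else:
        label = "rear-concentrated"
    return label, float(slope), slope_se
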