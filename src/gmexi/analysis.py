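"""Data-side computations around the exchange models.

Powder averaging and b0 normalization of 4D DWI volumes, the
signal-versus-diffusion-time slope test (the exchange signature), ROI
aggregation of parameter maps, mode + highest-density-interval summaries
of ROI distributions, scan–rescan repeatability statistics, and Pearson
correlations between ROI tables (e.g. exchange time vs myelin water
fraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "powder_average",
    "slope_test",
    "mode_hdi",
    "repeatability",
    "compare_difference_distributions",
    "correlate_roi_maps",
    "roi_table",
]


def powder_average(dwi, volume_table: pd.DataFrame, mask=None):
    """Arithmetic direction average per shell, b0-normalized per Δ.

    Parameters
    ----------
    dwi : ndarray (X, Y, Z, V) or (n_vox, V)
        Diffusion-weighted data, one volume per row of ``volume_table``.
    volume_table : DataFrame
        Per-volume ``b, Delta, delta`` (and optionally ``shell_index``).
        Shells are formed by unique (b, Delta, delta) in first-appearance
        order, matching protocol shell order.
    mask : ndarray (X, Y, Z) of bool, optional
        Voxels to process (4D input only).

    Returns
    -------
    curves : ndarray (n_vox, n_shells)
        Direction-averaged signal, each shell divided by the mean b = 0 of
        its diffusion time; b = 0 entries become exactly 1.  Voxels whose
        b0 mean is not positive are NaN.
    coords : ndarray (n_vox, 3) or None
        Voxel indices (4D input only).
    b0_mean : ndarray (n_vox,)
        Grand mean of the per-Δ b0 means (raw units), used to rescale σ.
    """
    data = np.asarray(dwi, dtype=float)
    coords = None
    if data.ndim == 4:
        if mask is None:
            mask = np.ones(data.shape[:3], dtype=bool)
        coords = np.argwhere(np.asarray(mask))
        flat = data[coords[:, 0], coords[:, 1], coords[:, 2], :]
    elif data.ndim == 2:
        flat = data
    else:
        raise ValueError("dwi must be 4-D (X,Y,Z,V) or 2-D (n_vox, V)")
    if len(volume_table) != flat.shape[1]:
        raise ValueError(
            f"volume table has {len(volume_table)} rows, data has {flat.shape[1]} volumes"
        )

    if "shell_index" in volume_table.columns:
        shell_ids = volume_table["shell_index"].to_numpy()
    else:
        keys = list(zip(volume_table["b"], volume_table["Delta"], volume_table["delta"]))
        order: dict[tuple, int] = {}
        for k in keys:
            order.setdefault(k, len(order))
        shell_ids = np.array([order[k] for k in keys])
    n_shells = int(shell_ids.max()) + 1
    shell_b = np.empty(n_shells)
    shell_Delta = np.empty(n_shells)
    for s in range(n_shells):
        rows = np.flatnonzero(shell_ids == s)
        shell_b[s] = volume_table["b"].to_numpy()[rows[0]]
        shell_Delta[s] = volume_table["Delta"].to_numpy()[rows[0]]

    # direction average per shell
    curves = np.empty((flat.shape[0], n_shells))
    for s in range(n_shells):
        curves[:, s] = flat[:, shell_ids == s].mean(axis=1)

    # per-Δ normalization by the mean b0 of that diffusion time
    b0_all = []
    for Delta in np.unique(shell_Delta):
        in_Delta = shell_Delta == Delta
        b0_shells = np.flatnonzero(in_Delta & (shell_b == 0))
        if b0_shells.size == 0:
            raise ValueError(f"no b = 0 volume for diffusion time Delta = {Delta}")
        b0_vols = np.isin(shell_ids, b0_shells)
        ref = flat[:, b0_vols].mean(axis=1)
        b0_all.append(ref)
        with np.errstate(divide="ignore", invalid="ignore"):
            curves[:, in_Delta] = np.where(
                ref[:, None] > 0, curves[:, in_Delta] / ref[:, None], np.nan
            )
        curves[:, np.flatnonzero(in_Delta & (shell_b == 0))] = np.where(
            ref[:, None] > 0, 1.0, np.nan
        )
    b0_mean = np.mean(b0_all, axis=0)
    return curves, coords, b0_mean


def slope_test(signals, Deltas):
    """Ordinary least-squares slope of signal against diffusion time.

    The exchange signature is a *negative* slope at fixed b.  Returns
    ``(slope, p_value)`` with a two-sided p for slope = 0; one-sided
    claims should be evaluated as slope < 0 and p/2 below the level.
    """
    signals = np.asarray(signals, dtype=float)
    Deltas = np.asarray(Deltas, dtype=float)
    if signals.size != Deltas.size or signals.size < 3:
        raise ValueError("slope_test needs at least 3 (Delta, signal) pairs")
    res = stats.linregress(Deltas, signals)
    pvalue = res.pvalue if np.isfinite(res.pvalue) else 0.0
    return float(res.slope), float(pvalue)


def mode_hdi(values, mass: float = 0.95, grid_size: int = 512):
    """Distribution mode and highest-density interval of a sample.

    A Gaussian kernel density estimate (Silverman bandwidth) is evaluated
    on a regular grid; the mode is its argmax and the interval is the
    outer envelope of the smallest density-superlevel set holding ``mass``
    of the estimated probability ("integrating around the mode").
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("mode_hdi needs at least 10 values")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    if np.ptp(values) == 0:
        v = float(values[0])
        return v, (v, v)
    kde = stats.gaussian_kde(values, bw_method="silverman")
    pad = 3.0 * values.std() * kde.factor
    grid = np.linspace(values.min() - pad, values.max() + pad, grid_size)
    dens = kde(grid)
    mode = float(grid[np.argmax(dens)])
    order = np.argsort(dens)[::-1]
    csum = np.cumsum(dens[order])
    csum /= csum[-1]
    k = np.searchsorted(csum, mass) + 1
    sel = grid[np.sort(order[:k])]
    return mode, (float(sel[0]), float(sel[-1]))


@dataclass
class RepeatabilityReport:
    """Scan–rescan variability summary over (subject, ROI) tables."""

    intra: np.ndarray  # |session1 − session2| per (subject, ROI)
    inter: np.ndarray  # |subj_a − subj_b| (session 1) per (pair, ROI)
    intra_corr: float  # Pearson r, session1 vs session2, pooled subjects
    inter_corr: float  # Pearson r, all subject pairs at session1, pooled


def repeatability(table: pd.DataFrame, value_col: str = "value") -> RepeatabilityReport:
    """Intra- vs inter-subject difference distributions and correlations.

    ``table`` has columns ``roi_id, subject, session, value`` with exactly
    two sessions per subject and matching ROI sets.  Intra-subject
    differences compare the two sessions of each subject; inter-subject
    differences compare the first sessions of all subject pairs.
    """
    required = {"roi_id", "subject", "session", value_col}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    wide = table.pivot_table(
        index=["subject", "roi_id"], columns="session", values=value_col
    )
    if wide.shape[1] != 2:
        raise ValueError(f"expected exactly 2 sessions, found {wide.shape[1]}")
    if wide.isna().any().any():
        raise ValueError("every subject needs both sessions for every ROI")
    s1, s2 = wide.iloc[:, 0], wide.iloc[:, 1]
    intra = np.abs(s1 - s2).to_numpy()
    intra_corr = float(stats.pearsonr(s1, s2).statistic)

    first = s1.unstack(level="roi_id")  # subjects × ROIs at session 1
    subjects = first.index.to_list()
    pair_a, pair_b, inter = [], [], []
    for i in range(len(subjects)):
        for j in range(i + 1, len(subjects)):
            a = first.loc[subjects[i]].to_numpy()
            b = first.loc[subjects[j]].to_numpy()
            inter.append(np.abs(a - b))
            pair_a.append(a)
            pair_b.append(b)
    inter = np.concatenate(inter) if inter else np.array([])
    if pair_a:
        inter_corr = float(
            stats.pearsonr(np.concatenate(pair_a), np.concatenate(pair_b)).statistic
        )
    else:
        inter_corr = np.nan
    return RepeatabilityReport(intra=intra, inter=inter, intra_corr=intra_corr, inter_corr=inter_corr)


def compare_difference_distributions(diff_a, diff_b):
    """Paired Wilcoxon signed-rank test between two methods' difference
    distributions (e.g. NEXI vs SMEX scan–rescan differences).

    Returns ``(statistic, p_value)``, two-sided.
    """
    diff_a = np.asarray(diff_a, dtype=float)
    diff_b = np.asarray(diff_b, dtype=float)
    if diff_a.shape != diff_b.shape:
        raise ValueError("paired comparison needs equal-length samples")
    res = stats.wilcoxon(diff_a, diff_b)
    return float(res.statistic), float(res.pvalue)


def correlate_roi_maps(a: pd.DataFrame, b: pd.DataFrame, value_col: str = "value"):
    """Pearson correlation between two measures across shared ROIs.

    Each table has columns ``roi_id, value`` and optionally ``subject``;
    values are averaged over subjects per ROI first.  Returns
    ``(r, p_value, paired_frame)``.
    """

    def roi_means(t):
        if "subject" in t.columns:
            return t.groupby("roi_id")[value_col].mean()
        return t.set_index("roi_id")[value_col]

    ma, mb = roi_means(a), roi_means(b)
    shared = ma.index.intersection(mb.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared ROIs")
    x, y = ma.loc[shared].to_numpy(), mb.loc[shared].to_numpy()
    res = stats.pearsonr(x, y)
    paired = pd.DataFrame({"roi_id": shared, "a": x, "b": y})
    return float(res.statistic), float(res.pvalue), paired


def roi_table(
    param_map, labels, lut: pd.DataFrame | None = None,
    subject: str = "", session: str = "", robust: bool = False,
) -> pd.DataFrame:
    """Aggregate a 3D parameter map over an integer ROI label image.

    ``labels`` is an integer 3D array (0 = background); ``lut`` an optional
    DataFrame with columns ``id, name``.  Mean aggregation by default;
    ``robust=True`` uses the median.  NaN voxels are excluded.
    """
    pm = np.asarray(param_map, dtype=float)
    lab = np.asarray(labels)
    if pm.shape != lab.shape:
        raise ValueError("parameter map and label image shapes disagree")
    rows = []
    names = {}
    if lut is not None:
        names = dict(zip(lut["id"], lut["name"]))
    agg = np.nanmedian if robust else np.nanmean
    for roi in np.unique(lab):
        if roi == 0:
            continue
        vals = pm[lab == roi]
        vals = vals[np.isfinite(vals)]
        rows.append(
            {
                "roi_id": names.get(roi, str(roi)),
                "subject": subject,
                "session": session,
                "value": agg(vals) if vals.size else np.nan,
                "n_voxels": int(vals.size),
            }
        )
    return pd.DataFrame(rows)
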