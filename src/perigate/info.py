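"""Histogram entropy and mutual-information estimators.

All estimators are plug-in (histogram) estimators in bits, matching the
time-resolved analyses: mutual information between the spike count in a time
bin and the identity of the central stimulus, conditioned on the time p since
the last peripheral shift; chain-rule decompositions over periphery, contrast
and intensity sequence; conditional mutual information given the previous
response; and a quadratic extrapolation in inverse data fraction to reduce
finite-sample bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import PeripheralSchedule, SpikeResponse

__all__ = [
    "DiscreteJoint",
    "InfoTimecourse",
    "entropy",
    "mutual_information",
    "joint_from_labels",
    "chain_rule_decompose",
    "info_center_given_p",
    "sequence_contrast_decompose",
    "conditional_mi_prev",
    "extrapolate_info",
    "quantize",
]

_ATOL = 1e-9


@dataclass
class DiscreteJoint:
    """A joint probability table with named axes."""

    table: np.ndarray
    axes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim != len(self.axes):
            raise ValueError("axes must name every table dimension")
        if np.any(self.table < -_ATOL):
            raise ValueError("joint table has negative mass")
        if abs(self.table.sum() - 1.0) > 1e-6:
            raise ValueError("joint table must sum to 1")

    def marginal(self, *names: str) -> np.ndarray:
        keep = tuple(self.axes.index(n) for n in names)
        drop = tuple(i for i in range(self.table.ndim) if i not in keep)
        out = self.table.sum(axis=drop)
        order = np.argsort(np.argsort(keep))
        return np.transpose(out, order) if out.ndim > 1 else out


@dataclass
class InfoTimecourse:
    """Mutual information (bits) per time bin relative to the peripheral shift."""

    p_bins: np.ndarray       # left edges of p bins (s since shift)
    info: np.ndarray         # bits per bin
    meta: dict = field(default_factory=dict)


def entropy(dist: np.ndarray) -> float:
    """Shannon entropy -sum p log2 p in bits, with 0 log 0 = 0."""
    p = np.asarray(dist, dtype=float).ravel()
    if np.any(p < -_ATOL):
        raise ValueError("negative probability mass")
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def mutual_information(joint: np.ndarray) -> float:
    """I(X;Y) in bits from a 2-D joint probability table."""
    pxy = np.asarray(joint, dtype=float)
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    return entropy(px) + entropy(py) - entropy(pxy)


def joint_from_labels(*label_arrays: np.ndarray) -> np.ndarray:
    """Empirical joint probability table from aligned integer label arrays."""
    labels = [np.asarray(a) for a in label_arrays]
    n = labels[0].size
    if any(a.size != n for a in labels):
        raise ValueError("label arrays must be aligned")
    uniq = [np.unique(a) for a in labels]
    idx = [np.searchsorted(u, a) for u, a in zip(uniq, labels)]
    shape = tuple(u.size for u in uniq)
    flat = np.ravel_multi_index(idx, shape)
    counts = np.bincount(flat, minlength=int(np.prod(shape)))
    return counts.reshape(shape) / n


def _mi_from_labels(x: np.ndarray, y: np.ndarray) -> float:
    return mutual_information(joint_from_labels(x, y))


def chain_rule_decompose(joint: DiscreteJoint | np.ndarray) -> dict:
    """Split I(R;P,C) into I(R;P) + <I(R;C|p)> over a 3-axis joint (R, P, C).

    The components satisfy exact additivity on the same discretization.
    """
    if isinstance(joint, DiscreteJoint):
        if set(joint.axes) != {"R", "P", "C"}:
            raise ValueError("joint must have axes R, P, C")
        tbl = np.transpose(joint.table, [joint.axes.index(n)
                                         for n in ("R", "P", "C")])
    else:
        tbl = np.asarray(joint, dtype=float)
        if tbl.ndim != 3:
            raise ValueError("need a 3-axis joint (R, P, C)")
    p_rp = tbl.sum(axis=2)
    i_rp = mutual_information(p_rp)
    p_p = tbl.sum(axis=(0, 2))
    i_rc_given_p = 0.0
    for k in range(tbl.shape[1]):
        if p_p[k] == 0:
            continue
        cond = tbl[:, k, :] / p_p[k]
        i_rc_given_p += p_p[k] * mutual_information(cond)
    p_r_pc = tbl.reshape(tbl.shape[0], -1)
    i_total = mutual_information(p_r_pc)
    return {"I(R;P)": i_rp, "I(R;C|p)": i_rc_given_p, "I(R;P,C)": i_total}


def info_center_given_p(responses: SpikeResponse, center_ids: np.ndarray,
                        schedule: PeripheralSchedule,
                        p_bin_s: float = 0.05,
                        average_phases: bool = True,
                        max_count: int | None = None) -> InfoTimecourse:
    """Time course of I(R;C|p): information between spike count and center id.

    ``responses.counts`` has one row per repeat trial and one column per time
    bin of width ``p_bin_s``; ``center_ids`` labels the central stimulus
    segment shown in each time bin (columns of the repeated sequence are the
    distinct central stimuli C).  For each p bin (time since shift, per shift
    phase) the plug-in information I = H(R|p) - H(R|C,p) is computed from the
    repeat trials, then averaged over the two shift phases.
    """
    counts = responses.counts
    if not np.isclose(responses.bin_s, p_bin_s):
        raise ValueError("responses must be binned at p_bin_s")
    center_ids = np.asarray(center_ids)
    if center_ids.size != counts.shape[1]:
        raise ValueError("center_ids must label every time bin")
    if max_count is not None:
        counts = np.minimum(counts, max_count)
    p, phase = schedule.time_since_shift(responses.times)
    half = schedule.period / 2.0
    n_p = int(round(half / p_bin_s))
    edges = np.arange(n_p + 1) * p_bin_s
    info = np.full(n_p, np.nan)
    per_phase = {0: np.full(n_p, np.nan), 1: np.full(n_p, np.nan)}
    for ph in (0, 1):
        for k in range(n_p):
            sel = ((phase == ph) & (p >= edges[k]) & (p < edges[k + 1]))
            cols = np.where(sel)[0]
            if cols.size == 0:
                continue
            r_all, c_all = [], []
            for j in cols:
                col = counts[:, j]
                if col.size < 2:
                    warnings.warn("center cell with < 2 trials excluded")
                    continue
                r_all.append(col)
                c_all.append(np.full(col.size, center_ids[j]))
            if not r_all:
                continue
            r = np.concatenate(r_all)
            c = np.concatenate(c_all)
            per_phase[ph][k] = _mi_from_labels(r, c)
    if average_phases:
        stacked = np.vstack([per_phase[0], per_phase[1]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            info = np.nanmean(stacked, axis=0)
    else:
        info = per_phase
    return InfoTimecourse(edges[:-1], info,
                          meta={"p_bin_s": p_bin_s,
                                "n_trials": counts.shape[0],
                                "extrapolated": False})


def sequence_contrast_decompose(observations: pd.DataFrame,
                                min_presentations: int = 10) -> pd.DataFrame:
    """Per-p decomposition of center information into contrast and sequence.

    ``observations`` has one row per presentation with columns ``p_bin``
    (int), ``window`` (intensity-sequence id), ``contrast`` and ``response``
    (discrete spike count).  Returns a frame indexed by p_bin with columns
    I(R;Sigma|p), I(R;M|p) and I(R;M|Sigma,p) in bits.  Raises if any design
    condition is missing or observed fewer than ``min_presentations`` times.
    """
    req = {"p_bin", "window", "contrast", "response"}
    if not req.issubset(observations.columns):
        raise ValueError(f"observations must have columns {sorted(req)}")
    census = observations.groupby(["p_bin", "window", "contrast"]).size()
    p_bins = observations["p_bin"].unique()
    windows = observations["window"].unique()
    contrasts = observations["contrast"].unique()
    full = pd.MultiIndex.from_product([sorted(p_bins), sorted(windows),
                                       sorted(contrasts)],
                                      names=["p_bin", "window", "contrast"])
    missing = full.difference(census.index)
    if len(missing):
        raise ValueError(f"missing design conditions: {list(missing[:5])}"
                         f"{' ...' if len(missing) > 5 else ''}")
    low = census[census < min_presentations]
    if len(low):
        raise ValueError(f"conditions with < {min_presentations} "
                         f"presentations: {list(low.index[:5])}")
    rows = []
    for pb, grp in observations.groupby("p_bin"):
        r = grp["response"].to_numpy()
        sig = grp["contrast"].to_numpy()
        win = grp["window"].to_numpy()
        i_sigma = _mi_from_labels(r, sig)
        i_seq = _mi_from_labels(r, win)
        # I(R;M|Sigma,p): average over contrasts of within-contrast MI
        i_seq_given_sigma = 0.0
        for s in np.unique(sig):
            m = sig == s
            i_seq_given_sigma += m.mean() * _mi_from_labels(r[m], win[m])
        rows.append({"p_bin": pb, "I(R;Sigma|p)": i_sigma,
                     "I(R;M|p)": i_seq,
                     "I(R;M|Sigma,p)": i_seq_given_sigma})
    return pd.DataFrame(rows).set_index("p_bin").sort_index()


def conditional_mi_prev(g_t: np.ndarray, r_t: np.ndarray, r_prev: np.ndarray,
                        n_bins: int = 16,
                        quantize_inputs: bool = True) -> float:
    """Conditional mutual information I(G_t; R_t | R_{t-Delta}) in bits.

    Computed as H(G_t|R_prev) - H(G_t|R_prev, R_t) from plug-in histograms.
    Continuous inputs are quantized to ``n_bins`` equal-occupancy bins;
    conditioning cells with a single sample contribute zero and trigger a
    merged-bin warning if they dominate.
    """
    g = np.asarray(g_t)
    rt = np.asarray(r_t)
    rp = np.asarray(r_prev)
    if not (g.size == rt.size == rp.size):
        raise ValueError("inputs must be aligned")
    if quantize_inputs:
        g = quantize(g, n_bins)
        rt = quantize(rt, n_bins)
        rp = quantize(rp, n_bins)
    total = 0.0
    n = g.size
    for v in np.unique(rp):
        m = rp == v
        k = int(m.sum())
        if k < 2:
            warnings.warn("conditioning cell with < 2 samples merged "
                          "(contributes 0)")
            continue
        total += (k / n) * _mi_from_labels(g[m], rt[m])
    return float(total)


def extrapolate_info(fractions: np.ndarray, info_values: np.ndarray) -> float:
    """Extrapolate plug-in information to the infinite-data limit.

    ``fractions`` are data fractions (e.g. 1, 1/2, 1/4) at which the plug-in
    estimate ``info_values`` was computed; a second-order polynomial in the
    inverse data fraction is fitted and evaluated at zero (infinite data).
    """
    f = np.asarray(fractions, dtype=float)
    y = np.asarray(info_values, dtype=float)
    if f.size < 3 or y.size != f.size:
        raise ValueError("need >= 3 (fraction, info) points")
    x = 1.0 / f
    coefs = np.polyfit(x, y, 2)
    return float(np.polyval(coefs, 0.0))


def quantize(values: np.ndarray, n_bins: int,
             strategy: str = "quantile") -> np.ndarray:
    """Discretize values into integer labels.

    Equal-occupancy quantile bins by default (a deterministic surrogate for
    information-maximizing bin placement), or equal-width bins
    (``strategy="width"``).  Inputs with fewer distinct values than bins
    collapse to the distinct values with a warning.
    """
    v = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    distinct = np.unique(v)
    if distinct.size <= n_bins:
        if distinct.size < n_bins:
            warnings.warn(f"only {distinct.size} distinct values for "
                          f"{n_bins} bins: collapsing")
        return np.searchsorted(distinct, v)
    if strategy == "width":
        edges = np.linspace(v.min(), v.max(), n_bins + 1)[1:-1]
        return np.searchsorted(edges, v, side="right")
    if strategy != "quantile":
        raise ValueError(f"unknown strategy: {strategy}")
    edges = np.quantile(v, np.linspace(0, 1, n_bins + 1))[1:-1]
    if np.unique(edges).size == edges.size:
        return np.searchsorted(edges, v, side="right")
    # point masses (e.g. a rectified signal that is mostly exactly zero)
    # collapse quantile edges; give each heavy atom its own label and spread
    # the remaining label budget over the continuous part, so the
    # informative tail keeps its resolution
    vals, counts = np.unique(v, return_counts=True)
    atoms = vals[counts / v.size >= 1.0 / n_bins]
    is_atom = np.isin(v, atoms)
    labels = np.full(v.size, -1, dtype=int)
    resid = v[~is_atom]
    n_resid_bins = max(n_bins - atoms.size, 1)
    if resid.size:
        redges = np.unique(np.quantile(resid,
                                       np.linspace(0, 1, n_resid_bins + 1)
                                       )[1:-1])
        labels[~is_atom] = np.searchsorted(redges, resid, side="right")
    n_resid_labels = labels.max() + 1 if resid.size else 0
    for k, a in enumerate(atoms):
        labels[v == a] = n_resid_labels + k
    # remap so labels are ordered by their mean value
    reps = [v[labels == lab].mean() for lab in range(labels.max() + 1)]
    order = np.argsort(np.argsort(reps))
    return order[labels]
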