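"""Permutation-based inference for sensor/source x time(-frequency) maps.

Implements the nonparametric tests used throughout the pipeline: cluster-mass
and max-statistic permutation tests (paired sign-flip at the participant level,
label exchange at the trial level), the two-step sliding-window cluster
procedure for sustained oscillatory effects, Benjamini-Hochberg FDR, skipped
(robust) Pearson correlation, the across-participant correlation-difference
contrast, and median splits.

Cluster adjacency is 4-neighbor on regular grids (time, time x frequency,
3-D voxel grids); an optional channel/source adjacency matrix can be supplied
for the leading axis of the map.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, sparse, stats as sps
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .containers import Cluster, ClusterResult

__all__ = [
    "cluster_permutation_test",
    "sliding_window_cluster",
    "fdr_bh",
    "robust_pearson",
    "correlation_condition_contrast",
    "median_split",
]


# ---------------------------------------------------------------------------
# t statistics, vectorized over permutations
# ---------------------------------------------------------------------------

def _paired_t_perms(d2d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t maps of sign-flipped paired differences.

    d2d: (units, bins); signs: (n_perm, units) of +-1. Sign flips leave d^2
    unchanged, so the per-permutation variance follows from the permuted mean
    alone. Returns (n_perm, bins).
    """
    n = d2d.shape[0]
    mean = signs @ d2d / n
    ss = np.sum(d2d**2, axis=0)  # invariant under sign flips
    var = (ss - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _indep_t_perms(x2d: np.ndarray, labels: np.ndarray, na: int) -> np.ndarray:
    """Pooled-variance two-sample t for permuted group labels.

    x2d: (na+nb, bins); labels: (n_perm, n) boolean, True marks group A rows
    (each row has exactly ``na`` True). Returns (n_perm, bins).
    """
    n = x2d.shape[0]
    nb = n - na
    colsum = x2d.sum(axis=0)
    colsum2 = (x2d**2).sum(axis=0)
    L = labels.astype(float)
    sa = L @ x2d
    sa2 = L @ x2d**2
    ma, mb = sa / na, (colsum - sa) / nb
    ssa = sa2 - na * ma**2
    ssb = (colsum2 - sa2) - nb * mb**2
    sp2 = (ssa + ssb) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _grid_structure(ndim: int) -> np.ndarray:
    # orthogonal (4-/6-) neighborhood, no diagonals
    return ndimage.generate_binary_structure(ndim, 1)


def _clusters_grid(mask: np.ndarray, tmap: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    """Connected components of ``mask`` under orthogonal grid adjacency.

    Returns (list of flat bin-index arrays, per-cluster summed t)."""
    if not mask.any():
        return [], np.empty(0)
    if mask.ndim == 0:
        return [np.array([0])], np.array([float(tmap)])
    lab, n = ndimage.label(mask, structure=_grid_structure(mask.ndim))
    flat_lab = lab.ravel()
    masses = np.bincount(flat_lab, weights=tmap.ravel(), minlength=n + 1)[1:]
    order = np.argsort(flat_lab, kind="stable")
    nz = flat_lab[order] > 0
    order = order[nz]
    bounds = np.searchsorted(flat_lab[order], np.arange(1, n + 2))
    members = [order[bounds[i]: bounds[i + 1]] for i in range(n)]
    return members, masses


def _clusters_chan_grid(
    mask: np.ndarray, tmap: np.ndarray, chan_adj: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray]:
    """Connected components when axis 0 is channels with its own adjacency and
    the remaining axes form a regular grid."""
    if not mask.any():
        return [], np.empty(0)
    flat_ids = -np.ones(mask.shape, dtype=np.int64)
    idx = np.flatnonzero(mask.ravel())
    flat_ids.ravel()[idx] = np.arange(idx.size)
    rows, cols = [], []
    # grid neighbors within each channel
    for ax in range(1, mask.ndim):
        sl_a = [slice(None)] * mask.ndim
        sl_b = [slice(None)] * mask.ndim
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        both = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        rows.append(flat_ids[tuple(sl_a)][both])
        cols.append(flat_ids[tuple(sl_b)][both])
    # channel neighbors at identical grid position
    ci, cj = np.nonzero(np.triu(np.asarray(chan_adj, dtype=bool), k=1))
    for a, b in zip(ci, cj):
        both = mask[a] & mask[b]
        rows.append(flat_ids[a][both])
        cols.append(flat_ids[b][both])
    r = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    c = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    g = sparse.coo_matrix(
        (np.ones(r.size), (r, c)), shape=(idx.size, idx.size)
    )
    n, labels = connected_components(g, directed=False)
    masses = np.bincount(labels, weights=tmap.ravel()[idx], minlength=n)
    members = [idx[labels == k] for k in range(n)]
    return members, masses


def _find_clusters(mask, tmap, chan_adj=None):
    if chan_adj is None:
        return _clusters_grid(mask, tmap)
    return _clusters_chan_grid(mask, tmap, chan_adj)


def _max_cluster_mass(tmap, thr, tails, chan_adj=None) -> float:
    """Maximal |summed t| over supra-threshold clusters of one t map."""
    best = 0.0
    _, mpos = _find_clusters(tmap > thr, tmap, chan_adj)
    if mpos.size:
        best = float(mpos.max())
    if tails == "two":
        _, mneg = _find_clusters(tmap < -thr, tmap, chan_adj)
        if mneg.size:
            best = max(best, float(-mneg.min()))
    return best


# ---------------------------------------------------------------------------
# main permutation tests
# ---------------------------------------------------------------------------

def cluster_permutation_test(
    data_a: np.ndarray,
    data_b: np.ndarray | None = None,
    *,
    unit: str = "participant",
    adjacency: np.ndarray | None = None,
    n_perm: int = 5000,
    mode: str = "cluster_mass",
    tails: str = "two",
    seed: int | None = None,
    alpha_cluster: float = 0.05,
    chunk: int = 256,
) -> ClusterResult:
    """Cluster-mass / max-statistic permutation test between two conditions.

    ``unit='participant'``: data_a/data_b are paired (units, *map) arrays and
    condition labels are exchanged within unit (sign flips of the difference);
    ``data_b=None`` tests data_a against zero. ``unit='trial'``: data_a/data_b
    are independent trial sets and group labels are exchanged.

    The cluster-forming threshold is the |t| quantile at ``alpha_cluster`` for
    the declared tails; ``mode='max_statistic'`` ranks single bins against the
    permutation distribution of the maximal statistic instead of clustering.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable p-values; refused")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    data_a = np.asarray(data_a, dtype=float)
    rng = np.random.default_rng(seed)

    if unit == "participant":
        d = data_a if data_b is None else data_a - np.asarray(data_b, float)
        n = d.shape[0]
        map_shape = d.shape[1:]
        d2d = d.reshape(n, -1)
        if not np.any(d2d.std(axis=0) > 0):
            raise ValueError("no variance across units")
        df = n - 1
        t_obs = _paired_t_perms(d2d, np.ones((1, n)))[0]

        def perm_tmaps(m):
            signs = rng.choice([-1.0, 1.0], size=(m, n))
            return _paired_t_perms(d2d, signs)

    elif unit == "trial":
        if data_b is None:
            raise ValueError("trial-level test needs two trial sets")
        data_b = np.asarray(data_b, dtype=float)
        na = data_a.shape[0]
        x = np.concatenate([data_a, data_b], axis=0)
        n = x.shape[0]
        map_shape = x.shape[1:]
        x2d = x.reshape(n, -1)
        if not np.any(x2d.std(axis=0) > 0):
            raise ValueError("no variance across trials")
        df = n - 2
        obs_labels = np.zeros((1, n), dtype=bool)
        obs_labels[0, :na] = True
        t_obs = _indep_t_perms(x2d, obs_labels, na)[0]

        def perm_tmaps(m):
            keys = rng.random((m, n))
            labels = np.argsort(keys, axis=1) < na
            return _indep_t_perms(x2d, labels, na)

    else:
        raise ValueError("unit must be 'participant' or 'trial'")

    alpha_form = alpha_cluster if tails == "one" else alpha_cluster / 2
    thr = float(sps.t.ppf(1 - alpha_form, df))
    t_map = t_obs.reshape(map_shape)

    # observed clusters / bins
    if mode == "cluster_mass":
        members, masses = _find_clusters(t_map > thr, t_map, adjacency)
        if tails == "two":
            mneg, massneg = _find_clusters(t_map < -thr, t_map, adjacency)
            members += mneg
            masses = np.concatenate([masses, massneg])
    elif mode == "max_statistic":
        supra = t_obs > thr if tails == "one" else np.abs(t_obs) > thr
        members = [np.array([i]) for i in np.flatnonzero(supra)]
        masses = t_obs[supra]
    else:
        raise ValueError("mode must be 'cluster_mass' or 'max_statistic'")

    # permutation null of the maximal statistic
    null = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        tm = perm_tmaps(m)
        for i in range(m):
            tmap_i = tm[i].reshape(map_shape)
            if mode == "cluster_mass":
                null[done + i] = _max_cluster_mass(tmap_i, thr, tails, adjacency)
            else:
                null[done + i] = (
                    tm[i].max() if tails == "one" else np.abs(tm[i]).max()
                )
        done += m

    clusters = []
    for mem, mass in zip(members, masses):
        obs = mass if tails == "one" else abs(mass)
        p = (1.0 + np.sum(null >= obs - 1e-12)) / (n_perm + 1.0)
        clusters.append(Cluster(bins=mem, mass=float(mass), p_value=float(p)))
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(
        clusters=clusters,
        stat_map=t_map,
        threshold=thr,
        tails=tails,
        n_permutations=n_perm,
        seed=seed,
        mode=mode,
    )


def sliding_window_cluster(
    data_a: np.ndarray,
    data_b: np.ndarray | None,
    times_ms: np.ndarray,
    freqs_hz: np.ndarray,
    *,
    window_len_ms: float = 300.0,
    time_range_ms: tuple[float, float] = (0.0, 2700.0),
    band_hz: tuple[float, float] = (2.0, 8.0),
    n_perm: int = 5000,
    seed: int | None = None,
    tails: str = "one",
) -> ClusterResult:
    """Two-step sliding-window cluster test for sustained TF effects.

    Step 1 runs a one-tailed cluster test inside every ``window_len_ms`` window
    sliding across ``time_range_ms`` (one bin step) and collects bins belonging
    to significant clusters (p < 0.05). Step 2 runs a single cluster test
    restricted to the union of those bins and reports the unified cluster(s).
    Data are paired participant maps of shape (units, freqs, times); an empty
    result (no clusters) is returned when step 1 finds nothing.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 refused")
    times_ms = np.asarray(times_ms, float)
    freqs_hz = np.asarray(freqs_hz, float)
    fsel = (freqs_hz >= band_hz[0]) & (freqs_hz <= band_hz[1])
    tsel = (times_ms >= time_range_ms[0]) & (times_ms <= time_range_ms[1])
    d = np.asarray(data_a, float)
    if data_b is not None:
        d = d - np.asarray(data_b, float)
    d = d[:, fsel][:, :, tsel]
    n, nf, nt = d.shape
    t_axis = times_ms[tsel]
    step = float(np.median(np.diff(t_axis)))
    wbins = max(1, int(round(window_len_ms / step)))
    if wbins > nt:
        raise ValueError("window longer than the tested range")
    starts = np.arange(0, nt - wbins + 1)

    rng = np.random.default_rng(seed)
    df = n - 1
    thr = float(sps.t.ppf(0.95, df))  # one-tailed cluster forming
    d2d = d.reshape(n, -1)
    t_obs = _paired_t_perms(d2d, np.ones((1, n)))[0].reshape(nf, nt)

    # per-window null of the maximal cluster mass, shared permutations
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    tmaps = _paired_t_perms(d2d, signs).reshape(n_perm, nf, nt)
    null_win = np.empty((n_perm, starts.size))
    for i in range(n_perm):
        for w, s0 in enumerate(starts):
            null_win[i, w] = _max_cluster_mass(
                tmaps[i][:, s0: s0 + wbins], thr, "one"
            )
    win_thresh = np.quantile(null_win, 0.95, axis=0)

    def union_mask(tmap, thresholds, windows=None):
        mask = np.zeros((nf, nt), dtype=bool)
        wsel = range(starts.size) if windows is None else windows
        for w in wsel:
            s0 = starts[w]
            sub = tmap[:, s0: s0 + wbins]
            members, masses = _find_clusters(sub > thr, sub, None)
            for mem, mass in zip(members, masses):
                if mass >= thresholds[w]:
                    fi, ti = np.unravel_index(mem, (nf, wbins))
                    mask[fi, ti + s0] = True
        return mask

    sig_mask = union_mask(t_obs, win_thresh)
    if not sig_mask.any():
        return ClusterResult(
            clusters=[], stat_map=t_obs, threshold=thr, tails="one",
            n_permutations=n_perm, seed=seed, mode="sliding_window",
        )

    # step 2: unified test on the union of step-1 bins. The null replays the
    # entire two-step selection on each permutation (its own step-1 union,
    # then the maximal cluster mass within it), so the selection bias of
    # conditioning on significant windows is accounted for.
    members, masses = _find_clusters(sig_mask & (t_obs > thr), t_obs, None)
    null2 = np.zeros(n_perm)
    for i in range(n_perm):
        winners = np.flatnonzero(null_win[i] >= win_thresh)
        if winners.size == 0:
            continue
        mask_i = union_mask(tmaps[i], win_thresh, winners)
        if mask_i.any():
            null2[i] = _max_cluster_mass(tmaps[i] * mask_i, thr, "one")
    clusters = []
    for mem, mass in zip(members, masses):
        p = (1.0 + np.sum(null2 >= mass - 1e-12)) / (n_perm + 1.0)
        clusters.append(Cluster(bins=mem, mass=float(mass), p_value=float(p)))
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(
        clusters=clusters, stat_map=t_obs, threshold=thr, tails="one",
        n_permutations=n_perm, seed=seed, mode="sliding_window",
    )


# ---------------------------------------------------------------------------
# FDR, robust correlation, correlation contrast, median split
# ---------------------------------------------------------------------------

def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


def _skipped_outliers(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bivariate outlier flags via the skipped-correlation convention:
    project all points onto the directions from the coordinatewise median to
    each data point and apply the boxplot (1.5 IQR) rule per projection."""
    pts = np.column_stack([x, y]).astype(float)
    center = np.median(pts, axis=0)
    rel = pts - center
    flagged = np.zeros(len(pts), dtype=bool)
    for i in range(len(pts)):
        norm = np.linalg.norm(rel[i])
        if norm == 0:
            continue
        u = rel[i] / norm
        proj = rel @ u
        q1, q3 = np.percentile(proj, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        flagged |= (proj < lo) | (proj > hi)
    return flagged


def robust_pearson(x: np.ndarray, y: np.ndarray) -> dict:
    """Skipped Pearson correlation: remove bivariate outliers (boxplot rule on
    projections through the median), then plain Pearson on the remainder.

    Returns ``{"rho", "t", "p", "kept"}``; ``kept`` are the retained indices.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need matched samples with n >= 5")
    out = _skipped_outliers(x, y)
    kept = np.flatnonzero(~out)
    if kept.size < 4:
        raise ValueError("fewer than 4 points after outlier removal")
    xs, ys = x[kept], y[kept]
    if np.std(xs) == 0 or np.std(ys) == 0:
        rho = 0.0
    else:
        rho = float(np.corrcoef(xs, ys)[0, 1])
    n = kept.size
    rho_c = min(max(rho, -0.9999999), 0.9999999)
    t = rho_c * np.sqrt((n - 2) / (1 - rho_c**2))
    p = 2 * sps.t.sf(abs(t), n - 2)
    return {"rho": rho, "t": float(t), "p": float(p), "kept": kept}


def correlation_condition_contrast(
    bold_a: np.ndarray,
    bold_b: np.ndarray,
    tf_a: np.ndarray,
    tf_b: np.ndarray,
    *,
    n_perm: int = 5000,
    seed: int | None = None,
    alpha_form: float = 0.05,
) -> ClusterResult:
    """Test whether across-participant BOLD-EEG correlation differs between
    two conditions at each time(-frequency) bin, with cluster correction.

    ``bold_*``: per-participant BOLD contrast scalars (n,); ``tf_*``:
    per-participant EEG power maps (n, *bins). The bin statistic is the
    Fisher-z correlation difference scaled to an approximate z score; the
    permutation swaps the condition pair within participant.
    """
    bold_a = np.asarray(bold_a, float)
    bold_b = np.asarray(bold_b, float)
    n = bold_a.size
    if n < 6:
        raise ValueError("fewer than 6 participants; refused")
    tf_a = np.asarray(tf_a, float)
    tf_b = np.asarray(tf_b, float)
    map_shape = tf_a.shape[1:]
    tf_a = tf_a.reshape(n, -1)
    tf_b = tf_b.reshape(n, -1)

    def _corr(b, t):
        bz = (b - b.mean()) / (b.std() + 1e-300)
        tz = (t - t.mean(axis=0)) / (t.std(axis=0) + 1e-300)
        return bz @ tz / n

    def _stat(ba, bb, ta, tb):
        ra = np.clip(_corr(ba, ta), -0.9999999, 0.9999999)
        rb = np.clip(_corr(bb, tb), -0.9999999, 0.9999999)
        return (np.arctanh(ra) - np.arctanh(rb)) * np.sqrt((n - 3) / 2.0)

    z_obs = _stat(bold_a, bold_b, tf_a, tf_b).reshape(map_shape)
    thr = float(sps.norm.ppf(1 - alpha_form / 2))
    members, masses = _find_clusters(z_obs > thr, z_obs, None)
    mneg, massneg = _find_clusters(z_obs < -thr, z_obs, None)
    members += mneg
    masses = np.concatenate([masses, massneg])

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        swap = rng.random(n) < 0.5
        ba = np.where(swap, bold_b, bold_a)
        bb = np.where(swap, bold_a, bold_b)
        ta = np.where(swap[:, None], tf_b, tf_a)
        tb = np.where(swap[:, None], tf_a, tf_b)
        z = _stat(ba, bb, ta, tb).reshape(map_shape)
        null[k] = _max_cluster_mass(z, thr, "two")
    clusters = []
    for mem, mass in zip(members, masses):
        p = (1.0 + np.sum(null >= abs(mass) - 1e-12)) / (n_perm + 1.0)
        clusters.append(Cluster(bins=mem, mass=float(mass), p_value=float(p)))
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(
        clusters=clusters, stat_map=z_obs, threshold=thr, tails="two",
        n_permutations=n_perm, seed=seed, mode="correlation_contrast",
    )


def median_split(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partition trial indices at the median of ``values``.

    Non-finite entries are omitted. Values equal to the median go to the lower
    set (deterministic tie rule). Raises when all valid values are identical.
    """
    v = np.asarray(values, dtype=float)
    valid = np.flatnonzero(np.isfinite(v))
    if valid.size < 2:
        raise ValueError("need at least 2 valid trials")
    vv = v[valid]
    if np.all(vv == vv[0]):
        raise ValueError("all values identical; split undefined")
    med = np.median(vv)
    low = valid[vv <= med]
    high = valid[vv > med]
    if high.size == 0:  # heavy ties at the median: fall back to strict split
        low = valid[vv < med]
        high = valid[vv >= med]
    return low, high
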