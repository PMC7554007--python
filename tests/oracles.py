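"""Independent brute-force oracles for the texture, autocorrelation and
first-order features.

Everything here is written as plain double loops over voxels / matrix cells,
deliberately sharing no code with the package's vectorized engines.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps


def glcm_matrix_bruteforce(levels, inside, direction, n_bins):
    """Symmetric co-occurrence counts by walking every voxel pair."""
    m = np.zeros((n_bins, n_bins), dtype=np.int64)
    nx, ny, nz = levels.shape
    dx, dy, dz = direction
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not inside[x, y, z]:
                    continue
                u, v, w = x + dx, y + dy, z + dz
                if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and inside[u, v, w]:
                    a, b = levels[x, y, z] - 1, levels[u, v, w] - 1
                    m[a, b] += 1
                    m[b, a] += 1
    return m


def glcm_features_bruteforce(counts):
    """The 25 co-occurrence features, scalar loops over matrix cells."""
    total = counts.sum()
    p = counts / total
    n = p.shape[0]
    feats = {}
    mu = sum((i + 1) * p[i, j] for i in range(n) for j in range(n))
    px = [p[i, :].sum() for i in range(n)]
    sigma2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(n))

    p_diff = np.zeros(n)
    p_sum = np.zeros(2 * n - 1)
    for i in range(n):
        for j in range(n):
            p_diff[abs(i - j)] += p[i, j]
            p_sum[i + j] += p[i, j]

    def H(q):
        return -sum(v * math.log2(v) for v in np.ravel(q) if v > 0)

    da = sum(k * p_diff[k] for k in range(n))
    sa = sum((k + 2) * p_sum[k] for k in range(2 * n - 1))
    feats["joint_maximum"] = p.max()
    feats["joint_average"] = mu
    feats["joint_variance"] = sum(
        (i + 1 - mu) ** 2 * p[i, j] for i in range(n) for j in range(n)
    )
    feats["joint_entropy"] = H(p)
    feats["difference_average"] = da
    feats["difference_variance"] = sum(
        (k - da) ** 2 * p_diff[k] for k in range(n)
    )
    feats["difference_entropy"] = H(p_diff)
    feats["sum_average"] = sa
    feats["sum_variance"] = sum(
        (k + 2 - sa) ** 2 * p_sum[k] for k in range(2 * n - 1)
    )
    feats["sum_entropy"] = H(p_sum)
    feats["angular_second_moment"] = sum(
        p[i, j] ** 2 for i in range(n) for j in range(n)
    )
    feats["contrast"] = sum(
        (i - j) ** 2 * p[i, j] for i in range(n) for j in range(n)
    )
    feats["dissimilarity"] = sum(
        abs(i - j) * p[i, j] for i in range(n) for j in range(n)
    )
    feats["inverse_difference"] = sum(
        p[i, j] / (1 + abs(i - j)) for i in range(n) for j in range(n)
    )
    feats["inverse_difference_normalized"] = sum(
        p[i, j] / (1 + abs(i - j) / n) for i in range(n) for j in range(n)
    )
    feats["inverse_difference_moment"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n)
    )
    feats["inverse_difference_moment_normalized"] = sum(
        p[i, j] / (1 + (i - j) ** 2 / n**2) for i in range(n) for j in range(n)
    )
    feats["inverse_variance"] = sum(
        p[i, j] / (i - j) ** 2 for i in range(n) for j in range(n) if i != j
    )
    if sigma2 == 0:
        feats["correlation"] = 1.0
    else:
        feats["correlation"] = (
            sum((i + 1) * (j + 1) * p[i, j] for i in range(n) for j in range(n))
            - mu**2
        ) / sigma2
    feats["autocorrelation"] = sum(
        (i + 1) * (j + 1) * p[i, j] for i in range(n) for j in range(n)
    )
    for name, power in (
        ("cluster_tendency", 2),
        ("cluster_shade", 3),
        ("cluster_prominence", 4),
    ):
        feats[name] = sum(
            (i + 1 + j + 1 - 2 * mu) ** power * p[i, j]
            for i in range(n)
            for j in range(n)
        )
    hxy = H(p)
    hx = H(np.array(px))
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * px[j])
        for i in range(n)
        for j in range(n)
        if p[i, j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * math.log2(px[i] * px[j])
        for i in range(n)
        for j in range(n)
        if px[i] * px[j] > 0
    )
    feats["information_correlation1"] = 0.0 if hx == 0 else (hxy - hxy1) / hx
    feats["information_correlation2"] = math.sqrt(
        max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))
    )
    return feats


def glrlm_matrix_bruteforce(levels, inside, direction, n_bins):
    """Run-length counts by explicit run walking from every run start."""
    nx, ny, nz = levels.shape
    dx, dy, dz = direction
    runs = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not inside[x, y, z]:
                    continue
                px_, py_, pz_ = x - dx, y - dy, z - dz
                starts = not (
                    0 <= px_ < nx
                    and 0 <= py_ < ny
                    and 0 <= pz_ < nz
                    and inside[px_, py_, pz_]
                    and levels[px_, py_, pz_] == levels[x, y, z]
                )
                if not starts:
                    continue
                length = 1
                u, v, w = x + dx, y + dy, z + dz
                while (
                    0 <= u < nx
                    and 0 <= v < ny
                    and 0 <= w < nz
                    and inside[u, v, w]
                    and levels[u, v, w] == levels[x, y, z]
                ):
                    length += 1
                    u, v, w = u + dx, v + dy, w + dz
                runs.append((levels[x, y, z], length))
    if not runs:
        return np.zeros((n_bins, 1), dtype=np.int64)
    max_len = max(l for _, l in runs)
    m = np.zeros((n_bins, max_len), dtype=np.int64)
    for g, l in runs:
        m[g - 1, l - 1] += 1
    return m


def glrlm_features_bruteforce(r, n_voxels):
    """The 16 run-length features with scalar loops."""
    ng, nl = r.shape
    n_runs = r.sum()
    feats = {}
    feats["short_run_emphasis"] = sum(
        r[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(nl)
    ) / n_runs
    feats["long_run_emphasis"] = sum(
        r[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(nl)
    ) / n_runs
    feats["low_gray_level_run_emphasis"] = sum(
        r[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(nl)
    ) / n_runs
    feats["high_gray_level_run_emphasis"] = sum(
        r[i, j] * (i + 1) ** 2 for i in range(ng) for j in range(nl)
    ) / n_runs
    feats["short_run_low_gray_level_emphasis"] = sum(
        r[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
        for i in range(ng)
        for j in range(nl)
    ) / n_runs
    feats["short_run_high_gray_level_emphasis"] = sum(
        r[i, j] * (i + 1) ** 2 / (j + 1) ** 2
        for i in range(ng)
        for j in range(nl)
    ) / n_runs
    feats["long_run_low_gray_level_emphasis"] = sum(
        r[i, j] * (j + 1) ** 2 / (i + 1) ** 2
        for i in range(ng)
        for j in range(nl)
    ) / n_runs
    feats["long_run_high_gray_level_emphasis"] = sum(
        r[i, j] * (i + 1) ** 2 * (j + 1) ** 2
        for i in range(ng)
        for j in range(nl)
    ) / n_runs
    feats["gray_level_nonuniformity"] = sum(
        r[i, :].sum() ** 2 for i in range(ng)
    ) / n_runs
    feats["gray_level_nonuniformity_normalized"] = sum(
        r[i, :].sum() ** 2 for i in range(ng)
    ) / n_runs**2
    feats["run_length_nonuniformity"] = sum(
        r[:, j].sum() ** 2 for j in range(nl)
    ) / n_runs
    feats["run_length_nonuniformity_normalized"] = sum(
        r[:, j].sum() ** 2 for j in range(nl)
    ) / n_runs**2
    feats["run_percentage"] = n_runs / n_voxels
    mu_i = sum((i + 1) * r[i, j] / n_runs for i in range(ng) for j in range(nl))
    mu_j = sum((j + 1) * r[i, j] / n_runs for i in range(ng) for j in range(nl))
    feats["gray_level_variance"] = sum(
        (i + 1 - mu_i) ** 2 * r[i, j] / n_runs
        for i in range(ng)
        for j in range(nl)
    )
    feats["run_length_variance"] = sum(
        (j + 1 - mu_j) ** 2 * r[i, j] / n_runs
        for i in range(ng)
        for j in range(nl)
    )
    feats["run_entropy"] = -sum(
        (r[i, j] / n_runs) * math.log2(r[i, j] / n_runs)
        for i in range(ng)
        for j in range(nl)
        if r[i, j] > 0
    )
    return feats


def moran_geary_bruteforce(values, inside):
    """O(n^2) Moran's I and Geary's C over all in-mask voxel pairs."""
    pts = np.argwhere(inside)
    x = np.array([values[tuple(p)] for p in pts], dtype=float)
    n = len(x)
    m = x.mean()
    num_i = num_c = W = 0.0
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            if np.abs(pts[a] - pts[b]).sum() == 1:  # face adjacency
                W += 1
                num_i += (x[a] - m) * (x[b] - m)
                num_c += (x[a] - x[b]) ** 2
    denom = ((x - m) ** 2).sum()
    moran = (n / W) * num_i / denom
    geary = ((n - 1) / (2 * W)) * num_c / denom
    return moran, geary


def first_order_voi_bruteforce(x, voxel_volume=1.0):
    """VOI first-order statistics via scipy/numpy reference routines."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    out = {
        "maximum": x.max(),
        "minimum": x.min(),
        "range": np.ptp(x),
        "mean": x.mean(),
        "median": np.median(x),
        "sd": sd,
        "iqr": sps.iqr(x, interpolation="linear"),
        "skewness": sps.skew(x, bias=True) if sd > 0 else 0.0,
        "kurtosis": sps.kurtosis(x, fisher=False, bias=True) if sd > 0 else 0.0,
        "excess_kurtosis": sps.kurtosis(x, fisher=True, bias=True)
        if sd > 0
        else 0.0,
        "median_ad_median": np.median(np.abs(x - np.median(x))),
        "mean_ad_median": np.mean(np.abs(x - np.median(x))),
        "mean_ad_mean": np.mean(np.abs(x - x.mean())),
        "total_energy": (x**2).sum() * voxel_volume,
        "variance": x.var(ddof=0),
        "rms": np.sqrt((x**2).mean()),
        "integrated_intensity": x.mean() * x.size * voxel_volume,
    }
    out["cov_percent"] = 100 * sd / x.mean() if x.mean() != 0 else 0.0
    return out
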