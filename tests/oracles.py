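"""Brute-force reference implementations used as independent test oracles.

Everything here is written as literal loops transcribing the reference
formulas — deliberately slow, deliberately independent of the vectorized
implementations in the package.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


# ---------------------------------------------------------------- matrices
def glcm(grid, n_levels, angle, distance=1):
    dr, dc = OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    rows, cols = grid.shape
    counts = np.zeros((n_levels, n_levels))
    for r in range(rows):
        for c in range(cols):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and grid[r, c] > 0 and grid[rr, cc] > 0:
                counts[grid[r, c] - 1, grid[rr, cc] - 1] += 1
    return counts + counts.T


def _lines(grid, angle):
    rows, cols = grid.shape
    if angle == 0:
        return [list(grid[r, :]) for r in range(rows)]
    if angle == 90:
        return [list(grid[:, c]) for c in range(cols)]
    lines = []
    if angle == 135:  # r - c constant, step (+1, +1)
        starts = [(r, 0) for r in range(rows)] + [(0, c) for c in range(1, cols)]
        step = (1, 1)
    else:  # 45: r + c constant, step (-1, +1)
        starts = [(r, 0) for r in range(rows)] + [(rows - 1, c) for c in range(1, cols)]
        step = (-1, 1)
    for r, c in starts:
        line = []
        while 0 <= r < rows and 0 <= c < cols:
            line.append(grid[r, c])
            r, c = r + step[0], c + step[1]
        lines.append(line)
    return lines


def glrlm(grid, n_levels, angle):
    max_len = max(grid.shape)
    counts = np.zeros((n_levels, max_len))
    for line in _lines(grid, angle):
        run_level, run_len = 0, 0
        for v in line + [0]:
            if v == run_level:
                run_len += 1
            else:
                if run_level > 0:
                    counts[run_level - 1, run_len - 1] += 1
                run_level, run_len = v, 1
    return counts


def glszm(grid, n_levels):
    rows, cols = grid.shape
    n_pixels = int((grid > 0).sum())
    counts = np.zeros((n_levels, max(n_pixels, 1)))
    seen = np.zeros_like(grid, dtype=bool)
    for r in range(rows):
        for c in range(cols):
            if grid[r, c] > 0 and not seen[r, c]:
                level = grid[r, c]
                stack, zone = [(r, c)], 0
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    zone += 1
                    for dr, dc in EIGHT:
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < rows and 0 <= nc < cols and not seen[nr, nc]
                                and grid[nr, nc] == level):
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                counts[level - 1, zone - 1] += 1
    return counts


def ngtdm(grid, n_levels):
    rows, cols = grid.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for r in range(rows):
        for c in range(cols):
            if grid[r, c] == 0:
                continue
            neigh = []
            for dr, dc in EIGHT:
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols and grid[nr, nc] > 0:
                    neigh.append(grid[nr, nc])
            if not neigh:
                continue
            n_i[grid[r, c] - 1] += 1
            s_i[grid[r, c] - 1] += abs(grid[r, c] - sum(neigh) / len(neigh))
    return np.stack([n_i, s_i])


def gldm(grid, n_levels, alpha=0):
    rows, cols = grid.shape
    counts = np.zeros((n_levels, 9))
    for r in range(rows):
        for c in range(cols):
            if grid[r, c] == 0:
                continue
            dep = 0
            for dr, dc in EIGHT:
                nr, nc = r + dr, c + dc
                if (0 <= nr < rows and 0 <= nc < cols and grid[nr, nc] > 0
                        and abs(int(grid[nr, nc]) - int(grid[r, c])) <= alpha):
                    dep += 1
            counts[grid[r, c] - 1, dep] += 1  # dependence size = dep + 1
    return counts


# ---------------------------------------------------------------- features
def _log2(x):
    return math.log2(x) if x > 0 else 0.0


def glcm_features(counts):
    total = counts.sum()
    ng = counts.shape[0]
    p = counts / total
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    sigma2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    n_present = sum(1 for i in range(ng) if px[i] > 0)

    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            p_diff[abs(i - j)] += p[i, j]
            p_sum[i + j] += p[i, j]

    autocorr = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    diff_avg = sum(k * p_diff[k] for k in range(ng))
    sum_avg = sum((k + 2) * p_sum[k] for k in range(2 * ng - 1))
    hxy = -sum(p[i, j] * _log2(p[i, j]) for i in range(ng) for j in range(ng))
    hx = -sum(px[i] * _log2(px[i]) for i in range(ng))
    hxy1 = -sum(
        p[i, j] * _log2(px[i] * px[j]) for i in range(ng) for j in range(ng) if p[i, j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * _log2(px[i] * px[j]) for i in range(ng) for j in range(ng)
    )
    if n_present > 1:
        present = [i for i in range(ng) if px[i] > 0]
        m = len(present)
        q = np.zeros((m, m))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                q[a, b] = sum(
                    p[i, k] * p[j, k] / (px[i] * px[k]) for k in present
                )
        eig = sorted(np.real(np.linalg.eigvals(q)))
        mcc = math.sqrt(max(0.0, eig[-2]))
    else:
        mcc = 1.0
    ngd = float(n_present)
    out = {
        "Autocorrelation": autocorr,
        "JointAverage": mu,
        "ClusterProminence": sum(
            (i + 1 + j + 1 - 2 * mu) ** 4 * p[i, j] for i in range(ng) for j in range(ng)
        ),
        "ClusterShade": sum(
            (i + 1 + j + 1 - 2 * mu) ** 3 * p[i, j] for i in range(ng) for j in range(ng)
        ),
        "ClusterTendency": sum(
            (i + 1 + j + 1 - 2 * mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
        ),
        "Contrast": sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)),
        "Correlation": (
            (autocorr - mu * mu) / sigma2 if sigma2 > 0 else 0.0
        ),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": -sum(p_diff[k] * _log2(p_diff[k]) for k in range(ng)),
        "DifferenceVariance": sum((k - diff_avg) ** 2 * p_diff[k] for k in range(ng)),
        "Id": sum(p_diff[k] / (1 + k) for k in range(ng)),
        "Idm": sum(p_diff[k] / (1 + k * k) for k in range(ng)),
        "Idmn": sum(p_diff[k] / (1 + (k / ngd) ** 2) for k in range(ng)),
        "Idn": sum(p_diff[k] / (1 + k / ngd) for k in range(ng)),
        "Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy)))),
        "InverseVariance": sum(p_diff[k] / k**2 for k in range(1, ng)),
        "JointEnergy": sum(p[i, j] ** 2 for i in range(ng) for j in range(ng)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": p.max(),
        "SumAverage": sum_avg,
        "SumEntropy": -sum(p_sum[k] * _log2(p_sum[k]) for k in range(2 * ng - 1)),
        "SumSquares": sigma2,
        "SumVariance": sum(
            (k + 2 - sum_avg) ** 2 * p_sum[k] for k in range(2 * ng - 1)
        ),
    }
    return out


def _size_features(counts, n_pixels):
    """Generic (level x size) features shared by GLRLM / GLSZM / GLDM."""
    total = counts.sum()
    ng, ns = counts.shape
    p = counts / total
    pi = [sum(p[i, j] for j in range(ns)) for i in range(ng)]
    pj = [sum(p[i, j] for i in range(ng)) for j in range(ns)]
    mu_i = sum((i + 1) * pi[i] for i in range(ng))
    mu_j = sum((j + 1) * pj[j] for j in range(ns))
    return {
        "small": sum(pj[j] / (j + 1) ** 2 for j in range(ns)),
        "large": sum(pj[j] * (j + 1) ** 2 for j in range(ns)),
        "gln": sum(sum(counts[i, j] for j in range(ns)) ** 2 for i in range(ng)) / total,
        "glnn": sum(pi[i] ** 2 for i in range(ng)),
        "sn": sum(sum(counts[i, j] for i in range(ng)) ** 2 for j in range(ns)) / total,
        "snn": sum(pj[j] ** 2 for j in range(ns)),
        "percentage": total / n_pixels,
        "glv": sum((i + 1 - mu_i) ** 2 * pi[i] for i in range(ng)),
        "sv": sum((j + 1 - mu_j) ** 2 * pj[j] for j in range(ns)),
        "entropy": -sum(
            p[i, j] * _log2(p[i, j]) for i in range(ng) for j in range(ns)
        ),
        "lowgl": sum(pi[i] / (i + 1) ** 2 for i in range(ng)),
        "highgl": sum(pi[i] * (i + 1) ** 2 for i in range(ng)),
        "small_low": sum(
            p[i, j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(ns)
        ),
        "small_high": sum(
            p[i, j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(ns)
        ),
        "large_low": sum(
            p[i, j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(ns)
        ),
        "large_high": sum(
            p[i, j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(ns)
        ),
    }


def glrlm_features(counts, n_pixels):
    g = _size_features(counts, n_pixels)
    return {
        "ShortRunEmphasis": g["small"], "LongRunEmphasis": g["large"],
        "GrayLevelNonUniformity": g["gln"], "GrayLevelNonUniformityNormalized": g["glnn"],
        "RunLengthNonUniformity": g["sn"], "RunLengthNonUniformityNormalized": g["snn"],
        "RunPercentage": g["percentage"], "GrayLevelVariance": g["glv"],
        "RunVariance": g["sv"], "RunEntropy": g["entropy"],
        "LowGrayLevelRunEmphasis": g["lowgl"], "HighGrayLevelRunEmphasis": g["highgl"],
        "ShortRunLowGrayLevelEmphasis": g["small_low"],
        "ShortRunHighGrayLevelEmphasis": g["small_high"],
        "LongRunLowGrayLevelEmphasis": g["large_low"],
        "LongRunHighGrayLevelEmphasis": g["large_high"],
    }


def glszm_features(counts, n_pixels):
    g = _size_features(counts, n_pixels)
    return {
        "SmallAreaEmphasis": g["small"], "LargeAreaEmphasis": g["large"],
        "GrayLevelNonUniformity": g["gln"], "GrayLevelNonUniformityNormalized": g["glnn"],
        "SizeZoneNonUniformity": g["sn"], "SizeZoneNonUniformityNormalized": g["snn"],
        "ZonePercentage": g["percentage"], "GrayLevelVariance": g["glv"],
        "ZoneVariance": g["sv"], "ZoneEntropy": g["entropy"],
        "LowGrayLevelZoneEmphasis": g["lowgl"], "HighGrayLevelZoneEmphasis": g["highgl"],
        "SmallAreaLowGrayLevelEmphasis": g["small_low"],
        "SmallAreaHighGrayLevelEmphasis": g["small_high"],
        "LargeAreaLowGrayLevelEmphasis": g["large_low"],
        "LargeAreaHighGrayLevelEmphasis": g["large_high"],
    }


def gldm_features(counts, n_pixels):
    g = _size_features(counts, n_pixels)
    return {
        "SmallDependenceEmphasis": g["small"], "LargeDependenceEmphasis": g["large"],
        "GrayLevelNonUniformity": g["gln"],
        "DependenceNonUniformity": g["sn"],
        "DependenceNonUniformityNormalized": g["snn"],
        "GrayLevelVariance": g["glv"], "DependenceVariance": g["sv"],
        "DependenceEntropy": g["entropy"],
        "LowGrayLevelEmphasis": g["lowgl"], "HighGrayLevelEmphasis": g["highgl"],
        "SmallDependenceLowGrayLevelEmphasis": g["small_low"],
        "SmallDependenceHighGrayLevelEmphasis": g["small_high"],
        "LargeDependenceLowGrayLevelEmphasis": g["large_low"],
        "LargeDependenceHighGrayLevelEmphasis": g["large_high"],
    }


def ngtdm_features(table):
    n_i, s_i = table
    nvp = n_i.sum()
    ng = len(n_i)
    p = [n_i[i] / nvp for i in range(ng)]
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    denom = sum(p[i] * s_i[i] for i in range(ng))
    coarseness = 1.0 / denom if denom > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1)) * sum(s_i) / nvp
        )
        busy_den = sum(
            abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
        )
        busyness = denom / busy_den if busy_den > 0 else 0.0
        complexity = sum(
            abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (p[i] + p[j])
            for i in present for j in present
        ) / nvp
        s_sum = sum(s_i)
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / s_sum
            if s_sum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness, "Contrast": contrast, "Busyness": busyness,
        "Complexity": complexity, "Strength": strength,
    }


# ------------------------------------------------------------- statistics
def pairwise_auc(values, labels):
    """AUC by brute-force pair counting (ties count one half)."""
    pos = [v for v, y in zip(values, labels) if y == 1]
    neg = [v for v, y in zip(values, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def exact_mannwhitney_p(x, y):
    """Two-sided Mann-Whitney p by exhaustive enumeration of group assignments."""
    from itertools import combinations

    pooled = list(x) + list(y)
    n1 = len(x)

    def ustat(group1):
        rest = list(pooled)
        g = []
        for v in group1:
            g.append(v)
            rest.remove(v)
        return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in g for b in rest)

    observed = ustat(list(x))
    n2 = len(y)
    mean_u = n1 * n2 / 2.0
    count = total = 0
    for comb in combinations(range(len(pooled)), n1):
        u = ustat([pooled[i] for i in comb])
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total
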