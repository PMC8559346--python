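"""Independent brute-force reference implementations used as test oracles.

Everything here is written directly from the textbook definitions, per
pixel / per pair / per point, without reusing the package's vectorised
code paths.
"""

from __future__ import annotations

import numpy as np


def naive_lbp_riu2_histogram(img: np.ndarray, radius: int, P: int = 8) -> np.ndarray:
    """Per-pixel enumeration of rotation-invariant uniform LBP codes.

    Neighbours sit on a circle of the given radius at angles 2*pi*p/P
    (image rows increase downward, so the row offset is -r*sin).  Sampling
    coordinates are rounded to 8 decimals before bilinear interpolation (the
    conventional stabilisation of near-grid points); a neighbour counts as 1
    when its interpolated value is >= the centre.  Uniform patterns (at most
    two 0/1 transitions around the circle) map to their bit count, all
    others to the single non-uniform bin P+1.
    """
    img = img.astype(float)
    H, W = img.shape
    codes = []
    for y in range(radius, H - radius):
        for x in range(radius, W - radius):
            c = img[y, x]
            bits = []
            for p in range(P):
                ang = 2 * np.pi * p / P
                yy = y + round(-radius * np.sin(ang), 8)
                xx = x + round(radius * np.cos(ang), 8)
                y0, x0 = int(np.floor(yy)), int(np.floor(xx))
                dy, dx = yy - y0, xx - x0
                y1, x1 = min(y0 + 1, H - 1), min(x0 + 1, W - 1)
                v = (
                    img[y0, x0] * (1 - dy) * (1 - dx)
                    + img[y0, x1] * (1 - dy) * dx
                    + img[y1, x0] * dy * (1 - dx)
                    + img[y1, x1] * dy * dx
                )
                bits.append(1 if v >= c else 0)
            transitions = sum(bits[i] != bits[(i + 1) % P] for i in range(P))
            codes.append(sum(bits) if transitions <= 2 else P + 1)
    hist = np.bincount(codes, minlength=P + 2).astype(float)
    return hist / hist.sum()


def naive_glcm(quantized: np.ndarray, offset: tuple[int, int], levels: int) -> np.ndarray:
    """Symmetric normalised co-occurrence matrix by explicit pair counting."""
    dr, dc = offset
    H, W = quantized.shape
    P = np.zeros((levels, levels))
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                i, j = int(quantized[r, c]), int(quantized[r2, c2])
                P[i, j] += 1
                P[j, i] += 1
    return P / P.sum()


def haralick_formulas(P: np.ndarray) -> dict[str, float]:
    """Literal transcription of the 14 co-occurrence statistics.

    Scalar loops over matrix entries; log(0) terms are skipped.
    """
    n = P.shape[0]
    px = [sum(P[i][j] for j in range(n)) for i in range(n)]
    py = [sum(P[i][j] for i in range(n)) for j in range(n)]
    mu_x = sum(i * px[i] for i in range(n))
    mu_y = sum(j * py[j] for j in range(n))
    sd_x = np.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(n)))
    sd_y = np.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(n)))

    p_sum = [0.0] * (2 * n - 1)
    p_diff = [0.0] * n
    for i in range(n):
        for j in range(n):
            p_sum[i + j] += P[i][j]
            p_diff[abs(i - j)] += P[i][j]

    def ent(ps):
        return -sum(p * np.log(p) for p in ps if p > 0)

    out = {}
    out["asm"] = sum(P[i][j] ** 2 for i in range(n) for j in range(n))
    out["contrast"] = sum(k**2 * p_diff[k] for k in range(n))
    if sd_x > 0 and sd_y > 0:
        out["correlation"] = (
            sum(i * j * P[i][j] for i in range(n) for j in range(n)) - mu_x * mu_y
        ) / (sd_x * sd_y)
    else:
        out["correlation"] = 0.0
    out["variance"] = sum((i - mu_x) ** 2 * P[i][j] for i in range(n) for j in range(n))
    out["idm"] = sum(P[i][j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    out["sum_average"] = sum(k * p_sum[k] for k in range(2 * n - 1))
    out["sum_variance"] = sum(
        (k - out["sum_average"]) ** 2 * p_sum[k] for k in range(2 * n - 1)
    )
    out["sum_entropy"] = ent(p_sum)
    out["entropy"] = ent([P[i][j] for i in range(n) for j in range(n)])
    diff_mean = sum(k * p_diff[k] for k in range(n))
    out["difference_variance"] = sum((k - diff_mean) ** 2 * p_diff[k] for k in range(n))
    out["difference_entropy"] = ent(p_diff)

    hxy = out["entropy"]
    hxy1 = -sum(
        P[i][j] * np.log(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if P[i][j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * np.log(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if px[i] * py[j] > 0
    )
    hx, hy = ent(px), ent(py)
    denom = max(hx, hy)
    out["imc1"] = (hxy - hxy1) / denom if denom > 0 else 0.0
    out["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    keep = [i for i in range(n) if px[i] > 0 and py[i] > 0]
    mcc = 0.0
    if len(keep) >= 2:
        Q = np.zeros((len(keep), len(keep)))
        for a, i in enumerate(keep):
            for b, j in enumerate(keep):
                Q[a][b] = sum(
                    P[i][k] * P[j][k] / (px[i] * py[k]) for k in keep
                )
        eig = sorted(np.real(np.linalg.eigvals(Q)), reverse=True)
        if len(eig) >= 2 and np.isfinite(eig[1]) and eig[1] > 0:
            mcc = float(np.sqrt(eig[1]))
    out["mcc"] = mcc
    return out


def brute_force_corner_distance_threshold(scores, labels):
    """Minimum of sqrt((1-sens)^2 + (1-spec)^2) over every score threshold.

    Evaluates the distance at each candidate cut (every distinct score plus
    +inf) by direct counting; ties resolved toward higher sensitivity.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    candidates = [np.inf] + sorted(set(scores), reverse=True)
    best = None
    for t in candidates:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fn = int((~pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        tn = int((~pred & (labels == 0)).sum())
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        d = np.sqrt((1 - sens) ** 2 + (1 - spec) ** 2)
        key = (round(d, 12), -sens)
        if best is None or key < best[0]:
            best = (key, t)
    return best[1]


def pearson_mcc(cm) -> float:
    """MCC via the Pearson correlation of reconstructed binary vectors."""
    truth = [1] * cm.TP + [1] * cm.FN + [0] * cm.FP + [0] * cm.TN
    pred = [1] * cm.TP + [0] * cm.FN + [1] * cm.FP + [0] * cm.TN
    return float(np.corrcoef(truth, pred)[0, 1])


def best_biopsy_subset(sizes: dict[str, int], test_fraction: float) -> float:
    """Smallest achievable |test count - target| over all proper subsets."""
    from itertools import combinations

    ids = list(sizes)
    target = test_fraction * sum(sizes.values())
    best = np.inf
    for r in range(1, len(ids)):
        for combo in combinations(ids, r):
            best = min(best, abs(sum(sizes[b] for b in combo) - target))
    return best
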