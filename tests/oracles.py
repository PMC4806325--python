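"""Independent brute-force oracles for the texture operators.

Everything here is written as plain nested loops over voxel pairs /
neighborhoods / runs, deliberately avoiding the vectorised code paths of the
package, so agreement to 1e-10 on small fixtures is a meaningful check.
"""

import math

import numpy as np


def log2_safe(p):
    return math.log2(p) if p > 0 else 0.0


# ---------------------------------------------------------------- GLCM

def glcm_matrix_bruteforce(level_slices, G, min_pixels=16):
    """Symmetric co-occurrence counts via explicit pair enumeration."""
    offsets = [(0, 1), (1, 1), (1, 0), (1, -1)]
    C = np.zeros((G, G))
    for L in level_slices:
        if (L > 0).sum() < min_pixels:
            continue
        H, W = L.shape
        for y in range(H):
            for x in range(W):
                if L[y, x] == 0:
                    continue
                for dy, dx in offsets:
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < H and 0 <= xx < W and L[yy, xx] > 0:
                        C[L[y, x] - 1, L[yy, xx] - 1] += 1
                        C[L[yy, xx] - 1, L[y, x] - 1] += 1
    total = C.sum()
    return C / total if total > 0 else C


def glcm_features_bruteforce(P):
    """Haralick features via scalar loops over the normalised matrix."""
    G = P.shape[0]
    feats = {}
    px = [sum(P[i, j] for j in range(G)) for i in range(G)]
    py = [sum(P[i, j] for i in range(G)) for j in range(G)]
    mu_x = sum((i + 1) * px[i] for i in range(G))
    mu_y = sum((j + 1) * py[j] for j in range(G))
    var_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(G))
    var_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(G))

    energy = entropy = contrast = dissim = homog = autoc = var = 0.0
    shade = prom = 0.0
    p_sum = {}
    p_diff = {}
    for i in range(G):
        for j in range(G):
            p = P[i, j]
            if p == 0:
                continue
            gi, gj = i + 1, j + 1
            energy += p * p
            entropy -= p * log2_safe(p)
            contrast += p * (gi - gj) ** 2
            dissim += p * abs(gi - gj)
            homog += p / (1 + (gi - gj) ** 2)
            autoc += p * gi * gj
            var += p * (gi - mu_x) ** 2
            shade += p * (gi + gj - mu_x - mu_y) ** 3
            prom += p * (gi + gj - mu_x - mu_y) ** 4
            p_sum[gi + gj] = p_sum.get(gi + gj, 0.0) + p
            p_diff[abs(gi - gj)] = p_diff.get(abs(gi - gj), 0.0) + p

    sa = sum(k * v for k, v in p_sum.items())
    sv = sum((k - sa) ** 2 * v for k, v in p_sum.items())
    se = -sum(v * log2_safe(v) for v in p_sum.values())
    da = sum(k * v for k, v in p_diff.items())
    dv = sum((k - da) ** 2 * v for k, v in p_diff.items())
    de = -sum(v * log2_safe(v) for v in p_diff.values())

    hx = -sum(p * log2_safe(p) for p in px if p > 0)
    hy = -sum(p * log2_safe(p) for p in py if p > 0)
    hxy1 = hxy2 = 0.0
    for i in range(G):
        for j in range(G):
            q = px[i] * py[j]
            hxy1 -= P[i, j] * log2_safe(q)
            hxy2 -= q * log2_safe(q)
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))
    corr = ((autoc - mu_x * mu_y) / math.sqrt(var_x * var_y)
            if var_x > 0 and var_y > 0 else 1.0)

    feats.update({
        "GLCM_Energy": energy, "GLCM_Entropy": entropy, "GLCM_Contrast": contrast,
        "GLCM_Dissimilarity": dissim, "GLCM_Homogeneity": homog,
        "GLCM_Correlation": corr, "GLCM_Variance": var, "GLCM_SumAverage": sa,
        "GLCM_SumVariance": sv, "GLCM_SumEntropy": se,
        "GLCM_DifferenceVariance": dv, "GLCM_DifferenceEntropy": de,
        "GLCM_IMC1": imc1, "GLCM_IMC2": imc2, "GLCM_Autocorrelation": autoc,
        "GLCM_ClusterShade": shade, "GLCM_ClusterProminence": prom,
    })
    return feats


# ---------------------------------------------------------------- GTDM

def gtdm_features_bruteforce(level_slices, G, eps=1e-12):
    s = [0.0] * G
    n = [0] * G
    for L in level_slices:
        H, W = L.shape
        for y in range(1, H - 1):
            for x in range(1, W - 1):
                if L[y, x] == 0:
                    continue
                neigh = [L[y + dy, x + dx] for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                         if not (dy == 0 and dx == 0)]
                if any(v == 0 for v in neigh):
                    continue
                mean = sum(neigh) / 8.0
                lev = L[y, x]
                s[lev - 1] += abs(lev - mean)
                n[lev - 1] += 1
    N = sum(n)
    if N == 0:
        return None
    p = [c / N for c in n]
    present = [i for i in range(G) if p[i] > 0]
    Ngp = len(present)
    ps_sum = sum(p[i] * s[i] for i in range(G))
    coarse = 1.0 / (eps + ps_sum)
    if Ngp > 1:
        contrast = (sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
                    / (Ngp * (Ngp - 1))) * (sum(s) / N)
        busy_den = sum(abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present)
        busy = ps_sum / busy_den if busy_den > eps else 0.0
        compl_ = sum(abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                     for i in present for j in present) / N
        strength = sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) \
            / (eps + sum(s))
    else:
        contrast = busy = compl_ = strength = 0.0
    return {"GTDM_Coarseness": coarse, "GTDM_Contrast": contrast,
            "GTDM_Busyness": busy, "GTDM_Complexity": compl_,
            "GTDM_Strength": strength}


# ---------------------------------------------------------------- run length

def _lines_for_direction(L, direction):
    H, W = L.shape
    if direction == "horizontal":
        return [[L[y, x] for x in range(W)] for y in range(H)]
    if direction == "vertical":
        return [[L[y, x] for y in range(H)] for x in range(W)]
    if direction == "diagonal":
        lines = []
        for k in range(-(H - 1), W):
            lines.append([L[y, y + k] for y in range(H) if 0 <= y + k < W])
        return lines
    if direction == "antidiagonal":
        lines = []
        for k in range(0, H + W - 1):
            lines.append([L[y, k - y] for y in range(H) if 0 <= k - y < W])
        return lines
    raise ValueError(direction)


def runlength_matrix_bruteforce(level_slices, G, directions):
    runs = {}
    n_pixels = 0
    max_len = 1
    for L in level_slices:
        if not (np.asarray(L) > 0).any():
            continue
        n_pixels += int((np.asarray(L) > 0).sum())
        for direction in directions:
            for line in _lines_for_direction(np.asarray(L), direction):
                i = 0
                while i < len(line):
                    if line[i] == 0:
                        i += 1
                        continue
                    j = i
                    while j + 1 < len(line) and line[j + 1] == line[i]:
                        j += 1
                    length = j - i + 1
                    runs[(line[i], length)] = runs.get((line[i], length), 0) + 1
                    max_len = max(max_len, length)
                    i = j + 1
    R = np.zeros((G, max_len))
    for (g, l), c in runs.items():
        R[g - 1, l - 1] = c
    return R, n_pixels * len(directions)


def runlength_features_bruteforce(level_slices, G, directions):
    R, np_dir = runlength_matrix_bruteforce(level_slices, G, directions)
    Nr = R.sum()
    feats = {k: 0.0 for k in ("RL_SRE", "RL_LRE", "RL_GLN", "RL_RLN", "RL_RP",
                              "RL_LGRE", "RL_HGRE", "RL_SRLGE", "RL_SRHGE",
                              "RL_LRLGE", "RL_LRHGE")}
    for gi in range(R.shape[0]):
        for li in range(R.shape[1]):
            r = R[gi, li]
            if r == 0:
                continue
            g, l = gi + 1, li + 1
            feats["RL_SRE"] += r / l ** 2
            feats["RL_LRE"] += r * l ** 2
            feats["RL_LGRE"] += r / g ** 2
            feats["RL_HGRE"] += r * g ** 2
            feats["RL_SRLGE"] += r / (g ** 2 * l ** 2)
            feats["RL_SRHGE"] += r * g ** 2 / l ** 2
            feats["RL_LRLGE"] += r * l ** 2 / g ** 2
            feats["RL_LRHGE"] += r * g ** 2 * l ** 2
    for k in ("RL_SRE", "RL_LRE", "RL_LGRE", "RL_HGRE", "RL_SRLGE",
              "RL_SRHGE", "RL_LRLGE", "RL_LRHGE"):
        feats[k] /= Nr
    feats["RL_GLN"] = sum(R[gi, :].sum() ** 2 for gi in range(R.shape[0])) / Nr
    feats["RL_RLN"] = sum(R[:, li].sum() ** 2 for li in range(R.shape[1])) / Nr
    feats["RL_RP"] = Nr / np_dir
    return feats


# ---------------------------------------------------------------- Laws

def convolve2d_reflect(img, kernel):
    """Direct convolution with reflect (mirror-without-repeat is NOT used:
    this matches scipy.ndimage 'reflect', i.e. edge-repeating symmetric)."""
    H, W = img.shape
    kh, kw = kernel.shape
    cy, cx = kh // 2, kw // 2
    out = np.zeros((H, W))
    def refl(i, n):
        while i < 0 or i >= n:
            if i < 0:
                i = -i - 1
            if i >= n:
                i = 2 * n - i - 1
        return i
    for y in range(H):
        for x in range(W):
            acc = 0.0
            for ky in range(kh):
                for kx in range(kw):
                    yy = refl(y + cy - ky, H)   # convolution flips the kernel
                    xx = refl(x + cx - kx, W)
                    acc += kernel[ky, kx] * img[yy, xx]
            out[y, x] = acc
    return out


def laws_features_bruteforce(img_slices, mask_slices, min_bbox=5):
    l5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
    e5 = np.array([-1.0, -2.0, 0.0, 2.0, 1.0])
    s5 = np.array([-1.0, 0.0, 2.0, 0.0, -1.0])
    pairs = {"Laws_L5E5": [(l5, e5), (e5, l5)], "Laws_L5S5": [(l5, s5), (s5, l5)],
             "Laws_E5E5": [(e5, e5)], "Laws_E5S5": [(e5, s5), (s5, e5)],
             "Laws_S5S5": [(s5, s5)]}
    sums = {k: 0.0 for k in pairs}
    count = 0
    for img, m in zip(img_slices, mask_slices):
        m = np.asarray(m, dtype=bool)
        if not m.any():
            continue
        ys, xs = np.nonzero(m)
        if (ys.max() - ys.min() + 1) < min_bbox or (xs.max() - xs.min() + 1) < min_bbox:
            continue
        count += int(m.sum())
        for name, ks in pairs.items():
            resp = np.zeros(img.shape)
            for a, b in ks:
                resp += np.abs(convolve2d_reflect(np.asarray(img, float), np.outer(a, b)))
            sums[name] += resp[m].sum() / len(ks)
    if count == 0:
        return None
    return {k: v / count for k, v in sums.items()}


# ---------------------------------------------------------------- edge frequency

def edge_frequency_bruteforce(img_slices, mask_slices, distances=(1, 2, 3)):
    sums = {d: 0.0 for d in distances}
    counts = {d: 0 for d in distances}
    dirs = [(0, 1), (0, -1), (1, 0), (-1, 0)]
    for img, m in zip(img_slices, mask_slices):
        img = np.asarray(img, float)
        m = np.asarray(m, dtype=bool)
        H, W = m.shape
        for d in distances:
            for dy, dx in dirs:
                for y in range(H):
                    for x in range(W):
                        yy, xx = y + dy * d, x + dx * d
                        if m[y, x] and 0 <= yy < H and 0 <= xx < W and m[yy, xx]:
                            sums[d] += abs(img[y, x] - img[yy, xx])
                            counts[d] += 1
    out = {}
    efs = []
    for d in distances:
        ef = sums[d] / counts[d] if counts[d] else float("nan")
        out[f"EF_d{d}"] = ef
        efs.append(ef)
    out["EF_Coarseness"] = 1.0 / (1.0 + sum(efs) / len(efs))
    return out


# ---------------------------------------------------------------- spatial correlation

def spatial_correlation_bruteforce(img_slices, mask_slices):
    out = {}
    for name, (dy, dx) in (("AutoCorr_X", (0, 1)), ("AutoCorr_Y", (1, 0))):
        xs, ys = [], []
        for img, m in zip(img_slices, mask_slices):
            img = np.asarray(img, float)
            m = np.asarray(m, dtype=bool)
            H, W = m.shape
            for y in range(H):
                for x in range(W):
                    yy, xx = y + dy, x + dx
                    if m[y, x] and yy < H and xx < W and m[yy, xx]:
                        xs.append(img[y, x])
                        ys.append(img[yy, xx])
        xs, ys = np.array(xs), np.array(ys)
        if xs.std() == 0 or ys.std() == 0:
            out[name] = 1.0
            continue
        mx, my = xs.mean(), ys.mean()
        out[name] = float(((xs - mx) * (ys - my)).sum()
                          / math.sqrt(((xs - mx) ** 2).sum() * ((ys - my) ** 2).sum()))
    return out
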