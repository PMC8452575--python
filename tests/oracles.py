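"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible (explicit Python loops,
no vectorisation tricks) so it can serve as an oracle for the optimised
library code.
"""

from __future__ import annotations

import math

import numpy as np

# the 13 unique 3-D direction offsets at Chebyshev distance 1
OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]

NEIGHBOURS26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _in_bounds(idx, shape):
    return all(0 <= i < n for i, n in zip(idx, shape))


# ---------------------------------------------------------------------------
# GLCM


def naive_glcm(levels: np.ndarray, ng: int, offset) -> np.ndarray:
    """Symmetric normalised co-occurrence matrix for one offset, by loops."""
    shape = levels.shape
    m = np.zeros((ng, ng))
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0:
                    continue
                nb = (x + offset[0], y + offset[1], z + offset[2])
                if not _in_bounds(nb, shape):
                    continue
                b = levels[nb]
                if b == 0:
                    continue
                m[a - 1, b - 1] += 1
                m[b - 1, a - 1] += 1
    total = m.sum()
    return m / total if total > 0 else m


def glcm_features_from_matrix(p: np.ndarray) -> dict:
    ng = p.shape[0]
    mu = 0.0
    for i in range(ng):
        for j in range(ng):
            mu += (i + 1) * p[i, j]
    sig2 = 0.0
    for i in range(ng):
        for j in range(ng):
            sig2 += (i + 1 - mu) ** 2 * p[i, j]
    out = {
        "GLCM contrast": 0.0, "GLCM dissimilarity": 0.0, "GLCM entropy": 0.0,
        "GLCM correlation": 0.0, "GLCM energy": 0.0, "GLCM homogeneity": 0.0,
        "GLCM cluster shade": 0.0, "GLCM cluster prominence": 0.0,
        "GLCM autocorrelation": 0.0,
    }
    corr_num = 0.0
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            d = abs(i - j)
            out["GLCM contrast"] += d**2 * v
            out["GLCM dissimilarity"] += d * v
            if v > 0:
                out["GLCM entropy"] -= v * math.log2(v)
            out["GLCM energy"] += v**2
            out["GLCM homogeneity"] += v / (1.0 + d)
            out["GLCM cluster shade"] += (i + j + 2 - 2 * mu) ** 3 * v
            out["GLCM cluster prominence"] += (i + j + 2 - 2 * mu) ** 4 * v
            out["GLCM autocorrelation"] += (i + 1) * (j + 1) * v
            corr_num += (i + 1 - mu) * (j + 1 - mu) * v
    out["GLCM correlation"] = corr_num / sig2 if sig2 > 1e-12 else 1.0
    return out


def naive_glcm_features(levels: np.ndarray, ng: int) -> dict:
    feats = []
    for off in OFFSETS:
        m = naive_glcm(levels, ng, off)
        if m.sum() > 0:
            feats.append(glcm_features_from_matrix(m))
    keys = feats[0].keys()
    return {k: float(np.mean([f[k] for f in feats])) for k in keys}


# ---------------------------------------------------------------------------
# GLRLM


def naive_glrlm(levels: np.ndarray, ng: int, direction) -> np.ndarray:
    """Run-length matrix by walking every maximal run."""
    shape = levels.shape
    runs = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0:
                    continue
                prev = (x - direction[0], y - direction[1], z - direction[2])
                if _in_bounds(prev, shape) and levels[prev] == g:
                    continue  # not the start of a run
                length = 1
                cur = (x, y, z)
                while True:
                    nxt = tuple(c + d for c, d in zip(cur, direction))
                    if _in_bounds(nxt, shape) and levels[nxt] == g:
                        length += 1
                        cur = nxt
                    else:
                        break
                runs.append((g, length))
    if not runs:
        return np.zeros((ng, 1))
    rmax = max(length for _, length in runs)
    mat = np.zeros((ng, rmax))
    for g, length in runs:
        mat[g - 1, length - 1] += 1
    return mat


def glrlm_features_from_matrix(r: np.ndarray, n_vox: int) -> dict:
    ng, rmax = r.shape
    nr = r.sum()
    sre = lre = gln = rln = lglre = hglre = lrlgle = lrhgle = 0.0
    for i in range(ng):
        row = 0.0
        for j in range(rmax):
            v = r[i, j]
            row += v
            sre += v / (j + 1) ** 2
            lre += v * (j + 1) ** 2
            lglre += v / (i + 1) ** 2
            hglre += v * (i + 1) ** 2
            lrlgle += v * (j + 1) ** 2 / (i + 1) ** 2
            lrhgle += v * (j + 1) ** 2 * (i + 1) ** 2
        gln += row**2
    for j in range(rmax):
        col = sum(r[i, j] for i in range(ng))
        rln += col**2
    mu_l = sum((j + 1) * sum(r[i, j] for i in range(ng)) for j in range(rmax)) / nr
    rlv = sum(
        (sum(r[i, j] for i in range(ng)) / nr) * ((j + 1) - mu_l) ** 2
        for j in range(rmax)
    )
    return {
        "GLRLM short run emphasis": sre / nr,
        "GLRLM long run emphasis": lre / nr,
        "GLRLM grey level non-uniformity": gln / nr,
        "GLRLM run length non-uniformity": rln / nr,
        "GLRLM run percentage": nr / n_vox,
        "GLRLM low grey level run emphasis": lglre / nr,
        "GLRLM high grey level run emphasis": hglre / nr,
        "GLRLM long run low grey level emphasis": lrlgle / nr,
        "GLRLM long run high grey level emphasis": lrhgle / nr,
        "GLRLM run length variance": rlv,
    }


def naive_glrlm_features(levels: np.ndarray, ng: int) -> dict:
    n_vox = int((levels > 0).sum())
    feats = [
        glrlm_features_from_matrix(naive_glrlm(levels, ng, d), n_vox)
        for d in OFFSETS
    ]
    return {k: float(np.mean([f[k] for f in feats])) for k in feats[0]}


# ---------------------------------------------------------------------------
# GLSZM


def naive_glszm(levels: np.ndarray, ng: int) -> np.ndarray:
    """Size-zone matrix via hand-rolled 26-connected flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0 or seen[x, y, z]:
                    continue
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cur = stack.pop()
                    size += 1
                    for off in NEIGHBOURS26:
                        nb = tuple(c + d for c, d in zip(cur, off))
                        if (
                            _in_bounds(nb, shape)
                            and not seen[nb]
                            and levels[nb] == g
                        ):
                            seen[nb] = True
                            stack.append(nb)
                zones.append((g, size))
    smax = max(s for _, s in zones)
    mat = np.zeros((ng, smax))
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return mat


def glszm_features_from_matrix(z: np.ndarray, n_vox: int) -> dict:
    ng, smax = z.shape
    nz = z.sum()
    sze = lze = gln = zsn = lglze = hglze = szlge = szhge = lzlge = lzhge = 0.0
    for i in range(ng):
        row = 0.0
        for j in range(smax):
            v = z[i, j]
            row += v
            sze += v / (j + 1) ** 2
            lze += v * (j + 1) ** 2
            lglze += v / (i + 1) ** 2
            hglze += v * (i + 1) ** 2
            szlge += v / ((j + 1) ** 2 * (i + 1) ** 2)
            szhge += v * (i + 1) ** 2 / (j + 1) ** 2
            lzlge += v * (j + 1) ** 2 / (i + 1) ** 2
            lzhge += v * (j + 1) ** 2 * (i + 1) ** 2
        gln += row**2
    for j in range(smax):
        col = sum(z[i, j] for i in range(ng))
        zsn += col**2
    mu_g = sum((i + 1) * sum(z[i, j] for j in range(smax)) for i in range(ng)) / nz
    glv = sum(
        (sum(z[i, j] for j in range(smax)) / nz) * ((i + 1) - mu_g) ** 2
        for i in range(ng)
    )
    return {
        "GLSZM small zone emphasis": sze / nz,
        "GLSZM large zone emphasis": lze / nz,
        "GLSZM grey level non-uniformity": gln / nz,
        "GLSZM zone size non-uniformity": zsn / nz,
        "GLSZM zone percentage": nz / n_vox,
        "GLSZM low grey level zone emphasis": lglze / nz,
        "GLSZM high grey level zone emphasis": hglze / nz,
        "GLSZM small zone low grey level emphasis": szlge / nz,
        "GLSZM small zone high grey level emphasis": szhge / nz,
        "GLSZM large zone low grey level emphasis": lzlge / nz,
        "GLSZM large zone high grey level emphasis": lzhge / nz,
        "GLSZM grey level variance": glv,
    }


def naive_glszm_features(levels: np.ndarray, ng: int) -> dict:
    n_vox = int((levels > 0).sum())
    return glszm_features_from_matrix(naive_glszm(levels, ng), n_vox)


# ---------------------------------------------------------------------------
# NGTDM


def naive_ngtdm(levels: np.ndarray, ng: int):
    """Per-level (n_i, p_i, s_i) via explicit neighbourhood loops."""
    shape = levels.shape
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0:
                    continue
                vals = []
                for off in NEIGHBOURS26:
                    nb = (x + off[0], y + off[1], z + off[2])
                    if _in_bounds(nb, shape) and levels[nb] > 0:
                        vals.append(levels[nb])
                if not vals:
                    continue
                n_i[g - 1] += 1
                s_i[g - 1] += abs(g - sum(vals) / len(vals))
    tot = n_i.sum()
    p_i = n_i / tot if tot > 0 else n_i
    return n_i, p_i, s_i


def naive_ngtdm_features(levels: np.ndarray, ng: int) -> dict:
    n_i, p_i, s_i = naive_ngtdm(levels, ng)
    n_tot = n_i.sum()
    occ = [i for i in range(ng) if p_i[i] > 0]
    n_g = len(occ)
    ps = sum(p_i[i] * s_i[i] for i in range(ng))
    coarseness = 1.0 / ps if ps > 1e-12 else 1e6
    contrast = 0.0
    busy_den = 0.0
    complexity = 0.0
    strength_num = 0.0
    if n_g > 1:
        for i in occ:
            for j in occ:
                contrast += p_i[i] * p_i[j] * (i - j) ** 2
                busy_den += abs((i + 1) * p_i[i] - (j + 1) * p_i[j])
                complexity += (
                    abs(i - j)
                    * (p_i[i] * s_i[i] + p_i[j] * s_i[j])
                    / (p_i[i] + p_i[j])
                )
                strength_num += (p_i[i] + p_i[j]) * (i - j) ** 2
        contrast *= s_i.sum() / n_tot / (n_g * (n_g - 1))
        complexity /= n_tot
    busyness = ps / busy_den if busy_den > 1e-12 else 0.0
    s_sum = s_i.sum()
    strength = strength_num / s_sum if s_sum > 1e-12 else 0.0
    return {
        "NGTDM coarseness": coarseness,
        "NGTDM contrast": contrast,
        "NGTDM busyness": busyness,
        "NGTDM complexity": complexity,
        "NGTDM strength": strength,
    }


def naive_texture_features(levels: np.ndarray, ng: int) -> dict:
    out = {}
    out.update(naive_glcm_features(levels, ng))
    out.update(naive_glrlm_features(levels, ng))
    out.update(naive_glszm_features(levels, ng))
    out.update(naive_ngtdm_features(levels, ng))
    return out


# ---------------------------------------------------------------------------
# correlation filter, AUC, Youden


def brute_force_correlation_filter(table, cutoff: float = 0.9) -> list:
    """One-pair-per-iteration redundancy filter, re-implemented naively."""
    cols = list(table.columns)
    data = {c: np.asarray(table[c], dtype=float) for c in cols}
    retained = [c for c in cols if np.std(data[c]) > 1e-12]

    def corr(a, b):
        return float(np.corrcoef(data[a], data[b])[0, 1])

    while True:
        best_pair, best_r = None, cutoff
        for i in range(len(retained)):
            for j in range(i + 1, len(retained)):
                r = abs(corr(retained[i], retained[j]))
                if r > best_r + 1e-15:  # strictly larger; first pair wins ties
                    best_r = r
                    best_pair = (retained[i], retained[j])
        if best_pair is None:
            break
        a, b = best_pair
        mean_a = np.mean([abs(corr(a, c)) for c in retained if c != a])
        mean_b = np.mean([abs(corr(b, c)) for c in retained if c != b])
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:  # tie: remove the later-indexed member
            drop = b if retained.index(b) > retained.index(a) else a
        retained.remove(drop)
    return retained


def pair_counting_auc(scores, labels) -> float:
    """AUC as the concordant-pair fraction with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def exhaustive_youden(scores, labels) -> float:
    """Exhaustive search over unique scores; lowest threshold wins ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_t, best_j = None, -np.inf
    for t in sorted(set(scores.tolist())):
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)
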