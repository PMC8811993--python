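"""Independent brute-force oracles used to validate the implementation.

Each function here recomputes a quantity by the most transparent route
available (exhaustive enumeration, pair counting, resampling) and stays
deliberately separate from the package's own code paths.
"""

import numpy as np
from scipy import ndimage


def pair_count_auc(scores, labels) -> float:
    """AUC by explicit enumeration of all positive x negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == labels.max()]
    neg = scores[labels != labels.max()]
    wins = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def intermeans_fixed_points(img) -> list[int]:
    """All t in 0..254 with t == round((mean(<=t) + mean(>t)) / 2)."""
    vals = np.asarray(img).ravel().astype(float)
    out = []
    for t in range(255):
        lo = vals[vals <= t]
        hi = vals[vals > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        if int(np.round((lo.mean() + hi.mean()) / 2.0)) == t:
            out.append(t)
    return out


def trimmed_histogram_values(img) -> np.ndarray:
    """Pixel values after the >50%-saturated-extreme trimming rule."""
    vals = np.asarray(img).ravel()
    n = vals.size
    for extreme in (0, 255):
        if (vals == extreme).sum() > n // 2:
            vals = vals[vals != extreme]
    if len(np.unique(vals)) < 2:
        vals = np.asarray(img).ravel()
    return vals


def ball_opening_subtract(img, radius) -> np.ndarray:
    """Exact rolling-ball subtraction: grayscale opening by a ball cap."""
    r = int(np.ceil(radius))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = x * x + y * y
    h = np.sqrt(np.maximum(radius * radius - d2, 0.0))
    fp = d2 <= radius * radius
    a = np.asarray(img, dtype=np.float64)
    ero = ndimage.grey_erosion(a, structure=h, footprint=fp, mode="nearest")
    bg = ndimage.grey_dilation(ero, structure=h, footprint=fp, mode="nearest")
    bg = np.minimum(bg, a)
    return np.clip(np.round(a - bg), 0, 255).astype(np.uint8)


def _psi(x, y):
    return (x[:, None] > y[None, :]) + 0.5 * (x[:, None] == y[None, :])


def permutation_delong_p(scores_a, scores_b, labels, n_perm=10_000, seed=0):
    """Permutation p for a paired AUC difference.

    The null of equal AUCs is simulated by independently swapping, per
    subject, which of the two predictors contributes that subject's score
    to each side of the comparison.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    pos = labels == labels.max()
    xa, xb = a[pos], b[pos]
    ya, yb = a[~pos], b[~pos]
    m00 = _psi(xa, ya)
    m01 = _psi(xa, yb)
    m10 = _psi(xb, ya)
    m11 = _psi(xb, yb)
    mn = m00.size
    obs = abs(m00.mean() - m11.mean())
    s = rng.integers(0, 2, (n_perm, len(xa))).astype(float)
    t = rng.integers(0, 2, (n_perm, len(ya))).astype(float)
    sa, ta = 1.0 - s, 1.0 - t
    auc_a = (
        np.einsum("ri,ij,rj->r", sa, m00, ta)
        + np.einsum("ri,ij,rj->r", sa, m01, t)
        + np.einsum("ri,ij,rj->r", s, m10, ta)
        + np.einsum("ri,ij,rj->r", s, m11, t)
    ) / mn
    auc_b = (
        np.einsum("ri,ij,rj->r", s, m00, t)
        + np.einsum("ri,ij,rj->r", s, m01, ta)
        + np.einsum("ri,ij,rj->r", sa, m10, t)
        + np.einsum("ri,ij,rj->r", sa, m11, ta)
    ) / mn
    return float(np.mean(np.abs(auc_a - auc_b) >= obs - 1e-12))


def bootstrap_auc_se(scores, labels, n_boot=2000, seed=0) -> float:
    """Stratified bootstrap standard error of the Mann-Whitney AUC."""
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == labels.max()]
    neg = scores[labels != labels.max()]
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        bp = rng.choice(pos, len(pos))
        bn = rng.choice(neg, len(neg))
        aucs[i] = _psi(bp, bn).mean()
    return float(aucs.std(ddof=1))
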