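"""Independent brute-force reference implementations used only by tests.

Everything here is written as directly as possible from the metric and
attention definitions — double loops over pixel pairs, per-query softmax
loops — and deliberately shares no code with the package's implementations.
"""

import numpy as np


def mask_points(mask: np.ndarray, spacing=(1.0, 1.0)):
    pts = []
    it = np.ndindex(mask.shape)
    for idx in it:
        if mask[idx]:
            pts.append(tuple(i * s for i, s in zip(idx, spacing)))
    return pts


def brute_dice(p, g):
    sp = {i for i in zip(*np.nonzero(p))}
    sg = {i for i in zip(*np.nonzero(g))}
    if not sp and not sg:
        return 1.0
    return 2 * len(sp & sg) / (len(sp) + len(sg))


def brute_voe(p, g):
    sp = {i for i in zip(*np.nonzero(p))}
    sg = {i for i in zip(*np.nonzero(g))}
    if not (sp | sg):
        return 0.0
    return 1 - len(sp & sg) / len(sp | sg)


def brute_rvd(p, g):
    np_, ng = int(np.sum(p)), int(np.sum(g))
    return (ng - np_) / np_


def _directed(pts_a, pts_b, reduce_outer):
    mins = []
    for a in pts_a:
        best = min(
            np.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a, b))) for b in pts_b
        )
        mins.append(best)
    return reduce_outer(mins)


def brute_hausdorff(p, g, spacing=(1.0, 1.0)):
    pa, pb = mask_points(p, spacing), mask_points(g, spacing)
    return max(_directed(pa, pb, max), _directed(pb, pa, max))


def brute_assd(p, g, spacing=(1.0, 1.0)):
    pa, pb = mask_points(p, spacing), mask_points(g, spacing)
    return 0.5 * (np.mean(_directed(pa, pb, list)) + np.mean(_directed(pb, pa, list)))


def enum_surface_distances(p, g, spacing=(1.0, 1.0)):
    """Full pairwise-distance enumeration (broadcasted, no spatial index):
    returns (hausdorff, assd) from the complete |P| x |G| distance matrix."""
    pa = np.argwhere(p).astype(float) * np.asarray(spacing)
    pb = np.argwhere(g).astype(float) * np.asarray(spacing)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    d_pg = d.min(axis=1)  # every p to nearest g
    d_gp = d.min(axis=0)
    hd = max(d_pg.max(), d_gp.max())
    assd = 0.5 * (d_pg.mean() + d_gp.mean())
    return hd, assd


def brute_attention(seq: np.ndarray, wq: np.ndarray, wk: np.ndarray,
                    wv: np.ndarray):
    """Per-query-token loop attention; returns (output, weights)."""
    q, k, v = seq @ wq, seq @ wk, seq @ wv
    n, dq = q.shape
    weights = np.zeros((n, n))
    out = np.zeros((n, v.shape[1]))
    for i in range(n):
        scores = np.array([q[i] @ k[j] / np.sqrt(dq) for j in range(n)])
        e = np.exp(scores - scores.max())
        w = e / e.sum()
        weights[i] = w
        out[i] = sum(w[j] * v[j] for j in range(n))
    return out, weights


def brute_layer_norm(x: np.ndarray, gamma, beta, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return gamma * (x - mu) / np.sqrt(var + eps) + beta


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f(x)
        x[idx] = orig - eps
        fm = f(x)
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
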