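"""Independent pure-loop reference for the channel attention gate.

Implements every step with explicit python loops in float64, sharing no code
with the package implementation; used to pin the vectorised path.
"""

import math

import numpy as np


def loop_lrelu(v, mu):
    return v if v > 0 else mu * v


def loop_project(xf, w, b, mu):
    c, n = xf.shape
    out = np.zeros((c, n))
    for i in range(c):
        for v in range(n):
            s = b[i]
            for j in range(c):
                s += w[i][j] * xf[j][v]
            out[i][v] = loop_lrelu(s, mu)
    return out


def loop_correlation(f, g):
    c, n = f.shape
    delta = np.zeros((c, c))
    for i in range(c):
        for j in range(c):
            for v in range(n):
                delta[i][j] += f[i][v] * g[j][v]
    return delta


def loop_softmax_rows(delta):
    c = delta.shape[0]
    alpha = np.zeros_like(delta)
    for i in range(c):
        m = max(delta[i])
        exps = [math.exp(d - m) for d in delta[i]]
        s = sum(exps)
        for j in range(c):
            alpha[i][j] = exps[j] / s
    return alpha


def loop_mix(w, b, z):
    c, n = z.shape
    out = np.zeros((c, n))
    for i in range(c):
        for v in range(n):
            s = b[i]
            for j in range(c):
                s += w[i][j] * z[j][v]
            out[i][v] = s
    return out


def loop_response(alpha, h):
    c, n = h.shape
    r = np.zeros((c, n))
    for i in range(c):
        for j in range(c):
            for v in range(n):
                r[i][v] += alpha[i][j] * h[j][v]
    return r


def loop_sigmoid(r):
    out = np.zeros_like(r)
    for i in range(r.shape[0]):
        for v in range(r.shape[1]):
            out[i][v] = 1.0 / (1.0 + math.exp(-r[i][v]))
    return out


def cag_oracle(x, y, params, merge_mode="concat"):
    """Full gate forward, all-loops, float64."""
    c = x.shape[0]
    spatial = x.shape[1:]
    n = int(np.prod(spatial))
    xf = np.asarray(x, dtype=np.float64).reshape(c, n)
    yf = np.asarray(y, dtype=np.float64).reshape(c, n)
    mu = params.mu
    f = loop_project(xf, np.asarray(params.w_f, float),
                     np.asarray(params.b_f, float), mu)
    g = loop_project(yf, np.asarray(params.w_g, float),
                     np.asarray(params.b_g, float), mu)
    delta = loop_correlation(f, g)
    alpha = loop_softmax_rows(delta)
    z = f + g
    h = loop_mix(np.asarray(params.w_h, float),
                 np.asarray(params.b_h, float), z)
    r = loop_response(alpha, h)
    omega = loop_sigmoid(r)
    gated = (f * omega).reshape((c,) + spatial)
    if merge_mode == "concat":
        return np.concatenate([gated, np.asarray(y, float)], axis=0)
    return gated + np.asarray(y, float)
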