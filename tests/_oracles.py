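"""Independent straight-loop reference implementations.

Everything here is written as plain Python loops and explicit closed-form
arithmetic, deliberately sharing no code with the package's vectorized
forward passes; the tests compare the two routes on small seeded instances.
"""

from __future__ import annotations

import numpy as np


def o_sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def o_relu(x):
    return np.maximum(np.asarray(x, dtype=np.float64), 0.0)


def o_conv2d(x, w, b=None, pad=0, dilation=1):
    """Dense stride-1 correlation via explicit quadruple loops."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    n, cin, h, wd = x.shape
    cout, _, k, _ = w.shape
    xp = np.zeros((n, cin, h + 2 * pad, wd + 2 * pad))
    xp[:, :, pad:pad + h, pad:pad + wd] = x
    out = np.zeros((n, cout, h, wd))
    for ni in range(n):
        for o in range(cout):
            for i in range(h):
                for j in range(wd):
                    acc = 0.0
                    for c in range(cin):
                        for ki in range(k):
                            for kj in range(k):
                                acc += (xp[ni, c, i + ki * dilation, j + kj * dilation]
                                        * w[o, c, ki, kj])
                    out[ni, o, i, j] = acc + (0.0 if b is None else b[o])
    return out


def o_depthwise_conv2d(x, w, b=None, pad=0):
    """Depthwise stride-1 correlation via explicit loops; w is (C, k, k)."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    n, c, h, wd = x.shape
    k = w.shape[-1]
    xp = np.zeros((n, c, h + 2 * pad, wd + 2 * pad))
    xp[:, :, pad:pad + h, pad:pad + wd] = x
    out = np.zeros((n, c, h, wd))
    for ni in range(n):
        for ci in range(c):
            for i in range(h):
                for j in range(wd):
                    acc = 0.0
                    for ki in range(k):
                        for kj in range(k):
                            acc += xp[ni, ci, i + ki, j + kj] * w[ci, ki, kj]
                    out[ni, ci, i, j] = acc + (0.0 if b is None else b[ci])
    return out


def o_batchnorm(x, gamma, beta, eps=1e-5):
    """Training-mode batch normalization with biased batch statistics."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    for c in range(x.shape[1]):
        vals = x[:, c, :, :]
        mu = vals.mean()
        var = ((vals - mu) ** 2).mean()
        out[:, c, :, :] = gamma[c] * (vals - mu) / np.sqrt(var + eps) + beta[c]
    return out


def o_layernorm(x, gamma, beta, eps=1e-5):
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    for nrow in range(x.shape[0]):
        row = x[nrow]
        mu = row.mean()
        var = ((row - mu) ** 2).mean()
        out[nrow] = gamma * (row - mu) / np.sqrt(var + eps) + beta
    return out


def o_avg_pool(x, r):
    x = np.asarray(x, dtype=np.float64)
    n, c, h, w = x.shape
    out = np.zeros((n, c, h // r, w // r))
    for ni in range(n):
        for ci in range(c):
            for i in range(h // r):
                for j in range(w // r):
                    out[ni, ci, i, j] = x[ni, ci, i * r:(i + 1) * r,
                                          j * r:(j + 1) * r].mean()
    return out


def o_bilinear_resize(x, out_h, out_w):
    """Half-pixel-center bilinear interpolation with explicit weights."""
    x = np.asarray(x, dtype=np.float64)
    n, c, h, w = x.shape
    out = np.zeros((n, c, out_h, out_w))
    for i in range(out_h):
        sy = min(max((i + 0.5) * h / out_h - 0.5, 0.0), h - 1.0)
        y0 = int(np.floor(sy))
        y1 = min(y0 + 1, h - 1)
        ty = sy - y0
        for j in range(out_w):
            sx = min(max((j + 0.5) * w / out_w - 0.5, 0.0), w - 1.0)
            x0 = int(np.floor(sx))
            x1 = min(x0 + 1, w - 1)
            tx = sx - x0
            out[:, :, i, j] = ((1 - ty) * (1 - tx) * x[:, :, y0, x0]
                               + (1 - ty) * tx * x[:, :, y0, x1]
                               + ty * (1 - tx) * x[:, :, y1, x0]
                               + ty * tx * x[:, :, y1, x1])
    return out


# ---------------------------------------------------------------------------
# whole-block compositions, reading weights off the built blocks
# ---------------------------------------------------------------------------

def _o_unit(module, x):
    """Apply a ConvBNReLU or DWSeparableConvBNReLU via the loop primitives."""
    name = type(module).__name__
    if name == "DWSeparableConvBNReLU":
        y = o_depthwise_conv2d(x, module.depthwise.weight.data,
                               None if module.depthwise.bias is None
                               else module.depthwise.bias.data,
                               pad=module.depthwise.padding)
        y = o_conv2d(y, module.pointwise.weight.data,
                     None if module.pointwise.bias is None
                     else module.pointwise.bias.data,
                     pad=module.pointwise.padding)
    elif name == "ConvBNReLU":
        y = o_conv2d(x, module.conv.weight.data,
                     None if module.conv.bias is None else module.conv.bias.data,
                     pad=module.conv.padding, dilation=module.conv.dilation)
    else:  # pragma: no cover - guard against silent contract drift
        raise TypeError(f"unexpected unit {name}")
    return o_relu(o_batchnorm(y, module.bn.gamma.data, module.bn.beta.data,
                              module.bn.eps))


def o_ecc_calibrate(block, x2):
    r = block.config.calibration_rate
    down = o_avg_pool(x2, r)
    refined = _o_unit(block.calibration, down)
    up = o_bilinear_resize(refined, x2.shape[2], x2.shape[3])
    return o_sigmoid(np.asarray(x2, dtype=np.float64) + up)


def o_ecc_forward(block, x):
    x = np.asarray(x, dtype=np.float64)
    half = block.config.in_channels // 2
    s = o_conv2d(x, block.split.weight.data,
                 None if block.split.bias is None else block.split.bias.data,
                 pad=0)
    x1, x2 = s[:, :half], s[:, half:]
    x1p = _o_unit(block.identity_branch, x1)
    x2p = _o_unit(block.feature, x2)
    att = o_ecc_calibrate(block, x2)
    fused = _o_unit(block.fuse, att * x2p)
    return x + np.concatenate([x1p, fused], axis=1)


def o_pcf_forward(block, x):
    x = np.asarray(x, dtype=np.float64)
    compressed = _o_unit(block.compress, x)
    xl = _o_unit(block.local, compressed)
    xs = _o_unit(block.surround, compressed)
    xprime = np.concatenate([xl, xs], axis=1)
    n, c, h, w = xprime.shape

    logits = o_conv2d(xprime, block.attn_logit.weight.data,
                      block.attn_logit.bias.data, pad=0)[:, 0]
    out = np.empty_like(x)
    for ni in range(n):
        # softmax over all positions, then attention pooling by double loop
        z = logits[ni] - logits[ni].max()
        expz = np.exp(z)
        beta = expz / expz.sum()
        pooled = np.zeros(c)
        for i in range(h):
            for j in range(w):
                pooled += beta[i, j] * xprime[ni, :, i, j]
        # bottleneck transform as plain matrix arithmetic
        hvec = pooled @ np.asarray(block.s2.weight.data, dtype=np.float64)
        hvec = hvec + block.s2.bias.data
        mu, var = hvec.mean(), ((hvec - hvec.mean()) ** 2).mean()
        hvec = (block.ln.gamma.data * (hvec - mu) / np.sqrt(var + block.ln.eps)
                + block.ln.beta.data)
        hvec = np.maximum(hvec, 0.0)
        ctx = hvec @ np.asarray(block.s3.weight.data, dtype=np.float64)
        ctx = ctx + block.s3.bias.data
        out[ni] = x[ni] + xprime[ni] + ctx[:, None, None]
    return out


def o_se_gate(block, g_vec):
    g = np.asarray(g_vec, dtype=np.float64)
    h = g @ np.asarray(block.fc1.weight.data, dtype=np.float64) + block.fc1.bias.data
    h = np.maximum(h, 0.0)
    return o_sigmoid(h @ np.asarray(block.fc2.weight.data, dtype=np.float64)
                     + block.fc2.bias.data)


def o_gap(x):
    """Global average pooling by explicit double loop."""
    x = np.asarray(x, dtype=np.float64)
    n, c, h, w = x.shape
    out = np.zeros((n, c))
    for ni in range(n):
        for ci in range(c):
            acc = 0.0
            for i in range(h):
                for j in range(w):
                    acc += x[ni, ci, i, j]
            out[ni, ci] = acc / (h * w)
    return out


def o_mpa_forward(block, levels):
    levels = [np.asarray(l, dtype=np.float64) for l in levels]
    h0, w0 = levels[0].shape[2:]
    aligned = [l if l.shape[2:] == (h0, w0) else o_bilinear_resize(l, h0, w0)
               for l in levels]
    fused = _o_unit(block.project, np.concatenate(aligned, axis=1))
    gate = o_se_gate(block, o_gap(fused))
    return fused * gate[:, :, None, None]
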