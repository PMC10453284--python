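"""Independent brute-force reference implementations used only by tests.

Everything here is written with plain nested loops over pixels/channels so
it shares no code path with the package's vectorised blocks.
"""

import numpy as np


def conv_naive(x, w, b=None, groups=1):
    """Loop-based same-padding stride-1 convolution; x (C,H,W), w (O,Cg,k,k)."""
    cin, h, wd = x.shape
    cout, cin_g, kh, kw = w.shape
    cout_g = cout // groups
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw)))
    out = np.zeros((cout, h, wd))
    for o in range(cout):
        g = o // cout_g
        for i in range(h):
            for j in range(wd):
                acc = 0.0
                for c in range(cin_g):
                    for a in range(kh):
                        for bb in range(kw):
                            acc += (w[o, c, a, bb]
                                    * xp[g * cin_g + c, i + a, j + bb])
                out[o, i, j] = acc
        if b is not None:
            out[o] += b[o]
    return out


def bn_eval_naive(x, gamma, beta, mean, var, eps=1e-5):
    out = np.zeros_like(x)
    for c in range(x.shape[0]):
        out[c] = (x[c] - mean[c]) / np.sqrt(var[c] + eps) * gamma[c] + beta[c]
    return out


def conv_bn_relu_naive(x, layer):
    """Evaluate a ConvBNReLU layer (in eval mode) with loops."""
    y = conv_naive(x, layer.conv.weight.data.astype(np.float64),
                   None if layer.conv.bias is None else layer.conv.bias.data,
                   groups=layer.conv.groups)
    y = bn_eval_naive(y, layer.bn.gamma.data, layer.bn.beta.data,
                      layer.bn.running_mean, layer.bn.running_var,
                      eps=layer.bn.eps)
    return np.maximum(y, 0.0)


def res2net_block_naive(block, x):
    """Step-by-step split/concat/conv re-implementation of a Res2NetBlock."""
    u = conv_bn_relu_naive(x, block.conv_in)
    s, c = block.n_subsets, block.sub_ch
    subsets = [u[i * c:(i + 1) * c] for i in range(s)]
    ys = [subsets[0]]
    for i in range(1, s):
        inp = np.concatenate([subsets[i], ys[-1]], axis=0)
        ys.append(conv_bn_relu_naive(inp, block.fs[i - 1]))
    merged = np.concatenate(ys, axis=0)
    out = conv_naive(merged, block.conv_out.weight.data.astype(np.float64),
                     block.conv_out.bias.data)
    out = bn_eval_naive(out, block.bn_out.gamma.data, block.bn_out.beta.data,
                        block.bn_out.running_mean, block.bn_out.running_var,
                        eps=block.bn_out.eps)
    if block.shortcut is not None:
        res = conv_naive(x, block.shortcut.weight.data.astype(np.float64),
                         block.shortcut.bias.data)
    else:
        res = x
    return np.maximum(out + res, 0.0)


def cot_block_naive(block, x):
    """Quadruple-nested-loop re-implementation of a CotBlock (eval mode)."""
    cfg = block.cfg
    c, g, ka = cfg.channels, cfg.groups, cfg.attn_kernel
    cpg = c // g
    feats = conv_bn_relu_naive(x, block.conv_in)
    ks = conv_naive(feats, block.key_conv.weight.data.astype(np.float64),
                    block.key_conv.bias.data, groups=g)
    v = conv_naive(feats, block.w_v.weight.data.astype(np.float64),
                   block.w_v.bias.data)
    concat = np.concatenate([ks, feats], axis=0)
    hidden = np.maximum(
        conv_naive(concat, block.w_theta.weight.data.astype(np.float64),
                   block.w_theta.bias.data), 0.0)
    logits = conv_naive(hidden, block.w_delta.weight.data.astype(np.float64),
                        block.w_delta.bias.data)  # (g*ka*ka, H, W)
    _, h, wd = x.shape
    pad = ka // 2
    out = ks.copy()
    for gi in range(g):
        for ci in range(cpg):
            ch = gi * cpg + ci
            for i in range(h):
                for j in range(wd):
                    # softmax over the ka*ka local offsets for this group/pixel
                    raw = np.array([logits[gi * ka * ka + o, i, j]
                                    for o in range(ka * ka)])
                    e = np.exp(raw - raw.max())
                    wts = e / e.sum()
                    acc = 0.0
                    for o, (dy, dx) in enumerate(
                            (dy, dx) for dy in range(ka) for dx in range(ka)):
                        yy, xx = i + dy - pad, j + dx - pad
                        if 0 <= yy < h and 0 <= xx < wd:  # zero padding
                            acc += wts[o] * v[ch, yy, xx]
                    out[ch, i, j] += acc
    return out


def confusion_naive(pred_binary, gt_binary):
    """Pixel-by-pixel tally loop."""
    tp = tn = fp = fn = 0
    for p, g in zip(np.asarray(pred_binary).ravel(),
                    np.asarray(gt_binary).ravel()):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn
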