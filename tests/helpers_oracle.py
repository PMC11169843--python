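"""Independent reference implementations used as test oracles.

Two deliberately different routes are provided, both written with explicit
scalar loops so they share no code with the vectorised engine:

* ``scalar_forward`` / ``scalar_grads`` — a literal, loop-based expansion of
  the layered chain rule for spiking networks: spike-pathway gradients are
  accumulated over the next layer's fan-out and the next timestep, folded
  onto the shared membrane through the rectangular surrogate, and turned
  into weight/threshold gradients exactly as the update equations are
  written (both the default "variant" temporal form and full standard STBP).
* ``TapeVar`` — a minimal scalar reverse-mode autodiff tape in which each
  spike node carries the surrogate derivative w.r.t. its membrane and
  threshold.  Running the whole forward computation on the tape and
  reversing it yields reference gradients with no hand-derived recursion at
  all; this independently pins down the standard-STBP mode (and any mode at
  a single timestep, where the temporal forms coincide).

Both operate on the package's parsed ``ArchSpec``/``NetworkParams`` so the
same tiny networks can be fed to the engine and to the oracles.
"""

from __future__ import annotations

import math

import numpy as np


def _h(u: float) -> float:
    """Rectangular surrogate window, strict inequality at the boundary."""
    return 1.0 if abs(u - 1.0) < 0.5 else 0.0


# ---------------------------------------------------------------------------
# scalar loop-based forward
# ---------------------------------------------------------------------------

def _conv_scalar(x, w):
    """Same-padding stride-1 correlation with quadruple loops.

    x: (C, H, W) nested lists/arrays; w: (M, C, k, k).  Returns (M, H, W).
    """
    m = len(w)
    c = len(w[0])
    k = len(w[0][0])
    p = k // 2
    hgt = len(x[0])
    wid = len(x[0][0])
    out = [[[0.0] * wid for _ in range(hgt)] for _ in range(m)]
    for om in range(m):
        for y in range(hgt):
            for xx in range(wid):
                acc = 0.0
                for ic in range(c):
                    for a in range(k):
                        for b in range(k):
                            yy, xc = y + a - p, xx + b - p
                            if 0 <= yy < hgt and 0 <= xc < wid:
                                acc += w[om][ic][a][b] * x[ic][yy][xc]
                out[om][y][xx] = acc
    return out


def _flatten(x):
    if isinstance(x[0], (int, float)):
        return list(x)
    out = []
    for sub in x:
        out.extend(_flatten(sub))
    return out


def scalar_forward(arch, params, images, timesteps):
    """Loop-based forward pass for one small batch; no dropout.

    ``images``: (B, H, W) array for single-channel input, or (B, C, H, W).
    Returns a record dict with per-layer, per-timestep currents ``i``,
    membranes ``v``, pathway spikes ``s`` and emitted outputs ``x``, plus
    the final output membranes ``out`` (B, classes).
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[:, None]
    bsz = images.shape[0]
    leak = params.leak
    nl = len(arch.layers)
    rec = {
        "v": [[[None] * timesteps for _ in range(nl)] for _ in range(bsz)],
        "s": [[[None] * timesteps for _ in range(nl)] for _ in range(bsz)],
        "x": [[[None] * timesteps for _ in range(nl)] for _ in range(bsz)],
        "xin": [[[None] * timesteps for _ in range(nl)] for _ in range(bsz)],
    }
    out = np.zeros((bsz, arch.layers[-1].size))
    for b in range(bsz):
        v_state = [None] * nl
        s0_state = [None] * nl
        for t in range(timesteps):
            x = [[[float(images[b, ci, y, xx]) for xx in range(images.shape[3])]
                  for y in range(images.shape[2])] for ci in range(images.shape[1])]
            for li, layer in enumerate(arch.layers):
                rec["xin"][b][li][t] = x
                if layer.kind == "pool":
                    s = layer.size
                    c = len(x)
                    nh, nw = len(x[0]) // s, len(x[0][0]) // s
                    pooled = [[[0.0] * nw for _ in range(nh)] for _ in range(c)]
                    for ci in range(c):
                        for y in range(nh):
                            for xx in range(nw):
                                acc = 0.0
                                for dy in range(s):
                                    for dx in range(s):
                                        acc += x[ci][y * s + dy][xx * s + dx]
                                pooled[ci][y][xx] = acc / (s * s)
                    x = pooled
                    rec["x"][b][li][t] = x
                    continue
                w = params.weights[li]
                if layer.kind in ("conv", "dtc"):
                    cur = _conv_scalar(x, w.tolist())
                    m = layer.size
                    hgt, wid = len(cur[0]), len(cur[0][0])
                    if v_state[li] is None:
                        v_state[li] = [[[0.0] * wid for _ in range(hgt)] for _ in range(m)]
                        s0_state[li] = [[[0.0] * wid for _ in range(hgt)] for _ in range(m)]
                    th = params.thresholds[li]
                    vmap = [[[0.0] * wid for _ in range(hgt)] for _ in range(m)]
                    smaps = [[[[0.0] * wid for _ in range(hgt)] for _ in range(m)]
                             for _ in range(len(th))]
                    for om in range(m):
                        for y in range(hgt):
                            for xx in range(wid):
                                vv = (leak * v_state[li][om][y][xx]
                                      * (1.0 - s0_state[li][om][y][xx])
                                      + cur[om][y][xx])
                                vmap[om][y][xx] = vv
                                for kth in range(len(th)):
                                    smaps[kth][om][y][xx] = 1.0 if vv >= th[kth] else 0.0
                    v_state[li] = vmap
                    s0_state[li] = smaps[0]
                    rec["v"][b][li][t] = vmap
                    rec["s"][b][li][t] = smaps
                    x = [row for smap in smaps for row in smap]  # concat pathways
                    rec["x"][b][li][t] = x
                else:  # fc / fc_out
                    flat = _flatten(x)
                    n_out = layer.size
                    cur = [sum(w[j][i] * flat[i] for i in range(len(flat)))
                           for j in range(n_out)]
                    if v_state[li] is None:
                        v_state[li] = [0.0] * n_out
                        s0_state[li] = [0.0] * n_out
                    if layer.kind == "fc_out":
                        vvec = [leak * v_state[li][j] + cur[j] for j in range(n_out)]
                        v_state[li] = vvec
                        rec["v"][b][li][t] = vvec
                        x = vvec
                        rec["x"][b][li][t] = x
                    else:
                        th = params.thresholds[li]
                        vvec = [leak * v_state[li][j] * (1.0 - s0_state[li][j]) + cur[j]
                                for j in range(n_out)]
                        svec = [[1.0 if vv >= th[kth] else 0.0 for vv in vvec]
                                for kth in range(len(th))]
                        v_state[li] = vvec
                        s0_state[li] = svec[0]
                        rec["v"][b][li][t] = vvec
                        rec["s"][b][li][t] = svec
                        x = svec[0]
                        rec["x"][b][li][t] = x
        out[b] = v_state[nl - 1]
    rec["out"] = out
    return rec


# ---------------------------------------------------------------------------
# scalar literal chain-rule gradients
# ---------------------------------------------------------------------------

def _softmax_grad(out, labels):
    out = np.asarray(out, dtype=float)
    b = out.shape[0]
    z = out - out.max(axis=1, keepdims=True)
    p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    loss = float(-np.mean(np.log(p[np.arange(b), labels])))
    g = p.copy()
    g[np.arange(b), labels] -= 1.0
    return loss, g / b


def scalar_grads(arch, params, images, labels, timesteps, standard=False):
    """Literal chain-rule expansion: weight and threshold gradients.

    Implements the spike/membrane gradient recursion with explicit loops:
    spatial pathway gradients summed over the next layer's fan-out plus the
    next-step temporal term, membranes receiving both pathways through the
    surrogate, thresholds through the ``-v/vth^2`` scaling term.  With
    ``standard=True`` the temporal recursion carries the direct
    membrane-to-membrane leak path instead of the spike-mediated form.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[:, None]
    bsz = images.shape[0]
    rec = scalar_forward(arch, params, images, timesteps)
    loss, g_out0 = _softmax_grad(rec["out"], labels)
    leak = params.leak
    nl = len(arch.layers)
    T = timesteps
    g_w = [None if params.weights[li] is None else np.zeros_like(params.weights[li])
           for li in range(nl)]
    g_th = [None if params.thresholds[li] is None
            else np.zeros_like(params.thresholds[li]) for li in range(nl)]

    for b in range(bsz):
        # grads w.r.t. the current layer's emitted output, nested lists per t
        g_stack = [None] * T
        for li in range(nl - 1, -1, -1):
            layer = arch.layers[li]
            if layer.kind == "pool":
                s = layer.size
                new_stack = []
                for t in range(T):
                    xin = rec["xin"][b][li][t]
                    c, hgt, wid = len(xin), len(xin[0]), len(xin[0][0])
                    g_in = [[[0.0] * wid for _ in range(hgt)] for _ in range(c)]
                    g_o = g_stack[t]
                    for ci in range(c):
                        for y in range(len(g_o[0])):
                            for xx in range(len(g_o[0][0])):
                                for dy in range(s):
                                    for dx in range(s):
                                        g_in[ci][y * s + dy][xx * s + dx] = (
                                            g_o[ci][y][xx] / (s * s)
                                        )
                    new_stack.append(g_in)
                g_stack = new_stack
                continue

            w = params.weights[li]
            if layer.kind == "fc_out":
                g_v = [None] * T
                g_v[T - 1] = [float(g_out0[b, j]) for j in range(layer.size)]
                for t in range(T - 2, -1, -1):
                    g_v[t] = [leak * g for g in g_v[t + 1]]
                new_stack = []
                for t in range(T):
                    flat_in = _flatten(rec["xin"][b][li][t])
                    for j in range(layer.size):
                        for i in range(len(flat_in)):
                            g_w[li][j, i] += g_v[t][j] * flat_in[i]
                    g_flat = [sum(g_v[t][j] * w[j][i] for j in range(layer.size))
                              for i in range(len(flat_in))]
                    new_stack.append(_unflatten_like(g_flat, rec["xin"][b][li][t]))
                g_stack = new_stack
                continue

            th = params.thresholds[li]
            n_path = len(th)
            # split spatial upstream into pathway blocks
            spatial = [None] * T
            for t in range(T):
                g_o = g_stack[t]
                if layer.kind in ("conv", "dtc"):
                    m = layer.size
                    spatial[t] = [g_o[kth * m:(kth + 1) * m] for kth in range(n_path)]
                else:
                    spatial[t] = [g_o]

            v_rec = rec["v"][b][li]
            s_rec = rec["s"][b][li]
            g_x = [None] * T
            g_v = [None] * T
            for t in range(T - 1, -1, -1):
                g_x[t] = [_map_like(spatial[t][kth], lambda g: g)
                          for kth in range(n_path)]
                if t < T - 1:
                    # temporal spike term: primary pathway only (reset gate)
                    def reset_term(idx):
                        vt = _get(v_rec[t], idx)
                        vt1 = _get(v_rec[t + 1], idx)
                        if standard:
                            return -leak * vt * _get(g_v[t + 1], idx)
                        return (-leak * vt * _get(g_x[t + 1][0], idx)
                                * _h(vt1 / th[0]) / th[0])
                    g_x[t][0] = _index_map(g_x[t][0], lambda g, idx: g + reset_term(idx))
                # membrane gradient
                def memb(idx):
                    vt = _get(v_rec[t], idx)
                    total = sum(
                        _get(g_x[t][kth], idx) * _h(vt / th[kth]) / th[kth]
                        for kth in range(n_path)
                    )
                    if t < T - 1:
                        s0t = _get(s_rec[t][0], idx)
                        if standard:
                            total += leak * (1.0 - s0t) * _get(g_v[t + 1], idx)
                        else:
                            vt1 = _get(v_rec[t + 1], idx)
                            total += leak * (1.0 - s0t) * sum(
                                _get(g_x[t + 1][kth], idx) * _h(vt1 / th[kth]) / th[kth]
                                for kth in range(n_path)
                            )
                    return total
                g_v[t] = _index_map(v_rec[t], lambda _val, idx: memb(idx))
                # threshold gradients
                for kth in range(n_path):
                    for idx in _indices(v_rec[t]):
                        vt = _get(v_rec[t], idx)
                        g_th[li][kth] += (
                            _get(g_x[t][kth], idx) * _h(vt / th[kth])
                            * (-vt / th[kth] ** 2)
                        )

            # weight gradients and input gradients
            new_stack = []
            for t in range(T):
                xin = rec["xin"][b][li][t]
                if layer.kind in ("conv", "dtc"):
                    k = layer.kernel
                    p = k // 2
                    c = len(xin)
                    hgt, wid = len(xin[0]), len(xin[0][0])
                    g_in = [[[0.0] * wid for _ in range(hgt)] for _ in range(c)]
                    for om in range(layer.size):
                        for y in range(hgt):
                            for xx in range(wid):
                                gv = g_v[t][om][y][xx]
                                if gv == 0.0:
                                    continue
                                for ic in range(c):
                                    for a in range(k):
                                        for bb in range(k):
                                            yy, xc = y + a - p, xx + bb - p
                                            if 0 <= yy < hgt and 0 <= xc < wid:
                                                g_w[li][om, ic, a, bb] += gv * xin[ic][yy][xc]
                                                g_in[ic][yy][xc] += gv * w[om][ic][a][bb]
                    new_stack.append(g_in)
                else:  # fc spiking
                    flat_in = _flatten(xin)
                    for j in range(layer.size):
                        for i in range(len(flat_in)):
                            g_w[li][j, i] += g_v[t][j] * flat_in[i]
                    g_flat = [sum(g_v[t][j] * w[j][i] for j in range(layer.size))
                              for i in range(len(flat_in))]
                    new_stack.append(_unflatten_like(g_flat, xin))
            g_stack = new_stack
    return loss, g_w, g_th


# nested-list helpers -------------------------------------------------------

def _indices(nested):
    if isinstance(nested, (int, float)):
        yield ()
        return
    for i, sub in enumerate(nested):
        if isinstance(sub, (int, float)):
            yield (i,)
        else:
            for rest in _indices(sub):
                yield (i,) + rest


def _get(nested, idx):
    for i in idx:
        nested = nested[i]
    return nested


def _set(nested, idx, value):
    for i in idx[:-1]:
        nested = nested[i]
    nested[idx[-1]] = value


def _map_like(nested, fn):
    if not isinstance(nested, list):
        return fn(nested)
    return [_map_like(sub, fn) for sub in nested]


def _index_map(nested, fn):
    out = _map_like(nested, lambda v: v)
    for idx in _indices(nested):
        _set(out, idx, fn(_get(nested, idx), idx))
    return out


def _unflatten_like(flat, template):
    it = iter(flat)

    def build(node):
        if isinstance(node, (int, float)):
            return next(it)
        return [build(sub) for sub in node]

    return build(template)


# ---------------------------------------------------------------------------
# scalar reverse-mode tape with surrogate spike derivatives
# ---------------------------------------------------------------------------

class TapeVar:
    """Scalar autodiff node: value plus (parent, local-derivative) edges."""

    __slots__ = ("value", "parents", "grad")

    def __init__(self, value, parents=()):
        self.value = float(value)
        self.parents = parents
        self.grad = 0.0

    def __add__(self, other):
        other = other if isinstance(other, TapeVar) else TapeVar(other)
        return TapeVar(self.value + other.value, ((self, 1.0), (other, 1.0)))

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, TapeVar) else TapeVar(other)
        return TapeVar(self.value * other.value,
                       ((self, other.value), (other, self.value)))

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        other = other if isinstance(other, TapeVar) else TapeVar(other)
        return self + (-other)

    def __rsub__(self, other):
        return TapeVar(other) + (-self)

    def exp(self):
        e = math.exp(self.value)
        return TapeVar(e, ((self, e),))

    def log(self):
        return TapeVar(math.log(self.value), ((self, 1.0 / self.value),))

    def recip(self):
        return TapeVar(1.0 / self.value, ((self, -1.0 / self.value**2),))


def tape_spike(v: TapeVar, vth: TapeVar) -> TapeVar:
    """Heaviside spike with surrogate partials.

    Value is the exact step ``[v >= vth]``; the backward edges carry
    ``h(u)/vth`` toward the membrane and ``-h(u) * v / vth^2`` toward the
    threshold, with ``u = v/vth``.
    """
    u = v.value / vth.value
    hu = _h(u)
    return TapeVar(
        1.0 if v.value >= vth.value else 0.0,
        ((v, hu / vth.value), (vth, -hu * v.value / vth.value**2)),
    )


def tape_backward(root: TapeVar) -> None:
    """Reverse accumulation from ``root`` (topological order via DFS)."""
    order = []
    seen = set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node.parents:
            stack.append((parent, False))
    root.grad = 1.0
    for node in reversed(order):
        for parent, local in node.parents:
            parent.grad += node.grad * local


def tape_grads(arch, params, images, labels, timesteps):
    """Full-network gradients from the scalar tape (standard STBP semantics).

    Returns ``(loss, weight_grads, threshold_grads)`` shaped like the
    parameters.  The reset term ``lam * v * (1 - s0)`` is differentiated
    exactly (with surrogate spike partials), so temporal credit flows along
    both the membrane leak path and the reset gate.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[:, None]
    bsz = images.shape[0]
    leak = params.leak
    nl = len(arch.layers)

    w_vars = []
    th_vars = []
    for li in range(nl):
        w = params.weights[li]
        w_vars.append(None if w is None else _map_like(w.tolist(), TapeVar))
        th = params.thresholds[li]
        th_vars.append(None if th is None else [TapeVar(x) for x in th])

    total_loss = TapeVar(0.0)
    for b in range(bsz):
        v_state = [None] * nl
        s0_state = [None] * nl
        out_vars = None
        for t in range(timesteps):
            x = [[[TapeVar(images[b, ci, y, xx]) for xx in range(images.shape[3])]
                  for y in range(images.shape[2])] for ci in range(images.shape[1])]
            for li, layer in enumerate(arch.layers):
                if layer.kind == "pool":
                    s = layer.size
                    c = len(x)
                    nh, nw = len(x[0]) // s, len(x[0][0]) // s
                    x = [[[sum((x[ci][y * s + dy][xx * s + dx]
                                for dy in range(s) for dx in range(s)),
                               TapeVar(0.0)) * (1.0 / (s * s))
                           for xx in range(nw)] for y in range(nh)]
                         for ci in range(c)]
                    continue
                wv = w_vars[li]
                if layer.kind in ("conv", "dtc"):
                    k = layer.kernel
                    p = k // 2
                    c = len(x)
                    hgt, wid = len(x[0]), len(x[0][0])
                    m = layer.size
                    if v_state[li] is None:
                        v_state[li] = [[[TapeVar(0.0)] * wid for _ in range(hgt)]
                                       for _ in range(m)]
                        s0_state[li] = [[[TapeVar(0.0)] * wid for _ in range(hgt)]
                                        for _ in range(m)]
                    th = th_vars[li]
                    new_v = [[[None] * wid for _ in range(hgt)] for _ in range(m)]
                    smaps = [[[[None] * wid for _ in range(hgt)] for _ in range(m)]
                             for _ in range(len(th))]
                    for om in range(m):
                        for y in range(hgt):
                            for xx in range(wid):
                                cur = TapeVar(0.0)
                                for ic in range(c):
                                    for a in range(k):
                                        for bb in range(k):
                                            yy, xc = y + a - p, xx + bb - p
                                            if 0 <= yy < hgt and 0 <= xc < wid:
                                                cur = cur + wv[om][ic][a][bb] * x[ic][yy][xc]
                                vv = (leak * v_state[li][om][y][xx]
                                      * (1.0 - s0_state[li][om][y][xx]) + cur)
                                new_v[om][y][xx] = vv
                                for kth in range(len(th)):
                                    smaps[kth][om][y][xx] = tape_spike(vv, th[kth])
                    v_state[li] = new_v
                    s0_state[li] = smaps[0]
                    x = [row for smap in smaps for row in smap]
                else:
                    flat = _flatten_vars(x)
                    n_out = layer.size
                    if v_state[li] is None:
                        v_state[li] = [TapeVar(0.0)] * n_out
                        s0_state[li] = [TapeVar(0.0)] * n_out
                    cur = [sum((wv[j][i] * flat[i] for i in range(len(flat))),
                               TapeVar(0.0)) for j in range(n_out)]
                    if layer.kind == "fc_out":
                        vvec = [leak * v_state[li][j] + cur[j] for j in range(n_out)]
                        v_state[li] = vvec
                        out_vars = vvec
                        x = vvec
                    else:
                        th = th_vars[li]
                        vvec = [leak * v_state[li][j] * (1.0 - s0_state[li][j]) + cur[j]
                                for j in range(n_out)]
                        svecs = [[tape_spike(vv, th[kth]) for vv in vvec]
                                 for kth in range(len(th))]
                        v_state[li] = vvec
                        s0_state[li] = svecs[0]
                        x = svecs[0]
        # softmax cross-entropy for this sample
        mx = max(v.value for v in out_vars)
        exps = [(v - mx).exp() for v in out_vars]
        denom = sum(exps[1:], exps[0])
        logp = (exps[labels[b]] * denom.recip()).log()
        total_loss = total_loss + (-logp)
    total_loss = total_loss * (1.0 / bsz)
    tape_backward(total_loss)

    g_w = []
    g_th = []
    for li in range(nl):
        wv = w_vars[li]
        if wv is None:
            g_w.append(None)
        else:
            g_w.append(np.array(_map_like(wv, lambda v: v.grad)))
        tv = th_vars[li]
        g_th.append(None if tv is None else np.array([v.grad for v in tv]))
    return total_loss.value, g_w, g_th


def _flatten_vars(x):
    if isinstance(x[0], TapeVar):
        return list(x)
    out = []
    for sub in x:
        out.extend(_flatten_vars(sub))
    return out


# ---------------------------------------------------------------------------
# brute-force synaptic-operation counter
# ---------------------------------------------------------------------------

def count_ops_bruteforce(layer) -> int:
    """Count synaptic events of one layer by enumerating them one by one.

    Walks every output position, membrane map, input channel and kernel tap
    of a same-padding stride-1 convolution (every input unit and output unit
    of a fully connected layer) and increments a counter per weight
    application, regardless of padding zeros — mirroring a dense hardware
    mapping of the weighted-sum computation.
    """
    n = 0
    if layer.kind in ("conv", "dtc"):
        c_in = layer.in_shape[0]
        _, ho, wo = layer.out_shape
        for _m in range(layer.size):
            for _y in range(ho):
                for _x in range(wo):
                    for _c in range(c_in):
                        for _a in range(layer.kernel):
                            for _b in range(layer.kernel):
                                n += 1
    elif layer.kind in ("fc", "fc_out"):
        n_in = int(np.prod(layer.in_shape))
        for _j in range(layer.size):
            for _i in range(n_in):
                n += 1
    return n
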