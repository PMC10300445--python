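"""Independent reverse-mode autodiff oracle for gradient checks.

A deliberately small tape-based engine, written without reference to the
package's hand-rolled backward pass.  It re-expresses the network forward
out of primitive ops (add/mul/matmul/exp/log/sum) plus a straight-through
spike op whose backward rule is the same exponential surrogate
exp(-2 (V - theta)^2), and lets reverse-mode accumulation produce the
gradients.  Agreement with snnwm.training.forward_backward is the primary
correctness check for the STBP implementation.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Var:
    """A tensor node on the tape."""

    def __init__(self, value, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.parents = parents
        self._backward = backward

    # -- primitive ops ----------------------------------------------------
    def __add__(self, other):
        other = as_var(other)
        out = Var(self.value + other.value, (self, other))

        def back():
            self.grad += _unbroadcast(out.grad, self.value.shape)
            other.grad += _unbroadcast(out.grad, other.value.shape)

        out._backward = back
        return out

    def __sub__(self, other):
        return self + (as_var(other) * -1.0)

    def __mul__(self, other):
        other = as_var(other)
        out = Var(self.value * other.value, (self, other))

        def back():
            self.grad += _unbroadcast(out.grad * other.value, self.value.shape)
            other.grad += _unbroadcast(out.grad * self.value, other.value.shape)

        out._backward = back
        return out

    __radd__ = __add__
    __rmul__ = __mul__

    def matmul(self, other):
        other = as_var(other)
        out = Var(self.value @ other.value, (self, other))

        def back():
            self.grad += out.grad @ other.value.T
            other.grad += self.value.T @ out.grad

        out._backward = back
        return out

    def exp(self):
        out = Var(np.exp(self.value), (self,))

        def back():
            self.grad += out.grad * out.value

        out._backward = back
        return out

    def log(self):
        out = Var(np.log(self.value), (self,))

        def back():
            self.grad += out.grad / self.value

        out._backward = back
        return out

    def sum(self, axis=None, keepdims=False):
        out = Var(self.value.sum(axis=axis, keepdims=keepdims), (self,))

        def back():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self.grad += np.broadcast_to(g, self.value.shape)

        out._backward = back
        return out

    # -- reverse sweep -----------------------------------------------------
    def backward(self):
        order: list[Var] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is not None:
                node._backward()


def as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(x)


def spike(v_mid: Var, theta: float, detach: bool = False) -> Var:
    """Hard threshold forward, exponential surrogate backward.

    Forward: H(V - theta) with H(0) = 1.  Backward: grad * exp(-2 (V-theta)^2),
    or nothing at all when ``detach`` (used for the detached-reset factor).
    """
    s = (v_mid.value >= theta).astype(np.float64)
    out = Var(s, (v_mid,))

    def back():
        if not detach:
            x = v_mid.value - theta
            v_mid.grad += out.grad * np.exp(-2.0 * x * x)

    out._backward = back
    return out


# ---------------------------------------------------------------------------
# Oracle network forward: mirrors the snnwm architecture from its NetworkSpec,
# step by step, entirely in tape ops.


def oracle_loss_and_grads(inputs: np.ndarray, labels: np.ndarray, net,
                          detach_reset: bool = False,
                          loss_kind: str = "cross_entropy"):
    """Full forward + reverse sweep on a (B, T, N) batch.

    Returns (loss_value, grads) in the same structure as
    snnwm.training.forward_backward.
    """
    inputs = np.asarray(inputs, dtype=np.float64)
    B, T, _ = inputs.shape

    layer_W1 = [Var(spec.kernel.W1) for spec in net.layers]
    layer_w2 = [[Var(w) for w in spec.kernel.w2] for spec in net.layers]
    head_W1 = Var(net.head.W1)
    w_time = [Var(w) for w in net.head.w_time]

    # per-timestep list of (B, N) Vars; inputs are constants
    S = [Var(inputs[:, t]) for t in range(T)]

    for li, spec in enumerate(net.layers):
        W1, w2 = layer_W1[li], layer_w2[li]
        delays = spec.kernel.delays
        P = [S[t].matmul(W1) for t in range(T)]
        Nj = spec.kernel.W1.shape[1]
        if spec.wm.mode in ("classic", "overlap"):
            I = []
            for t in range(T):
                acc = Var(np.zeros((B, Nj)))
                for k, d in enumerate(delays):
                    if t - d >= 0:
                        acc = acc + w2[k] * P[t - d]
                I.append(acc)
        elif spec.wm.mode == "segment":
            L = spec.wm.mem_len
            I = []
            for m in range(T // L):
                acc = Var(np.zeros((B, Nj)))
                for p in range(L):
                    acc = acc + w2[p] * P[m * L + p]
                I.extend([acc] * L)
        else:
            raise ValueError(spec.wm.mode)

        lif = spec.lif
        V = Var(np.full((B, Nj), lif.v_rest))
        out_spikes = []
        for t in range(T):
            V_mid = V * lif.leak + I[t]
            s = spike(V_mid, lif.theta)
            s_reset = spike(V_mid, lif.theta, detach=True) if detach_reset else s
            V = V_mid * (Var(np.ones((B, Nj))) - s_reset) + s_reset * lif.v_rest
            out_spikes.append(s)
        S = out_spikes

    # fusion readout
    C = net.head.W1.shape[1]
    logits = Var(np.zeros((B, C)))
    for t in range(T):
        logits = logits + w_time[t] * S[t].matmul(head_W1)

    onehot = np.zeros((B, C))
    onehot[np.arange(B), np.asarray(labels)] = 1.0
    if loss_kind == "cross_entropy":
        expz = logits.exp()
        logsumexp = expz.sum(axis=1, keepdims=True).log()
        loss = ((logits - logsumexp) * Var(onehot)).sum() * (-1.0 / B)
    else:
        diff = logits - Var(onehot)
        loss = (diff * diff).sum() * (1.0 / (B * C))
    loss.backward()

    grads = {
        "layers": [
            {"W1": layer_W1[li].grad,
             "w2": np.array([w.grad.item() for w in layer_w2[li]])}
            for li in range(len(net.layers))
        ],
        "head": {"W1": head_W1.grad,
                 "w_time": np.array([w.grad.item() for w in w_time])},
    }
    return float(loss.value), grads
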