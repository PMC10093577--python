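"""Numpy materialization of layer graphs: forward, backward, and Adam.

This backend turns a :class:`~disubnet.layer_graph.LayerGraph` into real
weight arrays and computes real convolutions, which makes it the independent
counterpart of the analytic engine: shapes and parameter counts observed here
come from allocated tensors, not from the counting formulas.

Scope: plain-numpy training at desk scale (small widths, thousands of
images).  Convolutions are evaluated through strided sliding-window views and
``einsum``; gradients are exact analytic backprop, not approximations.

Conventions: activations are ``float32`` arrays shaped ``(N, H, W, C)``
(channels last); dense activations are ``(N, features)``.
"""

from __future__ import annotations

import numpy as np

from .layer_graph import GraphError, LayerGraph, TensorShape, infer_shapes

__all__ = ["NumpyModel", "Adam", "softmax"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _same_pad(size: int, stride: int, eff_k: int) -> tuple[int, int]:
    out = -(-size // stride)
    total = max((out - 1) * stride + eff_k - size, 0)
    return total // 2, total - total // 2


def _window(x: np.ndarray, kh: int, kw: int, sh: int, sw: int, dil: int,
            pad: tuple[tuple[int, int], tuple[int, int]], fill: float = 0.0) -> np.ndarray:
    """(N, Ho, Wo, C, kh, kw) strided view of padded input."""
    (pt, pb), (pl, pr) = pad
    if pt or pb or pl or pr:
        x = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)), constant_values=fill)
    ekh, ekw = dil * (kh - 1) + 1, dil * (kw - 1) + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (ekh, ekw), axis=(1, 2))
    return win[:, ::sh, ::sw, :, ::dil, ::dil], x.shape


class _Node:
    """Runtime state for one graph node."""

    def __init__(self, spec, in_shape: TensorShape | None, out_shape: TensorShape):
        self.spec = spec
        self.in_shape = in_shape
        self.out_shape = out_shape
        self.params: dict[str, np.ndarray] = {}
        self.non_trainable: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.cache: dict = {}


class NumpyModel:
    """A trainable materialization of a layer graph.

    Weight initialization is He-uniform for conv/dense kernels, zeros for
    biases, ones/zeros for batch-norm scale/shift; all draws come from a
    generator seeded by ``seed`` so two models built from the same arguments
    are bit-identical.
    """

    def __init__(self, graph: LayerGraph, input_shape: TensorShape, seed: int = 0):
        self.graph = graph
        self.input_shape = input_shape
        self.shapes = infer_shapes(graph, input_shape)
        self.order = graph.topological_order()
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD15]))
        self.nodes: dict[str, _Node] = {}
        for name in self.order:
            spec = graph.nodes[name]
            in_shape = (self.shapes[spec.predecessors[0]] if len(spec.predecessors) == 1
                        else None)
            node = _Node(spec, in_shape, self.shapes[name])
            self._init_params(node, rng)
            self.nodes[name] = node

    # -- parameters --------------------------------------------------------

    def _init_params(self, node: _Node, rng: np.random.Generator) -> None:
        spec, x = node.spec, node.in_shape
        kh, kw = spec.kernel
        f = spec.filters_or_units

        def he(shape, fan_in):
            bound = np.sqrt(6.0 / max(fan_in, 1))
            return rng.uniform(-bound, bound, size=shape).astype(np.float32)

        if spec.kind == "conv2d":
            node.params["w"] = he((kh, kw, x.channels, f), kh * kw * x.channels)
        elif spec.kind == "depthwise_conv2d":
            node.params["w"] = he((kh, kw, x.channels), kh * kw)
        elif spec.kind == "pointwise_conv2d":
            node.params["w"] = he((x.channels, f), x.channels)
        elif spec.kind in ("dense", "softmax_output") and f > 0:
            node.params["w"] = he((x.size, f), x.size)
        elif spec.kind == "batchnorm":
            node.params["gamma"] = np.ones(x.channels, dtype=np.float32)
            node.params["beta"] = np.zeros(x.channels, dtype=np.float32)
            node.non_trainable["moving_mean"] = np.zeros(x.channels, dtype=np.float32)
            node.non_trainable["moving_var"] = np.ones(x.channels, dtype=np.float32)
        if spec.use_bias and spec.kind in ("conv2d", "pointwise_conv2d", "dense",
                                           "softmax_output") and "w" in node.params:
            node.params["b"] = np.zeros(f, dtype=np.float32)
        elif spec.use_bias and spec.kind == "depthwise_conv2d":
            node.params["b"] = np.zeros(x.channels, dtype=np.float32)

    def trainable_parameter_count(self) -> int:
        return sum(int(p.size) for n in self.nodes.values() for p in n.params.values())

    def non_trainable_parameter_count(self) -> int:
        return sum(int(p.size) for n in self.nodes.values()
                   for p in n.non_trainable.values())

    def parameters(self):
        for name in self.order:
            for key, arr in self.nodes[name].params.items():
                yield (name, key), arr

    # -- forward -----------------------------------------------------------

    def _activate(self, spec, z: np.ndarray) -> np.ndarray:
        if spec.activation_name == "relu":
            return np.maximum(z, 0)
        if spec.activation_name == "leaky_relu":
            return np.maximum(spec.negative_slope * z, z)
        return z

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Run the graph; returns the softmax class probabilities (N, C)."""
        if x.ndim != 4:
            raise GraphError("expected input of shape (N, H, W, C)")
        acts: dict[str, np.ndarray] = {}
        for name in self.order:
            node = self.nodes[name]
            spec = node.spec
            node.cache.clear()
            if spec.kind == "input":
                acts[name] = np.asarray(x, dtype=np.float32)
                continue
            ins = [acts[p] for p in spec.predecessors]
            acts[name] = self._forward_node(node, ins, training, rng)
        return acts[self.graph.output_node]

    def _forward_node(self, node: _Node, ins, training: bool, rng) -> np.ndarray:
        spec = node.spec
        kh, kw = spec.kernel
        sh, sw = spec.stride
        if spec.kind in ("conv2d", "depthwise_conv2d"):
            (x,) = ins
            dil = spec.dilation
            ekh, ekw = dil * (kh - 1) + 1, dil * (kw - 1) + 1
            if spec.padding == "same":
                pad = (_same_pad(x.shape[1], sh, ekh), _same_pad(x.shape[2], sw, ekw))
            else:
                pad = ((0, 0), (0, 0))
            win, padded_shape = _window(x, kh, kw, sh, sw, dil, pad)
            if spec.kind == "conv2d":
                z = np.einsum("nhwcij,ijcf->nhwf", win, node.params["w"], optimize=True)
            else:
                z = np.einsum("nhwcij,ijc->nhwc", win, node.params["w"], optimize=True)
            if "b" in node.params:
                z = z + node.params["b"]
            node.cache.update(win=win, pad=pad, padded_shape=padded_shape,
                              x_shape=x.shape, z=z)
            return self._activate(spec, z)
        if spec.kind == "pointwise_conv2d":
            (x,) = ins
            z = x @ node.params["w"]
            if "b" in node.params:
                z = z + node.params["b"]
            node.cache.update(x=x, z=z)
            return self._activate(spec, z)
        if spec.kind in ("dense", "softmax_output"):
            (x,) = ins
            x2 = x.reshape(x.shape[0], -1)
            if not node.params:
                return softmax(x2) if spec.kind == "softmax_output" else x2
            z = x2 @ node.params["w"] + node.params.get("b", 0.0)
            node.cache.update(x=x2, z=z)
            if spec.kind == "softmax_output":
                p = softmax(z)
                node.cache["p"] = p
                return p
            return self._activate(spec, z)
        if spec.kind in ("maxpool", "avgpool"):
            (x,) = ins
            if spec.padding == "same":
                pad = (_same_pad(x.shape[1], sh, kh), _same_pad(x.shape[2], sw, kw))
            else:
                pad = ((0, 0), (0, 0))
            fill = -np.inf if spec.kind == "maxpool" else 0.0
            win, padded_shape = _window(x, kh, kw, sh, sw, 1, pad, fill=fill)
            flat = win.reshape(win.shape[:4] + (kh * kw,))
            if spec.kind == "maxpool":
                idx = flat.argmax(axis=-1)
                out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
                node.cache.update(idx=idx)
            else:
                out = flat.mean(axis=-1)
            node.cache.update(pad=pad, padded_shape=padded_shape, x_shape=x.shape)
            return out
        if spec.kind == "batchnorm":
            (x,) = ins
            eps = 1e-3
            if training:
                mean = x.mean(axis=(0, 1, 2))
                var = x.var(axis=(0, 1, 2))
                momentum = 0.99
                nt = node.non_trainable
                nt["moving_mean"] = (momentum * nt["moving_mean"]
                                     + (1 - momentum) * mean).astype(np.float32)
                nt["moving_var"] = (momentum * nt["moving_var"]
                                    + (1 - momentum) * var).astype(np.float32)
            else:
                mean = node.non_trainable["moving_mean"]
                var = node.non_trainable["moving_var"]
            inv = 1.0 / np.sqrt(var + eps)
            xhat = (x - mean) * inv
            node.cache.update(xhat=xhat, inv=inv, training=training)
            return node.params["gamma"] * xhat + node.params["beta"]
        if spec.kind == "activation":
            (x,) = ins
            node.cache["z"] = x
            return self._activate(spec, x)
        if spec.kind == "dropout":
            (x,) = ins
            rate = 0.5
            if training:
                gen = rng if rng is not None else np.random.default_rng(0)
                mask = (gen.random(x.shape) >= rate).astype(np.float32) / (1 - rate)
                node.cache["mask"] = mask
                return x * mask
            return x
        if spec.kind == "flatten":
            (x,) = ins
            node.cache["x_shape"] = x.shape
            return x.reshape(x.shape[0], -1)
        if spec.kind == "concat":
            node.cache["splits"] = np.cumsum([a.shape[-1] for a in ins[:-1]])
            return np.concatenate(ins, axis=-1)
        if spec.kind == "add":
            node.cache["n_in"] = len(ins)
            return sum(ins)
        raise GraphError(f"kind {spec.kind!r} not supported by the backend")

    # -- backward ----------------------------------------------------------

    def loss_and_gradients(self, x: np.ndarray, y_onehot: np.ndarray,
                           rng: np.random.Generator | None = None,
                           l2_lambda: float = 0.0) -> tuple[float, np.ndarray]:
        """Mean cross-entropy over the batch; fills every node's ``grads``.

        Returns ``(loss, probabilities)``.  Softmax and cross-entropy are
        fused, so the output-layer gradient is ``(p - y) / N``.
        """
        probs = self.forward(x, training=True, rng=rng)
        n = x.shape[0]
        clipped = np.clip(probs, 1e-12, 1.0)
        loss = float(-(y_onehot * np.log(clipped)).sum() / n)
        if l2_lambda:
            loss += l2_lambda * sum(
                float((w ** 2).sum()) for (name, key), w in self.parameters() if key == "w"
            )

        grad_out: dict[str, np.ndarray] = {
            self.graph.output_node: (probs - y_onehot).astype(np.float32) / n
        }
        for name in reversed(self.order):
            node = self.nodes[name]
            spec = node.spec
            if spec.kind == "input" or name not in grad_out:
                continue
            dy = grad_out.pop(name)
            dins = self._backward_node(node, dy)
            for p, d in zip(spec.predecessors, dins):
                if p in grad_out:
                    grad_out[p] = grad_out[p] + d
                else:
                    grad_out[p] = d
        if l2_lambda:
            for node in self.nodes.values():
                if "w" in node.grads:
                    node.grads["w"] = node.grads["w"] + 2 * l2_lambda * node.params["w"]
        return loss, probs

    def _dactivate(self, spec, z: np.ndarray, dy: np.ndarray) -> np.ndarray:
        if spec.activation_name == "relu":
            return dy * (z > 0)
        if spec.activation_name == "leaky_relu":
            return dy * np.where(z > 0, 1.0, spec.negative_slope).astype(np.float32)
        return dy

    def _backward_node(self, node: _Node, dy: np.ndarray) -> list[np.ndarray]:
        spec = node.spec
        kh, kw = spec.kernel
        sh, sw = spec.stride
        c = node.cache
        if spec.kind in ("conv2d", "depthwise_conv2d"):
            dz = self._dactivate(spec, c["z"], dy)
            win = c["win"]
            if spec.kind == "conv2d":
                node.grads["w"] = np.einsum("nhwcij,nhwf->ijcf", win, dz, optimize=True)
            else:
                node.grads["w"] = np.einsum("nhwcij,nhwc->ijc", win, dz, optimize=True)
            if "b" in node.params:
                node.grads["b"] = dz.sum(axis=(0, 1, 2))
            # scatter into the padded input, one kernel tap at a time
            dil = spec.dilation
            dxp = np.zeros(c["padded_shape"], dtype=np.float32)
            ho, wo = dz.shape[1], dz.shape[2]
            w = node.params["w"]
            for i in range(kh):
                for j in range(kw):
                    if spec.kind == "conv2d":
                        contrib = np.einsum("nhwf,cf->nhwc", dz, w[i, j], optimize=True)
                    else:
                        contrib = dz * w[i, j]
                    dxp[:, i * dil:i * dil + sh * ho:sh,
                        j * dil:j * dil + sw * wo:sw, :] += contrib
            (pt, pb), (pl, pr) = c["pad"]
            h, wdt = c["x_shape"][1], c["x_shape"][2]
            return [dxp[:, pt:pt + h, pl:pl + wdt, :]]
        if spec.kind == "pointwise_conv2d":
            dz = self._dactivate(spec, c["z"], dy)
            x = c["x"]
            node.grads["w"] = np.einsum("nhwc,nhwf->cf", x, dz, optimize=True)
            if "b" in node.params:
                node.grads["b"] = dz.sum(axis=(0, 1, 2))
            return [dz @ node.params["w"].T]
        if spec.kind in ("dense", "softmax_output"):
            if not node.params:
                raise GraphError("pure softmax backward must go through the fused loss")
            if spec.kind == "softmax_output":
                dz = dy  # fused softmax + cross-entropy gradient
            else:
                dz = self._dactivate(spec, c["z"], dy)
            x = c["x"]
            node.grads["w"] = x.T @ dz
            if "b" in node.params:
                node.grads["b"] = dz.sum(axis=0)
            dx = dz @ node.params["w"].T
            return [dx.reshape((x.shape[0],) + tuple(node.in_shape.as_tuple()))
                    if node.in_shape is not None and node.in_shape.height > 1
                    else dx]
        if spec.kind in ("maxpool", "avgpool"):
            dxp = np.zeros(c["padded_shape"], dtype=np.float32)
            ho, wo = dy.shape[1], dy.shape[2]
            for t in range(kh * kw):
                i, j = divmod(t, kw)
                if spec.kind == "maxpool":
                    contrib = dy * (c["idx"] == t)
                else:
                    contrib = dy / (kh * kw)
                dxp[:, i:i + sh * ho:sh, j:j + sw * wo:sw, :] += contrib
            (pt, pb), (pl, pr) = c["pad"]
            h, wdt = c["x_shape"][1], c["x_shape"][2]
            return [dxp[:, pt:pt + h, pl:pl + wdt, :]]
        if spec.kind == "batchnorm":
            xhat, inv = c["xhat"], c["inv"]
            gamma = node.params["gamma"]
            node.grads["gamma"] = (dy * xhat).sum(axis=(0, 1, 2))
            node.grads["beta"] = dy.sum(axis=(0, 1, 2))
            if not c["training"]:
                return [dy * gamma * inv]
            m = dy.shape[0] * dy.shape[1] * dy.shape[2]
            dxhat = dy * gamma
            dx = (inv / m) * (m * dxhat - dxhat.sum(axis=(0, 1, 2))
                              - xhat * (dxhat * xhat).sum(axis=(0, 1, 2)))
            return [dx.astype(np.float32)]
        if spec.kind == "activation":
            return [self._dactivate(spec, c["z"], dy)]
        if spec.kind == "dropout":
            return [dy * c["mask"]] if "mask" in c else [dy]
        if spec.kind == "flatten":
            return [dy.reshape(c["x_shape"])]
        if spec.kind == "concat":
            return list(np.split(dy, c["splits"], axis=-1))
        if spec.kind == "add":
            return [dy] * c["n_in"]
        raise GraphError(f"kind {spec.kind!r} not supported by the backend")

    def activation_shapes(self, x: np.ndarray) -> dict[str, tuple[int, ...]]:
        """Observed per-node output shapes (without the batch axis) from a real
        forward pass; the empirical counterpart of analytic shape inference."""
        acts: dict[str, np.ndarray] = {}
        for name in self.order:
            node = self.nodes[name]
            if node.spec.kind == "input":
                acts[name] = np.asarray(x, dtype=np.float32)
            else:
                acts[name] = self._forward_node(
                    node, [acts[p] for p in node.spec.predecessors], False, None)
        return {name: a.shape[1:] for name, a in acts.items()}

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Argmax class indices; numpy argmax breaks ties toward the lowest index."""
        out = []
        for start in range(0, x.shape[0], batch_size):
            probs = self.forward(x[start:start + batch_size], training=False)
            out.append(probs.argmax(axis=1))
        return np.concatenate(out)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return np.concatenate([
            self.forward(x[s:s + batch_size], training=False)
            for s in range(0, x.shape[0], batch_size)
        ])


class Adam:
    """Adam with the canonical moment defaults (beta1 0.9, beta2 0.999, eps 1e-7)."""

    def __init__(self, model: NumpyModel, learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.model = model
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in model.parameters()}
        self.v = {k: np.zeros_like(v) for k, v in model.parameters()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for name in self.model.order:
            node = self.model.nodes[name]
            for key, g in node.grads.items():
                k = (name, key)
                self.m[k] = b1 * self.m[k] + (1 - b1) * g
                self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
                node.params[key] = (node.params[key]
                                    - lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)
                                    ).astype(np.float32)
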