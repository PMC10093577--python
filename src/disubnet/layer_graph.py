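"""Framework-independent layer graphs with shape inference and parameter accounting.

A convolutional network is represented as a directed acyclic graph of
:class:`LayerSpec` nodes.  The graph is the single source of truth for every
architecture in this package: the analytic engine below infers output shapes
and trainable/non-trainable parameter counts without ever allocating a weight
tensor, and :mod:`disubnet.backend` materializes the same graph for training.

Conventions (declared once, obeyed everywhere):

* channels-last shapes ``(height, width, channels)``;
* flatten uses row-major (C) order;
* "same" padding produces ``ceil(in / stride)`` spatial output;
* "valid" padding produces ``floor((in - effective_kernel) / stride) + 1``
  with ``effective_kernel = dilation * (k - 1) + 1``;
* a kernel larger than its input under valid padding is a hard error.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import yaml

__all__ = [
    "TensorShape",
    "LayerSpec",
    "LayerGraph",
    "ParamReport",
    "GraphError",
    "LAYER_KINDS",
    "PARAMETRIC_KINDS",
    "infer_shapes",
    "count_parameters",
    "validate_graph",
    "graph_to_yaml",
    "graph_from_yaml",
    "param_report_to_csv",
    "param_report_table",
]

LAYER_KINDS = frozenset(
    {
        "input",
        "conv2d",
        "depthwise_conv2d",
        "pointwise_conv2d",
        "dense",
        "maxpool",
        "avgpool",
        "batchnorm",
        "activation",
        "dropout",
        "flatten",
        "concat",
        "add",
        "softmax_output",
    }
)

#: kinds that own weights; everything else contributes zero parameters
PARAMETRIC_KINDS = frozenset(
    {"conv2d", "depthwise_conv2d", "pointwise_conv2d", "dense", "batchnorm"}
)

LEAKY_SLOPE = 0.1


class GraphError(ValueError):
    """Raised for invalid graphs or impossible shape inference."""


@dataclass(frozen=True)
class TensorShape:
    """A channels-last activation shape ``(height, width, channels)``."""

    height: int
    width: int
    channels: int

    def __post_init__(self) -> None:
        for name in ("height", "width", "channels"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise GraphError(f"TensorShape.{name} must be a positive integer, got {v!r}")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.height, self.width, self.channels)

    @property
    def size(self) -> int:
        return self.height * self.width * self.channels


@dataclass(frozen=True)
class LayerSpec:
    """One node of a layer graph.

    Only the fields relevant to ``kind`` are consulted; e.g. ``kernel`` is
    ignored for dense layers.  ``negative_slope`` is pinned to 0.1 whenever
    ``activation_name == "leaky_relu"``.
    """

    name: str
    kind: str
    kernel: tuple[int, int] = (1, 1)
    stride: tuple[int, int] = (1, 1)
    padding: str = "same"
    dilation: int = 1
    filters_or_units: int = 0
    use_bias: bool = True
    activation_name: str = "none"
    negative_slope: float = LEAKY_SLOPE
    predecessors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise GraphError(f"unknown layer kind {self.kind!r} (node {self.name!r})")
        object.__setattr__(self, "kernel", tuple(self.kernel))
        object.__setattr__(self, "stride", tuple(self.stride))
        object.__setattr__(self, "predecessors", tuple(self.predecessors))
        if self.kind == "pointwise_conv2d":
            if tuple(self.kernel) != (1, 1) or self.dilation != 1:
                raise GraphError(
                    f"pointwise_conv2d {self.name!r} must have kernel (1, 1) and dilation 1"
                )
        if self.dilation < 1:
            raise GraphError(f"dilation must be >= 1 (node {self.name!r})")
        if self.padding not in ("same", "valid"):
            raise GraphError(f"padding must be 'same' or 'valid' (node {self.name!r})")
        if self.activation_name not in ("relu", "leaky_relu", "none", "softmax"):
            raise GraphError(f"unknown activation {self.activation_name!r} ({self.name!r})")
        if self.activation_name == "leaky_relu":
            object.__setattr__(self, "negative_slope", LEAKY_SLOPE)


@dataclass
class LayerGraph:
    """A DAG of :class:`LayerSpec` nodes with one input and one softmax output."""

    nodes: dict[str, LayerSpec] = field(default_factory=dict)
    input_node: str = ""
    output_node: str = ""

    def add(self, spec: LayerSpec) -> str:
        if spec.name in self.nodes:
            raise GraphError(f"duplicate node name {spec.name!r}")
        self.nodes[spec.name] = spec
        if spec.kind == "input":
            self.input_node = spec.name
        if spec.kind == "softmax_output":
            self.output_node = spec.name
        return spec.name

    def topological_order(self) -> list[str]:
        """Kahn's algorithm over declared predecessors; deterministic by name."""
        indeg = {n: len(s.predecessors) for n, s in self.nodes.items()}
        succ: dict[str, list[str]] = {n: [] for n in self.nodes}
        for n, s in self.nodes.items():
            for p in s.predecessors:
                if p not in self.nodes:
                    raise GraphError(f"node {n!r} references unknown predecessor {p!r}")
                succ[p].append(n)
        ready = sorted(n for n, d in indeg.items() if d == 0)
        order: list[str] = []
        while ready:
            n = ready.pop(0)
            order.append(n)
            for m in sorted(succ[n]):
                indeg[m] -= 1
                if indeg[m] == 0:
                    ready.append(m)
            ready.sort()
        if len(order) != len(self.nodes):
            raise GraphError("graph contains a cycle")
        return order


@dataclass(frozen=True)
class ParamReport:
    """Per-node and total parameter counts for a graph at a fixed input shape."""

    per_node: Mapping[str, tuple[int, int]]
    total_trainable: int
    total_with_non_trainable: int

    def __post_init__(self) -> None:
        t = sum(v[0] for v in self.per_node.values())
        nt = sum(v[1] for v in self.per_node.values())
        if t != self.total_trainable or t + nt != self.total_with_non_trainable:
            raise GraphError("ParamReport totals do not match per-node sums")


# ---------------------------------------------------------------------------
# shape inference


def _spatial_out(size: int, k: int, stride: int, padding: str, dilation: int, node: str) -> int:
    eff = dilation * (k - 1) + 1
    if padding == "same":
        return math.ceil(size / stride)
    out = (size - eff) // stride + 1
    if out <= 0:
        raise GraphError(
            f"node {node!r}: effective kernel {eff} does not fit input extent {size} "
            f"under valid padding"
        )
    return out


def infer_shapes(graph: LayerGraph, input_shape: TensorShape) -> dict[str, TensorShape]:
    """Assign an output shape to every node.

    Raises :class:`GraphError` on spatial mismatch at a concat, non-positive
    output extents, or an unknown configuration.  The result is independent of
    node insertion order because propagation follows the topological order.
    """
    shapes: dict[str, TensorShape] = {}
    for name in graph.topological_order():
        spec = graph.nodes[name]
        if spec.kind == "input":
            shapes[name] = input_shape
            continue
        preds = [shapes[p] for p in spec.predecessors]
        if spec.kind == "concat":
            if len(preds) < 2:
                raise GraphError(f"concat {name!r} needs >= 2 predecessors")
            h, w = preds[0].height, preds[0].width
            for p, s in zip(spec.predecessors, preds):
                if (s.height, s.width) != (h, w):
                    raise GraphError(
                        f"concat {name!r}: spatial mismatch {s.as_tuple()} vs "
                        f"({h}, {w}, ...) from predecessor {p!r}"
                    )
            shapes[name] = TensorShape(h, w, sum(s.channels for s in preds))
            continue
        if spec.kind == "add":
            if len(preds) < 2:
                raise GraphError(f"add {name!r} needs >= 2 predecessors")
            first = preds[0]
            for p, s in zip(spec.predecessors, preds):
                if s != first:
                    raise GraphError(
                        f"add {name!r}: shape mismatch {s.as_tuple()} vs "
                        f"{first.as_tuple()} from predecessor {p!r}"
                    )
            shapes[name] = first
            continue
        if len(preds) != 1:
            raise GraphError(f"node {name!r} ({spec.kind}) must have exactly 1 predecessor")
        (x,) = preds
        if spec.kind in ("conv2d", "depthwise_conv2d", "pointwise_conv2d"):
            kh, kw = spec.kernel
            sh, sw = spec.stride
            h = _spatial_out(x.height, kh, sh, spec.padding, spec.dilation, name)
            w = _spatial_out(x.width, kw, sw, spec.padding, spec.dilation, name)
            c = x.channels if spec.kind == "depthwise_conv2d" else spec.filters_or_units
            shapes[name] = TensorShape(h, w, c)
        elif spec.kind in ("maxpool", "avgpool"):
            kh, kw = spec.kernel
            sh, sw = spec.stride
            h = _spatial_out(x.height, kh, sh, spec.padding, 1, name)
            w = _spatial_out(x.width, kw, sw, spec.padding, 1, name)
            shapes[name] = TensorShape(h, w, x.channels)
        elif spec.kind == "flatten":
            shapes[name] = TensorShape(1, 1, x.size)
        elif spec.kind in ("dense", "softmax_output"):
            if spec.kind == "softmax_output" and spec.filters_or_units == 0:
                shapes[name] = x  # pure activation over an already-sized input
                continue
            if (x.height, x.width) != (1, 1):
                raise GraphError(f"dense {name!r} expects a flattened input, got {x.as_tuple()}")
            shapes[name] = TensorShape(1, 1, spec.filters_or_units)
        elif spec.kind in ("batchnorm", "activation", "dropout"):
            shapes[name] = x
        else:  # pragma: no cover - kinds are closed above
            raise GraphError(f"unknown kind {spec.kind!r}")
    return shapes


# ---------------------------------------------------------------------------
# parameter accounting


def _node_params(spec: LayerSpec, cin: int, nin: int) -> tuple[int, int]:
    """(trainable, non_trainable) for one node given fan-in channels/features."""
    kh, kw = spec.kernel
    f = spec.filters_or_units
    b = 1 if spec.use_bias else 0
    if spec.kind == "conv2d":
        return kh * kw * cin * f + b * f, 0
    if spec.kind == "depthwise_conv2d":
        return kh * kw * cin + b * cin, 0
    if spec.kind == "pointwise_conv2d":
        return cin * f + b * f, 0
    if spec.kind in ("dense", "softmax_output"):
        return nin * f + b * f, 0
    if spec.kind == "batchnorm":
        # gamma/beta trainable; moving mean/variance tracked but not trained
        return 2 * cin, 2 * cin
    return 0, 0


def count_parameters(graph: LayerGraph, input_shape: TensorShape) -> ParamReport:
    """Analytic per-node and total parameter counts at ``input_shape``.

    Non-parametric kinds (pooling, activation, dropout, flatten, concat,
    input) contribute zero.  The grand total includes batch-norm moving
    statistics; ``total_trainable`` excludes them, so either reading of a
    printed "number of parameters" can be checked.
    """
    shapes = infer_shapes(graph, input_shape)
    per_node: dict[str, tuple[int, int]] = {}
    for name in graph.topological_order():
        spec = graph.nodes[name]
        if spec.kind == "input" or spec.kind not in PARAMETRIC_KINDS and spec.kind != "softmax_output":
            per_node[name] = (0, 0)
            continue
        if spec.kind == "softmax_output" and spec.filters_or_units == 0:
            per_node[name] = (0, 0)  # pure activation on an already-sized input
            continue
        (pred,) = spec.predecessors
        x = shapes[pred]
        per_node[name] = _node_params(spec, x.channels, x.size)
    total_t = sum(v[0] for v in per_node.values())
    total_nt = sum(v[1] for v in per_node.values())
    return ParamReport(per_node, total_t, total_t + total_nt)


# ---------------------------------------------------------------------------
# validation


def validate_graph(graph: LayerGraph) -> list[str]:
    """Return one diagnostic string per violated invariant (empty list = valid)."""
    diags: list[str] = []
    if not graph.nodes:
        return ["graph has no nodes"]

    inputs = [n for n, s in graph.nodes.items() if s.kind == "input"]
    outputs = [n for n, s in graph.nodes.items() if s.kind == "softmax_output"]
    if len(inputs) != 1:
        diags.append(f"graph must have exactly one input node, found {len(inputs)}")
    if len(outputs) != 1:
        diags.append(f"graph must have exactly one softmax_output node, found {len(outputs)}")

    for name, spec in graph.nodes.items():
        npred = len(spec.predecessors)
        if spec.kind == "input" and npred != 0:
            diags.append(f"node {name!r}: input nodes take no predecessors")
        elif spec.kind in ("concat", "add") and npred < 2:
            diags.append(f"node {name!r}: {spec.kind} needs >= 2 predecessors, has {npred}")
        elif spec.kind not in ("input", "concat", "add") and npred != 1:
            diags.append(f"node {name!r}: {spec.kind} needs exactly 1 predecessor, has {npred}")
        for p in spec.predecessors:
            if p not in graph.nodes:
                diags.append(f"node {name!r}: unknown predecessor {p!r}")

    # acyclicity + reachability
    try:
        order = graph.topological_order()
    except GraphError as e:
        diags.append(str(e))
        return diags

    if inputs:
        reach = {inputs[0]}
        for n in order:
            if any(p in reach for p in graph.nodes[n].predecessors):
                reach.add(n)
        for n in order:
            if n not in reach:
                diags.append(f"node {n!r} is not reachable from the input node")
        if outputs:
            # every node that feeds anything must lead to the output
            feeds_out = {outputs[0]}
            for n in reversed(order):
                succs = [m for m in order if n in graph.nodes[m].predecessors]
                if any(m in feeds_out for m in succs):
                    feeds_out.add(n)
            for n in order:
                if n in reach and n not in feeds_out:
                    diags.append(f"node {n!r} does not reach the output node (dangling)")
    return diags


# ---------------------------------------------------------------------------
# serialization


def graph_to_yaml(graph: LayerGraph) -> str:
    """Serialize the graph as a YAML node list (LayerSpec fields verbatim)."""
    doc = {
        "input_node": graph.input_node,
        "output_node": graph.output_node,
        "nodes": [
            {
                "name": s.name,
                "kind": s.kind,
                "kernel": list(s.kernel),
                "stride": list(s.stride),
                "padding": s.padding,
                "dilation": s.dilation,
                "filters_or_units": s.filters_or_units,
                "use_bias": s.use_bias,
                "activation_name": s.activation_name,
                "negative_slope": s.negative_slope,
                "predecessors": list(s.predecessors),
            }
            for s in (graph.nodes[n] for n in graph.topological_order())
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def graph_from_yaml(text: str) -> LayerGraph:
    doc = yaml.safe_load(text)
    g = LayerGraph()
    for nd in doc["nodes"]:
        nd = dict(nd)
        nd["kernel"] = tuple(nd.get("kernel", (1, 1)))
        nd["stride"] = tuple(nd.get("stride", (1, 1)))
        nd["predecessors"] = tuple(nd.get("predecessors", ()))
        g.add(LayerSpec(**nd))
    g.input_node = doc.get("input_node", g.input_node)
    g.output_node = doc.get("output_node", g.output_node)
    return g


def param_report_to_csv(graph: LayerGraph, report: ParamReport) -> str:
    """Columns: node, kind, trainable, non_trainable."""
    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(["node", "kind", "trainable", "non_trainable"])
    for name in graph.topological_order():
        t, nt = report.per_node[name]
        w.writerow([name, graph.nodes[name].kind, t, nt])
    return buf.getvalue()


def param_report_table(entries: Iterable[tuple[str, int, int | None]]) -> str:
    """Model-size comparison table: (model, achieved total, reference total or None)."""
    lines = [f"{'Model':<18}{'Number of Parameters':>22}{'Reference':>14}{'Match':>8}"]
    for model, achieved, ref in entries:
        ref_s = f"{ref:,}" if ref is not None else "-"
        flag = "" if ref is None else ("  yes" if achieved == ref else "  NO")
        lines.append(f"{model:<18}{achieved:>22,}{ref_s:>14}{flag:>8}")
    return "\n".join(lines)
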