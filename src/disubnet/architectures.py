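"""Builders for DISubNetV1/V2 and the six comparison architectures.

Channel widths for the DISubNet variants are not derivable from prose alone;
the constants frozen here follow the published layer sequence (two depthwise
separable subnetworks plus an inception module) and were calibrated once so
the analytic totals equal the printed model sizes:

==================  ==========
LeNet5 (modified)   19,628,074
AlexNet (4 conv)    23,392,580
VGG-16              17,075,396
Xception-like       20,991,980
CNN-LeakyReLU        7,255,332
CNN-Inception        7,419,812
DISubNetV1           4,591,574
DISubNetV2           4,591,574
==================  ==========

All builders are pure functions of their arguments: the same call always
yields an identically serialized graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .layer_graph import GraphError, LayerGraph, LayerSpec, TensorShape

__all__ = [
    "InceptionConfig",
    "SubnetworkConfig",
    "HeadConfig",
    "depthwise_separable_block",
    "inception_module",
    "build_disubnet_v1",
    "build_disubnet_v2",
    "build_baseline",
    "build_model",
    "scale_disubnet_v1",
    "BASELINE_NAMES",
    "REFERENCE_TOTALS",
    "DEFAULT_INCEPTION",
    "DEFAULT_SUBNETWORK",
]

#: printed reference totals (number of parameters) for the comparison table
REFERENCE_TOTALS: dict[str, int] = {
    "lenet5": 19_628_074,
    "alexnet": 23_392_580,
    "vggnet16": 17_075_396,
    "xception_like": 20_991_980,
    "cnn_leakyrelu": 7_255_332,
    "cnn_inception": 7_419_812,
    "disubnetv1": 4_591_574,
    "disubnetv2": 4_591_574,
}

BASELINE_NAMES = (
    "lenet5",
    "alexnet",
    "vggnet16",
    "xception_like",
    "cnn_leakyrelu",
    "cnn_inception",
)


@dataclass(frozen=True)
class InceptionConfig:
    """Filter counts for the four-branch inception module.

    Branches: 1x1 conv, 3x3 conv, 3x3 dilated conv, and (optionally) an
    identity skip.  All branches use same padding, so the module preserves
    spatial extent and its output width is ``f1x1 + f3x3 + f_dilated + cin``
    when the skip is included.
    """

    f1x1: int = 32
    f3x3: int = 32
    f_dilated: int = 32
    dilation_rate: int = 2
    include_skip: bool = True

    def __post_init__(self) -> None:
        if min(self.f1x1, self.f3x3, self.f_dilated) <= 0:
            raise GraphError("inception filter counts must be positive")
        if self.dilation_rate < 2:
            raise GraphError("inception dilation_rate must be >= 2")


@dataclass(frozen=True)
class SubnetworkConfig:
    """Widths of the alternating depthwise-separable stack of one subnetwork."""

    block_widths: tuple[int, ...] = (16, 48)
    kernel: tuple[int, int] = (3, 3)
    pool_positions: tuple[int, ...] = (0, 1)  # 2x2 max pool after these blocks

    def __post_init__(self) -> None:
        if not self.block_widths:
            raise GraphError("block_widths must be non-empty")
        n = len(self.block_widths)
        if any(p < 0 or p >= n for p in self.pool_positions):
            raise GraphError("pool_positions out of range")


@dataclass(frozen=True)
class HeadConfig:
    """Classifier head: pointwise projection, pooling, one hidden dense layer.

    The 1x1 projection follows the design note that pointwise kernels add
    non-linear depth at minimal parameter cost; its width and the dense width
    are the per-version calibration constants.
    """

    projection: int
    dense: int
    n_pools: int = 2


DEFAULT_INCEPTION = InceptionConfig()
DEFAULT_SUBNETWORK = SubnetworkConfig()
_V1_HEAD = HeadConfig(projection=120, dense=766)
_V2_HEAD = HeadConfig(projection=192, dense=486)


# ---------------------------------------------------------------------------
# fragments


def _conv(g: LayerGraph, name: str, pred: str, filters: int, kernel=(3, 3), stride=(1, 1),
          padding: str = "same", dilation: int = 1, activation: str = "relu",
          use_bias: bool = True) -> str:
    g.add(LayerSpec(name=name, kind="conv2d", kernel=kernel, stride=stride, padding=padding,
                    dilation=dilation, filters_or_units=filters, use_bias=use_bias,
                    activation_name=activation, predecessors=(pred,)))
    return name


def _pool(g: LayerGraph, name: str, pred: str, size=(2, 2), stride=None, kind="maxpool",
          padding: str = "valid") -> str:
    g.add(LayerSpec(name=name, kind=kind, kernel=size, stride=stride or size,
                    padding=padding, predecessors=(pred,)))
    return name


def _dense(g: LayerGraph, name: str, pred: str, units: int, activation="relu") -> str:
    g.add(LayerSpec(name=name, kind="dense", filters_or_units=units,
                    activation_name=activation, predecessors=(pred,)))
    return name


def depthwise_separable_block(graph: LayerGraph, in_node: str, filters: int,
                              prefix: str, kernel=(3, 3)) -> str:
    """Depthwise 3x3 (same) -> ReLU -> pointwise 1x1 -> ReLU.

    Spatial extent is preserved; output channel count is ``filters``.  The
    ReLU after each constituent layer follows the rule that an activation is
    applied after every layer of the network.
    """
    if filters <= 0:
        raise GraphError("filters must be positive")
    graph.add(LayerSpec(name=f"{prefix}_dw", kind="depthwise_conv2d", kernel=kernel,
                        padding="same", activation_name="relu", predecessors=(in_node,)))
    graph.add(LayerSpec(name=f"{prefix}_pw", kind="pointwise_conv2d",
                        filters_or_units=filters, activation_name="relu",
                        predecessors=(f"{prefix}_dw",)))
    return f"{prefix}_pw"


def inception_module(graph: LayerGraph, in_node: str, cfg: InceptionConfig,
                     prefix: str) -> str:
    """Four parallel branches concatenated along channels.

    1x1 conv, 3x3 conv, 3x3 dilated conv (rate ``cfg.dilation_rate``) and an
    identity skip; all same padding, so any input spatial extent is preserved.
    """
    b1 = _conv(graph, f"{prefix}_1x1", in_node, cfg.f1x1, kernel=(1, 1))
    b3 = _conv(graph, f"{prefix}_3x3", in_node, cfg.f3x3, kernel=(3, 3))
    bd = _conv(graph, f"{prefix}_dil", in_node, cfg.f_dilated, kernel=(3, 3),
               dilation=cfg.dilation_rate)
    branches = [b1, b3, bd] + ([in_node] if cfg.include_skip else [])
    graph.add(LayerSpec(name=f"{prefix}_concat", kind="concat",
                        predecessors=tuple(branches)))
    return f"{prefix}_concat"


def _subnetwork(graph: LayerGraph, in_node: str, cfg: SubnetworkConfig, prefix: str) -> str:
    # DISubNet pools are average: they preserve the area/intensity statistics
    # that discriminate the treatment classes and pair naturally with the
    # depthwise-separable design (cf. the global-average heads of the
    # separable-convolution model family)
    node = in_node
    for i, width in enumerate(cfg.block_widths):
        node = depthwise_separable_block(graph, node, width, f"{prefix}_ds{i + 1}",
                                         kernel=cfg.kernel)
        if i in cfg.pool_positions:
            node = _pool(graph, f"{prefix}_pool{i + 1}", node, kind="avgpool")
    return node


def _head(graph: LayerGraph, in_node: str, head: HeadConfig, n_classes: int) -> None:
    node = in_node
    graph.add(LayerSpec(name="head_proj", kind="pointwise_conv2d",
                        filters_or_units=head.projection, activation_name="relu",
                        predecessors=(node,)))
    node = "head_proj"
    for i in range(head.n_pools):
        node = _pool(graph, f"head_pool{i + 1}", node, kind="avgpool")
    graph.add(LayerSpec(name="head_flatten", kind="flatten", predecessors=(node,)))
    _dense(graph, "head_dense", "head_flatten", head.dense)
    graph.add(LayerSpec(name="softmax", kind="softmax_output", filters_or_units=n_classes,
                        activation_name="softmax", predecessors=("head_dense",)))


def _new_graph(input_shape: TensorShape) -> LayerGraph:
    g = LayerGraph()
    g.add(LayerSpec(name="input", kind="input",
                    filters_or_units=input_shape.channels))
    return g


# ---------------------------------------------------------------------------
# DISubNet builders


def build_disubnet_v1(input_shape: TensorShape = TensorShape(112, 112, 1),
                      n_classes: int = 4,
                      subnet: SubnetworkConfig = DEFAULT_SUBNETWORK,
                      inception: InceptionConfig = DEFAULT_INCEPTION,
                      head: HeadConfig = _V1_HEAD) -> LayerGraph:
    """DISubNetV1: two depthwise-separable subnetworks, concat, then inception.

    Both subnetworks consume the same input image.  Their final block outputs
    are concatenated along channels and fed to a single inception module,
    followed by the projection/pool/dense classifier head.
    """
    g = _new_graph(input_shape)
    a = _subnetwork(g, "input", subnet, "sub1")
    b = _subnetwork(g, "input", subnet, "sub2")
    g.add(LayerSpec(name="merge", kind="concat", predecessors=(a, b)))
    top = inception_module(g, "merge", inception, "inc")
    _head(g, top, head, n_classes)
    return g


def build_disubnet_v2(input_shape: TensorShape = TensorShape(112, 112, 1),
                      n_classes: int = 4,
                      subnet: SubnetworkConfig = DEFAULT_SUBNETWORK,
                      inception: InceptionConfig = DEFAULT_INCEPTION,
                      head: HeadConfig = _V2_HEAD) -> LayerGraph:
    """DISubNetV2: per-subnetwork inception modules, concat, shared DS stack.

    Each subnetwork opens with its own inception module on the raw input; the
    two module outputs are concatenated and processed by one shared
    depthwise-separable stack, then the classifier head.
    """
    g = _new_graph(input_shape)
    a = inception_module(g, "input", inception, "inc1")
    b = inception_module(g, "input", inception, "inc2")
    g.add(LayerSpec(name="merge", kind="concat", predecessors=(a, b)))
    top = _subnetwork(g, "merge", subnet, "stack")
    _head(g, top, head, n_classes)
    return g


def scale_disubnet_v1(divisor: int = 4, input_shape: TensorShape = TensorShape(112, 112, 1),
                      n_classes: int = 4) -> LayerGraph:
    """Width-reduced DISubNetV1 (every width divided by ``divisor``) for desk-scale runs."""
    if divisor < 1:
        raise GraphError("divisor must be >= 1")
    sub = SubnetworkConfig(
        block_widths=tuple(max(1, w // divisor) for w in DEFAULT_SUBNETWORK.block_widths))
    inc = InceptionConfig(f1x1=max(1, DEFAULT_INCEPTION.f1x1 // divisor),
                          f3x3=max(1, DEFAULT_INCEPTION.f3x3 // divisor),
                          f_dilated=max(1, DEFAULT_INCEPTION.f_dilated // divisor))
    head = HeadConfig(projection=max(1, _V1_HEAD.projection // divisor),
                      dense=max(1, _V1_HEAD.dense // divisor))
    return build_disubnet_v1(input_shape, n_classes, sub, inc, head)


# ---------------------------------------------------------------------------
# baselines


def _build_lenet5(shape: TensorShape, n_classes: int) -> LayerGraph:
    # two 5x5 stride-1 same-padding convs (20, 50 filters), each with 2x2 max
    # pooling; one 500-unit hidden dense layer; all layers biased
    g = _new_graph(shape)
    n = _conv(g, "conv1", "input", 20, kernel=(5, 5))
    n = _pool(g, "pool1", n)
    n = _conv(g, "conv2", n, 50, kernel=(5, 5))
    n = _pool(g, "pool2", n)
    g.add(LayerSpec(name="flatten", kind="flatten", predecessors=(n,)))
    _dense(g, "fc1", "flatten", 500)
    g.add(LayerSpec(name="softmax", kind="softmax_output", filters_or_units=n_classes,
                    activation_name="softmax", predecessors=("fc1",)))
    return g


def _build_alexnet(shape: TensorShape, n_classes: int) -> LayerGraph:
    # four convolutional layers (11x11, 5x5, 3x3, 3x3), 3x3 stride-2 max pools
    g = _new_graph(shape)
    n = _conv(g, "conv1", "input", 96, kernel=(11, 11), stride=(4, 4))
    n = _pool(g, "pool1", n, size=(3, 3), stride=(2, 2))
    n = _conv(g, "conv2", n, 256, kernel=(5, 5))
    n = _pool(g, "pool2", n, size=(3, 3), stride=(2, 2))
    n = _conv(g, "conv3", n, 384)
    n = _conv(g, "conv4", n, 256)
    n = _pool(g, "pool3", n, size=(3, 3), stride=(2, 2))
    g.add(LayerSpec(name="flatten", kind="flatten", predecessors=(n,)))
    n = _dense(g, "fc1", "flatten", 4096)
    g.add(LayerSpec(name="drop1", kind="dropout", predecessors=(n,)))
    n = _dense(g, "fc2", "drop1", 4096)
    g.add(LayerSpec(name="drop2", kind="dropout", predecessors=(n,)))
    g.add(LayerSpec(name="softmax", kind="softmax_output", filters_or_units=n_classes,
                    activation_name="softmax", predecessors=("drop2",)))
    return g


def _build_vggnet16(shape: TensorShape, n_classes: int) -> LayerGraph:
    # the standard 13-conv/5-pool stack; one 512-unit hidden dense layer
    g = _new_graph(shape)
    plan = [(64, 2), (128, 2), (256, 3), (512, 3), (512, 3)]
    n = "input"
    k = 0
    for block, (width, reps) in enumerate(plan, start=1):
        for r in range(reps):
            k += 1
            n = _conv(g, f"conv{k}", n, width)
        n = _pool(g, f"pool{block}", n)
    g.add(LayerSpec(name="flatten", kind="flatten", predecessors=(n,)))
    n = _dense(g, "fc1", "flatten", 512)
    g.add(LayerSpec(name="softmax", kind="softmax_output", filters_or_units=n_classes,
                    activation_name="softmax", predecessors=("fc1",)))
    return g


def _sep_unit_inverted(g: LayerGraph, pred: str, filters: int, prefix: str) -> str:
    # pointwise first, then depthwise: the inverted ordering that
    # distinguishes this separable block from the DISubNet one
    g.add(LayerSpec(name=f"{prefix}_pw", kind="pointwise_conv2d", filters_or_units=filters,
                    activation_name="relu", predecessors=(pred,)))
    g.add(LayerSpec(name=f"{prefix}_dw", kind="depthwise_conv2d", kernel=(3, 3),
                    padding="same", activation_name="relu", predecessors=(f"{prefix}_pw",)))
    return f"{prefix}_dw"


def _build_xception_like(shape: TensorShape, n_classes: int) -> LayerGraph:
    g = _new_graph(shape)
    n = _conv(g, "entry1", "input", 32, stride=(2, 2))
    n = _conv(g, "entry2", n, 64)
    # entry flow: separable blocks downsampled by 2x2 pooling, each merged with
    # a 1x1 stride-2 projection shortcut by elementwise addition
    for width in (128, 256, 728):
        a = _sep_unit_inverted(g, n, width, f"blk{width}_u1")
        a = _sep_unit_inverted(g, a, width, f"blk{width}_u2")
        a = _pool(g, f"blk{width}_pool", a, padding="same")
        s = _conv(g, f"blk{width}_short", n, width, kernel=(1, 1), stride=(2, 2),
                  activation="none")
        g.add(LayerSpec(name=f"blk{width}_add", kind="add", predecessors=(a, s)))
        n = f"blk{width}_add"
    # middle flow: identity-skip blocks of three separable units at width 728
    for i in range(7):
        m = _sep_unit_inverted(g, n, 728, f"mid{i + 1}_u1")
        m = _sep_unit_inverted(g, m, 728, f"mid{i + 1}_u2")
        m = _sep_unit_inverted(g, m, 728, f"mid{i + 1}_u3")
        g.add(LayerSpec(name=f"mid{i + 1}_add", kind="add", predecessors=(m, n)))
        n = f"mid{i + 1}_add"
    e = _sep_unit_inverted(g, n, 1024, "exit_u1")
    e = _sep_unit_inverted(g, e, 1024, "exit_u2")
    e = _pool(g, "exit_pool", e, padding="same")
    s = _conv(g, "exit_short", n, 1024, kernel=(1, 1), stride=(2, 2), activation="none")
    g.add(LayerSpec(name="exit_add", kind="add", predecessors=(e, s)))
    n = _sep_unit_inverted(g, "exit_add", 1784, "tail1")
    n = _sep_unit_inverted(g, n, 2320, "tail2")
    # global average pooling: collapse the remaining spatial extent
    g.add(LayerSpec(name="gap", kind="avgpool", kernel=(4, 4), stride=(4, 4),
                    padding="valid", predecessors=(n,)))
    g.add(LayerSpec(name="flatten", kind="flatten", predecessors=("gap",)))
    g.add(LayerSpec(name="softmax", kind="softmax_output", filters_or_units=n_classes,
                    activation_name="softmax", predecessors=("flatten",)))
    return g


_CNN_TRUNK = (16, 40, 64, 80, 88, 112)
_CNN_LRELU_DENSE = 320
_CNN_INCEPTION_FILTERS = (40, 72, 64)  # per-stage symmetric branch widths
_CNN_INCEPTION_DENSE = 112


def _build_cnn_trunk(g: LayerGraph, with_inception: bool) -> str:
    """Shared trunk: pairs of 3x3 convs + batch-norm + LeakyReLU, 2x2 pool after
    every even conv; optionally one inception module after each pool."""
    n = "input"
    for i, width in enumerate(_CNN_TRUNK, start=1):
        n = _conv(g, f"conv{i}", n, width, activation="none")
        g.add(LayerSpec(name=f"bn{i}", kind="batchnorm", predecessors=(n,)))
        g.add(LayerSpec(name=f"lrelu{i}", kind="activation", activation_name="leaky_relu",
                        predecessors=(f"bn{i}",)))
        n = f"lrelu{i}"
        if i % 2 == 0:
            n = _pool(g, f"pool{i // 2}", n)
            if with_inception:
                f = _CNN_INCEPTION_FILTERS[i // 2 - 1]
                n = inception_module(g, n, InceptionConfig(f, f, f), f"inc{i // 2}")
    return n


def _build_cnn_leakyrelu(shape: TensorShape, n_classes: int) -> LayerGraph:
    g = _new_graph(shape)
    n = _build_cnn_trunk(g, with_inception=False)
    g.add(LayerSpec(name="flatten", kind="flatten", predecessors=(n,)))
    _dense(g, "fc1", "flatten", _CNN_LRELU_DENSE)
    g.add(LayerSpec(name="softmax", kind="softmax_output", filters_or_units=n_classes,
                    activation_name="softmax", predecessors=("fc1",)))
    return g


def _build_cnn_inception(shape: TensorShape, n_classes: int) -> LayerGraph:
    g = _new_graph(shape)
    n = _build_cnn_trunk(g, with_inception=True)
    g.add(LayerSpec(name="flatten", kind="flatten", predecessors=(n,)))
    _dense(g, "fc1", "flatten", _CNN_INCEPTION_DENSE)
    g.add(LayerSpec(name="softmax", kind="softmax_output", filters_or_units=n_classes,
                    activation_name="softmax", predecessors=("fc1",)))
    return g


_BASELINE_BUILDERS = {
    "lenet5": _build_lenet5,
    "alexnet": _build_alexnet,
    "vggnet16": _build_vggnet16,
    "xception_like": _build_xception_like,
    "cnn_leakyrelu": _build_cnn_leakyrelu,
    "cnn_inception": _build_cnn_inception,
}


def build_baseline(name: str, input_shape: TensorShape = TensorShape(112, 112, 1),
                   n_classes: int = 4) -> LayerGraph:
    """Build one of the six comparison models by name."""
    try:
        builder = _BASELINE_BUILDERS[name]
    except KeyError:
        raise GraphError(
            f"unknown baseline {name!r}; choose from {sorted(_BASELINE_BUILDERS)}"
        ) from None
    return builder(input_shape, n_classes)


def build_model(name: str, input_shape: TensorShape = TensorShape(112, 112, 1),
                n_classes: int = 4) -> LayerGraph:
    """Build any named model, including the two DISubNet variants."""
    if name == "disubnetv1":
        return build_disubnet_v1(input_shape, n_classes)
    if name == "disubnetv2":
        return build_disubnet_v2(input_shape, n_classes)
    return build_baseline(name, input_shape, n_classes)
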