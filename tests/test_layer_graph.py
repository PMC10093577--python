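"""Shape inference, parameter accounting, validation, and serialization."""

import itertools

import numpy as np
import pytest

from disubnet.layer_graph import (
    GraphError,
    LayerGraph,
    LayerSpec,
    TensorShape,
    count_parameters,
    graph_from_yaml,
    graph_to_yaml,
    infer_shapes,
    param_report_to_csv,
    validate_graph,
)


def chain(*specs):
    g = LayerGraph()
    for s in specs:
        g.add(s)
    return g


def test_tensor_shape_requires_positive_components():
    with pytest.raises(GraphError):
        TensorShape(0, 10, 1)
    with pytest.raises(GraphError):
        TensorShape(10, 10, -2)


def test_pointwise_kernel_is_pinned():
    with pytest.raises(GraphError):
        LayerSpec(name="p", kind="pointwise_conv2d", kernel=(3, 3),
                  filters_or_units=4, predecessors=("x",))


def test_leaky_slope_is_pinned_to_tenth():
    s = LayerSpec(name="a", kind="activation", activation_name="leaky_relu",
                  negative_slope=0.3, predecessors=("x",))
    assert s.negative_slope == 0.1


@pytest.mark.parametrize(
    "spec,in_shape,expected",
    [
        # same padding preserves spatial dims
        (LayerSpec(name="c", kind="conv2d", kernel=(3, 3), filters_or_units=32,
                   predecessors=("input",)), (112, 112, 1), (112, 112, 32)),
        # 2x2/2 pooling halves spatial dims
        (LayerSpec(name="c", kind="maxpool", kernel=(2, 2), stride=(2, 2),
                   padding="valid", predecessors=("input",)), (112, 112, 20), (56, 56, 20)),
        # dilation under same padding still preserves spatial dims
        (LayerSpec(name="c", kind="conv2d", kernel=(3, 3), dilation=2,
                   filters_or_units=7, predecessors=("input",)), (28, 28, 3), (28, 28, 7)),
        # valid padding shrinks by the effective kernel
        (LayerSpec(name="c", kind="conv2d", kernel=(5, 5), padding="valid",
                   filters_or_units=6, predecessors=("input",)), (12, 12, 2), (8, 8, 6)),
        (LayerSpec(name="c", kind="flatten", predecessors=("input",)),
         (7, 7, 10), (1, 1, 490)),
    ],
)
def test_shape_inference_cases(spec, in_shape, expected):
    g = chain(LayerSpec(name="input", kind="input"), spec)
    shapes = infer_shapes(g, TensorShape(*in_shape))
    assert shapes["c"].as_tuple() == expected


def test_concat_sums_channels_and_requires_matching_spatial_dims():
    g = chain(
        LayerSpec(name="input", kind="input"),
        LayerSpec(name="a", kind="conv2d", kernel=(3, 3), filters_or_units=64,
                  predecessors=("input",)),
        LayerSpec(name="b", kind="conv2d", kernel=(3, 3), filters_or_units=32,
                  predecessors=("input",)),
        LayerSpec(name="cat", kind="concat", predecessors=("a", "b")),
    )
    assert infer_shapes(g, TensorShape(28, 28, 3))["cat"].as_tuple() == (28, 28, 96)

    g2 = chain(
        LayerSpec(name="input", kind="input"),
        LayerSpec(name="a", kind="conv2d", kernel=(3, 3), filters_or_units=8,
                  predecessors=("input",)),
        LayerSpec(name="b", kind="maxpool", kernel=(2, 2), stride=(2, 2),
                  padding="valid", predecessors=("input",)),
        LayerSpec(name="cat", kind="concat", predecessors=("a", "b")),
    )
    with pytest.raises(GraphError, match="spatial mismatch"):
        infer_shapes(g2, TensorShape(28, 28, 3))


def test_kernel_larger_than_input_is_a_hard_error():
    g = chain(
        LayerSpec(name="input", kind="input"),
        LayerSpec(name="c", kind="conv2d", kernel=(9, 9), padding="valid",
                  filters_or_units=2, predecessors=("input",)),
    )
    with pytest.raises(GraphError, match="does not fit"):
        infer_shapes(g, TensorShape(5, 5, 1))


def brute_force_conv_weights(kh, kw, cin, f, bias):
    """Independent oracle: enumerate weight-tensor entries one by one."""
    count = 0
    for _ in itertools.product(range(kh), range(kw), range(cin), range(f)):
        count += 1
    if bias:
        count += f
    return count


@pytest.mark.parametrize(
    "kind,kernel,cin,f,bias,expected",
    [
        ("conv2d", (5, 5), 1, 20, True, brute_force_conv_weights(5, 5, 1, 20, True)),
        ("conv2d", (3, 3), 16, 32, False, brute_force_conv_weights(3, 3, 16, 32, False)),
        ("depthwise_conv2d", (3, 3), 32, 0, True, 9 * 32 + 32),
        ("pointwise_conv2d", (1, 1), 16, 32, True, 16 * 32 + 32),
        ("dense", (1, 1), 0, 500, True, None),  # handled below on a flattened input
    ],
)
def test_parameter_formulas_against_enumeration(kind, kernel, cin, f, bias, expected):
    if kind == "dense":
        g = chain(
            LayerSpec(name="input", kind="input"),
            LayerSpec(name="flat", kind="flatten", predecessors=("input",)),
            LayerSpec(name="c", kind="dense", filters_or_units=f, use_bias=bias,
                      predecessors=("flat",)),
        )
        report = count_parameters(g, TensorShape(4, 4, 3))
        assert report.per_node["c"][0] == 4 * 4 * 3 * 500 + 500
        return
    g = chain(
        LayerSpec(name="input", kind="input"),
        LayerSpec(name="c", kind=kind, kernel=kernel, filters_or_units=f,
                  use_bias=bias, predecessors=("input",)),
    )
    report = count_parameters(g, TensorShape(12, 12, cin))
    assert report.per_node["c"][0] == expected


def test_separable_factorization_beats_standard_conv_on_a_grid():
    """K^2*Cin + Cin*Cout < K^2*Cin*Cout for all Cin, Cout in 2..64 (K=3)."""
    for cin in range(2, 65):
        for cout in range(2, 65):
            assert 9 * cin + cin * cout < 9 * cin * cout


def test_separable_example_from_fig_style_comparison():
    # standard 3x3 conv 16 -> 32 without bias vs its separable factorization
    assert 3 * 3 * 16 * 32 == 4608
    assert 3 * 3 * 16 + 16 * 32 == 656


def test_batchnorm_counts_trainable_and_moving_statistics():
    g = chain(
        LayerSpec(name="input", kind="input"),
        LayerSpec(name="bn", kind="batchnorm", predecessors=("input",)),
    )
    report = count_parameters(g, TensorShape(8, 8, 12))
    assert report.per_node["bn"] == (24, 24)
    assert report.total_trainable == 24
    assert report.total_with_non_trainable == 48


def test_count_is_additive_over_chained_subgraphs():
    def front():
        return [
            LayerSpec(name="input", kind="input"),
            LayerSpec(name="c1", kind="conv2d", kernel=(3, 3), filters_or_units=8,
                      predecessors=("input",)),
        ]

    def back(pred):
        return [
            LayerSpec(name="c2", kind="conv2d", kernel=(3, 3), filters_or_units=6,
                      predecessors=(pred,)),
        ]

    g_front = chain(*front())
    g_back = chain(LayerSpec(name="input", kind="input"), *back("input"))
    g_full = chain(*front(), *back("c1"))
    a = count_parameters(g_front, TensorShape(10, 10, 3)).total_trainable
    b = count_parameters(g_back, TensorShape(10, 10, 8)).total_trainable
    full = count_parameters(g_full, TensorShape(10, 10, 3)).total_trainable
    assert full == a + b


def test_shape_inference_is_insertion_order_independent():
    specs = [
        LayerSpec(name="input", kind="input"),
        LayerSpec(name="a", kind="conv2d", kernel=(3, 3), filters_or_units=4,
                  predecessors=("input",)),
        LayerSpec(name="b", kind="conv2d", kernel=(3, 3), filters_or_units=5,
                  predecessors=("input",)),
        LayerSpec(name="cat", kind="concat", predecessors=("a", "b")),
    ]
    g1 = chain(*specs)
    g2 = chain(specs[0], specs[2], specs[1], specs[3])
    s1 = infer_shapes(g1, TensorShape(9, 9, 2))
    s2 = infer_shapes(g2, TensorShape(9, 9, 2))
    assert s1 == s2


def test_validate_accepts_linear_chain(linear_chain):
    assert validate_graph(linear_chain) == []


def test_validate_flags_concat_mismatch_and_cycles():
    g = chain(
        LayerSpec(name="input", kind="input"),
        LayerSpec(name="solo", kind="concat", predecessors=("input",)),
    )
    assert any("concat" in d for d in validate_graph(g))

    g2 = LayerGraph()
    g2.add(LayerSpec(name="input", kind="input"))
    g2.add(LayerSpec(name="a", kind="conv2d", kernel=(3, 3), filters_or_units=2,
                     predecessors=("b",)))
    g2.add(LayerSpec(name="b", kind="conv2d", kernel=(3, 3), filters_or_units=2,
                     predecessors=("a",)))
    assert any("cycle" in d for d in validate_graph(g2))


def test_yaml_round_trip_preserves_graph(linear_chain):
    text = graph_to_yaml(linear_chain)
    back = graph_from_yaml(text)
    assert graph_to_yaml(back) == text
    assert back.nodes.keys() == linear_chain.nodes.keys()
    assert back.nodes["conv"] == linear_chain.nodes["conv"]


def test_param_report_csv_lists_every_node(linear_chain):
    report = count_parameters(linear_chain, TensorShape(8, 8, 1))
    csv_text = param_report_to_csv(linear_chain, report)
    lines = csv_text.strip().splitlines()
    assert lines[0] == "node,kind,trainable,non_trainable"
    assert len(lines) == 1 + len(linear_chain.nodes)
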