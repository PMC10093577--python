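"""Backend/analytic agreement and exactness of the backward pass.

The analytic engine derives shapes and counts from formulas; the backend
allocates real arrays and computes real convolutions.  Agreement between the
two routes on randomized graphs is the core correctness check for both.
"""

import numpy as np
import pytest

from conftest import random_small_graph
from disubnet.backend import NumpyModel, softmax
from disubnet.layer_graph import (
    LayerGraph,
    LayerSpec,
    TensorShape,
    count_parameters,
    infer_shapes,
)
from disubnet.training import one_hot


def test_shapes_and_counts_match_on_randomized_graphs():
    """>= 50 random small graphs: analytic shapes equal observed activation
    shapes, and analytic counts equal allocated array sizes, exactly."""
    rng = np.random.default_rng(2024)
    for trial in range(60):
        graph, shape = random_small_graph(rng)
        analytic_shapes = infer_shapes(graph, shape)
        report = count_parameters(graph, shape)
        model = NumpyModel(graph, shape, seed=trial)

        x = rng.random((2,) + shape.as_tuple()).astype(np.float32)
        observed = model.activation_shapes(x)
        for name, ts in analytic_shapes.items():
            spec = graph.nodes[name]
            if spec.kind in ("flatten", "dense", "softmax_output"):
                assert observed[name] == (ts.channels,), name
            else:
                assert observed[name] == ts.as_tuple(), name

        assert model.trainable_parameter_count() == report.total_trainable
        per_node_backend = {
            name: sum(p.size for p in model.nodes[name].params.values())
            for name in graph.nodes
        }
        for name, (trainable, _) in report.per_node.items():
            assert per_node_backend[name] == trainable, name


def test_materialization_is_deterministic_per_seed():
    rng = np.random.default_rng(7)
    graph, shape = random_small_graph(rng)
    a = NumpyModel(graph, shape, seed=5)
    b = NumpyModel(graph, shape, seed=5)
    c = NumpyModel(graph, shape, seed=6)
    for (ka, wa), (kb, wb) in zip(a.parameters(), b.parameters()):
        assert ka == kb and np.array_equal(wa, wb)
    assert any(not np.array_equal(wa, wc)
               for (_, wa), (_, wc) in zip(a.parameters(), c.parameters()))


def test_softmax_rows_are_probabilities():
    z = np.random.default_rng(0).normal(size=(8, 4)).astype(np.float32) * 10
    p = softmax(z)
    assert np.all(p >= 0)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)


def _smooth_graph():
    """A branching graph with no kinked nonlinearities (no ReLU, no max-pool)
    so central differences are exact to float32 precision; the activation
    derivatives themselves are checked separately away from zero."""
    g = LayerGraph()
    g.add(LayerSpec(name="input", kind="input"))
    g.add(LayerSpec(name="c1", kind="conv2d", kernel=(3, 3), filters_or_units=3,
                    predecessors=("input",)))
    g.add(LayerSpec(name="dw", kind="depthwise_conv2d", kernel=(3, 3),
                    predecessors=("c1",)))
    g.add(LayerSpec(name="pw", kind="pointwise_conv2d", filters_or_units=4,
                    predecessors=("dw",)))
    g.add(LayerSpec(name="cd", kind="conv2d", kernel=(3, 3), dilation=2,
                    filters_or_units=2, predecessors=("c1",)))
    g.add(LayerSpec(name="cat", kind="concat", predecessors=("pw", "cd")))
    g.add(LayerSpec(name="bn", kind="batchnorm", predecessors=("cat",)))
    g.add(LayerSpec(name="ap", kind="avgpool", kernel=(2, 2), stride=(2, 2),
                    padding="valid", predecessors=("bn",)))
    g.add(LayerSpec(name="fl", kind="flatten", predecessors=("ap",)))
    g.add(LayerSpec(name="d1", kind="dense", filters_or_units=5,
                    predecessors=("fl",)))
    g.add(LayerSpec(name="sm", kind="softmax_output", filters_or_units=4,
                    activation_name="softmax", predecessors=("d1",)))
    return g


def test_backward_matches_central_differences():
    """Analytic gradients agree with finite differences for every parameter
    tensor of a branching graph (conv, dilated conv, separable pair,
    batch-norm, dense)."""
    g = _smooth_graph()
    shape = TensorShape(8, 8, 2)
    model = NumpyModel(g, shape, seed=3)
    rng = np.random.default_rng(1)
    x = rng.random((4, 8, 8, 2)).astype(np.float32)
    y = one_hot(np.array([0, 1, 2, 3]), 4)
    model.loss_and_gradients(x, y)
    analytic = {(n, k): v.copy() for n in model.nodes
                for k, v in model.nodes[n].grads.items()}
    h = 1e-2
    for name, node in model.nodes.items():
        for key, arr in node.params.items():
            flat = arr.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + h
                lp, _ = model.loss_and_gradients(x, y)
                flat[i] = orig - h
                lm, _ = model.loss_and_gradients(x, y)
                flat[i] = orig
                numeric = (lp - lm) / (2 * h)
                ana = analytic[(name, key)].ravel()[i]
                assert abs(numeric - ana) <= 5e-3 * max(1.0, abs(numeric)), (name, key)


def test_activation_derivatives_away_from_the_kink():
    """ReLU and LeakyReLU backward slopes match finite differences for
    pre-activations bounded away from zero."""
    g = LayerGraph()
    g.add(LayerSpec(name="input", kind="input"))
    g.add(LayerSpec(name="act", kind="activation", activation_name="leaky_relu",
                    predecessors=("input",)))
    g.add(LayerSpec(name="fl", kind="flatten", predecessors=("act",)))
    g.add(LayerSpec(name="sm", kind="softmax_output", filters_or_units=2,
                    activation_name="softmax", predecessors=("fl",)))
    model = NumpyModel(g, TensorShape(2, 2, 1), seed=0)
    node = model.nodes["act"]
    x = np.array([[[[1.0]], [[-1.0]]], [[[0.5]], [[-2.0]]]], dtype=np.float32)
    x = x.reshape(2, 2, 1, 1)
    out = model._forward_node(node, [x], False, None)
    dy = np.ones_like(out)
    (dx,) = model._backward_node(node, dy)
    expected = np.where(x > 0, 1.0, 0.1)
    assert np.allclose(dx, expected)


def test_maxpool_backward_routes_to_argmax_entries():
    g = LayerGraph()
    g.add(LayerSpec(name="input", kind="input"))
    g.add(LayerSpec(name="mp", kind="maxpool", kernel=(3, 3), stride=(2, 2),
                    padding="same", predecessors=("input",)))
    g.add(LayerSpec(name="fl", kind="flatten", predecessors=("mp",)))
    g.add(LayerSpec(name="sm", kind="softmax_output", filters_or_units=3,
                    activation_name="softmax", predecessors=("fl",)))
    model = NumpyModel(g, TensorShape(7, 7, 2), seed=0)
    rng = np.random.default_rng(4)
    x = rng.random((2, 7, 7, 2)).astype(np.float32)
    node = model.nodes["mp"]
    out = model._forward_node(node, [x], False, None)
    dy = rng.random(out.shape).astype(np.float32)
    (dx,) = model._backward_node(node, dy)
    # the scattered mass is conserved and lands only on window maxima
    assert dx.shape == x.shape
    assert np.isclose(dx.sum(), dy.sum(), rtol=1e-5)
    assert np.count_nonzero(dx) <= dy.size


def test_untrained_model_on_balanced_split_scores_near_chance(small_dataset):
    from disubnet.architectures import scale_disubnet_v1

    from disubnet.training import preprocess_images

    scenes, _ = small_dataset
    x, y = scenes.split_arrays("test")
    model = NumpyModel(scale_disubnet_v1(4), TensorShape(112, 112, 1), seed=0)
    acc = float((model.predict(preprocess_images(x)) == y).mean())
    assert abs(acc - 0.25) <= 0.05
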