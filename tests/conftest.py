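import numpy as np
import pytest

from disubnet.layer_graph import LayerGraph, LayerSpec, TensorShape
from disubnet.synthetic_thermal import SceneParams, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """400 easy synthetic scenes with the stratified 60/20/20 split."""
    scenes, manifest = generate_dataset(400, seed=123)
    return scenes, manifest


@pytest.fixture
def linear_chain():
    """A minimal valid graph: input -> conv -> flatten -> dense -> softmax."""
    g = LayerGraph()
    g.add(LayerSpec(name="input", kind="input"))
    g.add(LayerSpec(name="conv", kind="conv2d", kernel=(3, 3), filters_or_units=8,
                    activation_name="relu", predecessors=("input",)))
    g.add(LayerSpec(name="flatten", kind="flatten", predecessors=("conv",)))
    g.add(LayerSpec(name="dense", kind="dense", filters_or_units=16,
                    activation_name="relu", predecessors=("flatten",)))
    g.add(LayerSpec(name="softmax", kind="softmax_output", filters_or_units=4,
                    activation_name="softmax", predecessors=("dense",)))
    return g


def random_small_graph(rng: np.random.Generator) -> tuple[LayerGraph, TensorShape]:
    """A random valid graph of <= 8 layers, channels <= 16, for oracle checks.

    Convolutions use same padding and stride 1 so branches always concat; a
    2x2 pool is inserted only while the spatial extent stays even.
    """
    shape = TensorShape(12, 12, int(rng.integers(1, 4)))
    g = LayerGraph()
    g.add(LayerSpec(name="input", kind="input"))
    cur, size, k = "input", 12, 0

    def conv_like(pred: str) -> str:
        nonlocal k
        k += 1
        kind = rng.choice(["conv2d", "depthwise_conv2d", "pointwise_conv2d"])
        name = f"n{k}"
        if kind == "conv2d":
            g.add(LayerSpec(name=name, kind=kind, kernel=(3, 3),
                            dilation=int(rng.integers(1, 3)),
                            filters_or_units=int(rng.integers(2, 17)),
                            use_bias=bool(rng.integers(0, 2)),
                            activation_name="relu", predecessors=(pred,)))
        elif kind == "depthwise_conv2d":
            g.add(LayerSpec(name=name, kind=kind, kernel=(3, 3),
                            use_bias=bool(rng.integers(0, 2)),
                            activation_name="leaky_relu", predecessors=(pred,)))
        else:
            g.add(LayerSpec(name=name, kind=kind,
                            filters_or_units=int(rng.integers(2, 17)),
                            activation_name="relu", predecessors=(pred,)))
        return name

    for _ in range(int(rng.integers(2, 5))):
        roll = rng.random()
        if roll < 0.25:
            a, b = conv_like(cur), conv_like(cur)
            k += 1
            g.add(LayerSpec(name=f"n{k}", kind="concat", predecessors=(a, b)))
            cur = f"n{k}"
        elif roll < 0.4 and size % 2 == 0 and size > 2:
            k += 1
            g.add(LayerSpec(name=f"n{k}", kind="maxpool", kernel=(2, 2), stride=(2, 2),
                            padding="valid", predecessors=(cur,)))
            cur, size = f"n{k}", size // 2
        elif roll < 0.5:
            k += 1
            g.add(LayerSpec(name=f"n{k}", kind="batchnorm", predecessors=(cur,)))
            cur = f"n{k}"
        else:
            cur = conv_like(cur)
    g.add(LayerSpec(name="flatten", kind="flatten", predecessors=(cur,)))
    g.add(LayerSpec(name="dense", kind="dense",
                    filters_or_units=int(rng.integers(2, 9)),
                    activation_name="relu", predecessors=("flatten",)))
    g.add(LayerSpec(name="softmax", kind="softmax_output", filters_or_units=4,
                    activation_name="softmax", predecessors=("dense",)))
    return g, shape
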