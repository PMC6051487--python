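"""Category-specific saliency maps via guided backpropagation.

A saliency map ``S_k`` measures how much each input pixel influences the
evidence for class ``k``.  Plain guided backpropagation takes the gradient
of the aggregated class score ``a_k`` (the last activation before the
softmax) with respect to the pixels, gating the backward error at every
rectifier: the error passes only where both the forward input and the
incoming error are positive.

The activation-weighted variant exploits the spatial encoding of the class
score maps ``F_k``: each map neuron ``h^n`` sees one receptive field, so the
saliency is formed as a weighted combination of per-neuron influences with
weights ``h^n`` thresholded at zero (negative class evidence contributes
nothing).  Operationally this is computed in a *single* guided backward pass
seeded with the thresholded map ``F_{>0}`` — the exact gradient seed of the
objective ``1/2 * sum_n (h^n_{>0})^2``.

A mathematical caveat, verified by this package's test suite: the identity
between the single seeded pass and the explicit per-neuron sum is exact for
true gradients, but the guided error-sign gate is *not additive* across
per-neuron error fields.  Two per-neuron decompositions are therefore
provided: ``gate="independent"`` (each neuron's pass gated by its own error
sign — diverges from the single pass on general networks) and
``gate="shared"`` (the rectifier gate computed from the accumulated error —
the additive decomposition, which reproduces the single pass exactly).  See
``docs/methods.md`` for the full discussion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Network, _as_batch

__all__ = [
    "SaliencyMap",
    "guided_backprop",
    "plain_saliency",
    "weighted_saliency",
    "weighted_saliency_per_neuron",
    "write_saliency",
]


@dataclass
class SaliencyMap:
    """Signed per-pixel influence map for one category."""

    values: np.ndarray  # (H, W), same size as the input frame
    category: int
    signed: bool = True


def _check_category(net: Network, k: int) -> None:
    K = net.config.num_classes
    if not 0 <= k < K:
        raise ValueError(f"category {k} out of range for {K} classes")


def guided_backprop(net: Network, frame, objective,
                    guided: bool = True,
                    guided_adaptation: bool = True) -> np.ndarray:
    """Backpropagate a scalar objective of the class score maps to the pixels.

    ``objective`` maps the score maps ``(K, H', W')`` to ``(value, dmaps)``
    where ``value`` is the scalar being differentiated and ``dmaps`` its
    gradient seed at the maps.  Returns the (guided) gradient w.r.t. the
    input pixels, shaped like the frame.
    """
    x = _as_batch(frame)
    maps = net.forward_maps(x, train=False)
    value, dmaps = objective(maps[0])
    if np.ndim(value) != 0:
        raise ValueError("objective must be scalar-valued")
    dmaps = np.asarray(dmaps, dtype=maps.dtype)
    if dmaps.shape != maps.shape[1:]:
        raise ValueError("objective seed must match the class score maps")
    gx = net.backward_from_maps(dmaps[None], guided=guided,
                                guided_adaptation=guided_adaptation)
    return gx[0, 0]


def plain_saliency(net: Network, frame, k: int,
                   guided: bool = True,
                   guided_adaptation: bool = True) -> SaliencyMap:
    """Unweighted guided saliency: gradient of ``a_k`` w.r.t. the pixels."""
    _check_category(net, k)

    def objective(maps):
        n_cells = maps[k].size
        seed = np.zeros_like(maps)
        seed[k] = 1.0 / n_cells  # d a_k / d F_k for the mean aggregation
        return maps[k].mean(), seed

    values = guided_backprop(net, frame, objective, guided=guided,
                             guided_adaptation=guided_adaptation)
    return SaliencyMap(values, category=k)


def weighted_saliency(net: Network, frame, k: int,
                      guided: bool = True,
                      guided_adaptation: bool = True) -> SaliencyMap:
    """Activation-weighted saliency in a single guided backward pass.

    The backward seed at the class score maps is ``F_{>0}`` for category
    ``k`` (zero elsewhere), i.e. the gradient of
    ``1/2 * sum((F_k)_{>0}^2)``.  If ``F_k`` is nowhere positive the
    saliency is identically zero.
    """
    _check_category(net, k)

    def objective(maps):
        fpos = np.maximum(maps[k], 0)
        seed = np.zeros_like(maps)
        seed[k] = fpos
        return 0.5 * float((fpos ** 2).sum()), seed

    values = guided_backprop(net, frame, objective, guided=guided,
                             guided_adaptation=guided_adaptation)
    return SaliencyMap(values, category=k)


def weighted_saliency_per_neuron(net: Network, frame, k: int,
                                 gate: str = "shared",
                                 guided: bool = True,
                                 guided_adaptation: bool = True) -> SaliencyMap:
    """Brute-force per-neuron weighted saliency (the O(#neurons) route).

    Every map neuron ``h^n`` with positive activation is backpropagated as
    its own error field and the fields are summed at the input, weighted by
    ``h^n_{>0}``.  ``gate`` selects how the guided error-sign gate treats
    the per-neuron fields:

    * ``"independent"`` — each field is gated by its own sign (the literal
      per-neuron reading; not additive, so it generally differs from the
      single-pass computation),
    * ``"shared"`` — the gate is computed from the summed field at each
      rectifier and applied to every per-neuron field (the additive
      decomposition; sums exactly to the single-pass result).
    """
    _check_category(net, k)
    if gate not in ("independent", "shared"):
        raise ValueError(f"unknown gate mode {gate!r}")
    x = _as_batch(frame)
    maps = net.forward_maps(x, train=False)
    fk = maps[0, k]
    weights = np.maximum(fk, 0)
    active = np.argwhere(weights > 0)
    out = np.zeros_like(x[0, 0], dtype=np.float64)
    if active.size == 0:
        return SaliencyMap(out, category=k)

    if gate == "independent":
        for (i, j) in active:
            seed = np.zeros_like(maps)
            seed[0, k, i, j] = weights[i, j]
            gx = net.backward_from_maps(seed, guided=guided,
                                        guided_adaptation=guided_adaptation)
            out += gx[0, 0]
        return SaliencyMap(out, category=k)

    # shared gate: carry all per-neuron fields as a batch and gate each
    # rectifier by the accumulated (summed) error
    n = len(active)
    seeds = np.zeros((n,) + maps.shape[1:], dtype=maps.dtype)
    for row, (i, j) in enumerate(active):
        seeds[row, k, i, j] = weights[i, j]
    g = seeds
    from .nn import ReLU

    for idx in range(len(net.layers) - 1, -1, -1):
        layer = net.layers[idx]
        use_guided = guided and (guided_adaptation or idx < net.adapt_start)
        if isinstance(layer, ReLU) and use_guided:
            g = np.where(layer._mask, g, 0)
            total = g.sum(axis=0, keepdims=True)
            g = np.where(total > 0, g, 0)
        else:
            g = layer.backward(g, guided=False)
    return SaliencyMap(g.sum(axis=0)[0].astype(np.float64), category=k)


def write_saliency(path_base, smap: SaliencyMap) -> None:
    """Export a saliency map as float32 TIFF + symmetric 8-bit PNG + JSON."""
    import json
    from pathlib import Path

    import imageio.v3 as iio

    base = Path(path_base)
    iio.imwrite(base.with_suffix(".tiff"), smap.values.astype(np.float32))
    peak = float(np.abs(smap.values).max()) or 1.0
    png = np.clip((smap.values / peak) * 127.5 + 127.5, 0, 255).astype(np.uint8)
    iio.imwrite(base.with_suffix(".png"), png)
    base.with_suffix(".json").write_text(json.dumps({
        "category": smap.category,
        "signed": smap.signed,
        "png_encoding": "value 0 maps to grey 127.5; range symmetric in peak",
        "peak_abs": peak,
    }))
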