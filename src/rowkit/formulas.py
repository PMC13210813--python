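"""Desk-scale complexity and pruning-score formulas.

Partial convolution (PConv) applies a k x k convolution to only ``cp`` of
the ``c`` input channels and bypasses the rest, which is the FLOPs- and
memory-reduction device of the FasterBlock.  Two FLOPs conventions are
provided: the linear form h*w*k^2*cp, and the quadratic form
h*w*k^2*cp^2 (cp input channels to cp output channels), which is the one
consistent with the claim that convolving a quarter of the channels costs
one-sixteenth of a full convolution.

Layer-adaptive magnitude pruning (LAMP) scores each weight by its squared
magnitude normalized by the tail sum of squared magnitudes over all
weights of equal or larger magnitude in the same layer:

    score(u) = W[u]^2 / sum_{v >= u} W[v]^2

with weights sorted in ascending magnitude order, so the largest weight in
every layer scores exactly 1 and global pruning of the lowest scores
removes small-magnitude weights while protecting thin layers.  A variant
flag reproduces the descending-order reading, under which the score
ordering inverts; it is provided for comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ConvSpec",
    "pconv_flops",
    "pconv_memory",
    "conv_flops",
    "flops_ratio",
    "lamp_scores",
    "lamp_mask",
]


@dataclass(frozen=True)
class ConvSpec:
    """Feature-map height/width, kernel size, total and convolved channels."""

    h: int
    w: int
    k: int
    c: int
    cp: int

    def __post_init__(self) -> None:
        for name in ("h", "w", "k", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.cp < 0 or self.cp > self.c:
            raise ValueError("cp must satisfy 0 <= cp <= c")


def pconv_flops(spec: ConvSpec, variant: Literal["as_printed", "quadratic"] = "as_printed") -> int:
    """FLOPs of a partial convolution over ``cp`` channels.

    ``as_printed``: h*w*k^2*cp.  ``quadratic``: h*w*k^2*cp^2 (cp -> cp
    channel mapping), the form under which the quarter-channel ratio is
    exactly one-sixteenth.
    """
    base = spec.h * spec.w * spec.k**2 * spec.cp
    if variant == "as_printed":
        return base
    if variant == "quadratic":
        return base * spec.cp
    raise ValueError(f"unknown variant {variant!r}")


def pconv_memory(spec: ConvSpec, approximate: bool = False) -> int:
    """Memory access of a partial convolution: h*w*2cp + k^2*cp^2.

    The approximate form drops the weight term k^2*cp^2, which vanishes
    relative to the feature-map term as h*w grows at fixed k, cp.
    """
    feature = spec.h * spec.w * 2 * spec.cp
    if approximate:
        return feature
    return feature + spec.k**2 * spec.cp**2


def conv_flops(h: int, w: int, k: int, c: int) -> int:
    """FLOPs of a standard c -> c convolution: h*w*k^2*c^2."""
    return h * w * k**2 * c**2


def flops_ratio(c: int, cp_fraction: float) -> float:
    """PConv-to-standard FLOPs ratio at ``cp = cp_fraction * c``.

    Uses the quadratic PConv form, so the ratio is cp_fraction^2 and
    independent of h, w and k: one-fourth of the channels -> one-sixteenth
    of the FLOPs.
    """
    if not (0 < cp_fraction <= 1):
        raise ValueError("cp_fraction must be in (0, 1]")
    cp = c * cp_fraction
    return float((cp * cp) / (c * c))


def lamp_scores(
    weights: Sequence[float],
    order: Literal["ascending", "descending_as_printed"] = "ascending",
) -> np.ndarray:
    """LAMP saliency per weight, returned at the original indices.

    Weights are sorted by magnitude (stable sort, so ties keep original
    order); score at sorted position u is W[u]^2 / sum_{v>=u} W[v]^2.
    All scores lie in (0, 1]; with ascending order the score is
    non-decreasing in magnitude and the largest weight scores exactly 1.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("weights must be a nonempty flat sequence")
    if not np.all(np.isfinite(w)):
        raise ValueError("weights contain non-finite values")
    sq = w**2
    if np.all(sq == 0):
        raise ValueError("all-zero layer: scores undefined")
    key = np.abs(w) if order == "ascending" else -np.abs(w)
    if order not in ("ascending", "descending_as_printed"):
        raise ValueError(f"unknown order {order!r}")
    perm = np.argsort(key, kind="stable")
    sq_sorted = sq[perm]
    # tail sums: sum_{v >= u} W[v]^2 in the sorted sequence
    tails = np.cumsum(sq_sorted[::-1])[::-1]
    scores_sorted = sq_sorted / tails
    scores = np.empty_like(scores_sorted)
    scores[perm] = scores_sorted
    return scores


def lamp_mask(layers: Sequence[Sequence[float]], global_sparsity: float) -> list[np.ndarray]:
    """Global magnitude-aware pruning masks (True = keep).

    Scores from all layers are pooled and the ``global_sparsity`` fraction
    with the lowest scores is pruned (count = floor(sparsity * total)),
    with stable tie-breaking by (layer, index) so masks at increasing
    sparsity are nested.
    """
    if not (0 <= global_sparsity < 1):
        raise ValueError("global_sparsity must be in [0, 1)")
    if len(layers) == 0:
        raise ValueError("need at least one layer")
    per_layer = [lamp_scores(layer) for layer in layers]
    pool = [
        (float(score), li, wi)
        for li, scores in enumerate(per_layer)
        for wi, score in enumerate(scores)
    ]
    total = len(pool)
    n_prune = int(global_sparsity * total)
    pool.sort()
    masks = [np.ones(len(scores), dtype=bool) for scores in per_layer]
    for _, li, wi in pool[:n_prune]:
        masks[li][wi] = False
    return masks
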