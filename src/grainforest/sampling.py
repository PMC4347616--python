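"""In-bag sampling schemes for grain-aware forest training.

Three ways of drawing the multiset of examples a single tree is trained on:

* ``standard``      — the ordinary bootstrap: n uniform draws with replacement
                      from the whole training set.
* ``stratified``    — bootstrap each grain partition separately, so every
                      partition is represented at its full size in every bag.
* ``hierarchical``  — exactly one example drawn uniformly from each grain
                      partition, so no grain value can occur twice in a bag.

Hierarchical sampling is the leakage fix: a tree that sees one example per
grain cannot memorise the grain-defining feature value as an identifier.
"""

from __future__ import annotations

import numpy as np

from .table import Partitioning

__all__ = [
    "SCHEMES",
    "draw_standard_bootstrap",
    "draw_stratified_bootstrap",
    "draw_hierarchical_sample",
    "draw_inbag",
]

SCHEMES = ("standard", "stratified", "hierarchical")


def draw_standard_bootstrap(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n example indices uniformly with replacement from 0..n-1."""
    if n < 1:
        raise ValueError("cannot bootstrap an empty table")
    return rng.integers(0, n, size=n)


def draw_stratified_bootstrap(part: Partitioning, rng: np.random.Generator) -> np.ndarray:
    """Bootstrap each grain partition separately.

    For a group of size s, s indices are drawn with replacement from within
    that group; the concatenated sample has size n.
    """
    pieces = []
    for idx in part.groups.values():
        s = len(idx)
        if s == 0:
            raise ValueError("empty partition")
        pieces.append(idx[rng.integers(0, s, size=s)])
    return np.concatenate(pieces)


def draw_hierarchical_sample(part: Partitioning, rng: np.random.Generator) -> np.ndarray:
    """Draw exactly one index, uniformly, from each grain partition.

    The resulting bag has size p and never contains two examples sharing a
    grain value.
    """
    out = np.empty(part.p, dtype=np.intp)
    for j, idx in enumerate(part.groups.values()):
        s = len(idx)
        if s == 0:
            raise ValueError("empty partition")
        out[j] = idx[rng.integers(0, s)]
    return out


def draw_inbag(scheme: str, n: int, part: Partitioning | None, rng: np.random.Generator) -> np.ndarray:
    """Dispatch to the configured sampling scheme."""
    if scheme == "standard":
        return draw_standard_bootstrap(n, rng)
    if part is None:
        raise ValueError(f"scheme {scheme!r} requires a grain partitioning")
    if scheme == "stratified":
        return draw_stratified_bootstrap(part, rng)
    if scheme == "hierarchical":
        return draw_hierarchical_sample(part, rng)
    raise ValueError(f"unknown sampling scheme {scheme!r}; expected one of {SCHEMES}")
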