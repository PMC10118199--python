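"""Deterministic random-stream management.

A run is keyed by one root integer seed.  Every stage, generation and
individual derives its own independent stream from that root by
counter-based splitting, so results never depend on execution order or
parallelization:

* stage/generation streams: ``SeedSequence(root, spawn_key=key)`` — a pure
  function of (root, key path);
* per-individual realization streams: Philox generators whose 256-bit key is
  derived from the stage stream plus the individual index (a counter), which
  makes spawning thousands of streams per generation cheap.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["substream", "child_seed", "realization_streams"]


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def child_seed(seed, *key: int) -> np.random.SeedSequence:
    """A SeedSequence child addressed by an integer key path.

    Pure in (seed, key): the same path always yields the same child, and
    siblings with different paths are statistically independent.
    """
    root = _as_seedseq(seed)
    return np.random.SeedSequence(
        entropy=root.entropy, spawn_key=tuple(root.spawn_key) + tuple(key)
    )


def substream(seed, *key: int) -> np.random.Generator:
    """An independent Generator for the given key path under ``seed``."""
    return np.random.Generator(np.random.PCG64(child_seed(seed, *key)))


def realization_streams(seed, n: int) -> list[np.random.Generator]:
    """``n`` independent per-individual Generators derived from ``seed``.

    Stream ``k`` is a Philox generator keyed by (base key from ``seed``, k),
    so creating N streams costs O(N) key arithmetic rather than N seed
    hashes.  ``realize_population`` guarantees its row ``k`` is bitwise equal
    to a single realization driven by stream ``k``.
    """
    base = child_seed(seed).generate_state(2, dtype=np.uint64)
    streams = []
    for k in range(n):
        key = base.copy()
        key[0] = key[0] + np.uint64(k)  # wraps mod 2**64; distinct for k < 2**64
        streams.append(np.random.Generator(np.random.Philox(key=key)))
    return streams
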