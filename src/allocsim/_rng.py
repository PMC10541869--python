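"""Keyed random substreams.

Every stochastic step draws from a generator keyed by (master seed, purpose,
optional date or id).  Two consequences the rest of the package relies on:

* advancing the waiting list day by day is exactly reproducible no matter how
  the days are batched, because each day owns its own stream;
* per-donor decision draws are independent of the order donors are processed,
  which is what makes parallel replication bit-identical across worker counts.
"""

from __future__ import annotations

import datetime
import zlib

import numpy as np


def _to_int(key) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    if isinstance(key, datetime.date):
        return key.toordinal()
    return int(key) & 0xFFFFFFFF


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the stream identified by (master_seed, *keys)."""
    entropy = [int(master_seed) & 0x7FFFFFFF] + [_to_int(k) for k in keys]
    return np.random.default_rng(entropy)


def derive_seed(master_seed: int, index: int) -> int:
    """Derive the master seed of replicate ``index``; always < 2**31."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, int(index)])
    return int(ss.generate_state(1)[0] % (2**31))
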