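"""Deterministic seed fan-out.

Every stochastic component of the pipeline draws its seed from the single
run seed through a stable label hash, so that independent stages never share
a random stream and the whole run is reproducible from one integer.
"""

from __future__ import annotations

import zlib

_MOD = 2**31 - 1


def child_seed(seed: int, label: str) -> int:
    """Derive a stage seed from the run seed and a stage label.

    Stable across platforms and Python versions (CRC32, not ``hash``);
    result fits in a signed 32-bit integer as every backing library requires.
    """
    h = zlib.crc32(f"{int(seed)}:{label}".encode("utf-8"))
    return (int(seed) * 1_000_003 + h) % _MOD
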