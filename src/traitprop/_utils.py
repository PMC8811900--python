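"""Small shared helpers: per-stage RNG seed derivation and logging setup."""
from __future__ import annotations

import hashlib
import logging


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive an independent, reproducible sub-seed for a pipeline stage.

    A single user-facing seed fans out to per-stage streams by hashing the
    stage name together with the master seed.  The result is kept below 2**31
    so it is a valid seed for every RNG API in the stack.
    """
    digest = hashlib.blake2s(f"{master_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)


def get_logger(name: str) -> logging.Logger:
    return logging.getLogger(name)
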