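"""Shared helpers: error types, seed fan-out, logging."""
from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger("fmtrack")


class FmtrackError(Exception):
    """Base class for all package errors."""


class ValidationError(FmtrackError, ValueError):
    """A container invariant was violated."""


class ParameterError(FmtrackError, ValueError):
    """An argument is outside its allowed range."""


class DegenerateInputError(FmtrackError, ValueError):
    """Input is structurally valid but carries no usable signal (e.g. all-zero sample)."""


class AlignmentError(FmtrackError, ValueError):
    """Two objects that must share an axis (samples, windows) do not."""


class ConfigurationError(FmtrackError, ValueError):
    """Metadata or pipeline configuration is inconsistent with the requested analysis."""


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds from one global seed.

    Uses :class:`numpy.random.SeedSequence` spawning so every stage of a
    pipeline gets a reproducible, statistically independent stream. Values are
    reduced below 2**31 so they remain usable as plain integer seeds.
    """
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def rng_from(seed) -> np.random.Generator:
    """Accept an int seed or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
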