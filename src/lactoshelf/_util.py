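"""Shared plumbing: reproducible RNG streams and package exceptions."""

from __future__ import annotations

import zlib

import numpy as np

MISSING_TOKEN = "NA"


class LactoshelfError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(LactoshelfError, ValueError):
    pass


class FormatError(LactoshelfError, ValueError):
    pass


class ValidationError(LactoshelfError, ValueError):
    pass


class JoinError(ValidationError):
    pass


class LayoutOverflowError(ValidationError):
    pass


class DegenerateInputError(LactoshelfError, ValueError):
    pass


class AlignmentError(LactoshelfError, ValueError):
    pass


class ConfigError(LactoshelfError, ValueError):
    pass


def stream(master_seed: int, *labels: str | int) -> np.random.Generator:
    """Derive an independent RNG stream from a master seed and identifiers.

    Labels are hashed with CRC32 so the same (seed, labels) pair always
    yields the same stream, regardless of how many other streams were
    drawn — per-plate and per-donor subsets are therefore reproducible
    in isolation.
    """
    keys = [int(master_seed)]
    for lab in labels:
        keys.append(zlib.crc32(str(lab).encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(keys))


def lognormal_noise_factors(
    rng: np.random.Generator, cv: float, size
) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv < 0:
        raise InvalidArgumentError("cv must be >= 0")
    if cv == 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))
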