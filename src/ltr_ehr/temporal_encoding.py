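"""Sine/cosine positional encoding of irregular inter-visit time.

Visits in referral cohorts are irregularly spaced, which rules out the
fixed-step assumptions of recurrent models. Instead the elapsed time t
(in days, used raw) is encoded with the transformer-style fixed frequencies

    PE(t, 2j-1) = sin(t / 10000^(2j/(D+d)))
    PE(t, 2j)   = cos(t / 10000^(2j/(D+d)))        j = 1 .. (D+d)/2,

and — unlike the additive transformer convention — applied multiplicatively:
the D columns of the stacked code-embedding matrix and the d lab entries are
each scaled by the corresponding PE entry. An additive mode is available for
ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import InvalidArgumentError


@dataclass(frozen=True)
class PEVector:
    """A positional-encoding vector of length D+d for elapsed time ``t``."""

    values: np.ndarray
    t: float


def positional_encoding(t: float, D: int, d: int) -> PEVector:
    """Evaluate the PE function for elapsed time ``t`` (days).

    Positions are numbered 1..D+d: odd positions carry the sine, even
    positions the cosine, and the pair (2j-1, 2j) shares the frequency
    ``1 / 10000^(2j/(D+d))``. Requires D+d even (every sine has its cosine).
    """
    if D < 1 or d < 1:
        raise InvalidArgumentError("D and d must be >= 1")
    if (D + d) % 2 != 0:
        raise InvalidArgumentError("D + d must be even")
    if t < 0:
        raise InvalidArgumentError("elapsed time must be non-negative")
    n = D + d
    j = np.arange(1, n // 2 + 1, dtype=float)
    angle = t / np.power(10000.0, 2.0 * j / n)
    values = np.empty(n)
    values[0::2] = np.sin(angle)  # positions 1, 3, 5, ... (1-based odd)
    values[1::2] = np.cos(angle)
    return PEVector(values=values, t=float(t))


def apply_pe(sample, mode: str = "multiplicative"):
    """Return a copy of ``sample`` with PE applied to X's columns and labs.

    Column k of X (k = 1..D) is scaled by PE entry k; lab entry k is scaled
    by PE entry D+k. ``t`` and ``y`` are untouched. Zero rows of X (absent
    codes) remain exactly zero. ``mode="additive"`` adds the PE entries to
    the nonzero rows / labs instead (ablation only).
    """
    D = sample.X.shape[1]
    d = sample.x.shape[0]
    pe = positional_encoding(sample.t, D, d).values
    if mode == "multiplicative":
        X = sample.X * pe[:D]
        x = sample.x * pe[D:]
    elif mode == "additive":
        X = sample.X.copy()
        if len(sample.code_indices):
            X[sample.code_indices] = X[sample.code_indices] + pe[:D]
        x = sample.x + pe[D:]
    else:
        raise InvalidArgumentError(f"unknown PE mode: {mode!r}")
    return replace(sample, X=X, x=x, pe_applied=True)
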