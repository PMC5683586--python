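"""Monotone map from selection strength to a conservation-like score."""

from __future__ import annotations

import numpy as np

SCORE_RANGE = (-2.0, 6.0)
_SLOPE = 2.0
_S0 = 2e-3  # selection coefficient mapping to score 0 before noise


def assign_scores(
    s_values,
    noise_sd: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Per-site scores: a*log10(s/s0) + noise for deleterious sites (s > 0),
    a mostly-non-positive distribution for neutral and beneficial sites;
    clipped to [-2, 6]. With ``noise_sd=0`` the map is deterministic in s."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    s = np.asarray(s_values, dtype=float)
    out = np.empty(len(s))
    dele = s > 0
    out[dele] = _SLOPE * np.log10(s[dele] / _S0)
    out[~dele] = -0.6
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=len(s))
    return np.clip(out, *SCORE_RANGE)


def apply_reference_bias(
    scores: np.ndarray,
    ref_is_derived: np.ndarray,
    rng: np.random.Generator,
    noise_sd: float = 0.5,
) -> np.ndarray:
    """Emulate the conservation-score artifact at sites where the reference
    genome carries the derived allele: the aligner treats the reference state
    as conserved, so such sites lose their deleteriousness signal and score
    like neutral sites. The bin-mean correction is meant to undo this."""
    out = scores.copy()
    k = int(ref_is_derived.sum())
    if k:
        out[ref_is_derived] = np.clip(
            -0.6 + rng.normal(0.0, max(noise_sd, 1e-12), size=k), *SCORE_RANGE
        )
    return out
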