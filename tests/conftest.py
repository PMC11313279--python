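"""Shared fixtures: simulated samples and hand-built profiles.

Everything is generated at test time from the seeded simulator — no stored
binary fixtures.  ``pipeline`` runs simulation + detection and caches per
(label, noise, seed, bleed) so multiple tests can reuse the same sample.
"""

from __future__ import annotations

import numpy as np
import pytest

from polytg.detect import FlankAnchors, ObservedTract, detect_forward_tract, detect_reverse_tract
from polytg.synthetic import SimulationSpec, simulate_read
from polytg.trace import (
    RelativeIntensityProfile,
    SignalConfig,
    orient_reverse,
    relative_intensities,
)

BASE_COL = {b: i for i, b in enumerate("ACGT")}


@pytest.fixture(scope="session")
def cfg() -> SignalConfig:
    return SignalConfig()


@pytest.fixture(scope="session")
def anchors() -> FlankAnchors:
    return FlankAnchors()


@pytest.fixture(scope="session")
def pipeline(cfg, anchors):
    """Factory: simulate a genotype and detect both tract windows."""
    cache: dict = {}

    def run(label: str, noise_sd: float = 0.0, seed: int = 0, bleed: float = 0.0):
        key = (label, noise_sd, seed, bleed)
        if key not in cache:
            spec = SimulationSpec(genotype=label, noise_sd=noise_sd, seed=seed, bleed_through=bleed)
            fwd = simulate_read(spec, "forward")
            rev = simulate_read(spec, "reverse")
            profile_f = relative_intensities(fwd, cfg)
            profile_r = orient_reverse(relative_intensities(rev, cfg))
            tract_f = detect_forward_tract(profile_f, anchors, cfg)
            tract_r = detect_reverse_tract(profile_r, anchors, cfg)
            cache[key] = (tract_f, tract_r, profile_f, profile_r)
        return cache[key]

    return run


def profile_from_rows(rows) -> RelativeIntensityProfile:
    """Build a profile from per-position specs.

    Each row is either a base letter (pure peak), ``None`` (uninformative),
    or a dict base->fraction (superposed peaks, fractions should sum to 1).
    """
    n = len(rows)
    rel = np.zeros((n, 4))
    total = np.full(n, 1000.0)
    informative = np.ones(n, dtype=bool)
    seq = []
    for i, row in enumerate(rows):
        if row is None:
            informative[i] = False
            total[i] = 0.0
            seq.append("N")
        elif isinstance(row, str):
            rel[i, BASE_COL[row]] = 1.0
            seq.append(row)
        else:
            for base, frac in row.items():
                rel[i, BASE_COL[base]] = frac
            seq.append(max(row, key=row.get))
    return RelativeIntensityProfile(
        base_sequence="".join(seq), rel=rel, total_signal=total, informative=informative
    )


def observed_from_profile(profile, start, length, direction, fully_detected=True) -> ObservedTract:
    return ObservedTract(
        direction=direction,
        start=start,
        length=length,
        ot=profile.rel[start : start + length, BASE_COL["T"]].copy(),
        og=profile.rel[start : start + length, BASE_COL["G"]].copy(),
        informative_mask=profile.informative[start : start + length].copy(),
        fully_detected=fully_detected,
        profile=profile,
    )
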