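"""Per-base relative signal intensities and orientation normalization.

Every downstream computation works on *relative* intensities — each
channel's analyzed-trace value at a called base's peak location divided by
the total signal there — which makes the model invariant to scanner gain.
Reverse reads are flipped into genomic-forward orientation (positions
reversed, channels complemented) so the tract always reads as T/G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .abif import BASE_INDEX, BASES, ChromatogramRead
from .errors import UninformativePositionError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# column permutation complementing channels: A<->T, C<->G
_COMP_COLS = np.array([BASE_INDEX[b] for b in "TGCA"])


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SignalConfig:
    """Signal thresholds.

    min_total_signal
        Raw analyzed-trace units; positions whose four-channel total falls
        below it are masked uninformative and ignored in all comparisons.
    presence_fraction
        Relative-intensity threshold (inclusive) for "this base's signal is
        observed".  0.10 keeps a 50/50 heterozygous peak (~0.5) robustly
        present while typical bleed-through (<10%) stays absent.
    """

    min_total_signal: float = 50.0
    presence_fraction: float = 0.10

    def __post_init__(self):
        if self.min_total_signal < 0:
            raise ValueError("min_total_signal must be >= 0")
        if not 0.0 < self.presence_fraction < 1.0:
            raise ValueError("presence_fraction must be in (0, 1)")


@dataclass
class RelativeIntensityProfile:
    base_sequence: str
    rel: np.ndarray  # (N, 4), columns A,C,G,T; rows of informative positions sum to 1
    total_signal: np.ndarray
    informative: np.ndarray
    oriented_from_reverse: bool = field(default=False)

    def __len__(self):
        return len(self.base_sequence)

    def argmax_base(self, position: int) -> str:
        """Dominant base letter at a position; 'N' when uninformative."""
        if not self.informative[position]:
            return "N"
        return BASES[int(np.argmax(self.rel[position]))]

    @property
    def argmax_sequence(self) -> str:
        out = np.full(len(self), "N")
        idx = np.flatnonzero(self.informative)
        best = np.argmax(self.rel[idx], axis=1)
        out[idx] = np.array(list(BASES))[best]
        return "".join(out)


def relative_intensities(read: ChromatogramRead, cfg: SignalConfig) -> RelativeIntensityProfile:
    """Sample each channel at every called base's peak location and normalize.

    One profile position per called base.  Uninformative positions (total
    signal below ``cfg.min_total_signal``) get all-zero relative intensities
    and are excluded from downstream sums.
    """
    peaks = read.peak_locations
    raw = np.stack([read.traces[b][peaks] for b in BASES], axis=1).astype(float)
    total = raw.sum(axis=1)
    informative = total >= cfg.min_total_signal
    rel = np.zeros_like(raw)
    np.divide(raw, total[:, None], out=rel, where=informative[:, None] & (total[:, None] > 0))
    return RelativeIntensityProfile(
        base_sequence=read.called_bases,
        rel=rel,
        total_signal=total,
        informative=informative,
    )


def orient_reverse(profile: RelativeIntensityProfile) -> RelativeIntensityProfile:
    """Flip a reverse-read profile into genomic-forward orientation.

    Position order is reversed and channel labels complemented, so a tract
    that reads as poly-A/(CA)m in the reverse read presents as (TG)mTn, the
    same frame the forward read uses.  Involution: applying this twice is
    the identity.
    """
    return RelativeIntensityProfile(
        base_sequence=reverse_complement(profile.base_sequence),
        rel=profile.rel[::-1][:, _COMP_COLS].copy(),
        total_signal=profile.total_signal[::-1].copy(),
        informative=profile.informative[::-1].copy(),
        oriented_from_reverse=not profile.oriented_from_reverse,
    )


def base_present(
    profile: RelativeIntensityProfile, position: int, base: str, cfg: SignalConfig
) -> bool:
    """True iff ``base``'s relative intensity at ``position`` reaches the
    presence threshold (inclusive).  Raises on masked positions."""
    if not profile.informative[position]:
        raise UninformativePositionError(f"position {position} is below the signal threshold")
    return bool(profile.rel[position, BASE_INDEX[base]] >= cfg.presence_fraction)
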