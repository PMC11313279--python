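"""Tract detection: flank anchoring, directional scans and flank QC.

Both directions are processed in genomic-forward orientation (the reverse
profile is complemented/reversed first), so the tract always presents as
(TG)mTn.  The forward chromatogram anchors the tract's 5' end on the
upstream 15 bp flank and scans 3'-ward until thymine signal ends; the
reverse chromatogram anchors the 3' end on the downstream flank and scans
5'-ward until adenine signal appears.

The forward termination rule is a reconstruction: "thymine no longer
detected" cannot be literal because clean guanine positions inside the TG
repeat lack thymine, so the scan ends at the first *two consecutive*
thymine-free positions — which is exactly the start of the downstream
flank, whose first two bases are non-T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import reference
from .abif import BASE_INDEX
from .errors import AmbiguousAnchorError, AnchorNotFoundError
from .trace import RelativeIntensityProfile, SignalConfig

_T = BASE_INDEX["T"]
_G = BASE_INDEX["G"]
_A = BASE_INDEX["A"]

#: positions scanned past the anchor before giving up — longest default
#: allele (2*16 + 11 = 43) plus margin
SCAN_CAP = 60

#: anchor Hamming-distance tolerance used by detection
DEFAULT_MAX_MISMATCH = 2

#: lenient tolerance used only by the indel QC check, which must locate the
#: anchor even when a heterozygous indel smears half the signal
QC_MAX_MISMATCH = 7

#: relative-intensity threshold for the adenine peak that terminates the
#: reverse-direction scan.  The terminating A is a genuine allele peak and
#: is never diluted below 0.5 (half amplitude in a heterozygote), whereas
#: baseline noise and bleed-through stay well under 0.25 — a single-position
#: stop rule at the generic presence fraction (0.10) would truncate the
#: window on ordinary baseline noise.
TERMINATION_FRACTION = 0.25


@dataclass(frozen=True)
class FlankAnchors:
    """The fixed 15 bp sequences flanking the tract on the forward strand."""

    upstream15: str = reference.UPSTREAM_FLANK
    downstream15: str = reference.DOWNSTREAM_FLANK

    def __post_init__(self):
        if len(self.upstream15) != 15 or len(self.downstream15) != 15:
            raise ValueError("flank anchors must be exactly 15 bases")
        if self.upstream15.endswith("TG"):
            raise ValueError("upstream anchor would ambiguously extend the TG repeat")
        if self.downstream15.startswith("TT"):
            raise ValueError("downstream anchor would ambiguously extend the poly-T run")


@dataclass
class ObservedTract:
    """Detected (TG)mTn window in one oriented profile.

    ``ot``/``og`` are observed relative thymine/guanine intensities per
    window position (5'->3'); ``length`` is the nF or nR of the difference
    score.  ``profile`` is retained so compatibility checks can look past
    the window end along the same frame.
    """

    direction: str
    start: int
    length: int
    ot: np.ndarray
    og: np.ndarray
    informative_mask: np.ndarray
    fully_detected: bool
    profile: RelativeIntensityProfile = field(repr=False)

    def __post_init__(self):
        if not (len(self.ot) == len(self.og) == len(self.informative_mask) == self.length):
            raise ValueError("window arrays must match the tract length")

    @property
    def end(self) -> int:
        return self.start + self.length


def find_anchor(
    profile: RelativeIntensityProfile, anchor: str, max_mismatch: int = DEFAULT_MAX_MISMATCH
) -> int:
    """Best unique match of ``anchor`` against the profile's dominant-base
    sequence (Hamming distance; uninformative positions match anything)."""
    k = len(anchor)
    seq = profile.argmax_sequence
    if len(seq) < k:
        raise AnchorNotFoundError(f"profile shorter than the {k} bp anchor")
    obs = np.frombuffer(seq.encode(), dtype="S1")
    target = np.frombuffer(anchor.encode(), dtype="S1")
    wildcard = obs == b"N"
    n_windows = len(seq) - k + 1
    dist = np.empty(n_windows, dtype=int)
    for offset in range(n_windows):
        window = obs[offset : offset + k]
        dist[offset] = int(np.sum((window != target) & ~wildcard[offset : offset + k]))
    best = int(dist.min())
    if best > max_mismatch:
        raise AnchorNotFoundError(
            f"no window within {max_mismatch} mismatches of anchor {anchor!r} (best: {best})"
        )
    hits = np.flatnonzero(dist == best)
    if len(hits) > 1:
        raise AmbiguousAnchorError(
            f"anchor {anchor!r} matches {len(hits)} windows at distance {best}"
        )
    return int(hits[0])


def _signal_free(profile: RelativeIntensityProfile, pos: int, channel: int, cfg: SignalConfig) -> bool:
    """True when the channel's signal is confidently absent at ``pos``.

    Uninformative and out-of-read positions are NOT free (absence cannot be
    asserted there), so low-signal gaps inside the tract neither terminate
    the scan nor shrink the window.
    """
    if pos < 0 or pos >= len(profile) or not profile.informative[pos]:
        return False
    return profile.rel[pos, channel] < cfg.presence_fraction


def _window(profile, direction, start, end, fully_detected) -> ObservedTract:
    return ObservedTract(
        direction=direction,
        start=start,
        length=end - start,
        ot=profile.rel[start:end, _T].copy(),
        og=profile.rel[start:end, _G].copy(),
        informative_mask=profile.informative[start:end].copy(),
        fully_detected=fully_detected,
        profile=profile,
    )


def detect_forward_tract(
    profile: RelativeIntensityProfile,
    anchors: FlankAnchors,
    cfg: SignalConfig,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> ObservedTract:
    """Anchor on the upstream flank, scan 3'-ward while thymine persists.

    A position stays in the tract while thymine is present there or at the
    next position; the first two consecutive thymine-free positions end it
    (both excluded).  The scan is capped at SCAN_CAP positions; hitting the
    cap or the read end leaves the window truncated with
    ``fully_detected=False``.
    """
    anchor_at = find_anchor(profile, anchors.upstream15, max_mismatch)
    start = anchor_at + 15
    for pos in range(start, start + SCAN_CAP):
        if pos + 1 >= len(profile):
            # read ended before the tract end could be confirmed
            return _window(profile, "forward", start, min(len(profile), pos + 1), False)
        if _signal_free(profile, pos, _T, cfg) and _signal_free(profile, pos + 1, _T, cfg):
            return _window(profile, "forward", start, pos, True)
    end = min(start + SCAN_CAP, len(profile))
    return _window(profile, "forward", start, end, False)


def detect_reverse_tract(
    oriented_profile: RelativeIntensityProfile,
    anchors: FlankAnchors,
    cfg: SignalConfig,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> ObservedTract:
    """Anchor on the downstream flank (in the oriented, genomic-forward
    profile), scan 5'-ward while adenine is absent; the first position with
    adenine signal ends the tract (that position excluded).  Window
    positions are reported 5'->3', co-oriented with the forward tract.
    """
    anchor_at = find_anchor(oriented_profile, anchors.downstream15, max_mismatch)
    rel = oriented_profile.rel
    informative = oriented_profile.informative
    for pos in range(anchor_at - 1, anchor_at - 1 - SCAN_CAP, -1):
        if pos < 0:
            return _window(oriented_profile, "reverse", 0, anchor_at, False)
        if informative[pos] and rel[pos, _A] >= TERMINATION_FRACTION:
            return _window(oriented_profile, "reverse", pos + 1, anchor_at, True)
    start = max(anchor_at - SCAN_CAP, 0)
    return _window(oriented_profile, "reverse", start, anchor_at, False)


@dataclass
class QCResult:
    flagged: bool
    message: str
    dirty_positions: int
    anchor_start: int | None


def flank_indel_check(
    profile: RelativeIntensityProfile,
    anchor: str,
    cfg: SignalConfig,
    anchor_start: int | None = None,
    max_mismatch: int = QC_MAX_MISMATCH,
) -> QCResult:
    """Screen an anchor window for heterozygous-indel interference.

    A heterozygous insertion/duplication/deletion elsewhere in the amplicon
    superposes a shifted copy of the sequence over the flank, so secondary
    peaks appear across the anchor.  If more than 3 of the 15 anchor
    positions show a second nucleotide besides the anchor base, the sample
    is flagged as unreliable (the tool does not attempt to deconvolve it).
    """
    if anchor_start is None:
        try:
            anchor_start = find_anchor(profile, anchor, max_mismatch)
        except (AnchorNotFoundError, AmbiguousAnchorError) as exc:
            return QCResult(True, f"flank anchor could not be located cleanly: {exc}", 15, None)
    dirty = 0
    for i, anchor_base in enumerate(anchor):
        pos = anchor_start + i
        if pos >= len(profile) or not profile.informative[pos]:
            continue
        for channel, base in enumerate("ACGT"):
            if base != anchor_base and profile.rel[pos, channel] >= cfg.presence_fraction:
                dirty += 1
                break
    if dirty > 3:
        return QCResult(
            True,
            "possible heterozygous indel in amplicon — results unreliable",
            dirty,
            anchor_start,
        )
    return QCResult(False, "", dirty, anchor_start)
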