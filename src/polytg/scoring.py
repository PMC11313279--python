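"""Genotype elimination and normalized-difference-score ranking.

For every candidate genotype the observed tract windows are compared with
the dual-aligned expected patterns.  Two stages:

Elimination
    A genotype is incompatible when, at any position where its expected set
    is a *single* base, that base's signal is confidently absent.  The check
    runs over the whole expected pattern: positions beyond the detected
    window are read from the chromatogram profile along the same frame
    (forward: rightward from the tract start; reverse: leftward from the
    downstream anchor), because a pattern longer than the true tract is
    contradicted precisely by the signal-free flank there.  {T,G} positions
    never eliminate, and observed-but-unexpected signal never eliminates —
    it only raises the score.

Scoring
    The normalized difference score over the nF + nR observed positions:

        D = sum_i [(OG_i - EG_i)^2 + (OT_i - ET_i)^2] / (2 (nF + nR))
            + (100 - mF - mR) / 1e5

    with expected intensities taken as 0 at observed positions beyond the
    expected length, uninformative positions contributing 0 to the sum while
    still counting in nF/nR, and the small additive term acting as a
    tie-break that favors longer expected tracts.  Lower is better.

Forward windows are compared left-aligned (both anchored at the tract 5'
end); reverse windows right-aligned (both anchored at the downstream
flank), indexed by distance from the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .abif import BASE_INDEX
from .detect import ObservedTract
from .errors import DegenerateObservationError, NoMatchingGenotypeError
from .model import (
    SET_G,
    SET_T,
    ExpectedTract,
    Genotype,
    SearchSpace,
    enumerate_genotypes,
    expected_pattern,
)
from .trace import SignalConfig

_T = BASE_INDEX["T"]
_G = BASE_INDEX["G"]

#: literals of the length-bonus term; part of the score's definition,
#: deliberately not user-adjustable
LENGTH_BONUS_OFFSET = 100
LENGTH_BONUS_SCALE = 1e5


@dataclass
class ScoringConfig:
    signal: SignalConfig = field(default_factory=SignalConfig)

    @property
    def length_bonus_offset(self) -> int:
        return LENGTH_BONUS_OFFSET

    @property
    def length_bonus_scale(self) -> float:
        return LENGTH_BONUS_SCALE


@dataclass
class GenotypeScore:
    genotype: Genotype
    eliminated: bool
    d: float | None
    rank: int | None
    position_diagnostics: dict | None = None


# ---------------------------------------------------------------------------
# frame extraction: observed values/presence along each direction's frame

def _forward_frame(obs: ObservedTract, cfg: SignalConfig, depth: int):
    """Observed OT/OG/flags for frame indices 0..depth-1 (left-aligned).

    Indices < nF come from the window; beyond it, the profile continues
    rightward from the tract start.  ``known`` marks positions where
    absence of a base could actually be asserted.
    """
    return _extract(obs, cfg, depth, [obs.start + j for j in range(depth)])


def _reverse_frame(obs: ObservedTract, cfg: SignalConfig, depth: int):
    """Observed values by distance d=1..depth from the downstream anchor."""
    return _extract(obs, cfg, depth, [obs.end - d for d in range(1, depth + 1)])


def _extract(obs: ObservedTract, cfg: SignalConfig, depth: int, positions):
    profile = obs.profile
    ot = np.zeros(depth)
    og = np.zeros(depth)
    informative = np.zeros(depth, dtype=bool)
    known = np.zeros(depth, dtype=bool)
    for k, pos in enumerate(positions):
        if 0 <= pos < len(profile) and profile.informative[pos]:
            ot[k] = profile.rel[pos, _T]
            og[k] = profile.rel[pos, _G]
            informative[k] = True
            known[k] = True
    present_t = known & (ot >= cfg.presence_fraction)
    present_g = known & (og >= cfg.presence_fraction)
    return ot, og, informative, known, present_t, present_g


# ---------------------------------------------------------------------------
# scalar reference implementations (per genotype)

def is_compatible(
    obs_f: ObservedTract,
    obs_r: ObservedTract,
    genotype: Genotype,
    patterns: tuple[ExpectedTract, ExpectedTract] | None = None,
    cfg: ScoringConfig | None = None,
) -> bool:
    cfg = cfg or ScoringConfig()
    if patterns is None:
        patterns = (expected_pattern(genotype, "forward"), expected_pattern(genotype, "reverse"))
    exp_f, exp_r = patterns
    for obs, exp, frame in ((obs_f, exp_f, _forward_frame), (obs_r, exp_r, _reverse_frame)):
        depth = exp.length
        _ot, _og, _inf, known, pres_t, pres_g = frame(obs, cfg.signal, depth)
        for j in range(depth):
            code = exp.codes[j] if exp.direction == "forward" else exp.codes[depth - 1 - j]
            if not known[j]:
                continue
            if code == SET_T and not pres_t[j]:
                return False
            if code == SET_G and not pres_g[j]:
                return False
    return True


def difference_score(
    obs_f: ObservedTract,
    obs_r: ObservedTract,
    exp_f: ExpectedTract,
    exp_r: ExpectedTract,
    cfg: ScoringConfig | None = None,
) -> float:
    """Evaluate the normalized difference score for one surviving genotype."""
    cfg = cfg or ScoringConfig()
    n_f, n_r = obs_f.length, obs_r.length
    if n_f + n_r == 0:
        raise DegenerateObservationError("no observed tract positions in either direction")
    numerator = 0.0
    for obs, exp in ((obs_f, exp_f), (obs_r, exp_r)):
        for i in range(obs.length):
            if not obs.informative_mask[i]:
                continue
            if exp.direction == "forward":
                j = i
            else:  # right-aligned: distance from anchor maps the frames
                j = exp.length - (obs.length - i)
            if 0 <= j < exp.length:
                et, eg = exp.et[j], exp.eg[j]
            else:  # observed beyond the expected length
                et = eg = 0.0
            numerator += (obs.og[i] - eg) ** 2 + (obs.ot[i] - et) ** 2
    m_f, m_r = exp_f.length, exp_r.length
    bonus = (LENGTH_BONUS_OFFSET - m_f - m_r) / LENGTH_BONUS_SCALE
    return numerator / (2.0 * (n_f + n_r)) + bonus


def position_diagnostics(
    obs: ObservedTract, exp: ExpectedTract, cfg: ScoringConfig | None = None
) -> list[dict]:
    """Per-position observed/expected comparison for reports and plots."""
    cfg = cfg or ScoringConfig()
    pf = cfg.signal.presence_fraction
    out = []
    for i in range(obs.length):
        if exp.direction == "forward":
            j = i
        else:
            j = exp.length - (obs.length - i)
        inside = 0 <= j < exp.length
        et = float(exp.et[j]) if inside else 0.0
        eg = float(exp.eg[j]) if inside else 0.0
        expected = exp.sets()[j] if inside else frozenset()
        if not obs.informative_mask[i]:
            status = "ignored"
        else:
            want_t, want_g = et > 0, eg > 0
            ok = (not want_t or obs.ot[i] >= pf) and (not want_g or obs.og[i] >= pf)
            unexpected = (not want_t and obs.ot[i] >= pf) or (not want_g and obs.og[i] >= pf)
            status = "match" if ok and not unexpected else "mismatch"
        out.append(
            {
                "position": i,
                "observed": {"T": float(obs.ot[i]), "G": float(obs.og[i])},
                "expected": {"T": et, "G": eg, "bases": "".join(sorted(expected))},
                "status": status,
            }
        )
    return out


# ---------------------------------------------------------------------------
# vectorized ranking over the whole search space

_MATRIX_CACHE: dict = {}


def _cached_matrices(space: SearchSpace, genotypes: list[Genotype], direction: str, depth: int):
    key = (space.min_t, space.max_t, space.min_tg, space.max_tg, direction, depth)
    if key not in _MATRIX_CACHE:
        if len(_MATRIX_CACHE) > 32:
            _MATRIX_CACHE.clear()
        _MATRIX_CACHE[key] = _pattern_matrices(genotypes, direction, depth)
    return _MATRIX_CACHE[key]


def _pattern_matrices(genotypes: list[Genotype], direction: str, depth: int):
    """Stack expected patterns into (G, depth) matrices in the comparison
    frame: forward indexed from the tract start, reverse by distance from
    the anchor (i.e. patterns reversed)."""
    n = len(genotypes)
    et = np.zeros((n, depth))
    eg = np.zeros((n, depth))
    is_t = np.zeros((n, depth), dtype=bool)
    is_g = np.zeros((n, depth), dtype=bool)
    lengths = np.zeros(n, dtype=int)
    for row, g in enumerate(genotypes):
        pat = expected_pattern(g, direction)
        codes = pat.codes if direction == "forward" else pat.codes[::-1]
        k = len(codes)
        lengths[row] = k
        et[row, :k] = pat.et if direction == "forward" else pat.et[::-1]
        eg[row, :k] = pat.eg if direction == "forward" else pat.eg[::-1]
        is_t[row, :k] = codes == SET_T
        is_g[row, :k] = codes == SET_G
    return et, eg, is_t, is_g, lengths


def rank_genotypes(
    obs_f: ObservedTract,
    obs_r: ObservedTract,
    space: SearchSpace | None = None,
    cfg: ScoringConfig | None = None,
) -> list[GenotypeScore]:
    """Enumerate, eliminate, score and rank the search space.

    Returns survivors first (rank 1..k, ascending score, ties broken by
    canonical genotype order), followed by eliminated genotypes with
    ``d=None``.  Raises :class:`NoMatchingGenotypeError` when nothing
    survives.
    """
    space = space or SearchSpace()
    cfg = cfg or ScoringConfig()
    genotypes = enumerate_genotypes(space)
    n_f, n_r = obs_f.length, obs_r.length
    if n_f + n_r == 0:
        raise DegenerateObservationError("no observed tract positions in either direction")
    depth = max(max(g.max_length for g in genotypes), n_f, n_r)

    d_total = np.zeros(len(genotypes))
    eliminated = np.zeros(len(genotypes), dtype=bool)
    for obs, direction, frame in (
        (obs_f, "forward", _forward_frame),
        (obs_r, "reverse", _reverse_frame),
    ):
        et, eg, is_t, is_g, lengths = _cached_matrices(space, genotypes, direction, depth)
        ot, og, informative, known, pres_t, pres_g = frame(obs, cfg.signal, depth)
        inside = np.arange(depth)[None, :] < lengths[:, None]
        # elimination: single-base expectation whose signal is absent
        absent_t = known & ~pres_t
        absent_g = known & ~pres_g
        eliminated |= np.any(inside & ((is_t & absent_t) | (is_g & absent_g)), axis=1)
        # score: observed positions only; E=0 beyond each pattern's length
        n_obs = obs.length
        in_window = (np.arange(depth) < n_obs) & informative
        diff = (ot[None, :] - np.where(inside, et, 0.0)) ** 2
        diff += (og[None, :] - np.where(inside, eg, 0.0)) ** 2
        d_total += np.sum(diff * in_window[None, :], axis=1)

    m = np.array([g.max_length for g in genotypes])  # mF == mR == max allele length
    d = d_total / (2.0 * (n_f + n_r)) + (LENGTH_BONUS_OFFSET - 2 * m) / LENGTH_BONUS_SCALE

    survivors = [i for i in range(len(genotypes)) if not eliminated[i]]
    if not survivors:
        raise NoMatchingGenotypeError(
            "every genotype in the search space is incompatible with the observation"
        )
    survivors.sort(key=lambda i: (d[i], genotypes[i].sort_key()))
    scores = [
        GenotypeScore(genotype=genotypes[i], eliminated=False, d=float(d[i]), rank=rank)
        for rank, i in enumerate(survivors, start=1)
    ]
    scores.extend(
        GenotypeScore(genotype=genotypes[i], eliminated=True, d=None, rank=None)
        for i in range(len(genotypes))
        if eliminated[i]
    )
    return scores
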