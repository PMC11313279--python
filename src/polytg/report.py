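"""End-to-end sample analysis, JSON reports and plots.

``run_sample`` never raises on the two reportable failure classes — an
undetectable tract or a fully eliminated search space become report
statuses (``tract_not_detected`` / ``no_matching_genotype``) so batch runs
keep going.  Reports use 1-based, inclusive positions (technologist-facing
convention); everything internal stays 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import detect, scoring
from .abif import read_abif
from .detect import FlankAnchors, ObservedTract
from .errors import (
    AmbiguousAnchorError,
    AnchorNotFoundError,
    DegenerateObservationError,
    NoMatchingGenotypeError,
)
from .model import SearchSpace, expected_pattern, informative_positions
from .scoring import GenotypeScore, ScoringConfig
from .trace import RelativeIntensityProfile, SignalConfig, orient_reverse, relative_intensities

STATUS_OK = "ok"
STATUS_TRACT_NOT_DETECTED = "tract_not_detected"
STATUS_NO_MATCHING_GENOTYPE = "no_matching_genotype"

EXIT_CODES = {STATUS_OK: 0, STATUS_TRACT_NOT_DETECTED: 2, STATUS_NO_MATCHING_GENOTYPE: 3}

#: how many ranked genotypes the JSON report tabulates
MAX_REPORTED = 25


@dataclass
class AnalysisParams:
    space: SearchSpace = field(default_factory=SearchSpace)
    signal: SignalConfig = field(default_factory=SignalConfig)
    anchor_max_mismatch: int = detect.DEFAULT_MAX_MISMATCH

    def to_dict(self) -> dict:
        return {
            "search_space": vars(self.space),
            "min_total_signal": self.signal.min_total_signal,
            "presence_fraction": self.signal.presence_fraction,
            "anchor_max_mismatch": self.anchor_max_mismatch,
        }


@dataclass
class SampleReport:
    sample_id: str
    status: str
    inputs: dict
    parameters: dict
    detection: dict
    ranked: list[dict]
    informative_positions: dict
    n_survivors: int
    n_eliminated: int
    warnings: list[str]

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "status": self.status,
            "inputs": self.inputs,
            "parameters": self.parameters,
            "detection": self.detection,
            "ranked_genotypes": self.ranked,
            "informative_positions": self.informative_positions,
            "n_survivors": self.n_survivors,
            "n_eliminated": self.n_eliminated,
            "warnings": self.warnings,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    """Everything a caller might want after one sample: the public report
    plus the intermediate objects needed for plotting."""

    report: SampleReport
    profile_forward: RelativeIntensityProfile | None = None
    profile_reverse: RelativeIntensityProfile | None = None  # oriented
    tract_forward: ObservedTract | None = None
    tract_reverse: ObservedTract | None = None
    scores: list[GenotypeScore] | None = None

    @property
    def survivors(self) -> list[GenotypeScore]:
        return [s for s in (self.scores or []) if not s.eliminated]


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _tract_summary(tract: ObservedTract | None) -> dict | None:
    if tract is None:
        return None
    return {
        "start": int(tract.start) + 1,  # 1-based for the report
        "length": int(tract.length),
        "fully_detected": bool(tract.fully_detected),
        "informative_positions_in_window": int(tract.informative_mask.sum()),
    }


def run_sample(forward_path, reverse_path, params: AnalysisParams | None = None,
               sample_id: str | None = None) -> PipelineResult:
    """Run the full pipeline on one bidirectional sample.

    I/O errors propagate; the two analysis failure classes become report
    statuses with the corresponding message.
    """
    params = params or AnalysisParams()
    sample_id = sample_id or Path(forward_path).stem
    inputs = {
        "forward": {"path": str(forward_path), "sha256": _sha256(forward_path)},
        "reverse": {"path": str(reverse_path), "sha256": _sha256(reverse_path)},
    }
    anchors = FlankAnchors()
    cfg = ScoringConfig(signal=params.signal)
    warnings: list[str] = []

    fwd = read_abif(forward_path, direction="forward")
    rev = read_abif(reverse_path, direction="reverse")
    profile_f = relative_intensities(fwd, params.signal)
    profile_r = orient_reverse(relative_intensities(rev, params.signal))
    result = PipelineResult(report=None, profile_forward=profile_f, profile_reverse=profile_r)

    def finish(status, detection, ranked=None, info=None, n_surv=0, n_elim=0):
        result.report = SampleReport(
            sample_id=sample_id,
            status=status,
            inputs=inputs,
            parameters=params.to_dict(),
            detection=detection,
            ranked=ranked or [],
            informative_positions=info or {"forward": [], "reverse": []},
            n_survivors=n_surv,
            n_eliminated=n_elim,
            warnings=warnings,
        )
        return result

    try:
        tract_f = detect.detect_forward_tract(
            profile_f, anchors, params.signal, params.anchor_max_mismatch
        )
        tract_r = detect.detect_reverse_tract(
            profile_r, anchors, params.signal, params.anchor_max_mismatch
        )
    except (AnchorNotFoundError, AmbiguousAnchorError) as exc:
        warnings.append(str(exc))
        return finish(
            STATUS_TRACT_NOT_DETECTED,
            {"forward": None, "reverse": None, "error": "unable to detect the (TG)mTn tract"},
        )
    result.tract_forward, result.tract_reverse = tract_f, tract_r

    for tract, name in ((tract_f, "forward"), (tract_r, "reverse")):
        if not tract.fully_detected:
            warnings.append(
                f"(TG)mTn tract only partially detected in the {name} chromatogram — "
                "results may be unreliable"
            )
    qc_f = detect.flank_indel_check(
        profile_f, anchors.upstream15, params.signal, anchor_start=tract_f.start - 15
    )
    qc_r = detect.flank_indel_check(
        profile_r, anchors.downstream15, params.signal, anchor_start=tract_r.end
    )
    for qc, name in ((qc_f, "forward/upstream"), (qc_r, "reverse/downstream")):
        if qc.flagged:
            warnings.append(f"{name} flank: {qc.message}")

    detection = {"forward": _tract_summary(tract_f), "reverse": _tract_summary(tract_r)}
    try:
        scores = scoring.rank_genotypes(tract_f, tract_r, params.space, cfg)
    except (NoMatchingGenotypeError, DegenerateObservationError) as exc:
        warnings.append(str(exc))
        detection["error"] = "unable to find a matching (TG)mTn genotype"
        return finish(STATUS_NO_MATCHING_GENOTYPE, detection)
    result.scores = scores

    survivors = [s for s in scores if not s.eliminated]
    n_elim = len(scores) - len(survivors)
    patterns_f = [expected_pattern(s.genotype, "forward") for s in survivors]
    patterns_r = [expected_pattern(s.genotype, "reverse") for s in survivors]
    info = {
        "forward": sorted(p + 1 for p in informative_positions(patterns_f, "forward")),
        "reverse": sorted(p + 1 for p in informative_positions(patterns_r, "reverse")),
    }
    ranked = [
        {"rank": s.rank, "genotype": s.genotype.label, "d": s.d}
        for s in survivors[:MAX_REPORTED]
    ]
    return finish(STATUS_OK, detection, ranked, info, len(survivors), n_elim)


def render_plot(result: PipelineResult, genotype_index: int, out_path) -> Path:
    """Plot observed relative intensities with the expected pattern letters
    for the survivor at ``genotype_index`` (0 = best fit).

    One panel per direction: the four channels across the tract +/- 15 bp,
    expected T/G/T-or-G letters beneath, informative positions shaded.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.report.status != STATUS_OK:
        raise ValueError(f"cannot plot a sample with status {result.report.status!r}")
    survivors = result.survivors
    if not 0 <= genotype_index < len(survivors):
        raise IndexError(
            f"genotype_index {genotype_index} out of range (have {len(survivors)} survivors)"
        )
    score = survivors[genotype_index]
    colors = {"A": "tab:green", "C": "tab:blue", "G": "black", "T": "tab:red"}

    fig, axes = plt.subplots(2, 1, figsize=(12, 6), sharex=False)
    panels = (
        ("forward", result.profile_forward, result.tract_forward),
        ("reverse", result.profile_reverse, result.tract_reverse),
    )
    for ax, (direction, profile, tract) in zip(axes, panels):
        exp = expected_pattern(score.genotype, direction)
        lo = max(tract.start - 15, 0)
        hi = min(tract.end + 15, len(profile))
        xs = range(lo, hi)
        for base, color in colors.items():
            ax.plot(xs, profile.rel[lo:hi, "ACGT".index(base)], color=color, lw=1.2, label=base)
        shaded = result.report.informative_positions[direction]
        # expected letters under the window
        letters = {"T": "T", "G": "G", "GT": "T/G"}
        for i in range(tract.length):
            j = i if direction == "forward" else exp.length - (tract.length - i)
            if 0 <= j < exp.length:
                text = letters["".join(sorted(exp.sets()[j]))]
                ax.text(tract.start + i, -0.12, text, ha="center", fontsize=7)
        # informative positions, converted from the padded alignment frame
        pad_len = max((expected_pattern(s.genotype, direction).length for s in survivors),
                      default=exp.length)
        for pos1 in shaded:
            j = pos1 - 1
            profile_pos = (tract.start + j if direction == "forward"
                           else tract.end - (pad_len - j))
            if lo <= profile_pos < hi:
                ax.axvspan(profile_pos - 0.5, profile_pos + 0.5, color="tab:blue", alpha=0.15)
        ax.axvspan(tract.start - 0.5, tract.end - 0.5, color="gray", alpha=0.08)
        ax.set_ylim(-0.2, 1.05)
        ax.set_ylabel("relative intensity")
        ax.set_title(f"{direction} chromatogram")
    axes[0].legend(ncol=4, loc="upper right", fontsize=8)
    axes[1].set_xlabel("profile position (0-based)")
    fig.suptitle(
        f"{result.report.sample_id}: {score.genotype.label} — rank {score.rank}, D = {score.d:.6g}"
    )
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


def run_batch(manifest_path, out_dir, params: AnalysisParams | None = None) -> Path:
    """Analyze a 3-column manifest (sample id, forward path, reverse path;
    TSV, '#' comments) and write one JSON per sample plus a summary TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for line in Path(manifest_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"manifest line needs 3 tab-separated fields: {line!r}")
        rows.append(parts)
    summary_lines = ["sample_id\tstatus\trank1_genotype\trank1_d\tn_warnings"]
    for sample_id, fwd, rev in rows:
        result = run_sample(fwd, rev, params, sample_id=sample_id)
        report = result.report
        (out_dir / f"{sample_id}.json").write_text(report.to_json() + "\n")
        top = report.ranked[0] if report.ranked else {"genotype": "", "d": ""}
        summary_lines.append(
            f"{sample_id}\t{report.status}\t{top['genotype']}\t{top['d']}\t{len(report.warnings)}"
        )
    summary = out_dir / "summary.tsv"
    summary.write_text("\n".join(summary_lines) + "\n")
    return summary
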