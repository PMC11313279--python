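"""Seeded bidirectional chromatogram simulator.

Renders each allele's full template (5' context + tract + 3' context) as a
train of Gaussian peaks at uniform spacing and superposes the two allele
traces anchored at the read's 5' end — both alleles share the
primer-proximal sequence, so heterozygous length differences put the distal
sequence out of register and produce the overlapping-peak phenomenology
that makes these chromatograms hard to read.  Channel bleed-through and
additive Gaussian baseline noise are optional.  The rendering is
deliberately idealized (uniform spacing, symmetric peaks, no mobility
shifts or quality decay): the pipeline consumes peak-sampled relative
intensities, so richer trace physics would add no test power.

Determinism: identical specs and seeds produce byte-identical ABIF files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import reference
from .abif import BASES, ChromatogramRead, write_abif
from .errors import InvalidSpecError
from .model import Genotype, allele_sequence, parse_genotype
from .trace import reverse_complement

# spectral leakage: each channel bleeds into one designated other channel
# (thymine into guanine and vice versa, mimicking the G-under-T shoulders
# seen in real traces; A/C likewise)
BLEED_TARGET = {"A": "C", "C": "A", "G": "T", "T": "G"}


@dataclass
class SimulationSpec:
    """Ground truth and rendering parameters for one simulated sample.

    Defaults emulate a clean clinical run: full-amplicon contexts from the
    packaged reference, 12 trace points per base, peak sigma 3 points,
    1000-unit total amplitude (split half per allele), no noise or bleed.
    ``extra_duplication=(offset, length)`` superposes a copy of the second
    haplotype carrying a tandem duplication of the ``length`` bases ending
    at template ``offset`` — the heterozygous-indel interference case.
    """

    genotype: Genotype | str
    context_5p: str | None = None
    context_3p: str | None = None
    peak_spacing: int = 12
    peak_sigma: float = 3.0
    amplitude: float = 1000.0
    noise_sd: float = 0.0
    bleed_through: float = 0.0
    seed: int = 0
    extra_duplication: tuple[int, int] | None = None

    def __post_init__(self):
        if isinstance(self.genotype, str):
            self.genotype = parse_genotype(self.genotype)
        if self.context_5p is None:
            self.context_5p = reference.LAYOUT.context_5p
        if self.context_3p is None:
            self.context_3p = reference.LAYOUT.context_3p
        if self.peak_spacing <= 2 * self.peak_sigma:
            raise InvalidSpecError("peak_spacing must exceed 2 * peak_sigma")
        if self.amplitude <= 0:
            raise InvalidSpecError("amplitude must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if not 0.0 <= self.bleed_through < 0.5:
            raise InvalidSpecError("bleed_through must be in [0, 0.5)")

    def templates(self) -> list[str]:
        """Per-haplotype template sequences on the genomic forward strand."""
        out = []
        for which, allele in enumerate((self.genotype.allele_a, self.genotype.allele_b)):
            t = self.context_5p + allele_sequence(allele) + self.context_3p
            if self.extra_duplication is not None and which == 1:
                offset, length = self.extra_duplication
                if not 0 < length <= offset <= len(t):
                    raise InvalidSpecError("extra_duplication outside the template")
                t = t[:offset] + t[offset - length : offset] + t[offset:]
            out.append(t)
        return out


def simulate_read(spec: SimulationSpec, direction: str) -> ChromatogramRead:
    """Render one direction's chromatogram for the spec's genotype."""
    if direction not in ("forward", "reverse"):
        raise InvalidSpecError(f"direction must be forward/reverse, got {direction!r}")
    templates = spec.templates()
    if direction == "reverse":
        templates = [reverse_complement(t) for t in templates]

    spacing, sigma = spec.peak_spacing, spec.peak_sigma
    n_calls = max(len(t) for t in templates)
    centers = spacing + spacing * np.arange(n_calls)
    trace_len = int(centers[-1] + spacing)

    # kernel support stops one point short of the next peak center, so a
    # peak contributes exactly zero at its neighbors' sampled centers and a
    # noiseless read yields exact relative intensities (0, 0.5, 1)
    half = min(int(np.ceil(4 * sigma)), spacing - 1)
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    traces = np.zeros((4, trace_len + 2 * half))  # padded; trimmed below
    amp = spec.amplitude / 2.0
    for template in templates:
        for j, base in enumerate(template):
            c = int(centers[j]) + half
            traces[BASES.index(base), c - half : c + half + 1] += amp * kernel
    traces = traces[:, half : half + trace_len]

    if spec.bleed_through > 0:
        clean = traces.copy()
        for src, dst in BLEED_TARGET.items():
            traces[BASES.index(dst)] += spec.bleed_through * clean[BASES.index(src)]

    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 0 if direction == "forward" else 1])
        traces = traces + rng.normal(0.0, spec.noise_sd, size=traces.shape)

    traces = np.rint(np.clip(traces, 0.0, None)).astype(np.int64)
    sampled = traces[:, centers]
    called = "".join(BASES[int(k)] for k in np.argmax(sampled, axis=0))
    return ChromatogramRead(
        sample_name=f"{spec.genotype.label} {direction} seed={spec.seed}",
        direction=direction,
        called_bases=called,
        peak_locations=centers,
        traces={b: traces[i] for i, b in enumerate(BASES)},
    )


def _slug(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9-]+", "", label.replace("/", "-")) or "sample"


def simulate_sample(spec: SimulationSpec, out_dir) -> tuple[Path, Path]:
    """Write the forward and reverse chromatograms as .ab1 files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    label = _slug(spec.genotype.label)
    paths = []
    for direction, tag in (("forward", "F"), ("reverse", "R")):
        read = simulate_read(spec, direction)
        path = out_dir / f"{label}_s{spec.seed}_{tag}.ab1"
        write_abif(read, path)
        paths.append(path)
    return tuple(paths)
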