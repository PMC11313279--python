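"""Packaged reference amplicon, flank anchor constants and in-silico PCR.

The bundled region is a SYNTHETIC stand-in for the primer-to-primer CFTR
intron 9-exon 10 junction amplicon (no genomic download is performed): the
published PCR primers sit at its ends, a (TG)11T7 reference tract in the
middle, and the fixed 15 bp flank anchors immediately around the tract.
The interior padding is generated, not genomic — see the FASTA header and
docs/methods.md for the construction constraints.  Everything the pipeline
relies on (anchor uniqueness, tract-terminating flank composition, 427 bp
product size) is asserted at import.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from Bio import SeqIO

from .trace import reverse_complement

FORWARD_PRIMER = "CCATGTGCTTTTCAAACTAATTG"
REVERSE_PRIMER = "CCAAAAATACCTTCCAGCACTACA"
EXPECTED_AMPLICON_SIZE = 427

UPSTREAM_FLANK = "CTGGCACAACCACCA"  # 15 bp immediately 5' of the TG repeat
DOWNSTREAM_FLANK = "AACAGCAAGGAAGCA"  # 15 bp immediately 3' of the poly-T run
REFERENCE_TRACT = "TG" * 11 + "T" * 7


def _load_amplicon() -> str:
    data = resources.files("polytg.data") / "synthetic_reference_amplicon.fasta"
    with resources.as_file(data) as path:
        record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


AMPLICON = _load_amplicon()


def locate_amplicon(template: str, forward_primer: str = FORWARD_PRIMER,
                    reverse_primer: str = REVERSE_PRIMER) -> tuple[int, int]:
    """In-silico PCR: locate the primer pair on ``template`` and return the
    half-open product bounds (forward primer start, end of the reverse
    primer's reverse complement)."""
    fwd_at = template.find(forward_primer)
    if fwd_at < 0 or template.find(forward_primer, fwd_at + 1) >= 0:
        raise ValueError("forward primer must match the template exactly once")
    rc_rev = reverse_complement(reverse_primer)
    rev_at = template.find(rc_rev, fwd_at)
    if rev_at < 0 or template.find(rc_rev, rev_at + 1) >= 0:
        raise ValueError("reverse primer must match the template exactly once")
    return fwd_at, rev_at + len(rc_rev)


def amplicon_size(template: str = AMPLICON) -> int:
    start, end = locate_amplicon(template)
    return end - start


@dataclass(frozen=True)
class ReferenceLayout:
    """Coordinates of the tract and its contexts within the amplicon."""

    tract_start: int
    tract_end: int

    @property
    def context_5p(self) -> str:
        return AMPLICON[: self.tract_start]

    @property
    def context_3p(self) -> str:
        return AMPLICON[self.tract_end :]


def _layout() -> ReferenceLayout:
    anchor_block = UPSTREAM_FLANK + REFERENCE_TRACT + DOWNSTREAM_FLANK
    at = AMPLICON.find(anchor_block)
    if at < 0 or AMPLICON.find(anchor_block, at + 1) >= 0:
        raise AssertionError("packaged amplicon does not contain the expected tract block once")
    return ReferenceLayout(tract_start=at + 15, tract_end=at + 15 + len(REFERENCE_TRACT))


LAYOUT = _layout()

# flank invariants: anchors must not ambiguously extend the tract
assert len(UPSTREAM_FLANK) == 15 and len(DOWNSTREAM_FLANK) == 15
assert not UPSTREAM_FLANK.endswith("TG"), "upstream flank would extend the TG repeat"
assert not DOWNSTREAM_FLANK.startswith("TT"), "downstream flank would extend the poly-T run"
assert amplicon_size() == EXPECTED_AMPLICON_SIZE
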