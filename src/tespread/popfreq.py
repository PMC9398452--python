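"""TE presence/absence calling in population strains and frequency classes.

For each annotated TE and each population strain, reads near the insertion
site are assembled (externally) into contigs and aligned back to the focal
assembly.  The geometry of those contig alignments determines the call:

* absent — a single contig spans continuously from at least 20 bp upstream
  of the TE to at least 20 bp downstream (the strain carries the empty
  site);
* present — (a) two separate contigs span the start and end boundaries
  respectively, each reaching at least 30 bp inside the TE and 20 bp
  outside it with at least 50 bp aligned in total, or (b) one such boundary
  contig plus one contig aligned wholly within the TE;
* missing — none of the criteria are met (or the evidence is
  contradictory).

A TE present in the focal strain but absent from every population strain
with a usable call is a singleton and classed as low population frequency;
presence in at least one population strain makes it high frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

ABSENT, PRESENT, MISSING = "absent", "present", "missing"
LOW, HIGH, UNKNOWN = "low", "high", "unknown"


@dataclass(frozen=True)
class ContigAlignment:
    """One contig-to-assembly alignment near a TE (0-based, half-open)."""

    contig_id: str
    chrom: str
    start: int
    end: int
    contig_start: int = 0
    contig_end: int = 0
    orientation: str = "+"

    def __post_init__(self):
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"contig {self.contig_id}: invalid target span")

    @property
    def aligned_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CallParams:
    span_pad: int = 20     # bp beyond both TE edges for the absence rule
    inside_min: int = 30   # bp inside the TE for a boundary contig
    outside_min: int = 20  # bp outside the TE for a boundary contig
    total_min: int = 50    # minimum total aligned length of a boundary contig


@dataclass(frozen=True)
class PopulationCall:
    te_id: str
    strain: str
    state: str
    evidence: tuple[str, ...] = ()


def call_te_state(
    alignments: Sequence[ContigAlignment],
    te_start: int,
    te_end: int,
    params: CallParams = CallParams(),
) -> tuple[str, tuple[str, ...]]:
    """State of one (TE, strain) pair from nearby contig alignments.

    Returns (state, evidence codes).  If both the absence and a presence
    criterion are satisfied by different contigs the evidence is
    contradictory and the call is missing.
    """
    absent_contigs = []
    start_boundary = []
    end_boundary = []
    internal = []
    for aln in alignments:
        if aln.start <= te_start - params.span_pad and aln.end >= te_end + params.span_pad:
            absent_contigs.append(aln.contig_id)
            continue
        # start boundary: crosses te_start with enough bases on both sides
        if (
            aln.start <= te_start - params.outside_min
            and aln.end >= te_start + params.inside_min
            and aln.aligned_length >= params.total_min
        ):
            start_boundary.append(aln.contig_id)
        if (
            aln.end >= te_end + params.outside_min
            and aln.start <= te_end - params.inside_min
            and aln.aligned_length >= params.total_min
        ):
            end_boundary.append(aln.contig_id)
        if aln.start >= te_start and aln.end <= te_end:
            internal.append(aln.contig_id)

    # criterion (a) requires two distinct contigs, one per boundary
    two_boundaries = any(c1 != c2 for c1 in start_boundary for c2 in end_boundary)
    one_boundary_plus_internal = bool((start_boundary or end_boundary) and internal)
    is_present = two_boundaries or one_boundary_plus_internal
    is_absent = bool(absent_contigs)

    if is_absent and is_present:
        return MISSING, ("contradictory",)
    if is_absent:
        return ABSENT, tuple(f"span:{c}" for c in absent_contigs)
    if is_present:
        ev = tuple(
            [f"start:{c}" for c in start_boundary]
            + [f"end:{c}" for c in end_boundary]
            + [f"internal:{c}" for c in internal]
        )
        return PRESENT, ev
    return MISSING, ()


def classify_frequency(
    calls: Sequence[PopulationCall], focal_present: bool = True
) -> str:
    """Population frequency class of a focal-strain TE.

    low — absent in every population strain with a non-missing call
    (singleton, only found in the focal genome); high — present in at least
    one population strain; unknown — every population call is missing.
    """
    if not focal_present:
        raise ValueError("frequency classes are defined for TEs carried by the focal strain")
    states = [c.state for c in calls]
    if any(s == PRESENT for s in states):
        return HIGH
    if any(s == ABSENT for s in states):
        return LOW
    return UNKNOWN
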