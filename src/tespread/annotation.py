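"""TE annotation post-processing: family assignment, merging, filtering.

Raw repeat calls (from a de novo repeat annotator run externally) are turned
into the analysis-ready TE set by a fixed rule set:

* iterative family assignment from alignment-hit tables — a TE joins a
  family only when at least 80% of its covered query bases hit one and only
  one family; newly assigned TEs enter the reference set for the next round
  (four rounds in total by default);
* same-family insertions within 500 bp are merged into one record, while
  different-family insertions within 500 bp are both discarded (ambiguous
  boundaries); DINE-1 and the telomeric families HeT-A/TART/TAHRE are
  dropped outright;
* records shorter than 500 bp or outside the supplied euchromatin intervals
  are removed;
* a TE is full-length when its span covers at least 70% of its family's
  canonical sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

EXCLUDED_FAMILIES = frozenset({"DINE-1", "HeT-A", "TART", "TAHRE"})

FAMILY_COVERAGE_FRACTION = 0.8
DEFAULT_MERGE_GAP = 500
DEFAULT_MIN_LENGTH = 500
FULL_LENGTH_FRACTION = 0.7


@dataclass(frozen=True)
class TeRecord:
    """One annotated euchromatic TE (0-based, half-open coordinates)."""

    te_id: str
    chrom: str
    start: int
    end: int
    te_class: str = "unknown"  # TIR/DNA, LTR, non-LTR/LINE, unknown
    family: str | None = None
    full_length: str = "unknown"  # full, truncated, unknown
    location_category: str = "intergenic"  # intergenic, intronic, exonic

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"TE {self.te_id}: end must exceed start")


def assign_families(
    hits: pd.DataFrame,
    rounds: int = 4,
    min_fraction: float = FAMILY_COVERAGE_FRACTION,
    reference_families: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Iterative one-and-only-one family assignment.

    ``hits`` is an outfmt-6-like table with columns ``query`` (TE id),
    ``subject`` (either a family name, or a TE id previously assigned —
    hits to assigned TEs vote for that TE's family), ``qstart``/``qend``
    (aligned query interval, 0-based half-open).  Rows are assumed
    pre-filtered at the aligner's e-value / identity thresholds.

    Per round, a TE is assigned iff >= ``min_fraction`` of its covered query
    bases (union over all usable hits) map to a single family; otherwise it
    stays unassigned and is retried next round, when hits to newly assigned
    TEs become usable.  Returns {te_id: family}.
    """
    assigned: dict[str, str] = {}
    ref = dict(reference_families or {})
    query_ids = set(hits["query"])
    for _ in range(rounds):
        newly: dict[str, str] = {}
        for te_id, sub in hits.groupby("query"):
            if te_id in assigned:
                continue
            per_family: dict[str, list[tuple[int, int]]] = {}
            for subject, qstart, qend in zip(sub["subject"], sub["qstart"], sub["qend"]):
                if subject in ref:
                    family = ref[subject]
                elif subject in assigned:
                    family = assigned[subject]
                elif subject in query_ids:
                    # hit to a still-unassigned TE carries no family vote yet
                    continue
                else:
                    family = subject
                per_family.setdefault(family, []).append((int(qstart), int(qend)))
            if not per_family:
                continue
            cover = {fam: _union_length(iv) for fam, iv in per_family.items()}
            total = _union_length([iv for ivs in per_family.values() for iv in ivs])
            if total == 0:
                continue
            best_family, best = max(cover.items(), key=lambda kv: kv[1])
            if best / total >= min_fraction:
                newly[te_id] = best_family
        if not newly:
            break
        assigned.update(newly)
    return assigned


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    ivs = sorted(intervals)
    total = 0
    cur_start = cur_end = None
    for s, e in ivs:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def merge_and_resolve(tes: Sequence[TeRecord], gap: int = DEFAULT_MERGE_GAP) -> list[TeRecord]:
    """Merge same-family neighbours, drop ambiguous and excluded families.

    TEs are processed left-to-right per chromosome.  Two consecutive records
    with inter-record gap <= ``gap``: merged into one spanning record if
    they share a family; both dropped if their families differ.  Chains are
    resolved greedily left-to-right.  DINE-1 and telomeric families are
    removed first.
    """
    kept = [t for t in tes if t.family not in EXCLUDED_FAMILIES]
    out: list[TeRecord] = []
    by_chrom: dict[str, list[TeRecord]] = {}
    for t in sorted(kept, key=lambda t: (t.chrom, t.start, t.end)):
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom_tes in by_chrom.values():
        i = 0
        while i < len(chrom_tes):
            cur = chrom_tes[i]
            dropped = False
            j = i + 1
            while j < len(chrom_tes) and chrom_tes[j].start - cur.end <= gap:
                nxt = chrom_tes[j]
                if nxt.family == cur.family and cur.family is not None:
                    cur = replace(cur, end=max(cur.end, nxt.end))
                    j += 1
                else:
                    # ambiguous adjacency: discard the whole conflicting pair
                    j += 1
                    dropped = True
                    break
            if not dropped:
                out.append(cur)
            i = j
    return sorted(out, key=lambda t: (t.chrom, t.start))


def filter_tes(
    tes: Sequence[TeRecord],
    boundaries: pd.DataFrame | None,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[TeRecord]:
    """Retain TEs >= min_length fully inside the euchromatin intervals.

    ``boundaries`` is a BED-like frame (chrom, start, end) of euchromatic
    intervals; it is a required input because heterochromatin boundaries are
    delineated upstream of this pipeline.
    """
    if boundaries is None:
        raise ValueError("euchromatin boundary intervals are required")
    iv_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in zip(boundaries["chrom"], boundaries["start"], boundaries["end"]):
        iv_by_chrom.setdefault(chrom, []).append((int(s), int(e)))
    out = []
    for t in tes:
        if t.length < min_length:
            continue
        if any(s <= t.start and t.end <= e for s, e in iv_by_chrom.get(t.chrom, [])):
            out.append(t)
    return out


def classify_length(
    te: TeRecord,
    canonical_lengths: Mapping[str, float],
    threshold: float = FULL_LENGTH_FRACTION,
) -> str:
    """'full' iff the TE covers >= threshold of its family's canonical length."""
    if te.family is None or te.family not in canonical_lengths:
        return "unknown"
    return "full" if te.length >= threshold * canonical_lengths[te.family] else "truncated"


def classify_location(te: TeRecord, genes: Sequence, exons: pd.DataFrame | None = None) -> str:
    """exonic > intronic > intergenic against a gene annotation.

    ``exons`` is an optional (chrom, start, end) frame; without it, any
    overlap with a gene span counts as intronic.
    """
    if exons is not None:
        sub = exons[exons["chrom"] == te.chrom]
        if ((sub["start"] < te.end) & (te.start < sub["end"])).any():
            return "exonic"
    for g in genes:
        if g.chrom == te.chrom and g.start < te.end and te.start < g.end:
            return "intronic"
    return "intergenic"
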