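"""Per-TE magnitude and extent of H3K9me2 enrichment.

The epigenetic effect of an individual euchromatic TE is quantified from
the HMD track in its flanks:

* local background: median of the non-missing 25-bp HMD values pooled from
  20-40 kb upstream and downstream of the TE (far enough that spreading,
  which dies off within ~10 kb, does not contaminate it);
* m-HMD: per 1-kb flanking window (20 windows per side, anchored at the TE
  boundary and stepping outward), the median of its 40 background-normalized
  25-bp units; windows with fewer than 10 non-missing units are missing;
* magnitude: mean of the two first-window m-HMDs (one side alone if the
  other is missing) — m-HMD 1 means no enrichment above background;
* extent: number of consecutive windows, starting at the window touching
  the TE, with m-HMD above 1; per-TE extent is the mean of the two sides,
  capped at 20 kb.

Estimates are computed per ChIP replicate and then averaged per TE.  For
species with two assembled strains a two-genome variant standardizes the
focal-strain m-HMD by the m-HMD at the homologous TE-free sequence in the
alternative strain instead of by the local background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import TeRecord
from .hmd import HmdTrack

N_WINDOWS = 20
WINDOW_BP = 1000
MIN_UNITS = 10
BACKGROUND_INNER = 20_000
BACKGROUND_OUTER = 40_000
EXTENT_THRESHOLD = 1.0


@dataclass
class TeEffect:
    """Magnitude and extent of one TE's H3K9me2 enrichment (one replicate)."""

    te_id: str
    replicate: str = "rep1"
    background: float | None = None
    mhmd_left: np.ndarray | None = None   # window 1 = touching the TE
    mhmd_right: np.ndarray | None = None
    magnitude: float | None = None
    extent_left: float | None = None
    extent_right: float | None = None
    extent: float | None = None
    excluded: str | None = None


@dataclass(frozen=True)
class SideAsymmetry:
    """Normalized intergenic-minus-genic side difference for one TE."""

    te_id: str
    intergenic_side: float
    genic_side: float
    z: float


def local_background(
    track: HmdTrack,
    te: TeRecord,
    inner: int = BACKGROUND_INNER,
    outer: int = BACKGROUND_OUTER,
) -> float | None:
    """Median HMD over 20-40 kb up- and downstream, pooled; None if empty.

    Regions running off a chromosome end are truncated; if one side is
    entirely off-chromosome the median uses the available side alone.
    """
    bs = track.bin_size
    sb, eb = te.start // bs, -(-te.end // bs)
    left = track.valid_values(sb - outer // bs, sb - inner // bs)
    right = track.valid_values(eb + inner // bs, eb + outer // bs)
    pooled = np.concatenate([left, right])
    if len(pooled) == 0:
        return None
    return float(np.median(pooled))


def window_mhmd(
    track: HmdTrack,
    te: TeRecord,
    side: str,
    background: float,
    n_windows: int = N_WINDOWS,
    min_units: int = MIN_UNITS,
) -> np.ndarray:
    """Per-1-kb m-HMD values for one side, window 1 touching the TE.

    Returns an array of length ``n_windows`` with NaN for missing windows
    (fewer than ``min_units`` non-missing 25-bp units, or windows truncated
    by the chromosome end).
    """
    if background is None or not background > 0:
        raise ValueError("background must be a positive number")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    bs = track.bin_size
    per_window = WINDOW_BP // bs
    out = np.full(n_windows, np.nan)
    for k in range(1, n_windows + 1):
        if side == "left":
            hi = te.start // bs - (k - 1) * per_window
            lo = hi - per_window
        else:
            lo = -(-te.end // bs) + (k - 1) * per_window
            hi = lo + per_window
        if lo < 0 or hi > track.n_bins:
            continue  # partial terminal windows are dropped
        vals = track.valid_values(lo, hi)
        if len(vals) >= min_units:
            out[k - 1] = np.median(vals) / background
    return out


def magnitude(mhmd_left: np.ndarray, mhmd_right: np.ndarray) -> float | None:
    """Mean of the two first-window m-HMDs; one side alone if the other is missing."""
    firsts = [w[0] for w in (mhmd_left, mhmd_right) if len(w) and not math.isnan(w[0])]
    if not firsts:
        return None
    return float(np.mean(firsts))


def extent(
    mhmd: np.ndarray, threshold: float = EXTENT_THRESHOLD, cap: int = N_WINDOWS
) -> float | None:
    """Consecutive-run length (kb) of windows with m-HMD above threshold.

    The run starts at window 1 and stops at the first window at or below
    the threshold; a missing first window makes the side unestimable.
    Missing windows further out also terminate the run.
    """
    if len(mhmd) == 0 or math.isnan(mhmd[0]):
        return None
    run = 0
    for v in mhmd[:cap]:
        if math.isnan(v) or v <= threshold:
            break
        run += 1
    return float(run)


def te_effect(
    track: HmdTrack,
    te: TeRecord,
    replicate: str = "rep1",
    threshold: float = EXTENT_THRESHOLD,
    min_units: int = MIN_UNITS,
) -> TeEffect:
    """Single-genome magnitude and extent of one TE in one replicate."""
    bg = local_background(track, te)
    if bg is None or bg <= 0:
        return TeEffect(te.te_id, replicate, excluded="background unestimable")
    left = window_mhmd(track, te, "left", bg, min_units=min_units)
    right = window_mhmd(track, te, "right", bg, min_units=min_units)
    mag = magnitude(left, right)
    e_l = extent(left, threshold)
    e_r = extent(right, threshold)
    sides = [e for e in (e_l, e_r) if e is not None]
    ext = float(np.mean(sides)) if sides else None
    eff = TeEffect(
        te.te_id, replicate, background=bg, mhmd_left=left, mhmd_right=right,
        magnitude=mag, extent_left=e_l, extent_right=e_r, extent=ext,
    )
    if mag is None and ext is None:
        eff.excluded = "both flanks missing"
    return eff


def average_replicates(effects: Sequence[TeEffect]) -> pd.DataFrame:
    """Replicate-averaged per-TE estimates.

    Magnitude and extent are means of the per-replicate values; a TE
    missing in one replicate uses the other alone.  Returns one row per TE
    with columns magnitude, extent, extent_left, extent_right, n_replicates.
    """
    rows = [
        {
            "te_id": e.te_id,
            "magnitude": e.magnitude,
            "extent": e.extent,
            "extent_left": e.extent_left,
            "extent_right": e.extent_right,
        }
        for e in effects
        if e.excluded is None
    ]
    if not rows:
        return pd.DataFrame(
            columns=["magnitude", "extent", "extent_left", "extent_right", "n_replicates"]
        )
    df = pd.DataFrame(rows)
    agg = df.groupby("te_id").agg(
        magnitude=("magnitude", "mean"),
        extent=("extent", "mean"),
        extent_left=("extent_left", "mean"),
        extent_right=("extent_right", "mean"),
        n_replicates=("magnitude", "size"),
    )
    return agg


def two_genome_effect(
    track_focal: HmdTrack,
    track_alt: HmdTrack,
    te: TeRecord,
    homolog_interval: tuple[int, int] | None,
    shared_peaks: pd.DataFrame | None = None,
    alt_tes: Sequence[TeRecord] = (),
    replicate: str = "rep1",
    cap: int = N_WINDOWS,
) -> TeEffect:
    """Two-genome estimate against the homologous TE-free sequence.

    ``homolog_interval`` is the (start, end) of the focal TE's insertion
    site lifted to the alternative strain's coordinates (empty interval for
    a clean absence).  Magnitude is the focal first-window m-HMD divided by
    the alternative-strain first-window m-HMD at the homolog; extent is the
    farthest consecutive window in which the focal m-HMD exceeds the
    alternative one.  TEs inside shared H3K9me2 peaks, with an
    alternative-strain TE within 1 kb of the homolog, or with no homology
    mapping are excluded with a logged reason.
    """
    if homolog_interval is None:
        return TeEffect(te.te_id, replicate, excluded="unmapped homologous region")
    if shared_peaks is not None:
        sub = shared_peaks[shared_peaks["chrom"] == te.chrom]
        if ((sub["start"] < te.end) & (te.start < sub["end"])).any():
            return TeEffect(te.te_id, replicate, excluded="inside shared peak")
    h_start, h_end = homolog_interval
    for alt in alt_tes:
        if alt.chrom == track_alt.chrom and alt.start < h_end + 1000 and h_start - 1000 < alt.end:
            return TeEffect(te.te_id, replicate, excluded="TE near homolog in alternative strain")

    bg_f = local_background(track_focal, te)
    homolog = TeRecord(te.te_id + "_homolog", track_alt.chrom, h_start, max(h_end, h_start + 1))
    bg_a = local_background(track_alt, homolog)
    if bg_f is None or bg_a is None or bg_f <= 0 or bg_a <= 0:
        return TeEffect(te.te_id, replicate, excluded="background unestimable")
    f_left = window_mhmd(track_focal, te, "left", bg_f)
    f_right = window_mhmd(track_focal, te, "right", bg_f)
    a_left = window_mhmd(track_alt, homolog, "left", bg_a)
    a_right = window_mhmd(track_alt, homolog, "right", bg_a)

    mags = []
    exts = []
    for f, a in ((f_left, a_left), (f_right, a_right)):
        if not math.isnan(f[0]) and not math.isnan(a[0]) and a[0] > 0:
            mags.append(f[0] / a[0])
        run = 0
        for fv, av in zip(f[:cap], a[:cap]):
            if math.isnan(fv) or math.isnan(av) or fv <= av:
                break
            run += 1
        exts.append(float(run) if not (math.isnan(f[0]) or math.isnan(a[0])) else None)
    mag = float(np.mean(mags)) if mags else None
    sides = [e for e in exts if e is not None]
    ext = float(np.mean(sides)) if sides else None
    eff = TeEffect(
        te.te_id, replicate, background=bg_f, mhmd_left=f_left, mhmd_right=f_right,
        magnitude=mag, extent_left=exts[0], extent_right=exts[1], extent=ext,
    )
    if mag is None and ext is None:
        eff.excluded = "both flanks missing"
    return eff


def side_asymmetry_z(
    per_side: Sequence[tuple[str, float, float]]
) -> list[SideAsymmetry]:
    """z-scores for the intergenic-minus-genic side difference across TEs.

    ``per_side`` holds (te_id, intergenic_side_value, genic_side_value) for
    intergenic TEs with one identified genic side; the value may be either
    the extent or the magnitude on that side.  z = difference / SD of the
    differences over all included TEs; positive z means the effect is more
    restricted on the genic side.
    """
    if len(per_side) < 2:
        raise ValueError("at least two TEs are required to normalize the differences")
    diffs = np.array([inter - genic for _, inter, genic in per_side], dtype=float)
    sd = diffs.std(ddof=1)
    if sd == 0:
        if np.all(diffs == 0):  # degenerate but well-defined: no asymmetry at all
            return [SideAsymmetry(t, i, g, 0.0) for t, i, g in per_side]
        raise ZeroDivisionError("SD of side differences is zero; z undefined")
    return [
        SideAsymmetry(te_id, inter, genic, float((inter - genic) / sd))
        for (te_id, inter, genic), d in zip(per_side, diffs)
    ]
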