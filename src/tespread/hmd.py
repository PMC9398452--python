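"""Spike-in-normalized histone modification density (HMD).

HMD quantifies the local abundance of a histone mark (here H3K9me2) from a
spike-in controlled ChIP-seq experiment.  Per 25-bp window,

    HMD = E_locus / E_si,
    E_locus = (fragment coverage in ChIP) / (fragment coverage in input),
    E_si    = (spike-in barcode fragments in ChIP) / (barcode fragments in input).

Dividing by the spike-in enrichment makes tracks comparable between samples
and species: a genome-wide background of HMD ~ 1 corresponds to the bulk
chromatin level represented by the spike-in nucleosome panel.  Windows with
fewer than five input fragments carry too little information and are masked
as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

DEFAULT_BIN_SIZE = 25
DEFAULT_MIN_INPUT = 5


class DegenerateSpikeInError(ValueError):
    """Spike-in counts do not define a usable enrichment ratio."""


@dataclass(frozen=True)
class SpikeInEnrichment:
    """Ratio of spike-in barcode fragments, ChIP over input."""

    e_si: float

    def __post_init__(self):
        if not self.e_si > 0:
            raise DegenerateSpikeInError(f"e_si must be > 0, got {self.e_si}")


@dataclass
class HmdTrack:
    """Per-chromosome HMD in fixed-width bins with a missing-data mask.

    Bin ``i`` covers ``[bin_size * i, bin_size * (i + 1))``.
    """

    chrom: str
    values: np.ndarray
    missing: np.ndarray
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.shape != self.missing.shape:
            raise ValueError("values and missing mask must have the same shape")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def length(self) -> int:
        return self.n_bins * self.bin_size

    def valid_values(self, start_bin: int, end_bin: int) -> np.ndarray:
        """Non-missing values in bin range [start_bin, end_bin), clipped."""
        start_bin = max(start_bin, 0)
        end_bin = min(end_bin, self.n_bins)
        if start_bin >= end_bin:
            return np.empty(0)
        sl = slice(start_bin, end_bin)
        return self.values[sl][~self.missing[sl]]


def compute_spikein_enrichment(
    chip_barcode_fragments: float, input_barcode_fragments: float
) -> SpikeInEnrichment:
    """E_si from spike-in barcode fragment counts."""
    if chip_barcode_fragments < 0 or input_barcode_fragments < 0:
        raise ValueError("barcode fragment counts must be non-negative")
    if input_barcode_fragments == 0:
        raise DegenerateSpikeInError("input barcode fragment count is zero (undefined ratio)")
    if chip_barcode_fragments == 0:
        raise DegenerateSpikeInError("ChIP barcode fragment count is zero (HMD would be infinite)")
    return SpikeInEnrichment(chip_barcode_fragments / input_barcode_fragments)


def compute_hmd_track(
    chip_cov: np.ndarray,
    input_cov: np.ndarray,
    e_si: SpikeInEnrichment | float,
    chrom: str = ".",
    bin_size: int = DEFAULT_BIN_SIZE,
    min_input_fragments: float = DEFAULT_MIN_INPUT,
) -> HmdTrack:
    """Per-bin HMD = (chip / input) / e_si with low-input bins masked.

    ``chip_cov`` and ``input_cov`` are per-bin mean fragment coverages over
    the same chromosome span.
    """
    chip = np.asarray(chip_cov, dtype=float)
    inp = np.asarray(input_cov, dtype=float)
    if chip.shape != inp.shape:
        raise ValueError("ChIP and input tracks cover different spans")
    ratio = float(e_si.e_si if isinstance(e_si, SpikeInEnrichment) else e_si)
    if not ratio > 0:
        raise DegenerateSpikeInError("spike-in enrichment must be > 0")
    missing = inp < min_input_fragments
    values = np.zeros_like(chip)
    ok = ~missing
    values[ok] = (chip[ok] / inp[ok]) / ratio
    return HmdTrack(chrom=chrom, values=values, missing=missing, bin_size=bin_size)


def compute_hmd_tracks(
    chip_cov: Mapping[str, np.ndarray],
    input_cov: Mapping[str, np.ndarray],
    e_si: SpikeInEnrichment | float,
    bin_size: int = DEFAULT_BIN_SIZE,
    min_input_fragments: float = DEFAULT_MIN_INPUT,
) -> dict[str, HmdTrack]:
    """Per-chromosome HMD tracks; chromosome sets must match."""
    if set(chip_cov) != set(input_cov):
        raise ValueError("ChIP and input cover different chromosome sets")
    return {
        chrom: compute_hmd_track(
            chip_cov[chrom], input_cov[chrom], e_si, chrom, bin_size, min_input_fragments
        )
        for chrom in chip_cov
    }


def metaprofile(
    tracks: Mapping[str, HmdTrack],
    tes: Sequence,
    flank: int = 20_000,
    loess_span: float = 0.15,
) -> pd.DataFrame:
    """TE-boundary-centered average HMD profile with LOESS smoothing.

    Distances are measured from the TE boundary, negative upstream of the
    start boundary and positive downstream of the end boundary; both
    boundaries of every TE contribute.  Returns one row per distance bin:
    distance (bp, bin midpoint offset), mean HMD, 95% CI half-width from the
    per-distance standard error, LOESS-smoothed mean (local linear, tricube
    weights at the given span) and the number of contributing TEs.
    """
    if not 0 < loess_span <= 1:
        raise ValueError("loess_span must be in (0, 1]")
    records: dict[int, list[float]] = {}
    for te in tes:
        track = tracks.get(te.chrom)
        if track is None:
            continue
        bs = track.bin_size
        n_flank = flank // bs
        start_bin = te.start // bs
        end_bin = -(-te.end // bs)
        # upstream of start boundary: offset -1 is the bin touching the TE
        for off in range(1, n_flank + 1):
            b = start_bin - off
            if 0 <= b < track.n_bins and not track.missing[b]:
                records.setdefault(-off * bs, []).append(track.values[b])
            b = end_bin + off - 1
            if 0 <= b < track.n_bins and not track.missing[b]:
                records.setdefault(off * bs, []).append(track.values[b])
    if not records:
        return pd.DataFrame(columns=["distance", "mean_hmd", "ci95", "smoothed", "n"])
    rows = []
    for dist in sorted(records):
        vals = np.asarray(records[dist])
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        rows.append((dist, vals.mean(), 1.96 * sem, len(vals)))
    df = pd.DataFrame(rows, columns=["distance", "mean_hmd", "ci95", "n"])
    if len(df) >= 3:
        sm = lowess(df["mean_hmd"], df["distance"], frac=loess_span, return_sorted=False)
        df["smoothed"] = sm
    else:
        df["smoothed"] = df["mean_hmd"]
    return df[["distance", "mean_hmd", "ci95", "smoothed", "n"]]
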