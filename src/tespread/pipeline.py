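"""End-to-end convenience runs: simulate, normalize, estimate, compare.

These helpers wire the generator to the estimators the way the real
analysis wires sequencing data to them: spike-in enrichment from barcode
counts, HMD tracks per replicate, per-TE magnitude/extent per replicate,
then replicate averaging.  They are the entry points used by the recovery
tests and the example scripts.
"""

from __future__ import annotations

import pandas as pd

from . import effects as fx
from . import hmd as hm
from . import simulate as sim


def hmd_tracks_from_coverage(cov: sim.CoverageSet, min_input_fragments: int = 5):
    """Spike-in-normalized HMD tracks for one simulated replicate."""
    e_si = hm.compute_spikein_enrichment(cov.chip_barcode, cov.input_barcode)
    return hm.compute_hmd_tracks(
        cov.chip, cov.input, e_si, bin_size=cov.bin_size,
        min_input_fragments=min_input_fragments,
    )


def estimate_effects(
    tes, tracks_by_replicate: dict[str, dict],
) -> pd.DataFrame:
    """Replicate-averaged per-TE magnitude and extent.

    ``tracks_by_replicate`` maps replicate name -> {chrom: HmdTrack}.
    """
    all_effects = []
    for rep, tracks in tracks_by_replicate.items():
        for te in tes:
            track = tracks.get(te.chrom)
            if track is None:
                continue
            all_effects.append(fx.te_effect(track, te, replicate=rep))
    return fx.average_replicates(all_effects)


def recovery_run(
    config: sim.SimulationConfig, n_replicates: int = 2
) -> tuple[pd.DataFrame, sim.SyntheticTruth]:
    """Simulate a full experiment and estimate every TE's effect.

    Returns (estimates joined with truth on te_id, truth object).
    """
    tes, genes, _ = sim.generate_annotations(config)
    amplitudes = sim._true_amplitudes(config, len(tes))
    tracks_by_rep = {}
    for rep in range(1, n_replicates + 1):
        cov = sim.simulate_coverage(tes, genes, config, replicate=rep, amplitudes=amplitudes)
        tracks_by_rep[f"rep{rep}"] = hmd_tracks_from_coverage(cov)
    estimates = estimate_effects(tes, tracks_by_rep)
    truth = sim.build_truth(tes, genes, config, amplitudes)
    joined = estimates.join(truth.te_table, how="inner")
    return joined, truth
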