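#!/usr/bin/env python
"""Synchronization stage: signal-level PLVs and synchronizer clustering.

Generates stimulus/produced envelope pairs for the simulated cohort (two
70-s runs per participant), measures windowed PLVs through the
resample/band-pass/Hilbert chain, clusters participants into high and low
synchronizers, and reports how well the generative labels are recovered.
Writes the PLV table under results/.
"""

from pathlib import Path

import numpy as np

from ratesync import sync
from ratesync import synthetic_data as synth

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260104


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cohort = synth.draw_sync_cohort(seed=SEED)
    cfg = sync.SyncConfig()
    rng = np.random.default_rng(SEED + 1)

    measured = []
    for _, rec in cohort.iterrows():
        runs = []
        for _ in range(2):
            pair = synth.synth_sync_pair(
                70.0, 4.5, float(rec["jitter_sd"]),
                seed=int(rng.integers(2**31 - 1)))
            pa = sync.phase_series(pair.stimulus_envelope, pair.sample_rate, cfg)
            pb = sync.phase_series(pair.produced_envelope, pair.sample_rate, cfg)
            runs.append(sync.windowed_plv(pa, pb, cfg).mean_plv)
        measured.append(float(np.mean(runs)))
    cohort = cohort.assign(mean_plv=measured)

    clusters = sync.cluster_synchronizers(cohort["mean_plv"].to_numpy(),
                                          seed=SEED)
    cohort["cluster"] = clusters.labels
    cohort.to_csv(OUT / "sync_plv_table.csv", index=False)

    agree = float(np.mean(cohort["cluster"] == cohort["group"]))
    print(f"measured PLV centroids: high {clusters.centroids[0]:.3f}, "
          f"low {clusters.centroids[1]:.3f} (generative targets 0.74/0.34)")
    print(f"cluster/label agreement: {100 * agree:.1f}% "
          f"({int(round(agree * len(cohort)))}/{len(cohort)} participants)")
    if clusters.unstable.size:
        print(f"unstable assignments across restarts: "
              f"{cohort['participant_id'].iloc[clusters.unstable].tolist()}")
    else:
        print("no assignment varied across k-means restarts")


if __name__ == "__main__":
    main()
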