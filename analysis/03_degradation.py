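"""Why short amplicons survive degradation: survival curves and contrasts.

Under Poisson fragmentation every 60-150 bp SNP-SNP amplicon outlives every
250-450 bp STR-sized amplicon at any severity, and the cfDNA log-normal
model (median 143 bp, <1% above 300 bp) leaves the panel largely intact.
Writes results/degradation_survival.csv and results/cffdna_length_histogram.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from snpsnp import default_panel
from snpsnp.degradation import (
    HEAT_PRESETS,
    FragmentationState,
    amplicon_survival,
    degraded_genotyping_comparison,
    sample_cffdna_length,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
STR_AMPLICONS = [250, 300, 350, 400, 450]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    panel = default_panel()

    frames = []
    for preset, mean_bp in HEAT_PRESETS.items():
        df = degraded_genotyping_comparison(
            panel, STR_AMPLICONS, FragmentationState.heat(preset)
        )
        df.insert(0, "preset", preset)
        df.insert(1, "mean_fragment_bp", mean_bp)
        frames.append(df)
    surv = pd.concat(frames, ignore_index=True)
    surv.to_csv(RESULTS / "degradation_survival.csv", index=False)
    for preset, grp in surv.groupby("preset", sort=False):
        snp = grp[grp["marker_class"] == "SNP-SNP"]["survival"]
        strs = grp[grp["marker_class"] == "STR"]["survival"]
        print(
            f"{preset:>12}: SNP-SNP survival {snp.min():.3f}-{snp.max():.3f}, "
            f"STR {strs.min():.4f}-{strs.max():.4f} -> panel wins: {snp.min() > strs.max()}"
        )

    rng = np.random.default_rng(20260923)
    draws = sample_cffdna_length(FragmentationState.cfdna(), rng, size=100_000)
    counts, edges = np.histogram(draws, bins=np.arange(0, 520, 10))
    pd.DataFrame(
        {"bin_left_bp": edges[:-1], "bin_right_bp": edges[1:], "count": counts}
    ).to_csv(RESULTS / "cffdna_length_histogram.csv", index=False)
    print(
        f"cfDNA model: median {np.median(draws):.1f} bp, "
        f"{100 * (draws > 300).mean():.2f}% above 300 bp; survival of the "
        f"longest panel amplicon (150 bp) = "
        f"{amplicon_survival(150, FragmentationState.cfdna()):.3f}"
    )


if __name__ == "__main__":
    main()
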