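"""Single-primer sensitivity series and extreme-dilution mixture detection.

Reproduces the two bench experiments in silico: (a) heterozygous
single-source dilutions (1, 0.5, 0.1, 0.05, 0.025 ng) recover each
primer's limit of detection; (b) a seven-locus informative two-person
mixture with the minor fixed at 0.05 ng stays detectable down to 1:1,000.
Writes results/sensitivity_lod.csv and results/mixture_series.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from snpsnp import default_panel
from snpsnp.amplification import (
    AmplificationParams,
    deepest_detected_ratio,
    mixture_series,
    sensitivity_assay,
)
from snpsnp.panel import HaplotypeGenotype

RESULTS = Path(__file__).resolve().parents[1] / "results"
MASSES = [1.0, 0.5, 0.1, 0.05, 0.025]
RATIOS = [1, 10, 20, 50, 100, 500, 1000]

G = HaplotypeGenotype.from_string
MINOR = {
    "MH8": G("AA-CG"), "MH3": G("TC-TC"), "MH11": G("CA-TG"),
    "MH13": G("CG-TG"), "MH9": G("CA-TG"), "MH10": G("CT-GT"),
    "MH12": G("CG-TG"),
}
MAJOR = {
    "MH8": G("CG-CG"), "MH3": G("CC-CC"), "MH11": G("TG-TG"),
    "MH13": G("TG-TG"), "MH9": G("CA-CA"), "MH10": G("CT-CT"),
    "MH12": G("CG-CA"),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    panel = default_panel()
    deterministic = AmplificationParams(noise_cv=0.0)

    frames = []
    for locus in panel:
        for primer in locus.primers:
            table = sensitivity_assay(locus, primer, MASSES, deterministic)
            table["lod_ng"] = primer.lod_ng
            frames.append(table)
    sens = pd.concat(frames, ignore_index=True)
    sens.to_csv(RESULTS / "sensitivity_lod.csv", index=False)
    recovered = (
        sens[sens["detection_rate"] == 1.0].groupby("primer_id")["mass_ng"].min()
    )
    lods = sens.groupby("primer_id")["lod_ng"].first()
    assert (recovered == lods).all()
    print(
        f"sensitivity: all {len(lods)} primers detect a heterozygous input "
        f"down to their LOD ({sorted(set(lods))} ng) and no further"
    )

    rng = np.random.default_rng(20260923)
    noisy = mixture_series(MINOR, MAJOR, RATIOS, panel, AmplificationParams(), rng)
    noisy.to_csv(RESULTS / "mixture_series.csv", index=False)
    det = mixture_series(MINOR, MAJOR, RATIOS, panel, deterministic)
    deepest = deepest_detected_ratio(det)
    print("deepest ratio detected per locus (deterministic):")
    print(deepest.to_string())
    n_full = int((deepest >= 1000).sum())
    print(
        f"{n_full}/7 informative loci track the 0.05 ng minor contributor "
        f"all the way to 1:1,000"
    )


if __name__ == "__main__":
    main()
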