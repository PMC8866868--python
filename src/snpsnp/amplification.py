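"""ARMS-PCR allele-specific amplification and SBE peak simulation.

The signal model is deliberately simple: an allele-specific primer sees the
mass of template carrying its target SNP1 allele (plus a small nonspecific
leak from non-target template), expected peak height is linear in that
effective mass, and realized heights carry multiplicative log-normal noise.
The per-primer gain is calibrated to its limit of detection: a
SNP1-heterozygous single-source input of ``lod_ng`` nanograms (target
template ``lod_ng / 2``) lands exactly on the 50 RFU detection threshold
under the standard protocol.  The elevated-cycle cfDNA protocol is modelled
as a flat multiplicative ``cycle_boost``.

A peak is *detected* when its height reaches ``threshold_rfu``.  Stutter is
never simulated: SNP markers produce none, which is a premise of the
method, not an omission.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import HaplotypeGenotype, MarkerLocus, Panel, PrimerSpec

__all__ = [
    "AmplificationParams",
    "Contributor",
    "MixtureSpec",
    "PEAK_COLUMNS",
    "peak_table",
    "target_mass",
    "nontarget_mass",
    "expected_height",
    "simulate_peak",
    "sensitivity_assay",
    "mixture_series",
    "deepest_detected_ratio",
]

PEAK_COLUMNS = (
    "sample_id",
    "locus_id",
    "primer_id",
    "observed_size_bp",
    "height_rfu",
    "detected",
)


@dataclass(frozen=True)
class AmplificationParams:
    """Tunable knobs of the peak model.

    threshold_rfu: detection threshold (50 RFU by default).
    gain: global scale on top of the per-primer LOD calibration (1.0 keeps
        the calibration anchor exact).
    noise_cv: coefficient of variation of the multiplicative log-normal
        peak noise; 0 switches the model to deterministic heights.
    nonspecific_rate: fraction of non-target template amplified; ``None``
        defers to each primer's own specificity.
    cycle_boost: gain multiplier for the elevated-cycle cfDNA protocol
        relative to the standard one (1.0 = standard).
    """

    threshold_rfu: float = 50.0
    gain: float = 1.0
    noise_cv: float = 0.3
    nonspecific_rate: float | None = None
    cycle_boost: float = 1.0

    def __post_init__(self) -> None:
        if min(self.threshold_rfu, self.gain, self.noise_cv, self.cycle_boost) < 0:
            raise ValueError("amplification parameters must be non-negative")
        if self.nonspecific_rate is not None and not 0 <= self.nonspecific_rate < 1:
            raise ValueError("nonspecific_rate must be in [0, 1)")

    def without_noise(self) -> "AmplificationParams":
        return replace(self, noise_cv=0.0)

    def effective_nonspecific(self, primer: PrimerSpec) -> float:
        return (
            primer.nonspecific_rate
            if self.nonspecific_rate is None
            else self.nonspecific_rate
        )


#: elevated-cycle protocol used for plasma cfDNA (32 vs 30 ARMS cycles,
#: roughly a doubling per extra cycle away from plateau)
PLASMA_PARAMS = AmplificationParams(cycle_boost=4.0)


@dataclass(frozen=True)
class Contributor:
    """One DNA source in a mixture: per-locus genotypes plus its mass."""

    genotypes: dict[str, HaplotypeGenotype]
    mass_ng: float

    def __post_init__(self) -> None:
        if self.mass_ng < 0:
            raise ValueError("contributor mass must be non-negative")


@dataclass(frozen=True)
class MixtureSpec:
    """A (possibly single-source) DNA mixture analyzed in one reaction."""

    contributors: tuple[Contributor, ...]
    ratio_label: str = ""
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if not self.contributors:
            raise ValueError("mixture needs at least one contributor")

    @property
    def minor(self) -> Contributor:
        return min(self.contributors, key=lambda c: c.mass_ng)

    @property
    def total_mass_ng(self) -> float:
        return sum(c.mass_ng for c in self.contributors)

    @classmethod
    def single_source(
        cls, genotypes: dict[str, HaplotypeGenotype], mass_ng: float, sample_id: str = "single"
    ) -> "MixtureSpec":
        return cls((Contributor(genotypes, mass_ng),), sample_id=sample_id)

    @classmethod
    def two_person(
        cls,
        minor_genotypes: dict[str, HaplotypeGenotype],
        major_genotypes: dict[str, HaplotypeGenotype],
        ratio: float,
        minor_mass_ng: float = 0.05,
        sample_id: str = "mixture",
    ) -> "MixtureSpec":
        """Minor fixed at ``minor_mass_ng``; major at ``ratio`` times that."""
        if ratio < 1:
            raise ValueError("ratio is major:minor and must be >= 1")
        return cls(
            (
                Contributor(minor_genotypes, minor_mass_ng),
                Contributor(major_genotypes, minor_mass_ng * ratio),
            ),
            ratio_label=f"1:{ratio:g}",
            sample_id=sample_id,
        )


def peak_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble peak rows into the canonical PeakTable DataFrame."""
    return pd.DataFrame(rows, columns=list(PEAK_COLUMNS))


def target_mass(locus: MarkerLocus, primer: PrimerSpec, mix: MixtureSpec) -> float:
    """Nanograms of template carrying the primer's target SNP1 allele.

    Each contributor donates mass * dosage/2 since a diploid genome splits
    its mass evenly over the two haplotypes.
    """
    total = 0.0
    for contrib in mix.contributors:
        if locus.locus_id not in contrib.genotypes:
            raise KeyError(
                f"contributor lacks a genotype for locus {locus.locus_id}"
            )
        dosage = contrib.genotypes[locus.locus_id].snp1_dosage(primer.target_snp1_allele)
        total += contrib.mass_ng * dosage / 2.0
    return total


def nontarget_mass(locus: MarkerLocus, primer: PrimerSpec, mix: MixtureSpec) -> float:
    return mix.total_mass_ng - target_mass(locus, primer, mix)


def expected_height(
    locus: MarkerLocus,
    primer: PrimerSpec,
    mix: MixtureSpec,
    params: AmplificationParams,
) -> float:
    """Deterministic expected peak height in RFU.

    Per-primer gain is ``threshold / (lod_ng / 2)`` RFU per ng of target
    template, anchoring a heterozygous input of ``lod_ng`` at threshold.
    """
    m_eff = target_mass(locus, primer, mix) + params.effective_nonspecific(
        primer
    ) * nontarget_mass(locus, primer, mix)
    per_ng = params.threshold_rfu / (primer.lod_ng / 2.0)
    return params.gain * params.cycle_boost * primer.efficiency * per_ng * m_eff


def _noise_factor(params: AmplificationParams, rng: np.random.Generator | None) -> float:
    if params.noise_cv == 0.0 or rng is None:
        return 1.0
    sigma2 = np.log1p(params.noise_cv**2)
    # mean-preserving log-normal multiplier
    return float(np.exp(rng.normal(-0.5 * sigma2, np.sqrt(sigma2))))


def simulate_peak(
    locus: MarkerLocus,
    primer: PrimerSpec,
    mix: MixtureSpec,
    params: AmplificationParams,
    rng: np.random.Generator | None = None,
) -> dict:
    """One PeakTable row for one primer on one reaction."""
    height = expected_height(locus, primer, mix, params) * _noise_factor(params, rng)
    return {
        "sample_id": mix.sample_id,
        "locus_id": locus.locus_id,
        "primer_id": primer.primer_id,
        "observed_size_bp": primer.observed_size_bp,
        "height_rfu": height,
        "detected": bool(height >= params.threshold_rfu),
    }


def sensitivity_assay(
    locus: MarkerLocus,
    primer: PrimerSpec,
    masses_ng: Sequence[float],
    params: AmplificationParams,
    rng: np.random.Generator | None = None,
    replicates: int = 1,
) -> pd.DataFrame:
    """Detection rate vs input mass for a SNP1-heterozygous template.

    The template carries one target and one non-target haplotype, the
    dilution-series design used to establish per-primer sensitivity.  With
    noise off, the smallest detected mass equals the primer's ``lod_ng``.
    """
    other = next(a for a in locus.snp1_alleles if a != primer.target_snp1_allele)
    genotype = HaplotypeGenotype(
        primer.target_snp1_allele + locus.snp2_alleles[0],
        other + locus.snp2_alleles[0],
    )
    rows = []
    for mass in masses_ng:
        if mass < 0:
            raise ValueError("input masses must be non-negative")
        mix = MixtureSpec.single_source({locus.locus_id: genotype}, mass)
        hits = sum(
            simulate_peak(locus, primer, mix, params, rng)["detected"]
            for _ in range(replicates)
        )
        rows.append(
            {
                "primer_id": primer.primer_id,
                "mass_ng": mass,
                "replicates": replicates,
                "detection_rate": hits / replicates,
            }
        )
    return pd.DataFrame(rows)


def _informative_primers(
    locus: MarkerLocus,
    minor: HaplotypeGenotype,
    major: HaplotypeGenotype,
) -> list[PrimerSpec]:
    """Primers targeting a minor SNP1 allele absent from the major."""
    major_alleles = set(major.snp1_alleles())
    alleles = [a for a in sorted(set(minor.snp1_alleles())) if a not in major_alleles]
    primers = []
    for allele in alleles:
        primer = locus.primer_for_allele(allele)
        if primer is not None:
            primers.append(primer)
    return primers


def mixture_series(
    minor_genotypes: dict[str, HaplotypeGenotype],
    major_genotypes: dict[str, HaplotypeGenotype],
    ratios: Sequence[float],
    panel: Panel,
    params: AmplificationParams,
    rng: np.random.Generator | None = None,
    minor_mass_ng: float = 0.05,
) -> pd.DataFrame:
    """Simulate the minor-specific primer across a major:minor dilution series.

    One peak per informative locus (minor SNP1 allele absent from the
    major), informative allele and ratio.  Returns an empty PeakTable with
    an attached warning attribute when no locus is informative.
    """
    rows = []
    for locus in panel:
        lid = locus.locus_id
        if lid not in minor_genotypes or lid not in major_genotypes:
            continue
        primers = _informative_primers(locus, minor_genotypes[lid], major_genotypes[lid])
        for primer in primers:
            for ratio in ratios:
                mix = MixtureSpec.two_person(
                    minor_genotypes,
                    major_genotypes,
                    ratio=ratio,
                    minor_mass_ng=minor_mass_ng,
                    sample_id=f"mix_1:{ratio:g}",
                )
                row = simulate_peak(locus, primer, mix, params, rng)
                row["ratio"] = ratio
                rows.append(row)
    table = pd.DataFrame(rows, columns=list(PEAK_COLUMNS) + ["ratio"])
    table.attrs["warning"] = (
        "" if rows else "no informative locus: minor and major share all SNP1 alleles"
    )
    return table


def deepest_detected_ratio(peaks: pd.DataFrame) -> pd.Series:
    """Per locus, the largest major:minor ratio still detected (NaN if none)."""
    detected = peaks[peaks["detected"]]
    return detected.groupby("locus_id")["ratio"].max().reindex(
        peaks["locus_id"].unique()
    )
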