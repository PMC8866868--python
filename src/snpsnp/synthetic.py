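"""Synthetic study data: HWE trio cohorts and maternal-plasma samples.

Parents are drawn under Hardy-Weinberg equilibrium from per-locus
haplotype frequencies; children inherit one random haplotype from each
parent, so every generated trio is Mendelian-consistent by construction.
Plasma samples emulate the measured study conditions: total cfDNA
concentration uniform on 0.156-1.43 ng/uL, fetal fraction uniform on
5-20%, and cfDNA fragment lengths log-normal with median 143 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as snpio
from .degradation import FragmentationState
from .informativeness import TrioRecord, classify_locus, expected_informative_count
from .panel import HaplotypeGenotype, Panel, save_panel
from .popgen import LocusFrequencies, sample_hwe_genotype

__all__ = [
    "PlasmaSample",
    "DEFAULT_CONC_RANGE",
    "DEFAULT_FF_RANGE",
    "generate_cohort",
    "generate_plasma",
    "table1_concentrations",
    "cohort_to_files",
    "cohort_from_files",
]

#: measured quantified-concentration range of the reference cohort (ng/uL)
DEFAULT_CONC_RANGE = (0.156, 1.43)
#: typical fetal fraction of total plasma cfDNA
DEFAULT_FF_RANGE = (0.05, 0.20)


@dataclass(frozen=True)
class PlasmaSample:
    """A maternal-plasma cfDNA sample tied to one family."""

    family_id: str
    cfdna_conc_ng_per_ul: float
    fetal_fraction: float
    maternal_genotypes: dict[str, HaplotypeGenotype]
    fetal_genotypes: dict[str, HaplotypeGenotype]
    fragment_state: FragmentationState

    def __post_init__(self) -> None:
        if not 0.0 <= self.fetal_fraction <= 1.0:
            raise ValueError("fetal fraction must lie in [0, 1]")
        if self.cfdna_conc_ng_per_ul < 0:
            raise ValueError("concentration must be non-negative")

    @property
    def fetal_conc_ng_per_ul(self) -> float:
        return self.fetal_fraction * self.cfdna_conc_ng_per_ul

    @property
    def maternal_conc_ng_per_ul(self) -> float:
        return (1.0 - self.fetal_fraction) * self.cfdna_conc_ng_per_ul


def _sample_trio(
    family_id: str,
    panel_freqs: list[LocusFrequencies],
    rng: np.random.Generator,
) -> TrioRecord:
    mother: dict[str, HaplotypeGenotype] = {}
    father: dict[str, HaplotypeGenotype] = {}
    child: dict[str, HaplotypeGenotype] = {}
    for freqs in panel_freqs:
        m = sample_hwe_genotype(freqs, rng)
        f = sample_hwe_genotype(freqs, rng)
        maternal_hap = m.haplotypes[rng.integers(2)]
        paternal_hap = f.haplotypes[rng.integers(2)]
        mother[freqs.locus_id] = m
        father[freqs.locus_id] = f
        child[freqs.locus_id] = HaplotypeGenotype(maternal_hap, paternal_hap)
    return TrioRecord(family_id, mother, father, child)


def _trio_expected_count(trio: TrioRecord) -> int:
    calls = [
        classify_locus(trio.mother[lid], trio.father[lid], trio.child[lid])
        for lid in trio.child
    ]
    return expected_informative_count(calls)


def generate_cohort(
    panel_freqs: list[LocusFrequencies],
    n_families: int,
    rng: np.random.Generator,
    force_zero_informative_family: bool = False,
    max_resamples: int = 2000,
) -> list[TrioRecord]:
    """Sample ``n_families`` Mendelian-consistent trios under HWE.

    With ``force_zero_informative_family`` the last family is resampled
    until it carries no informative marker (mirroring the occasional
    all-uninformative family real cohorts contain); if the resample budget
    runs out, the father is replaced by the mother's genotypes, which
    guarantees zero informative loci.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    cohort = [
        _sample_trio(f"F{i + 1:02d}", panel_freqs, rng) for i in range(n_families)
    ]
    if force_zero_informative_family:
        fid = cohort[-1].family_id
        for _ in range(max_resamples):
            if _trio_expected_count(cohort[-1]) == 0:
                break
            cohort[-1] = _sample_trio(fid, panel_freqs, rng)
        else:
            mother = cohort[-1].mother
            child = {lid: HaplotypeGenotype(*mother[lid].haplotypes) for lid in mother}
            cohort[-1] = TrioRecord(fid, mother, dict(mother), child)
    return cohort


def generate_plasma(
    trio: TrioRecord,
    rng: np.random.Generator,
    conc_range: tuple[float, float] = DEFAULT_CONC_RANGE,
    ff_range: tuple[float, float] = DEFAULT_FF_RANGE,
    fragment_state: FragmentationState | None = None,
) -> PlasmaSample:
    """Draw a plasma sample for a trio: the fetal component carries the
    child's genotypes, the background the mother's."""
    return PlasmaSample(
        family_id=trio.family_id,
        cfdna_conc_ng_per_ul=float(rng.uniform(*conc_range)),
        fetal_fraction=float(rng.uniform(*ff_range)),
        maternal_genotypes=trio.mother,
        fetal_genotypes=trio.child,
        fragment_state=fragment_state or FragmentationState.cfdna(),
    )


def table1_concentrations() -> list[float]:
    """The 25 quantified reference-cohort concentrations, for replay mode."""
    df = snpio.load_table1_counts()
    return df["cfdna_conc_ng_per_ul"].dropna().tolist()


def cohort_to_files(
    cohort: list[TrioRecord],
    plasma: list[PlasmaSample],
    out_dir: str | Path,
    panel: Panel | None = None,
) -> dict[str, Path]:
    """Write a cohort as mother/father/child genotype CSVs plus a plasma
    manifest (and a panel TSV copy when given).  Round-trip loadable."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for role in ("mother", "father", "child"):
        genotypes = {
            trio.family_id: getattr(trio, role) for trio in cohort
        }
        paths[role] = out / f"{role}_genotypes.csv"
        snpio.write_genotypes_csv(genotypes, paths[role])
    manifest = pd.DataFrame(
        [
            {
                "family_id": s.family_id,
                "cfdna_conc_ng_per_ul": s.cfdna_conc_ng_per_ul,
                "fetal_fraction": s.fetal_fraction,
            }
            for s in plasma
        ],
        columns=["family_id", "cfdna_conc_ng_per_ul", "fetal_fraction"],
    )
    paths["manifest"] = out / "plasma_manifest.csv"
    manifest.to_csv(paths["manifest"], index=False)
    if panel is not None:
        paths["panel"] = out / "panel.tsv"
        save_panel(panel, paths["panel"])
    return paths


def cohort_from_files(out_dir: str | Path) -> list[TrioRecord]:
    """Reload a cohort written by :func:`cohort_to_files`."""
    out = Path(out_dir)
    roles = {
        role: snpio.read_genotypes_csv(out / f"{role}_genotypes.csv")
        for role in ("mother", "father", "child")
    }
    return [
        TrioRecord(fid, roles["mother"][fid], roles["father"][fid], roles["child"][fid])
        for fid in roles["mother"]
    ]
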