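"""Population-genetic power of the panel under Hardy-Weinberg equilibrium.

With random mating, the probability that a locus is informative for a
random trio is the probability that the mother is SNP1-homozygous for some
allele *a* (p_a^2) and the father transmits a different allele (1 - p_a),
i.e. sum_a p_a^2 (1 - p_a); for a biallelic SNP1 this is p(1-p) regardless
of which allele is called minor.  Treating loci as unlinked, the number of
informative loci across a panel is Poisson-binomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .panel import HaplotypeGenotype, Panel

__all__ = [
    "LocusFrequencies",
    "DiversityStats",
    "prob_informative_locus",
    "informative_count_pmf",
    "panel_informative_count_distribution",
    "effective_allele_number",
    "sample_hwe_genotype",
    "simulate_informative_fraction",
    "default_panel_frequencies",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class LocusFrequencies:
    """Haplotype frequencies at one locus; SNP1 frequencies are marginals."""

    locus_id: str
    haplotype_freqs: dict[str, float]
    _haps: tuple[str, ...] = field(init=False, repr=False, compare=False)
    _probs: "np.ndarray" = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.haplotype_freqs:
            raise ValueError(f"{self.locus_id}: empty haplotype frequencies")
        probs = np.asarray(list(self.haplotype_freqs.values()), dtype=float)
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError(f"{self.locus_id}: frequencies outside [0,1]")
        if abs(probs.sum() - 1.0) > _SUM_TOL:
            raise ValueError(
                f"{self.locus_id}: haplotype frequencies sum to {probs.sum():.12f}, not 1"
            )
        object.__setattr__(self, "_haps", tuple(self.haplotype_freqs))
        object.__setattr__(self, "_probs", probs)

    @property
    def snp1_freqs(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for hap, q in self.haplotype_freqs.items():
            out[hap[0]] = out.get(hap[0], 0.0) + q
        return out

    @classmethod
    def biallelic(
        cls,
        locus_id: str,
        snp1_minor: float,
        snp2_minor: float = 0.5,
        alleles1: tuple[str, str] = ("A", "G"),
        alleles2: tuple[str, str] = ("C", "T"),
    ) -> "LocusFrequencies":
        """Two biallelic SNPs in linkage equilibrium (product haplotypes)."""
        p = {alleles1[0]: snp1_minor, alleles1[1]: 1.0 - snp1_minor}
        q = {alleles2[0]: snp2_minor, alleles2[1]: 1.0 - snp2_minor}
        freqs = {a1 + a2: p[a1] * q[a2] for a1 in p for a2 in q}
        return cls(locus_id, freqs)


def prob_informative_locus(freqs: LocusFrequencies) -> float:
    """P(random trio is informative) = sum_a p_a^2 (1 - p_a) over SNP1."""
    return float(sum(p * p * (1.0 - p) for p in freqs.snp1_freqs.values()))


def informative_count_pmf(probs: "np.ndarray | list[float]") -> np.ndarray:
    """Poisson-binomial pmf over counts 0..L from per-locus probabilities."""
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValueError("informative_count_pmf needs >= 1 locus probability")
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError("per-locus probabilities must lie in [0, 1]")
    dist = stats.poisson_binom(probs.tolist())
    return dist.pmf(np.arange(probs.size + 1))


def panel_informative_count_distribution(
    panel_freqs: list[LocusFrequencies],
) -> np.ndarray:
    """Poisson-binomial pmf of the informative-marker count over 0..L loci."""
    if not panel_freqs:
        raise ValueError("panel_informative_count_distribution needs >= 1 locus")
    return informative_count_pmf([prob_informative_locus(f) for f in panel_freqs])


@dataclass(frozen=True)
class DiversityStats:
    """Effective number of alleles Ae = 1/sum q^2 and heterozygosity 1 - sum q^2."""

    locus_id: str
    ae: float
    heterozygosity: float


def effective_allele_number(freqs: LocusFrequencies) -> DiversityStats:
    homozygosity = float(np.square(freqs._probs).sum())
    return DiversityStats(
        locus_id=freqs.locus_id,
        ae=1.0 / homozygosity,
        heterozygosity=1.0 - homozygosity,
    )


def sample_hwe_genotype(
    freqs: LocusFrequencies, rng: np.random.Generator
) -> HaplotypeGenotype:
    """Draw an individual: two i.i.d. haplotypes from the population pool."""
    i, j = rng.choice(len(freqs._haps), size=2, p=freqs._probs)
    return HaplotypeGenotype(freqs._haps[i], freqs._haps[j])


def simulate_informative_fraction(
    freqs: LocusFrequencies, n_trios: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo check of :func:`prob_informative_locus`.

    Samples maternal haplotype pairs and an independently transmitted
    paternal haplotype under HWE, and applies the definition directly:
    informative iff the mother is SNP1-homozygous and the paternal SNP1
    allele differs.  Vectorized; intended as an independent cross-check.
    """
    snp1 = np.asarray([h[0] for h in freqs._haps])
    draws = rng.choice(len(freqs._haps), size=(n_trios, 3), p=freqs._probs)
    m1, m2, pat = snp1[draws[:, 0]], snp1[draws[:, 1]], snp1[draws[:, 2]]
    informative = (m1 == m2) & (pat != m1)
    return float(informative.mean())


def default_panel_frequencies(
    panel: Panel,
    rng: np.random.Generator | None = None,
    maf_range: tuple[float, float] = (0.3, 0.5),
) -> list[LocusFrequencies]:
    """Synthetic per-locus frequencies for the shipped panel.

    Real population frequencies for these markers are not bundled; each
    locus gets a SNP1 minor-allele frequency drawn uniformly from
    ``maf_range`` (midpoint when ``rng`` is None) and SNP2 at 0.5, with
    haplotypes in linkage equilibrium.  Only the SNP1 marginal matters for
    informativeness, so the linkage-equilibrium simplification does not
    bias the power analyses it feeds.
    """
    out = []
    for locus in panel:
        if rng is None:
            maf = 0.5 * (maf_range[0] + maf_range[1])
        else:
            maf = float(rng.uniform(*maf_range))
        out.append(
            LocusFrequencies.biallelic(
                locus.locus_id,
                snp1_minor=maf,
                snp2_minor=0.5,
                alleles1=locus.snp1_alleles,
                alleles2=locus.snp2_alleles,
            )
        )
    return out
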