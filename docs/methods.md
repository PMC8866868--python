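# Methods

This note records the models behind `snpsnp`, the parameters that matter,
and the design choices made where the underlying experiments constrain the
model only loosely.

## Marker model and panel fixture

Each of the 15 loci carries two linked biallelic SNPs; haplotype alleles
are two bases (SNP1 first), genotypes are unordered haplotype pairs
("CA-TG" ≡ "TG-CA"), and all classification and amplification logic uses
the SNP1 projection only — the ARMS primers target SNP1 regardless of
SNP2, which is read downstream by SBE. The bundled panel TSV records, per
locus: the SNP1/SNP2 allele pairs, ARMS amplicon length (60–150 bp), SBE
amplicon length (26–71 bp), and per primer the target allele, the limit of
detection (0.025 or 0.05 ng) and the observed CE product size (designed
SBE length plus a non-negative dye/mobility offset, stored explicitly
rather than modelled physically).

The published record pins only part of the fixture: the amplicon
geometries, LOD classes and observed sizes of the 26 primers that were
ever informative, the MH9 primer→allele mapping, and the alleles that
appear in the published mixture genotypes (MH3, MH8, MH9, MH10, MH11,
MH12, MH13). The remaining allele labels and F1/F2 assignments are
synthetic placeholders (marked as such in the fixture header), chosen once
and consistent with everything that is pinned. Four primers never used on
plasma have no published observed size; they inherit their locus partner's
value.

Reported size means follow the source's conventions: the SBE mean is over
the 15 distinct per-locus SBE sizes (682/15 → 45 bp) — a locus's two
primers share one SBE amplicon — while the detection-table ARMS mean is
over the 26 used primer rows (→ 106 bp). All reported means and rates
round half-up.

## Informativeness classification

Classification implements the definition directly on the SNP1 projection:
with a heterozygous mother no fetal allele can be unshared, so the locus
is categorically unusable (kept as its own category, `MATERNAL_HET`,
because this is the method's main structural limitation); with a
homozygous mother the child's non-maternal SNP1 allele is unique, so Type
2 vs Type 3 is decided without phase ambiguity. Paternal *haplotype*
attribution can still be ambiguous when both child haplotypes are
maternal-compatible; the attribution is then flagged, and category calls
never depend on how the tie is broken (when either attribution would make
the locus uninformative, the SNP1 logic already returns the uninformative
category). Mendelian consistency is checked at haplotype level and
violations raise an error naming the locus and genotypes.

## Population-genetic power

Assumptions: random mating (HWE), unrelated parents, the father's
transmitted allele an independent draw from population frequencies, loci
unlinked (the panel spans the genome). Then P(informative) =
Σₐ pₐ²(1−pₐ) over SNP1 alleles, and the per-family count of informative
markers is Poisson-binomial over loci (scipy's `poisson_binom`; an
exhaustive convolution serves as the test oracle). Real per-locus
population frequencies are not bundled; the synthetic default draws each
SNP1 minor-allele frequency uniformly from 0.3–0.5 (a deliberately
high-polymorphism regime consistent with markers selected for mixture
work) with SNP2 at 0.5 and haplotypes in linkage equilibrium. Only the
SNP1 marginal enters informativeness, so the linkage-equilibrium
simplification does not bias the power results; it does make the default
Ae (≈3.5–4) an upper-bound-flavoured summary rather than an estimate for
the real markers.

## Amplification and detection model

Expected peak height is linear in effective template mass
`m_eff = target + nonspecific_rate × nontarget`, where a diploid
contributor donates `mass × dosage/2` of target. The per-primer gain is
calibrated to its LOD: a SNP1-heterozygous single-source input of
`lod_ng` (hence `lod_ng/2` of target template) lands exactly on the
50 RFU threshold under the standard protocol. This convention makes the
simulated dilution series recover the printed per-primer sensitivities at
their stated input masses, and makes a heterozygous 0.05 ng minor
(0.025 ng of target) detectable at 1:1,000 by 0.05-ng-class primers —
both behaviours the model is meant to reproduce. Realized heights carry
mean-preserving multiplicative log-normal noise with coefficient of
variation `noise_cv` (default 0.3; 0 = deterministic). Defaults:
`nonspecific_rate` 10⁻⁴ per primer (keeps 1:1,000 specificity while
allowing occasional noise peaks if raised), `cycle_boost` 1 for the
standard protocol and 4 for the elevated-cycle plasma protocol (two extra
cycles ≈ a doubling each, away from plateau), per-primer `efficiency` 1
(a configurable penalty hook for loci that underperform in multiplex).
Absolute RFU gain is unconstrained by the source data, so only the
height/threshold ratio is meaningful. Stutter is never simulated: SNP
markers produce none, which is a premise of the method.

## Fragment-length models

Heat degradation: Poisson random breaks at rate 1/λ give amplicon
survival `exp(−L/λ)`. Incubation presets map times to mean fragment
lengths (35/40/45 min → 150/120/100 bp; the M308 standard 120/160/170 min
→ 120/90/80 bp); these are acknowledged inventions calibrated to
"mostly below 200 bp" evidence, not kinetic fits. The Monte-Carlo
cross-check scatters Poisson-many uniform breakpoints on independent
molecules and counts windows containing none — independent of the closed
form it verifies.

Plasma cfDNA: log-normal fragment lengths with median 143 bp and σ = 0.30,
the largest round σ keeping P(length > 300 bp) below 1% (the constraint
gives σ ≤ 0.3186); an amplicon survives when its carrying fragment is at
least as long as the amplicon. Nucleosome-positioning structure in real
cfDNA size distributions is not modelled.

## Synthetic cohorts and the plasma pipeline

Cohorts: parents drawn under HWE per locus, children by one random
haplotype per parent, so Mendelian consistency holds by construction.
Plasma: total cfDNA concentration uniform on 0.156–1.43 ng/µL (the
measured quantified range; a replay mode exposes the 25 quantified values
verbatim), fetal fraction uniform on 5–20%, fetal component = child
genotypes, background = mother. An option forces one family to zero
informative markers, mirroring the real cohort's one such family, since
random cohorts contain one only ≈45% of the time under the default
frequencies. Gestational-age dependence of fetal fraction is not
parameterized.

`run_family` simulates each informative marker as an independent
single-plex reaction (matching the bench design — no inter-locus
competition) on a two-contributor mixture with 1 µL of template, both
components scaled by the locus's cfDNA amplicon survival, under the
elevated-cycle parameters. The cohort summary reports totals, the
detection rate (one decimal, half-up), per-primer successful/total
tallies and detected-product size statistics; the concentration analysis
reports a Spearman coefficient only, deliberately without a p-value,
because the claim it addresses is qualitative.

## Problem sizes and numerical choices

Stochastic checks use 100,000 draws (fragment lengths, Monte-Carlo
informativeness, breakpoint survival) or 10,000 replicates (mixture
false-peak tally) with 3-standard-error tolerances and fixed seeds;
generator-vs-closed-form agreement uses 2,000 families. Detection uses
`height ≥ threshold`, so calibration anchors count as detected.
Zero-length amplicons survive trivially; negative lengths, empty panels,
malformed files and frequency vectors off the simplex (tolerance 10⁻⁹)
raise validation errors. All randomness flows through
`numpy.random.Generator` instances supplied by the caller; nothing reads
global RNG state.

## Known limitations

The peak-height law, heat presets and default frequencies are modelling
choices constrained only by printed thresholds, LOD classes and
qualitative statements; absolute heights, real allele frequencies and
real per-family genotypes are not recoverable from the bundled fixtures.
Passing tests therefore demonstrate internal consistency with the printed
summaries and the stated models, not predictive accuracy for new wet-lab
runs. Paternity-index / likelihood-ratio computation is out of scope, as
is real electropherogram parsing.
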