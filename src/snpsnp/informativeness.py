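"""Trio informativeness: which loci let allele-specific primers see the fetus.

A marker is *informative* for a mother/father/child trio when the child's
paternally inherited SNP1 allele is not carried by the mother, so the
corresponding ARMS primer amplifies fetal (minor) template against the
maternal background.  Because a heterozygous mother always shares both of
her SNP1 alleles with any child she could have, informativeness requires a
SNP1-homozygous mother; the categories are then:

* ``TYPE1`` — parents are opposite SNP1 homozygotes: whichever allele the
  father transmits, it differs from the mother's, so the locus is always
  usable and the informative allele is the father's.
* ``TYPE2`` — mother homozygous, father heterozygous, and the transmitted
  paternal allele is the one the mother lacks: usable.
* ``TYPE3`` — mother homozygous, father heterozygous, but the transmitted
  allele is shared with the mother: not usable.
* ``MATERNAL_HET`` — mother SNP1-heterozygous: never usable.
* ``UNINFORMATIVE`` — both parents homozygous for the same allele.

SNP2 plays no role in the verdict (primers target SNP1 regardless of SNP2),
but the paternal haplotype is recorded so the SBE readout can be simulated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .panel import HaplotypeGenotype, MarkerLocus, Panel

__all__ = [
    "Category",
    "MendelianError",
    "InformativenessCall",
    "PaternalAttribution",
    "TrioRecord",
    "paternal_allele",
    "classify_locus",
    "classify_trio",
    "expected_informative_count",
]


class Category(str, enum.Enum):
    TYPE1 = "TYPE1"
    TYPE2 = "TYPE2"
    TYPE3 = "TYPE3"
    MATERNAL_HET = "MATERNAL_HET"
    UNINFORMATIVE = "UNINFORMATIVE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


INFORMATIVE_CATEGORIES = frozenset({Category.TYPE1, Category.TYPE2})


class MendelianError(ValueError):
    """Child genotype incompatible with the stated parents at a locus."""

    def __init__(self, message: str, locus_id: str | None = None, **genotypes):
        detail = ", ".join(f"{k}={v}" for k, v in genotypes.items())
        super().__init__(
            message + (f" [locus {locus_id}]" if locus_id else "") + (f" ({detail})" if detail else "")
        )
        self.locus_id = locus_id
        self.genotypes = genotypes


@dataclass(frozen=True)
class InformativenessCall:
    """Per-locus classification of a trio."""

    locus_id: str
    category: Category
    informative_allele: str | None = None
    primer_id: str | None = None
    paternal_haplotype: str | None = None
    ambiguous_attribution: bool = False

    @property
    def informative(self) -> bool:
        return self.category in INFORMATIVE_CATEGORIES


@dataclass(frozen=True)
class PaternalAttribution:
    """Which child haplotype came from the father.

    When both child haplotypes are compatible with the mother the
    attribution is ambiguous; ``candidates`` then holds both options and
    ``haplotype`` an arbitrary-but-deterministic one of them.
    """

    haplotype: str
    ambiguous: bool
    candidates: tuple[str, ...]


def paternal_allele(
    mother: HaplotypeGenotype, child: HaplotypeGenotype
) -> PaternalAttribution:
    """Attribute one child haplotype to the father given the mother.

    Raises :class:`MendelianError` if neither child haplotype could have
    come from the mother.
    """
    h1, h2 = child.haplotypes
    candidates = []
    for paternal, maternal in ((h2, h1), (h1, h2)):
        if mother.contains_haplotype(maternal) and paternal not in candidates:
            candidates.append(paternal)
    if not candidates:
        raise MendelianError(
            "no child haplotype is compatible with the mother",
            mother=mother,
            child=child,
        )
    return PaternalAttribution(
        haplotype=min(candidates),
        ambiguous=len(candidates) > 1,
        candidates=tuple(sorted(candidates)),
    )


def _check_mendelian(
    mother: HaplotypeGenotype,
    father: HaplotypeGenotype,
    child: HaplotypeGenotype,
    locus_id: str | None,
) -> None:
    h1, h2 = child.haplotypes
    ok = any(
        mother.contains_haplotype(m) and father.contains_haplotype(p)
        for m, p in ((h1, h2), (h2, h1))
    )
    if not ok:
        raise MendelianError(
            "child genotype incompatible with parents",
            locus_id=locus_id,
            mother=mother,
            father=father,
            child=child,
        )


def classify_locus(
    mother: HaplotypeGenotype,
    father: HaplotypeGenotype,
    child: HaplotypeGenotype,
    locus: MarkerLocus | None = None,
) -> InformativenessCall:
    """Classify one locus of a trio into the informativeness categories.

    ``locus`` is only needed to resolve the allele-specific primer for the
    informative allele; classification itself uses SNP1 alone.  Ambiguous
    paternal-haplotype attribution is resolved conservatively: whenever an
    attribution exists under which the locus is not informative, the
    non-informative category is returned (the SNP1 projection makes this
    automatic: with a homozygous mother the child's non-maternal SNP1
    allele is unique).
    """
    locus_id = locus.locus_id if locus is not None else "?"
    if locus is not None:
        for name, g in (("mother", mother), ("father", father), ("child", child)):
            if not g.valid_for(locus):
                raise ValueError(
                    f"{name} genotype {g} uses bases outside the declared "
                    f"alleles of locus {locus_id}"
                )
    _check_mendelian(mother, father, child, locus_id)

    attribution = paternal_allele(mother, child)

    m1, m2 = mother.snp1_alleles()
    if m1 != m2:
        return InformativenessCall(
            locus_id,
            Category.MATERNAL_HET,
            paternal_haplotype=attribution.haplotype,
            ambiguous_attribution=attribution.ambiguous,
        )
    maternal_allele = m1

    f1, f2 = father.snp1_alleles()
    father_homozygous = f1 == f2

    # Mother is SNP1-homozygous, so the child's maternally inherited SNP1
    # allele is fixed and the paternal SNP1 allele is whatever else the
    # child carries (or the shared allele if the child is homozygous).
    c1, c2 = child.snp1_alleles()
    non_maternal = [a for a in (c1, c2) if a != maternal_allele]
    paternal_snp1 = non_maternal[0] if non_maternal else maternal_allele

    def _call(category: Category, allele: str | None) -> InformativenessCall:
        primer_id = None
        if allele is not None and locus is not None:
            primer = locus.primer_for_allele(allele)
            primer_id = primer.primer_id if primer is not None else None
        return InformativenessCall(
            locus_id,
            category,
            informative_allele=allele,
            primer_id=primer_id,
            paternal_haplotype=attribution.haplotype,
            ambiguous_attribution=attribution.ambiguous,
        )

    if father_homozygous:
        if f1 == maternal_allele:
            return _call(Category.UNINFORMATIVE, None)
        # opposite homozygotes: informative whatever the child inherited
        return _call(Category.TYPE1, f1)
    if paternal_snp1 != maternal_allele:
        return _call(Category.TYPE2, paternal_snp1)
    return _call(Category.TYPE3, None)


@dataclass(frozen=True)
class TrioRecord:
    """Mother/father/child genotypes across the panel for one family."""

    family_id: str
    mother: dict[str, HaplotypeGenotype]
    father: dict[str, HaplotypeGenotype]
    child: dict[str, HaplotypeGenotype]

    def validate_mendelian(self) -> None:
        """Raise :class:`MendelianError` at the first inconsistent locus."""
        for locus_id in self.child:
            _check_mendelian(
                self.mother[locus_id], self.father[locus_id], self.child[locus_id], locus_id
            )


def classify_trio(trio: TrioRecord, panel: Panel) -> list[InformativenessCall]:
    """Classify every panel locus of a trio (one call per locus, panel order).

    The number of ``TYPE1``/``TYPE2`` calls is the family's *expected*
    number of informative markers.
    """
    calls = []
    for locus in panel:
        lid = locus.locus_id
        for role, genotypes in (
            ("mother", trio.mother),
            ("father", trio.father),
            ("child", trio.child),
        ):
            if lid not in genotypes:
                raise KeyError(
                    f"family {trio.family_id}: missing {role} genotype for locus {lid}"
                )
        calls.append(
            classify_locus(trio.mother[lid], trio.father[lid], trio.child[lid], locus)
        )
    return calls


def expected_informative_count(calls: list[InformativenessCall]) -> int:
    """Number of usable (TYPE1/TYPE2) loci among a trio's calls."""
    return sum(call.informative for call in calls)
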