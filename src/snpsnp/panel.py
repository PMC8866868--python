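"""Domain model for the 15-locus SNP-SNP microhaplotype panel.

A SNP-SNP marker is a microhaplotype of two tightly linked biallelic SNPs
inside one short amplicon (60-150 bp).  SNP1 is interrogated by two
allele-specific ARMS primers (F1/F2, one per allele); SNP2 is read out by
single-base extension (SBE/SNaPshot) on the ARMS product and sized on a
capillary electrophoresis platform.  Haplotype alleles are written as two
bases, SNP1 first ("CA"), and a genotype as an unordered pair of haplotypes
("CA-TG").
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "NUCLEOTIDES",
    "PanelFormatError",
    "PanelValidationError",
    "PrimerSpec",
    "MarkerLocus",
    "HaplotypeGenotype",
    "Panel",
    "PanelSizeSummary",
    "load_panel",
    "save_panel",
    "default_panel",
    "snp1_genotype",
    "panel_size_summary",
    "round_half_up",
]

NUCLEOTIDES = frozenset("ACGT")

#: columns of the panel TSV dialect, in order
PANEL_COLUMNS = (
    "locus_id",
    "snp1_alleles",
    "snp2_alleles",
    "arms_amplicon_bp",
    "sbe_amplicon_bp",
    "f1_target",
    "f1_lod_ng",
    "f1_observed_bp",
    "f2_target",
    "f2_lod_ng",
    "f2_observed_bp",
)


class PanelFormatError(ValueError):
    """Malformed panel/genotype file (carries the offending line)."""


class PanelValidationError(ValueError):
    """Structurally parseable but semantically invalid panel content."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the reporting convention used for
    all printed means and rates), unlike banker's rounding."""
    import decimal

    d = decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


@dataclass(frozen=True)
class PrimerSpec:
    """One allele-specific ARMS primer.

    ``lod_ng`` is the limit of detection expressed as the mass (ng) of a
    SNP1-heterozygous single-source input that still yields a peak at the
    50 RFU threshold; the corresponding detectable target-template mass is
    ``lod_ng / 2`` because a heterozygote carries the target allele on half
    its template.  ``specificity`` is the probability that a non-target
    template yields no product; ``efficiency`` is a per-primer relative
    amplification factor (1.0 = nominal).
    """

    primer_id: str
    target_snp1_allele: str
    lod_ng: float
    observed_size_bp: int
    specificity: float = 1.0 - 1e-4
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.target_snp1_allele not in NUCLEOTIDES:
            raise PanelValidationError(
                f"{self.primer_id}: target allele {self.target_snp1_allele!r} "
                "is not a nucleotide"
            )
        if self.lod_ng <= 0:
            raise PanelValidationError(f"{self.primer_id}: lod_ng must be positive")
        if not 0.0 <= self.specificity <= 1.0:
            raise PanelValidationError(f"{self.primer_id}: specificity outside [0,1]")

    @property
    def nonspecific_rate(self) -> float:
        """Fraction of non-target template that amplifies anyway."""
        return 1.0 - self.specificity


@dataclass(frozen=True)
class MarkerLocus:
    """One SNP-SNP microhaplotype locus with its two ARMS primers."""

    locus_id: str
    snp1_alleles: tuple[str, str]
    snp2_alleles: tuple[str, str]
    arms_amplicon_bp: int
    sbe_amplicon_bp: int
    primers: tuple[PrimerSpec, PrimerSpec]

    def __post_init__(self) -> None:
        for name, pair in (("snp1", self.snp1_alleles), ("snp2", self.snp2_alleles)):
            if len(pair) != 2 or len(set(pair)) != 2:
                raise PanelValidationError(f"{self.locus_id}: {name} alleles must be two distinct bases")
            if not set(pair) <= NUCLEOTIDES:
                raise PanelValidationError(f"{self.locus_id}: {name} alleles {pair} not nucleotides")
        if self.arms_amplicon_bp <= 0 or self.sbe_amplicon_bp <= 0:
            raise PanelValidationError(f"{self.locus_id}: amplicon lengths must be positive")
        if len(self.primers) != 2:
            raise PanelValidationError(f"{self.locus_id}: exactly two primers required")
        targets = {p.target_snp1_allele for p in self.primers}
        if targets != set(self.snp1_alleles):
            raise PanelValidationError(
                f"{self.locus_id}: primers must target the two SNP1 alleles "
                f"{self.snp1_alleles}, got {sorted(targets)}"
            )
        for p in self.primers:
            if p.observed_size_bp < self.sbe_amplicon_bp:
                raise PanelValidationError(
                    f"{p.primer_id}: observed CE size {p.observed_size_bp} smaller "
                    f"than designed SBE amplicon {self.sbe_amplicon_bp}"
                )

    def primer_for_allele(self, allele: str) -> PrimerSpec | None:
        """The allele-specific primer targeting ``allele``, if any."""
        for p in self.primers:
            if p.target_snp1_allele == allele:
                return p
        return None

    @property
    def haplotypes(self) -> tuple[str, ...]:
        """All four two-base haplotypes the declared alleles can form."""
        return tuple(a + b for a in self.snp1_alleles for b in self.snp2_alleles)


@dataclass(frozen=True, order=True)
class HaplotypeGenotype:
    """An unordered pair of two-base haplotypes at one locus ("CA-TG").

    Haplotypes are stored sorted so that "CA-TG" == "TG-CA".
    """

    hap1: str
    hap2: str

    def __post_init__(self) -> None:
        for hap in (self.hap1, self.hap2):
            if len(hap) != 2 or not set(hap) <= NUCLEOTIDES:
                raise PanelValidationError(f"invalid haplotype {hap!r}")
        if self.hap1 > self.hap2:  # normalize to unordered pair
            h1, h2 = self.hap2, self.hap1
            object.__setattr__(self, "hap1", h1)
            object.__setattr__(self, "hap2", h2)

    @classmethod
    def from_string(cls, text: str) -> "HaplotypeGenotype":
        parts = text.strip().split("-")
        if len(parts) != 2:
            raise PanelFormatError(f"genotype {text!r} is not of the form 'XY-ZW'")
        return cls(parts[0], parts[1])

    def __str__(self) -> str:
        return f"{self.hap1}-{self.hap2}"

    @property
    def haplotypes(self) -> tuple[str, str]:
        return (self.hap1, self.hap2)

    def snp1_alleles(self) -> tuple[str, str]:
        """SNP1 genotype: first base of each haplotype, sorted."""
        return tuple(sorted((self.hap1[0], self.hap2[0])))  # type: ignore[return-value]

    def snp1_dosage(self, allele: str) -> int:
        """Copies (0-2) of ``allele`` at SNP1."""
        return (self.hap1[0] == allele) + (self.hap2[0] == allele)

    def is_snp1_homozygous(self) -> bool:
        return self.hap1[0] == self.hap2[0]

    def contains_haplotype(self, hap: str) -> bool:
        return hap in (self.hap1, self.hap2)

    def valid_for(self, locus: MarkerLocus) -> bool:
        """Whether every base is drawn from the locus's declared alleles."""
        return all(
            h[0] in locus.snp1_alleles and h[1] in locus.snp2_alleles
            for h in self.haplotypes
        )


def snp1_genotype(g: HaplotypeGenotype) -> tuple[str, str]:
    """SNP1 genotype of a haplotype-pair genotype, order-insensitive.

    The ARMS primers target SNP1 regardless of SNP2, so mixture and plasma
    detection are driven entirely by this projection.
    """
    return g.snp1_alleles()


@dataclass(frozen=True)
class Panel:
    """An ordered collection of SNP-SNP loci with unique identifiers."""

    loci: tuple[MarkerLocus, ...]
    _by_id: dict[str, MarkerLocus] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = [loc.locus_id for loc in self.loci]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelValidationError(f"duplicate locus_id(s): {dupes}")
        object.__setattr__(self, "_by_id", {loc.locus_id: loc for loc in self.loci})

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[MarkerLocus]:
        return iter(self.loci)

    def __getitem__(self, locus_id: str) -> MarkerLocus:
        return self._by_id[locus_id]

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_id

    @property
    def locus_ids(self) -> tuple[str, ...]:
        return tuple(loc.locus_id for loc in self.loci)

    def primer(self, primer_id: str) -> PrimerSpec:
        for loc in self.loci:
            for p in loc.primers:
                if p.primer_id == primer_id:
                    return p
        raise KeyError(primer_id)

    def locus_of_primer(self, primer_id: str) -> MarkerLocus:
        for loc in self.loci:
            if any(p.primer_id == primer_id for p in loc.primers):
                return loc
        raise KeyError(primer_id)


def _parse_allele_pair(text: str, line_no: int) -> tuple[str, str]:
    parts = text.split("/")
    if len(parts) != 2:
        raise PanelFormatError(f"line {line_no}: allele pair {text!r} not 'X/Y'")
    return (parts[0], parts[1])


def _read_panel_stream(handle: Iterable[str], source: str) -> Panel:
    rows = []
    header: list[str] | None = None
    for line_no, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            if tuple(header) != PANEL_COLUMNS:
                raise PanelFormatError(
                    f"{source}, line {line_no}: header {header} does not match "
                    f"panel TSV columns {list(PANEL_COLUMNS)}"
                )
            continue
        if len(fields) != len(PANEL_COLUMNS):
            raise PanelFormatError(
                f"{source}, line {line_no}: expected {len(PANEL_COLUMNS)} "
                f"columns, got {len(fields)}"
            )
        rec = dict(zip(PANEL_COLUMNS, fields))
        try:
            snp1 = _parse_allele_pair(rec["snp1_alleles"], line_no)
            snp2 = _parse_allele_pair(rec["snp2_alleles"], line_no)
            loc = MarkerLocus(
                locus_id=rec["locus_id"],
                snp1_alleles=snp1,
                snp2_alleles=snp2,
                arms_amplicon_bp=int(rec["arms_amplicon_bp"]),
                sbe_amplicon_bp=int(rec["sbe_amplicon_bp"]),
                primers=(
                    PrimerSpec(
                        primer_id=f"{rec['locus_id']}-F1",
                        target_snp1_allele=rec["f1_target"],
                        lod_ng=float(rec["f1_lod_ng"]),
                        observed_size_bp=int(rec["f1_observed_bp"]),
                    ),
                    PrimerSpec(
                        primer_id=f"{rec['locus_id']}-F2",
                        target_snp1_allele=rec["f2_target"],
                        lod_ng=float(rec["f2_lod_ng"]),
                        observed_size_bp=int(rec["f2_observed_bp"]),
                    ),
                ),
            )
        except (ValueError, KeyError) as exc:
            if isinstance(exc, (PanelFormatError, PanelValidationError)):
                raise
            raise PanelFormatError(f"{source}, line {line_no}: {exc}") from exc
        rows.append(loc)
    if not rows:
        raise PanelFormatError(f"{source}: no panel rows found")
    return Panel(tuple(rows))


def load_panel(path: str | Path | None = None) -> Panel:
    """Load a panel TSV; with no path, the bundled 15-locus panel."""
    if path is None:
        return default_panel()
    p = Path(path)
    with p.open("r", encoding="utf-8") as handle:
        return _read_panel_stream(handle, str(p))


def default_panel() -> Panel:
    text = resources.files("snpsnp.data").joinpath("panel.tsv").read_text("utf-8")
    return _read_panel_stream(io.StringIO(text), "bundled panel.tsv")


def save_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel in the TSV dialect `load_panel` reads (lossless)."""
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(PANEL_COLUMNS)
        for loc in panel:
            f1, f2 = loc.primers
            writer.writerow(
                [
                    loc.locus_id,
                    "/".join(loc.snp1_alleles),
                    "/".join(loc.snp2_alleles),
                    loc.arms_amplicon_bp,
                    loc.sbe_amplicon_bp,
                    f1.target_snp1_allele,
                    _fmt_ng(f1.lod_ng),
                    f1.observed_size_bp,
                    f2.target_snp1_allele,
                    _fmt_ng(f2.lod_ng),
                    f2.observed_size_bp,
                ]
            )


def _fmt_ng(x: float) -> str:
    s = f"{x:.10f}".rstrip("0")
    return s + "0" if s.endswith(".") else s


@dataclass(frozen=True)
class PanelSizeSummary:
    """Amplicon-size accounting for a panel.

    ARMS statistics are over per-locus amplicon lengths; the SBE mean is
    over the distinct per-locus SBE amplicon sizes (the published averaging
    convention).  Means are rounded half-up to whole bp.
    """

    arms_mean_bp: int
    arms_min_bp: int
    arms_max_bp: int
    sbe_mean_bp: int
    sbe_min_bp: int
    sbe_max_bp: int
    sbe_sizes_bp: dict[str, int]


def panel_size_summary(panel: Panel) -> PanelSizeSummary:
    if len(panel) == 0:
        raise PanelValidationError("cannot summarize an empty panel")
    arms = [loc.arms_amplicon_bp for loc in panel]
    sbe = [loc.sbe_amplicon_bp for loc in panel]
    return PanelSizeSummary(
        arms_mean_bp=int(round_half_up(sum(arms) / len(arms))),
        arms_min_bp=min(arms),
        arms_max_bp=max(arms),
        sbe_mean_bp=int(round_half_up(sum(sbe) / len(sbe))),
        sbe_min_bp=min(sbe),
        sbe_max_bp=max(sbe),
        sbe_sizes_bp={loc.locus_id: loc.sbe_amplicon_bp for loc in panel},
    )
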