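"""End-to-end noninvasive prenatal paternity testing (NIPPT) analysis.

For each family: classify the panel against the reference trio genotypes,
then run one simulated single-primer ARMS/SBE reaction per informative
marker on the plasma mixture (maternal background + fetal component, both
attenuated by cfDNA fragment-length survival) under the elevated-cycle
protocol.  Cohort summaries reproduce the expected/observed accounting and
the per-primer detection-rate table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import io as snpio
from .amplification import (
    AmplificationParams,
    Contributor,
    MixtureSpec,
    PLASMA_PARAMS,
    simulate_peak,
)
from .degradation import amplicon_survival
from .informativeness import TrioRecord, classify_trio, expected_informative_count
from .panel import Panel, round_half_up
from .synthetic import PlasmaSample

__all__ = [
    "PrimerOutcome",
    "FamilyReport",
    "CohortSummary",
    "CorrelationReport",
    "run_family",
    "summarize_cohort",
    "summarize_primer_table",
    "correlation_report",
    "reports_from_counts",
    "load_table1_reports",
]


@dataclass(frozen=True)
class PrimerOutcome:
    """One single-primer plasma reaction for one informative marker."""

    primer_id: str
    locus_id: str
    detected: bool
    height_rfu: float
    observed_size_bp: int


@dataclass(frozen=True)
class FamilyReport:
    family_id: str
    cfdna_conc_ng_per_ul: float | None
    expected_count: int
    observed_count: int
    outcomes: tuple[PrimerOutcome, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.observed_count <= self.expected_count:
            raise ValueError(
                f"family {self.family_id}: observed_count must lie in "
                f"[0, expected_count]"
            )


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level accounting of informative-marker detection."""

    n_families: int
    total_expected: int
    total_observed: int
    #: 100 * observed/expected, rounded half-up to one decimal; None when
    #: no informative marker existed to attempt
    detection_rate_percent: float | None
    per_primer: pd.DataFrame = field(compare=False)
    size_min_bp: int | None = None
    size_max_bp: int | None = None
    size_mean_bp: int | None = None


def run_family(
    trio: TrioRecord,
    plasma: PlasmaSample,
    panel: Panel,
    params: AmplificationParams = PLASMA_PARAMS,
    rng: np.random.Generator | None = None,
    template_ul: float = 1.0,
) -> FamilyReport:
    """Detect a family's informative markers in its plasma sample.

    Each informative marker gets an independent single-plex reaction on a
    two-contributor mixture: maternal mass (1-ff) * conc * template_ul and
    fetal mass ff * conc * template_ul, each scaled by the probability
    that the locus's ARMS amplicon survives cfDNA fragmentation.  A family
    with no informative marker yields an empty (not erroneous) report.
    """
    calls = classify_trio(trio, panel)
    expected = expected_informative_count(calls)
    outcomes: list[PrimerOutcome] = []
    for call in calls:
        if not call.informative or call.primer_id is None:
            continue
        locus = panel[call.locus_id]
        primer = panel.primer(call.primer_id)
        survival = amplicon_survival(locus.arms_amplicon_bp, plasma.fragment_state)
        mix = MixtureSpec(
            (
                Contributor(
                    plasma.fetal_genotypes,
                    plasma.fetal_conc_ng_per_ul * template_ul * survival,
                ),
                Contributor(
                    plasma.maternal_genotypes,
                    plasma.maternal_conc_ng_per_ul * template_ul * survival,
                ),
            ),
            sample_id=f"{trio.family_id}-plasma",
        )
        row = simulate_peak(locus, primer, mix, params, rng)
        outcomes.append(
            PrimerOutcome(
                primer_id=call.primer_id,
                locus_id=call.locus_id,
                detected=row["detected"],
                height_rfu=row["height_rfu"],
                observed_size_bp=row["observed_size_bp"],
            )
        )
    observed = sum(o.detected for o in outcomes)
    return FamilyReport(
        family_id=trio.family_id,
        cfdna_conc_ng_per_ul=plasma.cfdna_conc_ng_per_ul,
        expected_count=expected,
        observed_count=observed,
        outcomes=tuple(outcomes),
    )


def summarize_cohort(reports: list[FamilyReport]) -> CohortSummary:
    """Totals, overall detection rate and per-primer tallies for a cohort."""
    if not reports:
        raise ValueError("summarize_cohort needs at least one family report")
    total_expected = sum(r.expected_count for r in reports)
    total_observed = sum(r.observed_count for r in reports)
    rate = (
        round_half_up(100.0 * total_observed / total_expected, 1)
        if total_expected > 0
        else None
    )
    tallies: dict[str, dict] = {}
    sizes: list[int] = []
    for report in reports:
        for out in report.outcomes:
            t = tallies.setdefault(
                out.primer_id,
                {"primer_id": out.primer_id, "successful": 0, "total": 0},
            )
            t["total"] += 1
            t["successful"] += out.detected
            if out.detected:
                sizes.append(out.observed_size_bp)
    per_primer = pd.DataFrame(
        sorted(tallies.values(), key=lambda t: t["primer_id"]),
        columns=["primer_id", "successful", "total"],
    )
    if len(per_primer):
        per_primer["detection_rate"] = per_primer["successful"] / per_primer["total"]
    else:
        per_primer["detection_rate"] = pd.Series(dtype=float)
    return CohortSummary(
        n_families=len(reports),
        total_expected=total_expected,
        total_observed=total_observed,
        detection_rate_percent=rate,
        per_primer=per_primer,
        size_min_bp=min(sizes) if sizes else None,
        size_max_bp=max(sizes) if sizes else None,
        size_mean_bp=int(round_half_up(sum(sizes) / len(sizes))) if sizes else None,
    )


def summarize_primer_table(detection: pd.DataFrame) -> dict:
    """Column summaries of a per-primer detection table.

    Reproduces the published averaging conventions: ARMS and observed-size
    means over primer rows, the SBE mean over the distinct per-locus SBE
    sizes (a locus's two primers share one SBE amplicon).
    """
    df = detection.copy()
    df["locus_id"] = df["primer_id"].str.split("-").str[0]
    per_locus_sbe = df.groupby("locus_id")["sbe_amplicon_bp"].first()
    return {
        "n_primers": int(len(df)),
        "total_successful": int(df["successful"].sum()),
        "total_attempts": int(df["total"].sum()),
        "arms_mean_bp": int(round_half_up(df["arms_amplicon_bp"].mean())),
        "arms_min_bp": int(df["arms_amplicon_bp"].min()),
        "arms_max_bp": int(df["arms_amplicon_bp"].max()),
        "sbe_per_locus_mean_bp": int(round_half_up(per_locus_sbe.mean())),
        "sbe_min_bp": int(df["sbe_amplicon_bp"].min()),
        "sbe_max_bp": int(df["sbe_amplicon_bp"].max()),
        "observed_mean_bp": int(round_half_up(df["observed_size_bp"].mean())),
        "per_primer_rates": dict(
            zip(df["primer_id"], df["successful"] / df["total"])
        ),
    }


@dataclass(frozen=True)
class CorrelationReport:
    """Association between cfDNA concentration and detection fraction."""

    spearman_rho: float
    n_families: int
    zero_variance: bool
    table: pd.DataFrame = field(compare=False)


def correlation_report(reports: list[FamilyReport]) -> CorrelationReport:
    """Spearman rank correlation of concentration vs per-family detection
    fraction, over families with >= 1 informative marker and a quantified
    concentration.  Descriptive only; no significance test is attached
    because the underlying claim is qualitative."""
    rows = [
        {
            "family_id": r.family_id,
            "cfdna_conc_ng_per_ul": r.cfdna_conc_ng_per_ul,
            "detection_fraction": r.observed_count / r.expected_count,
        }
        for r in reports
        if r.expected_count > 0 and r.cfdna_conc_ng_per_ul is not None
    ]
    if len(rows) < 3:
        raise ValueError(
            "correlation_report needs >= 3 families with informative markers "
            "and quantified concentrations"
        )
    table = pd.DataFrame(rows)
    zero_variance = (
        table["detection_fraction"].nunique() == 1
        or table["cfdna_conc_ng_per_ul"].nunique() == 1
    )
    if zero_variance:
        rho = float("nan")
    else:
        rho = float(
            stats.spearmanr(
                table["cfdna_conc_ng_per_ul"], table["detection_fraction"]
            ).statistic
        )
    return CorrelationReport(
        spearman_rho=rho,
        n_families=len(table),
        zero_variance=zero_variance,
        table=table,
    )


def reports_from_counts(counts: pd.DataFrame) -> list[FamilyReport]:
    """Build minimal FamilyReports from an accounting table with columns
    family_id, cfdna_conc_ng_per_ul, expected_informative, observed_informative."""
    reports = []
    for row in counts.itertuples(index=False):
        conc = row.cfdna_conc_ng_per_ul
        reports.append(
            FamilyReport(
                family_id=str(row.family_id),
                cfdna_conc_ng_per_ul=None if pd.isna(conc) else float(conc),
                expected_count=int(row.expected_informative),
                observed_count=int(row.observed_informative),
            )
        )
    return reports


def load_table1_reports() -> list[FamilyReport]:
    """FamilyReports for the bundled reference-cohort accounting fixture."""
    return reports_from_counts(snpio.load_table1_counts())
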