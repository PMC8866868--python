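"""Readers and writers for the package's plain-text interchange formats.

Genotype CSV: columns ``sample_id, locus_id, genotype`` with genotypes in
haplotype-pair notation ("CA-TG").  Bundled fixtures: the reference-cohort
accounting table (per-family concentration, expected and observed
informative-marker counts) and the per-primer detection table.
"""

from __future__ import annotations

import io as _io
from importlib import resources
from pathlib import Path

import pandas as pd

from .panel import HaplotypeGenotype, PanelFormatError

__all__ = [
    "read_genotypes_csv",
    "write_genotypes_csv",
    "load_table1_counts",
    "load_table2_detection",
]

GenotypeMap = dict[str, dict[str, HaplotypeGenotype]]


def read_genotypes_csv(path: str | Path) -> GenotypeMap:
    """Parse a genotype CSV into {sample_id: {locus_id: genotype}}."""
    df = pd.read_csv(path, comment="#", dtype=str)
    required = {"sample_id", "locus_id", "genotype"}
    if not required <= set(df.columns):
        raise PanelFormatError(
            f"{path}: genotype CSV must have columns {sorted(required)}"
        )
    out: GenotypeMap = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.sample_id), {})[str(row.locus_id)] = (
            HaplotypeGenotype.from_string(str(row.genotype))
        )
    return out


def write_genotypes_csv(genotypes: GenotypeMap, path: str | Path) -> None:
    rows = [
        {"sample_id": sid, "locus_id": lid, "genotype": str(g)}
        for sid, per_locus in genotypes.items()
        for lid, g in per_locus.items()
    ]
    pd.DataFrame(rows, columns=["sample_id", "locus_id", "genotype"]).to_csv(
        path, index=False
    )


def _read_bundled(name: str) -> pd.DataFrame:
    text = resources.files("snpsnp.data").joinpath(name).read_text("utf-8")
    return pd.read_csv(_io.StringIO(text), comment="#")


def load_table1_counts() -> pd.DataFrame:
    """Per-family cfDNA concentration and expected/observed counts.

    ``cfdna_conc_ng_per_ul`` is NaN for the one family whose plasma sample
    fell below the quantitation range.
    """
    df = _read_bundled("table1_counts.csv")
    df["family_id"] = df["family_id"].astype(str)
    return df


def load_table2_detection() -> pd.DataFrame:
    """Per-primer successful/total detection tallies and amplicon sizes."""
    return _read_bundled("table2_detection.csv")
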