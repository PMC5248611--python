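"""Exon-level copy-number detection from per-smMIP unique-read counts.

Unique-read counts per probe, across a cohort of samples, are normalized in
three steps: (1) each sample's counts are divided by that sample's total
(library-size correction), (2) each probe's values are divided by the
probe's cohort mean, so the cohort average per probe is 1 by construction,
(3) probe values are averaged per exon per sample.  A heterozygous exon
deletion in a tumor of purity rho then shows up as an exon ratio near
1 - rho/2 (0.5 for a germline heterozygous deletion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

DELETION_THRESHOLD = 0.7
DUPLICATION_THRESHOLD = 1.3


@dataclass
class ExonRatioProfile:
    """Normalized per-sample ratios at probe and exon resolution."""

    smmip_ratios: pd.DataFrame   # samples x smMIPs, cohort probe mean == 1
    exon_ratios: pd.DataFrame    # samples x exons
    excluded_samples: list[str] = field(default_factory=list)


def normalize_counts(
    counts: pd.DataFrame,
    exon_map: pd.Series | dict,
    min_sample_total: int = 1000,
) -> ExonRatioProfile:
    """Population normalization of a samples x smMIPs unique-read matrix.

    ``exon_map`` maps every smMIP column to exactly one exon.  Samples whose
    total unique-read count is below ``min_sample_total`` are excluded from
    the cohort before normalization (their depth makes ratios unreliable)
    and reported on the profile.  Needs at least 2 remaining samples.
    """
    if isinstance(exon_map, dict):
        exon_map = pd.Series(exon_map)
    missing = set(counts.columns) - set(exon_map.index)
    if missing:
        raise ValueError(f"smMIPs without an exon assignment: {sorted(missing)}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")

    totals = counts.sum(axis=1)
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise ValueError(f"all-zero sample(s): {zero}")
    excluded = list(totals.index[totals < min_sample_total])
    kept = counts.loc[totals >= min_sample_total]
    if len(kept) < 2:
        raise ValueError(
            "population normalization needs at least 2 samples above the "
            f"depth floor (have {len(kept)})"
        )
    per_exon = exon_map.loc[list(kept.columns)]
    n_per_exon = per_exon.value_counts()
    thin = n_per_exon[n_per_exon < 2]
    if len(thin):
        warnings.warn(
            f"exons covered by a single smMIP: {sorted(thin.index)}; "
            "exon ratios there rest on one probe"
        )

    step1 = kept.div(kept.sum(axis=1), axis=0)          # per-sample fraction
    step2 = step1.div(step1.mean(axis=0), axis=1)       # cohort probe mean -> 1
    exon = step2.T.groupby(per_exon).mean().T           # average probes per exon
    return ExonRatioProfile(
        smmip_ratios=step2, exon_ratios=exon, excluded_samples=excluded
    )


def call_exon_cnv(
    profile: ExonRatioProfile,
    deletion_threshold: float = DELETION_THRESHOLD,
    duplication_threshold: float = DUPLICATION_THRESHOLD,
) -> pd.DataFrame:
    """Flag exons per sample: ratio below 0.7 -> deletion, above 1.3 -> duplication.

    Ratios in roughly [0.4, 0.7) are consistent with a heterozygous deletion
    (ratio 0.5 in a pure germline carrier; 1 - rho/2 for a somatic event at
    purity rho).  Returns a tidy frame (sample, exon, ratio, flag).
    """
    rows = []
    er = profile.exon_ratios
    for sample in er.index:
        for exon in er.columns:
            ratio = float(er.loc[sample, exon])
            if ratio < deletion_threshold:
                flag = "deletion"
            elif ratio > duplication_threshold:
                flag = "duplication"
            else:
                continue
            rows.append({"sample": sample, "exon": exon, "ratio": ratio, "flag": flag})
    return pd.DataFrame(rows, columns=["sample", "exon", "ratio", "flag"])


def load_count_matrix(path) -> pd.DataFrame:
    """Counts TSV: first column sample id, remaining columns smMIP ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def load_exon_map(path) -> pd.Series:
    """Two-column TSV: smmip_id, exon."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def write_ratios(profile: ExonRatioProfile, path) -> None:
    profile.exon_ratios.to_csv(path, sep="\t")
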