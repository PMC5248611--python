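"""MLPA and MS-MLPA peak-table normalization and ratio calling.

Multiplex ligation-dependent probe amplification reports one peak intensity
per probe per sample.  Population normalization adjusts each sample's peaks
by that sample's all-probe mean and each probe by its cohort mean, centring
the copy-number-neutral state at 1 without relying on designated reference
probes (so aneuploidies elsewhere do not skew the analysis).  The
methylation-specific variant (MS-MLPA) compares a HhaI-digested aliquot with
an undigested one: methylated targets resist digestion, so the normalized
digested/undigested signal ratio estimates the methylated fraction.

The 0.7/1.3 copy-number thresholds and the 0.15 methylation threshold are
kit-convention defaults, configurable per call.
"""

from __future__ import annotations

import pandas as pd

from .cnv import DELETION_THRESHOLD, DUPLICATION_THRESHOLD

METHYLATION_THRESHOLD = 0.15


def population_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize a samples x probes peak-intensity table to be centred at 1.

    Each sample's peaks are divided by that sample's mean over all probes,
    then each probe by its cohort mean.  Invariant to per-sample scaling and
    to sample order.
    """
    if len(table) < 2:
        raise ValueError("population normalization needs at least 2 samples")
    if (table.to_numpy() < 0).any():
        raise ValueError("negative peak intensities")
    means = table.mean(axis=1)
    if (means == 0).any():
        zero = list(means.index[means == 0])
        raise ValueError(f"all-zero sample(s): {zero}")
    step1 = table.div(means, axis=0)
    return step1.div(step1.mean(axis=0), axis=1)


def call_mlpa_cnv(
    ratios: pd.DataFrame,
    deletion_threshold: float = DELETION_THRESHOLD,
    duplication_threshold: float = DUPLICATION_THRESHOLD,
) -> pd.DataFrame:
    """Flag probes per sample from normalized ratios (tidy output frame)."""
    rows = []
    for sample in ratios.index:
        for probe in ratios.columns:
            r = float(ratios.loc[sample, probe])
            if r < deletion_threshold:
                flag = "deletion"
            elif r > duplication_threshold:
                flag = "duplication"
            else:
                continue
            rows.append({"sample": sample, "probe": probe, "ratio": r, "flag": flag})
    return pd.DataFrame(rows, columns=["sample", "probe", "ratio", "flag"])


def msmlpa_methylation(
    digested: pd.DataFrame,
    undigested: pd.DataFrame,
    methylation_probes: list[str] | None = None,
    reference_probes: list[str] | None = None,
    threshold: float = METHYLATION_THRESHOLD,
) -> pd.DataFrame:
    """Per-probe methylated fraction and binary call from paired peak tables.

    Both tables must share samples and probes (each probe pairs with itself
    across the two digests).  Within each sample, peaks are normalized by the
    mean of the reference probes (probes without a HhaI site, whose signal
    survives digestion — by default every probe not listed as
    methylation-sensitive); the methylated fraction of a sensitive probe is
    then its normalized digested signal over its normalized undigested
    signal.  A fraction at or above ``threshold`` is called methylated.
    Returns a tidy frame (sample, probe, fraction, methylated).
    """
    if set(digested.columns) != set(undigested.columns) or set(
        digested.index
    ) != set(undigested.index):
        raise ValueError("digested and undigested tables must pair sample-for-sample "
                         "and probe-for-probe")
    probes = methylation_probes if methylation_probes is not None else list(digested.columns)
    unknown = set(probes) - set(digested.columns)
    if unknown:
        raise ValueError(f"unpaired methylation probes: {sorted(unknown)}")
    if reference_probes is None:
        reference_probes = [p for p in digested.columns if p not in set(probes)]
        if not reference_probes:
            reference_probes = list(digested.columns)
    ref_d = digested[reference_probes].mean(axis=1)
    ref_u = undigested[reference_probes].mean(axis=1)
    if (ref_d == 0).any() or (ref_u == 0).any():
        raise ValueError("zero reference-probe signal in at least one sample")
    rows = []
    for sample in digested.index:
        for probe in probes:
            u = float(undigested.loc[sample, probe] / ref_u[sample])
            d = float(digested.loc[sample, probe] / ref_d[sample])
            fraction = max(0.0, d / u) if u > 0 else 0.0
            rows.append(
                {
                    "sample": sample,
                    "probe": probe,
                    "fraction": fraction,
                    "methylated": fraction >= threshold,
                }
            )
    return pd.DataFrame(rows, columns=["sample", "probe", "fraction", "methylated"])


def load_peak_table(path) -> pd.DataFrame:
    """Long-form TSV (sample, probe, intensity) -> samples x probes table."""
    df = pd.read_csv(path, sep="\t")
    return df.pivot(index="sample", columns="probe", values="intensity")
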