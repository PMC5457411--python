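"""Per-base-per-cycle error rates, intervals, LA correction and recurrence.

The headline statistic of the assay is a phenomenological rate: the number
of erroneous consensus bases divided by the product of the number of UMI
tags (templates), the template length, and the number of first-PCR cycles,

    rate = E / (U * L * C),

with a normal-approximation binomial 95% confidence interval.  Because the
linear-amplification synthesis that attaches the UMI contributes its own
errors (measured separately by the non-bottlenecked protocol), the PCR-only
rate is obtained by subtracting the expected linear-amplification
contribution: ``rate - la_rate / C``, equivalent to removing
``la_rate * U * L`` expected errors from the numerator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorRateEstimate",
    "estimate_error_rate",
    "binomial_ci",
    "correct_for_la",
    "make_estimate",
    "tabulate_error_rates",
    "aggregate_umi_counts",
    "la_pcr_ratio",
    "recurrence_table",
]


@dataclass
class ErrorRateEstimate:
    """One rate-table row: a (sample, experiment) error-rate estimate."""

    sample: str
    experiment: int
    error_count: int
    umi_count: int
    template_length: int
    cycles: int
    rate: float
    ci_low: float
    ci_high: float
    la_rate: float | None = None
    corrected_rate: float | None = None
    corrected_ci_low: float | None = None
    corrected_ci_high: float | None = None


def estimate_error_rate(error_count: int, umi_count: int,
                        template_length: int, cycles: int) -> float:
    """Errors per template base per PCR cycle: ``E / (U * L * C)``."""
    if error_count < 0:
        raise ValueError("error_count must be >= 0")
    if min(umi_count, template_length, cycles) < 1:
        raise ValueError("umi_count, template_length and cycles must be >= 1")
    return error_count / (umi_count * template_length * cycles)


def binomial_ci(rate: float, n: int, z: float = 1.96) -> tuple:
    """Normal-approximation binomial CI ``rate +/- z*sqrt(rate(1-rate)/n)``.

    The lower bound is floored at 0.  ``n`` is the number of Bernoulli
    trials, i.e. ``U * L * C`` for a rate estimate.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    half = z * np.sqrt(rate * (1.0 - rate) / n)
    return (max(0.0, rate - half), rate + half)


def correct_for_la(rate: float, la_rate: float, cycles: int) -> float:
    """PCR-only rate after removing the linear-amplification contribution.

    Subtracts ``la_rate / cycles`` (the single LA synthesis spread over the
    per-cycle denominator); a negative result is floored at 0 with a
    warning.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    corrected = rate - la_rate / cycles
    if corrected < 0:
        warnings.warn(
            f"LA correction exceeds the observed rate "
            f"({rate:.3g} < {la_rate / cycles:.3g}); flooring at 0",
            stacklevel=2,
        )
        return 0.0
    return corrected


def make_estimate(
    sample: str,
    experiment: int,
    error_count: int,
    umi_count: int,
    template_length: int = 150,
    cycles: int = 20,
    la_rate: float | None = None,
    z: float = 1.96,
) -> ErrorRateEstimate:
    """Build a complete rate-table row from raw counts."""
    n = umi_count * template_length * cycles
    rate = estimate_error_rate(error_count, umi_count, template_length, cycles)
    lo, hi = binomial_ci(rate, n, z)
    est = ErrorRateEstimate(
        sample, experiment, error_count, umi_count, template_length, cycles,
        rate, lo, hi, la_rate,
    )
    if la_rate is not None:
        est.corrected_rate = correct_for_la(rate, la_rate, cycles)
        shift = rate - est.corrected_rate
        est.corrected_ci_low = max(0.0, lo - shift)
        est.corrected_ci_high = max(0.0, hi - shift)
    return est


def tabulate_error_rates(manifest: pd.DataFrame, z: float = 1.96) -> pd.DataFrame:
    """Rate table from a run manifest.

    ``manifest`` columns: sample, experiment, error_count, umi_count and
    optionally template_length (default 150), cycles (default 20), la_rate.
    """
    rows = []
    for rec in manifest.to_dict("records"):
        est = make_estimate(
            sample=rec["sample"],
            experiment=int(rec["experiment"]),
            error_count=int(rec["error_count"]),
            umi_count=int(rec["umi_count"]),
            template_length=int(rec.get("template_length", 150) or 150),
            cycles=int(rec.get("cycles", 20) or 20),
            la_rate=None if pd.isna(rec.get("la_rate", np.nan)) else float(rec["la_rate"]),
            z=z,
        )
        rows.append(vars(est))
    return pd.DataFrame(rows)


def aggregate_umi_counts(umi_table: pd.DataFrame) -> tuple:
    """Combined per-assay UMI totals and their summary statistics.

    ``umi_table`` columns: sample, experiment, umi_count — normally two
    experiments per assay.  Assays missing a replicate are excluded with a
    warning.  Returns ``(per_assay_series, summary_dict)`` where the
    summary holds combined min/max/mean over assays.
    """
    counts = umi_table.groupby("sample")["umi_count"].agg(["sum", "count"])
    expected = umi_table["experiment"].nunique()
    incomplete = counts.index[counts["count"] < expected]
    if len(incomplete):
        warnings.warn(
            f"assays missing a replicate excluded: {sorted(incomplete)}",
            stacklevel=2,
        )
    combined = counts.loc[counts["count"] >= expected, "sum"]
    summary = {
        "min": float(combined.min()),
        "max": float(combined.max()),
        "mean": float(combined.mean()),
        "n_assays": int(len(combined)),
    }
    return combined, summary


def la_pcr_ratio(la_rate: float, per_cycle_rates) -> float:
    """How much more error-prone the LA synthesis is than one PCR cycle.

    ``la_rate`` divided by the mean of the assay's uncorrected per-cycle
    rates across experiments.
    """
    rates = np.asarray(list(per_cycle_rates), dtype=float)
    if np.any(rates <= 0) or la_rate < 0:
        raise ValueError("rates must be positive")
    return float(la_rate / rates.mean())


def recurrence_table(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    coverage_a: int | None = None,
    coverage_b: int | None = None,
) -> tuple:
    """Pair individual error frequencies across two replicate experiments.

    Outer join on (position, ref, alt); an error absent from one
    experiment is imputed at the detection floor, 1 / coverage of that
    experiment.  Returns ``(paired_frame, pearson_r_of_log10_frequencies)``.
    """
    key = ["position", "ref", "alt"]
    a = calls_a[key + ["frequency"]].rename(columns={"frequency": "freq_1"})
    b = calls_b[key + ["frequency"]].rename(columns={"frequency": "freq_2"})
    merged = a.merge(b, on=key, how="outer", sort=True)
    cov_a = coverage_a if coverage_a is not None else (
        int(calls_a["coverage"].max()) if len(calls_a) else 1
    )
    cov_b = coverage_b if coverage_b is not None else (
        int(calls_b["coverage"].max()) if len(calls_b) else 1
    )
    merged["detected_1"] = merged["freq_1"].notna()
    merged["detected_2"] = merged["freq_2"].notna()
    merged["freq_1"] = merged["freq_1"].fillna(1.0 / max(cov_a, 1))
    merged["freq_2"] = merged["freq_2"].fillna(1.0 / max(cov_b, 1))
    if len(merged) >= 2:
        r = float(stats.pearsonr(np.log10(merged["freq_1"]),
                                 np.log10(merged["freq_2"]))[0])
    else:
        r = float("nan")
    return merged, r
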