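"""Consensus-error analytics, quality-threshold analysis and rate modeling.

Three questions are handled here.  First, how safe is majority consensus:
the probability that sequencing noise alone produces a consensus error is
computed analytically from the binomial tail (for Phred 30, five reads and
a 3-of-5 majority over a 100-nt read it is below one per million UMIs).
Second, what errors persist in quality-filtered data from an unamplified
library: thresholding base calls by quality and recomputing per-class
error rates exposes bridge-PCR (cluster-generation) errors, which carry
high quality scores and therefore grow in relative weight as the threshold
rises.  Third, which factors shape the error rate: a linear model on log10
rates with polymerase, substituted nucleotide, their interaction, template
position bin and local GC content, decomposed by sequential (type I)
ANOVA into percent of variance explained.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .simdata import SUBSTITUTIONS

__all__ = [
    "consensus_error_probability",
    "quality_threshold_errors",
    "profile_correlation",
    "normalize_positional_rates",
    "gc_window",
    "build_rate_model_input",
    "variance_decomposition",
    "error_rate_anova",
    "DEFAULT_ANOVA_TERMS",
]


def consensus_error_probability(
    per_base_error: float, reads: int, majority: int, read_length: int
) -> float:
    """Probability that sequencing noise creates >=1 consensus error per UMI.

    A position is corrupted when at least ``majority`` of the ``reads``
    covering it err there simultaneously; over ``read_length`` independent
    positions the per-UMI probability is
    ``1 - (1 - P[Binom(reads, p) >= majority])**read_length``.
    """
    if not (0.0 <= per_base_error <= 1.0):
        raise ValueError("per_base_error must be in [0, 1]")
    if majority > reads:
        raise ValueError("majority cannot exceed the number of reads")
    if majority < 1 or read_length < 0:
        raise ValueError("majority must be >= 1 and read_length >= 0")
    p_site = float(stats.binom.sf(majority - 1, reads, per_base_error))
    if p_site >= 1.0:
        return 1.0 if read_length >= 1 else 0.0
    return float(-math.expm1(read_length * math.log1p(-p_site)))


def quality_threshold_errors(
    reads,
    reference: str,
    thresholds,
) -> pd.DataFrame:
    """Per-class error rates of positionally aligned reads above quality cuts.

    ``reads`` yields objects with ``sequence`` and ``quality`` (Phred+33)
    aligned to ``reference`` from position 1.  For every threshold, only
    base calls with quality >= threshold are retained; the rate of class
    X>Y is the number of retained X>Y mismatches divided by the number of
    retained calls at X positions.  Thresholds retaining no bases for a
    class are reported with rate NaN.
    """
    ref_arr = np.frombuffer(reference.encode(), dtype=np.uint8)
    L = len(ref_arr)
    seqs, quals = [], []
    for r in reads:
        n = min(len(r.sequence), L)
        s = np.full(L, 0, dtype=np.uint8)
        q = np.full(L, -1, dtype=np.int64)
        s[:n] = np.frombuffer(r.sequence[:n].encode(), dtype=np.uint8)
        q[:n] = np.frombuffer(r.quality[:n].encode(), dtype=np.uint8).astype(np.int64) - 33
        seqs.append(s)
        quals.append(q)
    S = np.vstack(seqs) if seqs else np.zeros((0, L), np.uint8)
    Q = np.vstack(quals) if quals else np.zeros((0, L), np.int64)
    rows = []
    for thr in thresholds:
        keep = Q >= thr
        for sub in SUBSTITUTIONS:
            src, alt = ord(sub[0]), ord(sub[2])
            at_src = keep & (ref_arr[None, :] == src)
            retained = int(at_src.sum())
            errors = int((at_src & (S == alt)).sum())
            rows.append({
                "threshold": thr,
                "class": sub,
                "errors": errors,
                "retained_bases": retained,
                "rate": errors / retained if retained else np.nan,
            })
    return pd.DataFrame(rows)


def profile_correlation(profile_a, profile_b) -> float:
    """Pearson correlation of two equal-length fingerprints (NaN if degenerate)."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def normalize_positional_rates(rates: pd.DataFrame) -> tuple:
    """Z-scale log10 rates within (sample, base) strata; Spearman vs position.

    ``rates`` columns: sample, ref, position, rate (positive; zeros must be
    excluded upstream).  Within every (sample, ref) stratum the log10 rates
    are scaled to zero mean and unit standard deviation; strata smaller
    than 2 (or with zero variance) are dropped with a warning.  Returns
    ``(frame_with_z, spearman_r, p_value)``.
    """
    if (rates["rate"] <= 0).any():
        raise ValueError("rates must be positive (exclude zeros before log)")
    df = rates.copy()
    df["log_rate"] = np.log10(df["rate"].astype(float))
    pieces = []
    dropped = []
    for key, grp in df.groupby(["sample", "ref"], sort=True):
        sd = grp["log_rate"].std(ddof=0)
        if len(grp) < 2 or sd == 0:
            dropped.append(key)
            continue
        out = grp.copy()
        out["z"] = (grp["log_rate"] - grp["log_rate"].mean()) / sd
        pieces.append(out)
    if dropped:
        warnings.warn(f"strata dropped from positional normalization: {dropped}",
                      stacklevel=2)
    if not pieces:
        raise ValueError("no stratum large enough to normalize")
    result = pd.concat(pieces, ignore_index=True)
    rho, pval = stats.spearmanr(result["z"], result["position"])
    return result, float(rho), float(pval)


def gc_window(template: str, position: int, window: int = 15) -> float:
    """GC fraction in a window centered on a 1-based position, truncated at ends."""
    half = window // 2
    lo = max(0, position - 1 - half)
    hi = min(len(template), position - 1 + half + 1)
    seg = template[lo:hi]
    return (seg.count("G") + seg.count("C")) / len(seg)


def build_rate_model_input(
    calls: pd.DataFrame,
    template: str,
    bin_width: int = 15,
    gc_window_size: int = 15,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Model frame: log10 rate per (sample, position, ref, alt) + covariates.

    Covariates: ``polymerase`` (sample label), ``nucleotide`` (substituted
    source base), ``position_bin`` (index of the non-overlapping
    ``bin_width``-bp bin, ``ceil(position / bin_width)``), ``gc`` (GC
    fraction of a ``gc_window_size``-bp window centered on the base,
    truncated at template ends).  Zero-frequency cells are absent by
    construction; with ``pseudocount`` set, that value (e.g. half the
    minimum observable frequency) replaces zeros if any appear.
    """
    df = calls.copy()
    freq = df["frequency"].astype(float)
    if pseudocount is not None:
        freq = freq.where(freq > 0, pseudocount)
    if (freq <= 0).any():
        raise ValueError("zero frequencies present; set a pseudocount or drop them")
    out = pd.DataFrame({
        "polymerase": df["sample"].astype(str),
        "nucleotide": df["ref"].astype(str),
        "alt": df["alt"].astype(str),
        "position": df["position"].astype(int),
        "log_rate": np.log10(freq),
    })
    out["position_bin"] = ((out["position"] - 1) // bin_width + 1).astype(int)
    out["gc"] = [gc_window(template, p, gc_window_size) for p in out["position"]]
    return out


#: Sequential ANOVA term order used by :func:`error_rate_anova`.
DEFAULT_ANOVA_TERMS = (
    "C(polymerase)",
    "C(nucleotide)",
    "C(polymerase):C(nucleotide)",
    "C(position_bin)",
    "gc",
)


def variance_decomposition(
    data: pd.DataFrame,
    response: str,
    terms,
) -> tuple:
    """Sequential (type I) ANOVA as percent of total response variance.

    Fits an OLS model ``response ~ term_1 + ... + term_k`` and converts
    each term's sequential sum of squares to percent of the total sum of
    squares.  Returns ``(anova_frame, summary)`` where the frame has one
    row per term plus a residual row (percentages summing to 100), and the
    summary carries the total explained percentage and the Pearson
    correlation between fitted and observed values.  Rank-deficient terms
    are flagged, not dropped.
    """
    terms = list(terms)
    if not terms:
        raise ValueError("at least one model term is required")
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data).fit()
    anova = sm.stats.anova_lm(model, typ=1)
    y = np.asarray(data[response], dtype=float)
    total_ss = float(((y - y.mean()) ** 2).sum())
    frame = anova.reset_index().rename(columns={"index": "term"})
    if total_ss > 0:
        frame["percent_variance"] = 100.0 * frame["sum_sq"] / total_ss
    else:  # constant response: nothing to explain
        frame["percent_variance"] = 0.0
    frame["flagged"] = ~np.isfinite(frame["sum_sq"]) | (frame["df"] < 1)
    rank_deficient = model.df_model + 1 > np.linalg.matrix_rank(model.model.exog)
    if rank_deficient:
        warnings.warn("design matrix is rank deficient; flagged terms are unreliable",
                      stacklevel=2)
    explained = float(frame.loc[frame["term"] != "Residual", "percent_variance"].sum())
    fitted = model.fittedvalues
    observed = data[response]
    r = float(np.corrcoef(fitted, observed)[0, 1]) if observed.std() > 0 else float("nan")
    summary = {
        "total_explained_percent": explained,
        "r_predicted_observed": r,
        "n": int(model.nobs),
        "rank_deficient": bool(rank_deficient),
    }
    return frame, summary


def error_rate_anova(
    calls: pd.DataFrame,
    template: str,
    terms=DEFAULT_ANOVA_TERMS,
    **model_input_kwargs,
) -> tuple:
    """Variance decomposition of log10 error rates with the standard factors."""
    data = build_rate_model_input(calls, template, **model_input_kwargs)
    return variance_decomposition(data, "log_rate", terms)
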