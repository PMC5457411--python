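"""Substitution spectra, positional error profiles and fingerprint clustering.

A polymerase's substitution spectrum is the share of its errors falling in
each substitution class, normalized by template base composition: class
counts are divided by the template fraction of the mutated source base and
the result is renormalized to sum to 1, so a template rich in (say) A does
not inflate the apparent A>G share.  Spectra come in two flavors: the
strand-aware 12-class spectrum (available when strand identity is
preserved, as in linear amplification) and the strand-collapsed 6-class
spectrum pairing each substitution with its reverse complement.

An error profile (fingerprint) is the vector of substitution frequencies
over (template position x 3 alternative bases); replicate experiments with
one polymerase produce correlated profiles, and hierarchical clustering of
profiles separates polymerases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .simdata import SUBSTITUTIONS

__all__ = [
    "COLLAPSED_CLASSES",
    "SubstitutionSpectrum",
    "substitution_spectrum",
    "error_profile",
    "profile_matrix",
    "ClusteringResult",
    "cluster_profiles",
    "frequency_histograms",
]

#: Strand-collapsed classes pairing reverse-complement substitutions.
COLLAPSED_CLASSES = ("A>C/T>G", "A>G/T>C", "A>T/T>A", "C>A/G>T", "C>G/G>C", "C>T/G>A")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _collapse_class(sub: str) -> str:
    rc = f"{_COMPLEMENT[sub[0]]}>{_COMPLEMENT[sub[2]]}"
    for cls in COLLAPSED_CLASSES:
        if sub in cls.split("/") or rc in cls.split("/"):
            return cls
    raise ValueError(sub)


@dataclass
class SubstitutionSpectrum:
    """Composition-normalized substitution shares of one sample."""

    sample: str
    mode: str  # "stranded" (12 classes) or "collapsed" (6 classes)
    shares: pd.Series

    def __post_init__(self):
        total = float(self.shares.sum())
        if total > 0 and not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"shares must sum to 1, got {total}")


def _base_fractions(template: str) -> dict:
    L = len(template)
    return {b: template.count(b) / L for b in "ACGT"}


def substitution_spectrum(
    calls: pd.DataFrame,
    template: str,
    mode: str = "collapsed",
    sample: str | None = None,
) -> SubstitutionSpectrum:
    """Class shares of the called errors, normalized by base composition.

    Class counts are summed ``umi_count`` values; each count is divided by
    the template fraction of the class's source base (for collapsed
    classes, the combined fraction of both source bases) and shares are
    renormalized to 1.
    """
    if mode not in ("collapsed", "stranded"):
        raise ValueError(f"mode must be 'collapsed' or 'stranded', got {mode!r}")
    fractions = _base_fractions(template)
    for ref in calls["ref"].unique():
        if fractions.get(ref, 0.0) == 0.0:
            raise ValueError(f"calls reference base {ref!r} absent from template")
    label = sample if sample is not None else (
        str(calls["sample"].iloc[0]) if len(calls) else ""
    )
    if mode == "stranded":
        classes = list(SUBSTITUTIONS)
        keys = calls["ref"] + ">" + calls["alt"]
        denom = {c: fractions[c[0]] for c in classes}
    else:
        classes = list(COLLAPSED_CLASSES)
        keys = (calls["ref"] + ">" + calls["alt"]).map(_collapse_class)
        denom = {
            c: fractions[c.split("/")[0][0]] + fractions[c.split("/")[1][0]]
            for c in classes
        }
    counts = pd.Series(0.0, index=classes)
    if len(calls):
        grouped = calls.groupby(keys.values)["umi_count"].sum()
        counts.loc[grouped.index] = grouped.astype(float)
    normalized = pd.Series(
        [counts[c] / denom[c] if denom[c] > 0 else 0.0 for c in classes],
        index=classes,
    )
    total = normalized.sum()
    shares = normalized / total if total > 0 else normalized
    return SubstitutionSpectrum(label, mode, shares)


def _profile_index(template: str) -> pd.MultiIndex:
    tuples = []
    for pos, ref in enumerate(template, start=1):
        for alt in "ACGT":
            if alt != ref:
                tuples.append((pos, ref, alt))
    return pd.MultiIndex.from_tuples(tuples, names=["position", "ref", "alt"])


def error_profile(calls: pd.DataFrame, template: str) -> pd.Series:
    """Fingerprint vector: frequency of each (position, alt), zero-filled.

    Length ``3 * len(template)`` — three alternative bases per position —
    indexed by (position, ref, alt).
    """
    profile = pd.Series(0.0, index=_profile_index(template))
    for rec in calls.itertuples(index=False):
        key = (int(rec.position), rec.ref, rec.alt)
        if key not in profile.index:
            raise ValueError(f"call {key} inconsistent with template")
        profile.loc[key] = float(rec.frequency)
    return profile


def profile_matrix(profiles: dict) -> pd.DataFrame:
    """Stack ``{sample: profile}`` into a (units x samples) matrix."""
    return pd.DataFrame({name: profiles[name] for name in sorted(profiles)})


@dataclass
class ClusteringResult:
    sample_linkage: np.ndarray
    sample_labels: list
    sample_order: list
    unit_linkage: np.ndarray | None
    dropped: list

    def newick(self) -> str:
        """Sample dendrogram in Newick format."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.sample_linkage, self.sample_labels)
        return str(tree).strip()


def cluster_profiles(
    profiles: pd.DataFrame,
    method: str = "average",
    cluster_units: bool = True,
) -> ClusteringResult:
    """Agglomerative clustering of fingerprints.

    Samples (columns) are clustered with correlation distance
    (1 - Pearson r) and profile units (rows) with Euclidean distance,
    both with the given linkage (default average).  Columns are ordered
    lexicographically before clustering so the result is input-order
    invariant; zero-variance columns are dropped with a warning.
    """
    cols = sorted(profiles.columns)
    data = profiles[cols]
    variances = data.var(axis=0, ddof=0)
    dropped = [c for c in cols if variances[c] == 0.0]
    if dropped:
        warnings.warn(
            f"zero-variance profiles dropped from clustering: {dropped}",
            stacklevel=2,
        )
        data = data.drop(columns=dropped)
    if data.shape[1] < 2:
        raise ValueError("need at least two non-degenerate profiles to cluster")
    sample_dist = pdist(data.T.to_numpy(), metric="correlation")
    sample_linkage = hierarchy.linkage(sample_dist, method=method)
    unit_linkage = None
    if cluster_units:
        unit_linkage = hierarchy.linkage(
            pdist(data.to_numpy(), metric="euclidean"), method=method
        )
    order = [list(data.columns)[i] for i in hierarchy.leaves_list(sample_linkage)]
    return ClusteringResult(sample_linkage, list(data.columns), order, unit_linkage, dropped)


def frequency_histograms(
    calls: pd.DataFrame,
    mode: str = "collapsed",
    bins: int = 20,
    mean_rate: float | None = None,
) -> dict:
    """Log10 frequency histograms of individual errors, per substitution class.

    Returns ``{class: (bin_edges, counts)}`` plus the overall mean rate
    under key ``"mean_rate"`` (annotation for the reference line).  Bins
    span the observed log10 frequency range; classes without calls map to
    empty histograms.
    """
    if not len(calls):
        raise ValueError("calls must be nonempty")
    keys = calls["ref"] + ">" + calls["alt"]
    if mode == "collapsed":
        keys = keys.map(_collapse_class)
        classes = COLLAPSED_CLASSES
    else:
        classes = SUBSTITUTIONS
    logf = np.log10(calls["frequency"].to_numpy(dtype=float))
    lo, hi = float(logf.min()), float(logf.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, bins + 1)
    out = {}
    for cls in classes:
        vals = logf[(keys == cls).to_numpy()]
        counts, _ = np.histogram(vals, bins=edges)
        out[cls] = (edges, counts)
    out["mean_rate"] = mean_rate
    return out
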