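"""Kinetic-profile classification and profile characterization.

Significant classes are labelled ``decreasing``, ``increasing`` or
``fluctuating`` by a rule that codifies what is otherwise a manual call:
the Spearman rank correlation rho between replicate-level counts and
time, combined with an endpoint comparison of per-timepoint means.

* rho <= -0.5 and last mean <= first mean  ->  decreasing
* rho >= +0.5 and last mean >= first mean  ->  increasing
* otherwise                                ->  fluctuating

Classes set aside by the constancy filter carry the fourth label,
``constant``, and are reintegrated for profile characterization. Profiles
are then characterized by their member peptides' property distributions
(Wilcoxon-Mann-Whitney for two groups, Kruskal-Wallis for more) and a PCA
of the standardized nine-descriptor space, one point per unique peptide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_aggregate import ClassAbundanceMatrix
from .properties import DESCRIPTOR_ORDER

__all__ = [
    "classify_profile",
    "classify_profiles",
    "compare_property_distributions",
    "profile_pca",
    "summarize_profiles",
    "PCAResult",
]

PROFILE_LABELS = ("decreasing", "increasing", "constant", "fluctuating")


def classify_profile(
    counts: pd.Series,
    rho_threshold: float = 0.5,
) -> tuple[str, float]:
    """Label one significant class from its replicate-level counts.

    *counts* is indexed by (replicate, timepoint_h). Returns
    ``(label, rho)`` where label is decreasing / increasing / fluctuating.
    Deterministic given the counts. Classes the constancy filter should
    have removed must not reach this function.
    """
    times = counts.index.get_level_values("timepoint_h").to_numpy(dtype=float)
    values = counts.to_numpy(dtype=float)
    if np.all(values == values[0]):
        raise ValueError(
            "constant counts reached profile classification; "
            "apply the constancy filter first"
        )
    rho = float(stats.spearmanr(values, times).statistic)
    means = counts.groupby(level="timepoint_h").mean()
    first, last = means.iloc[0], means.iloc[-1]
    if rho <= -rho_threshold and last <= first:
        return "decreasing", rho
    if rho >= rho_threshold and last >= first:
        return "increasing", rho
    return "fluctuating", rho


def classify_profiles(
    matrix: ClassAbundanceMatrix,
    significant: Sequence[str],
    constant: Sequence[str] = (),
    rho_threshold: float = 0.5,
) -> pd.DataFrame:
    """Label significant classes and reintegrate constant ones.

    Returns a DataFrame indexed by class with columns ``label, rho``
    (rho is NaN for constant classes).
    """
    rows = []
    for cls in significant:
        counts = matrix.counts.loc[cls].sort_index()
        label, rho = classify_profile(counts, rho_threshold)
        rows.append({"class": cls, "label": label, "rho": rho})
    for cls in constant:
        rows.append({"class": cls, "label": "constant", "rho": np.nan})
    out = pd.DataFrame(rows, columns=["class", "label", "rho"])
    return out.set_index("class")


def compare_property_distributions(
    groups: Mapping[str, pd.DataFrame],
) -> pd.Series:
    """Per-descriptor p-values for a difference between peptide groups.

    Each value of *groups* is a peptides x descriptors frame (columns as
    in :data:`~pepkin.properties.DESCRIPTOR_ORDER`). Two groups are
    compared by the Wilcoxon-Mann-Whitney rank-sum test, more than two by
    Kruskal-Wallis. Every group needs at least two members.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, frame in groups.items():
        if len(frame) < 2:
            raise ValueError(f"group {name!r} has fewer than two members")
    frames = list(groups.values())
    pvals = {}
    for prop in DESCRIPTOR_ORDER:
        samples = [f[prop].to_numpy(dtype=float) for f in frames]
        if np.ptp(np.concatenate(samples)) == 0:
            pvals[prop] = 1.0  # identical constant distributions
            continue
        if len(samples) == 2:
            res = stats.mannwhitneyu(samples[0], samples[1],
                                     alternative="two-sided")
        else:
            res = stats.kruskal(*samples)
        pvals[prop] = float(res.pvalue)
    return pd.Series(pvals, name="p_value")


@dataclass(frozen=True)
class PCAResult:
    """Scores, loadings and explained variance of the descriptor PCA.

    ``scores`` is peptides x components, ``loadings`` descriptors x
    components (orthonormal columns), ``explained`` the per-component
    fraction of total variance (sums to 1). ``labels`` aligns with the
    score rows; ``dropped`` lists zero-variance descriptors excluded
    before standardization.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained: np.ndarray
    labels: pd.Series
    dropped: tuple[str, ...] = ()


def profile_pca(
    properties: pd.DataFrame,
    labels: pd.Series,
) -> PCAResult:
    """PCA of standardized peptide descriptors, one point per peptide.

    Descriptors are centred and scaled to unit variance (PCA on the
    correlation structure); zero-variance descriptors are dropped with a
    warning. Requires at least three peptides.
    """
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    if len(properties) < 3:
        raise ValueError("PCA needs at least three peptides")
    cols = [c for c in DESCRIPTOR_ORDER if c in properties.columns]
    X = properties[cols].to_numpy(dtype=float)
    variances = X.var(axis=0)
    scale = np.maximum(np.abs(X).max(axis=0), 1.0) ** 2
    dropped = tuple(
        c for c, v, s in zip(cols, variances, scale) if v <= 1e-12 * s
    )
    if dropped:
        warnings.warn(
            f"dropping zero-variance descriptor(s): {', '.join(dropped)}",
            stacklevel=2,
        )
        keep = [c for c in cols if c not in dropped]
        cols = keep
        X = properties[cols].to_numpy(dtype=float)
    Z = StandardScaler().fit_transform(X)
    pca = PCA()
    scores = pca.fit_transform(Z)
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=properties.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=cols, columns=comp_names),
        explained=pca.explained_variance_ratio_,
        labels=labels.reindex(properties.index),
        dropped=dropped,
    )


def summarize_profiles(
    labels: pd.DataFrame,
    matrix: ClassAbundanceMatrix,
) -> pd.DataFrame:
    """Per-profile class, peptide and spectra counts.

    *labels* is the frame from :func:`classify_profiles`. Peptide counts
    are unique member sequences per profile; spectra are summed over all
    samples of the member classes.
    """
    rows = []
    for profile in PROFILE_LABELS:
        classes = list(labels.index[labels["label"] == profile])
        peptides = set()
        for cls in classes:
            peptides.update(matrix.members.get(cls, ()))
        spectra = (
            int(matrix.counts.loc[classes].to_numpy().sum()) if classes else 0
        )
        rows.append(
            {
                "profile": profile,
                "n_classes": len(classes),
                "n_peptides": len(peptides),
                "n_spectra": spectra,
            }
        )
    return pd.DataFrame(rows).set_index("profile")
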