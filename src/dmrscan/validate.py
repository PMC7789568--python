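"""Validation battery: permutation null, PCA nearest-centroid classification,
leave-one-out cross-validation, and batch-outlier DMR removal.

The classifier is deliberately minimal: center per-DMR RPKM, project onto the
first two principal components of the labeled training samples, and assign
each sample to the nearer group centroid (Euclidean).  Exact ties are left
unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .difftest import test_all
from .dmr import DMR, call_dmrs
from .windows import CountMatrix, WindowGrid

__all__ = [
    "PCAModel",
    "PermutationNull",
    "CVResult",
    "ClassificationResult",
    "dmr_rpkm",
    "pca_fit",
    "classify",
    "remove_outlier_dmrs",
    "permutation_test",
    "cross_validate",
    "blinded_workflow",
]


@dataclass
class PCAModel:
    dmrs: list[str]  # DMR labels, fixing the feature order
    means: np.ndarray  # per-DMR centering means (training samples)
    loadings: np.ndarray  # (2, n_dmrs), orthonormal rows
    explained_variance: np.ndarray  # fractions for the 2 kept components
    centroids: dict[str, np.ndarray]  # group -> 2-vector


@dataclass
class PermutationNull:
    n_permutations: int
    null_counts: list[int]
    observed: int
    seed: int

    @property
    def empirical_p(self) -> float:
        n_ge = sum(1 for c in self.null_counts if c >= self.observed)
        return (1 + n_ge) / (self.n_permutations + 1)


@dataclass
class CVResult:
    scheme: str
    folds: pd.DataFrame  # held_out, predicted, truth, n_dmrs_in_fold

    @property
    def accuracy(self) -> float:
        ok = (self.folds["predicted"] == self.folds["truth"]).sum()
        return ok / len(self.folds)


@dataclass
class ClassificationResult:
    sample: str
    predicted: str  # "case" | "control" | "unclassified"
    distances: dict[str, float]
    dmrs_removed_as_outliers: int = 0


def dmr_rpkm(
    counts: CountMatrix, dmrs: list[DMR], grid: WindowGrid | None = None
) -> pd.DataFrame:
    """Per-DMR RPKM (DMR rows x sample columns): member-window counts summed,
    normalized by DMR length and each sample's full library size."""
    zero = counts.library_size[counts.library_size <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    rows = {}
    for d in dmrs:
        member = counts.counts.loc[list(d.window_labels)].sum(axis=0)
        rows[d.label] = member / ((d.stop - d.start) / 1000.0) / (
            counts.library_size / 1e6
        )
    out = pd.DataFrame(rows).T
    out.index.name = "dmr"
    return out


def pca_fit(rpkm_matrix: pd.DataFrame, groups: pd.Series) -> PCAModel:
    """PCA (per-DMR centering, no scaling) of labeled training samples.

    ``rpkm_matrix`` has DMR rows and sample columns; only samples labeled
    case/control contribute to the fit and the centroids.
    """
    labeled = [s for s in rpkm_matrix.columns if groups.get(s) in ("case", "control")]
    if len(rpkm_matrix) < 2:
        raise ValueError("need at least 2 DMRs for PCA")
    for g in ("case", "control"):
        if sum(groups.get(s) == g for s in labeled) < 2:
            raise ValueError(f"need >= 2 {g} samples")
    X = rpkm_matrix[labeled].to_numpy().T  # samples x dmrs
    means = X.mean(axis=0)
    Xc = X - means
    _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[:2]
    var = S**2
    explained = var[:2] / var.sum() if var.sum() > 0 else np.zeros(2)
    scores = Xc @ loadings.T
    centroids = {}
    for g in ("case", "control"):
        sel = [i for i, s in enumerate(labeled) if groups[s] == g]
        centroids[g] = scores[sel].mean(axis=0)
    return PCAModel(
        dmrs=list(rpkm_matrix.index),
        means=means,
        loadings=loadings,
        explained_variance=explained,
        centroids=centroids,
    )


def classify(model: PCAModel, sample_rpkm: np.ndarray | pd.Series) -> ClassificationResult:
    """Nearest-centroid call in the model's 2-component space."""
    v = np.asarray(sample_rpkm, dtype=float)
    if v.shape != model.means.shape:
        raise ValueError(
            f"sample vector length {v.size} does not match model ({model.means.size} DMRs)"
        )
    z = (v - model.means) @ model.loadings.T
    dists = {g: float(np.linalg.norm(z - c)) for g, c in model.centroids.items()}
    d_case, d_control = dists["case"], dists["control"]
    if d_case == d_control:
        predicted = "unclassified"
    else:
        predicted = "case" if d_case < d_control else "control"
    name = sample_rpkm.name if isinstance(sample_rpkm, pd.Series) else ""
    return ClassificationResult(sample=str(name), predicted=predicted, distances=dists)


def remove_outlier_dmrs(
    train_rpkm: pd.DataFrame,
    groups: pd.Series,
    blinded_rpkm: pd.DataFrame,
    k: float = 3.0,
) -> tuple[list[str], int]:
    """Drop DMRs where some blinded value is > k SD from BOTH group means.

    Returns (surviving DMR labels, number removed).  Operationalizes batch-
    effect outlier removal; idempotent on the surviving set.
    """
    if not train_rpkm.index.equals(blinded_rpkm.index):
        raise ValueError("train and blinded matrices must share the same DMR rows")
    case = [s for s in train_rpkm.columns if groups.get(s) == "case"]
    control = [s for s in train_rpkm.columns if groups.get(s) == "control"]
    keep: list[str] = []
    removed = 0
    for label in train_rpkm.index:
        row = train_rpkm.loc[label]
        b = blinded_rpkm.loc[label].to_numpy(dtype=float)
        out_both = np.ones(len(b), dtype=bool)
        for cols in (case, control):
            m = row[cols].mean()
            sd = row[cols].std(ddof=1)
            out_both &= np.abs(b - m) > k * sd
        if out_both.any():
            removed += 1
        else:
            keep.append(label)
    if not keep:
        raise ValueError(
            "outlier rule removed every DMR; raise k (outlier SD threshold)"
        )
    return keep, removed


def permutation_test(
    counts: CountMatrix,
    grid: WindowGrid,
    n_permutations: int = 100,
    p_threshold: float = 1e-5,
    seed: int = 0,
    **test_kwargs,
) -> PermutationNull:
    """Label-permutation null for the DMR count at the working threshold.

    Group labels are shuffled among labeled samples preserving group sizes;
    a permutation that happens to equal the original labeling is kept and
    counted.  Empirical p uses the add-one rule, so it is never zero.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    labeled = counts.samples_in("case") + counts.samples_in("control")
    sizes = (len(counts.samples_in("case")), len(counts.samples_in("control")))
    sub = counts.subset_samples(labeled)
    observed = len(call_dmrs(test_all(sub, **test_kwargs), grid, p_threshold))
    rng = np.random.default_rng(seed)
    null_counts: list[int] = []
    for _ in range(n_permutations):
        perm = rng.permutation(labeled)
        relabeled = {s: "case" for s in perm[: sizes[0]]} | {
            s: "control" for s in perm[sizes[0]:]
        }
        permuted = sub.with_groups(relabeled)
        n = len(call_dmrs(test_all(permuted, **test_kwargs), grid, p_threshold))
        null_counts.append(n)
    return PermutationNull(
        n_permutations=n_permutations,
        null_counts=null_counts,
        observed=observed,
        seed=seed,
    )


def cross_validate(
    counts: CountMatrix,
    grid: WindowGrid,
    p_threshold: float = 1e-5,
    **test_kwargs,
) -> CVResult:
    """Leave-one-out CV with DMRs re-derived inside every fold.

    The held-out sample never influences DMR selection or the PCA fit; folds
    where no DMR reaches the threshold yield an ``unclassified`` prediction.
    """
    labeled = counts.samples_in("case") + counts.samples_in("control")
    for g in ("case", "control"):
        if len(counts.samples_in(g)) < 3:
            raise ValueError(f"need >= 3 {g} samples for leave-one-out")
    rows = []
    for held in labeled:
        train_ids = [s for s in labeled if s != held]
        train = counts.subset_samples(train_ids)
        results = test_all(train, **test_kwargs)
        dmrs = call_dmrs(results, grid, p_threshold)
        if not dmrs:
            rows.append(
                {"held_out": held, "predicted": "unclassified",
                 "truth": counts.groups[held], "n_dmrs_in_fold": 0}
            )
            continue
        fold_rpkm = dmr_rpkm(counts.subset_samples(labeled), dmrs, grid)
        model = pca_fit(fold_rpkm[train_ids], counts.groups[train_ids])
        pred = classify(model, fold_rpkm[held])
        rows.append(
            {"held_out": held, "predicted": pred.predicted,
             "truth": counts.groups[held], "n_dmrs_in_fold": len(dmrs)}
        )
    return CVResult(scheme="leave-one-out", folds=pd.DataFrame(rows))


def blinded_workflow(
    train: CountMatrix,
    blinded: CountMatrix,
    grid: WindowGrid,
    p_threshold: float = 1e-5,
    outlier_sd: float = 3.0,
    **test_kwargs,
) -> tuple[list[ClassificationResult], dict]:
    """Derive DMRs from training samples only, then classify blinded samples.

    Pipeline: test + call DMRs on the training set, per-DMR RPKM for both
    sets, batch-outlier DMR removal, PCA fit on training, nearest-centroid
    prediction per blinded sample.  Returns predictions plus provenance
    (DMR counts before/after outlier removal).
    """
    if not train.counts.index.equals(blinded.counts.index):
        raise ValueError("train and blinded counts must share the same window grid")
    results = test_all(train, **test_kwargs)
    dmrs = call_dmrs(results, grid, p_threshold)
    provenance = {"n_dmrs": len(dmrs), "n_dmrs_after_outlier_removal": len(dmrs),
                  "p_threshold": p_threshold, "outlier_sd": outlier_sd}
    if not blinded.samples:
        return [], provenance
    if not dmrs:
        raise ValueError(f"no DMRs at p < {p_threshold}; cannot classify")
    train_rpkm = dmr_rpkm(train, dmrs, grid)
    blinded_rpkm = dmr_rpkm(blinded, dmrs, grid)
    surviving, removed = remove_outlier_dmrs(
        train_rpkm, train.groups, blinded_rpkm, k=outlier_sd
    )
    provenance["n_dmrs_after_outlier_removal"] = len(surviving)
    model = pca_fit(train_rpkm.loc[surviving], train.groups)
    out = []
    for sample in blinded.samples:
        res = classify(model, blinded_rpkm.loc[surviving, sample])
        res.dmrs_removed_as_outliers = removed
        out.append(res)
    return out, provenance
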