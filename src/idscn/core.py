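"""Individualized differential structural covariance networks (IDSCN) by
network-template perturbation.

A structural covariance network (SCN) has one node per brain region and
edge weights given by the Pearson correlation of a morphometric measure
(here regional gray-matter volume) across subjects. The individualized
variant asks how much a *single* subject K perturbs the healthy-reference
network:

1.  rSCN: Pearson correlations over the n reference subjects, after
    residualizing each region's volumes on age, sex, education and total
    intracranial volume (so edges are partial correlations given those
    covariates).
2.  pSCN: the same construction over the n + 1 subjects obtained by
    adding K to the reference cohort.
3.  dSCN = pSCN - rSCN, standardized per edge into a Z-score

        Z = dSCN / ((1 - r^2) / (n - 1))

    where r is the reference edge correlation. (1 - r^2)/(n - 1) is the
    scale of the change a single additional subject can induce in a
    sample correlation, so Z is a unit-scale edge weight. Positive Z
    means the edge covariance is stronger in K than in the reference
    population, negative Z weaker. Two-sided p-values are read from the
    standard normal; edges passing a Bonferroni threshold over all
    R(R-1)/2 edges form K's differential-edge set.

The standard-normal null for Z is an approximation: empirically the null
Z is unit-scale and symmetric but heavier-tailed than Gaussian (it
behaves like a product of two near-normal scores), which makes the
per-subject edge test anti-conservative far in the tail. See the methods
note for measurements; group-level inference on Z (``idscn.group``) does
not rely on this approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import AlignedDataset, CovariateTable, RegionalVolumeTable, COVARIATE_COLUMNS

__all__ = [
    "CovariateModel",
    "ReferenceSCN",
    "IDSCN",
    "SignificantEdge",
    "residualize",
    "residualize_array",
    "pearson_correlation",
    "compute_reference_scn",
    "compute_perturbed_scn",
    "compute_idscn",
    "significant_edges",
    "individual_network",
    "cohort_networks",
    "upper_triangle",
]

#: minimum reference size: 4 covariates + intercept need n - 5 > 1 residual df
MIN_REFERENCE_SIZE = 7


@dataclass(frozen=True)
class CovariateModel:
    """Per-region OLS coefficients for [1, age, sex, education, tiv]."""

    coefficients: np.ndarray  # shape (5, R)
    covariate_names: tuple[str, ...] = ("intercept",) + COVARIATE_COLUMNS


@dataclass
class ReferenceSCN:
    """Reference structural covariance network.

    r_matrix is the R x R Pearson correlation matrix of covariate-adjusted
    gray-matter volumes over the n_ref reference subjects.
    """

    r_matrix: np.ndarray
    n_ref: int
    region_labels: tuple[str, ...]
    covariate_model: CovariateModel

    def __post_init__(self) -> None:
        r = np.asarray(self.r_matrix, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("r_matrix must be square")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("r_matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-12):
            raise ValueError("r_matrix must have unit diagonal")
        if np.any(np.abs(r) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        if self.n_ref < MIN_REFERENCE_SIZE:
            raise ValueError(
                f"reference cohort must have at least {MIN_REFERENCE_SIZE} "
                f"subjects (got {self.n_ref})"
            )
        self.r_matrix = r

    @property
    def n_regions(self) -> int:
        return self.r_matrix.shape[0]

    @property
    def n_edges(self) -> int:
        r = self.n_regions
        return r * (r - 1) // 2


@dataclass(frozen=True, order=True)
class SignificantEdge:
    """One differential edge of a subject's IDSCN (i < j, 0-based)."""

    p: float
    i: int
    j: int
    z: float
    label_i: str
    label_j: str


@dataclass
class IDSCN:
    """Individualized differential SCN of one subject."""

    subject_id: str
    region_labels: tuple[str, ...]
    delta_matrix: np.ndarray
    z_matrix: np.ndarray
    p_matrix: np.ndarray
    n_ref: int
    alpha: float
    significant: tuple[SignificantEdge, ...]

    @property
    def z_vector(self) -> np.ndarray:
        """Canonical upper-triangle (i < j) vectorization of z_matrix."""
        iu = np.triu_indices(self.z_matrix.shape[0], 1)
        return self.z_matrix[iu]


def upper_triangle(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (i < j) edge ordering for R regions: length R(R-1)/2."""
    return np.triu_indices(n_regions, 1)


# ---------------------------------------------------------------------------
# residualization

def _design_matrix(covariates: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(covariates)), covariates])
    return X


def residualize_array(
    volumes: np.ndarray, covariates: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """OLS-residualize each region (column) on [1, age, sex, education, tiv].

    Returns (residuals, coefficients); coefficients have shape (5, R).
    """
    V = np.asarray(volumes, dtype=float)
    X = _design_matrix(np.asarray(covariates, dtype=float))
    if V.shape[0] != X.shape[0]:
        raise ValueError("volumes and covariates disagree on subject count")
    # full-rank check, naming the offending covariate when possible
    names = ("intercept",) + COVARIATE_COLUMNS
    for k in range(1, X.shape[1]):
        if np.ptp(X[:, k]) == 0:
            raise ValueError(
                f"covariate {names[k]!r} is constant; design matrix is rank-deficient"
            )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design matrix is rank-deficient (collinear columns)")
    beta, *_ = np.linalg.lstsq(X, V, rcond=None)
    return V - X @ beta, beta


def residualize(
    volumes: RegionalVolumeTable, covariates: CovariateTable
) -> tuple[np.ndarray, CovariateModel]:
    """Table-level residualization; subjects must match and be aligned."""
    if volumes.subject_ids != covariates.subject_ids:
        raise ValueError(
            "volume and covariate tables list different subjects; "
            "run idscn.io.align_subjects first"
        )
    resid, beta = residualize_array(volumes.values, covariates.values)
    return resid, CovariateModel(coefficients=beta)


# ---------------------------------------------------------------------------
# correlation networks

def pearson_correlation(residuals: np.ndarray,
                        region_labels: Sequence[str] | None = None) -> np.ndarray:
    """Pearson correlation across subjects (rows) for each pair of regions."""
    resid = np.asarray(residuals, dtype=float)
    sd = resid.std(axis=0)
    if np.any(sd == 0):
        k = int(np.argwhere(sd == 0)[0][0])
        name = region_labels[k] if region_labels is not None else f"index {k}"
        raise ValueError(f"region {name} has zero variance after adjustment")
    return np.corrcoef(resid, rowvar=False)


def compute_reference_scn(
    volumes: RegionalVolumeTable, covariates: CovariateTable
) -> ReferenceSCN:
    """Build the reference SCN from the healthy cohort (residualize, then
    Pearson-correlate every pair of regions)."""
    resid, model = residualize(volumes, covariates)
    r = pearson_correlation(resid, volumes.region_labels)
    return ReferenceSCN(
        r_matrix=r,
        n_ref=len(volumes.subject_ids),
        region_labels=tuple(volumes.region_labels),
        covariate_model=model,
    )


def compute_perturbed_scn(
    ref_volumes: RegionalVolumeTable,
    ref_covariates: CovariateTable,
    subject_volumes: RegionalVolumeTable,
    subject_covariates: CovariateTable,
    *,
    refit: bool = True,
    reference_model: CovariateModel | None = None,
) -> np.ndarray:
    """Perturbed SCN: correlations over the n + 1 cohort formed by adding
    one subject to the reference cohort.

    By default the covariate regression is refit on all n + 1 subjects
    ("constructed in the same manner" as the reference). With
    ``refit=False`` the reference coefficients are applied unchanged to
    the added subject.
    """
    if subject_volumes.region_labels != ref_volumes.region_labels:
        raise ValueError("region labels of subject and reference differ")
    if len(subject_volumes.subject_ids) != 1:
        raise ValueError("exactly one subject must be added")
    k = subject_volumes.subject_ids[0]
    if k in set(ref_volumes.subject_ids):
        raise ValueError(f"subject {k!r} is already in the reference cohort")
    V = np.vstack([ref_volumes.values, subject_volumes.values])
    X = np.vstack([ref_covariates.values, subject_covariates.values])
    if refit:
        resid, _ = residualize_array(V, X)
    else:
        if reference_model is None:
            _, beta = residualize_array(ref_volumes.values, ref_covariates.values)
        else:
            beta = reference_model.coefficients
        resid = V - _design_matrix(X) @ beta
    return pearson_correlation(resid, ref_volumes.region_labels)


def compute_idscn(
    reference: ReferenceSCN,
    perturbed: np.ndarray,
    subject_id: str,
    *,
    alpha: float = 0.05,
    sqrt_variant: bool = False,
) -> IDSCN:
    """Standardize dSCN = pSCN - rSCN into edge Z-scores and p-values.

    Z = dSCN / ((1 - r^2)/(n - 1)) with r the reference edge correlation;
    ``sqrt_variant`` divides by the square root of that quantity instead
    (sensitivity analysis, off by default). Two-sided normal p-values;
    Bonferroni-significant edges (p < alpha / n_edges) are attached,
    ordered by ascending p with lexicographic tie-break.
    """
    r = reference.r_matrix
    p_mat = np.asarray(perturbed, dtype=float)
    if p_mat.shape != r.shape:
        raise ValueError("perturbed and reference matrices differ in shape")
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1 - 1e-12):
        i, j = np.argwhere((np.abs(r) >= 1 - 1e-12) & off)[0]
        raise ValueError(
            f"degenerate reference edge |r| = 1 between "
            f"{reference.region_labels[i]} and {reference.region_labels[j]}"
        )
    delta = p_mat - r
    scale = (1.0 - r**2) / (reference.n_ref - 1)
    if sqrt_variant:
        scale = np.sqrt(scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = delta / scale
    np.fill_diagonal(z, 0.0)
    np.fill_diagonal(delta, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    np.fill_diagonal(p, 1.0)
    sig = significant_edges(p, z, alpha, reference.region_labels)
    return IDSCN(
        subject_id=str(subject_id),
        region_labels=reference.region_labels,
        delta_matrix=delta,
        z_matrix=z,
        p_matrix=p,
        n_ref=reference.n_ref,
        alpha=alpha,
        significant=sig,
    )


def significant_edges(
    p_matrix: np.ndarray,
    z_matrix: np.ndarray,
    alpha: float,
    region_labels: Sequence[str],
) -> tuple[SignificantEdge, ...]:
    """Edges with p < alpha / n_edges (Bonferroni), as (i < j) pairs ordered
    by ascending p then lexicographically."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    R = p_matrix.shape[0]
    iu = upper_triangle(R)
    n_edges = iu[0].size
    thresh = alpha / n_edges
    mask = p_matrix[iu] < thresh
    edges = [
        SignificantEdge(
            p=float(p_matrix[i, j]),
            i=int(i),
            j=int(j),
            z=float(z_matrix[i, j]),
            label_i=str(region_labels[i]),
            label_j=str(region_labels[j]),
        )
        for i, j in zip(iu[0][mask], iu[1][mask])
    ]
    edges.sort(key=lambda e: (e.p, e.i, e.j))
    return tuple(edges)


# ---------------------------------------------------------------------------
# convenience drivers

def individual_network(
    ref_volumes: RegionalVolumeTable,
    ref_covariates: CovariateTable,
    subject_volumes: RegionalVolumeTable,
    subject_covariates: CovariateTable,
    *,
    alpha: float = 0.05,
    refit: bool = True,
    sqrt_variant: bool = False,
    reference: ReferenceSCN | None = None,
) -> IDSCN:
    """Full template-perturbation pass for one subject.

    ``reference`` may be passed to reuse a precomputed reference SCN when
    scoring many subjects against the same cohort.
    """
    if reference is None:
        reference = compute_reference_scn(ref_volumes, ref_covariates)
    pscn = compute_perturbed_scn(
        ref_volumes, ref_covariates, subject_volumes, subject_covariates,
        refit=refit, reference_model=reference.covariate_model,
    )
    return compute_idscn(
        reference, pscn, subject_volumes.subject_ids[0],
        alpha=alpha, sqrt_variant=sqrt_variant,
    )


def cohort_networks(
    dataset: AlignedDataset,
    reference_ids: Sequence[str],
    target_ids: Sequence[str] | None = None,
    *,
    alpha: float = 0.05,
    leave_one_out: bool = True,
    refit: bool = True,
    sqrt_variant: bool = False,
) -> dict[str, IDSCN]:
    """IDSCNs for every target subject against a reference cohort.

    Subjects outside the reference cohort are scored against the full
    reference. A reference subject's own network is built leave-one-out
    (the reference excludes that subject) unless ``leave_one_out=False``,
    in which case it is scored against the other n - 1 subjects as well
    but the perturbed network still uses all n.
    """
    ref_ids = list(reference_ids)
    ref_set = set(ref_ids)
    if target_ids is None:
        target_ids = dataset.subject_ids
    volumes, covariates = dataset.volumes, dataset.covariates
    ref_vol = volumes.subset(ref_ids)
    ref_cov = covariates.subset(ref_ids)
    full_reference = compute_reference_scn(ref_vol, ref_cov)

    out: dict[str, IDSCN] = {}
    for sid in target_ids:
        if sid in ref_set:
            sub_vol = volumes.subset([sid])
            sub_cov = covariates.subset([sid])
            if leave_one_out:
                # template excludes the subject; perturbation re-adds them
                others = [s for s in ref_ids if s != sid]
                loo_ref = compute_reference_scn(
                    volumes.subset(others), covariates.subset(others)
                )
                pscn = compute_perturbed_scn(
                    volumes.subset(others), covariates.subset(others),
                    sub_vol, sub_cov, refit=refit,
                    reference_model=loo_ref.covariate_model,
                )
                out[sid] = compute_idscn(
                    loo_ref, pscn, sid, alpha=alpha, sqrt_variant=sqrt_variant
                )
            else:
                # template keeps the subject; perturbation duplicates them
                dup_vol = RegionalVolumeTable(
                    sub_vol.data.set_axis([f"{sid}__dup"], axis=0)
                )
                dup_cov = CovariateTable(
                    sub_cov.data.set_axis([f"{sid}__dup"], axis=0)
                )
                pscn = compute_perturbed_scn(
                    ref_vol, ref_cov, dup_vol, dup_cov, refit=refit,
                    reference_model=full_reference.covariate_model,
                )
                out[sid] = compute_idscn(
                    full_reference, pscn, sid, alpha=alpha,
                    sqrt_variant=sqrt_variant,
                )
        else:
            out[sid] = individual_network(
                ref_vol, ref_cov, volumes.subset([sid]), covariates.subset([sid]),
                alpha=alpha, refit=refit, sqrt_variant=sqrt_variant,
                reference=full_reference,
            )
    return out
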