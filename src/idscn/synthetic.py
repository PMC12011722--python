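"""Synthetic cohorts with known covariance structure, injected edge-level
aberrations, and linked clinical variables.

The generator emulates a case-control morphometry study: a healthy
reference cohort and a patient group, each subject described by regional
gray-matter volumes (ml), nuisance covariates (age, sex, education,
total intracranial volume) and, for patients, clinical variables (HAMD
depression score, four cerebral small-vessel-disease MRI markers).

Generative model per subject::

    volume[r] = base[r] * (tiv / 1435)            # TIV proportionality
                + age_slope * (age - 65)
                + sex_effect * sex
                + edu_slope * (education - 12)
                + structural_sd * z[r]             # correlated component
                + noise_sd * eps[r]                # independent noise

with z ~ N(0, C) for a block-structured correlation matrix C. The
observable (covariate-adjusted) between-region correlation is C
attenuated by structural_sd^2 / (structural_sd^2 + noise_sd^2); the
attenuated matrix is reported as ground truth.

Patient aberrations are edge-level: for an injected edge (i, j) with
magnitude ``delta``, the patient's residuals at regions i and j are
*shifted* by ``delta`` residual standard deviations per region along
the direction that weakens (sign=+1) or strengthens (sign=-1) the
pair's covariance — a displacement of (+delta, -t*delta) in
residual-SD units, where t is the sign of the pair's true correlation.
At delta=0 the patient is exactly a healthy draw. The displacement side
alternates with patient index so group-level marginal means stay
balanced; the covariance displacement is identical on both sides.
A one-sided displacement of region j alone (conditional on region i)
was rejected: whatever its size, it moves the sample correlation by at
most ~|z_i|/sqrt(n) and cannot reliably dominate a 6,670-edge network
at reference sizes of a few dozen (see methods note).

Clinical link: a latent severity s ~ N(0,1) per patient drives both
HAMD and marker presence through Gaussian channels of correlation
``clinical_link``; at the default 0.85 the population Spearman
correlation between the 0-4 marker-count burden and HAMD is ~0.70.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._aal import AAL116_LABELS
from .io import (
    CovariateTable,
    RegionalVolumeTable,
    write_clinical_table,
    write_covariate_table,
    write_volume_table,
)

__all__ = [
    "BlockCorrelation",
    "CovariateEffects",
    "EdgePerturbation",
    "CohortSpec",
    "GroundTruth",
    "SyntheticCohort",
    "default_cohort_spec",
    "generate_reference_cohort",
    "generate_patient",
    "generate_cohort",
    "write_cohort",
]

#: displacement (residual SDs per region) for single-patient top-edge recovery
DELTA_INDIVIDUAL = 3.5
#: displacement for a group-shared aberrant edge (kept moderate so the
#: aberration does not bleed into neighbouring edges at group level)
DELTA_GROUP = 2.0

# marker prevalences among patients used to place probit cut-offs
_MARKER_PREVALENCE = {
    "wmh_present": 0.92,
    "lacune_present": 0.80,
    "epvs_present": 0.50,
    "cmb_present": 0.45,
}
# HAMD (patients) = 8 + floor(exp(mu + sigma * g)), g standard normal:
# mean ~10.8, SD ~4.4, floor 8 (patient inclusion requires HAMD > 7)
_HAMD_LOG_MU = 0.640
_HAMD_LOG_SIGMA = 1.053
_HAMD_MAX = 52  # ceiling of the 17-item scale


@dataclass(frozen=True)
class BlockCorrelation:
    """Block-structured correlation: a partition of regions into blocks
    with a common within-block correlation each, and one between-block
    correlation. Validated by Cholesky factorization."""

    blocks: tuple[tuple[int, ...], ...]
    within: tuple[float, ...]
    between: float = 0.05

    def matrix(self, n_regions: int) -> np.ndarray:
        C = np.full((n_regions, n_regions), self.between, dtype=float)
        if len(self.within) != len(self.blocks):
            raise ValueError("one within-correlation per block required")
        seen: set[int] = set()
        for block, w in zip(self.blocks, self.within):
            for a in block:
                if not 0 <= a < n_regions:
                    raise ValueError(f"region index {a} out of range")
                if a in seen:
                    raise ValueError(f"region index {a} in two blocks")
                seen.add(a)
            for a in block:
                for b in block:
                    if a != b:
                        C[a, b] = w
        np.fill_diagonal(C, 1.0)
        try:
            np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "block correlation model is not positive definite"
            ) from exc
        return C

    @classmethod
    def contiguous(cls, n_regions: int, block_size: int = 4,
                   within: float = 0.3, between: float = 0.05,
                   special_pairs: Sequence[tuple[int, int, float]] = (),
                   ) -> "BlockCorrelation":
        """Contiguous blocks of ``block_size`` over all regions, except that
        regions named in ``special_pairs`` (i, j, r) form their own
        two-region blocks with correlation r."""
        taken = {idx for i, j, _ in special_pairs for idx in (i, j)}
        rest = [r for r in range(n_regions) if r not in taken]
        blocks = [tuple(rest[s:s + block_size])
                  for s in range(0, len(rest), block_size)]
        within_list = [within] * len(blocks)
        for i, j, r in special_pairs:
            blocks.append((i, j))
            within_list.append(r)
        return cls(tuple(blocks), tuple(within_list), between)


@dataclass(frozen=True)
class CovariateEffects:
    """Linear covariate effects on regional volume (ml units)."""

    age_ml_per_year: float = -0.03
    sex_ml: float = 0.1
    education_ml_per_year: float = 0.02
    tiv_reference_ml: float = 1435.0
    tiv_proportional: bool = True

    @classmethod
    def null(cls) -> "CovariateEffects":
        return cls(0.0, 0.0, 0.0, 1435.0, False)


@dataclass(frozen=True)
class EdgePerturbation:
    """One injected covariance aberration: regions (i, j), displacement
    ``delta`` in residual SDs per region, sign +1 weakens / -1 strengthens."""

    region_i: int
    region_j: int
    delta: float = DELTA_INDIVIDUAL
    sign: int = 1

    def __post_init__(self) -> None:
        if self.region_i == self.region_j:
            raise ValueError("aberrant edge must join two distinct regions")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 (weaken) or -1 (strengthen)")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic study; identical specs (including
    seed) reproduce identical cohorts bit-for-bit."""

    n_reference: int = 34
    n_patients: int = 22
    n_regions: int = 116
    covariance_model: BlockCorrelation | None = None
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    structural_sd: float = 0.5
    noise_sd: float = 0.15
    aberrant_edges: tuple[tuple[EdgePerturbation, ...], ...] | None = None
    clinical_link: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least two regions")
        if self.n_reference < 1 or self.n_patients < 0:
            raise ValueError("cohort sizes must be positive")
        if not 0 <= self.clinical_link <= 1:
            raise ValueError("clinical_link must lie in [0, 1]")
        if self.structural_sd <= 0 or self.noise_sd < 0:
            raise ValueError("structural_sd must be > 0 and noise_sd >= 0")
        if self.aberrant_edges is not None:
            if len(self.aberrant_edges) != self.n_patients:
                raise ValueError(
                    "aberrant_edges must list one (possibly empty) tuple per patient"
                )
            for per_patient in self.aberrant_edges:
                for e in per_patient:
                    if not (0 <= e.region_i < self.n_regions
                            and 0 <= e.region_j < self.n_regions):
                        raise ValueError(
                            f"aberrant edge ({e.region_i}, {e.region_j}) out of range"
                        )

    def correlation_model(self) -> BlockCorrelation:
        if self.covariance_model is not None:
            return self.covariance_model
        return default_covariance_model(self.n_regions)

    def region_labels(self) -> tuple[str, ...]:
        if self.n_regions == 116:
            return AAL116_LABELS
        return tuple(f"R{k + 1:03d}" for k in range(self.n_regions))

    def patient_edges(self, patient_index: int) -> tuple[EdgePerturbation, ...]:
        if self.aberrant_edges is None:
            return ()
        return self.aberrant_edges[patient_index]


@dataclass
class GroundTruth:
    """What the generator knows: the observable (attenuated) correlation
    matrix, the injected edges per patient, and each patient's latent
    clinical severity. ``base_volumes`` carries the per-region mean scale
    needed to regenerate individual patients deterministically."""

    true_correlation: np.ndarray
    injected_edges: tuple[tuple[EdgePerturbation, ...], ...]
    latent_severity: np.ndarray
    base_volumes: np.ndarray
    cholesky: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(np.diag(self.true_correlation), 1.0):
            raise ValueError("ground-truth correlation must have unit diagonal")


@dataclass
class SyntheticCohort:
    volumes: RegionalVolumeTable       # reference + patients
    covariates: CovariateTable
    clinical: pd.DataFrame
    ground_truth: GroundTruth
    reference_ids: list[str]
    patient_ids: list[str]


# ---------------------------------------------------------------------------

def default_covariance_model(n_regions: int) -> BlockCorrelation:
    """Modular default: blocks of 4 at r = 0.3, plus — for the 116-region
    default parcellation — one strongly coupled caudate-cerebellar pair
    (Caudate_L, Cerebelum_6_R) at r = 0.7 that serves as the canonical
    aberration site."""
    if n_regions == 116:
        i, j = AAL116_LABELS.index("Caudate_L"), AAL116_LABELS.index("Cerebelum_6_R")
        return BlockCorrelation.contiguous(
            n_regions, special_pairs=((i, j, 0.7),)
        )
    return BlockCorrelation.contiguous(n_regions)


def default_cohort_spec(
    seed: int = 0,
    *,
    shared_edge: bool = True,
    delta: float = DELTA_GROUP,
    sign: int = 1,
    clinical_link: float = 0.85,
) -> CohortSpec:
    """Study-shaped spec: 34 reference subjects, 22 patients, 116 regions.

    With ``shared_edge=True`` every patient carries the same weakened
    caudate-cerebellar edge, mirroring a homogeneous disease effect that
    group comparison should isolate as a single differential edge.
    """
    i, j = AAL116_LABELS.index("Caudate_L"), AAL116_LABELS.index("Cerebelum_6_R")
    edges: tuple[tuple[EdgePerturbation, ...], ...] | None = None
    if shared_edge:
        edges = tuple(
            (EdgePerturbation(i, j, delta=delta, sign=sign),) for _ in range(22)
        )
    return CohortSpec(aberrant_edges=edges, clinical_link=clinical_link, seed=seed)


def _rng(spec: CohortSpec, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, *stream])


def _draw_covariates(rng: np.random.Generator, n: int) -> np.ndarray:
    age = np.clip(rng.normal(65.0, 7.0, n), 50.0, 80.0)
    sex = rng.integers(0, 2, n).astype(float)
    education = rng.integers(6, 21, n).astype(float)
    tiv = rng.normal(1435.0, 133.0, n)
    return np.column_stack([age, sex, education, tiv])


def _mean_volumes(spec: CohortSpec, base: np.ndarray, cov: np.ndarray) -> np.ndarray:
    eff = spec.covariate_effects
    age, sex, edu, tiv = cov[:, 0:1], cov[:, 1:2], cov[:, 2:3], cov[:, 3:4]
    if eff.tiv_proportional:
        mean = base * (tiv / eff.tiv_reference_ml)
    else:
        mean = np.broadcast_to(base, (len(cov), len(base))).copy()
    mean = mean + eff.age_ml_per_year * (age - 65.0)
    mean = mean + eff.sex_ml * sex
    mean = mean + eff.education_ml_per_year * (edu - 12.0)
    return mean


def _observable_correlation(spec: CohortSpec, C: np.ndarray) -> np.ndarray:
    atten = spec.structural_sd**2 / (spec.structural_sd**2 + spec.noise_sd**2)
    obs = C * atten
    np.fill_diagonal(obs, 1.0)
    return obs


def generate_reference_cohort(
    spec: CohortSpec,
) -> tuple[RegionalVolumeTable, CovariateTable, GroundTruth]:
    """Draw the healthy reference cohort and fix all cohort-level ground
    truth (base volumes, correlation factor, patient latent severities)."""
    C = spec.correlation_model().matrix(spec.n_regions)
    L = np.linalg.cholesky(C)
    rng = _rng(spec, 0)
    base = rng.uniform(4.0, 14.0, spec.n_regions)
    cov = _draw_covariates(rng, spec.n_reference)
    z = rng.standard_normal((spec.n_reference, spec.n_regions)) @ L.T
    eps = rng.standard_normal((spec.n_reference, spec.n_regions))
    V = _mean_volumes(spec, base, cov) + spec.structural_sd * z + spec.noise_sd * eps

    labels = spec.region_labels()
    ids = [f"HC{k + 1:03d}" for k in range(spec.n_reference)]
    volumes = RegionalVolumeTable(pd.DataFrame(V, index=ids, columns=labels))
    covariates = CovariateTable(
        pd.DataFrame(cov, index=ids, columns=["age", "sex", "education", "tiv"])
    )
    severity = _rng(spec, 2).standard_normal(max(spec.n_patients, 1))
    ground = GroundTruth(
        true_correlation=_observable_correlation(spec, C),
        injected_edges=tuple(
            spec.patient_edges(k) for k in range(spec.n_patients)
        ),
        latent_severity=severity[: spec.n_patients],
        base_volumes=base,
        cholesky=L,
    )
    return volumes, covariates, ground


def _apply_aberrations(
    spec: CohortSpec,
    ground: GroundTruth,
    patient_index: int,
    volume_row: np.ndarray,
) -> np.ndarray:
    """Shift the pair residuals of each injected edge along the
    covariance-breaking direction (see module docstring)."""
    sd_res = float(np.hypot(spec.structural_sd, spec.noise_sd))
    orient = 1.0 if patient_index % 2 == 0 else -1.0
    v = volume_row.copy()
    for e in ground.injected_edges[patient_index]:
        r_true = ground.true_correlation[e.region_i, e.region_j]
        t = np.sign(r_true) if r_true != 0 else 1.0
        # sign=+1: displace against the correlation (weaken/reverse);
        # sign=-1: displace along it (strengthen)
        d_j = -t * e.sign * e.delta
        v[e.region_i] += orient * e.delta * sd_res
        v[e.region_j] += orient * d_j * sd_res
    return v


def _clinical_record(
    spec: CohortSpec, rng: np.random.Generator, severity: float
) -> dict:
    lam = spec.clinical_link
    mix = np.sqrt(1.0 - lam**2)
    g_h = lam * severity + mix * rng.standard_normal()
    hamd = int(min(_HAMD_MAX,
                   8 + np.floor(np.exp(_HAMD_LOG_MU + _HAMD_LOG_SIGMA * g_h))))
    record: dict = {"hamd": hamd}
    for marker, prev in _MARKER_PREVALENCE.items():
        cut = stats.norm.isf(prev)
        g_m = lam * severity + mix * rng.standard_normal()
        record[marker] = int(g_m > cut)
    return record


def generate_patient(
    spec: CohortSpec, ground: GroundTruth, patient_index: int
) -> tuple[RegionalVolumeTable, CovariateTable, dict]:
    """One patient row (volumes + covariates) and their clinical record.

    Deterministic in (spec.seed, patient_index); independent of the order
    in which patients are generated.
    """
    if not 0 <= patient_index < spec.n_patients:
        raise ValueError(
            f"patient_index {patient_index} out of range (n_patients="
            f"{spec.n_patients})"
        )
    rng = _rng(spec, 1, patient_index)
    cov = _draw_covariates(rng, 1)
    z = rng.standard_normal(spec.n_regions) @ ground.cholesky.T
    eps = rng.standard_normal(spec.n_regions)
    mean = _mean_volumes(spec, ground.base_volumes, cov)[0]
    v = mean + spec.structural_sd * z + spec.noise_sd * eps
    v = _apply_aberrations(spec, ground, patient_index, v)

    sid = f"PA{patient_index + 1:03d}"
    labels = spec.region_labels()
    volumes = RegionalVolumeTable(
        pd.DataFrame(v[None, :], index=[sid], columns=labels)
    )
    covariates = CovariateTable(
        pd.DataFrame(cov, index=[sid], columns=["age", "sex", "education", "tiv"])
    )
    clinical = {"subject_id": sid, "group": "CSVD+D"}
    clinical.update(
        _clinical_record(spec, rng, float(ground.latent_severity[patient_index]))
    )
    return volumes, covariates, clinical


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Reference cohort + all patients + clinical table, in one call."""
    ref_vol, ref_cov, ground = generate_reference_cohort(spec)
    vol_frames = [ref_vol.data]
    cov_frames = [ref_cov.data]
    clinical_rows = []

    hc_rng = _rng(spec, 3)
    for sid in ref_vol.subject_ids:
        # healthy controls: HAMD <= 7 (inclusion criterion), no CSVD markers
        clinical_rows.append({
            "subject_id": sid,
            "group": "HC",
            "hamd": int(min(7, hc_rng.poisson(0.3))),
            "lacune_present": 0, "cmb_present": 0,
            "wmh_present": 0, "epvs_present": 0,
        })
    for k in range(spec.n_patients):
        p_vol, p_cov, p_clin = generate_patient(spec, ground, k)
        vol_frames.append(p_vol.data)
        cov_frames.append(p_cov.data)
        clinical_rows.append(p_clin)

    volumes = RegionalVolumeTable(pd.concat(vol_frames))
    covariates = CovariateTable(pd.concat(cov_frames))
    clinical = pd.DataFrame(clinical_rows).set_index("subject_id")
    return SyntheticCohort(
        volumes=volumes,
        covariates=covariates,
        clinical=clinical,
        ground_truth=ground,
        reference_ids=ref_vol.subject_ids,
        patient_ids=[f"PA{k + 1:03d}" for k in range(spec.n_patients)],
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write volumes.tsv, covariates.tsv, clinical.tsv and ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "volumes": out / "volumes.tsv",
        "covariates": out / "covariates.tsv",
        "clinical": out / "clinical.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_volume_table(cohort.volumes, paths["volumes"])
    write_covariate_table(cohort.covariates, paths["covariates"])
    write_clinical_table(cohort.clinical, paths["clinical"])
    gt = cohort.ground_truth
    payload = {
        "true_correlation": gt.true_correlation.tolist(),
        "latent_severity": gt.latent_severity.tolist(),
        "injected_edges": [
            [asdict(e) for e in per_patient] for per_patient in gt.injected_edges
        ],
        "reference_ids": cohort.reference_ids,
        "patient_ids": cohort.patient_ids,
    }
    paths["ground_truth"].write_text(json.dumps(payload))
    return paths


def spec_to_dict(spec: CohortSpec) -> dict:
    """JSON/YAML-serializable form of a CohortSpec (round-trips losslessly)."""
    d = asdict(spec)
    if spec.covariance_model is not None:
        d["covariance_model"] = {
            "blocks": [list(b) for b in spec.covariance_model.blocks],
            "within": list(spec.covariance_model.within),
            "between": spec.covariance_model.between,
        }
    if spec.aberrant_edges is not None:
        d["aberrant_edges"] = [
            [asdict(e) for e in per_patient] for per_patient in spec.aberrant_edges
        ]
    return d


def spec_from_dict(d: dict) -> CohortSpec:
    d = dict(d)
    if d.get("covariance_model") is not None:
        cm = d["covariance_model"]
        d["covariance_model"] = BlockCorrelation(
            blocks=tuple(tuple(b) for b in cm["blocks"]),
            within=tuple(cm["within"]),
            between=float(cm.get("between", 0.05)),
        )
    if d.get("covariate_effects") is not None and isinstance(
        d["covariate_effects"], dict
    ):
        d["covariate_effects"] = CovariateEffects(**d["covariate_effects"])
    if d.get("aberrant_edges") is not None:
        d["aberrant_edges"] = tuple(
            tuple(EdgePerturbation(**e) for e in per_patient)
            for per_patient in d["aberrant_edges"]
        )
    return CohortSpec(**d)
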