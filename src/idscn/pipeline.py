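"""End-to-end orchestration: simulate (or load) a cohort, build the
reference network, score every subject's individualized network, compare
groups edge-wise, and run the clinical analyses — all from one config,
reproducibly.

Outputs under ``out_dir``:

- ``volumes.tsv`` / ``covariates.tsv`` / ``clinical.tsv`` (synthetic runs)
- ``reference_scn.tsv`` — reference correlation matrix
- ``subjects/<id>_edges.tsv`` — per-subject edge table
  (region_i, region_j, r_ref, delta, z, p, significant)
- ``subjects/<id>_z.tsv`` — per-subject Z matrix
- ``group_stats.tsv`` / ``incidence.tsv``
- ``burden.tsv`` / ``correlations.tsv``
- ``manifest.json`` — config hash, stage record, row counts
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import burden_table, spearman_with_bonferroni, two_sample_t
from .core import IDSCN, ReferenceSCN, compute_reference_scn, cohort_networks, upper_triangle
from .group import edge_incidence, group_edge_ttest
from .io import (
    align_subjects,
    load_clinical_table,
    load_covariate_table,
    load_volume_table,
)
from .synthetic import (
    CohortSpec,
    default_cohort_spec,
    generate_cohort,
    spec_from_dict,
    spec_to_dict,
    write_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

_FLOAT_FMT = "%.17g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a run needs; round-trips through YAML losslessly."""

    out_dir: str = "results"
    # either a cohort spec (simulate) or paths to existing tables
    cohort: CohortSpec | None = None
    volumes_path: str | None = None
    covariates_path: str | None = None
    clinical_path: str | None = None
    reference_group: str = "HC"
    patient_group: str = "CSVD+D"
    edge_alpha: float = 0.05          # per-subject Bonferroni family alpha
    group_alpha: float = 0.05         # group edge t-test family alpha
    spearman_threshold: float = 0.005  # corrected threshold for 2 analyses
    t_variant: str = "pooled"
    sqrt_variant: bool = False
    refit_covariates: bool = True
    leave_one_out: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("edge_alpha", "group_alpha", "spearman_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.cohort is None and not (self.volumes_path and self.covariates_path):
            raise ValueError(
                "config needs either a synthetic cohort spec or volume + "
                "covariate table paths"
            )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            d["cohort"] = spec_to_dict(self.cohort)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("cohort") is not None:
            d["cohort"] = spec_from_dict(d["cohort"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        # output location does not change the analysis
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_matrix(mat: np.ndarray, labels, path: Path) -> None:
    pd.DataFrame(mat, index=labels, columns=labels).rename_axis("region").to_csv(
        path, sep="\t", float_format=_FLOAT_FMT
    )


def _subject_edge_table(net: IDSCN, reference: ReferenceSCN,
                        alpha: float) -> pd.DataFrame:
    iu = upper_triangle(len(net.region_labels))
    thresh = alpha / iu[0].size
    return pd.DataFrame({
        "region_i": [net.region_labels[i] for i in iu[0]],
        "region_j": [net.region_labels[j] for j in iu[1]],
        "r_ref": reference.r_matrix[iu],
        "delta": net.delta_matrix[iu],
        "z": net.z_matrix[iu],
        "p": net.p_matrix[iu],
        "significant": net.p_matrix[iu] < thresh,
    })


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "idscn_version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    # stage 1: obtain data -------------------------------------------------
    stage = "simulate" if config.cohort is not None else "load"
    try:
        if config.cohort is not None:
            cohort = generate_cohort(config.cohort)
            paths = write_cohort(cohort, out)
            volumes, covariates, clinical = (
                cohort.volumes, cohort.covariates, cohort.clinical,
            )
            manifest["stages"][stage] = {
                "outputs": [p.name for p in paths.values()],
                "n_subjects": len(volumes.subject_ids),
            }
        else:
            volumes = load_volume_table(config.volumes_path)
            covariates = load_covariate_table(config.covariates_path)
            clinical = (
                load_clinical_table(config.clinical_path)
                if config.clinical_path else None
            )
            manifest["stages"][stage] = {
                "inputs": [config.volumes_path, config.covariates_path,
                           config.clinical_path],
                "n_subjects": len(volumes.subject_ids),
            }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # stage 2: align -------------------------------------------------------
    try:
        data = align_subjects(volumes, covariates, clinical)
        if data.clinical is None:
            raise ValueError("a clinical table with a 'group' column is required")
        groups = data.clinical["group"]
        reference_ids = [s for s in data.subject_ids
                         if groups[s] == config.reference_group]
        patient_ids = [s for s in data.subject_ids
                       if groups[s] == config.patient_group]
        if not reference_ids:
            raise ValueError(
                f"no subjects in reference group {config.reference_group!r}"
            )
        manifest["stages"]["align"] = {
            "n_reference": len(reference_ids),
            "n_patients": len(patient_ids),
            "dropped": data.dropped,
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("align", str(exc)) from exc

    # stage 3: reference SCN ----------------------------------------------
    try:
        reference = compute_reference_scn(
            data.volumes.subset(reference_ids), data.covariates.subset(reference_ids)
        )
        _write_matrix(reference.r_matrix, reference.region_labels,
                      out / "reference_scn.tsv")
        manifest["stages"]["reference"] = {
            "n_ref": reference.n_ref,
            "n_regions": reference.n_regions,
            "n_edges": reference.n_edges,
        }
    except Exception as exc:
        raise PipelineError("reference", str(exc)) from exc

    # stage 4: individual networks ----------------------------------------
    try:
        networks = cohort_networks(
            data, reference_ids,
            alpha=config.edge_alpha,
            leave_one_out=config.leave_one_out,
            refit=config.refit_covariates,
            sqrt_variant=config.sqrt_variant,
        )
        subj_dir = out / "subjects"
        subj_dir.mkdir(exist_ok=True)
        for sid, net in networks.items():
            _subject_edge_table(net, reference, config.edge_alpha).to_csv(
                subj_dir / f"{sid}_edges.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT,
            )
            _write_matrix(net.z_matrix, net.region_labels,
                          subj_dir / f"{sid}_z.tsv")
        manifest["stages"]["individual"] = {
            "n_networks": len(networks),
            "n_edges_tested": reference.n_edges,
            "significant_per_subject": {
                sid: len(net.significant) for sid, net in networks.items()
            },
        }
    except Exception as exc:
        raise PipelineError("individual", str(exc)) from exc

    # stage 5: group comparison -------------------------------------------
    try:
        pat_nets = [networks[s] for s in patient_ids]
        ref_nets = [networks[s] for s in reference_ids]
        if len(pat_nets) >= 2 and len(ref_nets) >= 2:
            gstats = group_edge_ttest(
                pat_nets, ref_nets,
                variant=config.t_variant, alpha=config.group_alpha,
            )
            gstats.to_csv(out / "group_stats.tsv", sep="\t", index=False,
                          float_format=_FLOAT_FMT)
            sig = gstats[gstats["significant"]]
            manifest["stages"]["group"] = {
                "n_edges_tested": int(len(gstats)),
                "n_significant": int(len(sig)),
                "top_edges": [
                    f"{r.region_i}--{r.region_j}" for r in sig.head(5).itertuples()
                ],
            }
        else:
            gstats = None
            manifest["stages"]["group"] = {"skipped": "need >= 2 subjects per group"}
        incidence = edge_incidence(pat_nets) if pat_nets else None
        if incidence is not None:
            incidence.to_csv(out / "incidence.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("group", str(exc)) from exc

    # stage 6: clinical ----------------------------------------------------
    try:
        clin = data.clinical
        burden = burden_table(clin.loc[patient_ids]) if patient_ids else None
        if burden is not None:
            burden.to_csv(out / "burden.tsv", sep="\t")
        correlations = None
        if burden is not None and len(patient_ids) >= 4:
            hamd = clin.loc[patient_ids, "hamd"].astype(float).to_numpy()
            pairs = [(burden["burden"].to_numpy(dtype=float), hamd,
                      "csvd_burden_vs_hamd")]
            if gstats is not None and len(gstats):
                top = gstats.iloc[0]
                i, j = int(top["index_i"]), int(top["index_j"])
                edge_z = np.array(
                    [networks[s].z_matrix[i, j] for s in patient_ids]
                )
                pairs.append(
                    (edge_z, hamd,
                     f"edge_{top['region_i']}--{top['region_j']}_z_vs_hamd")
                )
            correlations = spearman_with_bonferroni(
                pairs, threshold=config.spearman_threshold
            )
            correlations.to_csv(out / "correlations.tsv", sep="\t", index=False,
                                float_format=_FLOAT_FMT)
        hamd_test = None
        if patient_ids and len(reference_ids) >= 2 and len(patient_ids) >= 2:
            t, df, p = two_sample_t(
                clin.loc[patient_ids, "hamd"].astype(float),
                clin.loc[reference_ids, "hamd"].astype(float),
                variant=config.t_variant,
            )
            hamd_test = {"t": t, "df": df, "p": p}
        manifest["stages"]["clinical"] = {
            "burden_mean": None if burden is None else float(burden["burden"].mean()),
            "hamd_group_test": hamd_test,
            "correlations": None if correlations is None else
                correlations.to_dict(orient="records"),
        }
    except Exception as exc:
        raise PipelineError("clinical", str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def default_run_config(out_dir: str = "results", seed: int = 0) -> RunConfig:
    """Synthetic study-shaped run: 34 reference subjects vs 22 patients
    sharing one weakened caudate-cerebellar edge."""
    return RunConfig(out_dir=out_dir, cohort=default_cohort_spec(seed), seed=seed)
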