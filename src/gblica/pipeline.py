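"""End-to-end pipeline driver, cohort bookkeeping and run configuration.

The driver chains the four stages -- microbiome preparation, dual
regression, linked factorization, component reporting -- under a single
YAML-serializable configuration, writing every stage output plus a log and
the resolved configuration into one run directory.  Re-running from the
emitted configuration reproduces all deterministic outputs bit-identically.

Cohort bookkeeping follows explicit per-subject exclusion reasons (high
depression score, missing feces sample, or head movement exceeding 4 mm
between acquisitions); subjects are aligned across modalities by id with a
hard failure on any mismatch so the analysed n is always auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dualreg import TemplateSet, run_dual_regression
from .errors import ParameterError, PipelineError
from .lica import contribution_fractions, fit_lica, standardize_modalities
from .microbiome import AbundanceTable, read_table, write_table, write_composition, prepare_microbiome
from .report import build_reports, render_report
from .synthetic import SyntheticCohort

__all__ = [
    "EXCLUSION_REASONS",
    "SubjectRecord",
    "CohortManifest",
    "RunConfig",
    "apply_exclusions",
    "run_pipeline",
    "write_cohort",
]

logger = logging.getLogger("gblica")

EXCLUSION_REASONS = ("depression_score", "missing_feces", "movement_gt_4mm")


@dataclass
class SubjectRecord:
    subject_id: str
    included: bool = True
    exclusion_reason: str | None = None
    fmri_path: str | None = None


@dataclass
class CohortManifest:
    """Per-subject inclusion bookkeeping with exclusion reasons."""

    records: list[SubjectRecord]

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ParameterError("subject ids in the manifest must be unique")
        for r in self.records:
            if r.included and r.exclusion_reason:
                raise ParameterError(
                    f"subject {r.subject_id!r} is included but carries "
                    f"exclusion reason {r.exclusion_reason!r}"
                )
            if not r.included:
                if not r.exclusion_reason:
                    raise ParameterError(
                        f"excluded subject {r.subject_id!r} carries no reason"
                    )
                if r.exclusion_reason not in EXCLUSION_REASONS:
                    raise ParameterError(
                        f"subject {r.subject_id!r}: unknown exclusion reason "
                        f"{r.exclusion_reason!r} (expected one of {EXCLUSION_REASONS})"
                    )

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    @classmethod
    def from_tsv(cls, path) -> "CohortManifest":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
        records = []
        for _, row in df.iterrows():
            records.append(SubjectRecord(
                subject_id=row["subject_id"],
                included=str(row.get("included", "1")).lower() in ("1", "true", "yes"),
                exclusion_reason=row.get("exclusion_reason") or None,
                fmri_path=row.get("fmri") or None,
            ))
        return cls(records)

    def to_tsv(self, path) -> None:
        pd.DataFrame([
            {"subject_id": r.subject_id, "included": int(r.included),
             "exclusion_reason": r.exclusion_reason or "",
             "fmri": r.fmri_path or ""}
            for r in self.records
        ]).to_csv(path, sep="\t", index=False)


def apply_exclusions(manifest: CohortManifest) -> list[str]:
    """Included subject ids after removing every subject with a reason."""
    included = [r.subject_id for r in manifest.records if r.included]
    counts: dict[str, int] = {}
    for r in manifest.records:
        if not r.included:
            counts[r.exclusion_reason] = counts.get(r.exclusion_reason, 0) + 1
    logger.info(
        "cohort: %d enrolled, %d included, excluded by reason: %s",
        len(manifest.records), len(included), counts or "none",
    )
    if not included:
        warnings.warn("all subjects excluded; the included list is empty", stacklevel=2)
    return included


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run; one YAML round-trips it."""

    counts_table: str = "counts.tsv"
    templates: str = "templates.nii"
    manifest: str = "cohort_manifest.tsv"
    out_dir: str = "run"
    network_names: list[str] = field(default_factory=list)   # template order
    select: list[str] = field(default_factory=list)
    min_prevalence: float = 0.30
    prevalence_order: str = "filter-first"
    output_stat: str = "z"
    n_components: int = 10
    max_iter: int = 1000
    tol: float = 1e-6
    seed: int = 0
    n_restarts: int = 0
    select_threshold: float = 0.2
    dominance_threshold: float = 0.5
    brain_z: float = 3.0
    micro_z: float = 2.3
    constant_rel_var: float = 1e-8

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def _write_matrix(path: Path, M: np.ndarray, index, columns, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config-hash: {cfg_hash}\n")
        pd.DataFrame(M, index=index, columns=columns).to_csv(fh, sep="\t")


def read_matrix(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0).to_numpy(dtype=float)


def _subset_samples(table: AbundanceTable, sample_ids: list[str]) -> AbundanceTable:
    pos = {s: i for i, s in enumerate(table.sample_ids)}
    missing = [s for s in sample_ids if s not in pos]
    if missing:
        raise ParameterError(f"samples missing from the count table: {missing}")
    rows = [pos[s] for s in sample_ids]
    return AbundanceTable(
        counts=table.counts[rows],
        taxonomy=list(table.taxonomy),
        sample_ids=list(sample_ids),
        taxon_ids=list(table.taxon_ids),
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute prep-microbiome -> dual regression -> fit -> report.

    Returns the run directory.  Any stage failure is re-raised as a
    :class:`PipelineError` naming the stage.
    """
    import nibabel as nib

    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("run config hash %s", cfg_hash)
        for label, p in (("counts", config.counts_table),
                         ("templates", config.templates),
                         ("manifest", config.manifest)):
            logger.info("input %s: %s sha256:%s", label, p, _sha256(Path(p)))

        def stage(name, fn, *args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                result = fn(*args, **kwargs)
                logger.info("stage %s: done", name)
                return result
            except Exception as e:
                logger.error("stage %s failed: %s", name, e)
                raise PipelineError(f"stage {name!r} failed: {e}") from e

        manifest = stage("manifest", CohortManifest.from_tsv, config.manifest)
        included = stage("exclusions", apply_exclusions, manifest)

        def _prep():
            table = read_table(config.counts_table)
            unknown = set(table.sample_ids) - set(manifest.subject_ids)
            if unknown:
                raise ParameterError(
                    f"samples in data but absent from manifest: {sorted(unknown)}"
                )
            table = _subset_samples(table, included)
            comp = prepare_microbiome(table, config.min_prevalence,
                                      order=config.prevalence_order)
            write_composition(comp, outdir / "composition.tsv",
                              header_comment=f"config-hash: {cfg_hash}")
            return comp

        comp = stage("prep-microbiome", _prep)

        def _dualreg():
            templates = TemplateSet.from_nifti(config.templates, config.network_names)
            fmri = []
            for r in manifest.records:
                if not r.included:
                    continue
                if not r.fmri_path:
                    raise ParameterError(f"subject {r.subject_id!r} has no fMRI path")
                img = nib.load(r.fmri_path)
                data = np.asarray(img.dataobj, dtype=float)
                fmri.append(data.reshape(-1, data.shape[3]))
            select = config.select or config.network_names
            return templates, run_dual_regression(
                templates, fmri, select=select, output=config.output_stat,
                subject_ids=included,
            )

        templates, net_maps = stage("dualreg", _dualreg)

        def _fit():
            raw = [m.maps.T for m in net_maps] + [comp.relabund.T]
            names = [m.network_name for m in net_maps] + ["genus"]
            if comp.sample_ids != included:
                diff = sorted(set(comp.sample_ids) ^ set(included))
                raise ParameterError(f"subject mismatch across modalities: {diff}")
            lica_input = standardize_modalities(raw, names, subject_ids=included)
            model = fit_lica(lica_input, n_components=config.n_components,
                             max_iter=config.max_iter, tol=config.tol,
                             seed=config.seed, n_restarts=config.n_restarts)
            return model

        model = stage("fit", _fit)
        P = stage("contributions", contribution_fractions, model)

        def _report():
            reports = build_reports(
                model, P, micro_modality="genus",
                select_threshold=config.select_threshold,
                dominance_threshold=config.dominance_threshold,
                brain_z=config.brain_z, micro_z=config.micro_z,
                constant_rel_var=config.constant_rel_var,
                genus_ids=comp.genus_ids,
            )
            geometries = {m.network_name: (m.shape, m.affine) for m in net_maps}
            render_report(reports, comp.genus_ids,
                          [m.network_name for m in net_maps],
                          outdir / "report", model=model, geometries=geometries)
            return reports

        stage("report", _report)

        def _write_outputs():
            comp_ids = [f"comp{c}" for c in range(model.n_components)]
            _write_matrix(outdir / "H.tsv", model.H, comp_ids, included, cfg_hash)
            _write_matrix(outdir / "lambda.tsv", model.lambdas,
                          model.modality_names, comp_ids, cfg_hash)
            _write_matrix(outdir / "beta.tsv", model.betas[:, None],
                          model.modality_names, ["beta"], cfg_hash)
            _write_matrix(outdir / "P.tsv", P.P, model.modality_names,
                          comp_ids, cfg_hash)
            k_genus = model.modality_index("genus")
            _write_matrix(outdir / "sources_genus.tsv", model.sources[k_genus],
                          comp.genus_ids, comp_ids, cfg_hash)
            for m in net_maps:
                k = model.modality_index(m.network_name)
                data = model.sources[k].reshape(*m.shape, model.n_components)
                nib.save(nib.Nifti1Image(data.astype(np.float32), m.affine),
                         str(outdir / f"sources_{m.network_name}.nii"))
            config.to_yaml(outdir / "config.yaml")

        stage("write-outputs", _write_outputs)
        logger.info("run complete: %s", outdir)
        return outdir
    finally:
        logger.removeHandler(handler)
        handler.close()


def write_cohort(cohort: SyntheticCohort, outdir, params: dict | None = None) -> RunConfig:
    """Write a simulated cohort to disk and return a ready-to-run config.

    Outputs: 4D template and per-subject fMRI NIfTI volumes, a TSV genus
    count table, TSV ground-truth matrices, the cohort manifest, and a YAML
    manifest of the generator parameters.  Requires a cohort generated with
    ``make_fmri=True``.
    """
    import nibabel as nib

    if cohort.fmri is None or cohort.templates is None:
        raise ParameterError("cohort has no fMRI volumes; regenerate with make_fmri=True")
    if cohort.counts is None:
        raise ParameterError("cohort has no count table; regenerate with make_counts=True")
    outdir = Path(outdir)
    (outdir / "fmri").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    cohort.templates.to_nifti(outdir / "templates.nii")
    records = []
    shape = cohort.templates.shape
    for i, sid in enumerate(cohort.subject_ids):
        path = outdir / "fmri" / f"{sid}.nii"
        data = cohort.fmri[i].reshape(*shape, -1)
        nib.save(nib.Nifti1Image(data.astype(np.float32), cohort.templates.affine),
                 str(path))
        records.append(SubjectRecord(subject_id=sid, fmri_path=str(path)))
    manifest = CohortManifest(records)
    manifest.to_tsv(outdir / "cohort_manifest.tsv")

    write_table(cohort.counts, outdir / "counts.tsv")

    for m in cohort.network_maps:            # planted per-network map stacks
        m.to_nifti(outdir / f"maps_{m.network_name}.nii")

    truth = cohort.truth
    comp_ids = [f"comp{c}" for c in range(truth.H.shape[0])]
    pd.DataFrame(truth.H, index=comp_ids, columns=cohort.subject_ids).to_csv(
        outdir / "truth" / "H_true.tsv", sep="\t")
    pd.DataFrame(truth.lambdas, index=cohort.modality_names, columns=comp_ids).to_csv(
        outdir / "truth" / "lambda_true.tsv", sep="\t")
    for name, S in zip(cohort.modality_names, truth.sources):
        pd.DataFrame(S, columns=comp_ids).to_csv(
            outdir / "truth" / f"S_true_{name}.tsv", sep="\t", index=False)

    with open(outdir / "simulation.yaml", "w") as fh:
        yaml.safe_dump({"seed": truth.seed, "n_subjects": len(cohort.subject_ids),
                        "modalities": cohort.modality_names,
                        "noise_sd": truth.noise_sd.tolist(),
                        **(params or {})}, fh, sort_keys=True)

    n_components = truth.H.shape[0]
    return RunConfig(
        counts_table=str(outdir / "counts.tsv"),
        templates=str(outdir / "templates.nii"),
        manifest=str(outdir / "cohort_manifest.tsv"),
        out_dir=str(outdir / "run"),
        network_names=list(cohort.templates.network_names),
        select=list(cohort.templates.network_names),
        n_components=n_components,
        seed=truth.seed,
    )
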