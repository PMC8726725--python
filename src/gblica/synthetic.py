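"""Synthetic joint brain--microbiome cohorts with planted ground truth.

Every modality matrix is driven by one shared subject-loading matrix
``H`` (components x subjects), per-modality sparse source patterns ``S_k``
(features x components, unit-norm columns) and non-negative component
weights ``lambda_k``::

    X_k = S_k . diag(lambda_k) . H + E_k,     E_k ~ N(0, noise_sd_k^2) i.i.d.

with features centered across subjects afterwards.  This is exactly the
structure a linked ICA assumes: one mixing matrix shared by all modalities,
sparse (hence non-Gaussian, hence identifiable) sources, and independent
Gaussian observation noise.

The microbiome side additionally derives a compositional table from its
signal matrix: genus logits are a fixed baseline log-abundance plus the
planted signal, pushed through a softmax so every sample lies on the
simplex, and sequencing counts are drawn multinomially at a fixed read
depth.  Brain networks live on small independent 3D voxel grids; optional
per-subject fMRI series are generated so that dual regression against the
stored templates recovers the planted subject maps.

Weight units: ``lambda_matrix`` entries are per-entry RMS signal
amplitudes.  Internally the effective weight is ``w * sqrt(F_k * N)`` so a
weight of 1 contributes unit variance per matrix entry regardless of how
many features a modality has; ``noise_sd`` is then directly comparable
across modalities.

All randomness flows from one integer seed through a counter-based
child-seed scheme (`numpy.random.SeedSequence` spawn keys), so identical
seeds reproduce cohorts bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dualreg import SubjectNetworkMaps, TemplateSet
from .errors import DimensionError, ParameterError
from .microbiome import AbundanceTable, CompositionTable

__all__ = [
    "GroundTruth",
    "SyntheticCohort",
    "child_rng",
    "make_joint_dataset",
    "make_fmri_from_maps",
    "make_counts_table",
]

# canonical resting-state network names used for the first four modalities
_NETWORK_NAMES = ("DMN", "ECN", "FPl", "FPr")

# fixed stream ids for the counter-based child-seed scheme
_STREAM_H = 0
_STREAM_SOURCES = 1
_STREAM_NOISE = 2
_STREAM_BASELINE = 3
_STREAM_COUNTS = 4
_STREAM_TEMPLATES = 5
_STREAM_TIMECOURSES = 6
_STREAM_FMRI = 100  # + subject index


def child_rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic child generator for (seed, stream)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(stream),))
    return np.random.default_rng(ss)


def network_names(n_networks: int) -> list[str]:
    return [
        _NETWORK_NAMES[i] if i < len(_NETWORK_NAMES) else f"NET{i}"
        for i in range(n_networks)
    ]


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic cohort.

    ``H`` rows and ``sources`` columns are unit Euclidean norm; ``lambdas``
    holds the effective non-negative weights on the raw data scale.
    """

    H: np.ndarray                      # (C, N), unit-norm rows
    sources: list[np.ndarray]          # K arrays (F_k, C), unit-norm columns
    lambdas: np.ndarray                # (K, C) effective weights, >= 0
    noise_sd: np.ndarray               # (K,)
    seed: int
    lambda_weights: np.ndarray | None = None   # (K, C) as requested
    artifact_subject: int | None = None
    single_subject_component: int | None = None
    constant_map: tuple[int, int] | None = None  # (modality, component)

    def __post_init__(self) -> None:
        row_norms = np.linalg.norm(self.H, axis=1)
        if not np.allclose(row_norms, 1.0, atol=1e-8):
            raise ParameterError("H rows must have unit Euclidean norm")
        for k, S in enumerate(self.sources):
            col = np.linalg.norm(S, axis=0)
            if not np.allclose(col, 1.0, atol=1e-8):
                raise ParameterError(f"source columns of modality {k} must be unit norm")
        if np.any(self.lambdas < 0):
            raise ParameterError("lambdas must be non-negative")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth.

    ``modalities`` are the feature x subject matrices that enter the linked
    factorization directly (networks first, microbiome signal last);
    ``composition``/``counts`` are the derived compositional views used by
    the microbiome preprocessing stage.
    """

    composition: CompositionTable
    network_maps: list[SubjectNetworkMaps]
    truth: GroundTruth
    modalities: list[np.ndarray]
    modality_names: list[str]
    subject_ids: list[str]
    counts: AbundanceTable | None = None
    fmri: list[np.ndarray] | None = None         # per subject (V_total, T)
    templates: TemplateSet | None = None
    taxonomy: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        for name, X in zip(self.modality_names, self.modalities):
            if X.shape[1] != n:
                raise DimensionError(f"modality {name!r} has {X.shape[1]} subjects, expected {n}")
        for m in self.network_maps:
            if m.maps.shape[0] != n:
                raise DimensionError("network map stack subject count mismatch")
        if self.composition.relabund.shape[0] != n:
            raise DimensionError("composition sample count mismatch")
        sums = self.composition.relabund.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ParameterError("composition rows must sum to 1")


def _as_noise_vector(noise_sd, n_modalities: int) -> np.ndarray:
    arr = np.asarray(noise_sd, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_modalities, float(arr))
    if arr.shape != (n_modalities,):
        raise DimensionError(
            f"noise_sd must be scalar or length {n_modalities}, got shape {arr.shape}"
        )
    if np.any(arr < 0):
        raise ParameterError("noise_sd must be non-negative")
    return arr


def _sparse_sources(rng: np.random.Generator, n_features: int, n_components: int,
                    sparsity: float) -> np.ndarray:
    """Standard-normal entries, a (1 - sparsity) fraction zeroed, columns unit-norm."""
    n_nonzero = max(1, int(round(sparsity * n_features)))
    S = np.zeros((n_features, n_components))
    for c in range(n_components):
        idx = rng.choice(n_features, size=n_nonzero, replace=False)
        vals = rng.standard_normal(n_nonzero)
        while np.linalg.norm(vals) == 0.0:  # pragma: no cover - measure zero
            vals = rng.standard_normal(n_nonzero)
        S[idx, c] = vals / np.linalg.norm(vals)
    return S


def _softmax_columns(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def default_taxonomy(n_genera: int) -> list[str]:
    """Synthetic but structurally realistic semicolon-ranked lineages."""
    phyla = ("Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria")
    out = []
    for g in range(n_genera):
        p = phyla[g % len(phyla)]
        out.append(
            f"k__Bacteria;p__{p};c__Class{g % 3};o__Order{g % 5};"
            f"f__Family{g % 7:02d};g__Genus{g:03d}"
        )
    return out


def make_fmri_from_maps(network_maps_subject: np.ndarray, timecourses: np.ndarray,
                        noise_sd: float, seed: int) -> np.ndarray:
    """Simulate a voxel x timepoint series from spatial maps and timecourses.

    Returns ``maps @ timecourses.T + noise`` so that, absent noise, dual
    regression against the maps is exactly invertible.
    """
    maps = np.asarray(network_maps_subject, dtype=float)
    tc = np.asarray(timecourses, dtype=float)
    if maps.ndim != 2 or tc.ndim != 2:
        raise DimensionError("maps and timecourses must be 2-D")
    if maps.shape[1] != tc.shape[1]:
        raise DimensionError(
            f"maps have {maps.shape[1]} networks but timecourses have {tc.shape[1]}"
        )
    if tc.shape[0] <= tc.shape[1]:
        raise ParameterError(
            "timepoints must exceed the network count (stage-1 regression "
            f"underdetermined: {tc.shape[0]} <= {tc.shape[1]})"
        )
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    out = maps @ tc.T
    if noise_sd > 0:
        out = out + noise_sd * child_rng(seed, 0).standard_normal(out.shape)
    return out


def make_counts_table(composition: CompositionTable, depth: int, seed: int,
                      taxonomy: list[str] | None = None) -> AbundanceTable:
    """Multinomial sequencing counts at fixed read depth per sample."""
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    P = np.asarray(composition.relabund, dtype=float)
    if np.any(P < 0):
        raise ParameterError("composition proportions must be non-negative")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ParameterError("composition rows must sum to 1")
    rng = child_rng(seed, 0)
    counts = np.empty_like(P, dtype=np.int64)
    for i in range(P.shape[0]):
        p = P[i] / P[i].sum()
        counts[i] = rng.multinomial(depth, p)
    if taxonomy is None:
        taxonomy = [f"g__{g}" for g in composition.genus_ids]
    return AbundanceTable(
        counts=counts,
        taxonomy=list(taxonomy),
        sample_ids=list(composition.sample_ids),
        taxon_ids=list(composition.genus_ids),
    )


def make_joint_dataset(
    n_subjects: int = 40,
    n_genera: int = 30,
    grid_shape: tuple[int, int, int] = (6, 6, 6),
    n_networks: int = 2,
    n_components: int = 3,
    lambda_matrix: np.ndarray | None = None,
    sparsity: float = 0.1,
    noise_sd=0.1,
    seed: int = 0,
    depth: int = 10_000,
    make_counts: bool = True,
    make_fmri: bool = False,
    n_timepoints: int = 100,
    fmri_noise_sd: float = 1.0,
    single_subject_component: int | None = None,
    constant_map: tuple[int, int] | None = None,
    baseline_log_sd: float = 1.5,
    logit_scale: float = 1.0,
) -> SyntheticCohort:
    """Generate a joint cohort with known shared loadings across modalities.

    Modalities are ``n_networks`` voxel-grid map stacks plus one genus-level
    microbiome matrix.  ``lambda_matrix`` is (n_networks + 1) x n_components
    (defaults to all ones); ``single_subject_component`` plants an artifact
    component whose loading row is dominated by one subject;
    ``constant_map=(k, c)`` plants a spatially constant source column in
    modality ``k``.
    """
    n_voxels = int(np.prod(grid_shape))
    K = n_networks + 1
    C = int(n_components)
    N = int(n_subjects)
    if n_networks < 1:
        raise ParameterError("need at least one network modality")
    if not 0.0 < sparsity <= 1.0:
        raise ParameterError(f"sparsity must be in (0, 1], got {sparsity}"
                             + (" (degenerate sources)" if sparsity == 0 else ""))
    if C > min(N, n_genera, n_voxels):
        raise ParameterError(
            f"n_components={C} exceeds min(n_subjects, n_genera, voxels)="
            f"{min(N, n_genera, n_voxels)}"
        )
    noise = _as_noise_vector(noise_sd, K)
    if lambda_matrix is None:
        lambda_matrix = np.ones((K, C))
    lambda_matrix = np.asarray(lambda_matrix, dtype=float)
    if lambda_matrix.shape != (K, C):
        raise DimensionError(
            f"lambda_matrix must have shape ({K}, {C}) "
            f"(modalities x components), got {lambda_matrix.shape}"
        )
    if np.any(lambda_matrix < 0):
        raise ParameterError("lambda_matrix weights must be non-negative")
    if constant_map is not None:
        mk, mc = constant_map
        if not (0 <= mk < K and 0 <= mc < C):
            raise ParameterError(f"constant_map {constant_map} out of range")
    if single_subject_component is not None and not 0 <= single_subject_component < C:
        raise ParameterError("single_subject_component out of range")

    # shared subject loadings, unit-norm rows
    rng_h = child_rng(seed, _STREAM_H)
    H = rng_h.standard_normal((C, N))
    artifact_subject = None
    if single_subject_component is not None:
        c = single_subject_component
        artifact_subject = int(rng_h.integers(N))
        rest_rms = math.sqrt(float(np.mean(np.delete(H[c], artifact_subject) ** 2)))
        H[c, artifact_subject] = 10.0 * rest_rms
    H /= np.linalg.norm(H, axis=1, keepdims=True)

    feature_counts = [n_voxels] * n_networks + [n_genera]
    rng_s = child_rng(seed, _STREAM_SOURCES)
    rng_e = child_rng(seed, _STREAM_NOISE)
    sources: list[np.ndarray] = []
    modalities: list[np.ndarray] = []
    lam_eff = lambda_matrix * np.sqrt(np.asarray(feature_counts, float)[:, None] * N)
    for k, F in enumerate(feature_counts):
        S = _sparse_sources(rng_s, F, C, sparsity)
        if constant_map is not None and constant_map[0] == k:
            S[:, constant_map[1]] = 1.0 / math.sqrt(F)
        X = S @ (lam_eff[k, :, None] * H)
        if noise[k] > 0:
            X = X + noise[k] * rng_e.standard_normal((F, N))
        X = X - X.mean(axis=1, keepdims=True)  # center features across subjects
        sources.append(S)
        modalities.append(X)

    truth = GroundTruth(
        H=H,
        sources=sources,
        lambdas=lam_eff,
        noise_sd=noise,
        seed=int(seed),
        lambda_weights=lambda_matrix,
        artifact_subject=artifact_subject,
        single_subject_component=single_subject_component,
        constant_map=constant_map,
    )

    subject_ids = [f"sub-{i:03d}" for i in range(N)]
    genus_ids = [f"Genus{g:03d}" for g in range(n_genera)]
    taxonomy = default_taxonomy(n_genera)
    net_names = network_names(n_networks)

    # compositional view of the microbiome signal: softmax of baseline + signal
    M_micro = modalities[-1]
    rms = math.sqrt(float(np.mean(M_micro**2)))
    Z = M_micro / rms if rms > 0 else M_micro
    baseline = child_rng(seed, _STREAM_BASELINE).normal(0.0, baseline_log_sd, size=n_genera)
    comp = _softmax_columns(baseline[:, None] + logit_scale * Z)
    composition = CompositionTable(
        relabund=comp.T.copy(),
        genus_ids=genus_ids,
        sample_ids=subject_ids,
    )

    counts = None
    if make_counts:
        counts = make_counts_table(composition, depth, seed=seed * 1000 + _STREAM_COUNTS,
                                   taxonomy=taxonomy)

    affine = np.eye(4)
    network_maps = [
        SubjectNetworkMaps(
            maps=modalities[k].T.copy(),
            network_name=net_names[k],
            shape=tuple(grid_shape),
            affine=affine,
            subject_ids=subject_ids,
        )
        for k in range(n_networks)
    ]

    fmri = None
    templates = None
    if make_fmri:
        # networks concatenated along z into one volume; each template occupies
        # its own block, so templates are mutually orthogonal by construction
        V_total = n_voxels * n_networks
        rng_t = child_rng(seed, _STREAM_TEMPLATES)
        T_maps = np.zeros((V_total, n_networks))
        for j in range(n_networks):
            n_active = max(1, int(round(0.2 * n_voxels)))
            idx = rng_t.choice(n_voxels, size=n_active, replace=False)
            T_maps[j * n_voxels + idx, j] = 3.0 + rng_t.standard_normal(n_active)
        full_shape = (grid_shape[0], grid_shape[1], grid_shape[2] * n_networks)
        templates = TemplateSet(
            maps=T_maps, network_names=net_names, shape=full_shape, affine=affine
        )
        rng_tc = child_rng(seed, _STREAM_TIMECOURSES)
        fmri = []
        for i in range(N):
            subj_maps = T_maps.copy()
            for j in range(n_networks):
                subj_maps[j * n_voxels:(j + 1) * n_voxels, j] += modalities[j][:, i]
            tc = rng_tc.standard_normal((n_timepoints, n_networks))
            fmri.append(
                make_fmri_from_maps(subj_maps, tc, fmri_noise_sd,
                                    seed=seed * 1000 + _STREAM_FMRI + i)
            )

    return SyntheticCohort(
        composition=composition,
        network_maps=network_maps,
        truth=truth,
        modalities=modalities,
        modality_names=net_names + ["genus"],
        subject_ids=subject_ids,
        counts=counts,
        fmri=fmri,
        templates=templates,
        taxonomy=taxonomy,
    )
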