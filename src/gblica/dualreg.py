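"""Dual (spatial then temporal) regression of template networks on fMRI.

Stage 1 regresses each fMRI volume, jointly, on all template network maps
(over voxels) to obtain subject-specific network timecourses.  Stage 2
regresses every voxel's time series, jointly, on all (variance-normalized)
timecourses to obtain subject-specific spatial maps, expressed either as
raw regression coefficients or as z-scores via the t-to-z transform with
the residual degrees of freedom.  Intercepts are handled by demeaning over
the regression dimension, which is numerically identical to an explicit
constant column.

Both stages always condition on ALL templates; restriction to networks of
interest happens only when stacking the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import special, stats

from .errors import DimensionError, ParameterError, RankDeficientError

__all__ = [
    "TemplateSet",
    "SubjectNetworkMaps",
    "stage1_spatial_regression",
    "stage2_temporal_regression",
    "run_dual_regression",
    "t_to_z",
]

_Z_CLIP = 40.0  # beyond this the normal tail probability underflows


@dataclass
class TemplateSet:
    """Group template z-maps on one 3D grid, networks along the last axis."""

    maps: np.ndarray                   # (n_voxels, n_networks)
    network_names: list[str]
    shape: tuple[int, int, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise DimensionError("template maps must be voxel x network")
        if self.maps.shape[0] != int(np.prod(self.shape)):
            raise DimensionError(
                f"voxel count {self.maps.shape[0]} does not match grid {self.shape}"
            )
        if len(self.network_names) != self.maps.shape[1]:
            raise DimensionError("network_names length mismatch")
        if len(set(self.network_names)) != len(self.network_names):
            raise ParameterError("network names must be unique")
        zero = [n for n, col in zip(self.network_names, self.maps.T)
                if not np.any(col)]
        if zero:
            raise ParameterError(f"all-zero template column(s): {zero}")

    @property
    def n_networks(self) -> int:
        return self.maps.shape[1]

    @classmethod
    def from_nifti(cls, path, network_names: list[str]) -> "TemplateSet":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise DimensionError(f"{path}: expected a 4D template volume")
        shape = data.shape[:3]
        return cls(
            maps=data.reshape(-1, data.shape[3]),
            network_names=list(network_names),
            shape=shape,
            affine=np.asarray(img.affine),
        )

    def to_nifti(self, path) -> None:
        data = self.maps.reshape(*self.shape, self.n_networks)
        nib.save(nib.Nifti1Image(data.astype(np.float32), self.affine), str(path))


@dataclass
class SubjectNetworkMaps:
    """Stacked subject-specific spatial maps for one network."""

    maps: np.ndarray                   # (n_subjects, n_voxels)
    network_name: str
    shape: tuple[int, int, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_ids: list[str] | None = None
    mask: np.ndarray | None = None     # (n_voxels,) bool; True = analysed

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise DimensionError("subject maps must be subject x voxel")
        if self.maps.shape[1] != int(np.prod(self.shape)):
            raise DimensionError("voxel count does not match grid shape")
        if not np.all(np.isfinite(self.maps)):
            raise ParameterError("subject maps must be finite")
        if self.subject_ids is not None and len(self.subject_ids) != self.maps.shape[0]:
            raise DimensionError("subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.maps.shape[0]

    @classmethod
    def from_nifti(cls, path, network_name: str,
                   subject_ids: list[str] | None = None) -> "SubjectNetworkMaps":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise DimensionError(f"{path}: expected a 4D stack (subjects last)")
        return cls(
            maps=data.reshape(-1, data.shape[3]).T,
            network_name=network_name,
            shape=data.shape[:3],
            affine=np.asarray(img.affine),
            subject_ids=subject_ids,
        )

    def to_nifti(self, path) -> None:
        data = self.maps.T.reshape(*self.shape, self.n_subjects)
        nib.save(nib.Nifti1Image(data.astype(np.float32), self.affine), str(path))


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Convert t statistics to z-scores with matched two-sided tail area.

    Uses log tail probabilities so large statistics stay finite and
    monotone instead of saturating at the double-precision tail.
    """
    t = np.asarray(t, dtype=float)
    logp = stats.t.logsf(np.abs(t), df)
    z = -special.ndtri_exp(logp)
    return np.sign(t) * np.clip(z, 0.0, _Z_CLIP)


def _check_design_rank(D: np.ndarray, names: list[str], context: str) -> None:
    """Raise listing collinear (or degenerate) columns if D is rank deficient."""
    M = D.shape[1]
    if np.linalg.matrix_rank(D) >= M:
        return
    norms = np.linalg.norm(D, axis=0)
    problems = [names[j] for j in np.flatnonzero(norms == 0)]
    nz = np.flatnonzero(norms > 0)
    if nz.size >= 2:
        Dn = D[:, nz] / norms[nz]
        G = np.abs(Dn.T @ Dn)
        for a in range(len(nz)):
            for b in range(a + 1, len(nz)):
                if G[a, b] > 1 - 1e-10:
                    problems.append(f"{names[nz[a]]}~{names[nz[b]]}")
    raise RankDeficientError(
        f"{context}: design matrix is rank deficient "
        f"(degenerate/collinear: {problems or 'unidentified combination'})"
    )


def stage1_spatial_regression(templates: TemplateSet, fmri: np.ndarray) -> np.ndarray:
    """Joint OLS of each fMRI volume on all templates; returns timecourses.

    ``fmri`` is voxel x timepoint; the result is timepoint x network.
    """
    Y = np.asarray(fmri, dtype=float)
    if Y.ndim != 2:
        raise DimensionError("fmri must be voxel x timepoint")
    V, T = Y.shape
    if V != templates.maps.shape[0]:
        raise DimensionError(
            f"voxel mismatch: fmri has {V}, templates have {templates.maps.shape[0]}"
        )
    M = templates.n_networks
    if T <= M:
        raise ParameterError(f"timepoints ({T}) must exceed network count ({M})")
    D = templates.maps - templates.maps.mean(axis=0, keepdims=True)
    _check_design_rank(D, templates.network_names, "stage 1")
    Yc = Y - Y.mean(axis=0, keepdims=True)
    coef, *_ = np.linalg.lstsq(D, Yc, rcond=None)
    return coef.T  # (T, M)


def stage2_temporal_regression(timecourses: np.ndarray, fmri: np.ndarray,
                               output: str = "z",
                               variance_normalize: bool = True) -> np.ndarray:
    """Joint per-voxel OLS of the time series on all network timecourses.

    Returns voxel x network coefficients (``output="beta"``) or z-scores of
    coefficient / SE under the residual degrees of freedom (``output="z"``).
    Timecourses are demeaned and, by default, variance-normalized before
    fitting so betas are comparable across subjects.
    """
    if output not in ("beta", "z"):
        raise ParameterError(f"output must be 'beta' or 'z', got {output!r}")
    D = np.asarray(timecourses, dtype=float)
    Y = np.asarray(fmri, dtype=float)
    if D.ndim != 2 or Y.ndim != 2:
        raise DimensionError("timecourses and fmri must be 2-D")
    T, M = D.shape
    if Y.shape[1] != T:
        raise DimensionError(
            f"timepoint mismatch: fmri has {Y.shape[1]}, timecourses have {T}"
        )
    df = T - M - 1  # demeaning consumes one further degree of freedom
    if df <= 0:
        raise ParameterError(f"residual degrees of freedom must be positive (got {df})")
    D = D - D.mean(axis=0, keepdims=True)
    names = [f"tc{j}" for j in range(M)]
    _check_design_rank(D, names, "stage 2")
    if variance_normalize:
        D = D / D.std(axis=0, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    G = D.T @ D
    Ginv = np.linalg.inv(G)
    B = Yc @ D @ Ginv                      # (V, M)
    if output == "beta":
        return B
    resid = Yc - B @ D.T
    rss = np.einsum("vt,vt->v", resid, resid)
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2[:, None] * np.diag(Ginv)[None, :], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, B / np.where(se > 0, se, 1.0),
                         np.sign(B) * np.inf)
    tstat = np.where((se == 0) & (B == 0), 0.0, tstat)
    return t_to_z(tstat, df)


def run_dual_regression(templates: TemplateSet, fmri_per_subject: list[np.ndarray],
                        select: list[str] | None = None, output: str = "z",
                        subject_ids: list[str] | None = None,
                        ) -> list[SubjectNetworkMaps]:
    """Both regression stages per subject; one stacked map per selected network.

    Voxels with zero temporal variance in ANY subject are excluded from the
    regressions for all subjects and recorded in each output's ``mask``
    (their map values are zero-filled).
    """
    V = templates.maps.shape[0]
    names = templates.network_names
    if select is None:
        select = list(names)
    missing = [n for n in select if n not in names]
    if missing:
        raise ParameterError(f"selected networks not in template set: {missing}")
    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(len(fmri_per_subject))]

    mask = np.ones(V, dtype=bool)
    for i, Y in enumerate(fmri_per_subject):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[0] != V:
            raise DimensionError(
                f"subject {subject_ids[i]}: fmri shape {np.shape(Y)} does not "
                f"match template grid ({V} voxels)"
            )
        mask &= Y.var(axis=1) > 0

    masked_templates = TemplateSet(
        maps=templates.maps[mask], network_names=names,
        shape=(int(mask.sum()), 1, 1), affine=templates.affine,
    )
    all_maps = np.zeros((len(fmri_per_subject), V, templates.n_networks))
    for i, Y in enumerate(fmri_per_subject):
        Ym = np.asarray(Y, dtype=float)[mask]
        tc = stage1_spatial_regression(masked_templates, Ym)
        all_maps[i][mask] = stage2_temporal_regression(tc, Ym, output=output)

    out = []
    for name in select:
        j = names.index(name)
        out.append(SubjectNetworkMaps(
            maps=all_maps[:, :, j],
            network_name=name,
            shape=templates.shape,
            affine=templates.affine,
            subject_ids=list(subject_ids),
            mask=mask.copy(),
        ))
    return out
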