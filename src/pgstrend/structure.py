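"""Population-structure adjustment: genotype PCA on a reference subgroup and
residualization of scores on the top components."""

from __future__ import annotations

import dataclasses

import numpy as np

from .scoring import GenotypePanel, ScoreVector, standardize

__all__ = ["PcProjection", "compute_pcs", "residualize"]


@dataclasses.dataclass
class PcProjection:
    """Top-k genotype principal components.

    Loadings are defined by the reference samples only; coordinates are the
    projections of ALL samples onto those loadings.  ``variant_mask`` marks
    panel variants retained (polymorphic in the reference).
    """

    loadings: np.ndarray
    coords: np.ndarray
    k: int
    reference_mask: np.ndarray
    variant_mask: np.ndarray
    center: np.ndarray
    scale: np.ndarray


def compute_pcs(
    panel: GenotypePanel,
    reference_mask: np.ndarray | None = None,
    k: int = 10,
) -> PcProjection:
    """PCA of reference-sample dosages, PLINK-style standardized.

    Dosages are centered by twice the reference alt-allele frequency and
    scaled by ``sqrt(2 p (1-p))``; variants monomorphic in the reference are
    dropped.  Missing dosages are mean-imputed (zero after centering).  The
    sign of each component is fixed so its largest-magnitude loading is
    positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if reference_mask is None:
        reference_mask = np.ones(panel.n_samples, dtype=bool)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != (panel.n_samples,):
        raise ValueError("reference_mask length does not match panel")
    n_ref = int(reference_mask.sum())
    if n_ref == 0:
        raise ValueError("empty reference set")
    if n_ref < k + 1:
        raise ValueError(f"reference must contain at least k+1={k + 1} samples")

    ref_dos = panel.dosages[reference_mask]
    observed = ~np.isnan(ref_dos)
    counts = observed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.where(
            counts > 0,
            np.where(observed, ref_dos, 0.0).sum(axis=0) / (2.0 * counts),
            np.nan,
        )
    variant_mask = (counts > 0) & (p_hat > 0.0) & (p_hat < 1.0)
    m_kept = int(variant_mask.sum())
    if k > min(m_kept, n_ref - 1):
        raise ValueError("k exceeds the rank supported by reference/variants")

    center = 2.0 * p_hat[variant_mask]
    scale = np.sqrt(center * (1.0 - p_hat[variant_mask]))
    z_all = (panel.dosages[:, variant_mask] - center) / scale
    z_all = np.where(np.isnan(z_all), 0.0, z_all)
    z_ref = z_all[reference_mask]

    _, _, vt = np.linalg.svd(z_ref, full_matrices=False)
    loadings = vt[:k].T.copy()
    for j in range(k):
        i_star = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_star, j] < 0:
            loadings[:, j] = -loadings[:, j]
    coords = z_all @ loadings
    return PcProjection(
        loadings=loadings,
        coords=coords,
        k=k,
        reference_mask=reference_mask,
        variant_mask=variant_mask,
        center=center,
        scale=scale,
    )


def residualize(scores: ScoreVector, proj: PcProjection | None) -> ScoreVector:
    """Residualize standardized scores on the PC coordinates, then
    re-standardize.  ``proj=None`` (k = 0) is the identity on standardized
    scores.  Residuals are exactly orthogonal to every retained component."""
    if proj is None:
        return ScoreVector(
            sample_ids=list(scores.sample_ids),
            raw=scores.std.copy(),
            std=scores.std.copy(),
            n_variants_used=scores.n_variants_used,
        )
    n = len(scores.std)
    if proj.coords.shape[0] != n:
        raise ValueError("projection and scores have different sample counts")
    X = np.column_stack([np.ones(n), proj.coords])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear principal components in residualization")
    coef, *_ = np.linalg.lstsq(X, scores.std, rcond=None)
    resid = scores.std - X @ coef
    if resid.std(ddof=1) < 1e-10:
        raise ValueError("residual variance is zero after PC adjustment")
    return ScoreVector(
        sample_ids=list(scores.sample_ids),
        raw=resid,
        std=standardize(resid),
        n_variants_used=scores.n_variants_used,
    )
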