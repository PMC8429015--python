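"""Mapping target subjects into the learned subspace and fusing views.

Target subjects are projected through the learned U and V (Fea = Z'P),
each projected feature is self-weighted by its own magnitude
(|x| * |x|, i.e. an elementwise square), and the two views are fused
by a convex combination with weight eta on the thickness view. The
result is a nonnegative m x c biomarker matrix.
"""

from __future__ import annotations

import numpy as np

from .projection import ProjectionPair, ShapeError, SubspaceModel


def project_view(Z: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Subspace representation Z'P of target subjects (m x c).

    ``Z`` is the d x m target feature block, already standardized with
    the training transform when standardization is enabled.
    """
    Z = np.asarray(Z, dtype=float)
    P = np.asarray(P, dtype=float)
    if Z.shape[0] != P.shape[0]:
        raise ShapeError(f"Z has {Z.shape[0]} features but P has {P.shape[0]} rows")
    return Z.T @ P


def fuse_biomarkers(Fea_CT: np.ndarray, Fea_CV: np.ndarray, eta: float) -> np.ndarray:
    """Self-weighted fusion eta*|Fea_CT|^2 + (1-eta)*|Fea_CV|^2, elementwise.

    Every output entry is >= 0 and invariant to sign flips of the
    projected features.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must be in [0, 1], got {eta}")
    Fea_CT = np.asarray(Fea_CT, dtype=float)
    Fea_CV = np.asarray(Fea_CV, dtype=float)
    if Fea_CT.shape != Fea_CV.shape:
        raise ShapeError(f"view shapes differ: {Fea_CT.shape} vs {Fea_CV.shape}")
    return eta * (np.abs(Fea_CT) * np.abs(Fea_CT)) + (1.0 - eta) * (np.abs(Fea_CV) * np.abs(Fea_CV))


def extract_biomarkers(Z_ct: np.ndarray, Z_cv: np.ndarray, pair: ProjectionPair, eta: float) -> np.ndarray:
    """Project both views and fuse: the full target-side pipeline."""
    return fuse_biomarkers(project_view(Z_ct, pair.U), project_view(Z_cv, pair.V), eta)


def biomarkers_from_model(model: SubspaceModel, Z_ct: np.ndarray, Z_cv: np.ndarray) -> np.ndarray:
    """Apply a fitted model: standardize with training statistics, then extract."""
    Zct = model.scaler_ct.transform(Z_ct)
    Zcv = model.scaler_cv.transform(Z_cv)
    return extract_biomarkers(Zct, Zcv, model.pair, model.hp.eta)
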