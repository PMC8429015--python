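"""Joint label-subspace projection learning over two views.

Given aligned thickness and volume blocks X_CT, X_CV (d x n), a 0-1
class-indicator matrix Y (n x c) and per-view graph Laplacians, the
method learns projections U, V (d x c) minimizing

    Q(U, V) = lambda (||Y - X_CT'U||_F^2 + ||Y - X_CV'V||_F^2)
            + (1 - lambda) ||X_CT'U - X_CV'V||_F^2
            + alpha (tr(U'X_CT L_CT X_CT'U) + tr(V'X_CV L_CV X_CV'V))
            + beta (||U||_F^2 + ||V||_F^2)

by alternating exact closed-form ridge updates: each block subproblem
is a symmetric positive-definite linear system, so the objective is
nonincreasing and each update zeroes the corresponding block gradient.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

from .graphs import GraphLaplacian, build_affinity, build_laplacian


class ShapeError(ValueError):
    pass


class LabelingError(ValueError):
    pass


@dataclasses.dataclass
class ViewPair:
    """Two aligned d x n feature blocks sharing subject (column) order."""

    X_CT: np.ndarray
    X_CV: np.ndarray

    def __post_init__(self) -> None:
        self.X_CT = np.asarray(self.X_CT, dtype=float)
        self.X_CV = np.asarray(self.X_CV, dtype=float)
        if self.X_CT.shape != self.X_CV.shape:
            raise ShapeError(
                f"views must share shape, got {self.X_CT.shape} vs {self.X_CV.shape}"
            )
        if not (np.isfinite(self.X_CT).all() and np.isfinite(self.X_CV).all()):
            raise ShapeError("views contain non-finite entries")

    @property
    def d(self) -> int:
        return self.X_CT.shape[0]

    @property
    def n(self) -> int:
        return self.X_CT.shape[1]


@dataclasses.dataclass
class LabelIndicator:
    """n x c one-hot class matrix; each row selects exactly one class."""

    Y: np.ndarray
    class_order: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def c(self) -> int:
        return self.Y.shape[1]


def encode_labels(codes: Sequence[str], class_order: Sequence[str]) -> LabelIndicator:
    """One-hot encode class codes into an n x c indicator matrix.

    A class in ``class_order`` with no subjects is accepted with a
    warning (the optimization stays well-posed); an unknown code is an
    error.
    """
    codes = list(codes)
    class_order = tuple(class_order)
    if len(codes) == 0:
        raise LabelingError("empty label sequence")
    if len(class_order) < 2:
        raise LabelingError("need at least two classes in class_order")
    index = {cls: j for j, cls in enumerate(class_order)}
    Y = np.zeros((len(codes), len(class_order)))
    for i, code in enumerate(codes):
        if code not in index:
            raise LabelingError(f"unknown class code {code!r}; expected one of {class_order}")
        Y[i, index[code]] = 1.0
    empty = [cls for j, cls in enumerate(class_order) if Y[:, j].sum() == 0]
    if empty:
        warnings.warn(f"classes with zero subjects: {empty}", stacklevel=2)
    return LabelIndicator(Y=Y, class_order=class_order)


@dataclasses.dataclass(frozen=True)
class HyperParams:
    """Balancing and graph parameters of the joint objective.

    Defaults are the combination selected in our reference evaluation:
    lam=0.1, alpha=0.1, beta=10, k_ct=11, k_cv=3, eta=0.03.

    lam
        Weight in (0, 1] trading the label-regression terms against the
        cross-view consistency term (lam=1 switches the cross term off).
    alpha
        Weight >= 0 of the graph-regularization terms.
    beta
        Ridge weight > 0; guarantees the block systems are positive
        definite.
    k_ct, k_cv
        Neighbour counts of the per-view affinity graphs.
    eta
        Fusion weight in [0, 1] of the thickness view in the final
        biomarker.
    sigma_ct, sigma_cv
        Heat-kernel bandwidth per view: "median" or a positive float.
    """

    lam: float = 0.1
    alpha: float = 0.1
    beta: float = 10.0
    k_ct: int = 11
    k_cv: int = 3
    eta: float = 0.03
    sigma_ct: float | str = "median"
    sigma_cv: float | str = "median"

    def __post_init__(self) -> None:
        if not 0.0 < self.lam <= 1.0:
            raise ValueError(f"lam must be in (0, 1], got {self.lam}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must be in [0, 1], got {self.eta}")


@dataclasses.dataclass
class ProjectionPair:
    """The learned projections: U for the thickness view, V for volume."""

    U: np.ndarray
    V: np.ndarray


@dataclasses.dataclass
class FitTrace:
    objective_values: list[float]
    n_iter: int
    converged: bool


def objective(
    U: np.ndarray,
    V: np.ndarray,
    views: ViewPair,
    Y: LabelIndicator | np.ndarray,
    L_ct: GraphLaplacian,
    L_cv: GraphLaplacian,
    hp: HyperParams,
) -> float:
    """Evaluate the joint objective Q(U, V); always >= 0."""
    Ym = Y.Y if isinstance(Y, LabelIndicator) else np.asarray(Y, dtype=float)
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if U.shape != (views.d, Ym.shape[1]) or V.shape != U.shape:
        raise ShapeError(
            f"U, V must be {(views.d, Ym.shape[1])}, got {U.shape} and {V.shape}"
        )
    if Ym.shape[0] != views.n:
        raise ShapeError(f"Y has {Ym.shape[0]} rows but views have n={views.n}")
    A_ct = views.X_CT.T @ U
    A_cv = views.X_CV.T @ V
    label = np.sum((Ym - A_ct) ** 2) + np.sum((Ym - A_cv) ** 2)
    cross = np.sum((A_ct - A_cv) ** 2)
    graph = float(np.sum((U.T @ views.X_CT @ L_ct.L) * (U.T @ views.X_CT))) + float(
        np.sum((V.T @ views.X_CV @ L_cv.L) * (V.T @ views.X_CV))
    )
    ridge = np.sum(U**2) + np.sum(V**2)
    return float(hp.lam * label + (1.0 - hp.lam) * cross + hp.alpha * graph + hp.beta * ridge)


def _solve_block(X: np.ndarray, L: np.ndarray, other_term: np.ndarray, hp: HyperParams) -> np.ndarray:
    """Solve (X X' + alpha X L X' + beta I) P = rhs for one block.

    ``other_term`` is lam * X Y + (1 - lam) * X X_other' P_other. The
    system matrix is symmetric positive definite (beta > 0), so it is
    solved by Cholesky factorization, never by explicit inversion.
    """
    d = X.shape[0]
    A = X @ X.T + hp.alpha * (X @ L @ X.T) + hp.beta * np.eye(d)
    return scipy.linalg.solve(A, other_term, assume_a="pos")


def update_U(
    V: np.ndarray,
    views: ViewPair,
    Y: LabelIndicator | np.ndarray,
    L_ct: GraphLaplacian,
    hp: HyperParams,
) -> np.ndarray:
    """Exact minimizer of Q over U with V fixed (block gradient zero)."""
    Ym = Y.Y if isinstance(Y, LabelIndicator) else np.asarray(Y, dtype=float)
    V = np.asarray(V, dtype=float)
    if not np.isfinite(V).all():
        raise ShapeError("V contains non-finite entries")
    rhs = hp.lam * (views.X_CT @ Ym) + (1.0 - hp.lam) * (views.X_CT @ views.X_CV.T @ V)
    return _solve_block(views.X_CT, L_ct.L, rhs, hp)


def update_V(
    U: np.ndarray,
    views: ViewPair,
    Y: LabelIndicator | np.ndarray,
    L_cv: GraphLaplacian,
    hp: HyperParams,
) -> np.ndarray:
    """Exact minimizer of Q over V with U fixed; mirror of update_U."""
    Ym = Y.Y if isinstance(Y, LabelIndicator) else np.asarray(Y, dtype=float)
    U = np.asarray(U, dtype=float)
    if not np.isfinite(U).all():
        raise ShapeError("U contains non-finite entries")
    rhs = hp.lam * (views.X_CV @ Ym) + (1.0 - hp.lam) * (views.X_CV @ views.X_CT.T @ U)
    return _solve_block(views.X_CV, L_cv.L, rhs, hp)


class ConvergenceError(RuntimeError):
    """Objective increased beyond tolerance (should be unreachable)."""


def fit_projections(
    views: ViewPair,
    Y: LabelIndicator | np.ndarray,
    L_ct: GraphLaplacian,
    L_cv: GraphLaplacian,
    hp: HyperParams,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[ProjectionPair, FitTrace]:
    """Alternating minimization from zero initialization.

    Each iteration updates U then V by their closed-form minimizers and
    records Q. Stops when |Q_t - Q_{t-1}| / max(1, Q_{t-1}) < tol or
    after ``max_iter`` iterations. Exact block minimization makes the
    trace nonincreasing; an increase beyond numerical tolerance raises
    ConvergenceError.
    """
    if not tol > 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")
    Ym = Y.Y if isinstance(Y, LabelIndicator) else np.asarray(Y, dtype=float)
    c = Ym.shape[1]
    U = np.zeros((views.d, c))
    V = np.zeros((views.d, c))
    trace: list[float] = []
    q_prev = objective(U, V, views, Y, L_ct, L_cv, hp)
    converged = False
    for _ in range(max_iter):
        U = update_U(V, views, Y, L_ct, hp)
        V = update_V(U, views, Y, L_cv, hp)
        q = objective(U, V, views, Y, L_ct, L_cv, hp)
        trace.append(q)
        if q > q_prev + 1e-9 * max(1.0, q_prev):
            raise ConvergenceError(
                f"objective increased from {q_prev!r} to {q!r}"
            )
        if abs(q - q_prev) / max(1.0, q_prev) < tol:
            converged = True
            break
        q_prev = q
    return ProjectionPair(U=U, V=V), FitTrace(
        objective_values=trace, n_iter=len(trace), converged=converged
    )


@dataclasses.dataclass
class Standardizer:
    """Per-feature affine rescaling fit on the learning set, reused on targets.

    Thickness (mm) and volume (mm^3) live on very different scales, so
    features are rescaled with auxiliary-set statistics before graph
    construction and projection learning; the same transform is applied
    to target subjects. The default mode divides by the per-feature
    standard deviation without centering: the label regression X'U has
    no intercept, so the overall (positive) feature baseline is what
    lets the projections reach the 0-1 indicator targets, and removing
    it by centering forces the subspace coordinates to be sign-
    symmetric across classes, which the magnitude-based fusion cannot
    distinguish. Full z-scoring remains available. Constant features
    get unit scale.
    """

    mean_: np.ndarray
    scale_: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, center: bool = False) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=1) if center else np.zeros(X.shape[0])
        scale = X.std(axis=1)
        scale = np.where(scale < 1e-12, 1.0, scale)
        return cls(mean_=mean, scale_=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_[:, None]) / self.scale_[:, None]

    @classmethod
    def identity(cls, d: int) -> "Standardizer":
        return cls(mean_=np.zeros(d), scale_=np.ones(d))


@dataclasses.dataclass
class SubspaceModel:
    """A fitted projection model plus everything needed to apply it."""

    pair: ProjectionPair
    class_order: tuple[str, ...]
    scaler_ct: Standardizer
    scaler_cv: Standardizer
    hp: HyperParams
    sigma_ct: float
    sigma_cv: float
    trace: FitTrace | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "U": self.pair.U.tolist(),
            "V": self.pair.V.tolist(),
            "class_order": list(self.class_order),
            "scaler_ct": {"mean": self.scaler_ct.mean_.tolist(), "scale": self.scaler_ct.scale_.tolist()},
            "scaler_cv": {"mean": self.scaler_cv.mean_.tolist(), "scale": self.scaler_cv.scale_.tolist()},
            "hyperparams": {
                "lam": self.hp.lam,
                "alpha": self.hp.alpha,
                "beta": self.hp.beta,
                "k_ct": self.hp.k_ct,
                "k_cv": self.hp.k_cv,
                "eta": self.hp.eta,
                "sigma_ct": self.hp.sigma_ct,
                "sigma_cv": self.hp.sigma_cv,
            },
            "sigma_ct": self.sigma_ct,
            "sigma_cv": self.sigma_cv,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SubspaceModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        hp = HyperParams(**doc["hyperparams"])
        return cls(
            pair=ProjectionPair(U=np.array(doc["U"]), V=np.array(doc["V"])),
            class_order=tuple(doc["class_order"]),
            scaler_ct=Standardizer(
                mean_=np.array(doc["scaler_ct"]["mean"]), scale_=np.array(doc["scaler_ct"]["scale"])
            ),
            scaler_cv=Standardizer(
                mean_=np.array(doc["scaler_cv"]["mean"]), scale_=np.array(doc["scaler_cv"]["scale"])
            ),
            hp=hp,
            sigma_ct=doc["sigma_ct"],
            sigma_cv=doc["sigma_cv"],
        )


def fit_model(
    X_CT: np.ndarray,
    X_CV: np.ndarray,
    labels: Sequence[str],
    class_order: Sequence[str],
    hp: HyperParams,
    standardize: bool | str = "scale",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> SubspaceModel:
    """End-to-end projection learning on one labeled two-view set.

    Rescales features (``standardize``: "scale" divides by the
    per-feature standard deviation, "zscore" additionally centers,
    "off" leaves features raw; True is a synonym for "scale", False
    for "off"), builds the per-view kNN heat-kernel graphs and
    Laplacians, encodes labels and runs the alternating solver.
    Returns a model that can rescale and project new subjects.
    """
    X_CT = np.asarray(X_CT, dtype=float)
    X_CV = np.asarray(X_CV, dtype=float)
    d = X_CT.shape[0]
    if standardize is True:
        standardize = "scale"
    if standardize is False:
        standardize = "off"
    if standardize == "off":
        scaler_ct = Standardizer.identity(d)
        scaler_cv = Standardizer.identity(d)
    elif standardize in ("scale", "zscore"):
        center = standardize == "zscore"
        scaler_ct = Standardizer.fit(X_CT, center=center)
        scaler_cv = Standardizer.fit(X_CV, center=center)
    else:
        raise ValueError(f"standardize must be 'scale', 'zscore' or 'off', got {standardize!r}")
    Xct = scaler_ct.transform(X_CT)
    Xcv = scaler_cv.transform(X_CV)
    views = ViewPair(X_CT=Xct, X_CV=Xcv)

    n = views.n
    k_ct = min(hp.k_ct, n - 1)
    k_cv = min(hp.k_cv, n - 1)
    g_ct = build_affinity(Xct, k=k_ct, sigma=hp.sigma_ct, view_tag="CT")
    g_cv = build_affinity(Xcv, k=k_cv, sigma=hp.sigma_cv, view_tag="CV")
    L_ct = build_laplacian(g_ct)
    L_cv = build_laplacian(g_cv)

    Y = encode_labels(labels, class_order)
    pair, trace = fit_projections(views, Y, L_ct, L_cv, hp, tol=tol, max_iter=max_iter)
    return SubspaceModel(
        pair=pair,
        class_order=tuple(class_order),
        scaler_ct=scaler_ct,
        scaler_cv=scaler_cv,
        hp=hp,
        sigma_ct=g_ct.sigma,
        sigma_cv=g_cv.sigma,
        trace=trace,
    )
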